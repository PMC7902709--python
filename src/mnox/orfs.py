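"""Stop-to-stop ORF database construction from contig-level assemblies.

Draft fungal genome assemblies often lack gene models, so peptide
identifications cannot be mapped onto predicted proteins.  The gene-agnostic
alternative used here is the *stop-to-stop* search space: every maximal
translated segment between two in-frame stop codons (or a contig edge) of at
least ``min_len`` amino acids, in three forward frames or all six frames.
Peptides are then matched against these segments by substring search.

Coordinates are 0-based half-open on the forward strand regardless of ORF
strand, so ``contig.sequence[start:end]`` is always the encoding segment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID_NT = frozenset("ACGTN")

#: strand symbols, in deterministic sort order
STRANDS = ("+", "-")


@dataclass(frozen=True)
class Contig:
    """A nucleotide contig (A/C/G/T/N, case-insensitive)."""

    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.contig_id:
            raise ValueError("contig_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"contig {self.contig_id!r}: empty sequence")
        seq = self.sequence.upper()
        bad = next((i for i, c in enumerate(seq) if c not in _VALID_NT), None)
        if bad is not None:
            raise ValueError(
                f"contig {self.contig_id!r}: invalid nucleotide "
                f"{self.sequence[bad]!r} at position {bad}"
            )
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class OrfRecord:
    """One maximal stop-to-stop translated segment.

    ``frame`` is the offset (0-2) of the first codon in the reading
    direction: relative to the forward sequence for ``strand == '+'`` and to
    the reverse complement for ``strand == '-'``.  ``edge5``/``edge3`` mark
    segments bounded by the contig edge rather than a stop codon at their
    5'/3' end (in reading direction).
    """

    contig_id: str
    strand: str
    frame: int
    start: int
    end: int
    protein: str
    edge5: bool = False
    edge3: bool = False

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")
        if not 0 <= self.frame <= 2:
            raise ValueError(f"frame must be 0-2, got {self.frame}")
        if "*" in self.protein:
            raise ValueError("protein must not contain a stop symbol")
        if self.end - self.start != 3 * len(self.protein):
            raise ValueError(
                f"span {self.end - self.start} nt inconsistent with "
                f"{len(self.protein)} aa"
            )

    @property
    def orf_id(self) -> str:
        return f"{self.contig_id}:{self.strand}{self.frame}:{self.start}-{self.end}"


@dataclass(frozen=True)
class OrfDbConfig:
    """Parameters of the stop-to-stop extraction.

    min_len
        Minimum segment length in amino acids (default 30).
    frames
        3 = forward-strand frames only; 6 = both strands (default).  Contig
        orientation is arbitrary in a draft assembly, so 6 frames is the
        safer default; 3 frames reproduces a forward-strand-only search.
    genetic_code
        NCBI translation table id (default 1, standard code).
    """

    min_len: int = 30
    frames: int = 6
    genetic_code: int = 1

    def __post_init__(self) -> None:
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if self.frames not in (3, 6):
            raise ValueError("frames must be 3 or 6")


def _codon_translator(table_id: int):
    table = CodonTable.unambiguous_dna_by_id[table_id]
    forward = table.forward_table
    stops = frozenset(table.stop_codons)

    def translate(codon: str) -> str:
        # N-containing (or otherwise ambiguous) codons become X, never a
        # stop: X matches no peptide residue, so no false provenance.
        if codon in stops:
            return "*"
        return forward.get(codon, "X")

    return translate


def _frame_segments(
    seq: str, frame: int, min_len: int, translate
) -> Iterator[tuple[int, int, str, bool, bool]]:
    """Yield (codon_start, codon_end, protein, edge5, edge3) for one frame.

    Offsets are codon-aligned positions within *seq* (reading direction).
    """
    n_codons = (len(seq) - frame) // 3
    run_start = frame  # nt offset of current between-stop run
    run: list[str] = []
    preceded_by_stop = False
    for i in range(n_codons):
        off = frame + 3 * i
        aa = translate(seq[off : off + 3])
        if aa == "*":
            if len(run) >= min_len:
                yield run_start, off, "".join(run), not preceded_by_stop, False
            run = []
            run_start = off + 3
            preceded_by_stop = True
        else:
            run.append(aa)
    if len(run) >= min_len:
        end = run_start + 3 * len(run)
        yield run_start, end, "".join(run), not preceded_by_stop, True


def extract_orfs(
    contigs: Iterable[Contig], config: OrfDbConfig | None = None
) -> list[OrfRecord]:
    """Extract all maximal stop-to-stop translated segments.

    Returns records in deterministic order (contig, strand, frame, start).
    Segments bounded by a contig edge instead of a stop codon are included
    and flagged — discarding them would silently drop genes truncated by
    assembly fragmentation.
    """
    config = config or OrfDbConfig()
    translate = _codon_translator(config.genetic_code)
    out: list[OrfRecord] = []
    for contig in contigs:
        seq = contig.sequence
        length = len(seq)
        for frame in range(3):
            for cstart, cend, prot, e5, e3 in _frame_segments(
                seq, frame, config.min_len, translate
            ):
                out.append(
                    OrfRecord(contig.contig_id, "+", frame, cstart, cend, prot, e5, e3)
                )
        if config.frames == 6:
            rc = str(Seq(seq).reverse_complement())
            for frame in range(3):
                for cstart, cend, prot, e5, e3 in _frame_segments(
                    rc, frame, config.min_len, translate
                ):
                    # map reverse-complement offsets back to forward strand
                    out.append(
                        OrfRecord(
                            contig.contig_id,
                            "-",
                            frame,
                            length - cend,
                            length - cstart,
                            prot,
                            e5,
                            e3,
                        )
                    )
    out.sort(key=lambda r: (r.contig_id, r.strand, r.frame, r.start))
    return out


# ---------------------------------------------------------------------------
# FASTA / TSV round-trip

_HEADER_RE = re.compile(
    r"^(?P<orf_id>[^|]+)\|(?P<contig>[^|]+)\|(?P<strand>[+-])\|(?P<frame>[0-2])"
    r"\|(?P<start>\d+)-(?P<end>\d+)\|(?P<e5>[01]),(?P<e3>[01])$"
)


def write_orf_fasta(orfs: Sequence[OrfRecord], path) -> None:
    """Write a protein FASTA whose headers round-trip to :class:`OrfRecord`.

    Header layout: ``orfid|contig|strand|frame|start-end|edge5,edge3``.
    """
    seen: set[str] = set()
    records = []
    for orf in orfs:
        if orf.orf_id in seen:
            raise ValueError(f"duplicate orf_id {orf.orf_id!r}")
        seen.add(orf.orf_id)
        header = (
            f"{orf.orf_id}|{orf.contig_id}|{orf.strand}|{orf.frame}"
            f"|{orf.start}-{orf.end}|{int(orf.edge5)},{int(orf.edge3)}"
        )
        records.append(SeqRecord(Seq(orf.protein), id=header, description=""))
    SeqIO.write(records, path, "fasta")


def read_orf_fasta(path) -> list[OrfRecord]:
    """Read a protein FASTA written by :func:`write_orf_fasta`."""
    out = []
    for rec in SeqIO.parse(path, "fasta"):
        m = _HEADER_RE.match(rec.id)
        if m is None:
            raise ValueError(f"unparseable ORF header {rec.id!r}")
        out.append(
            OrfRecord(
                contig_id=m["contig"],
                strand=m["strand"],
                frame=int(m["frame"]),
                start=int(m["start"]),
                end=int(m["end"]),
                protein=str(rec.seq),
                edge5=m["e5"] == "1",
                edge3=m["e3"] == "1",
            )
        )
    return out


def read_contig_fasta(path) -> list[Contig]:
    """Read nucleotide contigs from FASTA."""
    return [Contig(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]


def write_contig_fasta(contigs: Sequence[Contig], path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(c.sequence), id=c.contig_id, description="") for c in contigs],
        path,
        "fasta",
    )
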