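"""Synthetic genomes, gel-band peptide reports and assay plates.

Every downstream stage of the pipeline is testable offline against data
with known ground truth:

* :func:`generate_genome` plants protein-coding stop-to-stop segments in
  random contigs so ORF extraction and peptide mapping can be checked
  against a truth table;
* :func:`simulate_band_reports` emits per-band peptide observations with
  biological-replicate structure, contaminant peptides and control-band
  leakage, so subtraction/aggregation/filtering can be checked end to end;
* :func:`simulate_plate` produces linear-response absorbance tables with
  KMnO4-style standards and Gaussian noise for the calibration code.

All generators are pure functions of (parameters, seed): the same call
with the same seed yields byte-identical outputs.  The unit of simulation
is the identified peptide — no spectra, m/z or retention times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from mnox.orfs import Contig
from mnox.peptides import PeptideObservation, canonicalize

_AA20 = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Synthetic decoy peptides standing in for the trypsin autolysis and human
#: keratin contaminants that real gel-band searches are amended with.  The
#: sequences are invented (tryptic-looking: end in K/R, 7-20 residues), not
#: copied from any real contaminant database.
TRYPSIN_KERATIN_LIKE_DECOYS: tuple[str, ...] = (
    "LSSPATLNSR",
    "VATVSLPR",
    "LGEHNLDVLEGNEQFLNAAK",
    "SGLQVAEVK",
    "FESNFNTQATNR",
    "AGFAGDDAPR",
    "SYELPDGQVLTLGAER",
    "QEYDESGPSLVHR",
    "TLLSNLEEAK",
    "DVDAAYLNK",
    "NQLLQPLNVELDPK",
    "GVLDGLSER",
    "AEAESLYQSK",
    "WELLQQVDTSTR",
    "TNAENEFVTLK",
)


@dataclass(frozen=True)
class PlantedProtein:
    """Ground-truth protein to embed in a synthetic contig.

    ``abundance_profile`` maps time point (days) to the expected total
    peptide-observation count summed over replicates for that time point.
    """

    protein_id: str
    sequence: str
    contig_id: str
    strand: str = "+"
    frame: int = 0
    secreted: bool = True
    abundance_profile: Mapping[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not 0 <= self.frame <= 2:
            raise ValueError(f"frame must be 0-2, got {self.frame}")
        bad = set(self.sequence.upper()) - _AA20
        if bad:
            raise ValueError(
                f"planted protein {self.protein_id!r}: illegal residues {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass(frozen=True)
class Placement:
    """Forward-strand coordinates of a planted protein's coding segment."""

    contig_id: str
    strand: str
    frame: int
    start: int  # first coding nt (0-based, excludes the bounding stop)
    end: int  # half-open end of coding nts

    @property
    def orf_id(self) -> str:
        return f"{self.contig_id}:{self.strand}{self.frame}:{self.start}-{self.end}"


@dataclass(frozen=True)
class SimulationTruth:
    """Everything needed to verify pipeline output against ground truth."""

    species: str
    planted: tuple[PlantedProtein, ...]
    placements: Mapping[str, Placement]  # protein_id -> placement
    contaminant_peptides: tuple[str, ...]
    control_leak_rate: float
    seed: int


@dataclass(frozen=True)
class BandReportTruth:
    """Realized per-(protein, time point) outcomes of one report simulation.

    ``expected_totals`` holds the post-control-subtraction peptide totals
    the pipeline should reproduce exactly; ``leaked_peptides`` are the
    canonical peptides present in the control report.
    """

    expected_totals: Mapping[tuple[str, int], int]
    expected_replicates: Mapping[tuple[str, int], int]
    leaked_peptides: frozenset[str]


def _synonymous_codons(table_id: int = 1) -> dict[str, list[str]]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    by_aa: dict[str, list[str]] = {}
    for codon, aa in sorted(table.forward_table.items()):
        by_aa.setdefault(aa, []).append(codon)
    return by_aa


def _encode(
    protein: str, rng: np.random.Generator, codons_by_aa: dict[str, list[str]]
) -> str:
    parts = []
    for aa in protein:
        options = codons_by_aa[aa]
        parts.append(options[rng.integers(len(options))])
    return "".join(parts)


def generate_genome(
    n_contigs: int,
    contig_length: int | tuple[int, int],
    planted: Sequence[PlantedProtein],
    seed: int,
    species: str = "synthetic sp.",
    contaminant_peptides: Sequence[str] = TRYPSIN_KERATIN_LIKE_DECOYS,
    control_leak_rate: float = 1.0,
    min_len: int = 30,
) -> tuple[list[Contig], SimulationTruth]:
    """Generate contigs with planted stop-to-stop coding segments.

    Background nucleotides are i.i.d. uniform A/C/G/T, which guarantees
    frequent random stop codons (3/64 per frame position).  Each planted
    protein is encoded with randomly chosen synonymous codons, flanked by
    stop codons, and written into its contig at a frame-consistent offset,
    so stop-to-stop extraction at ``min_len`` recovers exactly its
    translation at the recorded coordinates.

    Contig ids are ``contig_1`` .. ``contig_{n}``.  Planted proteins that
    do not fit their contig are rejected with an explicit message.
    """
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    rng = np.random.default_rng(seed)
    if isinstance(contig_length, int):
        lengths = [contig_length] * n_contigs
    else:
        lo, hi = contig_length
        lengths = [int(rng.integers(lo, hi + 1)) for _ in range(n_contigs)]

    for p in planted:
        if len(p.sequence) < min_len:
            raise ValueError(
                f"planted protein {p.protein_id!r} is {len(p.sequence)} aa, "
                f"shorter than min_len {min_len}"
            )

    ids = [f"contig_{i + 1}" for i in range(n_contigs)]
    by_contig: dict[str, list[PlantedProtein]] = {cid: [] for cid in ids}
    for p in planted:
        if p.contig_id not in by_contig:
            raise ValueError(
                f"planted protein {p.protein_id!r} references unknown contig "
                f"{p.contig_id!r} (have {ids[0]}..{ids[-1]})"
            )
        by_contig[p.contig_id].append(p)

    codons_by_aa = _synonymous_codons()
    nt = np.array(list("ACGT"))
    stop_codons = ("TAA", "TAG", "TGA")
    contigs: list[Contig] = []
    placements: dict[str, Placement] = {}
    for cid, length in zip(ids, lengths):
        seq = list("".join(nt[rng.integers(4, size=length)]))
        cursor = 0
        for p in by_contig[cid]:
            seg = (
                stop_codons[rng.integers(3)]
                + _encode(p.sequence, rng, codons_by_aa)
                + stop_codons[rng.integers(3)]
            )
            if p.strand == "-":
                comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
                seg = "".join(comp[c] for c in reversed(seg))
            seg_len = len(seg)
            gap = int(rng.integers(3, 30))
            pos = cursor + gap
            # advance to the frame-consistent offset
            if p.strand == "+":
                want = p.frame  # first coding nt at pos+3 => pos % 3 == frame
            else:
                want = (length - p.frame - seg_len) % 3
            pos += (want - pos) % 3
            if pos + seg_len > length:
                raise ValueError(
                    f"planted protein {p.protein_id!r} ({seg_len} nt with stops) "
                    f"does not fit in contig {cid!r} of length {length}"
                )
            seq[pos : pos + seg_len] = seg
            placements[p.protein_id] = Placement(
                contig_id=cid,
                strand=p.strand,
                frame=p.frame,
                start=pos + 3,
                end=pos + seg_len - 3,
            )
            cursor = pos + seg_len
        contigs.append(Contig(cid, "".join(seq)))

    truth = SimulationTruth(
        species=species,
        planted=tuple(planted),
        placements=placements,
        contaminant_peptides=tuple(contaminant_peptides),
        control_leak_rate=float(control_leak_rate),
        seed=int(seed),
    )
    return contigs, truth


def tryptic_peptides(
    protein: str,
    missed_cleavages: int = 2,
    min_len: int = 7,
    max_len: int = 40,
) -> list[str]:
    """Fully tryptic peptides (cleave after K/R, not before P).

    Returns unique peptides of ``min_len``..``max_len`` residues with up to
    ``missed_cleavages`` internal missed cleavage sites, in order of first
    occurrence.
    """
    cuts = [0]
    for i, aa in enumerate(protein[:-1]):
        if aa in "KR" and protein[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(protein))
    peptides: list[str] = []
    seen = set()
    for i in range(len(cuts) - 1):
        for j in range(i + 1, min(i + 2 + missed_cleavages, len(cuts))):
            pep = protein[cuts[i] : cuts[j]]
            if min_len <= len(pep) <= max_len and pep not in seen:
                seen.add(pep)
                peptides.append(pep)
    return peptides


def simulate_band_reports(
    truth: SimulationTruth,
    n_replicates: int = 4,
    seed: int = 0,
    time_points: Sequence[int] = (7, 14, 21),
    missed_cleavages: int = 2,
    min_pep_len: int = 7,
    max_pep_len: int = 40,
    contaminant_count: int = 1,
    leak_scope: str = "contaminants",
) -> tuple[list[PeptideObservation], list[PeptideObservation], BandReportTruth]:
    """Simulate per-band peptide reports plus the negative-control report.

    For each secreted planted protein and time point, the expected total
    from ``abundance_profile`` is distributed multinomially over
    (replicate, tryptic peptide) cells.  Contaminant peptides appear in
    every sample-band replicate with count ``contaminant_count``.  Each
    leak-eligible distinct peptide then leaks into the control report
    independently with probability ``truth.control_leak_rate``; eligibility
    is set by ``leak_scope`` — "contaminants" (default: only contaminant
    peptides can appear in controls) or "all" (any sample peptide can; at
    rate 1 control subtraction then empties the sample report).

    Returns ``(sample_report, control_report, realized_truth)`` where the
    realized truth carries the post-subtraction totals the pipeline should
    reproduce.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    reps = [f"rep{i + 1}" for i in range(n_replicates)]
    tp_set = set(time_points)

    samples: list[PeptideObservation] = []
    pep_sources: dict[str, set[str]] = {}  # canonical peptide -> protein ids

    for protein in truth.planted:
        unknown = set(protein.abundance_profile) - tp_set
        if unknown:
            raise ValueError(
                f"planted protein {protein.protein_id!r}: abundance profile "
                f"references unknown time points {sorted(unknown)}"
            )
        if not protein.secreted:
            continue
        peps = tryptic_peptides(
            protein.sequence, missed_cleavages, min_pep_len, max_pep_len
        )
        if not peps:
            raise ValueError(
                f"planted protein {protein.protein_id!r} yields no tryptic "
                f"peptides of {min_pep_len}-{max_pep_len} aa"
            )
        for tp in sorted(protein.abundance_profile):
            total = int(protein.abundance_profile[tp])
            if total == 0:
                continue
            cells = rng.multinomial(
                total, np.full(n_replicates * len(peps), 1.0 / (n_replicates * len(peps)))
            ).reshape(n_replicates, len(peps))
            for r, rep in enumerate(reps):
                for c, pep in enumerate(peps):
                    count = int(cells[r, c])
                    if count == 0:
                        continue
                    samples.append(
                        PeptideObservation(
                            species=truth.species,
                            time_point=tp,
                            band_id=f"band_{tp}d",
                            replicate=rep,
                            peptide=pep,
                            count=count,
                        )
                    )
                    pep_sources.setdefault(canonicalize(pep), set()).add(
                        protein.protein_id
                    )

    if truth.contaminant_peptides and contaminant_count > 0:
        for tp in time_points:
            for rep in reps:
                for pep in truth.contaminant_peptides:
                    samples.append(
                        PeptideObservation(
                            species=truth.species,
                            time_point=tp,
                            band_id=f"band_{tp}d",
                            replicate=rep,
                            peptide=pep,
                            count=contaminant_count,
                        )
                    )
                    pep_sources.setdefault(canonicalize(pep), set())

    # leakage into the control band, decided once per distinct peptide
    if leak_scope == "contaminants":
        eligible = sorted({canonicalize(p) for p in truth.contaminant_peptides})
    elif leak_scope == "all":
        eligible = sorted({canonicalize(o.peptide) for o in samples})
    else:
        raise ValueError(f"leak_scope must be 'contaminants' or 'all', got {leak_scope!r}")
    leaked = frozenset(
        pep for pep in eligible if rng.random() < truth.control_leak_rate
    )
    controls = [
        PeptideObservation(
            species=truth.species,
            time_point=tp,
            band_id="control",
            replicate="control",
            peptide=pep,
            count=1,
            is_control=True,
        )
        for tp in time_points
        for pep in sorted(leaked)
    ]

    totals: dict[tuple[str, int], int] = {}
    reps_detected: dict[tuple[str, int], set[str]] = {}
    for o in samples:
        cpep = canonicalize(o.peptide)
        if cpep in leaked:
            continue
        for pid in pep_sources.get(cpep, ()):
            key = (pid, o.time_point)
            totals[key] = totals.get(key, 0) + o.count
            reps_detected.setdefault(key, set()).add(o.replicate)
    report_truth = BandReportTruth(
        expected_totals=totals,
        expected_replicates={k: len(v) for k, v in reps_detected.items()},
        leaked_peptides=leaked,
    )
    return samples, controls, report_truth


def simulate_plate(
    true_conc: Sequence[float],
    slope: float,
    intercept: float,
    noise_sd: float,
    seed: int,
    standards: Sequence[float] = (0.0, 5.0, 10.0, 25.0, 50.0, 100.0),
    treatment: Sequence[str] | None = None,
    dose_uM: Sequence[float] | None = None,
    replicate: Sequence[str] | None = None,
    protein_ug: float = 1.0,
    hours: float = 1.0,
) -> pd.DataFrame:
    """Simulate a plate-reader absorbance table with KMnO4-style standards.

    ``absorbance = intercept + slope * conc + N(0, noise_sd)`` for both
    standards and samples.  Samples carry the treatment metadata columns
    used downstream; their true concentrations are in ``conc_uM`` only for
    standards (samples get NaN, as on a real plate).
    """
    if slope <= 0:
        raise ValueError(f"slope must be > 0, got {slope}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    conc = np.asarray(true_conc, dtype=float)
    stds = np.asarray(standards, dtype=float)
    if np.any(conc < 0) or np.any(stds < 0):
        raise ValueError("concentrations must be non-negative")
    n = conc.size
    treatment = list(treatment) if treatment is not None else ["none"] * n
    dose = np.asarray(dose_uM, dtype=float) if dose_uM is not None else np.zeros(n)
    replicate = list(replicate) if replicate is not None else [
        f"rep{i + 1}" for i in range(n)
    ]
    if not (len(treatment) == dose.size == len(replicate) == n):
        raise ValueError("treatment/dose_uM/replicate must match true_conc length")

    rng = np.random.default_rng(seed)
    rows = []
    for i, c in enumerate(stds):
        a = intercept + slope * c + (rng.normal(0, noise_sd) if noise_sd else 0.0)
        rows.append(
            {
                "sample_id": f"std_{i + 1}",
                "role": "standard",
                "conc_uM": c,
                "absorbance": a,
                "treatment": "",
                "dose_uM": np.nan,
                "replicate": "",
                "protein_ug": np.nan,
                "hours": np.nan,
            }
        )
    for i, c in enumerate(conc):
        a = intercept + slope * c + (rng.normal(0, noise_sd) if noise_sd else 0.0)
        rows.append(
            {
                "sample_id": f"sample_{i + 1}",
                "role": "sample",
                "conc_uM": np.nan,
                "absorbance": a,
                "treatment": treatment[i],
                "dose_uM": dose[i],
                "replicate": replicate[i],
                "protein_ug": protein_ug,
                "hours": hours,
            }
        )
    return pd.DataFrame(rows)
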