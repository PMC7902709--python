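"""Annotation transfer from BLAST tabular hits and candidate-table assembly.

Stop-to-stop ORFs carry no annotation of their own; function is transferred
from database homologs found by BLAST.  The transfer rules are deliberately
conservative:

* hits at or above the E-value threshold (default 1e-10) are discarded;
* among the survivors the highest raw score wins, except that hits whose
  description marks them as hypothetical/uncharacterized are passed over in
  favour of the best-scoring informative hit;
* a query with no surviving informative hit — or no surviving hit at all —
  is reported as hypothetical.

Cofactor classes (Cu, FAD, Fe/heme, ...) are assigned by an ordered keyword
map over the chosen description, and CAZy families come from a user-supplied
lookup (family classification is curated, not recomputed).  A configurable
residue-pattern scan is available for Cu-binding-site spotting; no built-in
pattern is asserted as biologically validated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from mnox.peptides import ProteinEvidence

#: cofactor classes used in the candidate tables
COFACTOR_CLASSES = (
    "Cu",
    "FAD",
    "Fe/heme",
    "Fe-S",
    "Cu/Zn",
    "Fe/Mn",
    "NAD(P)",
    "peroxidatic-Cys",
    "none",
)

DEFAULT_HYPOTHETICAL_MARKERS = (
    "hypothetical",
    "uncharacterized",
    "predicted protein",
)

#: ordered (case-insensitive substring, class) rules; first match wins.
#: Covers the classes seen in Ascomycete secretome screens; user-overridable
#: because cofactor assignment is ultimately a curation call.
DEFAULT_COFACTOR_KEYWORDS: tuple[tuple[str, str], ...] = (
    ("copper/zinc", "Cu/Zn"),
    ("superoxide dismutase (cu/zn)", "Cu/Zn"),
    ("superoxide dismutase (fe/mn)", "Fe/Mn"),
    ("copper amine oxidase", "Cu"),
    ("tyrosinase", "Cu"),
    ("di-copper", "Cu"),
    ("cupredoxin", "Cu"),
    ("multicopper oxidase", "Cu"),
    ("laccase", "Cu"),
    ("bilirubin oxidase", "Cu"),
    ("ascorbate oxidase", "Cu"),
    ("glyoxal oxidase", "Cu"),
    ("carbohydrate binding module family 18", "Cu"),
    ("gmc oxidoreductase", "FAD"),
    ("alcohol oxidase", "FAD"),
    ("choline dehydrogenase", "FAD"),
    ("glucose oxidase", "FAD"),
    ("solanapyrone synthase", "FAD"),
    ("berberine", "FAD"),
    ("fad", "FAD"),
    ("heme peroxidase", "Fe/heme"),
    ("2-methylcitrate dehydratase", "Fe-S"),
    ("peroxiredoxin", "peroxidatic-Cys"),
    ("ahpc/tsa", "peroxidatic-Cys"),
    ("thioredoxin-like peroxidase", "peroxidatic-Cys"),
    ("alkyl hydroperoxide reductase", "peroxidatic-Cys"),
    ("nad(p)", "NAD(P)"),
    ("nadp", "NAD(P)"),
    ("nadh", "NAD(P)"),
)


@dataclass(frozen=True)
class BlastHit:
    """One row of tabular BLAST output for a query."""

    query_id: str
    subject_accession: str
    description: str
    raw_score: float
    e_value: float
    percent_identity: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError(f"e_value must be >= 0, got {self.e_value}")
        if not 0 <= self.percent_identity <= 100:
            raise ValueError(
                f"percent_identity must be in [0, 100], got {self.percent_identity}"
            )


@dataclass(frozen=True)
class AnnotationConfig:
    e_value_threshold: float = 1e-10
    hypothetical_markers: tuple[str, ...] = DEFAULT_HYPOTHETICAL_MARKERS
    cofactor_keywords: tuple[tuple[str, str], ...] = DEFAULT_COFACTOR_KEYWORDS
    motif_patterns: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.e_value_threshold <= 0:
            raise ValueError("e_value_threshold must be > 0")

    def is_hypothetical(self, description: str) -> bool:
        d = description.lower()
        return any(m.lower() in d for m in self.hypothetical_markers)


@dataclass(frozen=True)
class AnnotationRecord:
    """Chosen annotation for one query ORF."""

    query_id: str
    hit: BlastHit | None
    annotation_status: str  # "annotated" | "hypothetical"
    cazy_family: str | None = None
    cofactor_class: str = "none"

    def __post_init__(self) -> None:
        if self.annotation_status not in ("annotated", "hypothetical"):
            raise ValueError(f"bad annotation_status {self.annotation_status!r}")
        if self.cofactor_class not in COFACTOR_CLASSES:
            raise ValueError(f"unknown cofactor_class {self.cofactor_class!r}")

    @property
    def redox_active(self) -> bool:
        return self.cofactor_class != "none"


def select_best_hit(
    query_id: str,
    hits: Sequence[BlastHit],
    config: AnnotationConfig | None = None,
) -> AnnotationRecord:
    """Choose the reportable hit for one query.

    Hits with ``e_value >= e_value_threshold`` are discarded.  Among the
    survivors the highest raw score wins; if that hit is hypothetical, the
    highest-scoring non-hypothetical survivor is reported instead.  When no
    informative survivor exists the record is hypothetical.  Ties break by
    lower E-value, then lexicographic subject accession, so the choice is
    order-invariant.
    """
    config = config or AnnotationConfig()
    survivors = [h for h in hits if h.e_value < config.e_value_threshold]
    informative = [h for h in survivors if not config.is_hypothetical(h.description)]
    if not informative:
        return AnnotationRecord(query_id, None, "hypothetical")
    best = min(
        informative,
        key=lambda h: (-h.raw_score, h.e_value, h.subject_accession),
    )
    return AnnotationRecord(query_id, best, "annotated")


def classify_cofactor(
    record: AnnotationRecord,
    config: AnnotationConfig | None = None,
) -> AnnotationRecord:
    """Assign a cofactor class from the chosen hit's description.

    The first matching rule in the ordered keyword map wins (so specific
    patterns like "copper/zinc" must precede generic ones).  Hypothetical
    records get class "none" and are not redox-active.
    """
    config = config or AnnotationConfig()
    if record.annotation_status == "hypothetical" or record.hit is None:
        return replace(record, cofactor_class="none")
    desc = record.hit.description.lower()
    for keyword, klass in config.cofactor_keywords:
        if keyword.lower() in desc:
            return replace(record, cofactor_class=klass)
    return replace(record, cofactor_class="none")


def annotate_queries(
    hits_by_query: Mapping[str, Sequence[BlastHit]],
    config: AnnotationConfig | None = None,
    cazy_lookup: Mapping[str, str] | None = None,
) -> dict[str, AnnotationRecord]:
    """Run best-hit selection + cofactor classification for many queries.

    ``cazy_lookup`` maps query id to a curated CAZy family label; families
    are assigned from this table, never recomputed.
    """
    config = config or AnnotationConfig()
    cazy_lookup = cazy_lookup or {}
    out = {}
    for query_id, hits in hits_by_query.items():
        rec = classify_cofactor(select_best_hit(query_id, hits, config), config)
        if query_id in cazy_lookup:
            rec = replace(rec, cazy_family=cazy_lookup[query_id])
        out[query_id] = rec
    return out


# ---------------------------------------------------------------------------
# Motif scan

_MOTIF_TOKEN = re.compile(r"[A-WYZ]|X|\[[A-Z]+\]")


def _compile_motif(name: str, pattern: str) -> re.Pattern:
    """Compile a residue-class pattern: letters literal, X any residue,
    [ABC] a residue class."""
    pos, parts = 0, []
    while pos < len(pattern):
        m = _MOTIF_TOKEN.match(pattern, pos)
        if m is None:
            raise ValueError(
                f"motif {name!r}: invalid pattern syntax at position {pos} "
                f"in {pattern!r}"
            )
        tok = m.group(0)
        parts.append("." if tok == "X" else tok)
        pos = m.end()
    if not parts:
        raise ValueError(f"motif {name!r}: empty pattern")
    return re.compile("".join(parts))


def scan_motifs(
    protein: str, motif_patterns: Mapping[str, str]
) -> list[tuple[str, int]]:
    """Report non-overlapping matches of each named residue pattern.

    Returns ``(motif name, 0-based position)`` pairs in scan order.
    """
    out: list[tuple[str, int]] = []
    seq = protein.upper()
    for name, pattern in motif_patterns.items():
        rx = _compile_motif(name, pattern)
        out.extend((name, m.start()) for m in rx.finditer(seq))
    return out


# ---------------------------------------------------------------------------
# Candidate-table assembly


def build_candidate_table(
    evidence: Sequence[ProteinEvidence],
    annotations: Mapping[str, AnnotationRecord],
    metadata: Mapping[str, Mapping[str, str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join evidence with annotations into the candidate table.

    Returns ``(candidates, other_proteins)``: one row per protein per
    species with best-hit fields and per-time-point evidence columns
    (``bio_reps_{t}d``, ``total_peptides_{t}d``).  Redox-active proteins
    (cofactor class other than "none") form the candidate table; everything
    else goes to the secondary listing.  Rows sort by species, then
    descending peak total peptides.  Every evidence row must have an
    annotation record (possibly hypothetical) — a missing one is an error,
    not an implicit hypothetical.

    The join is pure: the output row multiset does not depend on input
    order.
    """
    metadata = metadata or {}
    missing = sorted({e.orf_id for e in evidence} - set(annotations))
    if missing:
        raise ValueError(f"evidence without annotation records: {missing}")

    time_points = sorted({e.time_point for e in evidence})
    grouped: dict[tuple[str, str], list[ProteinEvidence]] = {}
    for e in sorted(evidence, key=lambda e: (e.species, e.orf_id, e.time_point)):
        grouped.setdefault((e.species, e.orf_id), []).append(e)

    rows = []
    for (species, orf_id), evs in grouped.items():
        rec = annotations[orf_id]
        hit = rec.hit
        row: dict[str, object] = {
            "orf_id": orf_id,
            "species": species,
            "annotation_status": rec.annotation_status,
            "description": hit.description if hit else "hypothetical protein",
            "subject_accession": hit.subject_accession if hit else "",
            "genome": (metadata.get(orf_id) or {}).get("genome", ""),
            "raw_score": hit.raw_score if hit else float("nan"),
            "e_value": hit.e_value if hit else float("nan"),
            "percent_identity": hit.percent_identity if hit else float("nan"),
            "cazy_family": rec.cazy_family or "",
            "cofactor": rec.cofactor_class,
        }
        for key, value in (metadata.get(orf_id) or {}).items():
            row.setdefault(key, value)
        by_tp = {e.time_point: e for e in evs}
        peak = 0
        for tp in time_points:
            e = by_tp.get(tp)
            row[f"bio_reps_{tp}d"] = e.bio_reps if e else ""
            row[f"total_peptides_{tp}d"] = e.total_peptides if e else 0
            if e:
                peak = max(peak, e.total_peptides)
        row["peak_total_peptides"] = peak
        row["redox_active"] = rec.redox_active
        rows.append(row)

    df = pd.DataFrame(rows)
    if df.empty:
        cols = ["orf_id", "species", "annotation_status", "description",
                "subject_accession", "genome", "raw_score", "e_value",
                "percent_identity", "cazy_family", "cofactor",
                "peak_total_peptides", "redox_active"]
        empty = pd.DataFrame(columns=cols)
        return empty, empty.copy()
    df = df.sort_values(
        ["species", "peak_total_peptides", "orf_id"],
        ascending=[True, False, True],
    ).reset_index(drop=True)
    candidates = df[df["redox_active"]].drop(columns="redox_active")
    others = df[~df["redox_active"]].drop(columns="redox_active")
    return candidates.reset_index(drop=True), others.reset_index(drop=True)


ANNOTATION_COLUMNS = [
    "query_id",
    "annotation_status",
    "subject_accession",
    "description",
    "raw_score",
    "e_value",
    "percent_identity",
    "cazy_family",
    "cofactor_class",
]


def write_annotations(annotations: Mapping[str, AnnotationRecord], path) -> None:
    rows = []
    for query_id in sorted(annotations):
        rec = annotations[query_id]
        hit = rec.hit
        rows.append(
            (
                query_id,
                rec.annotation_status,
                hit.subject_accession if hit else "",
                hit.description if hit else "",
                hit.raw_score if hit else "",
                hit.e_value if hit else "",
                hit.percent_identity if hit else "",
                rec.cazy_family or "",
                rec.cofactor_class,
            )
        )
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_annotations(path) -> dict[str, AnnotationRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = {}
    for row in df.to_dict("records"):
        hit = None
        if row["annotation_status"] == "annotated":
            hit = BlastHit(
                query_id=row["query_id"],
                subject_accession=row["subject_accession"],
                description=row["description"],
                raw_score=float(row["raw_score"]),
                e_value=float(row["e_value"]),
                percent_identity=float(row["percent_identity"]),
            )
        out[row["query_id"]] = AnnotationRecord(
            query_id=row["query_id"],
            hit=hit,
            annotation_status=row["annotation_status"],
            cazy_family=row["cazy_family"] or None,
            cofactor_class=row["cofactor_class"] or "none",
        )
    return out


# ---------------------------------------------------------------------------
# BLAST tabular I/O

#: standard -outfmt 6 column order
OUTFMT6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


def read_blast_tabular(
    path,
    columns: Sequence[str] = OUTFMT6_COLUMNS,
    score_field: str = "bitscore",
    description_field: str = "sseqid",
) -> dict[str, list[BlastHit]]:
    """Read outfmt-6-style TSV into hits grouped by query.

    The standard 12-column layout carries no description or raw score, so
    by default the subject id doubles as the description and the bit score
    as the raw score; extended layouts (e.g. with ``stitle`` and ``score``
    columns) can name their fields via *columns*, *score_field* and
    *description_field*.  Malformed rows are rejected with their line
    number.
    """
    for needed in ("qseqid", "sseqid", "evalue", "pident", score_field):
        if needed not in columns:
            raise ValueError(f"column layout lacks required field {needed!r}")
    idx = {c: i for i, c in enumerate(columns)}
    hits: dict[str, list[BlastHit]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(columns):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(columns)} fields, "
                    f"got {len(fields)}"
                )
            try:
                hit = BlastHit(
                    query_id=fields[idx["qseqid"]],
                    subject_accession=fields[idx["sseqid"]],
                    description=fields[idx[description_field]],
                    raw_score=float(fields[idx[score_field]]),
                    e_value=float(fields[idx["evalue"]]),
                    percent_identity=float(fields[idx["pident"]]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            hits.setdefault(hit.query_id, []).append(hit)
    return hits
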