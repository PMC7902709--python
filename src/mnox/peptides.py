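"""Peptide-to-ORF mapping and gel-band evidence aggregation.

Identified peptides from excised Mn(II)-oxidizing gel bands are mapped to
stop-to-stop ORFs by substring search, negative-control-band peptides are
subtracted by identity, counts are summed across biological replicates per
(species, time point), and proteins below the minimum peptide-observation
threshold are dropped.

Isobaric residues: I and L are indistinguishable at the instrument level,
so peptides and ORF proteins are compared in a canonical form with every I
replaced by L (configurable).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

# 20 standard residues; I allowed on input, collapsed to L canonically
_VALID_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

REPORT_COLUMNS = [
    "species",
    "time_point",
    "band_id",
    "replicate",
    "peptide",
    "count",
    "is_control",
]

EVIDENCE_COLUMNS = [
    "orf_id",
    "species",
    "time_point",
    "bio_reps",
    "total_peptides",
    "distinct_peptides",
    "unique_peptides",
]


@dataclass(frozen=True)
class PeptideObservation:
    """One peptide seen in one gel band of one biological replicate."""

    species: str
    time_point: int
    band_id: str
    replicate: str
    peptide: str
    count: int = 1
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")
        if not self.peptide:
            raise ValueError("peptide must be non-empty")


@dataclass(frozen=True)
class PeptideMapping:
    """Where one canonical peptide occurs in the ORF database."""

    peptide: str  # canonical form
    orf_ids: tuple[str, ...]
    positions: Mapping[str, tuple[int, ...]]  # orf_id -> 0-based match starts
    terminus_status: str  # fully-tryptic / partially-tryptic / non-tryptic

    @property
    def unique(self) -> bool:
        return len(self.orf_ids) == 1


@dataclass(frozen=True)
class ProteinEvidence:
    """Per-(ORF, species, time point) aggregate after control subtraction."""

    orf_id: str
    species: str
    time_point: int
    total_peptides: int
    bio_reps_detected: int
    bio_reps_analyzed: int
    distinct_peptides: int
    unique_peptides: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.distinct_peptides <= self.total_peptides:
            raise ValueError("need total_peptides >= distinct_peptides >= 0")
        if self.bio_reps_detected > self.bio_reps_analyzed:
            raise ValueError("bio_reps_detected cannot exceed bio_reps_analyzed")

    @property
    def bio_reps(self) -> str:
        return f"{self.bio_reps_detected}/{self.bio_reps_analyzed}"


@dataclass(frozen=True)
class InferenceConfig:
    """Counting, subtraction and filtering rules.

    min_peptides
        Minimum summed peptide observations per aggregated band (default 2):
        the retention threshold applied after replicate summation.
    il_equivalence
        Collapse I to L before any comparison (default on).
    tryptic_requirement
        'none', 'partial' (default: at least one terminus tryptic or at a
        protein terminus) or 'full'.
    subtraction_scope
        'global' (default): every control band applies to every sample band.
        Alternatively a mapping ``band_id -> list of control band_ids``.
    """

    min_peptides: int = 2
    il_equivalence: bool = True
    tryptic_requirement: str = "partial"
    subtraction_scope: str | Mapping[str, Sequence[str]] = "global"

    def __post_init__(self) -> None:
        if self.min_peptides < 0:
            raise ValueError("min_peptides must be >= 0")
        if self.tryptic_requirement not in ("none", "partial", "full"):
            raise ValueError(
                f"tryptic_requirement must be none/partial/full, "
                f"got {self.tryptic_requirement!r}"
            )


def canonicalize(peptide: str, il_equivalence: bool = True) -> str:
    """Return the canonical (uppercase, optionally I→L) peptide form.

    Idempotent: ``canonicalize(canonicalize(x)) == canonicalize(x)``.
    """
    pep = peptide.upper()
    bad = next((c for c in pep if c not in _VALID_AA), None)
    if bad is not None:
        raise ValueError(f"illegal residue {bad!r} in peptide {peptide!r}")
    return pep.replace("I", "L") if il_equivalence else pep


def _terminus_status(protein: str, pos: int, pep_len: int) -> str:
    """Tryptic status of one peptide occurrence within a protein.

    Trypsin cleaves after K/R but not before P; a protein terminus counts
    as a valid cleavage site.
    """
    end = pos + pep_len
    n_ok = pos == 0 or (protein[pos - 1] in "KR" and protein[pos] != "P")
    c_ok = end == len(protein) or (
        protein[end - 1] in "KR" and protein[end] != "P"
    )
    if n_ok and c_ok:
        return "fully-tryptic"
    if n_ok or c_ok:
        return "partially-tryptic"
    return "non-tryptic"


_STATUS_RANK = {"non-tryptic": 0, "partially-tryptic": 1, "fully-tryptic": 2}


def _find_all(haystack: str, needle: str) -> list[int]:
    positions, i = [], haystack.find(needle)
    while i != -1:
        positions.append(i)
        i = haystack.find(needle, i + 1)
    return positions


def map_peptides(
    peptides: Iterable[str],
    orf_db,
    config: InferenceConfig | None = None,
) -> tuple[list[PeptideMapping], set[str]]:
    """Map canonical peptides onto an ORF database by substring search.

    A mapping lists an ORF iff the canonical peptide occurs in the
    canonical ORF protein with termini satisfying ``tryptic_requirement``.
    Returns ``(mappings, unmapped)``; peptides matching no ORF land in
    *unmapped*, never silently dropped.  Input peptides are deduplicated on
    their canonical form.
    """
    config = config or InferenceConfig()
    orfs = list(orf_db)
    if not orfs:
        raise ValueError("ORF database is empty")
    required = {
        "none": _STATUS_RANK["non-tryptic"],
        "partial": _STATUS_RANK["partially-tryptic"],
        "full": _STATUS_RANK["fully-tryptic"],
    }[config.tryptic_requirement]
    # X stays in place in the canonical protein: it is outside the peptide
    # alphabet, so a substring search can never match across it, whereas
    # deleting it would create spurious residue junctions.
    canon_prot = {
        o.orf_id: o.protein.upper().replace("I", "L")
        if config.il_equivalence
        else o.protein.upper()
        for o in orfs
    }

    mappings: list[PeptideMapping] = []
    unmapped: set[str] = set()
    canon_seen: set[str] = set()
    for pep in peptides:
        cpep = canonicalize(pep, config.il_equivalence)
        if cpep in canon_seen:
            continue
        canon_seen.add(cpep)
        hits: dict[str, tuple[int, ...]] = {}
        best_status = "non-tryptic"
        for orf in orfs:
            prot = canon_prot[orf.orf_id]
            positions = _find_all(prot, cpep)
            if not positions:
                continue
            kept = []
            for p in positions:
                status = _terminus_status(prot, p, len(cpep))
                if _STATUS_RANK[status] >= required:
                    kept.append(p)
                    if _STATUS_RANK[status] > _STATUS_RANK[best_status]:
                        best_status = status
            if kept:
                hits[orf.orf_id] = tuple(kept)
        if hits:
            mappings.append(
                PeptideMapping(
                    peptide=cpep,
                    orf_ids=tuple(sorted(hits)),
                    positions=hits,
                    terminus_status=best_status,
                )
            )
        else:
            unmapped.add(cpep)
    return mappings, unmapped


def _control_sets(
    observations: Sequence[PeptideObservation], config: InferenceConfig
) -> Mapping[str, set[str]] | set[str]:
    il = config.il_equivalence
    if config.subtraction_scope == "global":
        return {
            canonicalize(o.peptide, il) for o in observations if o.is_control
        }
    per_band: dict[str, set[str]] = defaultdict(set)
    for o in observations:
        if o.is_control:
            per_band[o.band_id].update({canonicalize(o.peptide, il)})
    scoped: dict[str, set[str]] = {}
    for band, controls in config.subtraction_scope.items():
        scoped[band] = set().union(*(per_band.get(c, set()) for c in controls))
    return scoped


def subtract_controls(
    observations: Sequence[PeptideObservation],
    config: InferenceConfig | None = None,
) -> list[PeptideObservation]:
    """Remove sample observations whose peptide occurs in an in-scope control.

    Subtraction removes peptide *identities* (canonical sequences), not
    count offsets.  Idempotent.  Control observations themselves are not
    returned.  A sample band with no in-scope control defined is passed
    through unchanged with a warning.
    """
    config = config or InferenceConfig()
    controls = _control_sets(observations, config)
    survivors = []
    warned: set[str] = set()
    for o in observations:
        if o.is_control:
            continue
        if isinstance(controls, set):
            in_scope = controls
        elif o.band_id in controls:
            in_scope = controls[o.band_id]
        else:
            if o.band_id not in warned:
                logger.warning(
                    "band %r has no in-scope control; no subtraction applied",
                    o.band_id,
                )
                warned.add(o.band_id)
            in_scope = set()
        if canonicalize(o.peptide, config.il_equivalence) not in in_scope:
            survivors.append(o)
    return survivors


def aggregate_evidence(
    mappings: Sequence[PeptideMapping],
    observations: Sequence[PeptideObservation],
    config: InferenceConfig | None = None,
) -> list[ProteinEvidence]:
    """Sum mapped peptide counts across replicates per (ORF, species, time).

    *observations* must already be control-subtracted.  Shared peptides
    contribute to every ORF they map to; ``unique_peptides`` counts only
    observations of peptides mapping to a single ORF.  ``bio_reps_analyzed``
    is the number of distinct replicate labels seen for that
    (species, time point), which must be consistent across its bands.
    """
    config = config or InferenceConfig()
    pep_to_orfs: dict[str, tuple[str, ...]] = {
        m.peptide: m.orf_ids for m in mappings
    }

    # replicate census per (species, time point); bands within one group
    # must agree on the replicate label set
    reps_by_group: dict[tuple[str, int], set[str]] = defaultdict(set)
    reps_by_band: dict[tuple[str, int, str], set[str]] = defaultdict(set)
    for o in observations:
        if o.is_control:
            continue
        reps_by_group[(o.species, o.time_point)].add(o.replicate)
        reps_by_band[(o.species, o.time_point, o.band_id)].add(o.replicate)
    for (sp, tp, band), reps in reps_by_band.items():
        expected = reps_by_group[(sp, tp)]
        if reps != expected:
            raise ValueError(
                f"inconsistent replicate labels in band {band!r} for "
                f"({sp!r}, {tp}): {sorted(reps)} vs {sorted(expected)}"
            )

    totals: dict[tuple[str, str, int], int] = defaultdict(int)
    uniques: dict[tuple[str, str, int], int] = defaultdict(int)
    distinct: dict[tuple[str, str, int], set[str]] = defaultdict(set)
    reps_det: dict[tuple[str, str, int], set[str]] = defaultdict(set)
    for o in observations:
        if o.is_control:
            continue
        cpep = canonicalize(o.peptide, config.il_equivalence)
        orf_ids = pep_to_orfs.get(cpep)
        if not orf_ids:
            continue
        for orf_id in orf_ids:
            key = (orf_id, o.species, o.time_point)
            totals[key] += o.count
            distinct[key].add(cpep)
            reps_det[key].add(o.replicate)
            if len(orf_ids) == 1:
                uniques[key] += o.count

    out = []
    for key in sorted(totals):
        orf_id, sp, tp = key
        out.append(
            ProteinEvidence(
                orf_id=orf_id,
                species=sp,
                time_point=tp,
                total_peptides=totals[key],
                bio_reps_detected=len(reps_det[key]),
                bio_reps_analyzed=len(reps_by_group[(sp, tp)]),
                distinct_peptides=len(distinct[key]),
                unique_peptides=uniques[key],
            )
        )
    return out


def filter_evidence(
    evidence: Sequence[ProteinEvidence],
    config: InferenceConfig | None = None,
) -> list[ProteinEvidence]:
    """Retain records with ``total_peptides >= min_peptides`` (default 2)."""
    config = config or InferenceConfig()
    return [e for e in evidence if e.total_peptides >= config.min_peptides]


# ---------------------------------------------------------------------------
# Tab-separated I/O


def read_peptide_report(path) -> list[PeptideObservation]:
    """Read a peptide report TSV (columns: species, time_point, band_id,
    replicate, peptide, count, is_control)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(REPORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"peptide report missing columns: {sorted(missing)}")
    return [
        PeptideObservation(
            species=row["species"],
            time_point=int(row["time_point"]),
            band_id=row["band_id"],
            replicate=row["replicate"],
            peptide=row["peptide"],
            count=int(row["count"]),
            is_control=str(row["is_control"]).lower() in ("1", "true", "yes"),
        )
        for row in df.to_dict("records")
    ]


def write_peptide_report(observations: Sequence[PeptideObservation], path) -> None:
    df = pd.DataFrame(
        [
            (o.species, o.time_point, o.band_id, o.replicate, o.peptide, o.count,
             int(o.is_control))
            for o in observations
        ],
        columns=REPORT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def write_mappings(mappings: Sequence[PeptideMapping], unmapped: set[str], path) -> None:
    """Write peptide→ORF mappings as TSV (unmapped peptides keep an empty
    orf_ids field)."""
    rows = [
        (m.peptide, ";".join(m.orf_ids), m.terminus_status, int(m.unique))
        for m in mappings
    ]
    rows += [(p, "", "", 0) for p in sorted(unmapped)]
    pd.DataFrame(
        rows, columns=["peptide", "orf_ids", "terminus_status", "unique"]
    ).to_csv(path, sep="\t", index=False)


def read_mappings(path) -> tuple[list[PeptideMapping], set[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    mappings, unmapped = [], set()
    for row in df.to_dict("records"):
        if row["orf_ids"]:
            orf_ids = tuple(row["orf_ids"].split(";"))
            mappings.append(
                PeptideMapping(
                    peptide=row["peptide"],
                    orf_ids=orf_ids,
                    positions={o: () for o in orf_ids},
                    terminus_status=row["terminus_status"],
                )
            )
        else:
            unmapped.add(row["peptide"])
    return mappings, unmapped


def write_evidence(evidence: Sequence[ProteinEvidence], path) -> None:
    df = evidence_frame(evidence)
    df.to_csv(path, sep="\t", index=False)


def read_evidence(path) -> list[ProteinEvidence]:
    """Read an evidence TSV written by :func:`write_evidence`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for row in df.to_dict("records"):
        det, tot = row["bio_reps"].split("/")
        out.append(
            ProteinEvidence(
                orf_id=row["orf_id"],
                species=row["species"],
                time_point=int(row["time_point"]),
                total_peptides=int(row["total_peptides"]),
                bio_reps_detected=int(det),
                bio_reps_analyzed=int(tot),
                distinct_peptides=int(row["distinct_peptides"]),
                unique_peptides=int(row.get("unique_peptides", 0) or 0),
            )
        )
    return out


def evidence_frame(evidence: Sequence[ProteinEvidence]) -> pd.DataFrame:
    """Tidy evidence table mirroring the candidate-table evidence columns."""
    return pd.DataFrame(
        [
            (e.orf_id, e.species, e.time_point, e.bio_reps, e.total_peptides,
             e.distinct_peptides, e.unique_peptides)
            for e in evidence
        ],
        columns=EVIDENCE_COLUMNS,
    )
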