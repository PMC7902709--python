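"""End-to-end orchestration: genome → ORF db → evidence → candidate tables,
and plate → calibration → rates → gated comparisons.

Each stage logs its input/output record counts so every filter is auditable:
records in minus records removed equals records out at every step.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from mnox import annotate as ann
from mnox import assay as asy
from mnox import orfs as orfmod
from mnox import peptides as pep

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full proteogenomics and/or assay run."""

    genome_fasta: str | None = None
    peptide_reports: list[str] = field(default_factory=list)
    blast_tsv: str | None = None
    blast_columns: list[str] | None = None
    blast_score_field: str = "bitscore"
    blast_description_field: str = "sseqid"
    cazy_table: str | None = None
    plate_csv: str | None = None
    output_dir: str = "mnox_out"
    seed: int = 0
    orf: orfmod.OrfDbConfig = field(default_factory=orfmod.OrfDbConfig)
    inference: pep.InferenceConfig = field(default_factory=pep.InferenceConfig)
    annotation: ann.AnnotationConfig = field(default_factory=ann.AnnotationConfig)
    alpha: float = 0.05
    gate_test: str = "levene"
    control_group: str = "control"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        orf_cfg = orfmod.OrfDbConfig(**raw.pop("orf", {}))
        inf_cfg = pep.InferenceConfig(**raw.pop("inference", {}))
        ann_raw = raw.pop("annotation", {})
        if "cofactor_keywords" in ann_raw:
            ann_raw["cofactor_keywords"] = tuple(
                (k, v) for k, v in ann_raw["cofactor_keywords"]
            )
        ann_cfg = ann.AnnotationConfig(**ann_raw)
        return cls(orf=orf_cfg, inference=inf_cfg, annotation=ann_cfg, **raw)


def _read_cazy_table(path) -> tuple[dict[str, str], dict[str, str]]:
    """Read the curated lookup: query_id, cazy_family[, cofactor_class]."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    cazy = {
        r["query_id"]: r["cazy_family"]
        for r in df.to_dict("records")
        if r.get("cazy_family")
    }
    cofactor = (
        {
            r["query_id"]: r["cofactor_class"]
            for r in df.to_dict("records")
            if r.get("cofactor_class")
        }
        if "cofactor_class" in df.columns
        else {}
    )
    return cazy, cofactor


def run_proteogenomics(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run genome → ORFs → mapping → aggregation → annotation → tables.

    Writes ``orfs.faa``, ``evidence.tsv``, ``annotations.tsv``,
    ``candidates.tsv``, ``other_proteins.tsv`` and ``run_log.json`` into
    ``config.output_dir`` and returns the main tables.
    """
    if not config.genome_fasta:
        raise ValueError("run_proteogenomics requires genome_fasta")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    contigs = orfmod.read_contig_fasta(config.genome_fasta)
    counts["contigs"] = len(contigs)
    orf_db = orfmod.extract_orfs(contigs, config.orf)
    counts["orfs"] = len(orf_db)
    orfmod.write_orf_fasta(orf_db, outdir / "orfs.faa")
    logger.info("extracted %d ORFs from %d contigs", len(orf_db), len(contigs))

    observations: list[pep.PeptideObservation] = []
    for path in config.peptide_reports:
        observations.extend(pep.read_peptide_report(path))
    counts["observations_in"] = len(observations)
    counts["control_observations"] = sum(o.is_control for o in observations)

    survivors = pep.subtract_controls(observations, config.inference)
    counts["observations_after_subtraction"] = len(survivors)
    n_sample = counts["observations_in"] - counts["control_observations"]
    counts["observations_removed_by_subtraction"] = n_sample - len(survivors)
    logger.info(
        "control subtraction: %d sample observations in, %d out",
        n_sample,
        len(survivors),
    )

    if survivors:
        distinct = sorted(
            {
                pep.canonicalize(o.peptide, config.inference.il_equivalence)
                for o in survivors
            }
        )
        mappings, unmapped = pep.map_peptides(distinct, orf_db, config.inference)
    else:
        mappings, unmapped = [], set()
    counts["distinct_peptides"] = len(mappings) + len(unmapped)
    counts["mapped_peptides"] = len(mappings)
    counts["unmapped_peptides"] = len(unmapped)
    pep.write_mappings(mappings, unmapped, outdir / "mappings.tsv")

    evidence = pep.aggregate_evidence(mappings, survivors, config.inference)
    counts["evidence_records"] = len(evidence)
    kept = pep.filter_evidence(evidence, config.inference)
    counts["evidence_after_min_peptides"] = len(kept)
    counts["evidence_removed_by_min_peptides"] = len(evidence) - len(kept)
    logger.info(
        "evidence: %d records aggregated, %d pass min_peptides=%d",
        len(evidence),
        len(kept),
        config.inference.min_peptides,
    )
    pep.write_evidence(kept, outdir / "evidence.tsv")

    hits_by_query: dict[str, list[ann.BlastHit]] = {}
    if config.blast_tsv:
        hits_by_query = ann.read_blast_tabular(
            config.blast_tsv,
            columns=config.blast_columns or ann.OUTFMT6_COLUMNS,
            score_field=config.blast_score_field,
            description_field=config.blast_description_field,
        )
    cazy_lookup: dict[str, str] = {}
    cofactor_override: dict[str, str] = {}
    if config.cazy_table:
        cazy_lookup, cofactor_override = _read_cazy_table(config.cazy_table)

    need = {e.orf_id for e in kept}
    for orf_id in need - set(hits_by_query):
        hits_by_query[orf_id] = []
    annotations = ann.annotate_queries(
        hits_by_query, config.annotation, cazy_lookup
    )
    from dataclasses import replace as _replace

    for qid, klass in cofactor_override.items():
        if qid in annotations:
            annotations[qid] = _replace(annotations[qid], cofactor_class=klass)
    ann.write_annotations(annotations, outdir / "annotations.tsv")

    candidates, others = ann.build_candidate_table(kept, annotations)
    counts["candidate_rows"] = len(candidates)
    counts["other_protein_rows"] = len(others)
    candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    others.to_csv(outdir / "other_proteins.tsv", sep="\t", index=False)

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(
            {"seed": config.seed, "counts": counts},
            fh,
            indent=2,
            sort_keys=True,
        )
    return {"candidates": candidates, "other_proteins": others, "counts": counts}


def run_assay_analysis(config: RunConfig) -> dict[str, object]:
    """Calibrate, convert, rate-normalize and compare an assay plate.

    The plate CSV must contain standard rows (``role == standard`` with
    ``conc_uM``) and sample rows with treatment metadata.  Samples are
    grouped by ``treatment``; values are normalized to the matrix-control
    group (``config.control_group``) when present.  Two groups dispatch to
    the t test, three or more to the gated comparison.
    """
    if not config.plate_csv:
        raise ValueError("run_assay_analysis requires plate_csv")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    plate = pd.read_csv(config.plate_csv)
    stds = plate[plate["role"] == "standard"]
    if len(stds) < 2:
        raise ValueError("plate must contain at least 2 standard rows")
    curve = asy.fit_standard_curve(stds["conc_uM"], stds["absorbance"])

    samples = plate[plate["role"] == "sample"].copy()
    conc, clamped = asy.absorbance_to_mnox(samples["absorbance"].to_numpy(), curve)
    samples["mnox_uM"] = conc
    samples["clamped"] = clamped
    samples["rate_uM_per_ug_per_hr"] = asy.oxidation_rate(
        conc, samples["protein_ug"].to_numpy(), samples["hours"].to_numpy()
    )

    groups = {
        str(t): g["rate_uM_per_ug_per_hr"].to_numpy()
        for t, g in samples.groupby("treatment")
    }
    if config.control_group in groups:
        ctrl = groups[config.control_group]
        samples["percent_of_control"] = asy.normalize_to_control(
            samples["rate_uM_per_ug_per_hr"].to_numpy(), ctrl
        )

    report: dict[str, object] = {
        "calibration": {
            "slope": curve.slope,
            "intercept": curve.intercept,
            "r_squared": curve.r_squared,
            "n_standards": curve.n_standards,
        }
    }
    if len(groups) == 2:
        (la, a), (lb, b) = sorted(groups.items())
        stat, p = asy.two_group_test(a, b, config.alpha)
        report["comparison"] = {
            "test": "t-test",
            "groups": [la, lb],
            "statistic": stat,
            "p": p,
            "significant": bool(p < config.alpha),
        }
    elif len(groups) > 2:
        res = asy.compare_groups(groups, config.alpha, config.gate_test)
        report["comparison"] = {
            "gate": res.gate,
            "gate_test": res.gate_test,
            "gate_p": res.gate_p,
            "omnibus": res.omnibus,
            "omnibus_statistic": res.omnibus_statistic,
            "omnibus_p": res.omnibus_p,
            "posthoc_test": res.posthoc_test,
            "posthoc_p": {
                a: {b: float(res.posthoc_p.loc[a, b]) for b in res.posthoc_p.columns}
                for a in res.posthoc_p.index
            },
            "letters": dict(res.letters),
        }

    samples.to_csv(outdir / "rates.tsv", sep="\t", index=False)
    with open(outdir / "comparisons.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return {"rates": samples, "report": report, "curve": curve}
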