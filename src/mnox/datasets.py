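"""Bundled curated example data.

The package ships a small curated dataset: the candidate Mn(II)-oxidizing
proteins identified by LC/MS/MS in Mn(II)-oxidizing native-PAGE gel bands
from the secretomes of three filamentous Ascomycete fungi (*Stagonospora*
sp., *Pyrenochaeta* sp. and *Paraconiothyrium sporulosum*) sampled at 7, 14
and 21 days, together with their curated best BLAST hits, CAZy families and
redox-cofactor classes.  Peptide totals are summed over biological
replicates per gel band after negative-control subtraction; per-peptide
detail and distinct-peptide counts are not part of the curated summary and
load as zero.

These tables exercise the reporting stage (annotation join + candidate
table assembly) on real evidence summaries without any external downloads.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from mnox.annotate import AnnotationRecord, BlastHit
from mnox.peptides import ProteinEvidence

SPECIES = ("Stagonospora sp.", "Pyrenochaeta sp.", "P. sporulosum")


def _data_path(name: str):
    return resources.files("mnox").joinpath("data", name)


def load_curated_candidates() -> tuple[
    list[ProteinEvidence], dict[str, AnnotationRecord], dict[str, dict[str, str]]
]:
    """Load the curated Ascomycete gel-band dataset.

    Returns ``(evidence, annotations, metadata)`` ready for
    :func:`mnox.annotate.build_candidate_table`.
    """
    with _data_path("ascomycete_candidates_evidence.tsv").open() as fh:
        ev_df = pd.read_csv(fh, sep="\t", dtype=str)
    evidence = []
    for row in ev_df.to_dict("records"):
        det, tot = row["bio_reps"].split("/")
        evidence.append(
            ProteinEvidence(
                orf_id=row["orf_id"],
                species=row["species"],
                time_point=int(row["time_point"]),
                total_peptides=int(row["total_peptides"]),
                bio_reps_detected=int(det),
                bio_reps_analyzed=int(tot),
                distinct_peptides=0,  # not recorded in the curated summary
                unique_peptides=0,
            )
        )

    with _data_path("ascomycete_candidates_annotation.tsv").open() as fh:
        ann_df = pd.read_csv(fh, sep="\t", dtype=str).fillna("")
    annotations: dict[str, AnnotationRecord] = {}
    metadata: dict[str, dict[str, str]] = {}
    for row in ann_df.to_dict("records"):
        qid = row["query_id"]
        hit = BlastHit(
            query_id=qid,
            subject_accession=row["subject_accession"],
            description=row["description"],
            raw_score=float(row["raw_score"]),
            e_value=float(row["e_value"]),
            percent_identity=float(row["percent_identity"]),
        )
        annotations[qid] = AnnotationRecord(
            query_id=qid,
            hit=hit,
            annotation_status="annotated",
            cazy_family=row["cazy_family"] or None,
            cofactor_class=row["cofactor_class"],
        )
        metadata[qid] = {
            "jgi_id": row["jgi_id"],
            "jgi_annotation": row["jgi_annotation"],
            "genome": row["genome"],
        }
    return evidence, annotations, metadata
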