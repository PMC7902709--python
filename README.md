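# mnox

Proteogenomic identification of candidate Mn(II)-oxidizing enzymes in
fungal secretomes, plus the colorimetric-assay calibration and statistics
that go with it.

## The problem

Filamentous Ascomycete fungi secrete enzymes that oxidize dissolved Mn(II)
to highly reactive Mn(III/IV) oxide minerals. Finding *which* secreted
proteins are responsible is awkward: the organisms of interest usually have
only draft, contig-level genome assemblies with no gene models, so peptides
identified by LC/MS/MS from Mn(II)-oxidizing gel bands cannot be mapped to
predicted proteins. `mnox` implements the desk half of such a screen for
microbiologists and geomicrobiologists:

1. **ORF database** (`mnox.orfs`) — a gene-agnostic search space of
   *stop-to-stop* translations: every maximal translated segment between
   two in-frame stop codons (or a contig edge) of ≥ `min_len` amino acids
   (default 30), in 3 forward frames or all 6 frames.
2. **Peptide evidence** (`mnox.peptides`) — gel-band peptide
   identifications are canonicalized (I→L, since the instrument cannot
   distinguish isobaric residues), mapped onto ORFs by substring search
   with tryptic-terminus validation, stripped of any peptide that also
   occurs in a negative-control band, summed across biological replicates
   per (species, time point), and filtered to proteins with ≥ 2 peptide
   observations per band.
3. **Annotation transfer** (`mnox.annotate`) — BLAST tabular results are
   reduced to one reportable hit per ORF: discard hits with E ≥ 10⁻¹⁰,
   then take the highest raw score, passing over hypothetical or
   uncharacterized descriptions in favour of the best informative hit.
   Cofactor classes (Cu, FAD, Fe/heme, …) come from an ordered keyword
   map; CAZy families from a curated lookup. Redox-active proteins form
   the candidate table, everything else a secondary listing.
4. **Assay calibration and statistics** (`mnox.assay`) — leucoberbelin
   blue (LBB) absorbance at 620 nm is calibrated against KMnO₄ standards
   (linear OLS), inverted to Mn(IV)-equivalent concentrations, converted
   to oxidation rates (μM Mn(IV) μg⁻¹ protein hr⁻¹) and percent of a
   matrix control. Group comparisons are variance-gated: Levene (or
   Bartlett) decides between one-way ANOVA + Tukey–Kramer and
   Kruskal–Wallis + Dunn–Bonferroni; two groups get an independent-samples
   t-test; post hoc matrices are summarized as compact letter displays.
5. **Synthetic data** (`mnox.simulate`) — generators for contigs with
   planted coding segments, band-level peptide reports with replicate
   structure, contaminants and control leakage, and linear-response
   absorbance plates, all pure functions of (parameters, seed), so every
   stage is testable against known ground truth.

## Worked example

The package ships a curated dataset: the candidate Mn(II)-oxidizing
proteins identified by LC/MS/MS in Mn(II)-oxidizing native-PAGE gel bands
of three Ascomycetes (*Stagonospora* sp., *Pyrenochaeta* sp.,
*Paraconiothyrium sporulosum*) at secretome ages 7, 14 and 21 days.

```python
from mnox.datasets import load_curated_candidates
from mnox.annotate import build_candidate_table

evidence, annotations, metadata = load_curated_candidates()
candidates, others = build_candidate_table(evidence, annotations, metadata)
print(candidates.groupby("species").size())
```

```
species
P. sporulosum        7
Pyrenochaeta sp.     5
Stagonospora sp.    10
```

Ten redox-active candidates in *Stagonospora* sp., five in *Pyrenochaeta*
sp., seven in *P. sporulosum*. The per-species table carries the chosen
hit, cofactor, CAZy family and per-time-point evidence; for *Stagonospora*
sp. the top rows (by peak total peptides) are its Cu-enzymes:

```
    orf_id                           description cofactor   cazy_family  total_peptides_7d  total_peptides_14d  total_peptides_21d
OAL06359.1   Di-copper-center-containing protein       Cu         AA1_3                 61                  49                  39
OAL02734.1                            Cupredoxin       Cu         AA1_3                 41                  26                   0
OAL06112.1 Carbohydrate binding module family 18       Cu AA5_1, CBM 18                 26                  38                  21
OAK93932.1                       Alcohol oxidase      FAD         AA3_3                  0                   3                  12
```

The tyrosinase-like di-copper protein peaks at 61 peptide observations in
the 7-day band; the FAD enzymes appear later — candidate diversity grows
with secretome age.

A fully synthetic run (no external data at all):

```bash
mnox simulate -o demo --seed 4          # genome + band report + plate + truth
mnox orfdb demo/genome.fasta -o demo/orfs.faa
mnox map demo/orfs.faa demo/band_report.tsv -o demo/map.tsv
mnox aggregate demo/map.tsv demo/band_report.tsv -o demo/evidence.tsv
mnox assay demo/plate.csv -o demo/assay_out
```

`evidence.tsv` reports exactly the two planted secreted proteins with the
simulated per-time-point totals (`truth.json` holds the answer key), and
the assay command prints the fitted standard curve and the
control-vs-inhibitor t-test.

## Layout

```
src/mnox/
  orfs.py        stop-to-stop ORF extraction, FASTA round-trip
  peptides.py    canonicalization, mapping, control subtraction, aggregation
  annotate.py    best-hit rules, cofactor/CAZy classification, motif scan,
                 candidate-table assembly, BLAST tabular I/O
  assay.py       LBB calibration, rates, normalization, gated statistics,
                 compact letter displays
  simulate.py    synthetic genomes, band reports, plates (seeded)
  datasets.py    bundled curated gel-band dataset
  pipeline.py    end-to-end runs with count-accounted logging
  cli.py         `mnox` subcommand CLI
docs/methods.md  models, assumptions, parameter choices, limitations
```
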