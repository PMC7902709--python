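# Methods

This note records the models, conventions and design choices behind
`mnox`, in the order the pipeline runs.

## Stop-to-stop ORF database

Draft fungal assemblies arrive as contigs without gene models, so the
peptide search space is built gene-agnostically: every maximal translated
segment between two in-frame stop codons, of at least `min_len` amino
acids. Defaults and conventions:

* `min_len = 30` aa — short enough to keep small secreted proteins,
  long enough that random between-stop segments (expected length ≈ 64/3
  codons under a uniform base model) do not dominate the database.
* `frames = 6` by default. Contig orientation in a draft assembly is
  arbitrary and genes lie on both strands; `frames = 3` restricts to
  forward-strand frames for compatibility with forward-only searches.
  The 3-frame output is always a subset of the 6-frame output.
* Segments bounded by a contig edge rather than a stop codon are
  **included** and flagged (`edge5`/`edge3`, in reading direction).
  Excluding them would silently drop genes truncated by assembly
  fragmentation; the flags keep them auditable. A consequence worth
  knowing: even a stop-only sequence yields tiny edge fragments in the
  off-frames at permissive `min_len`.
* Codons containing N (or otherwise untranslatable) become `X`, never a
  stop. `X` is outside the peptide alphabet, so no peptide can ever match
  across an ambiguous position — conservative with respect to false
  peptide provenance.
* Coordinates are 0-based half-open on the forward strand regardless of
  ORF strand; `contig[start:end]` is always the coding segment, and
  re-translating it under the recorded strand/frame reproduces the
  protein. This single convention round-trips losslessly through the
  FASTA header format `orfid|contig|strand|frame|start-end|edge5,edge3`.
* Genetic code: NCBI table 1 (standard); alternative tables are a config
  option.

## Peptide evidence

* **Canonical form.** Peptides and ORF proteins are compared uppercase
  with I replaced by L (`il_equivalence`, default on): leucine and
  isoleucine are isobaric and indistinguishable to the instrument class
  that produces these reports. Canonicalization is idempotent and rejects
  non-residue characters.
* **Mapping** is exact substring search of the canonical peptide in the
  canonical ORF protein. Tryptic termini are validated, not re-searched:
  a terminus is tryptic if preceded by K/R not followed by P, or if it is
  a protein terminus. The default requirement is `partial` (≥ 1 valid
  terminus), mirroring partially-tryptic search settings; `none` and
  `full` are options. Peptides matching no ORF are returned in an
  explicit unmapped set, never dropped.
* **Control subtraction** removes peptide *identities*: a sample
  observation survives iff its canonical sequence does not occur in any
  in-scope negative-control band. This reads the subtraction rule as
  identity removal, not count offsetting, and makes the operation
  idempotent. Scope defaults to global (every control applies to every
  band); a per-band mapping is available, and a band with no in-scope
  control passes through with a logged warning rather than failing.
* **Aggregation** sums observation counts per (ORF, species, time point)
  across biological replicates, reporting detected/analyzed replicates
  (the denominator is the replicate census of that species/time point,
  which must be consistent across its bands), distinct peptides, and
  unique-peptide counts. Shared peptides count toward every ORF they map
  to, with the uniqueness flag preserved — no parsimony collapse, since
  collapsing would hide exactly the ambiguity a reader needs to see.
* **Filtering** retains records with `total_peptides >= min_peptides`
  (default 2). "Per band" is interpreted as the (species, time point)
  aggregate after replicate summation — the same unit the candidate
  tables report, whose totals go as low as 2.

## Annotation transfer

* Hits with `e_value >= 1e-10` are discarded (strict inequality: an
  E-value exactly at the threshold does not qualify).
* Among survivors the highest raw score wins; if its description matches
  a hypothetical marker ("hypothetical", "uncharacterized", "predicted
  protein", case-insensitive substring), the best-scoring informative
  survivor is reported instead; with none left the query is hypothetical.
  Ties break by lower E-value, then subject accession, so selection is
  deterministic and order-invariant.
* Cofactor classes are assigned by the first matching rule of an ordered,
  user-overridable keyword map (specific rules such as "copper/zinc"
  precede generic ones). Cofactor assignment is ultimately a curation
  call; the shipped map covers the classes appearing in Ascomycete
  secretome screens. `redox_active` is simply `cofactor_class != none`.
* CAZy families are table-driven from a curated lookup, never recomputed:
  family classification by automated tools is out of scope and published
  families are typically hand-checked anyway.
* The motif scan accepts named residue patterns (letters literal, `X` any
  residue, `[ABC]` classes) and reports non-overlapping 0-based matches.
  No built-in pattern ships as biologically validated; Cu-site spotting
  is a user-configured convenience, not a claim.
* Standard 12-column BLAST outfmt-6 has neither subject titles nor raw
  scores, so the reader defaults `description := sseqid` and
  `raw_score := bitscore`; extended layouts can name a `stitle` and
  `score` column instead.

## Assay calibration and statistics

* The LBB response is modelled as linear over the calibrated range
  (absorbance = intercept + slope·conc), fitted by OLS to KMnO₄
  standards; concentrations are expressed as Mn(IV) equivalents on the
  permanganate scale. An r² below 0.98 warns but does not fail — a poor
  curve is a bench problem the analyst must see, not a reason to destroy
  a run. Inversion clamps negative concentrations (blank noise) to zero
  with a flag.
* Rates are μM Mn(IV) per μg protein per hour: `conc / (mass × hours)`.
  Published rate magnitudes in this assay family are hard to reconcile
  across loading conventions (per-μg vs per-mg); the unit is stated in
  the column name and the conversion is left to the caller rather than
  guessed.
* Percent-of-control is `100 × value / mean(matrix control)`; the control
  group itself normalizes to mean 100.
* Group comparisons are variance-gated at α = 0.05: Levene
  (median-centered; robust to the non-normality typical of n = 4 assay
  data) or optionally Bartlett decides homogeneity. Homogeneous →
  one-way ANOVA with Tukey–Kramer (scipy's studentized-range
  implementation, valid for unequal n); heterogeneous → Kruskal–Wallis
  with Dunn's rank-based pairwise z-tests, tie-corrected, Bonferroni-
  adjusted over all pairs. Dunn's test is implemented in-package and
  verified against hand-derived rank arithmetic. Two groups dispatch to
  an independent-samples t-test (Welch by default; pooled optional); two
  constant equal groups return p = 1 by convention instead of NaN.
* Compact letter displays are built by insert-and-absorb from the
  adjusted-p matrix; the resulting sharing relation equals the
  non-significance relation exactly, which the tests verify on random
  matrices. All-identical data short-circuits to the trivially
  non-significant result, since every test statistic is degenerate there.

## Synthetic data: what it does and does not emulate

The generators exist so the pipeline's counting rules can be verified
exactly, not to imitate mass spectrometry.

* Background sequence is i.i.d. uniform A/C/G/T — this guarantees
  frequent random stops (3/64 per codon) and realistic ORF *structure*,
  but no codon bias, GC skew or repeats.
* Planted proteins are reverse-translated with random synonymous codons,
  flanked by stop codons, and placed at frame-consistent offsets, so
  stop-to-stop extraction provably recovers them at recorded coordinates.
* Band reports distribute each protein's expected per-time-point total
  multinomially over (replicate, fully-tryptic peptide) cells. Digestion
  follows the common search convention: cleave after K/R not before P,
  up to 2 missed cleavages, 7–40 aa. Real per-band peptide-count
  distributions are not published for this kind of experiment, so
  abundances are caller-supplied parameters, not asserted defaults.
* Contaminants come from a packaged list of invented, tryptic-looking
  decoy peptides (trypsin/keratin-like in spirit, synthetic in sequence).
  Control-band leakage is decided once per distinct peptide at
  `control_leak_rate`; `leak_scope` selects whether only contaminants
  ("contaminants", default) or all sample peptides ("all") are eligible.
  At rate 1 with scope "all", subtraction provably empties the report.
* Plates are the linear model plus Gaussian noise; no spectra, m/z,
  retention times, carryover or edge effects.

Passing tests on these data therefore demonstrate that the *rules* —
extraction, mapping, subtraction, summation, thresholds, best-hit
selection, calibration algebra, gating — are implemented exactly; they do
not validate instrument-level behaviour.

## Problem sizes and determinism

Every stochastic component takes an explicit integer seed
(`numpy.random.default_rng`); identical seeds give byte-identical
outputs, which the golden-file regression test pins down. The shipped
verification runs use 100 × 10-kb contigs for the ORF oracle, a
3-protein / 3-contig genome with 4 replicates for end-to-end recovery,
1,000-instance randomized sweeps for the counting invariants, and 10,000
null simulations (4 groups × n = 4) for the type-I-error check of the
gated omnibus, which is exercised through the same gate code path the
full comparison uses. The acceptance script uses 25 contigs and 4,000
null simulations, sizes at which each quantity is stable to well within
its Monte-Carlo error.

## Known limitations

* No FDR/decoy modelling, no protein grouping beyond the uniqueness
  flag, no spectral quality control — those live upstream in the search
  engine that produced the peptide reports.
* Stop-to-stop ORFs ignore splicing; intron-containing genes appear as
  fragmented or truncated segments, which is inherent to the search-space
  construction, not a bug of it.
* The cofactor keyword map is string matching over free-text
  descriptions; unusual phrasing needs a user-supplied rule.
* The linear LBB model is not validated beyond the standard range; no
  saturation or kinetic models are provided.
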