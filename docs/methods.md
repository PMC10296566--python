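# Methods

## Quantification model

The abundance proxy throughout is the spectral count: the number of peptide
spectrum matches (PSMs) assigned to a protein in one LC-MS run. Counts are
first **total-count normalized** — every run column is scaled so its total
equals the mean of the raw run totals — which preserves within-run
proportions and is idempotent. Normalized runs are then averaged to
condition-level **aPSM** profiles: the arithmetic mean over all runs of a
condition (6 in the default design). A nested variant (technical replicates
first, then biological) is available; it differs only for unbalanced
designs. Total-count scaling is deliberately the simplest defensible
normalization and is isolated behind `quantify.normalize_runs` so an
alternative can be swapped in without touching anything downstream.

## Differential indexes

For a protein with aPSM X and Y in two compared conditions:

* DAve = (X − Y)/(X + Y)/0.5 = 2(X − Y)/(X + Y), bounded in [−2, 2];
  a planted fold change f corresponds to DAve = 2(f − 1)/(f + 1)
  (f = 2 → 2/3, f = 3 → 1; ±2 means presence/absence).
* DCI = (X + Y)(X − Y)/2, an abundance-weighted difference that suppresses
  low-count fluctuations.

A protein is a DEP when |DAve| ≥ 0.2 **and** |DCI| ≥ 2. Both thresholds are
exposed; setting `dci_threshold=0` reproduces DAve-only calling. X = Y = 0
yields DAve = DCI = 0 and never a DEP: absence in both samples is no
evidence. DAve is antisymmetric and scale-invariant; DCI is antisymmetric
and scales as c². In reports DAve is rounded to two decimals; full
precision is kept internally.

Comparison families mirror the study layout: the six BPA+ vs BPA−
comparisons at matched dose/harvest (X = BPA+, so positive DAve = up under
treatment), and four within-BPA+ dose contrasts (highest dose vs each lower
dose at each harvest; X = high dose). Single comparisons on 6-run averages
are intentionally permissive; the **common-trend** step (same direction,
DEP in ≥ min_support comparisons, default all) is the precision mechanism —
on default simulations its full-support set is essentially purely planted
proteins.

## F-ratio screen, clustering, PCA

The retention screen is a per-protein one-way ANOVA on normalized run-level
counts: F = model mean square / error mean square with (g − 1, N − g)
degrees of freedom (default grouping: the 12 condition cells over 72 runs,
df = 11, 60; configurable, e.g. `grouping="bpa"`). A protein is retained
when F ≥ 2 and p ≤ 0.05. Degenerate rows: no variance anywhere → F = 0,
p = 1; zero within-group variance with distinct group means → F = ∞,
p = 0, retained. p-values are raw by design (matching the screen's
definition); a Benjamini–Hochberg adjustment can be applied externally to
the emitted TSV if desired. A linear-discriminant projection is provided
only as a diagnostic (`discriminant_projection`); retention itself is the
univariate F rule.

Hierarchical clustering uses Ward linkage on Euclidean distances between
column profiles, computed on **row-standardized** (z-scored per protein)
matrices by default — the convention of the JMP clustering platform this
emulates, and necessary so that a handful of high-abundance proteins'
replicate noise does not dominate the metric; `standardize=False` gives the
raw-profile variant. Columns are sorted lexicographically before linkage so
the dendrogram is invariant to input column order; export is Newick with
branch lengths = parent height − child height.

PCA operates on condition-level aPSM profiles (conditions as samples,
proteins as features, protein rows centred), full SVD, components ordered
by explained variance.

## PTM occupancy

Modification rates are spectra-level occupancies: modified PSMs divided by
PSMs whose peptide contains the residue (Met for oxidation, Tyr for
nitrosylation) — not distinct-peptide fractions. The pooled rate is exactly
the count-weighted mean of per-condition rates. `contribution_ratio` is the
ratio of modified-PSM counts (undefined when the denominator is zero, and
reported as such). `compare_rates` is a two-sided two-proportion test:
continuity-corrected z-test (via the equivalent corrected chi-square on the
2×2 table) by default, Fisher's exact test as the small-count option.

## Simulator

The generator emulates the statistical structure of the 72-run experiment;
it does not simulate chromatography, spectra, intensities or search-engine
scoring.

* **Design**: 2 BPA arms × 3 doses (0 Gy/0 min, 1.9 Gy/10 min,
  11.3 Gy/60 min) × 2 harvests (6 h, 24 h) × 3 biological × 2 technical
  replicates.
* **Proteome**: 1000 human proteins with log-normal relative abundances
  (log-sd 1.5, ≈ 2.5 decades of dynamic range, typical of EV shotgun data)
  and 20 bovine proteins carrying `contaminant_psm_fraction` (default 0.5)
  of the expected PSM mass, half of it on a single albumin-like protein —
  the serum-albumin-dominated FBS background.
* **Counts**: negative binomial via Gamma–Poisson mixing,
  Var = μ(1 + dμ), dispersion d = 0.005 (Poisson when 0). Technical
  replicates are pure resampling noise at the same expected depth
  (re-injection reproducibility, ≈ 7% CV asymptote); biological replicates
  additionally jitter each human protein's abundance by a log-normal factor
  (sd 0.12) shared by both technical runs of that replicate. This pair
  (d, jitter sd) was calibrated once so that the replicate-agreement
  ordering observed in such experiments — technical R² above biological
  R² — holds robustly: because biological pairs are compared after
  averaging technical runs, the jitter must exceed the averaging gain,
  which a 10% biological CV does not once d ≤ 0.02; 12% is the smallest
  round value that does. The bovine background gets no biological jitter
  (it is shared serum, not cell biology).
* **Planted effects**: `n_dep` (default 50) human proteins get a
  multiplicative fold (default 2) in every BPA+ condition, optionally with
  a per-dose trend factor. Expected totals are not re-scaled after
  planting, so BPA+ runs are ≈ 2.5% deeper; normalization absorbs this,
  which is why recovered DAve sits slightly below the closed form
  (≈ 0.63 vs 2/3 at fold 2).
* **Peptides/PTMs**: each protein has a fixed pool of 8 tryptic-like
  peptides (length 7–21, ending K/R) containing Met and Tyr each with
  probability 0.5; every PSM draws a pool peptide and, if the residue is
  present, a Bernoulli modification flag at the condition's rate —
  Met 0.115 (0.14 at 11.3 Gy, a weak dose trend), Tyr 0.103, matching the
  pooled occupancies 767/6671 and 144/1396. Because Met and Tyr occurrence
  are symmetric by construction, the simulated Met:Tyr contribution ratio
  is ≈ 1.2, not the ≈ 5 of the real data, where far more peptides carry
  Met than Tyr; the ≈ 5-fold figure is exercised as worked-example
  arithmetic on the printed counts instead.
* **Determinism**: one seeded generator drives the count layer; a second
  stream (derived from the same seed) drives the PSM-level expansion, so
  `simulate_counts` is reproducible on its own and
  `aggregate_counts(simulate_experiment(cfg))` equals
  `simulate_counts(cfg)` exactly. Identical config ⇒ byte-identical
  emitted files.

What passing recovery tests show — and what they do not: the simulator
reproduces count overdispersion, replicate nesting, contaminant dominance
and planted mean shifts, so tests demonstrate that the indexes, screen and
clustering recover *those* structures at realistic depths. Real data add
correlated protein covariation, missingness from identification (not just
sampling), shared peptides and search-engine artefacts, none of which are
modelled; passing here does not certify performance on those.

## Numerical and interface choices

* Repeatability R² is the squared Pearson correlation of two count vectors
  over the union of proteins with zeros filled (hence exactly symmetric);
  untransformed counts are used. Technical pairs are the two technical
  runs of a (condition, biological replicate); biological pairs are
  replicate pairs within a condition after averaging technical runs.
* Presence for the frequency filter is aPSM > 0 in ≥ 2 conditions
  (any-evidence threshold).
* Species assignment requires each accession in exactly one FASTA;
  ambiguous or missing accessions are errors — inputs are expected to be
  post-grouping, parsimony-resolved identifications.
* The PSM TSV contract is one row per spectrum with header
  `run_id protein_accession species gene_symbol peptide met_oxidized
  tyr_nitrosylated`; peptides are uppercase, ≥ 6 residues; a modification
  flag without the residue is a parse error naming the line.
* All-zero run columns abort normalization (naming the run); empty PTM
  scopes give rate 0 over 0 counts rather than an error.
* The pipeline summary JSON excludes the output directory and timestamps,
  so its SHA-256 digest is a pure function of parameters + seed.

## Problem sizes

Recovery and structure tests run on the counts layer of the default
conditions (1000 proteins × 72 runs, depth 20 000) over 20 seeds in the
test suite and 10 seeds in `scripts/acceptance.py`; the acceptance script
additionally runs one full PSM-level pipeline (~1.5 M spectra). The whole
suite completes in well under a minute on one CPU, the acceptance script in
a few seconds.

## Known limitations

* No FDR modelling, protein grouping or shared-peptide handling; the
  pipeline starts from disambiguated PSM tables.
* DAve/DCI carry no significance statement (none is defined for them);
  error control comes operationally from the joint thresholds and the
  common-trend support requirement.
* The two-proportion test behind PTM contrasts is a choice, not a
  reconstruction — the study did not name its test, and its printed
  p-values are not reproduction targets.
* Ward clustering of run profiles assumes complete matrices; missing runs
  must be dropped from the design, not imputed.
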