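# Methods

This note documents the statistical procedures implemented in
`metabotype`, the assumptions behind them, the defaults that matter, and
what the synthetic-data generators do and do not emulate.

## Scope and data model

The package analyzes multi-batch untargeted metabolomics screens of
cultured cell lines measured by flow injection (one spectrum per
injection, no chromatography). The central container is the `IonTable`:
a samples × ions intensity matrix with per-sample acquisition metadata
(cell line, batch, injection time in minutes, confluency, QC flag,
replicate index) and per-ion annotation (m/z, candidate molecular
formulas). All artifacts are modeled as multiplicative — ionization and
matrix effects scale signals rather than shift them — so every
correction operates on log-transformed intensities internally and
exponentiates on output. Zero intensities are treated as missing,
imputed per ion with half the minimum positive value for the duration
of a correction, and restored as zeros afterwards.

## Injection quality control

The total ion current (TIC) of an injection summarizes sample amount
and instrument response; extreme values indicate failed preparation or
injection. An injection is removed when its log-TIC deviates from the
cohort median by more than `k` robust standard deviations
(MAD × 1.4826, default `k = 4`). If the spread is degenerate (MAD = 0),
any deviation at all is flagged. Cell lines whose injections are all
removed are dropped and reported.

## Normalization stacks

Three method classes address three artifact sources, composable in the
fixed order sample_variance → signal_drift → batch_effect, at most one
method per class:

* **Sample variance** — per-sample scale differences (cell amount,
  pipetting, injection volume). Scaling methods divide each sample by a
  statistic (geometric mean, median, standard deviation, MAD, TIC sum,
  or measured confluency) and re-multiply by the cohort median of that
  statistic, which makes them idempotent for data-derived statistics.
  Confluency scaling is the exception: the statistic is metadata, so a
  second application rescales again; suspension cultures (flagged via an
  optional `is_suspension` column) are left unscaled with a warning.
  Quantile normalization replaces each sample's sorted intensities with
  the across-sample mean quantile profile (tied ranks receive the
  averaged profile value). PQN divides each sample by the median of its
  ion-wise quotients against the median reference spectrum; it is only
  approximately idempotent because the reference changes.
* **Signal drift** — chronological trends over the injection sequence.
  A per-ion trendline over injection time is estimated by a running
  median (window 120 min by default, mirror-padded at the run
  boundaries so monotone trends are estimated without edge bias) or by
  locally weighted regression (LOESS, 0 robustifying iterations, or
  robust LOESS with 4). Intensities are divided by the trend and
  re-multiplied by the ion's overall median.
* **Batch effect** — systematic per-batch, per-ion location/scale
  shifts. The adjustment standardizes each ion against the
  batch-size-weighted grand mean and pooled variance, estimates
  per-batch locations and scales, shrinks them by parametric empirical
  Bayes (normal prior on locations, inverse-gamma on scales,
  moment-matched hyperparameters, iterated to convergence), and returns
  batch-adjusted data on the intensity scale. `empirical_bayes=False`
  disables shrinkage, in which case every batch is matched exactly in
  per-ion mean and variance (useful as a closed-form check; with
  shrinkage the residual batch-mean gap equals the sampling noise of
  the batch means, by design). Batch parameters can be estimated on QC
  samples only and applied to all samples.

Two published normalizers (two RUV variants and QC-based support-vector
drift correction) are exposed as named plug-in slots with the stack
interface but no bundled implementation; external implementations can
be attached with `register_normalizer`.

## Reproducibility criteria

Normalization quality is scored on QC cell lines replicated in every
batch, with five criteria, each scaled so the un-normalized table is
exactly 1 and smaller is better:

1. **Batch scoring FC** — draw two disjoint sets of 6 replicates of one
   QC line, compute per-ion |log2 fold-change| between the set means,
   pool over 1,000 draws, and report the 95th percentile (the threshold
   at a 5% false-discovery level for calling a fold-change real).
   Disjointness is enforced; the resampling seed is explicit, and a
   Monte-Carlo block standard error is available.
2. **FC reproducibility** — per batch, the per-ion log2 fold-change
   vector between the two QC lines; report the mean pairwise Euclidean
   distance over batches. Log2 fold-changes are used (raw fold-changes
   are exposed nowhere; the log choice makes distances symmetric in the
   two lines).
3. **FC reproducibility, amino acids** — the same restricted to ions
   whose candidate formulas exactly match one of the 20 proteinogenic
   amino acids (leucine/isoleucine collapse to one formula).
4. **Interbatch distance** — PCA on log, ion-centered intensities; per
   batch a Gaussian is fitted to the first 2 PC scores; report the mean
   pairwise Bhattacharyya distance
   BD = ⅛ Δμᵀ Σ̄⁻¹ Δμ + ½ ln(det Σ̄ / √(det Σ₁ det Σ₂)), Σ̄ = (Σ₁+Σ₂)/2,
   with a small diagonal added to near-singular covariances.
5. **KS rate** — for every ion and batch pair, a two-sample
   Kolmogorov–Smirnov test on one QC line's intensities; report the
   fraction of tests with p < 0.05. Batch pairs are aggregated by an
   unweighted mean; batches with fewer than 2 QC replicates are skipped
   with a warning.

A caveat worth stating: the two overlap-based criteria (interbatch
distance, KS rate) can be "improved" by anything that blurs batches,
including pure noise. The fold-change criteria cannot, which is why the
benchmark reads all five jointly and the test suite asserts the
no-spurious-improvement property only for the fold-change criteria.

## Pathway curation, mapping and PC1 activity scores

Pathway databases define substantially overlapping pathways. Before
mapping, every reaction that appears in two or more pathways is deleted
from all of them together with its substrates and products; a
metabolite survives in a pathway only if a remaining reaction of that
pathway still touches it, and emptied pathways are dropped. Ions are
matched to pathway metabolites at the formula level, so structural
isomers are retained and one ion may feed several pathways. A pathway
is scoreable only with at least 4 mapped ions of distinct m/z.

When flux through a pathway changes, most intermediates shift with a
coherent sign, because enzymes typically operate near their substrate
affinity and far from saturation; strong but isolated changes instead
indicate interruption or local regulation. The pathway activity score
captures the coherent component: member-ion intensities are
log-transformed and z-scored per ion across all replicate-level samples
(so abundant ions do not dominate), PCA is fitted jointly on
replicates, and the first principal component score is the replicate's
activity. The component sign is intrinsically arbitrary; it is fixed by
requiring the sum of loadings to be positive (tie broken by positive
correlation with the mean member-ion level), which makes scores
reproducible across runs but does not guarantee that a higher score
means higher flux — pathways whose ions respond mostly inversely to
flux (the minority-exponent case) have reversed scores, and the flux
validation report flags them. Replicate scores are averaged per cell
line and then each pathway's scores are divided by their maximum
absolute value, giving comparable scores in [−1, 1] (scaling after
averaging).

## Metabolic typing and the branch association scan

Cell lines are clustered by Ward's method on Euclidean distances
between pathway-score vectors; input rows are sorted lexicographically
first so the dendrogram is deterministic. The two major types are the
top split (type numbers ordered by descending cluster size).

The association scan does not commit to one cut: it iterates over every
internal branch covering at least 10% of the cohort (ceil(0.10 × n);
18 cell lines for a 180-line screen; the root is excluded because its
complement is empty, while both root children qualify if large enough)
and tests each (branch, trait) pair:

* categorical traits: one-sided upper-tail hypergeometric P(X ≥ k) for
  each trait level against the branch, keeping the minimal-p level.
  Because the minimum over L levels is anticonservative as a pooled
  p-value, the scan applies a Šidák adjustment 1 − (1 − p)^L before
  pooling; without it, null-trait simulations produce spurious
  discoveries and the π₀ estimate collapses. For two-level traits the
  direction is +1 when the recognizably "positive" level (true/1/yes/
  pos; deterministic fallback otherwise) is the enriched one, −1
  otherwise; multi-level traits report +1 for the winning level.
* continuous traits: two-tailed pooled-variance t-test of the branch
  against all other cell lines with data; direction is the sign of the
  mean difference. Missing values shrink the background per trait;
  untestable pairs are skipped with machine-readable reasons.

All p-values are pooled into one global q-value computation
(Storey–Tibshirani): π₀(λ) = #{p > λ}/(m(1 − λ)) on
λ ∈ {0, 0.05, …, 0.90}, smoothed by a cubic smoothing spline (GCV);
π₀ is the fit at λ = 0.90 clipped into (0, 1], and
q_i = min_{t ≥ p_i} π₀ m t / #{p ≤ t}, monotone in p. On a pooled
family that mixes discrete hypergeometric and continuous t p-values the
π₀ estimate is conservative-leaning but not exactly 1 even under the
null; the false-discovery calibration is therefore verified directly by
simulation in the tests. Each significant record carries a signed q
(direction × q) for visualization.

## ¹³C tracing

A metabolite with n carbons has isotopologues M+0 … M+n; the mass
distribution vector (MDV) is the unit-sum fraction vector. Raw
intensity vectors are corrected for natural ¹³C abundance
(p = 0.0107): the correction matrix has entries
C[j, i] = Binom(n − i, p) evaluated at j − i (tracer-labeled positions
are fully ¹³C; the rest carry natural abundance), and the corrected MDV
solves the non-negative least-squares deconvolution, renormalized to
unit sum. Non-negativity (rather than plain matrix inversion) prevents
negative fractions on noisy vectors. Only carbon is corrected; at unit
resolution and for the ion panels considered this dominates the
isotope pattern. The fractional contribution is FC = (Σ i·mᵢ)/n — the
fraction of the metabolite's carbon derived from the labeled tracer —
and the fractional difference Δ is the type-1 mean minus type-2 mean of
per-cell-line FC (cell-line means over replicates first, so lines weigh
equally regardless of replicate count), ranked descending. Tracers are
always stratified, never pooled.

Lipidomics summaries operate on species-level concentrations
(normalized upstream to class internal standards): per-sample class
totals (an absent class is missing, not zero), the unsaturation index
as the concentration-weighted mean of double bonds per acyl chain
(chains per class: lyso 1, diacyl and sphingolipid 2, TAG 3,
cardiolipin 4), and the chain-length concentration profile. Group
comparisons use two-sided pooled t-tests per class, with
Benjamini–Hochberg adjustment across the per-species panel.

## Enrichment and dependency comparisons

* **Tail enrichment**: the top and bottom ⌈0.25 N⌉ items of a ranked
  list (the fraction is a package choice, exposed as a parameter);
  per set and tail, an upper-tail hypergeometric p on the overlap,
  BH-adjusted within each tail family (global Storey pooling of the two
  families is available for consistency with the scan). Ties at a tail
  boundary are resolved by item id and flagged.
* **Group comparison**: classical two-sided unpaired pooled-variance
  t-test per gene or drug, with group means reported on the dependency
  scale (CERES-style scores: common-essential genes have median −1, so
  more negative means more essential).
* **Gene ranking**: point-biserial correlation between each gene's
  dependency scores and the binary type coding (type 1 = 1), ranked
  descending; positive values mean less essential in type 1.
* **Pre-ranked GSEA**: weighted Kolmogorov–Smirnov running sum — hits
  increment by |score|^w (w = 1 by default) normalized over hits,
  misses decrement by 1/(N − K); ES is the maximal signed deviation.
  The null permutes gene labels (equivalently, random member positions
  of the same size; 1,000 permutations by default); NES is ES divided
  by the mean |ES| of same-sign permutations, and permutation p-values
  use the add-one rule so they are never 0, with BH adjustment per sign
  family.

## Synthetic data: what it emulates, and what it does not

The generators produce every input the pipeline consumes, with ground
truth returned for parameter-recovery testing:

* **Flux/metabolite panel** — ion level
  L = a·v^γ·exp(ε), ε ~ N(0, σ²): a monotone power-law link between a
  pathway's latent flux v and its intermediates, with per-ion response
  exponents γ ~ Uniform(0.3, 1) and a ≤ 20% minority negated to emulate
  incoherent intermediates. Condition-to-condition fluxes are
  log-normal with log-sd 1.5 — a deliberately diverse flux panel, as a
  validation dataset requires (with a narrow flux range the weakest
  exponents are not resolvable above noise). Default noise σ = 0.2.
* **Cell-line screen** — defaults mirror the screen design the package
  targets: 180 cell lines in 7 batches, 6 measurements per line, two QC
  lines with 6 replicates in every batch (1,164 injections), 300 ions
  in 10 pathways (the ion count is reduced relative to a real
  ~1,800-ion screen purely to keep simulations light; the first ~19
  ions carry amino-acid formulas so the amino-acid criterion is
  populated). Biology: type-dependent pathway fluxes (half the pathways
  shifted by 1.0 log-unit between the two planted types, alternating
  sign) through the same power-law link, replicate noise σ = 0.25.
  Artifacts, all multiplicative: per-batch per-ion batch effects with
  batch-level magnitude 2–3× and per-ion log2 jitter (sd 0.5) — the
  jitter matters, since a batch effect common to all ions would be
  removed by sample scaling alone; smooth cubic drift of injection time
  with per-ion amplitude up to 2-fold; per-sample size factors with
  log-sd 0.25, calibrated so that each artifact class is recoverable by
  its corresponding corrector class (per-ion batch effects cancel
  exactly between two cell lines measured in the same batch, so the
  two-line fold-change criteria are improvable only by the
  sample-variance class under this model).
* **Trait tables** — null categorical (3 levels) and continuous traits
  independent of the types; planted continuous traits shifted by
  `effect` sd units in type 1; planted categorical traits with a
  log-odds shift (`effect = inf` makes the trait a deterministic copy
  of type membership).
* **Isotopologue vectors** — a two-population labeling mixture (labeled
  fraction with per-position enrichment 0.99, unlabeled rest) whose FC
  equals the planted value exactly (for FC* above the enrichment the
  whole population is labeled at enrichment FC*), convolved with the
  natural-abundance binomial and multiplied by per-isotopologue
  log-normal noise.

Not emulated: raw mass spectra, isotope fine structure, adducts,
chemical backgrounds, non-multiplicative artifacts (detector
saturation, additive carryover), missing-not-at-random dropout, and
correlated biology across pathways. Passing tests therefore demonstrate
that the algorithms recover the structure they assume, at realistic
magnitudes — not that the assumed structure exhausts real screens.

## Numerical choices and problem sizes

Intensity logs use half-minimum imputation for zeros; PCA is computed
by SVD on centered matrices; covariances in the Bhattacharyya distance
get an εI ridge only when near-singular; p-values are floored at
1e-300 to stay in (0, 1]; hypergeometric tails use survival functions
rather than sums. The test suite and the acceptance script run
reduced problem sizes chosen for quick iteration — e.g. 120–180
synthetic cell lines, 150–300 ions, 1,000 traits, 10 calibration
seeds, 50 q-value simulations — all package choices that keep every
check end-to-end.

## Known limitations

* The branch scan's pooled family mixes discrete and continuous tests;
  π₀ is estimated on the pool, and calibration is demonstrated by
  simulation rather than guaranteed analytically.
* The ComBat-style adjustment assumes log-normal intensities and
  location/scale batch effects; rank-distorting batch effects are out
  of its reach (quantile normalization upstream mitigates this).
* The confluency scaler trusts metadata and is not idempotent.
* Natural-abundance correction covers carbon only and assumes the
  tracer-labeled positions are fully enriched.
* The plug-in normalizer slots (RUV, QC-SVR) ship without reference
  implementations.
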