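# Methods

This note documents the models, numerical choices and limitations of
`driftqc`.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

A `FeatureTable` holds an `n_samples x n_features` matrix of non-negative
abundances (unitless peak areas; the field reports no absolute unit for
untargeted data) with NaN marking *not detected* — distinct from a
measured zero, because the presence filters count detections.  Rows are
ordered by a global injection order; within that order each batch is one
contiguous block.  Sample roles are `QC` (repeated pooled sample),
`BLANK` (extraction solvent), `EXPERIMENTAL`, and `NO_INJECTION`
(mobile-phase-only runs, which appear in worklists but never carry a
matrix row and are therefore not part of a table).  The opening QC block
of each batch is flagged `is_conditioning`; conditioning injections
stabilise the system and are excluded from every QC statistic
(presence denominators, RSD, correction anchors).

The internal-standard panel is five isotope-labelled compounds spanning
the reverse-phase retention window (0.70–34.54 min) and six
chromatographic peaks (the lysophosphocholine elutes twice).  IS
channels are spiked at fixed concentration, so in the generator they
carry no biological variation and their per-sample sum is a pure
instrument-performance monitor.

## Synthetic cohort generator

The generator emulates a two-batch serum study:

x[s, f] = comp[subject(s), f] · β[f, b] · g[f, b](t_s) · L[s, f] · e[s, f]

* **Worklist** — per batch: 3 no-injection runs, 3 solvent blanks, 10
  conditioning QCs, then one QC before every 5 experimental samples, a
  closing QC and 3 final no-injection runs; 82 experimental samples per
  batch by default.
* **Composition** — per-feature mean abundance μ_f is log-normal
  (log-mean 11, log-sd 1); subjects vary log-normally around μ_f with
  log-sd 0.4 (typical between-subject spread for serum metabolites); the
  QC composition is the pooled mean of the batch-1 experimental
  baselines, mirroring a QC pooled from the first batch's samples.
* **Batch factors** — β[f, 1] = 1; later batches draw log-normal factors
  with log-sd 0.15 (a ±15% typical response shift after source
  cleaning).
* **Drift** — g[f, b](t) = exp(a·t + c·(1 − exp(−t/τ))) with t the
  within-batch injection index, a ~ N(0, 0.004), c ~ N(0, 0.35),
  τ = 20 injections.  g(0) = 1, strictly positive, smooth; the two terms
  give slow monotone trends plus a faster early-batch transient.  The
  magnitudes were chosen so that pre-correction within-batch QC RSDs
  fall in the ~10–30% range reported for internal standards in real
  multi-batch serum runs; smaller drift would be invisible next to the
  ε = 5% tolerance tube of the correction itself.
* **Noise** — multiplicative log-normal with mean 1 and CV 10%
  (2% in drift-isolation tests), independent per cell.  The generator
  has *no* shared per-injection efficiency component, so IS-sum and TUS
  normalization cannot help on synthetic data — they can only be tested
  for "no harm".
* **Missingness** — detection-limit (MNAR) dropout: cells in the lowest
  5% quantile of realized abundances go missing with probability 0.8.
* **Low-IS samples** — a configurable subset of experimental samples has
  its IS channels multiplied by 0.1, non-IS channels untouched
  (emulating depressed IS response with normal biological signal).
* **Replicates** — n pairs of slots in batches 1 and 2 share one subject
  composition; their post-correction agreement validates batch
  integration.

Everything systematic (μ, β, drift curves, low-IS ids, background
features, pairs) is emitted as `GroundTruth` for parameter-recovery
tests.  Generation is a pure function of the spec including its seed.

What a green test on this generator does **not** establish: behaviour
under retention-time misalignment, ion suppression, correlated noise,
non-multiplicative drift, or vendor peak-picking artefacts — none of
which are simulated.

## Filter cascade

Order: blank filter → presence filter → kNN imputation → QC-RSD filter,
then the sample-level screens (low-IS flagging, TUS outlier exclusion).
All inequalities are strict, taken literally from the conventional
thresholds: presence > 50% of counted QCs **and** > 75% of experimental
samples; QC RSD < 30%.

* The blank filter defaults to `any_detect` (a feature seen in any blank
  is background); a `fold_ratio` mode (median experimental < 3× median
  blank) is offered because strict any-detection is often too
  aggressive.
* kNN imputation (k = 5): Euclidean distance over autoscaled complete
  features among experimental + counted-QC rows; each missing cell takes
  the mean of its k nearest donors that have the feature.  Only "the kNN
  algorithm" is conventionally specified; these defaults follow common
  metabolomics practice and are exposed in the config.
* QC RSD uses the sample SD (n − 1); a zero mean or fewer than two
  usable QC values yields +inf (the feature fails any RSD filter).
* The TUS outlier screen removes experimental samples outside
  mean ± 3 SD of their own batch (QCs are never removed); a zero SD
  removes nothing.
* Low-IS flagging sums all IS channels (mix-level, not per-compound) over
  experimental samples of all batches pooled and flags samples below
  mean − 2 SD; flagged samples are reported, not deleted.

## Normalization

All four corrections are multiplicative, hence scale-equivariant.

**IS-sum / TUS** divide each row by its IS sum (or total useful signal,
the sum over non-IS features) and rescale by the cohort median so
corrected values stay on the original intensity scale — without the
rescaling, cross-method RSD comparisons would be meaningless.

**QC-SVRC** fits, independently per feature and batch, an RBF-kernel
ε-SVR of counted-QC abundance against injection order.  Numerical
choices:

* The within-batch injection order is rescaled to [0, 1].  With raw
  injection units and QCs every 6 injections, every γ in the
  2⁻³…2⁶ grid would give a near-diagonal kernel
  (exp(−0.125·6²) ≈ 0.01) — no smooth regime at all; on the unit
  interval the same grid spans length scales from roughly the whole
  batch down to ~1/8 of it, a sensible model-selection range.
* ε = 0.05 and C = 0.5 of the per-feature per-batch QC median, keeping
  the fit unit-free; γ is chosen by leave-one-out CV minimising RMSE,
  ties going to the smaller (smoother) γ.
* The correction is x' = x · median(QC)/d(t).  Non-positive drift
  predictions (possible when extrapolating at batch edges) fall back to
  the prediction at the nearest QC injection, then to the QC median
  (no correction) — ratios must stay positive.
* Because each batch is anchored to its **own** QC median, QC-SVRC
  deliberately leaves inter-batch offsets in place; drift removal must
  therefore be judged by within-batch QC RSD.  The ε-insensitive tube
  also bounds what correction can achieve: residual drift up to ~ε
  remains even on noise-free data, so replicate pairs corrected with the
  default tube agree to ~2ε, and the exact-recovery property only
  emerges as ε → 0 (both are tested).
* Fits with fewer than 5 usable QC points per batch are refused rather
  than silently extrapolated.

**QC-norm** divides each feature in batch b by
r_{f,b} = median(QC_{f,b}) / median(QC_f pooled).  "Pooled" means the
median over all counted QC injections of all batches (not the median of
batch medians; the two coincide when batch QC counts are equal).  The
correction is exact — post-correction batch medians are equal to
machine precision — and idempotent (all r = 1 on a second pass).

`run_pipeline` composes methods in order and re-applies the RSD < 30%
filter after each one; blank rows are dropped at entry because ratio
corrections are undefined for rows without IS or biological signal.

## Assessment

* **PCA** on autoscaled data (zero-variance features dropped with a log
  line), scores by SVD, sign fixed by making each component's
  largest-magnitude loading positive so runs are reproducible.
  Replicate distances are measured in the first 2 score dimensions (the
  space practitioners plot); configurable.
* **Replicate test**: Euclidean pair distances before vs after, two-sided
  paired t-test; identical score sets report t = 0, p = 1.  Distances
  are non-negative, so normality is approximate at best — a Wilcoxon
  signed-rank alternative is available behind a flag.
* **Ward HCA** of the replicate samples only; a pair "clusters" when its
  two members are each other's first merge partner (immediate siblings).
  The full merge list is returned so proximal-node near-misses can be
  reported without being counted.
* **Group comparison**: two-sided Mann–Whitney U per feature, exact when
  both groups ≤ 8 and tie-free, otherwise the normal approximation with
  tie and continuity correction.  No multiplicity correction by default
  (matching common single-study reporting); Benjamini–Hochberg is
  available behind a flag for discovery-style use.

## Pipeline and reproducibility

`PipelineConfig` carries every threshold with the conventional defaults
and a mandatory seed; `run_all` executes the stages in order, writes
every intermediate table and report as TSV/JSON with fixed numeric
formatting, and is bit-for-bit deterministic for a fixed config.  The
multi-seed acceptance tests run at the study's QC density (82
experimental samples per batch — leave-one-out γ selection needs the
full ~18 counted QCs per batch to be stable) but with 40–80 features
instead of 400, since the tested per-feature statistics do not depend on
the feature count; the drift-removal check runs once at the full 400.

## Known limitations

* Single-analyte (one polarity) tables; acquisition modes are handled as
  separate datasets by construction.
* No LOESS/spline drift correction and no empirical-Bayes batch
  correction — only the four QC-anchored methods above.
* The paired t-test on distances is reported as-is even for small pair
  counts; p-values there are indicative, not confirmatory.
* IS-sum normalization inflates QC RSD slightly (~1–2 points at 10%
  noise) on synthetic data because IS channels carry independent noise
  and no shared efficiency component exists to be removed; this is a
  property of the simulated world, not of the method on real data.
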