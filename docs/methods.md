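# Methods

This note documents the statistical models implemented in `ovorisk`, the
defaults they ship with, and the assumptions behind the synthetic data the
tests run on.

## Concentration model and units

All tissue concentrations are carried in mg/kg dry weight (identical to
µg/g dw). Digest conversion follows `Ct = Cs·Vs / Wt` with the solution
concentration `Cs` in µg/L, the made-up digest volume `Vs` in L and the dry
sample mass `Wt` in g; the typical preparation (0.5 g digested, made up to
50 mL) means 1000 µg/L in solution corresponds to 100 µg/g in tissue.
Unit handling is centralized: the only other conversion in the package is
the reference-dose rescaling µg/kg/day → mg/kg/day inside `compute_thq`.

Non-detects (left-censored cells below the limit of detection) are carried
as explicit flags, never as silent zeros. Three substitution policies are
exposed — `zero`, `half_lod` (LOD/2, needs an LOD map) and `drop` — because
summary statistics of censored environmental data depend materially on this
choice and the convention used for any given published table is usually
unstated. The default for risk scoring is `zero`: it can only under-state
the hazard quotient, which is the conservative direction for a bound of the
form "TTHQ stays below 1". Summaries computed under `drop` report the
reduced per-cell `n` rather than imputing.

## Hazard quotients

`THQ = (EF·ED·IR·C)/(BW·AT·RfD)` per metal; `TTHQ` is the plain sum and
the risk flag is `TTHQ > 1`. Defaults (lifetime adult exposure):

| parameter | default | units |
|---|---|---|
| EF | 365 | days/year |
| ED | 75.88 | years |
| IR | 0.0328 | kg eggs/person/day |
| BW | 70 | kg |
| AT | 365 × 75.88 | days |

With these defaults EF·ED/AT = 1 exactly, so THQ reduces to
`C·IR/(BW·RfD)`; the test suite asserts this cancellation to machine
precision. The registry ships the twelve standard oral reference doses
(µg/kg/day): Al 1000, Cr 1500, Mn 140, Co 43, Ni 20, Cu 40, Zn 300,
As 0.304, Cd 1, Sn 0.3, Hg 0.571, Pb 3.57.

Exposure uses the edible fraction only (shell rows are excluded); the
default combination of white and yolk is their unweighted mean, with a
mass-weighted option (`white_mass_fraction`) for users who prefer a
dry-mass basis. Concentrations enter on the dry-weight basis as measured
while IR is a fresh-weight intake rate; this mismatch is inherited from
standard practice with such tables and a moisture-correction factor is
available but off by default. Metals with no concentration column are
skipped with a warning, never imputed, and the metal set entering the sum
is explicit configuration: summing all nine metals with reported
concentrations (including Ni and Pb) yields totals around 0.32 for typical
mean diets, while the subset excluding those two reproduces per-egg totals
in the 0.06–0.23 range; both views are computed in the tests.

## PCA

Fitted by SVD of the centered matrix; the default also scales columns to
unit variance (ddof = 1), the usual auto-scaling when element magnitudes
span five orders of magnitude (Ca in shell ~10⁵ vs REEs ~10⁻²). Eigenvalues
are score variances; variable "contributions" are `100·loading²` per
component (loadings are unit-norm, so each component's contributions sum to
100), with the `100/p` uniform reference line exported alongside. A
zero-variance column under scaling is a named error rather than a silent
NaN. Component signs are fixed by forcing each component's
largest-magnitude loading positive, making all outputs deterministic.

Outlier trimming replaces a visual score-plot judgement with an explicit
rule: squared Mahalanobis distance on the first `dims` (default 2) score
dimensions — diagonal covariance, so `d² = Σ tₖ²/λₖ` — against the
χ²(dims) quantile (default 0.999). The χ² reference is only calibrated for
roughly elliptical score clouds; on strongly clustered data (three egg
parts) it is still effective for gross outliers but the quantile should not
be read as an exact false-positive rate. A manual id-list override exists
for reproducing any given hand trimming.

## Sparse PLS-DA

The discriminant engine is written from scratch (NIPALS), with
scikit-learn used in the tests only as an independent PLS2/PCA oracle.

* Coding: Y is the one-hot class indicator, column-centered. X is
  auto-scaled (center + unit variance, ddof = 1); columns that are constant
  within a training fold get scale 1 and therefore zero weight influence.
* Per component: `u` is initialized from the dominant singular direction of
  `XᵀY` (the deterministic, init-insensitive choice), then the NIPALS loop
  alternates `w ∝ Xᵀu`, soft-thresholding, `t = Xw`, `c ∝ Yᵀt`, `u ∝ Yc`
  until `w` is stable (tolerance 1e-12, cap 10⁴ iterations — the cap
  matters for near-degenerate eigengaps, where loose iteration caps are the
  dominant source of disagreement between implementations).
* keepX: the weight vector is soft-thresholded by its (keepX+1)-th largest
  absolute entry, leaving exactly keepX nonzero weights, then renormalized;
  keepX = p reproduces unpenalized PLS2-DA exactly (the oracle equivalence
  is asserted to 1e-6).
* Deflation: X is deflated by regression on its scores; Y is not deflated.
  Because the deflated X is orthogonal to all earlier scores, the
  accumulated regression coefficients — and hence predictions — are
  unchanged by Y deflation, so omitting it is a simplification, not an
  approximation.
* Prediction rules: `max` (argmax of the predicted dummy response),
  `centroid` (nearest class centroid in score space) and `mahalanobis`
  (nearest centroid under the pooled within-class score covariance, with a
  tiny ridge for singular folds). Distance ties are broken toward the first
  class in sorted order, with a warning. The max rule can err on 3-class
  boundaries when the latent space has fewer dimensions than would linearly
  separate the dummy responses; the centroid rules are the robust default.
* Tuning: repeated stratified cross-validation (default 5 folds × 10
  repeats) over a grid of components {1,2,3}, a keepX ladder
  {1,…,10,15,17,20,30,50} applied to every component, and all three
  distances. Scaling and selection are refitted inside each training fold
  (no leakage); per keepX one model is fitted at the maximal component
  count and truncated, which is exact because components are nested. The
  selection criterion is minimum mean BER (the unweighted mean of
  per-class error rates, insensitive to the 55:15 class imbalance), ties
  broken toward fewer components, then smaller keepX, then the distance
  order max/centroid/mahalanobis.
* Held-out evaluation: shuffled stratified 70/30 split, seeded; the report
  carries the confusion matrix, accuracy, and sensitivity/specificity
  (first-class recall / second-class recall for two classes,
  macro-averaged for more).

## Synthetic-data generator

The generator emulates the study conditions the analysis assumes: 70 eggs
(55 home/backyard, 15 commercial) × three components × the 64-element
panel. Its defaults are fixed once and are not tuned per experiment.

* **Marginals.** Lognormal per (element, part, system) — concentrations are
  positive and right-skewed. Each cell is parameterized by its target mean;
  the log-scale sigma is solved from a reported min–max envelope where one
  exists (the log range spans 2 × 2.5758 sigmas, putting ≈99% of the mass
  inside), from a one-sided solve when only a maximum is reported (Cr, Mn),
  and defaults to a geometric SD of 1.8 otherwise. Elements reported only
  as a group-level mean (REEs, TCEs, PGEs, transition/post-transition
  metals, Th) share that mean uniformly.
* **Panel fill-in.** Three panel members (Fe, Se, Sb) and a few shell cells
  have no reported values at all; they receive part-uniform means at
  plausible food-matrix magnitudes so that no unreported discriminative
  structure is invented. All assumed entries are marked in
  `data/calibration.yaml`.
* **Rearing-system effects.** Where per-system means are reported (Al, Cr,
  Mn, Cu, Zn, Cd, Hg) they enter as multiplicative factors — the system
  mean over its egg-count-weighted pool — so the pooled mean stays on
  target. On top of that, `inject_structure` shifts 17 marker elements by a
  configurable standardized log-scale difference (default 0.5 SD, the
  regime producing solid-but-imperfect discrimination around 80–85%
  held-out accuracy) and can rebuild Cu as an almost perfect negative
  copula partner of Mg. Block loadings act on the latent Gaussian, so they
  set rank (Spearman) correlations; the lognormal transform attenuates
  Pearson correlations below the latent value.
* **Censoring and outliers.** Non-detects are realized by flagging cells
  whose latent normal score falls below the nd-rate quantile (0.05 for Mn
  and Cr, 0.02 for REE/TCE/PGE groups), which makes the per-element ND
  fraction converge to the configured rate; per-element LODs are recorded
  for half-LOD substitution. Three outlier samples (rows) are injected at
  +10 SD on 8 random elements each — gross contamination-style artifacts
  that the score-space flagging rule recovers exactly.

What passing tests on this generator do **not** show: real ICP-MS data have
instrument drift, matrix effects, correlated measurement error and a dense,
unknown inter-element covariance; the generator realizes only the sparse
correlation blocks described above. Perfect egg-part classification
transfers to real data only insofar as the macro-element part contrasts
(Na, K, Ca, Mg, P) are as large as the calibration targets suggest;
rearing-system accuracy depends directly on the assumed 0.5 SD marker
shift.

## Pipeline

`reproduce()` runs generate → summarize → PCA (full) → outlier flagging →
PCA (trimmed) → risk → egg-part PLS-DA → rearing-system PLS-DA (eight
stages), writing plain CSV/JSON artifacts plus a manifest with the package
version, seed, config echo and SHA-256 of every artifact. Stage outputs are
pure functions of (input, config, seed): rerunning with the same seed gives
bit-identical hashes. The trimmed PCA consumes exactly the outlier stage's
report; the risk stage intentionally uses the untrimmed table (trimming is
a chemometric step, not an exposure decision). Chemometric stages default
to fixed model configurations; CV tuning is opt-in (`tune: true`) since the
full grid is ~45× the cost of a single fit per fold.

## Problem sizes and determinism

Default analyses run at the study scale (210 rows × 64 elements) and
complete in well under a second; calibration checks use 5000 eggs. Every
random operation takes an explicit seed (`numpy.random.default_rng`), and
fixed-seed runs are bit-reproducible, including cross-validation folds and
train/test splits.

## Known limitations

* The PCA χ² outlier cutoff assumes approximately Gaussian scores; see
  above.
* The per-component keepX grid is applied uniformly across components
  during tuning (one budget per grid point), a deliberate simplification
  of per-component ladder search; arbitrary per-component budgets are
  supported at fit time.
* BER is estimated by pooling fold predictions within a repeat and
  averaging over repeats; with 15 commercial eggs the commercial-class
  error rate is quantized in steps of 1/15 per repeat.
* The dry-weight/fresh-weight basis mismatch in THQ is reproduced as-is by
  default (see Hazard quotients).
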