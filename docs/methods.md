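# Methods

## Model

Two regions of interest (ROIs) X and Y contain m and n voxels whose
recorded series are stacked into one vector Z_t ∈ R^(m+n) (X voxels first).
The package fits the order-1 vector autoregression

    Z_t = B Z_{t−1} + E_t,

where B is an (m+n)×(m+n) coefficient matrix and E_t white Gaussian noise.
Entry b_ij is the weight with which voxel j at time t−1 predicts voxel i at
time t: rows receive, columns send.  B tiles into four coupling blocks,
named predictor-first — B_xx and B_yy within-region, B_yx (Y→X, rows X)
and B_xy (X→Y, rows Y).  A coefficient significantly different from zero
is a significant Granger causality (GC) from sender to receiver; the
signed t-score of the coefficient doubles as the GC strength (positive =
enhancing, negative = suppressing).  Because all other voxels of both
ROIs sit in the same regression, each coefficient is automatically a
*conditional* GC: influences routed through third voxels are not
re-attributed to direct links.

All regressions are fit without an intercept; voxel series are demeaned
per voxel (within each trial) during design assembly.  Lagged windows
never straddle trial boundaries.  The t-test degrees of freedom are
n_obs − (fitted predictors).

## LASSO pre-selection

With p·(m+n) predictors per row equation and limited observations, the
full regression is not estimable by OLS.  Assuming sparse connectivity,
each row equation is first passed through the LASSO: minimize
½‖y − Xb‖² + λ‖b‖₁, equivalently least squares under Σ|b| ≤ c.  The
entire solution path is traced by least-angle regression (LARS) with the
LASSO modification (a predictor whose coefficient crosses zero is dropped
and the direction recomputed).  The solver maintains the running
correlations X'(y − Xb) and, at every knot, satisfies the stationarity
conditions of the penalized objective to ~1e-12 (verified against a
convergence-tight coordinate-descent solver and, for orthonormal designs,
the soft-thresholding closed form).  Equal-correlation ties break to the
lowest predictor index; with more predictors than observations the path
ends when the residual is exhausted.

The constraint value is tuned by generalized cross-validation,
GCV(c) = (RSS/n)/(1 − df/n)², with df = number of active predictors.
Candidates are the union of the path knots and a 100-point linear grid on
[0, c_max] (coefficients at off-knot candidates are exact linear
interpolations within their path segment; RSS is recomputed from the
design).  The active set at the global GCV minimum is the pre-selected
predictor set; ties go to the smaller c.  GCV's df penalty is AIC-like:
it reliably *covers* a strong true support but admits each pure-noise
predictor with probability ≈ 0.16, so selected sets are supersets of the
recoverable signal rather than exact supports.  This matters for
interpreting f below.

## Refit and inference — the data-splitting choice

After selection, the row equation is refit by OLS on the selected columns
and each coefficient receives a signed t-score and two-sided p-value.
`fit_lasso_gc(split=...)` controls the relationship between the selection
and refit samples:

* `split="half"` (default): observations — whole trials, in
  `across_trials` mode — are randomly halved with one global seeded
  split; selection uses one half (odd counts favor it), refit the other.
  Selection and inference are disjoint, so the refit p-values are valid
  post-selection tests.  The null-calibration property (below) holds in
  this mode.
* `split="none"`: both stages use all observations.  This is the only
  option when a single short realization exists and is what the
  simulation study uses.  Its p-values are inflated by the selection
  (the selected predictors were chosen for in-sample correlation) and
  should be read as a ranking device feeding the summary statistics, not
  as confirmatory per-connection tests.  The inflation is not incidental:
  at the study's signal-to-noise level (coefficient scales 0.08–0.2
  against innovation sd 0.1 at T = 200) most individual true couplings
  are below the detection threshold of any honest test, and the
  summary-level density tracking shown in the study depends on the
  selection stage concentrating power on in-sample-correlated predictors.

Degenerate cases: a selected set as large as the refit sample falls back
to an empty selection (warning); collinear selected columns are dropped
deterministically, lowest index kept; numerically perfect fits report
signed-infinity t sentinels with p = 0 and are excluded from
z-normalization.

## Baselines

*Pairwise GC*: a separate bivariate AR(1) per ordered voxel pair, fit by
OLS on all observations; the cross coefficient fills entry (receiver,
sender).  Diagonal entries come from univariate AR(1) fits, so every
entry is estimated exactly once.  Omitting the other m+n−2 voxels makes
this baseline prone to spurious causality: on chain data x→y→z with
autocorrelated sources it flags the absent x→z link in roughly half the
runs, versus ~1% for the conditional LASSO-GC fit.

*Averaged GC*: each ROI is collapsed to its voxel-mean series and a
single bivariate AR(1) yields one t per direction (t_yx, t_xy).

## Summary statistics

Significance is controlled by Benjamini–Hochberg FDR at q = 0.05.  The
default family is the set of hypotheses actually tested — the selected
entries (for pairwise GC this is the full matrix); `full` (never-tested
entries counted at p = 1) and `per_block` families are options.  The
`full` family is strictly more conservative and, at the study's SNR,
drives both methods' significant fractions to ≈0.

Per coupling block:

* **f** — significant entries / block size: a connection-density measure.
  Within-region blocks count the self-lag diagonal by default (so that
  estimated f and the generator's truth f share a denominator); an
  exclude-diagonal option exists.
* **W** — over receiving voxels (rows) with at least one significant
  input, the mean of the signed sums of their significant scores.
  Opposing inputs to one receiver cancel; convergence of same-signed
  inputs amplifies.  Before computing W, scores are z-normalized over the
  *non-zero entries of the full matrix* (estimated t-scores and truth
  b-values thereby land on one scale and share a code path).  Per-block
  normalization is deliberately not used: for truth summaries the
  significant set would equal the normalization population and W would
  collapse to exactly zero in every block.

Truth summaries (`model_truth_summary`) apply the same formulas to the
generating coefficients with "significant" meaning non-zero.

A zero-lag Pearson correlation comparator (`correlation_connectivity`)
computes the symmetric correlation matrix over pooled observations, tests
it via the t transform with FDR over unordered off-diagonal pairs
(optionally restricted to a selection mask), and reports f and W on raw
correlation values with the diagonal excluded.

## Synthetic data generator

The generator reproduces the packaged 56-model schedule: two pseudo-ROIs
with m = 30 and n = 50 voxels; per block, exactly round(frac × size)
entries at uniformly random positions (diagonal included) are drawn
N(0, sd²) with sd 0.08 within regions, 0.2 for Y→X, 0.1 for X→Y; the
innovation process is N(0, 0.1²); series of T = 200 points are produced
by iteration from N(0, 0.1) initial values, with an optional burn-in
(default 0) and an overflow guard at |value| > 1e12.  Stability is
enforced by redrawing until the spectral radius is below 1 (up to 100
redraws; an allow-unstable override reproduces the divergent regime).
The scheduled fractions rise from ≈0.05 to ≈0.29 in seven blocks of
eight models.

What the generator does *not* emulate about real BOLD data: hemodynamic
convolution and its regional lag variability, measurement noise,
spatial autocorrelation between neighboring voxels, slow drifts and
physiological confounds, and trial structure.  Passing the simulation
study therefore shows that the estimator recovers sparse linear VAR
structure at matched SNR — not that empirical fMRI GC is unbiased.

## The simulation study

`run_simulation_study` builds each scheduled model, iterates one
T = 200 realization, fits LASSO-GC (`split="none"`), pairwise GC and
averaged GC, and summarizes (FDR q = 0.05, selected family).  The seed
ladder is documented in the module: model, data, and split seeds are
fixed offsets from the base seed and iteration.  `compare_methods`
reports, per statistic and block, the paired t-test across models of
|estimate − truth| for LASSO-GC versus pairwise (LASSO-GC is closer with
p < 1e-6 in all eight tests at the default settings), and the Pearson
correlations of the z-normalized averaged t-scores with truth f and W.

Two structural findings from this package's own runs, documented here
because they qualify the interpretation:

1. Estimated f *undershoots* truth increasingly with density (the
   sparsity assumption degrades; the per-block Spearman trend of the
   error across the seven density blocks is positive).  The ordering
   across blocks and the superiority over pairwise GC are robust; the
   absolute level is not a calibrated density estimate.
2. The signed averaged-signal t-score shares a component with truth W:
   both are proportional to the block's realized net mean coupling
   (random across draws, since coefficients are drawn zero-mean).  Their
   correlation across the schedule is therefore significantly positive
   even though neither tracks the *designed* density schedule; reading
   the averaged strength as a magnitude (|t|) removes it.  The f
   correlations are non-significant under either reading.

## Numerical choices

LARS tie tolerance 1e-12 (scale-aware); GCV tie-break toward smaller c;
BH via statsmodels; z-normalization uses the sample (n−1) standard
deviation; collinearity detection by modified Gram–Schmidt at relative
tolerance 1e-10; VAR stability via companion-matrix spectral radius.
Monte-Carlo test sizes (100 seeds; 10-voxel null; 3-voxel chain;
T = 200) are the package's chosen problem sizes for calibration checks.

## Limitations

Order p = 1 only for the summary semantics (the assembly supports p > 1,
but block significance for multi-lag GC would need per-pair tests over
lags and redefined summaries).  No frequency-domain GC, no time-varying
coefficients, no hemodynamic forward model.  Grouped-selection variants
of the LASSO (elastic net, group LASSO), which mitigate correlated-
predictor selection instability, are out of scope.
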