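# Methods

This note documents the models, parameter choices and numerical conventions
behind `eegattn`, and what its synthetic tests do and do not establish.

## Spectral processing

All filtering is FFT-coefficient masking: compute the DFT of the window,
zero the coefficients outside the retained frequency set symmetrically in
conjugate pairs, invert, and discard the (machine-epsilon) imaginary
residual. Masking is a projection — idempotent, zero-phase, and energy
non-increasing (Parseval).

Conventions that matter:

- Bin *k* of an *n*-point window at *fs* Hz sits at *k·fs/n* Hz; for the
  default 1 s / 512-point windows the resolution is exactly 1 Hz.
- Band intervals are half-open, [f_low, f_high): a shared edge (δ/θ at 4 Hz,
  θ/α at 8 Hz, α/SMR at 12 Hz) belongs to the upper band. This makes the
  disjoint bands non-overlapping and the bin sets deterministic. At 1 Hz
  resolution α maps to bins {8,9,10,11} and SMR (upper edge 14.99 Hz) to
  {12,13,14}.
- The lowpass denoiser retains frequencies ≤ 50 Hz *inclusive*, DC included
  (whether the 50 Hz bin itself survives is underdetermined by the method's
  description; we keep it). DC removal is not the denoiser's job — the EMD
  detrending stage absorbs offsets and drift.
- Band extraction never keeps bin 0, so every extracted wave is zero-mean.

## Empirical mode decomposition

- **Extrema.** Strict neighbor comparison; a plateau counts once, at its
  floor-midpoint index.
- **Envelopes.** Cubic splines through the maxima (resp. minima), with the
  two nearest extrema mirrored across each end of the window before fitting.
  Mirroring is a standard counter to end-swing artifacts; the method's
  original description is silent on boundaries.
- **Sifting stop.** SD = Σₜ m(t)²/d(t)² < 0.3, computed pointwise with
  samples where d(t)² < 1e−30 skipped (the pointwise ratio is otherwise
  unbounded at zero crossings). Caps: 100 sifting iterations per IMF (a
  warning is emitted when hit — common on noisy windows, harmless in
  practice) and 12 IMFs per decomposition.
- **Termination.** The decomposition stops when the residue is monotone or
  has fewer than 4 extrema (cubic-spline support). The textbook IMF
  condition "zero area between consecutive extrema" is unattainable in
  floating point; IMF-ness is asserted in tests via the extrema/zero-crossing
  count condition instead.
- **Detrending** drops the last two components of [c₁, …, c_{N−1}, residue].
  Degenerate cases keep oscillatory content: with exactly two components only
  the residue is dropped; a residue-only decomposition (pure trend) returns
  the zero signal.

## Singular spectrum analysis

The L-eigendecomposition of X Xᵀ is used instead of an SVD of the L×K
trajectory matrix (cheaper for L ≪ K). The elementary matrix is computed as
Sᵢ = Uᵢ Uᵢᵀ X, algebraically equal to √λᵢ Uᵢ Vᵢᵀ with Vᵢ = Xᵀ Uᵢ/√λᵢ but
exact to machine precision even for null eigenvalues, so the elementary
series always sum to the input (no rank-tolerance leakage). Right singular
vectors are materialized only for λᵢ > 1e−12·λ₁. Eigenvalues are sorted
descending with a stable sort; elementary series are quadratic in Uᵢ and
hence invariant to eigenvector sign.

Diagonal averaging is implemented by bincount over anti-diagonal indices
t = a + b (0-based), equivalent to the three-case boundary formula, and
inverts Hankelization exactly.

Fixed schemes: L = 6 with grouping {1},{2,3},{4,5},{6} for the detrended
EEG; L = 2, singleton groups, for each band. Component order is
EEG-SSA1..4 then (δ, θ, α, SMR, mid-β, high-β, low-β, β, γ) × (SSA1, SSA2).

## Features

- **ApEn.** m = 2 (the embedding length is not fixed by the method's
  description; 2 is the standard choice in physiological ApEn work and is
  exposed as a parameter), r = 0.5, threshold P = r × sample SD of the whole
  series. Self-matches are included (log is always defined); similar
  subsequences are counted as Chebyshev distance ≤ P. The opposite count
  ("greater than P") appears in one description of the statistic but makes
  the quantity non-positive and non-discriminative; it is available via
  `similarity="greater"` for comparison, never used by the pipeline.
  φ for m and m+1 share one pairwise sample-distance matrix, so a window of
  n points costs O(n²) memory — fine up to the 10 s (5120-point) windows.
- **Moments.** Variance uses N−1; skewness and kurtosis standardize by the
  sample SD but divide by N, and kurtosis is non-excess (normal ≈ 3) —
  fidelity to the printed formulas rather than textbook conventions.
  Constant series get skew = kurt = ApEn = 0 by convention.
- **Quartiles** by linear interpolation of order statistics
  (`np.percentile` default).
- The ANOVA screen is a per-feature one-way F-test (scipy); features
  constant across all samples get p = 1. Power is the percentage of cells
  with p < α (default 0.05), with no multiple-testing correction — the
  screen is descriptive, mirroring the reference analysis.

## Classification and scoring

- Split: per class, ⌊0.3·n⌋ (≥ 1) windows to test; the training pool is
  balanced by uniform undersampling of the majority class without
  replacement.
- Repeats: repeat k uses split seed s+k; the model seed is derived from the
  split seed. Reported scores are means over repeats; per-class scores are
  per-class recall of the single binary model on that class's test windows.
- Random forest: 30 trees, min leaf 5, √d features per split, Gini; no
  standardization (trees are scale-invariant).
- SVM: RBF kernel, C = 1, kernel width by the median heuristic by default;
  the two tuned parameter sets reported for the reference data (polynomial
  degree 2 / C 23.891 and Gaussian scale 140.88 / C 127.57) ship as presets.
  z-scoring on training statistics is applied.
- BP network: one hidden layer of 10 logistic units, adam optimizer
  (gradient-descent family), early stopping on a 10% validation split,
  ≤ 500 iterations, z-scored inputs. Everything beyond the 10-unit layer is
  underdetermined by the reference description; these are this package's
  choices.
- End-to-end invariance: a common positive affine transform a·x + b of all
  raw windows leaves z-scored proposed features unchanged (detrending
  absorbs b; every statistic is homogeneous in a or scale-free), so
  standardized-model scores are invariant.

## Synthetic data

Each generated window is Σ_b A_b sin(2π f_b t + φ_b) + trend + noise with
the carrier f_b drawn uniformly from the integer-Hz bin centers inside band
b and φ_b uniform per window; the trend is a slow sinusoid (default
amplitude 30, period 10 s — effectively a drift within a 1 s window) or
linear ramp; high-frequency noise is white noise ideal-highpassed at 55 Hz
(disjoint from the retained 0–50 Hz range); broadband noise is white.
Default amplitudes (δ 20, θ 15, α 10, SMR 6, mid-β 6, high-β 4, γ 2,
high-frequency noise 5, broadband 2, arbitrary units) follow the usual
amplitude ordering of resting EEG rhythms. Classes differ by a
multiplicative band-amplitude shift (default α × 4 for "immersion").

This emulates only the statistical structure the pipeline consumes. It has
no 1/f background, no transient artifacts, no inter-window dependence, and
no physiological attention signature — so a green classification test
establishes that the pipeline detects the band-power structure it is built
to detect, not that the score measures human attention. Conversely the
reference feature-screen table is real-data evidence, shipped as data, not
recomputed.

## Known limitations

- Real recordings of the reference corpus are not available; per-participant
  accuracy tables cannot be reproduced, only the pipeline structure on
  synthetic data.
- The printed reference p-value table contains 196 cells below 0.05 although
  the accompanying summary reports 195 (80.58%); the package counts
  strictly and reports 196 (80.99%) for that table.
- EMD sifting frequently hits the 100-iteration cap on noisy windows (the
  pointwise SD statistic converges slowly in noise); the resulting IMFs are
  over-sifted relative to gentler stopping rules but the reconstruction and
  detrending guarantees are unaffected.
- Scoring datasets with fewer than ~14 windows per class make the 30% test
  split very small; scores then quantize coarsely.
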