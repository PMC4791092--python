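# Methods

## Signal models

All times are milliseconds; magnitudes are arbitrary intensity units.
Three forward models describe an mGRE magnitude decay:

* monoexponential: `S(TE) = PD·exp(−TE/T2*)`;
* offset model: `S(TE) = PD·exp(−TE/T2*) + C`, with `C ≥ 0`
  approximating the rectified-noise plateau of magnitude images;
* second-moment noise-corrected model (M2NCM): for an L-coil
  root-sum-of-squares (RSS) reconstruction with per-channel Gaussian
  noise SD σ the squared magnitude satisfies `E[M²] = S² + 2Lσ²`
  exactly; the floor `K = 2Lσ²` is treated as a free parameter (or
  held fixed when σ is known). Second-moment fits minimise residuals
  in the squared-signal domain, `M² − (S² + K)`.

Fitting is unweighted least squares by a Nelder–Mead simplex
(reflection/expansion/contraction coefficients 1, 2, 0.5, 0.5;
relative tolerance 1e−8 on both parameters and SSE; at most 2000
iterations; single start). The start is the closed-form WLSL estimate
— weighted linear regression of `ln S` on TE with weights `S²`, the
variance-stabilising weight for log-transformed exponential data —
plus `min(S)` for the offset `C` and `min(S²)` for the floor `K`.
Parameters are constrained by a sloped penalty: `T2* ∈ (0, 10·max TE]`
and `PD, C, K ≥ 0`. The ceiling keeps the downstream truncation rule
well defined on decay-free (e.g. background) input; a WLSL slope ≥ 0
maps to the same ceiling. The simplex is implemented as a
numba-compiled kernel because the Monte-Carlo studies need on the
order of 10⁶ fits per run; tests cross-check it against SciPy's
Nelder–Mead and against brute-force parameter grids.

## The switching estimator

`adapts_estimate` consumes one ROI-averaged signal (pixel averaging
is the caller's job) and proceeds: offset-model pre-fit on all echoes
→ initial estimate `T2*_init` → discard echoes with
`TE > P1·T2*_init` (boundary inclusive: only strict exceedance drops
an echo) → if the surviving count is at least `P2`, final
two-parameter monoexponential fit on the survivors ("truncation"
branch); otherwise final three-parameter second-moment fit on **all**
echoes ("noise_corrected" branch). Defaults `P1 = 4.5`, `P2 = 9` are
the optimised constants for the 10-echo clinical protocols; for the
cardiac echo spacing the branch switch sits at
`T2*_init = 22.5/4.5 = 5.0` ms, for the liver spacing at 4.0 ms. The
rationale: a truncated two-parameter fit is more precise when enough
clean echoes exist, while the noise-corrected model is less biased
when T2* is short and most echoes sit in the floor.

Degenerate inputs: fewer than four echoes raise (the pre-fit needs a
residual degree of freedom); all-zero or non-finite signals raise; a
pre-fit pinned at the T2* ceiling simply keeps all echoes. At least
two surviving echoes are required for the truncated fit, otherwise
the noise-corrected branch is taken. The result records the branch,
the surviving-echo prefix, final parameters and fit diagnostics; the
estimate is deterministic given identical input.

## Subregion uncertainty

With per-pixel data the ROI of `N` pixels is chunked, in stable
(row-major) pixel order, into non-overlapping subregions of
`n = max(2, round(0.04·N))` pixels (trailing pixels that cannot fill
a group are excluded from the ensemble only). ADAPTS runs on each
subregion mean; assuming independent pixels and locally linear error
propagation, a subregion estimate's standard error exceeds the ROI
estimate's by `√(N/n)`, so the reported SD is
`σ̂ = √(n/N)·SD(subregion T2*s)` (ddof = 1), the 95% CI size is
`3.92·σ̂` (normal-theory interval — chosen over percentiles because
the ensembles are small, ~20–25 values) and `CoV = σ̂/T2*_ROI`.
Subregions whose fit fails are dropped; fewer than three survivors,
or fewer than 8 ROI pixels, make the uncertainty unavailable. The 4%
default is the size at which the CI estimate tracks the reference CI
most closely while remaining precise; chunk-order partitioning is
deterministic and approximately contiguous for compact ROIs (the
partition geometry is otherwise immaterial under the homogeneity
assumption).

`fit_roi` adds a delineation-review advisory when CoV exceeds 0.30
(the upper tail of CoV values seen in patient measurements) or when
the estimate is pinned at the no-decay ceiling (background ROI).

## Simulator

Each receive channel carries the same decay on its real and imaginary
component; zero-mean Gaussian noise of SD σ is added per component
and channels are combined by RSS, giving a noncentral-chi magnitude
with `2L` degrees of freedom. The per-channel amplitude is
`a = S0/√(2L)`, so the noiseless RSS at TE = 0 equals `S0` (fixed at
100 arbitrary units; every estimator is scale invariant).

SNR is defined per channel: `SNR = S0/σ` with
`σ = S0/(SNR·√(2L))` per component. This convention keeps the
relative rectified-noise floor near `1/SNR` for every coil count —
rising slightly from one to six coils and converging toward 32, the
noncentral-chi behaviour — and makes image noise fall as coils are
added. It is the only amplitude/noise pairing consistent with the
observed simulation behaviour of RSS reconstructions (bias growing
then converging with L, precision improving with L); defining σ
against the combined image amplitude instead makes the floor grow
like `√L` and degrades multi-coil results catastrophically.

ROI averaging draws `roi_pixels` independent pixels (default 40) and
averages echo-wise. Experiment cells use RNG streams keyed on
`(seed, cell indices)` via `SeedSequence`, so runs are reproducible
and order independent. The simulator emulates homogeneous tissue
with spatially uniform, uncorrelated noise; real acquisitions add
T2* heterogeneity, inter-channel noise correlation and spatially
varying sensitivity, so passing tests bound estimator behaviour under
the model's assumptions, not under arbitrary scanner conditions.

## Experiments

* **Accuracy/precision sweep** — per (true T2\*, L, estimator): mean
  bias and the 2.5–97.5 percentile span ("95% CI") of the repetition
  ensemble. Estimators: `adapts`, the two-parameter `m2ncm_true_sigma`
  comparator (floor fixed at the true `2Lσ²`), `truncation_only`
  (truncated fit regardless of the surviving count) and
  `noise_corrected_only` (free-floor fit on all echoes). All
  estimators of a cell share the simulated draws (paired comparison).
  The fixed-floor comparator consumes the ROI *mean of squared*
  magnitudes (the sample second moment, for which the `2Lσ²` floor is
  exact); ADAPTS and its component models consume the plain ROI mean,
  whose free floor absorbs the small plateau difference.
* **CI validation** — per true T2\*: each simulated ROI yields a
  subregion CI estimate; the reference is the percentile span of the
  full-ROI estimates across repetitions. Reported: ensemble summary
  of the CI estimates, mean bias against the reference, and whether
  the reference lies inside the estimates' 2.5–97.5% limits.
* **Parameter sweep** — the accuracy/precision sweep over a (P1, P2)
  grid, on identical RNG streams so a single pair reproduces the main
  sweep bit-for-bit.
* **Subregion optimisation** — CI validation over ROI sizes and
  subregion fractions; infeasible partitions are skipped with a
  warning.

Non-converged repetitions are excluded from ensembles and counted; a
cell with more than 1% failures is flagged invalid.

## Problem sizes and numerical choices

The validation study (`scripts/acceptance.py`) uses 1 ms T2\* grids
(cardiac 2.2, 3–50; liver 1–50), SNR 15, 40-pixel ROIs and coil
counts {1, 6, 32}, with 1000 repetitions per sweep cell. The
CI-estimator validation runs 2000 repetitions on 7-point T2\* grids
spanning 2–50 ms with ROI sizes {40, 100, 200, 400}: its target
quantity is a difference between two ensemble spreads, and the
sampling noise of a percentile-span reference at a few hundred
repetitions (~0.15 ms at T2\* = 50) would exceed the ~0.1 ms effects
being measured. The test suite runs the same studies at 500
repetitions with correspondingly widened tolerance bands.

Known limitations: the truncation branch retains a small positive
bias where the switch first activates (the surviving echoes still
touch the noise floor); on the liver echo spacing this peaks around
T2\* ≈ 5 ms at ~0.5 ms before decaying, because the last echo
(20.1 ms) sits right at the truncation threshold there. Percentiles
use NumPy's linear interpolation. The estimator is ROI-based by
design; pixelwise mapping, motion correction, fat–water modelling
and maximum-likelihood (noncentral-chi likelihood) fitting are out of
scope.
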