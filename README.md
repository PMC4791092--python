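# adapts — adaptive ROI T2\* estimation from magnitude MRI

`adapts` measures the effective transverse relaxation time T2\* from
multi-echo gradient-echo (mGRE) magnitude images. T2\* shortens with
tissue iron, so quantitative T2\* of the myocardial septum and liver
parenchyma is the clinical standard for grading iron overload and
titrating chelation therapy. The package targets offline,
vendor-independent analysis: its only manual input is a region of
interest (ROI), and alongside each T2\* value it reports a
per-measurement 95% confidence interval so that changes between
follow-up scans can be judged against measurement noise.

## The estimation problem

An mGRE acquisition samples the decay `S(TE) = PD·exp(−TE/T2*)` at
echo times TE (ms). Magnitude images, however, do not decay to zero:
rectified noise leaves a positive plateau (for a root-sum-of-squares
reconstruction with L coils the magnitude is noncentral-chi
distributed with `E[M²] = S² + 2Lσ²`), which biases a naive
exponential fit upward — badly so for the short T2\* of heavy iron
load. The package implements an adaptive model-switching scheme
(ADAPTS — ADAPtive T2\* estimation from combined Signal models):

1. **Pre-fit** — the offset model `S(TE) = PD·exp(−TE/T2*) + C` is
   fitted to the ROI-mean signal (Nelder–Mead simplex, started from
   the closed-form weighted log-linear WLSL estimate); `C` absorbs
   the noise plateau and yields an initial estimate `T2*_init`.
2. **Truncation** — echoes with `TE > P1·T2*_init` (default
   `P1 = 4.5`) have decayed into the floor and are discarded.
3. **Branch** — if at least `P2` echoes survive (default `P2 = 9` of
   the 10-echo clinical protocols), T2\* is re-estimated by a plain
   two-parameter monoexponential fit on the surviving echoes; with
   fewer survivors the series is too short for a stable truncated fit
   and T2\* comes instead from the three-parameter second-moment fit
   `M² = S² + K` on all echoes (noise-corrected branch, the free
   floor `K` standing in for the unknown `2Lσ²`).

**Uncertainty.** The ROI is split into non-overlapping subregions of
4% of its pixels; ADAPTS runs on each subregion mean, and since a
subregion average of `n` of the ROI's `N` pixels has a `√(N/n)`-times
larger standard error, the ROI-level T2\* standard deviation is
`σ̂_T2* = √(n/N)·SD(subregion T2*s)`. Reported alongside:
`CI95 = 3.92·σ̂_T2*` and the coefficient of variation
`CoV = σ̂_T2*/T2*_ROI`, which drives a "review your delineation"
advisory when it exceeds 0.30.

A seeded multi-coil simulator (Gaussian channel noise on the real and
imaginary parts, RSS combination, ROI averaging) and four Monte-Carlo
experiment pipelines reproduce the estimator's accuracy, precision
and CI-calibration characteristics from scratch.

## A worked example

```python
import numpy as np
from adapts import CARDIAC_PROTOCOL, DecaySignal, adapts_estimate

te = CARDIAC_PROTOCOL.te_array                    # 2.5 ... 25.0 ms
for true_t2 in (3.0, 12.0):
    sig = DecaySignal(CARDIAC_PROTOCOL, 100 * np.exp(-te / true_t2))
    r = adapts_estimate(sig)
    print(true_t2, round(r.t2, 3), r.branch, len(r.kept_te_indices))
```

prints

```
3.0   3.0  noise_corrected  5
12.0  12.0 truncation       10
```

— at T2\* = 3 ms only five echoes survive truncation (below P2 = 9),
so the noise-corrected branch is used; at 12 ms all ten echoes
survive and the truncated monoexponential fit applies. Both recover
the generating value exactly on noiseless input.

With per-pixel data the uncertainty estimate comes for free
(`examples/02_uncertainty_from_roi.py`): a simulated 100-pixel liver
ROI at T2\* = 10 ms, per-channel SNR 15 and a six-coil reconstruction
gives

```
ROI T2*      :  10.30 ms
95% CI size  :  0.114 ms
CoV          :  0.003
```

i.e. a measurement whose repeat-scan spread is about a tenth of a
millisecond. The `examples/` directory walks through each capability
(single fits, uncertainty, accuracy/precision sweeps, CI-estimator
validation, a full DICOM→report workflow), and the `adapts` command
line (`adapts fit`, `adapts simulate`, `adapts validate ...`) exposes
the same functionality for shell use.

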