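"""Seeded Monte-Carlo experiment pipelines.

Four studies are packaged, each emitting a tidy :class:`pandas.DataFrame`:

* :func:`run_accuracy_precision_sweep` — estimator mean bias and 95% CI
  (2.5-97.5 percentile span of the repetition ensemble) over a grid of
  true T2* values and coil counts;
* :func:`run_ci_validation` — the subregion CI estimator compared, per
  true T2*, against the reference CI of repeated full-ROI estimates;
* :func:`run_parameter_sweep` — the accuracy/precision sweep over a
  grid of (P1, P2) algorithm constants;
* :func:`run_subregion_optimization` — CI-estimator bias/precision over
  ROI sizes and subregion fractions.

All cells draw from independent RNG streams keyed on (seed, cell
indices), so results are reproducible and independent of evaluation
order.  Repetitions whose fit does not converge are excluded from the
ensembles; a run is flagged invalid when more than 1% of its
repetitions failed.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from ._fastfit import (
    _batch_adapts,
    _batch_second_moment_fixed,
    _batch_second_moment_free,
)
from .core import AdaptsConfig
from .simulator import SimulationConfig, _rss_magnitudes, rng_for_cell
from .uncertainty import CI95_FACTOR, subregion_size

__all__ = [
    "ESTIMATORS",
    "run_accuracy_precision_sweep",
    "run_ci_validation",
    "run_parameter_sweep",
    "run_subregion_optimization",
]

ESTIMATORS = ("adapts", "m2ncm_true_sigma", "truncation_only", "noise_corrected_only")

#: Maximum tolerated fraction of non-converged repetitions per cell.
MAX_FAILURE_FRACTION = 0.01


def _percentile_span(x: np.ndarray) -> float:
    return float(np.percentile(x, 97.5) - np.percentile(x, 2.5))


def _simulate_cell(
    config: SimulationConfig, t2: float, n_coils: int, rng: np.random.Generator
) -> np.ndarray:
    """Pixel signals of shape (repetitions, roi_pixels, n_echoes)."""
    return _rss_magnitudes(
        config.protocol.te_array,
        t2,
        config.s0,
        config.channel_sigma(n_coils),
        n_coils,
        (config.repetitions, config.roi_pixels),
        rng,
    )


def _estimate_batch(
    te: np.ndarray,
    roi_means: np.ndarray,
    roi_sq_means: np.ndarray,
    estimator: str,
    config: AdaptsConfig,
    sigma: float,
    n_coils: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Dispatch one estimator over ROI signals; returns (t2, converged).

    ADAPTS and its component models consume the plain ROI mean
    (``roi_means`` rows); the fixed-floor M2NCM comparator consumes the
    ROI sample second moment (``roi_sq_means``), for which the floor
    2 L sigma^2 is exact.
    """
    if estimator == "adapts":
        t2, _, conv = _batch_adapts(te, roi_means, config.p1, float(config.p2))
    elif estimator == "truncation_only":
        # truncated two-parameter fit regardless of surviving echo count
        t2, _, conv = _batch_adapts(te, roi_means, config.p1, 2.0)
    elif estimator == "noise_corrected_only":
        t2, conv = _batch_second_moment_free(te, roi_means)
    elif estimator == "m2ncm_true_sigma":
        k_true = 2.0 * n_coils * sigma * sigma
        t2, conv = _batch_second_moment_fixed(te, roi_sq_means, k_true)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return t2, conv


def run_accuracy_precision_sweep(
    config: SimulationConfig,
    estimators: Sequence[str] = ("adapts", "m2ncm_true_sigma"),
    adapts_config: AdaptsConfig | None = None,
) -> pd.DataFrame:
    """Mean bias and 95% CI per (true T2*, coil count, estimator).

    All estimators of a cell are evaluated on the same simulated ROI
    averages, so estimator comparisons are paired.
    """
    if adapts_config is None:
        adapts_config = AdaptsConfig()
    for est in estimators:
        if est not in ESTIMATORS:
            raise ValueError(f"unknown estimator {est!r}")
    te = config.protocol.te_array
    rows = []
    for i_t2, t2 in enumerate(config.t2_grid):
        for i_l, n_coils in enumerate(config.coil_counts):
            rng = rng_for_cell(config.seed, i_t2, i_l)
            pixels = _simulate_cell(config, t2, n_coils, rng)
            roi_means = pixels.mean(axis=1)
            roi_sq_means = (pixels**2).mean(axis=1)
            for est in estimators:
                t2_hat, conv = _estimate_batch(
                    te, roi_means, roi_sq_means, est, adapts_config,
                    config.channel_sigma(n_coils), n_coils,
                )
                good = t2_hat[conv]
                n_failed = int(config.repetitions - good.size)
                rows.append(
                    {
                        "protocol": config.protocol.name,
                        "t2_true": t2,
                        "n_coils": n_coils,
                        "estimator": est,
                        "mean_bias": float(np.mean(good) - t2) if good.size else np.nan,
                        "ci95": _percentile_span(good) if good.size else np.nan,
                        "repetitions": config.repetitions,
                        "n_failed": n_failed,
                        "valid": n_failed <= MAX_FAILURE_FRACTION * config.repetitions,
                    }
                )
    return pd.DataFrame(rows)


def run_ci_validation(
    config: SimulationConfig,
    fraction: float = 0.04,
    adapts_config: AdaptsConfig | None = None,
) -> pd.DataFrame:
    """Validate the subregion CI estimator against repeated measurements.

    Per (true T2*, coil count): ``repetitions`` independent ROIs are
    simulated; each yields one full-ROI ADAPTS estimate and one
    subregion-based CI estimate.  The reference CI is the 2.5-97.5
    percentile span of the full-ROI estimates, and ``contains_reference``
    records whether it falls inside the same percentile limits of the
    CI-estimate ensemble.
    """
    if adapts_config is None:
        adapts_config = AdaptsConfig()
    te = config.protocol.te_array
    n_px = config.roi_pixels
    n_sub = subregion_size(n_px, fraction)
    n_groups = n_px // n_sub
    if n_groups < 2:
        raise ValueError(
            f"ROI of {n_px} pixels cannot form two subregions at fraction {fraction}"
        )
    corr = CI95_FACTOR * np.sqrt(n_sub / n_px)

    rows = []
    for i_t2, t2 in enumerate(config.t2_grid):
        for i_l, n_coils in enumerate(config.coil_counts):
            rng = rng_for_cell(config.seed, n_px, i_t2, i_l)
            pixels = _simulate_cell(config, t2, n_coils, rng)
            reps = config.repetitions

            roi_t2, _, roi_conv = _batch_adapts(
                te, pixels.mean(axis=1), adapts_config.p1, float(adapts_config.p2)
            )
            ref_ests = roi_t2[roi_conv]
            ci_reference = _percentile_span(ref_ests) if ref_ests.size else np.nan

            group_means = (
                pixels[:, : n_groups * n_sub, :]
                .reshape(reps, n_groups, n_sub, te.size)
                .mean(axis=2)
            )
            sub_t2, _, sub_conv = _batch_adapts(
                te,
                group_means.reshape(reps * n_groups, te.size),
                adapts_config.p1,
                float(adapts_config.p2),
            )
            sub_t2 = np.where(sub_conv, sub_t2, np.nan).reshape(reps, n_groups)
            n_ok = np.sum(~np.isnan(sub_t2), axis=1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                sd = np.nanstd(sub_t2, axis=1, ddof=1)
            ci_est = np.where(n_ok >= 3, corr * sd, np.nan)
            good = ci_est[~np.isnan(ci_est)]

            lo, hi = (
                (np.percentile(good, 2.5), np.percentile(good, 97.5))
                if good.size
                else (np.nan, np.nan)
            )
            n_failed = int(reps - good.size)
            rows.append(
                {
                    "protocol": config.protocol.name,
                    "t2_true": t2,
                    "n_coils": n_coils,
                    "roi_pixels": n_px,
                    "fraction": fraction,
                    "n_sub": n_sub,
                    "median_ci_est": float(np.median(good)) if good.size else np.nan,
                    "mean_ci_est": float(np.mean(good)) if good.size else np.nan,
                    "ci_est_limits_2_5": float(lo),
                    "ci_est_limits_97_5": float(hi),
                    "ci_reference": ci_reference,
                    "mean_bias": float(np.mean(good) - ci_reference)
                    if good.size
                    else np.nan,
                    "contains_reference": bool(lo <= ci_reference <= hi)
                    if good.size
                    else False,
                    "repetitions": reps,
                    "n_failed": n_failed,
                    "valid": n_failed <= MAX_FAILURE_FRACTION * reps,
                }
            )
    return pd.DataFrame(rows)


def run_parameter_sweep(
    p1_values: Sequence[float],
    p2_values: Sequence[int],
    config: SimulationConfig,
) -> pd.DataFrame:
    """ADAPTS accuracy/precision over a grid of (P1, P2) constants.

    Every (P1, P2) pair is evaluated on the same simulated signals
    (identical RNG streams as :func:`run_accuracy_precision_sweep`), so
    a single pair reproduces that sweep exactly.
    """
    if not p1_values or not p2_values:
        raise ValueError("p1_values and p2_values must be non-empty")
    te = config.protocol.te_array
    rows = []
    for i_t2, t2 in enumerate(config.t2_grid):
        for i_l, n_coils in enumerate(config.coil_counts):
            rng = rng_for_cell(config.seed, i_t2, i_l)
            roi_means = _simulate_cell(config, t2, n_coils, rng).mean(axis=1)
            for p1 in p1_values:
                for p2 in p2_values:
                    cfg = AdaptsConfig(p1=float(p1), p2=int(p2))
                    t2_hat, _, conv = _batch_adapts(
                        te, roi_means, cfg.p1, float(cfg.p2)
                    )
                    good = t2_hat[conv]
                    n_failed = int(config.repetitions - good.size)
                    rows.append(
                        {
                            "protocol": config.protocol.name,
                            "p1": float(p1),
                            "p2": int(p2),
                            "t2_true": t2,
                            "n_coils": n_coils,
                            "estimator": "adapts",
                            "mean_bias": float(np.mean(good) - t2)
                            if good.size
                            else np.nan,
                            "ci95": _percentile_span(good) if good.size else np.nan,
                            "repetitions": config.repetitions,
                            "n_failed": n_failed,
                            "valid": n_failed
                            <= MAX_FAILURE_FRACTION * config.repetitions,
                        }
                    )
    return pd.DataFrame(rows)


def run_subregion_optimization(
    roi_sizes: Sequence[int],
    fractions: Sequence[float],
    config: SimulationConfig,
    adapts_config: AdaptsConfig | None = None,
) -> pd.DataFrame:
    """CI-estimator bias and precision over ROI sizes and fractions.

    Infeasible combinations (fewer than two subregions) are skipped
    with a warning.
    """
    from dataclasses import replace

    frames = []
    for roi_size in roi_sizes:
        for fraction in fractions:
            n_sub = subregion_size(int(roi_size), float(fraction))
            if int(roi_size) // n_sub < 2:
                warnings.warn(
                    f"skipping ROI size {roi_size} at fraction {fraction}: "
                    "cannot form two subregions",
                    stacklevel=2,
                )
                continue
            cfg = replace(config, roi_pixels=int(roi_size))
            frames.append(run_ci_validation(cfg, float(fraction), adapts_config))
    if not frames:
        raise ValueError("no feasible (roi_size, fraction) combinations")
    return pd.concat(frames, ignore_index=True)
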