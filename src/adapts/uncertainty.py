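"""Subregion-based uncertainty estimation for ROI T2* values.

The ROI is split into non-overlapping subregions of ``n`` pixels each
(``n`` a fixed fraction of the ROI size ``N``, by default 4%).  ADAPTS
is run on each subregion mean, giving an ensemble of T2* values whose
spread reflects the measurement noise.  Because a subregion average
uses fewer pixels than the full ROI, its standard error is larger by
``sqrt(N/n)``; assuming independent pixels and locally linear error
propagation from the data points to the estimate, the ROI-level T2*
standard deviation is recovered as

    sigma_T2* = sqrt(n / N) * SD(subregion T2* ensemble)

from which the 95% confidence-interval size (3.92 * sigma_T2*, the
normal-theory interval) and the coefficient of variation
(sigma_T2* / T2*_ROI) are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AdaptsConfig, adapts_estimate
from .exceptions import AdaptsError, UncertaintyUnavailableError
from .signal_models import DecaySignal, EchoProtocol

__all__ = [
    "RoiPixels",
    "UncertaintyResult",
    "partition_roi",
    "estimate_uncertainty",
    "CI95_FACTOR",
]

#: Size of a two-sided 95% normal-theory interval in units of SD.
CI95_FACTOR = 3.92

#: Minimum ROI size for which a subregion ensemble is meaningful.
MIN_ROI_PIXELS = 8


@dataclass(frozen=True)
class RoiPixels:
    """Per-pixel magnitude decays of one ROI sharing a single protocol.

    ``pixel_signals`` has shape (N, n_echoes) in a stable (row-major
    image) pixel order; ``pixel_ids`` preserves that ordering.
    """

    protocol: EchoProtocol
    pixel_signals: np.ndarray
    pixel_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        sig = np.asarray(self.pixel_signals, dtype=np.float64)
        object.__setattr__(self, "pixel_signals", sig)
        if sig.ndim != 2 or sig.shape[1] != len(self.protocol):
            raise ValueError(
                "pixel_signals must be (n_pixels, n_echoes) matching the protocol"
            )
        ids = self.pixel_ids
        if ids is None:
            ids = np.arange(sig.shape[0])
        else:
            ids = np.asarray(ids)
            if ids.shape != (sig.shape[0],):
                raise ValueError("pixel_ids must have one entry per pixel")
        object.__setattr__(self, "pixel_ids", ids)

    @property
    def n_pixels(self) -> int:
        return int(self.pixel_signals.shape[0])

    def mean_signal(self) -> DecaySignal:
        """Echo-wise mean over all pixels (the signal the ROI fit uses)."""
        return DecaySignal(self.protocol, self.pixel_signals.mean(axis=0))

    def rms_signal(self) -> DecaySignal:
        """Echo-wise root mean square over pixels.

        Squaring this signal gives the ROI sample second moment, for
        which the identity ``E[M^2] = S^2 + 2 L sigma^2`` holds
        exactly; second-moment fits with a known noise floor should
        consume this signal rather than the plain mean.
        """
        return DecaySignal(
            self.protocol, np.sqrt(np.mean(self.pixel_signals**2, axis=0))
        )


@dataclass(frozen=True)
class UncertaintyResult:
    t2_roi: float
    sd_corrected: float
    ci95_size: float
    cov: float
    subregion_t2s: tuple[float, ...]
    n_sub: int


def subregion_size(n_pixels: int, fraction: float) -> int:
    """Pixels per subregion: ``max(2, round(fraction * N))`` (half-up)."""
    return max(2, int(np.floor(fraction * n_pixels + 0.5)))


def partition_roi(roi: RoiPixels, fraction: float = 0.04) -> list[np.ndarray]:
    """Chunk the ROI pixels, in stable order, into equal subregions.

    Groups have ``n = max(2, round(fraction * N))`` pixels; trailing
    pixels that cannot fill a complete group are left out of the
    ensemble (they still contribute to the full-ROI fit).

    Raises
    ------
    UncertaintyUnavailableError
        If fewer than two complete groups can be formed.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    n_pixels = roi.n_pixels
    n = subregion_size(n_pixels, fraction)
    n_groups = n_pixels // n
    if n_groups < 2:
        raise UncertaintyUnavailableError(
            f"ROI of {n_pixels} pixels cannot form two subregions of {n}"
        )
    idx = np.arange(n_groups * n)
    return [idx[g * n : (g + 1) * n] for g in range(n_groups)]


def estimate_uncertainty(
    roi: RoiPixels,
    config: AdaptsConfig | None = None,
    fraction: float = 0.04,
) -> UncertaintyResult:
    """ROI T2* with subregion-derived 95% CI size and CoV.

    Subregions whose ADAPTS fit fails are dropped from the ensemble; at
    least three surviving subregions are required.  The ensemble SD
    (ddof = 1) is scaled by ``sqrt(n/N)`` before forming the interval.
    """
    if config is None:
        config = AdaptsConfig()
    if roi.n_pixels < MIN_ROI_PIXELS:
        raise UncertaintyUnavailableError(
            f"uncertainty estimation needs >= {MIN_ROI_PIXELS} pixels"
        )
    groups = partition_roi(roi, fraction)
    n_sub = len(groups[0])

    roi_fit = adapts_estimate(roi.mean_signal(), config)

    sub_t2s: list[float] = []
    for g in groups:
        sub_mean = DecaySignal(roi.protocol, roi.pixel_signals[g].mean(axis=0))
        try:
            fit = adapts_estimate(sub_mean, config)
        except AdaptsError:
            continue
        if fit.diagnostics.converged:
            sub_t2s.append(fit.t2)
    if len(sub_t2s) < 3:
        raise UncertaintyUnavailableError(
            "fewer than three subregion fits survived; uncertainty unavailable"
        )

    sd_raw = float(np.std(sub_t2s, ddof=1))
    sd_corrected = float(np.sqrt(n_sub / roi.n_pixels)) * sd_raw
    return UncertaintyResult(
        t2_roi=roi_fit.t2,
        sd_corrected=sd_corrected,
        ci95_size=CI95_FACTOR * sd_corrected,
        cov=sd_corrected / roi_fit.t2,
        subregion_t2s=tuple(sub_t2s),
        n_sub=n_sub,
    )
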