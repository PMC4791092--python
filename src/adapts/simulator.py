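"""Multi-coil magnitude-noise simulator for T2* decay signals.

Each receive channel carries the same monoexponential decay on both its
real and imaginary component, contaminated with independent zero-mean
Gaussian noise of SD ``sigma``:

    Re_l(TE) = a * exp(-TE/T2*) + eps,   Im_l(TE) = a * exp(-TE/T2*) + eps'
    M_l = sqrt(Re_l^2 + Im_l^2),         RSS = sqrt(sum_l M_l^2)

The per-channel amplitude is normalised as ``a = S0 / sqrt(2 L)`` so
that the noiseless RSS magnitude at TE = 0 equals ``S0`` for any coil
count.  The RSS magnitude of an L-coil reconstruction follows a
noncentral chi distribution with ``2L`` degrees of freedom and
satisfies the second-moment identity ``E[RSS^2] = S^2 + 2 L sigma^2``.

``SNR = S0/sigma`` is the *per-channel* SNR: the ratio of a channel's
component decay amplitude to its noise SD, i.e. ``sigma = a / SNR =
s0 / (SNR * sqrt(2 L))``.  With this convention the relative
rectified-noise floor stays near ``1/SNR`` for every coil count (rising
slightly and converging as L grows, the expected noncentral-chi
behaviour) and image noise falls as coils are added, matching how RSS
reconstructions of a fixed-SNR acquisition behave.

ROI averaging is simulated by drawing ``roi_pixels`` statistically
independent pixel signals and averaging them echo-wise, mirroring how
the estimator consumes ROI means of clinical images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_models import DecaySignal, EchoProtocol
from .uncertainty import RoiPixels

__all__ = [
    "CoilNoiseModel",
    "SimulationConfig",
    "DEFAULT_S0",
    "rng_for_cell",
    "simulate_pixel",
    "simulate_roi_pixels",
    "simulate_roi_signal",
]

#: Reference magnitude at TE = 0, in arbitrary intensity units.  All
#: estimators are scale invariant, so the absolute value is immaterial;
#: 100 keeps simulated intensities in a familiar image-like range.
DEFAULT_S0 = 100.0


@dataclass(frozen=True)
class CoilNoiseModel:
    """Receive-chain description: coil count L and per-channel noise SD."""

    n_coils: int
    sigma: float

    def __post_init__(self) -> None:
        if int(self.n_coils) != self.n_coils or self.n_coils < 1:
            raise ValueError("n_coils must be an integer >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        object.__setattr__(self, "n_coils", int(self.n_coils))


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of one Monte-Carlo experiment.

    ``snr`` is the per-channel SNR (see module docstring); the channel
    noise SD of an L-coil cell is ``s0 / (snr * sqrt(2 L))``.
    """

    t2_grid: tuple[float, ...]
    snr: float
    protocol: EchoProtocol
    coil_counts: tuple[int, ...] = (1, 6, 32)
    roi_pixels: int = 40
    repetitions: int = 2000
    seed: int = 0
    s0: float = DEFAULT_S0

    def __post_init__(self) -> None:
        grid = tuple(float(t) for t in self.t2_grid)
        object.__setattr__(self, "t2_grid", grid)
        object.__setattr__(
            self, "coil_counts", tuple(int(c) for c in self.coil_counts)
        )
        if not grid or any(t <= 0 for t in grid):
            raise ValueError("t2_grid must be non-empty and positive")
        if not self.snr > 0:
            raise ValueError("snr must be positive")
        if any(c < 1 for c in self.coil_counts):
            raise ValueError("coil counts must be >= 1")
        if self.roi_pixels < 1 or self.repetitions < 1:
            raise ValueError("roi_pixels and repetitions must be >= 1")

    def channel_sigma(self, n_coils: int) -> float:
        """Per-channel noise SD for an L-coil cell: s0 / (snr * sqrt(2L))."""
        return self.s0 / (self.snr * float(np.sqrt(2.0 * n_coils)))


def rng_for_cell(seed: int, *key: int) -> np.random.Generator:
    """Independent, reproducible RNG stream for one experiment cell.

    Streams derived from the same ``seed`` with different integer keys
    are statistically independent, so experiment cells can be computed
    in any order (or in parallel) without changing results.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def _rss_magnitudes(
    te: np.ndarray,
    t2: float,
    s0: float,
    sigma: float,
    n_coils: int,
    shape: tuple[int, ...],
    rng: np.random.Generator,
) -> np.ndarray:
    """RSS magnitude draws of shape ``shape + (n_te,)``.

    Accumulates per-coil squared magnitudes instead of materialising
    the full (coils x draws) complex array, keeping memory flat in L.
    """
    a = s0 / np.sqrt(2.0 * n_coils)
    s = a * np.exp(-te / t2)
    out_shape = tuple(shape) + (te.size,)
    rss_sq = np.zeros(out_shape)
    for _ in range(n_coils):
        re = s + rng.normal(0.0, sigma, out_shape)
        im = s + rng.normal(0.0, sigma, out_shape)
        rss_sq += re * re + im * im
    return np.sqrt(rss_sq)


def simulate_pixel(
    t2: float,
    s0: float,
    noise: CoilNoiseModel,
    protocol: EchoProtocol,
    rng: np.random.Generator,
) -> np.ndarray:
    """One noisy RSS magnitude decay vector for a single pixel."""
    if not t2 > 0 or not s0 >= 0:
        raise ValueError("t2 must be positive and s0 non-negative")
    return _rss_magnitudes(
        protocol.te_array, t2, s0, noise.sigma, noise.n_coils, (), rng
    )


def simulate_roi_pixels(
    t2: float,
    protocol: EchoProtocol,
    snr: float,
    n_coils: int,
    roi_pixels: int,
    rng: np.random.Generator,
    s0: float = DEFAULT_S0,
) -> RoiPixels:
    """Independent pixel decays of one homogeneous ROI.

    ``snr`` is the per-channel SNR; the channel noise SD is
    ``s0 / (snr * sqrt(2 * n_coils))``.
    """
    if roi_pixels < 1:
        raise ValueError("roi_pixels must be >= 1")
    sigma = s0 / (snr * np.sqrt(2.0 * n_coils))
    signals = _rss_magnitudes(
        protocol.te_array, t2, s0, sigma, int(n_coils), (int(roi_pixels),), rng
    )
    return RoiPixels(protocol=protocol, pixel_signals=signals)


def simulate_roi_signal(
    t2: float,
    protocol: EchoProtocol,
    snr: float,
    n_coils: int,
    roi_pixels: int,
    rng: np.random.Generator,
    s0: float = DEFAULT_S0,
) -> DecaySignal:
    """ROI-averaged decay: echo-wise mean over independent pixel draws."""
    roi = simulate_roi_pixels(t2, protocol, snr, n_coils, roi_pixels, rng, s0=s0)
    return roi.mean_signal()
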