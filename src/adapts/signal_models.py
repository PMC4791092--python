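"""Decay signal models for multi-echo gradient-echo T2* relaxometry.

Three forward models are provided, all functions of the echo time TE
(milliseconds throughout):

* monoexponential:      ``S(TE) = PD * exp(-TE / T2*)``
* offset model:         ``S(TE) = PD * exp(-TE / T2*) + C``, where the
  constant ``C`` approximates the rectified-noise plateau of magnitude
  images;
* second-moment noise-corrected model (M2NCM): the expected *squared*
  magnitude of a root-sum-of-squares reconstruction with ``L`` coils and
  per-channel noise SD sigma is ``E[M^2] = S(TE)^2 + 2 L sigma^2``; the
  floor ``K = 2 L sigma^2`` is fitted as a single free parameter (or held
  fixed when the true sigma is known).

Fits minimise the sum of squared residuals with a Nelder-Mead simplex
started from the closed-form WLSL estimate (weighted least squares on
the signal logarithm, weights ``S^2``).  The second-moment model is
fitted in the squared-signal domain, i.e. residuals are
``M^2 - (S^2 + K)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._fastfit import T2_CAP_FACTOR, _nelder_mead, _wlsl
from .exceptions import InvalidSignalError, UnderdeterminedFitError

__all__ = [
    "EchoProtocol",
    "DecaySignal",
    "MonoExpParams",
    "OffsetModelParams",
    "NoiseCorrectedParams",
    "FitDiagnostics",
    "CARDIAC_PROTOCOL",
    "LIVER_PROTOCOL",
    "predict_monoexp",
    "predict_offset",
    "predict_second_moment",
    "wlsl_fit",
    "fit_model",
]


@dataclass(frozen=True)
class EchoProtocol:
    """Ordered echo times of a multi-echo acquisition, in milliseconds."""

    tes: tuple[float, ...]
    name: str = ""

    def __post_init__(self) -> None:
        tes = tuple(float(t) for t in self.tes)
        object.__setattr__(self, "tes", tes)
        if len(tes) < 2:
            raise ValueError("an echo protocol needs at least two echo times")
        arr = np.asarray(tes)
        if not np.all(arr > 0):
            raise ValueError("echo times must be positive")
        if not np.all(np.diff(arr) > 0):
            raise ValueError("echo times must be strictly increasing")

    @property
    def te_array(self) -> np.ndarray:
        return np.asarray(self.tes, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.tes)


#: Clinical cardiac multi-echo GRE echo times (ms).
CARDIAC_PROTOCOL = EchoProtocol(
    (2.5, 5.0, 7.5, 10.0, 12.5, 15.0, 17.5, 20.0, 22.5, 25.0), name="cardiac"
)

#: Clinical liver multi-echo GRE echo times (ms).
LIVER_PROTOCOL = EchoProtocol(
    (1.3, 3.4, 5.5, 7.6, 9.7, 11.8, 13.9, 16.0, 18.0, 20.1), name="liver"
)


@dataclass(frozen=True)
class DecaySignal:
    """An echo protocol paired with measured (or ROI-averaged) magnitudes."""

    protocol: EchoProtocol
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size != len(self.protocol):
            raise ValueError("signal length must match the number of echo times")
        if not np.all(np.isfinite(vals)):
            raise InvalidSignalError("signal contains non-finite values")
        if np.any(vals < 0):
            raise ValueError("magnitudes must be non-negative")


@dataclass(frozen=True)
class MonoExpParams:
    pd: float
    t2: float

    def __post_init__(self) -> None:
        if not (self.pd > 0 and self.t2 > 0):
            raise ValueError("pd and t2 must be strictly positive")


@dataclass(frozen=True)
class OffsetModelParams:
    pd: float
    t2: float
    c: float

    def __post_init__(self) -> None:
        if not (self.pd > 0 and self.t2 > 0):
            raise ValueError("pd and t2 must be strictly positive")
        if self.c < 0:
            raise ValueError("offset c must be non-negative")


@dataclass(frozen=True)
class NoiseCorrectedParams:
    """Second-moment model parameters; ``k`` is the floor 2 L sigma^2."""

    pd: float
    t2: float
    k: float

    def __post_init__(self) -> None:
        if not (self.pd > 0 and self.t2 > 0):
            raise ValueError("pd and t2 must be strictly positive")
        if self.k < 0:
            raise ValueError("noise floor k must be non-negative")


@dataclass(frozen=True)
class FitDiagnostics:
    sse: float
    n_iterations: int
    converged: bool

    def __post_init__(self) -> None:
        if self.sse < 0:
            raise ValueError("sse must be non-negative")


def predict_monoexp(params: MonoExpParams, protocol: EchoProtocol) -> np.ndarray:
    """``PD * exp(-TE / T2*)`` evaluated at every echo time."""
    te = protocol.te_array
    return params.pd * np.exp(-te / params.t2)


def predict_offset(params: OffsetModelParams, protocol: EchoProtocol) -> np.ndarray:
    """Monoexponential decay on top of a constant noise-plateau offset."""
    te = protocol.te_array
    return params.pd * np.exp(-te / params.t2) + params.c


def predict_second_moment(
    params: NoiseCorrectedParams, protocol: EchoProtocol
) -> np.ndarray:
    """Expected squared magnitude ``S(TE)^2 + k`` of the noisy signal."""
    te = protocol.te_array
    s = params.pd * np.exp(-te / params.t2)
    return s * s + params.k


def wlsl_fit(signal: DecaySignal) -> MonoExpParams:
    """Closed-form log-linear fit, weights ``S^2``.

    Regresses ``ln S`` on TE with weights equal to the squared signal
    (the variance-stabilising choice for log-transformed exponential
    data) and maps intercept/slope back to ``PD`` and ``T2*``.  A
    non-negative slope is clamped to the T2* ceiling of
    ``10 x max(TE)``.

    Raises
    ------
    InvalidSignalError
        If any signal value is not strictly positive (the logarithm
        would be undefined).
    """
    y = signal.values
    if np.any(y <= 0):
        raise InvalidSignalError("WLSL requires strictly positive signal values")
    te = signal.protocol.te_array
    pd, t2 = _wlsl(te, y, T2_CAP_FACTOR * te[-1])
    return MonoExpParams(pd=float(pd), t2=float(t2))


def _pos(v: float) -> float:
    # fitted amplitudes may land exactly on the pd >= 0 boundary for
    # signal-free inputs; keep the returned params strictly valid
    return max(float(v), 1e-12)


_MODEL_IDS = {"monoexp": 0, "offset": 1, "second_moment": 2}
_N_PARAMS = {"monoexp": 2, "offset": 3, "second_moment": 3}


def _default_init(model_id: str, signal: DecaySignal):
    base = wlsl_fit(signal)
    if model_id == "monoexp":
        return base
    if model_id == "offset":
        return OffsetModelParams(base.pd, base.t2, float(np.min(signal.values)))
    return NoiseCorrectedParams(base.pd, base.t2, float(np.min(signal.values) ** 2))


def _params_to_vector(model_id: str, init) -> np.ndarray:
    if model_id == "monoexp":
        return np.array([init.pd, init.t2])
    if model_id == "offset":
        return np.array([init.pd, init.t2, init.c])
    return np.array([init.pd, init.t2, init.k])


def fit_model(
    model_id: str,
    signal: DecaySignal,
    init=None,
    *,
    fixed_noise: float | None = None,
):
    """Least-squares fit of one decay model to a signal.

    Parameters
    ----------
    model_id : {"monoexp", "offset", "second_moment"}
        Which forward model to fit.  ``second_moment`` fits squared
        magnitudes against ``S^2 + k``.
    signal : DecaySignal
        Measured magnitudes.
    init : model parameters, optional
        Starting point; defaults to the WLSL estimate (plus the minimum
        measured value for the offset ``c`` / minimum squared value for
        the floor ``k``).
    fixed_noise : float, optional
        Only for ``second_moment``: hold the floor ``k`` fixed at this
        value (the two-parameter M2NCM comparator with known sigma).

    Returns
    -------
    (params, FitDiagnostics)
    """
    if model_id not in _MODEL_IDS:
        raise ValueError(f"unknown model {model_id!r}")
    if fixed_noise is not None and model_id != "second_moment":
        raise ValueError("fixed_noise only applies to the second_moment model")

    y = signal.values
    te = signal.protocol.te_array
    n_free = _N_PARAMS[model_id] - (1 if fixed_noise is not None else 0)
    if y.size < n_free:
        raise UnderdeterminedFitError(
            f"{model_id} has {n_free} free parameters but only {y.size} echoes given"
        )
    if not np.all(np.isfinite(y)):
        raise InvalidSignalError("signal contains non-finite values")

    if init is None:
        init = _default_init(model_id, signal)
    t2_cap = T2_CAP_FACTOR * te[-1]

    if model_id == "second_moment":
        yd = y * y
        if fixed_noise is not None:
            x0 = np.array([init.pd, init.t2])
            x, sse, it, conv = _nelder_mead(x0, te, yd, 3, float(fixed_noise), t2_cap)
            params = NoiseCorrectedParams(_pos(x[0]), _pos(x[1]), float(fixed_noise))
        else:
            x0 = _params_to_vector(model_id, init)
            x, sse, it, conv = _nelder_mead(x0, te, yd, 2, 0.0, t2_cap)
            params = NoiseCorrectedParams(_pos(x[0]), _pos(x[1]), float(x[2]))
    else:
        x0 = _params_to_vector(model_id, init)
        x, sse, it, conv = _nelder_mead(x0, te, y, _MODEL_IDS[model_id], 0.0, t2_cap)
        if model_id == "monoexp":
            params = MonoExpParams(_pos(x[0]), _pos(x[1]))
        else:
            params = OffsetModelParams(_pos(x[0]), _pos(x[1]), float(x[2]))

    diag = FitDiagnostics(sse=float(sse), n_iterations=int(it), converged=bool(conv))
    return params, diag
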