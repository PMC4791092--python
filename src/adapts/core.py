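"""The ADAPTS model-switching T2* estimator.

ADAPTS (ADAPtive T2* estimation from combined Signal models) estimates
T2* from an ROI-averaged magnitude decay in three steps:

1. a three-parameter offset model ``PD*exp(-TE/T2*) + C`` is fitted to
   all echoes (WLSL-initialised) to obtain an initial estimate
   ``T2*_init`` robust to the rectified-noise plateau;
2. echoes with ``TE > P1 * T2*_init`` are discarded (automatic
   truncation of echoes that have decayed into the noise floor);
3. if at least ``P2`` echoes survive, T2* is re-estimated by a
   two-parameter monoexponential fit on the surviving echoes
   (truncation branch); otherwise the series is deemed too short for a
   stable truncated fit and T2* comes from the three-parameter
   second-moment noise-corrected fit on *all* echoes (noise-corrected
   branch).

The switch trades precision (truncated two-parameter fit, high SNR /
long T2*) against noise-bias robustness (noise-corrected fit, short T2*
close to the first echo time).  Defaults ``P1 = 4.5`` and ``P2 = 9``
are the optimised values for 10-echo clinical cardiac and liver
protocols.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._fastfit import BRANCH_TRUNCATION, _adapts_core
from .exceptions import InvalidSignalError, UnderdeterminedFitError
from .signal_models import (
    DecaySignal,
    EchoProtocol,
    FitDiagnostics,
    MonoExpParams,
    NoiseCorrectedParams,
)

__all__ = ["AdaptsConfig", "AdaptsResult", "truncate_tes", "adapts_estimate"]


@dataclass(frozen=True)
class AdaptsConfig:
    """Algorithm constants: truncation multiple P1, minimum echo count P2."""

    p1: float = 4.5
    p2: int = 9

    def __post_init__(self) -> None:
        if not self.p1 > 0:
            raise ValueError("p1 must be positive")
        if int(self.p2) != self.p2 or self.p2 < 2:
            raise ValueError("p2 must be an integer >= 2")
        object.__setattr__(self, "p2", int(self.p2))


@dataclass(frozen=True)
class AdaptsResult:
    """Outcome of one ADAPTS estimation.

    ``kept_te_indices`` records the echoes surviving truncation (a
    prefix of the protocol).  On the truncation branch these are the
    echoes the final fit used; on the noise-corrected branch the final
    fit used all echoes and the prefix documents why the branch
    switched (fewer than P2 survivors).
    """

    t2: float
    branch: str
    t2_initial: float
    kept_te_indices: tuple[int, ...]
    params: MonoExpParams | NoiseCorrectedParams
    diagnostics: FitDiagnostics


def truncate_tes(
    protocol: EchoProtocol, t2_initial: float, config: AdaptsConfig
) -> list[int]:
    """Indices of echoes with ``TE <= P1 * t2_initial`` (boundary kept).

    Echo times are strictly increasing, so the result is always a
    prefix ``[0, 1, ..., k-1]`` of the protocol; it may be empty.
    """
    if not t2_initial > 0:
        raise ValueError("t2_initial must be positive")
    thr = config.p1 * t2_initial
    return [i for i, te in enumerate(protocol.tes) if te <= thr]


def adapts_estimate(
    signal: DecaySignal, config: AdaptsConfig | None = None
) -> AdaptsResult:
    """Run the full ADAPTS pass on one (ROI-averaged) decay signal.

    The caller is responsible for pixel averaging; this operation
    consumes a single signal vector.  Deterministic: identical signal
    and config give a bit-identical result.

    Raises
    ------
    UnderdeterminedFitError
        Fewer than four echoes (the three-parameter pre-fit needs a
        residual degree of freedom).
    InvalidSignalError
        All-zero or non-finite signal.
    """
    if config is None:
        config = AdaptsConfig()
    y = signal.values
    if y.size < 4:
        raise UnderdeterminedFitError("ADAPTS needs at least four echoes")
    if not np.all(np.isfinite(y)):
        raise InvalidSignalError("signal contains non-finite values")
    if not np.any(y > 0):
        raise InvalidSignalError("signal is identically zero")

    te = signal.protocol.te_array
    t2, branch, t2_init, kept, sse, n_iter, conv, pd, k = _adapts_core(
        te, y, config.p1, float(config.p2)
    )
    diag = FitDiagnostics(sse=float(sse), n_iterations=int(n_iter), converged=bool(conv))
    t2 = float(max(t2, 1e-12))
    pd = float(max(pd, 1e-12))
    if branch == BRANCH_TRUNCATION:
        params: MonoExpParams | NoiseCorrectedParams = MonoExpParams(pd, t2)
        branch_name = "truncation"
    else:
        params = NoiseCorrectedParams(pd, t2, float(k))
        branch_name = "noise_corrected"
    return AdaptsResult(
        t2=t2,
        branch=branch_name,
        t2_initial=float(t2_init),
        kept_te_indices=tuple(range(int(kept))),
        params=params,
        diagnostics=diag,
    )
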