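"""Fit T2* to one ROI-averaged decay signal and inspect the branch taken.

ADAPTS first fits the three-parameter offset model to get an initial
T2*, truncates echoes that have decayed past P1 x that estimate into
the noise floor, and then either re-fits a plain monoexponential on
the surviving echoes (if at least P2 remain) or falls back to the
noise-corrected second-moment fit on all echoes.
"""

import numpy as np

from adapts import CARDIAC_PROTOCOL, DecaySignal, adapts_estimate

te = CARDIAC_PROTOCOL.te_array

for true_t2 in (3.0, 12.0):
    signal = DecaySignal(CARDIAC_PROTOCOL, 100.0 * np.exp(-te / true_t2))
    result = adapts_estimate(signal)
    print(f"true T2* = {true_t2:5.1f} ms  ->  estimate {result.t2:7.3f} ms, "
          f"branch={result.branch}, echoes kept={len(result.kept_te_indices)}")

# A short T2* truncates most echoes (fewer than P2 = 9 survive), so the
# noise-corrected branch handles it; a long T2* keeps enough echoes for
# the more precise truncated monoexponential fit.  On noiseless input
# both branches recover the generating T2* almost exactly.
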