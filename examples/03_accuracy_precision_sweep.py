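"""Monte-Carlo accuracy/precision sweep over true T2* and coil counts.

For each (T2*, coil count) cell, many independent 40-pixel ROIs are
simulated; the mean bias and the 2.5-97.5 percentile span (95% CI) of
the estimate ensemble quantify accuracy and precision.  The
two-parameter M2NCM comparator receives the true noise SD and serves
as a near-optimal reference.
"""

from adapts import LIVER_PROTOCOL, SimulationConfig, run_accuracy_precision_sweep

config = SimulationConfig(
    t2_grid=(2.0, 5.0, 10.0, 20.0, 40.0),
    snr=15.0,
    protocol=LIVER_PROTOCOL,
    coil_counts=(1, 6),
    roi_pixels=40,
    repetitions=300,   # demo scale; validation studies use 1000-2000
    seed=42,
)

df = run_accuracy_precision_sweep(config, ("adapts", "m2ncm_true_sigma"))
print(df.pivot_table(index="t2_true", columns=["estimator", "n_coils"],
                     values="mean_bias").round(3))
print()
print(df.pivot_table(index="t2_true", columns=["estimator", "n_coils"],
                     values="ci95").round(2))

# mean_bias stays within a few tenths of a millisecond across the
# clinically relevant range; the CI shrinks with more coils (higher
# image SNR) and grows for T2* beyond the last echo time, where the
# decay is barely sampled.
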