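"""Basic plots for waveform contrasts and behavioral trends.

Matplotlib is imported lazily so the core package works without it.
"""

from __future__ import annotations

import numpy as np

from .simulate import PeriodRecord, records_to_frame
from .stats import WaveformTestResult


def plot_waveform_result(result: WaveformTestResult, ax=None):
    """Condition-mean waveforms with significant latencies shaded."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(result.times, result.mean_a, label="condition A")
    ax.plot(result.times, result.mean_b, label="condition B")
    for lo, hi in result.intervals:
        ax.axvspan(lo, hi, alpha=0.2, color="grey")
    ax.set_xlabel("time after event (s)")
    ax.set_ylabel("conductance change (μS)")
    ax.legend()
    return ax


def plot_bribe_evolution(records: list[PeriodRecord], ax=None):
    """Mean bribe per period, with the treatment switch marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    df = records_to_frame(records)
    bribe = (df["b1"] + df["b2"]) / 2.0
    mean = bribe.groupby(df["period"]).mean()
    ax.plot(mean.index, mean.values, marker="o")
    t0_max = df.loc[df["treatment"] == "T0", "period"].max()
    if np.isfinite(t0_max):
        ax.axvline(t0_max + 0.5, linestyle="--", color="grey")
    ax.set_xlabel("period")
    ax.set_ylabel("mean bribe (monetary units)")
    return ax
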