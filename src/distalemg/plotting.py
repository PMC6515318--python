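"""Plot helpers (matplotlib imported lazily)."""

from __future__ import annotations

from .evaluation import GaitCycleSet


def plot_average_cycles(measured: GaitCycleSet, estimated: GaitCycleSet | None = None, ax=None):
    """Average +/- sd envelope over the normalized gait cycle."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(measured.grid, measured.average, color="tab:red", label="measured (avg)")
    ax.fill_between(
        measured.grid,
        measured.average - measured.sd,
        measured.average + measured.sd,
        color="tab:red",
        alpha=0.2,
    )
    if estimated is not None:
        ax.plot(estimated.grid, estimated.average, color="tab:blue", label="estimated (avg)")
        ax.fill_between(
            estimated.grid,
            estimated.average - estimated.sd,
            estimated.average + estimated.sd,
            color="tab:blue",
            alpha=0.2,
        )
    ax.set_xlabel("normalized cycle time (0-100)")
    ax.set_ylabel("normalized amplitude (0-100)")
    ax.legend()
    return ax
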