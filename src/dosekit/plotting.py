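"""Optional trajectory plots (requires matplotlib)."""

from __future__ import annotations

from .simulation import DosingTrajectory, TherapeuticRange

__all__ = ["plot_trajectory"]


def plot_trajectory(
    trajectory: DosingTrajectory,
    therapeutic_range: TherapeuticRange | None = None,
    ax=None,
    label: str | None = None,
):
    """Step plot of concentration vs time, with the dose sequence below."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.step(trajectory.times, trajectory.outputs, where="post", label=label)
    if therapeutic_range is not None:
        ax.axhspan(
            therapeutic_range.lower,
            therapeutic_range.upper,
            alpha=0.15,
            color="green",
            label="therapeutic range",
        )
    ax.set_xlabel("time (h)")
    ax.set_ylabel("concentration (mg/mL)")
    if label or therapeutic_range is not None:
        ax.legend()
    return ax
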