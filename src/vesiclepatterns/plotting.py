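"""Matplotlib summaries of a state-space table.

All functions take the records DataFrame produced by
:func:`vesiclepatterns.statespace.run_pipeline` and return a Figure;
nothing is shown or saved here.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .statespace import estimate_boundary

CLASS_COLORS = {
    "lattice": "black",
    "disordered": "tab:blue",
    "associated": "tab:red",
    "indeterminate": "tab:gray",
}


def _base_class(value: str) -> str:
    return "associated" if str(value).startswith("associated") else str(value)


def plot_state_space(records: pd.DataFrame, class_column: str = "pattern_class"):
    """Scatter of N against excess area, coloured by pattern class, with
    the empirical boundary gap shaded."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for cls, group in records.groupby(records[class_column].map(_base_class)):
        ax.semilogy(
            group["axs"],
            group["N"],
            "o",
            ms=4,
            color=CLASS_COLORS.get(cls, "tab:green"),
            label=cls,
        )
    try:
        boundary = estimate_boundary(records, class_column=class_column)
        if not boundary.overlapping:
            ax.axvspan(boundary.lower, boundary.upper, color="gold", alpha=0.3)
    except Exception:
        pass
    ax.set_xlabel("excess area $A_{xs}$")
    ax.set_ylabel("plate number $N$")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def plot_condition_histogram(records: pd.DataFrame, class_column: str = "pattern_class"):
    """Per-condition bar chart of pattern-class counts."""
    conditions = sorted(records["condition"].unique())
    fig, axes = plt.subplots(1, len(conditions), figsize=(3 * len(conditions), 3), squeeze=False)
    for ax, condition in zip(axes[0], conditions):
        subset = records[records["condition"] == condition]
        counts = subset[class_column].map(_base_class).value_counts()
        ax.bar(
            counts.index,
            counts.values,
            color=[CLASS_COLORS.get(c, "tab:green") for c in counts.index],
        )
        ax.set_title(condition)
        ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    return fig


def plot_step_function(records: pd.DataFrame, class_column: str = "pattern_class"):
    """Mean Dee/Dd against excess area — the step-function transition."""
    fig, ax = plt.subplots(figsize=(5, 4))
    persistent = records[
        records[class_column].map(_base_class).isin(["lattice", "associated"])
    ]
    for cls, group in persistent.groupby(persistent[class_column].map(_base_class)):
        ax.plot(
            group["axs"],
            group["dee_over_dd_mean"],
            "o",
            ms=4,
            color=CLASS_COLORS.get(cls, "tab:green"),
            label=cls,
        )
    ax.set_xlabel("excess area $A_{xs}$")
    ax.set_ylabel(r"$D_{ee}/D_d$")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig
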