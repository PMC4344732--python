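"""Percentile-curve and paired-difference figures for validity reports."""

from __future__ import annotations

from .validity import PERCENTILES, ValidityReport

_METHOD_COLORS = {"constant": "black", "linear": "purple", "spline": "tab:blue"}


def plot_percentile_curves(
    report: ValidityReport, metric: str, orientation: str, ax=None
):
    """Percentile curves of one metric versus spacing, one colour per method."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = report.percentiles
    sel = t[(t.orientation == orientation) & (t.metric == metric)]
    for method, group in sel.groupby("method"):
        color = _METHOD_COLORS.get(method, None)
        for q in PERCENTILES:
            curve = group[group.percentile == q].sort_values("spacing")
            ax.plot(
                curve.spacing, curve.value, color=color, lw=1,
                label=method if q == 50 else None,
            )
    ax.set_xlabel("linear spacing (mm)")
    ax.set_ylabel(metric)
    ax.set_title(f"{metric}, {orientation}")
    ax.legend()
    return ax


def plot_paired_differences(report: ValidityReport, ax=None):
    """Mean constant-minus-spline MAPE difference with 95% CI per orientation."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = report.paired_tests
    for orientation, group in t.groupby("orientation"):
        group = group.sort_values("spacing")
        line = ax.plot(group.spacing, group.mean_diff, label=orientation)[0]
        ax.fill_between(
            group.spacing, group.ci_low, group.ci_high,
            alpha=0.2, color=line.get_color(),
        )
    ax.axhline(0.0, color="gray", lw=0.5)
    ax.set_xlabel("linear spacing (mm)")
    ax.set_ylabel("MAPE difference, constant − spline (pct points)")
    ax.legend()
    return ax
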