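"""Optional figures: distance-decay panels and contribution bars.

Matplotlib is imported lazily so headless pipeline runs never touch it.
"""

from __future__ import annotations

from pathlib import Path

from .mantel import unfold
from .pipeline import AnalysisReport


def decay_panels(report: AnalysisReport, path: str | Path) -> None:
    """3x3 grid of dissimilarity vs distance with the OLS fit.

    Solid fit lines mark relationships whose Mantel test (not the OLS t
    test) is significant at 0.05; dashed lines are non-significant.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    beta_names = list(report.beta)
    pred_names = list(report.predictors)
    fig, axes = plt.subplots(3, 3, figsize=(10, 9), sharey="row")
    for i, b in enumerate(beta_names):
        for j, pred in enumerate(pred_names):
            ax = axes[i][j]
            x = unfold(report.predictors[pred])
            y = unfold(report.beta[b])
            ax.scatter(x, y, s=12, alpha=0.6, color="tab:blue", edgecolors="none")
            fit = report.decay[pred][b]
            res = report.mantel[pred][b]
            style = "-" if (res is not None and res.p < 0.05) else "--"
            xs = (x.min(), x.max())
            ax.plot(xs, [fit.intercept + fit.slope * v for v in xs], style, color="black")
            if i == 0:
                ax.set_title(pred)
            if i == len(beta_names) - 1:
                ax.set_xlabel(f"{pred} distance")
            if j == 0:
                ax.set_ylabel(f"beta ({b})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def contribution_bars(report: AnalysisReport, path: str | Path) -> None:
    """Per-predictor independent contribution (%) for each beta index."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    parts = {b: res["hier_part"] for b, res in report.partition.items() if res}
    fig, axes = plt.subplots(1, len(parts), figsize=(4 * len(parts), 4), sharey=True)
    if len(parts) == 1:
        axes = [axes]
    for ax, (b, hp) in zip(axes, parts.items()):
        names = list(hp.independent_pct)
        ax.bar(range(len(names)), [hp.independent_pct[n] for n in names], color="tab:green")
        ax.set_xticks(range(len(names)))
        ax.set_xticklabels(names, rotation=90)
        ax.set_title(f"{b} (R² = {hp.full_r_squared:.2f})")
    axes[0].set_ylabel("independent contribution (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
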