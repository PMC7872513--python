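"""Plain-text summary and a simple forest plot of an association table."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def text_report(assoc: pd.DataFrame, threshold: float | None, target_fdr: float) -> str:
    lines = ["Association summary", "==================="]
    if threshold is None:
        lines.append(f"No p-value threshold reached FDR <= {target_fdr:.0%}.")
    else:
        lines.append(
            f"Permutation FDR {target_fdr:.0%} threshold: p <= {threshold:.3g}"
        )
    sig = assoc[assoc.get("fdr_significant", 0) == 1]
    lines.append(f"Significant associations: {len(sig)} of {len(assoc)}")
    for _, row in sig.sort_values("p").iterrows():
        lines.append(
            f"  {row['determinant']:<22s} -> {row['indicator']:<16s} "
            f"beta={row['beta']:+.3f}  p={row['p']:.2e}"
        )
    return "\n".join(lines) + "\n"


def forest_plot(assoc: pd.DataFrame, path: str | Path, indicator: str = "composite_sum"):
    """Standardized betas with ±1.96 SE bars for one indicator column."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = assoc[assoc["indicator"] == indicator]
    fig, ax = plt.subplots(figsize=(6, 0.3 * len(sub) + 1.5))
    ypos = range(len(sub))
    ax.errorbar(
        sub["beta"], list(ypos), xerr=1.96 * sub["se"], fmt="o", color="k",
        ecolor="gray", capsize=2, markersize=4,
    )
    sig = sub.get("fdr_significant", pd.Series(0, index=sub.index)) == 1
    if sig.any():
        ax.scatter(
            sub.loc[sig, "beta"], [i for i, s in zip(ypos, sig) if s],
            color="red", marker="*", zorder=3, s=60,
        )
    ax.axvline(0, color="lightgray", lw=1)
    ax.set_yticks(list(ypos))
    ax.set_yticklabels(sub["determinant"])
    ax.set_xlabel("standardized beta")
    ax.set_title(f"{indicator}: determinant associations")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
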