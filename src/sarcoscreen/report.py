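"""Figures and text summary for a completed run directory."""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def _stars_for(stats: pd.DataFrame, label: str) -> str:
    """Stars for a group across analyses (control-comparison first)."""
    rows = stats[stats["group_label"] == label]
    if rows.empty:
        return ""
    s = rows.iloc[0]["stars"]
    return s if isinstance(s, str) else ""


def write_report(run_dir) -> Path:
    """Render the per-group bar figure and a text summary.

    The bar plot shows each group's metric as percent of control
    (mean of per-well values scaled by the control mean) with +/- SD
    whiskers and the trend-test significance stars from ``stats.csv``.
    """
    run_dir = Path(run_dir)
    groups_path = run_dir / "groups.csv"
    stats_path = run_dir / "stats.csv"
    if not groups_path.is_file() or not stats_path.is_file():
        raise FileNotFoundError(f"incomplete run: missing tables in {run_dir}")
    groups = pd.read_csv(groups_path)
    stats = pd.read_csv(stats_path)
    stats["stars"] = stats["stars"].fillna("")
    manifest = json.loads((run_dir / "manifest.json").read_text())
    metric = manifest.get("metric", "hsi")

    control_mean = groups.iloc[0]["mean"]
    rel_sd = 100.0 * groups["sd"] / control_mean

    fig, ax = plt.subplots(figsize=(1.2 * len(groups) + 2, 4))
    x = range(len(groups))
    ax.bar(x, groups["percent_of_control"], yerr=rel_sd, capsize=4,
           color=["#777777"] + ["#2b7bba"] * (len(groups) - 1))
    for i, row in groups.iterrows():
        stars = _stars_for(stats, row["group_label"])
        if stars:
            ax.text(i, row["percent_of_control"] + rel_sd[i] + 2, stars,
                    ha="center", fontsize=12)
    ax.set_xticks(list(x))
    ax.set_xticklabels(groups["group_label"], rotation=30, ha="right")
    ax.set_ylabel(f"{metric.upper()} (% of control)")
    ax.axhline(100.0, color="k", lw=0.5, ls=":")
    fig.tight_layout()
    fig_path = run_dir / "report.png"
    fig.savefig(fig_path, dpi=150)
    plt.close(fig)

    lines = [f"sarcoscreen report — metric: {metric}",
             f"groups ({groups['n_wells'].iloc[0]} wells/group):"]
    for _, row in groups.iterrows():
        stars = _stars_for(stats, row["group_label"])
        lines.append(
            f"  {row['group_label']:<22} {metric}={row['mean']:.3f} ± {row['sd']:.3f}"
            f"  ({row['percent_of_control']:.1f}% of control) "
            f"n={row['n_wells']} {stars}"
        )
    lines.append("trend tests:")
    for _, row in stats.iterrows():
        flag = "significant" if row["significant"] else "n.s."
        lines.append(
            f"  [{row['analysis']}] {row['group_label']} vs {row['control_label']}: "
            f"{row['test']} stat={row['statistic']:.3f} "
            f"crit={row['critical_value']:.3f} -> {flag} {row['stars']}"
        )
    summary = run_dir / "report.txt"
    summary.write_text("\n".join(lines) + "\n")
    return summary
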