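"""Well- and group-level indices from per-cell measurements.

Two readouts are computed, both as per-well cell fractions and then
normalized to the vehicle-control group:

* **Healthy Sarcomere Index (HSI)** — fraction of cells in a well whose
  mean Z-line length strictly exceeds the cutoff (default 3.1 um).
  Cells with no detected Z-line count in the denominator but can never
  be classified well-organized.
* **YAP1 nuclear-localization index** — fraction of measurable cells
  whose nuclear/cytoplasmic mean-intensity ratio strictly exceeds the
  ratio threshold (default 1.3).

Group summaries report the mean +/- SD of the per-well values and the
percent of control computed as a ratio of group means, so the control
group is 100% by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from sarcoscreen.core import GroupResult, WellMetrics


@dataclass
class ScoringParams:
    """Decision thresholds for per-cell classification."""

    z_cutoff_um: float = 3.1
    yap_ratio_threshold: float = 1.3
    min_cells_per_well: int = 50
    cytoplasm_floor: float = 1e-6  # guards the ratio against a zero denominator

    def __post_init__(self) -> None:
        if self.z_cutoff_um <= 0 or self.yap_ratio_threshold <= 0:
            raise ValueError("thresholds must be positive")


def mean_z_length(z_line_lengths_um) -> float:
    """Arithmetic mean of a cell's Z-line lengths; NaN when none detected."""
    lengths = list(z_line_lengths_um)
    if not lengths:
        return float("nan")
    return float(np.mean(lengths))


def classify_well_organized(mean_length_um: float,
                            params: ScoringParams | None = None) -> bool:
    """A cell is well-organized iff its mean Z-line length > cutoff (strict)."""
    params = params or ScoringParams()
    if mean_length_um is None or np.isnan(mean_length_um):
        return False
    return bool(mean_length_um > params.z_cutoff_um)


def classify_yap_nuclear(nuclear_mean: float, cytoplasm_mean: float,
                         params: ScoringParams | None = None) -> bool:
    """Nuclear-localized iff nuclear/cytoplasm ratio > threshold (strict)."""
    params = params or ScoringParams()
    if np.isnan(nuclear_mean) or np.isnan(cytoplasm_mean):
        return False
    ratio = nuclear_mean / max(cytoplasm_mean, params.cytoplasm_floor)
    return bool(ratio > params.yap_ratio_threshold)


def compute_hsi(cells: pd.DataFrame, params: ScoringParams | None = None,
                well: str | None = None, group_label: str = "") -> WellMetrics:
    """HSI for one well from its per-cell table (``mean_z_length_um`` column)."""
    params = params or ScoringParams()
    if well is None:
        well = str(cells["well"].iloc[0]) if len(cells) else ""
    n_total = int(len(cells))
    if n_total == 0:
        warnings.warn(f"well {well}: no cells, HSI undefined", stacklevel=2)
        return WellMetrics(well=well, group_label=group_label, n_cells_total=0)
    healthy = cells["mean_z_length_um"].apply(
        lambda m: classify_well_organized(m, params)
    )
    n_healthy = int(healthy.sum())
    return WellMetrics(
        well=well, group_label=group_label, n_cells_total=n_total,
        n_healthy=n_healthy, hsi=n_healthy / n_total,
        low_count=n_total < params.min_cells_per_well,
    )


def compute_yap_index(cells: pd.DataFrame, params: ScoringParams | None = None,
                      well: str | None = None, group_label: str = "") -> WellMetrics:
    """YAP1 nuclear-localization index for one well (measurable cells only)."""
    params = params or ScoringParams()
    if well is None:
        well = str(cells["well"].iloc[0]) if len(cells) else ""
    n_total = int(len(cells))
    measurable = cells.get("yap_measurable")
    if measurable is None:
        measurable = pd.Series(True, index=cells.index)
    measurable = measurable.fillna(False).astype(bool)
    n_meas = int(measurable.sum())
    if n_meas == 0:
        warnings.warn(f"well {well}: no measurable cells, YAP index undefined",
                      stacklevel=2)
        return WellMetrics(well=well, group_label=group_label,
                           n_cells_total=n_total)
    sub = cells[measurable]
    nuclear = sub.apply(
        lambda row: classify_yap_nuclear(row["yap_nuclear_mean"],
                                         row["yap_cytoplasm_mean"], params),
        axis=1,
    )
    n_nuc = int(nuclear.sum())
    return WellMetrics(
        well=well, group_label=group_label, n_cells_total=n_total,
        n_measurable=n_meas, n_yap_nuclear=n_nuc, yap_index=n_nuc / n_meas,
        low_count=n_total < params.min_cells_per_well,
    )


def score_wells(cells: pd.DataFrame, layout: pd.DataFrame, mode: str,
                params: ScoringParams | None = None) -> pd.DataFrame:
    """Per-well metrics table for a whole plate.

    ``cells`` is the concatenated per-cell table (all wells and fields);
    ``layout`` maps wells to group labels and doses.
    """
    params = params or ScoringParams()
    group_of = dict(zip(layout["well"], layout["group_label"]))
    rows = []
    for well, sub in cells.groupby("well", sort=True):
        label = group_of.get(well, "")
        if mode == "sarcomere_60x":
            m = compute_hsi(sub, params, well=well, group_label=label)
        else:
            m = compute_yap_index(sub, params, well=well, group_label=label)
        rows.append(vars(m))
    wells = pd.DataFrame(rows)
    meta = layout[["well", "group_label", "dose_uM", "is_control"]]
    return wells.drop(columns=["group_label"]).merge(meta, on="well", how="left")


def relative_to_control(wells: pd.DataFrame, metric: str,
                        control_label: str) -> pd.DataFrame:
    """Group summaries of a per-well metric as percent of the control group.

    ``percent_of_control`` is ``100 * group_mean / control_mean`` (ratio
    of group means), so the control group reads exactly 100.
    """
    valid = wells[np.isfinite(wells[metric])]
    if control_label not in set(valid["group_label"]):
        raise ValueError(f"control group {control_label!r} has no valid wells")
    control_mean = float(valid.loc[valid["group_label"] == control_label,
                                   metric].mean())
    if control_mean == 0:
        raise ZeroDivisionError("control group mean is zero; ratios undefined")
    rows = []
    order = valid.groupby("group_label", sort=False)["dose_uM"].first()
    for label in valid["group_label"].unique():
        sub = valid[valid["group_label"] == label]
        values = sub[metric].tolist()
        mean = float(np.mean(values))
        sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
        rows.append(GroupResult(
            group_label=label, dose_uM=float(order[label]),
            n_wells=len(values), well_values=values, mean=mean, sd=sd,
            percent_of_control=100.0 * mean / control_mean,
        ))
    out = pd.DataFrame([vars(r) for r in rows])
    is_control = out["group_label"] == control_label
    return pd.concat([out[is_control], out[~is_control]]).reset_index(drop=True)


def optimize_cutoff(lengths_control, lengths_positive,
                    grid=None, params: ScoringParams | None = None) -> float:
    """Search a cutoff grid for the best control/positive separation.

    The criterion is the Youden-style difference between the two sets'
    well-organized fractions at each candidate cutoff (fraction of
    cells with mean length strictly above the cutoff); ties break
    toward the smaller cutoff.  Degenerate inputs (identical
    distributions, no separation) return the grid minimum with a
    warning.
    """
    control = np.asarray([x for x in lengths_control if np.isfinite(x)], dtype=float)
    positive = np.asarray([x for x in lengths_positive if np.isfinite(x)], dtype=float)
    if control.size == 0 or positive.size == 0:
        raise ValueError("both cell sets must contain defined mean lengths")
    if grid is None:
        grid = np.arange(1.0, 6.0 + 1e-9, 0.1)
    grid = np.asarray(sorted(grid), dtype=float)
    frac_control = (control[None, :] > grid[:, None]).mean(axis=1)
    frac_positive = (positive[None, :] > grid[:, None]).mean(axis=1)
    youden = frac_control - frac_positive
    best = float(youden.max())
    if best <= 0.0:
        warnings.warn("no cutoff separates the two populations; "
                      "returning grid minimum", stacklevel=2)
        return float(grid[0])
    return float(grid[np.argmax(youden)])  # argmax takes the first (smallest) tie
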