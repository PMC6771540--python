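"""Rosette, leaf, stomatal, pigment and survival metrics from tabular
phenotyping measurements.

The growth metrics operate on per-plant daily series of projected rosette
area A (mm^2), perimeter (mm) and convex-hull area (mm^2) segmented
upstream from top-view images:

* relative growth rate    RGR = (ln A_t - ln A_{t-dt}) / dt      [day^-1]
* stockiness              4 pi area / perimeter^2                 (1 = circle)
* compactness             rosette area / convex-hull area         (1 = convex)

Cellular and stomatal metrics: stomatal index = guard cells / epidermal
cells (as printed in the source protocol; the conventional variant
stomata / (stomata + epidermal) is available via ``conventional=True``);
cells per leaf = leaf area x average cell density; ostiole aperture ratio
R_wl = width / length.  The anthocyanin index is (A530 - A657) per gram
fresh weight.  Survival is summarized per replicate as percent survived
with the across-replicate mean and SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ROSETTE_COLUMNS = ("plant_id", "species", "treatment", "day",
                   "area", "perimeter", "hull_area", "survived")


def read_rosette_table(path) -> pd.DataFrame:
    """Long-format phenotyping TSV with one row per plant per day."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in ROSETTE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"rosette table missing columns: {missing}")
    return df


def relative_growth_rate(days, areas) -> pd.DataFrame:
    """Per-interval RGR = (ln A_t - ln A_{t-dt}) / dt for consecutive days.

    Areas must be strictly positive on both interval endpoints.
    """
    days = np.asarray(days, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if len(days) != len(areas):
        raise ValueError("days and areas must have equal length")
    if np.any(np.diff(days) <= 0):
        raise ValueError("days must be strictly increasing")
    if np.any(areas <= 0):
        raise ValueError("areas must be positive to take logarithms")
    dt = np.diff(days)
    rgr = np.diff(np.log(areas)) / dt
    return pd.DataFrame({"day_start": days[:-1], "day_end": days[1:], "rgr": rgr})


def stockiness(area: float, perimeter: float) -> float:
    """4 pi area / perimeter^2; 1 for a circle, < 1 for any other shape."""
    if perimeter <= 0:
        raise ValueError("perimeter must be positive")
    return 4.0 * math.pi * area / perimeter ** 2


def compactness(area: float, hull_area: float) -> float:
    """Rosette area over convex-hull area; 1 for a convex rosette."""
    if area <= 0:
        raise ValueError("area must be positive")
    if hull_area < area:
        raise ValueError("convex-hull area cannot be smaller than the area")
    return area / hull_area


def stomatal_index(guard_cells: int, epidermal_cells: int,
                   conventional: bool = False) -> float:
    """Guard cells over epidermal cells.

    With ``conventional=True``, the textbook index
    stomata / (stomata + epidermal cells) is returned instead.
    """
    if epidermal_cells <= 0:
        raise ValueError("epidermal cell count must be positive")
    if guard_cells < 0:
        raise ValueError("guard cell count must be nonnegative")
    if conventional:
        return guard_cells / (guard_cells + epidermal_cells)
    return guard_cells / epidermal_cells


def cells_per_leaf(leaf_area: float, cells_per_area: float) -> float:
    """Total leaf area times average cell number per area (unrounded)."""
    if leaf_area < 0 or cells_per_area < 0:
        raise ValueError("area and density must be nonnegative")
    return leaf_area * cells_per_area


def aperture_ratio(width: float, length: float) -> float:
    """Ostiole width over length, R_wl in [0, 1]."""
    if length <= 0:
        raise ValueError("ostiole length must be positive")
    if width < 0 or width > length:
        raise ValueError("width must satisfy 0 <= width <= length")
    return width / length


def anthocyanin_index(a530: float, a657: float, fresh_weight_g: float) -> float:
    """(A530 - A657) per gram fresh weight; may be negative."""
    if fresh_weight_g <= 0:
        raise ValueError("fresh weight must be positive")
    return (a530 - a657) / fresh_weight_g


@dataclass
class SurvivalSummary:
    per_replicate_percent: list[float]
    mean_percent: float
    sd_percent: float


def survival_rate(survived, replicate) -> SurvivalSummary:
    """Percent survival per replicate and the across-replicate mean +- SD."""
    df = pd.DataFrame({"survived": list(survived), "replicate": list(replicate)})
    if df.empty:
        raise ValueError("no plants")
    per_rep = (
        df.groupby("replicate", sort=True)["survived"]
        .apply(lambda s: 100.0 * s.astype(bool).mean())
    )
    vals = per_rep.to_list()
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return SurvivalSummary(vals, float(np.mean(vals)), sd)


def first_growth_reduction_day(
    ww: pd.DataFrame, wd: pd.DataFrame, alpha: float = 0.05
) -> float | None:
    """Earliest day with a significant WD < WW reduction in projected area.

    Per shared day, a one-sided Welch t-test compares WD against WW areas;
    the first day with p <= alpha is returned, or None if none.  Days with
    fewer than 2 plants per group are skipped.
    """
    days = sorted(set(ww["day"]) & set(wd["day"]))
    for day in days:
        a_ww = ww.loc[ww["day"] == day, "area"].to_numpy(dtype=float)
        a_wd = wd.loc[wd["day"] == day, "area"].to_numpy(dtype=float)
        if len(a_ww) < 2 or len(a_wd) < 2:
            continue
        if np.std(a_ww) == 0 and np.std(a_wd) == 0:
            if np.mean(a_wd) < np.mean(a_ww):
                return day  # exact separation, zero variance
            continue
        res = stats.ttest_ind(a_wd, a_ww, equal_var=False, alternative="less")
        if res.pvalue <= alpha:
            return day
    return None


def growth_metrics_table(rosette: pd.DataFrame) -> pd.DataFrame:
    """Per-plant per-day stockiness and compactness plus per-interval RGR."""
    rows = []
    for pid, sub in rosette.groupby("plant_id", sort=False):
        sub = sub.sort_values("day")
        rgr = relative_growth_rate(sub["day"], sub["area"])
        rgr_by_day_end = dict(zip(rgr["day_end"], rgr["rgr"]))
        for _, r in sub.iterrows():
            rows.append({
                "plant_id": pid,
                "species": r["species"],
                "treatment": r["treatment"],
                "day": r["day"],
                "stockiness": stockiness(r["area"], r["perimeter"]),
                "compactness": compactness(r["area"], r["hull_area"]),
                "rgr": rgr_by_day_end.get(r["day"], np.nan),
            })
    return pd.DataFrame(rows)
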