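"""Between-cohort replicability: per-category curve agreement and
DAP growth-chart agreement.

Given monthly mean category curves from two cohorts on the same bin grid,
each category is compared with Pearson's r (with two-sided p) and the mean
absolute error in percentage points; zero-variance (degenerate) categories
report MAE but a flagged, undefined r by default.  DAP chart agreement is
the Pearson correlation between monthly DAP means, per-parameter bootstrap
CI overlap of the 4PL fits, and the overlap of the ±1SD bands.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .chart import ChartBundle


@dataclasses.dataclass
class CohortComparison:
    per_category: pd.DataFrame       # category, r, p, mae_pp, n_bins, flagged
    group_summary: pd.DataFrame      # group, mean_r, min_r, max_r, mean_mae, ...


def compare_category_curves(curves_a: pd.DataFrame, curves_b: pd.DataFrame,
                            drop_degenerate_r: bool = True,
                            min_shared_bins: int = 3) -> CohortComparison:
    """Per-category (r, p, MAE) between two cohorts' monthly mean curves.

    Inputs are :func:`motorchart.features.agegroup_mean_curves` tables with
    identical category columns and bin grid; only bins populated in both
    cohorts are used.  MAE is reported in percentage points.
    """
    cats_a = [c for c in curves_a.columns if c.startswith(("posture_", "movement_", "cond_"))]
    cats_b = [c for c in curves_b.columns if c.startswith(("posture_", "movement_", "cond_"))]
    if cats_a != cats_b:
        raise ValueError("cohorts have different category inventories")
    if not curves_a["bin_start"].equals(curves_b["bin_start"]):
        raise ValueError("cohorts are on different bin grids")
    shared = (curves_a["n"].to_numpy() > 0) & (curves_b["n"].to_numpy() > 0)
    rows = []
    for cat in cats_a:
        a = curves_a.loc[shared, cat].to_numpy(dtype=float)
        b = curves_b.loc[shared, cat].to_numpy(dtype=float)
        n_bins = int(shared.sum())
        if n_bins < min_shared_bins:
            rows.append({"category": cat, "r": np.nan, "p": np.nan,
                         "mae_pp": np.nan, "n_bins": n_bins, "flagged": True})
            continue
        mae = float(np.mean(np.abs(a - b)) * 100.0)
        degenerate = np.ptp(a) == 0 or np.ptp(b) == 0
        if degenerate and drop_degenerate_r:
            rows.append({"category": cat, "r": np.nan, "p": np.nan,
                         "mae_pp": mae, "n_bins": n_bins, "flagged": True})
            continue
        if degenerate:
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(a, b)
        rows.append({"category": cat, "r": float(r), "p": float(p),
                     "mae_pp": mae, "n_bins": n_bins, "flagged": bool(degenerate)})
    per_category = pd.DataFrame(rows)

    def summarize(prefix: str) -> dict:
        sub = per_category[per_category["category"].str.startswith(prefix)]
        ok = sub[~sub["flagged"]]
        return {
            "group": prefix.rstrip("_"),
            "n_categories": len(sub),
            "mean_r": float(ok["r"].mean()) if len(ok) else np.nan,
            "min_r": float(ok["r"].min()) if len(ok) else np.nan,
            "max_r": float(ok["r"].max()) if len(ok) else np.nan,
            "mean_mae_pp": float(sub["mae_pp"].mean()),
            "min_mae_pp": float(sub["mae_pp"].min()),
            "max_mae_pp": float(sub["mae_pp"].max()),
        }
    prefixes = sorted({c.split("_")[0] + "_" for c in cats_a})
    group_summary = pd.DataFrame([summarize(p) for p in prefixes])
    return CohortComparison(per_category=per_category, group_summary=group_summary)


@dataclasses.dataclass
class ChartAgreement:
    agegroup_dap_r: float
    agegroup_dap_p: float
    params_overlap: dict[str, bool]
    all_params_overlap: bool
    band_overlap_fraction: float
    n_shared_bins: int


def compare_dap_models(chart_a: ChartBundle, chart_b: ChartBundle,
                       grid: np.ndarray | None = None) -> ChartAgreement:
    """Agreement between two DAP growth charts built on the same bin grid.

    Reports the Pearson correlation of monthly DAP means over bins populated
    in both charts, whether each 4PL parameter's bootstrap CIs overlap, and
    the fraction of an age grid where the two ±1SD bands intersect.
    """
    ta, tb = chart_a.monthly_table, chart_b.monthly_table
    if not ta["bin_start"].equals(tb["bin_start"]):
        raise ValueError("charts are on different bin grids")
    shared = (ta["n"].to_numpy() > 0) & (tb["n"].to_numpy() > 0)
    if shared.sum() < 3:
        raise ValueError("fewer than 3 shared populated bins")
    r, p = stats.pearsonr(ta.loc[shared, "mean"], tb.loc[shared, "mean"])
    params_overlap = {
        name: chart_a.param_ci[name].overlaps(chart_b.param_ci[name])
        for name in ("L", "U", "x0", "k")
    }
    if grid is None:
        lo = ta.loc[shared, "bin_start"].min()
        hi = ta.loc[shared, "bin_start"].max() + 1.0
        grid = np.linspace(lo, hi, 101)
    alo, ahi = chart_a.band(grid)
    blo, bhi = chart_b.band(grid)
    overlap = np.mean((alo <= bhi) & (blo <= ahi))
    return ChartAgreement(
        agegroup_dap_r=float(r), agegroup_dap_p=float(p),
        params_overlap=params_overlap,
        all_params_overlap=all(params_overlap.values()),
        band_overlap_fraction=float(overlap),
        n_shared_bins=int(shared.sum()),
    )
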