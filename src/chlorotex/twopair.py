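"""Exhaustive two-pair VI x TF combinations regressed linearly against LCC.

Each vegetation index VI is paired with each texture feature TF in three
algebraic forms:

    SR-type   = TF / VI
    NDVI-type = (VI - TF) / (VI + TF)
    DVI-type  = VI - TF

and ordinary least squares relates LCC to each combined value. With the
full registries (20 VIs x 8 TFs per PC image) that is 160 combinations per
type per PC image. The best pair per type is reported in the convention
``y = a*x + b`` with x the combination and y the LCC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "COMBINATION_TYPES",
    "TwoPairResult",
    "build_combination",
    "fit_linear",
    "exhaustive_search",
    "best_combination",
    "results_frame",
    "r2_grid",
    "plot_r2_grid",
]

COMBINATION_TYPES = ("SR", "NDVI", "DVI")


@dataclass
class TwoPairResult:
    """One (type, VI, TF) combination and its linear fit against LCC."""

    type: str
    vi_name: str
    tf_name: str
    pc_image: str
    slope: float
    intercept: float
    r2: float
    rmse: float
    n_used: int
    low_support: bool = False  # fit retained < 80% of points

    @property
    def model_string(self) -> str:
        return f"y = {self.slope:.4f}*x + {self.intercept:.4f}"


def build_combination(vi, tf, type: str):
    """Combine VI and TF values in one of the three forms.

    Division by zero yields NaN (flagged, never dropped silently here; the
    fit drops non-finite pairs and logs the count).
    """
    if type not in COMBINATION_TYPES:
        raise DataError(f"unknown combination type '{type}'; use {COMBINATION_TYPES}")
    vi = np.asarray(vi, dtype=float)
    tf = np.asarray(tf, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        if type == "SR":
            return np.where(vi != 0, tf / vi, np.nan)
        if type == "NDVI":
            den = vi + tf
            return np.where(den != 0, (vi - tf) / den, np.nan)
        return vi - tf


def fit_linear(combo, lcc) -> tuple[float, float, float, float, int]:
    """OLS of LCC on a combination: (slope, intercept, r2, rmse, n_used).

    Non-finite pairs are dropped; r2 = 1 - SS_res/SS_tot and
    rmse = sqrt(SS_res/n). A constant combination raises ``DataError`` (the
    search skips such pairs and records them as undefined).
    """
    x = np.asarray(combo, dtype=float)
    y = np.asarray(lcc, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise DataError("need >= 3 finite pairs for a linear fit")
    if np.ptp(x) == 0:
        raise DataError("constant combination: slope undefined")
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    sxy = float(((x - xm) * (y - ym)).sum())
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (slope * x + intercept)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - ym) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    rmse = float(np.sqrt(ss_res / n))
    return slope, intercept, float(r2), rmse, n


def exhaustive_search(
    vis: pd.DataFrame,
    tfs: pd.DataFrame,
    lcc,
    pc_image: str = "PC1",
    types=COMBINATION_TYPES,
) -> list[TwoPairResult]:
    """Fit every (vi, tf, type) combination; constant combos are skipped.

    ``vis`` and ``tfs`` are FeatureTable slices (rows = points). Results are
    sorted by descending r2 with ties broken by (type, vi, tf).
    """
    if vis.shape[1] < 1 or tfs.shape[1] < 1:
        raise DataError("need at least one VI and one TF column")
    y = np.asarray(lcc, dtype=float)
    n_total = y.size
    results = []
    for ctype in types:
        for vi_name in vis.columns:
            for tf_name in tfs.columns:
                combo = build_combination(vis[vi_name].to_numpy(),
                                          tfs[tf_name].to_numpy(), ctype)
                try:
                    slope, intercept, r2, rmse, n_used = fit_linear(combo, y)
                except DataError:
                    continue
                results.append(TwoPairResult(
                    type=ctype, vi_name=vi_name, tf_name=tf_name,
                    pc_image=pc_image, slope=slope, intercept=intercept,
                    r2=r2, rmse=rmse, n_used=n_used,
                    low_support=n_used < 0.8 * n_total,
                ))
    results.sort(key=lambda r: (-r.r2, r.type, r.vi_name, r.tf_name))
    return results


def best_combination(
    results: list[TwoPairResult], per_type: bool = True
) -> pd.DataFrame:
    """Argmax-r2 report shaped like the optimal-combination summary table.

    Ties resolve lexicographically on (type, vi, tf), so the report is
    deterministic across runs.
    """
    if not results:
        raise DataError("no results to summarize")
    pool: dict[str, TwoPairResult] = {}
    for res in sorted(results, key=lambda r: (-r.r2, r.type, r.vi_name, r.tf_name)):
        key = res.type if per_type else "all"
        if key not in pool:
            pool[key] = res
    rows = []
    for res in pool.values():
        label = {
            "SR": f"{res.tf_name}/{res.vi_name}",
            "NDVI": f"({res.vi_name}-{res.tf_name})/({res.vi_name}+{res.tf_name})",
            "DVI": f"{res.vi_name}-{res.tf_name}",
        }[res.type]
        rows.append({
            "type": f"{res.type}-type", "pc_image": res.pc_image,
            "combination": label, "model": res.model_string,
            "r2": res.r2, "rmse": res.rmse,
        })
    return pd.DataFrame(rows)


def results_frame(results: list[TwoPairResult]) -> pd.DataFrame:
    """Long-form results table (one row per combination)."""
    return pd.DataFrame([{
        "type": r.type, "pc": r.pc_image, "vi": r.vi_name, "tf": r.tf_name,
        "slope": r.slope, "intercept": r.intercept, "r2": r.r2,
        "rmse": r.rmse, "n_used": r.n_used, "low_support": r.low_support,
    } for r in results])


def r2_grid(results: list[TwoPairResult], type: str, pc_image: str) -> pd.DataFrame:
    """R2 matrix (VI rows x TF columns) for one type and PC image."""
    sub = [r for r in results if r.type == type and r.pc_image == pc_image]
    frame = results_frame(sub) if sub else pd.DataFrame(
        columns=["vi", "tf", "r2"])
    return frame.pivot(index="vi", columns="tf", values="r2") if len(frame) else frame


def plot_r2_grid(grid: pd.DataFrame, path, title: str = "") -> None:
    """Heatmap of an R2 grid (combination-search overview figure)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1 + 0.5 * grid.shape[1], 1 + 0.35 * grid.shape[0]))
    im = ax.imshow(grid.to_numpy(), cmap="viridis", vmin=0, vmax=1, aspect="auto")
    ax.set_xticks(range(grid.shape[1]), grid.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(grid.shape[0]), grid.index, fontsize=7)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="$R^2$")
    fig.tight_layout()
    fig.savefig(path, dpi=120, metadata={"Software": None})
    plt.close(fig)
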