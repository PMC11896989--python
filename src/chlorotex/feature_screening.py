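"""Feature screening against LCC by Pearson |r| and MIC.

The maximal information coefficient follows the original MINE recipe: for
every grid shape (nx, ny) with nx*ny <= n^alpha, one axis is equipartitioned
by rank and the other is optimally partitioned by dynamic programming over
candidate cut points ("clumps"); the mutual information of the resulting
grid is normalized by log2(min(nx, ny)) and the maximum over shapes and the
two orientations is the MIC. Defaults alpha=0.6, c=15 match the original
estimator.

Features with |r| or MIC strictly above the screening threshold (0.8 by
default) are selected as candidate predictors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .errors import DataError, UndefinedCorrelationError
from .spectral_features import FeatureTable

__all__ = ["ScreeningResult", "pearson_r", "mic", "select_features",
           "equipartition", "clump_cumulative", "optimal_partition_info"]


def pearson_r(x, y) -> float:
    """Sample Pearson correlation; constant input is an error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DataError("need two equal-length samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# MIC


def equipartition(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Rank-equipartition into ``n_bins`` bins; ties share a bin.

    Returns a bin label per observation (same order as input). Equal values
    always land in the same bin, which makes the statistic invariant under
    strictly monotone transforms.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    order = np.argsort(values, kind="mergesort")
    desired = np.floor(np.arange(n) * n_bins / n).astype(np.int64)
    labels_sorted = desired.copy()
    # push ties into the bin of their first occurrence
    for t in range(1, n):
        if values[order[t]] == values[order[t - 1]]:
            labels_sorted[t] = labels_sorted[t - 1]
    labels = np.empty(n, dtype=np.int64)
    labels[order] = labels_sorted
    # compact to consecutive labels
    uniq = np.unique(labels)
    remap = {v: k for k, v in enumerate(uniq)}
    return np.array([remap[v] for v in labels], dtype=np.int64)


def clump_cumulative(x: np.ndarray, q: np.ndarray, n_bins_y: int,
                     max_clumps: int) -> np.ndarray:
    """Cumulative y-bin counts at candidate x-cut points.

    Points are ordered by x; groups of identical x are atomic, and adjacent
    atoms whose points all share one y-bin are merged (a cut inside such a
    run never improves the optimum). If more clumps remain than
    ``max_clumps``, clumps are coarsened by size-equipartition. Returns an
    array of shape (k+1, n_bins_y): row t holds counts of the first t clumps.
    """
    order = np.argsort(x, kind="mergesort")
    xs, qs = np.asarray(x, float)[order], np.asarray(q)[order]
    n = xs.size
    # atoms: runs of equal x
    atom_id = np.zeros(n, dtype=np.int64)
    for t in range(1, n):
        atom_id[t] = atom_id[t - 1] + (1 if xs[t] != xs[t - 1] else 0)
    n_atoms = atom_id[-1] + 1
    atom_counts = np.zeros((n_atoms, n_bins_y), dtype=np.int64)
    for t in range(n):
        atom_counts[atom_id[t], qs[t]] += 1
    # merge adjacent single-bin atoms sharing the same y-bin
    clumps: list[np.ndarray] = []
    for a in range(n_atoms):
        row = atom_counts[a]
        if clumps:
            prev = clumps[-1]
            nz_prev = np.nonzero(prev)[0]
            nz_row = np.nonzero(row)[0]
            if (nz_prev.size == 1 and nz_row.size == 1
                    and nz_prev[0] == nz_row[0]):
                clumps[-1] = prev + row
                continue
        clumps.append(row.copy())
    counts = np.asarray(clumps)
    if counts.shape[0] > max_clumps:
        # coarsen by size-equipartition of points across superclumps
        sizes = counts.sum(axis=1)
        cum = np.cumsum(sizes)
        target = np.floor(cum * max_clumps / cum[-1] - 1e-9).astype(np.int64)
        merged = np.zeros((target[-1] + 1, n_bins_y), dtype=np.int64)
        for k_, row in enumerate(counts):
            merged[target[k_]] += row
        counts = merged
    return np.vstack([np.zeros((1, n_bins_y), dtype=np.int64),
                      np.cumsum(counts, axis=0)])


@njit(cache=False)
def _dp_max_info(cum, nx):  # pragma: no cover
    """Max over <=nx-bin partitions of sum_bins sum_q c*ln(c/c_bin) (nats)."""
    k = cum.shape[0] - 1
    ny = cum.shape[1]
    neg_inf = -1.0e300
    G = np.full((k + 1, nx + 1), neg_inf)
    for l in range(nx + 1):
        G[0, l] = 0.0
    for t in range(1, k + 1):
        for l in range(1, nx + 1):
            best = neg_inf
            for s in range(t):
                if G[s, l - 1] <= neg_inf / 2:
                    continue
                tot = 0.0
                gval = 0.0
                for qb in range(ny):
                    cqb = cum[t, qb] - cum[s, qb]
                    tot += cqb
                    if cqb > 0:
                        gval += cqb * np.log(cqb)
                if tot > 0:
                    gval -= tot * np.log(tot)
                cand = G[s, l - 1] + gval
                if cand > best:
                    best = cand
            G[t, l] = best
    best_all = neg_inf
    for l in range(1, nx + 1):
        if G[k, l] > best_all:
            best_all = G[k, l]
    return best_all


def optimal_partition_info(x: np.ndarray, y: np.ndarray, nx: int, ny: int,
                           c: int = 15) -> float:
    """Max I(X;Y) in bits over <=nx x-bins with the y axis equipartitioned."""
    q = equipartition(y, ny)
    ny_eff = int(q.max()) + 1
    if ny_eff < 2:
        return 0.0
    cum = clump_cumulative(np.asarray(x, float), q, ny_eff, max_clumps=c * nx)
    n = int(cum[-1].sum())
    totals = cum[-1].astype(float)
    p = totals / n
    h_q_nats = float(-(p[p > 0] * np.log(p[p > 0])).sum())
    g = _dp_max_info(cum.astype(np.int64), np.int64(nx))
    info_nats = h_q_nats + g / n
    return max(0.0, info_nats / np.log(2.0))


def mic(x, y, alpha: float = 0.6, c: int = 15) -> float:
    """Maximal information coefficient of two samples, in [0, 1].

    ``alpha`` bounds the grid budget (nx*ny <= n**alpha); ``c`` limits the
    number of candidate cut points per axis to ``c * nx``. Constant input
    yields 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 10:
        raise DataError("MIC needs two equal-length samples with n >= 10")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        warnings.warn("constant input: MIC is 0", stacklevel=2)
        return 0.0
    n = x.size
    budget = max(int(np.floor(n**alpha)), 4)
    best = 0.0
    for nx in range(2, budget // 2 + 1):
        for ny in range(2, budget // nx + 1):
            info = max(
                optimal_partition_info(x, y, nx, ny, c=c),
                optimal_partition_info(y, x, nx, ny, c=c),
            )
            val = info / np.log2(min(nx, ny))
            if val > best:
                best = val
    return float(min(best, 1.0))


# ---------------------------------------------------------------------------
# Selection


@dataclass
class ScreeningResult:
    """Per-feature correlation screening report."""

    table: pd.DataFrame  # feature, provenance, r, abs_r, mic, selected flags
    r_threshold: float
    mic_threshold: float

    def selected(self, method: str) -> list[str]:
        col = {"r": "selected_by_r", "mic": "selected_by_mic"}[method]
        return self.table.loc[self.table[col], "feature"].tolist()

    def selected_by_provenance(self, method: str) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for name in self.selected(method):
            prov = self.table.set_index("feature").loc[name, "provenance"]
            out.setdefault(prov, []).append(name)
        return out


def select_features(
    table: FeatureTable,
    r_threshold: float = 0.8,
    mic_threshold: float = 0.8,
    mic_alpha: float = 0.6,
    mic_c: int = 15,
) -> ScreeningResult:
    """Screen every feature column against SPAD by |r| and MIC.

    Selection is strict (> threshold). Rows are ordered by descending |r|
    with lexicographic tie-breaks on the feature name, so reports are
    deterministic.
    """
    y = table.spad.to_numpy()
    rows = []
    for name in table.feature_names:
        xcol = table.data[name].to_numpy()
        try:
            r = pearson_r(xcol, y)
        except UndefinedCorrelationError:
            r = np.nan
        m = mic(xcol, y, alpha=mic_alpha, c=mic_c)
        rows.append({
            "feature": name,
            "provenance": table.provenance.get(name, "VI"),
            "r": r,
            "abs_r": abs(r) if np.isfinite(r) else np.nan,
            "mic": m,
            "selected_by_r": bool(np.isfinite(r) and abs(r) > r_threshold),
            "selected_by_mic": bool(m > mic_threshold),
        })
    df = pd.DataFrame(rows).sort_values(
        ["abs_r", "feature"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    if not (df["selected_by_r"].any() or df["selected_by_mic"].any()):
        warnings.warn("no feature passed either screening threshold", stacklevel=2)
    return ScreeningResult(table=df, r_threshold=r_threshold,
                           mic_threshold=mic_threshold)
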