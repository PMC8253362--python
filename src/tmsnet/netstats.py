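"""Edge-wise comparison of time-varying networks between conditions.

Each directed edge (source j → target i) at each time point is compared
between two groups of units with Welch's two-sample t-test; the resulting
p-value family (all off-diagonal edges × all time points, one family) is
corrected by Benjamini–Hochberg false-discovery-rate control.  Significant
edges within a time window of interest are summarized as increased/decreased
connection lists grouped by scalp region.

"Units" are whatever carries independent Q² tensors — subjects in a group
study, or disjoint trial sub-ensembles on a single synthetic session.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .montage import REGION_MAP

__all__ = ["EdgeComparison", "edgewise_ttest", "bh_fdr", "summarize_connections"]


@dataclass
class EdgeComparison:
    """Per-(time, target, source) test results for a two-group comparison.

    ``sign`` is +1 where FDR-significant and group B exceeds group A
    (connection increased under B), −1 where decreased, 0 elsewhere.  The
    diagonal and degenerate (zero-variance-in-both-groups) cells carry NaN
    statistics; degenerate cells get p = 1 and are flagged.
    """

    t_stat: np.ndarray  # (T, n, n)
    p_raw: np.ndarray
    p_adj: np.ndarray
    sign: np.ndarray  # int8
    alpha: float
    n_a: int
    n_b: int
    times: np.ndarray
    channels: list[str] | None = None
    degenerate: np.ndarray | None = None


def edgewise_ttest(
    group_a: np.ndarray,
    group_b: np.ndarray,
    times: np.ndarray | None = None,
    channels: list[str] | None = None,
    paired: bool = False,
) -> EdgeComparison:
    """Welch two-sample t-test per (time, target, source) cell.

    ``group_a``/``group_b`` are (units, T, n, n) stacks of per-unit Q²
    tensors.  Positive t means group B > group A.  Diagonal cells are
    excluded (NaN); cells with zero variance in both groups get t = 0, p = 1
    and a degenerate flag.  With ``paired=True`` units are matched across
    groups (within-subject design) and a paired t replaces Welch.  FDR
    adjustment is applied afterwards by :func:`bh_fdr` via the ``alpha``
    default of 0.05.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.ndim != 4 or b.ndim != 4:
        raise ValueError("groups must be (units, time, n, n)")
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("group tensors must share (time, n, n) shape")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 units")
    if paired and a.shape[0] != b.shape[0]:
        raise ValueError("paired mode needs equal unit counts")
    t_len, n, _ = a.shape[1:]
    if paired:
        res = scipy.stats.ttest_rel(b, a, axis=0)
    else:
        res = scipy.stats.ttest_ind(b, a, axis=0, equal_var=False)
    t_stat = np.asarray(res.statistic, dtype=float)
    p_raw = np.asarray(res.pvalue, dtype=float)
    degenerate = (a.var(axis=0) == 0) & (b.var(axis=0) == 0)
    t_stat[degenerate] = 0.0
    p_raw[degenerate] = 1.0
    diag = np.eye(n, dtype=bool)
    t_stat[:, diag] = np.nan
    p_raw[:, diag] = np.nan
    if times is None:
        times = np.arange(t_len, dtype=float)
    comp = EdgeComparison(
        t_stat=t_stat, p_raw=p_raw, p_adj=np.full_like(p_raw, np.nan),
        sign=np.zeros(p_raw.shape, dtype=np.int8), alpha=np.nan,
        n_a=a.shape[0], n_b=b.shape[0], times=np.asarray(times, float),
        channels=channels, degenerate=degenerate,
    )
    return comp


def bh_fdr(pvals: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up adjusted p-values and significance mask.

    NaN entries (excluded cells) are ignored and stay NaN/non-significant.
    The mask is the BH rejection set, i.e. adjusted p ≤ alpha.
    """
    p = np.asarray(pvals, dtype=float)
    flat = p.ravel()
    valid = ~np.isnan(flat)
    if np.any((flat[valid] < 0) | (flat[valid] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    adj = np.full(flat.shape, np.nan)
    mask = np.zeros(flat.shape, dtype=bool)
    if valid.any():
        rej, p_adj, *_ = multipletests(flat[valid], alpha=alpha, method="fdr_bh")
        adj[valid] = p_adj
        mask[valid] = rej
    return adj.reshape(p.shape), mask.reshape(p.shape)


def apply_fdr(comp: EdgeComparison, alpha: float = 0.05) -> EdgeComparison:
    """Fill in FDR-adjusted p-values and the signed significance mask."""
    adj, mask = bh_fdr(comp.p_raw, alpha)
    sign = np.zeros(comp.p_raw.shape, dtype=np.int8)
    sign[mask & (comp.t_stat > 0)] = 1
    sign[mask & (comp.t_stat < 0)] = -1
    comp.p_adj = adj
    comp.sign = sign
    comp.alpha = alpha
    return comp


def compare_networks(
    group_a: np.ndarray,
    group_b: np.ndarray,
    times: np.ndarray | None = None,
    channels: list[str] | None = None,
    alpha: float = 0.05,
    paired: bool = False,
) -> EdgeComparison:
    """Edge-wise t-tests (Welch or paired) followed by BH FDR in one family."""
    return apply_fdr(edgewise_ttest(group_a, group_b, times, channels, paired),
                     alpha)


def summarize_connections(
    comp: EdgeComparison,
    window: tuple[float, float],
    min_frac: float = 0.5,
    region_map: dict[str, str] | None = None,
) -> dict[str, list[dict]]:
    """Increased/decreased directed edges within a time window of interest.

    An edge is reported if it is FDR-significant with a consistent sign in at
    least ``min_frac`` of the window's time points.  Edges are annotated with
    source/target scalp regions from ``region_map`` (10-20 default).
    """
    t0, t1 = window
    sel = (comp.times >= t0) & (comp.times <= t1)
    if not sel.any():
        raise ValueError(f"window [{t0:g}, {t1:g}] contains no time points")
    region_map = REGION_MAP if region_map is None else region_map
    sign = comp.sign[sel]  # (w, n, n)
    n = sign.shape[1]
    w = sign.shape[0]
    labels = comp.channels or [f"ch{i}" for i in range(n)]
    result: dict[str, list[dict]] = {"increased": [], "decreased": []}
    for direction, val in (("increased", 1), ("decreased", -1)):
        frac = (sign == val).sum(axis=0) / w  # (target, source)
        for i in range(n):
            for j in range(n):
                if i == j or frac[i, j] < min_frac:
                    continue
                src, tgt = labels[j], labels[i]
                result[direction].append({
                    "source": src,
                    "target": tgt,
                    "source_region": region_map.get(src, "unknown"),
                    "target_region": region_map.get(tgt, "unknown"),
                    "fraction_significant": float(frac[i, j]),
                })
    for lst in result.values():
        lst.sort(key=lambda d: -d["fraction_significant"])
    return result
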