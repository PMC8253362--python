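"""ERP window amplitudes, behavioral summaries, and within-subject ANOVA.

ERP component amplitudes are window means of condition-averaged waveforms:
P1 (60–110 ms), N1 (112–200 ms), N270 (220–320 ms) and P3 (322–500 ms)
relative to S2 onset, read at posterior electrodes for P1/N1 and
centro-parietal electrodes for N270/P3.  Behavioral trials are filtered
(correct responses with 200 ms ≤ RT ≤ 1500 ms; boundary values retained) and
summarized per (condition, task, type) cell.  The factorial repeated-measures
ANOVA applies the Greenhouse–Geisser epsilon correction for non-sphericity
and Bonferroni-corrected pairwise follow-ups.

The ANOVA engine handles any number of fully-crossed within-subject factors
via orthonormal Kronecker contrasts: for effect E the contrast matrix is the
Kronecker product over factors of an orthonormal contrast basis (factors in
E) or the normalized unit vector (factors averaged out); with D = Y C' the
effect F-statistic is (n‖d̄‖²/q) / (Σ‖D − d̄‖²/(q(n−1))) and ε is computed
from the covariance of the contrast scores, ε = tr(Σ)²/(q·tr(Σ²)).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .containers import EpochSet

__all__ = [
    "ComponentWindow",
    "DEFAULT_COMPONENTS",
    "average_erp",
    "window_amplitude",
    "filter_trials",
    "behavior_summary",
    "rm_anova_gg",
    "AnovaTable",
]

#: seconds from the alignment (pulse) event to S2 onset
S2_OFFSET_S = 0.3


@dataclass
class ComponentWindow:
    """A named ERP component: latency window (ms, relative to S2) + electrodes."""

    name: str
    window_ms: tuple[float, float]
    electrodes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.window_ms[0] >= self.window_ms[1]:
            raise ValueError("window start must precede end")


DEFAULT_COMPONENTS: list[ComponentWindow] = [
    ComponentWindow("P1", (60.0, 110.0), ("P3", "P4", "O1", "O2")),
    ComponentWindow("N1", (112.0, 200.0), ("P3", "P4", "O1", "O2")),
    ComponentWindow("N270", (220.0, 320.0), ("C3", "C4", "P3", "P4")),
    ComponentWindow("P3", (322.0, 500.0), ("C3", "C4", "P3", "P4")),
]


def average_erp(
    ep: EpochSet,
    group_by: list[str] | None = None,
) -> dict[tuple, np.ndarray]:
    """Per-cell mean waveforms (channels × time), honoring the bad-sample mask.

    Masked (artifact-interpolated) samples are excluded from the mean per
    time point.  With ``group_by=None`` a single grand average is returned
    under the key ``("all",)``.
    """
    if group_by:
        if ep.metadata is None:
            raise ValueError("group_by requires trial metadata")
        groups = ep.metadata.groupby(group_by, sort=True).indices
        cells = {k if isinstance(k, tuple) else (k,): np.asarray(v)
                 for k, v in groups.items()}
    else:
        cells = {("all",): np.arange(ep.n_trials)}
    out: dict[tuple, np.ndarray] = {}
    for key, rows in cells.items():
        if rows.size == 0:
            raise ValueError(f"empty cell {key!r}")
        data = ep.data[rows]  # (k, C, T)
        good = ~ep.mask[rows]  # (k, T)
        weights = good[:, None, :].astype(float)
        denom = weights.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = (data * weights).sum(axis=0) / denom
        # time points masked in every trial fall back to the plain mean
        allbad = denom[0] == 0
        if allbad.any():
            mean[:, allbad] = data.mean(axis=0)[:, allbad]
        out[key] = mean
    return out


def window_amplitude(
    waveform: np.ndarray,
    times: np.ndarray,
    cw: ComponentWindow,
    channels: list[str],
    s2_offset: float = S2_OFFSET_S,
) -> dict[str, float]:
    """Mean amplitude of ``cw`` per electrode from one averaged waveform.

    The window is half-open in S2-relative latency: samples with
    ``start <= (t - s2_offset)*1000 < end`` enter the mean.
    """
    lat_ms = (np.asarray(times) - s2_offset) * 1000.0
    lo, hi = cw.window_ms
    sel = (lat_ms >= lo) & (lat_ms < hi)
    if not sel.any():
        raise ValueError(f"window {cw.window_ms} ms outside the waveform span")
    out = {}
    for el in cw.electrodes:
        if el not in channels:
            raise ValueError(f"electrode {el!r} not in montage")
        out[el] = float(waveform[channels.index(el), sel].mean())
    return out


def amplitude_table(
    averages: dict[tuple, np.ndarray],
    times: np.ndarray,
    channels: list[str],
    components: list[ComponentWindow] | None = None,
    group_names: list[str] | None = None,
    s2_offset: float = S2_OFFSET_S,
) -> pd.DataFrame:
    """Long-format window-amplitude table over cells × components × electrodes."""
    components = DEFAULT_COMPONENTS if components is None else components
    rows = []
    for key, wave in averages.items():
        for cw in components:
            amps = window_amplitude(wave, times, cw, channels, s2_offset)
            for el, amp in amps.items():
                row = {"component": cw.name, "electrode": el, "amplitude_uv": amp}
                if group_names:
                    row.update(dict(zip(group_names, key)))
                else:
                    row["cell"] = "/".join(map(str, key))
                rows.append(row)
    return pd.DataFrame(rows)


def filter_trials(
    tt: pd.DataFrame,
    rt_min: float = 200.0,
    rt_max: float = 1500.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Exclude incorrect trials and RT outliers (strictly <rt_min or >rt_max).

    Boundary RTs are retained.  Returns the surviving rows and a log of
    exclusion counts per reason (a trial is counted once, first reason wins:
    incorrect, then too-fast, then too-slow).
    """
    if "rt_ms" not in tt.columns or "correct" not in tt.columns:
        raise ValueError("trial table needs 'rt_ms' and 'correct' columns")
    incorrect = ~tt["correct"].astype(bool)
    fast = tt["rt_ms"] < rt_min
    slow = tt["rt_ms"] > rt_max
    log = {
        "incorrect": int(incorrect.sum()),
        "rt_too_fast": int((fast & ~incorrect).sum()),
        "rt_too_slow": int((slow & ~incorrect).sum()),
    }
    keep = ~(incorrect | fast | slow)
    log["kept"] = int(keep.sum())
    return tt.loc[keep].reset_index(drop=True), log


def behavior_summary(tt: pd.DataFrame) -> pd.DataFrame:
    """Per-(condition, task, type) mean RT, SD, and correct rate.

    The correct rate is computed over all attempted trials in the cell; RT
    statistics use only correct trials inside the RT window.  Cells with no
    surviving RT trials get NaN RT statistics, flagged, not an error.
    """
    if tt.empty:
        raise ValueError("empty trial table")
    keys = ["condition", "task", "stim_type"]
    filtered, _ = filter_trials(tt)
    rows = []
    for key, cell in tt.groupby(keys, sort=True):
        sub = filtered
        for k, v in zip(keys, key):
            sub = sub[sub[k] == v]
        rows.append({
            "condition": key[0], "task": key[1], "stim_type": key[2],
            "n_trials": len(cell),
            "correct_rate": float(cell["correct"].mean()),
            "rt_mean_ms": float(sub["rt_ms"].mean()) if len(sub) else np.nan,
            "rt_sd_ms": float(sub["rt_ms"].std(ddof=1)) if len(sub) > 1 else np.nan,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# repeated-measures ANOVA with Greenhouse–Geisser correction


@dataclass
class AnovaTable:
    """Within-subject ANOVA results: one row per effect, plus follow-ups."""

    effects: pd.DataFrame
    pairwise: pd.DataFrame | None = None
    factors: dict[str, list] = field(default_factory=dict)


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k matrix with orthonormal rows spanning the centering space."""
    c = np.eye(k) - 1.0 / k
    q, _ = np.linalg.qr(c.T)
    return q[:, : k - 1].T


def rm_anova_gg(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    within: list[str],
) -> AnovaTable:
    """Fully-crossed within-subject factorial ANOVA with GG correction.

    ``data`` is long-format with one row per (subject, cell); the design must
    be complete and balanced (exactly one observation per subject and cell —
    average repeats beforehand).  For every effect (main effects and all
    interactions) the table reports uncorrected and ε-corrected degrees of
    freedom, F, both p-values, and the Greenhouse–Geisser ε.  Effects with
    zero error variance get NaN F and a flag instead of a crash.  Pairwise
    follow-ups (paired t-tests per factor, averaged over the other factors)
    are Bonferroni-corrected with the multiplier capped so p ≤ 1.
    """
    for col in [dv, subject, *within]:
        if col not in data.columns:
            raise ValueError(f"missing column {col!r}")
    levels = {f: sorted(data[f].unique().tolist()) for f in within}
    subjects = sorted(data[subject].unique().tolist())
    n = len(subjects)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    cells = list(itertools.product(*[levels[f] for f in within]))
    pivot = data.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    if isinstance(pivot.columns, pd.MultiIndex):
        pivot = pivot.reindex(columns=pd.MultiIndex.from_tuples(cells, names=within))
    else:
        pivot = pivot.reindex(columns=[c[0] for c in cells])
    if pivot.isna().any().any():
        raise ValueError("incomplete design: every subject needs every cell")
    y = pivot.loc[subjects].to_numpy(dtype=float)  # (n, n_cells)

    contrasts = {f: _orthonormal_contrasts(len(levels[f])) for f in within}
    means_vec = {f: np.full((1, len(levels[f])), 1.0 / np.sqrt(len(levels[f])))
                 for f in within}

    rows = []
    for r in range(1, len(within) + 1):
        for combo in itertools.combinations(within, r):
            c = np.ones((1, 1))
            for f in within:
                block = contrasts[f] if f in combo else means_vec[f]
                c = np.kron(c, block)
            d = y @ c.T  # (n, q)
            q = d.shape[1]
            dbar = d.mean(axis=0)
            ss_eff = n * float(dbar @ dbar)
            resid = d - dbar
            ss_err = float((resid**2).sum())
            df1, df2 = q, q * (n - 1)
            cov = np.cov(d, rowvar=False).reshape(q, q)
            tr = np.trace(cov)
            tr2 = np.trace(cov @ cov)
            eps = 1.0 if q == 1 or tr2 == 0 else float(tr**2 / (q * tr2))
            eps = min(max(eps, 1.0 / q), 1.0)
            if ss_err > 0:
                f_val = (ss_eff / df1) / (ss_err / df2)
                p_unc = float(scipy.stats.f.sf(f_val, df1, df2))
                p_gg = float(scipy.stats.f.sf(f_val, df1 * eps, df2 * eps))
                degenerate = False
            else:
                f_val, p_unc, p_gg, degenerate = np.nan, np.nan, np.nan, True
            rows.append({
                "effect": " x ".join(combo), "df1": df1, "df2": df2,
                "df1_gg": df1 * eps, "df2_gg": df2 * eps,
                "F": f_val, "p": p_unc, "p_gg": p_gg, "epsilon": eps,
                "ss_effect": ss_eff, "ss_error": ss_err, "degenerate": degenerate,
            })
    effects = pd.DataFrame(rows)

    pw_rows = []
    for f in within:
        lv = levels[f]
        if len(lv) < 2:
            continue
        n_pairs = len(lv) * (len(lv) - 1) // 2
        by = pivot.T.groupby(level=f).mean().T if len(within) > 1 else pivot
        for a, b in itertools.combinations(lv, 2):
            da = by[a].to_numpy(dtype=float)
            db = by[b].to_numpy(dtype=float)
            diff = da - db
            if np.allclose(diff.std(ddof=1), 0):
                t_val, p_val = (np.nan, np.nan) if np.allclose(diff.mean(), 0) else (np.inf, 0.0)
            else:
                t_val, p_val = scipy.stats.ttest_rel(da, db)
            pw_rows.append({
                "factor": f, "level_a": a, "level_b": b,
                "mean_diff": float(diff.mean()), "t": float(t_val),
                "p_bonf": float(min(p_val * n_pairs, 1.0)) if np.isfinite(p_val) else p_val,
            })
    pairwise = pd.DataFrame(pw_rows) if pw_rows else None
    return AnovaTable(effects=effects, pairwise=pairwise, factors=levels)
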