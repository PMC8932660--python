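"""Occupancy, slope, duration and z-distribution statistics over brain-state
sequences, with frequentist and Bayes-factor group comparisons.

The headline statistic is the occupancy-versus-similarity slope: within each
session, the probability of occurrence of each brain state is regressed (OLS)
on the state's structure-function similarity. Anesthesia concentrates
occupancy on the most structure-like states (large positive slope); wakeful
or restored dynamics spread occupancy across the repertoire (slope near
zero). Slopes are compared across conditions with a two-sample t test and a
JZS Bayes factor (Cauchy prior scale sqrt(2)/2); BF10 > 3 is read as strong
evidence for a difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sp_stats
from scipy.spatial.distance import pdist

from .brain_states import vectorize_fc
from .dynamic_fc import FCWindowStack

__all__ = [
    "SlopeResult",
    "BFResult",
    "occupancy",
    "similarity_slope",
    "slopes_by_session",
    "state_durations",
    "durations_table",
    "z_histogram",
    "z_histograms",
    "z_vs_distance",
    "compare_slopes",
]


@dataclass
class SlopeResult:
    """OLS fit of occupancy against state similarity for one session."""

    slope: float
    intercept: float
    resid_sd: float
    condition: str = ""
    session_id: str = ""


@dataclass
class BFResult:
    """Two-sample comparison: t statistic, p, and JZS Bayes factors."""

    t: float
    p: float
    bf10: float
    bf01: float
    n_a: int
    n_b: int


# ---------------------------------------------------------------------------
# occupancy
# ---------------------------------------------------------------------------

def occupancy(
    label_sequences: dict[tuple[str, str], np.ndarray], k: int
) -> pd.DataFrame:
    """Within-session probability of occurrence of each state.

    Rows are indexed by (condition, session); columns are states 1..k; each
    row sums to 1. Zero-count states are reported as 0.
    """
    rows = {}
    for (cond, sess), labels in label_sequences.items():
        labels = np.asarray(labels)
        if labels.size == 0:
            raise ValueError(f"empty label sequence for session {(cond, sess)!r}")
        if labels.min() < 1 or labels.max() > k:
            raise ValueError(f"labels outside 1..{k} for session {(cond, sess)!r}")
        counts = np.bincount(labels, minlength=k + 1)[1:]
        rows[(cond, sess)] = counts / counts.sum()
    df = pd.DataFrame.from_dict(rows, orient="index", columns=range(1, k + 1))
    df.index = pd.MultiIndex.from_tuples(df.index, names=["condition", "session"])
    return df


# ---------------------------------------------------------------------------
# occupancy-vs-similarity slope
# ---------------------------------------------------------------------------

def similarity_slope(
    occupancy_row: np.ndarray, similarities: np.ndarray
) -> SlopeResult:
    """OLS slope of state occupancy against structure-function similarity."""
    y = np.asarray(occupancy_row, dtype=float)
    x = np.asarray(similarities, dtype=float)
    if y.shape != x.shape:
        raise ValueError("occupancy and similarity vectors must match")
    if np.ptp(x) == 0:
        raise ValueError("similarities are all equal; slope undefined")
    res = sp_stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    dof = max(1, y.size - 2)
    return SlopeResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        resid_sd=float(np.sqrt((resid**2).sum() / dof)),
    )


def slopes_by_session(occ: pd.DataFrame, similarities: np.ndarray) -> pd.DataFrame:
    """Per-session slope table from an occupancy table."""
    rows = []
    for (cond, sess), row in occ.iterrows():
        fit = similarity_slope(row.to_numpy(), similarities)
        rows.append(
            {
                "condition": cond,
                "session": sess,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "resid_sd": fit.resid_sd,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# state durations
# ---------------------------------------------------------------------------

def state_durations(label_sequence: np.ndarray, k: int | None = None) -> pd.DataFrame:
    """Mean run length (in windows) and run count per state for one sequence.

    The sequence is decomposed into maximal runs of a single state; states
    that never occur get NaN mean length and zero runs.
    """
    labels = np.asarray(label_sequence)
    if labels.size == 0:
        raise ValueError("label sequence is empty")
    if k is None:
        k = int(labels.max())
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    run_states = labels[starts]
    run_lengths = ends - starts
    rows = []
    for s in range(1, k + 1):
        lens = run_lengths[run_states == s]
        rows.append(
            {
                "state": s,
                "mean_duration": float(lens.mean()) if lens.size else np.nan,
                "n_runs": int(lens.size),
            }
        )
    return pd.DataFrame(rows)


def durations_table(
    label_sequences: dict[tuple[str, str], np.ndarray], k: int
) -> pd.DataFrame:
    """Per-(condition, state) mean run length pooled over sessions."""
    pooled: dict[tuple[str, int], list[np.ndarray]] = {}
    for (cond, _sess), labels in label_sequences.items():
        per = state_durations(labels, k)
        for _, r in per.iterrows():
            pooled.setdefault((cond, int(r["state"])), []).append(
                (r["mean_duration"], r["n_runs"])
            )
    rows = []
    for (cond, s), vals in sorted(pooled.items()):
        durs = [m for m, n in vals if n > 0]
        n_runs = int(sum(n for _, n in vals))
        # weighted mean of per-session means by run counts
        if n_runs > 0:
            mean = sum(m * n for m, n in vals if n > 0) / n_runs
        else:
            mean = np.nan
        rows.append(
            {"condition": cond, "state": s, "mean_duration": mean, "n_runs": n_runs}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# z-value histograms
# ---------------------------------------------------------------------------

def _state_z_values(
    stack: FCWindowStack | np.ndarray, labels: np.ndarray, state: int
) -> np.ndarray:
    x = vectorize_fc(stack)
    labels = np.asarray(labels)
    if labels.size != x.shape[0]:
        raise ValueError("labels must have one entry per window")
    mask = labels == state
    if not mask.any():
        raise ValueError(f"state {state} does not occur in the label sequence")
    return x[mask].ravel()


def z_histogram(
    stack: FCWindowStack | np.ndarray,
    labels: np.ndarray,
    state: int,
    n_bins: int = 45,
    value_range: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized histogram of a state's upper-triangle z values.

    Returns (bin_edges, masses); masses sum to 1. Pass a common
    ``value_range`` when comparing states so the bins align (see
    :func:`z_histograms`).
    """
    vals = _state_z_values(stack, labels, state)
    counts, edges = np.histogram(vals, bins=n_bins, range=value_range)
    return edges, counts / counts.sum()


def z_histograms(
    stack: FCWindowStack | np.ndarray,
    labels: np.ndarray,
    states: list[int],
    n_bins: int = 45,
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Histograms for several states over a shared global bin range."""
    pooled = [(s, _state_z_values(stack, labels, s)) for s in states]
    lo = min(v.min() for _, v in pooled)
    hi = max(v.max() for _, v in pooled)
    out = {}
    for s, vals in pooled:
        counts, edges = np.histogram(vals, bins=n_bins, range=(lo, hi))
        out[s] = (edges, counts / counts.sum())
    return out


def z_vs_distance(
    stack: FCWindowStack | np.ndarray,
    labels: np.ndarray,
    state: int,
    coords: np.ndarray,
    n_bins_z: int = 45,
    n_bins_d: int = 45,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Joint (inter-ROI distance, z) histogram for one state.

    Distances are Euclidean (L2) in 3-D between ROI coordinates; the joint
    histogram is normalized to total mass 1. Returns (d_edges, z_edges, H).
    """
    z = stack.z if isinstance(stack, FCWindowStack) else np.asarray(stack)
    n_rois = z.shape[1]
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (n_rois, 3):
        raise ValueError("coords must be (n_rois, 3) matching the stack's ROI order")
    dists = pdist(coords)  # pair order matches vectorize_fc
    vals = _state_z_values(stack, labels, state)
    n_windows = vals.size // dists.size
    d_rep = np.tile(dists, n_windows)
    H, d_edges, z_edges = np.histogram2d(d_rep, vals, bins=(n_bins_d, n_bins_z))
    return d_edges, z_edges, H / H.sum()


# ---------------------------------------------------------------------------
# Bayes-factor slope comparison
# ---------------------------------------------------------------------------

def compare_slopes(
    slopes_a: np.ndarray, slopes_b: np.ndarray, equal_var: bool = True
) -> BFResult:
    """Two-sample comparison of per-session slopes.

    Classical two-sided Student t test (equal variance by default; Welch via
    ``equal_var=False``) plus the JZS Bayes factor with a Cauchy prior of
    scale sqrt(2)/2 on the standardized effect. BF01 = 1 / BF10.
    """
    a = np.asarray(slopes_a, dtype=float)
    b = np.asarray(slopes_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 sessions")
    pooled_var = np.concatenate([a - a.mean(), b - b.mean()]).var()
    if pooled_var == 0:
        raise ValueError("zero pooled variance; comparison undefined")
    t, p = sp_stats.ttest_ind(a, b, equal_var=equal_var)
    bf10 = float(
        pg.bayesfactor_ttest(float(t), a.size, b.size, paired=False, r=np.sqrt(2) / 2)
    )
    return BFResult(
        t=float(t), p=float(p), bf10=bf10, bf01=1.0 / bf10, n_a=a.size, n_b=b.size
    )
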