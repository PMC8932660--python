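"""Sliding-window and static Fisher-z functional connectivity.

Turns an ROI-by-scan session into the stack of windowed Fisher-z correlation
matrices that brain-state clustering consumes, plus the static whole-interval
summaries (mean positive/negative z, thresholded graphs) used to describe
stimulation epochs.

Boundary convention: a session of N scans analysed with window width w and
step 1 yields N - w - 1 windows — the first and last feasible placements are
discarded — so a 500-scan run at width 35 gives 464 windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WindowSpec",
    "FCWindowStack",
    "StaticFCMatrix",
    "ROITimeSeries",
    "sliding_windows",
    "windowed_fc",
    "static_fc",
    "epoch_fc_summary",
    "threshold_graph",
    "R_CLIP",
]

#: Correlations are clipped to |r| <= 1 - R_CLIP before atanh so z is finite.
R_CLIP = 1e-6


@dataclass
class ROITimeSeries:
    """One session's region-by-scan signal matrix."""

    data: np.ndarray  # scans x n_rois
    tr: float
    condition: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2:
            raise ValueError("data must be scans x n_rois")
        if not np.all(np.isfinite(d)):
            raise ValueError("data must not contain missing values")
        self.data = d

    @property
    def n_scans(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass
class WindowSpec:
    """Sliding-window parameters (defaults: 35-scan Hamming taper, step 1)."""

    width: int = 35
    step: int = 1
    taper: str | None = "hamming"

    def __post_init__(self) -> None:
        if self.width < 3:
            raise ValueError("width must be >= 3 scans")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.taper not in (None, "none", "hamming"):
            raise ValueError("taper must be 'hamming' or None")

    def taper_weights(self) -> np.ndarray:
        if self.taper == "hamming":
            return np.hamming(self.width)
        return np.ones(self.width)


@dataclass
class FCWindowStack:
    """Windowed Fisher-z connectivity for one session (the Z_{c,s,w} array)."""

    z: np.ndarray  # n_windows x n_rois x n_rois
    window_starts: np.ndarray
    condition: str = ""
    session_id: str = ""

    @property
    def n_windows(self) -> int:
        return self.z.shape[0]

    @property
    def n_rois(self) -> int:
        return self.z.shape[1]


@dataclass
class StaticFCMatrix:
    """Whole-interval Fisher-z connectivity."""

    z: np.ndarray
    interval: tuple[int, int]
    condition: str = ""


def sliding_windows(n_scans: int, spec: WindowSpec | None = None) -> np.ndarray:
    """Window start indices (0-based) for a session of ``n_scans`` scans.

    For step 1 the starts are 1 .. n_scans - width - 1, i.e. the count is
    ``n_scans - width - 1``; larger steps subsample the same range.
    """
    spec = spec or WindowSpec()
    min_scans = spec.width + 2
    if n_scans < min_scans:
        raise ValueError(
            f"need at least {min_scans} scans for width {spec.width}, got {n_scans}"
        )
    return np.arange(1, n_scans - spec.width, spec.step)


def _corr_matrix(segment: np.ndarray, taper: np.ndarray) -> np.ndarray:
    """Tapered Pearson correlation of a scans-by-ROIs segment."""
    seg = segment - segment.mean(axis=0)
    seg = seg * taper[:, None]
    cov = seg.T @ seg
    sd = np.sqrt(np.diag(cov))
    bad = sd == 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} zero-variance ROI(s) in window; correlations set to 0",
            stacklevel=3,
        )
        sd = np.where(bad, 1.0, sd)
    r = cov / np.outer(sd, sd)
    if bad.any():
        r[bad, :] = 0.0
        r[:, bad] = 0.0
    return r


def _fisher_z(r: np.ndarray) -> np.ndarray:
    z = np.arctanh(np.clip(r, -1 + R_CLIP, 1 - R_CLIP))
    np.fill_diagonal(z, 0.0)
    return z


def windowed_fc(ts: ROITimeSeries, spec: WindowSpec | None = None) -> FCWindowStack:
    """Sliding-window Fisher-z connectivity stack for one session.

    Per window the ROI signals are demeaned within the window, multiplied by
    the taper, correlated pairwise, clipped to |r| <= 1 - 1e-6 and
    Fisher-transformed (z = atanh r); the diagonal is set to 0.
    """
    spec = spec or WindowSpec()
    starts = sliding_windows(ts.n_scans, spec)
    taper = spec.taper_weights()
    z = np.empty((starts.size, ts.n_rois, ts.n_rois))
    for i, s in enumerate(starts):
        r = _corr_matrix(ts.data[s : s + spec.width], taper)
        z[i] = _fisher_z(r)
    return FCWindowStack(
        z=z, window_starts=starts, condition=ts.condition, session_id=ts.session_id
    )


def static_fc(
    ts: ROITimeSeries, interval: tuple[int, int] | None = None
) -> StaticFCMatrix:
    """Full-interval Pearson correlation, Fisher-z transformed.

    ``interval`` is a half-open (start, stop) scan range; default whole run.
    """
    if interval is None:
        interval = (0, ts.n_scans)
    start, stop = interval
    if start < 0 or stop > ts.n_scans:
        raise ValueError("interval outside the session")
    if stop - start < 3:
        raise ValueError("interval must span at least 3 scans")
    r = _corr_matrix(ts.data[start:stop], np.ones(stop - start))
    return StaticFCMatrix(z=_fisher_z(r), interval=(start, stop), condition=ts.condition)


def epoch_fc_summary(
    ts: ROITimeSeries,
    stim_onsets: list[int] | np.ndarray,
    tr_counts: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Mean positive/negative z around stimulation onsets.

    For each onset, three epochs are summarized: ``before`` (the ``before``
    TRs immediately preceding the onset), ``during`` (the ``during`` TRs from
    the onset), and ``after`` (``after`` TRs starting ``after_lag`` TRs past
    the onset). Each epoch's static FC is reduced to the mean of the strictly
    positive and strictly negative upper-triangle z values.

    Returns a tidy frame with columns onset, epoch, mean_pos_z, mean_neg_z,
    n_pos, n_neg, empty_pos, empty_neg. Out-of-bounds epochs are skipped with
    a warning.
    """
    counts = {"before": 10, "during": 10, "after": 10, "after_lag": 25}
    if tr_counts:
        counts.update(tr_counts)
    iu = np.triu_indices(ts.n_rois, k=1)
    rows = []
    for onset in np.asarray(stim_onsets, dtype=int):
        epochs = {
            "before": (onset - counts["before"], onset),
            "during": (onset, onset + counts["during"]),
            "after": (
                onset + counts["after_lag"],
                onset + counts["after_lag"] + counts["after"],
            ),
        }
        for name, (a, b) in epochs.items():
            if a < 0 or b > ts.n_scans:
                warnings.warn(
                    f"epoch {name!r} at onset {onset} out of bounds; skipped",
                    stacklevel=2,
                )
                continue
            zvals = static_fc(ts, (a, b)).z[iu]
            pos = zvals[zvals > 0]
            neg = zvals[zvals < 0]
            rows.append(
                {
                    "onset": int(onset),
                    "epoch": name,
                    "mean_pos_z": float(pos.mean()) if pos.size else 0.0,
                    "mean_neg_z": float(neg.mean()) if neg.size else 0.0,
                    "n_pos": int(pos.size),
                    "n_neg": int(neg.size),
                    "empty_pos": pos.size == 0,
                    "empty_neg": neg.size == 0,
                }
            )
    return pd.DataFrame(rows)


def threshold_graph(fc: StaticFCMatrix, threshold: float = 0.3) -> pd.DataFrame:
    """Undirected edges where |z| exceeds the threshold (default 0.3)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    i, j = np.triu_indices(fc.z.shape[0], k=1)
    w = fc.z[i, j]
    keep = np.abs(w) > threshold
    return pd.DataFrame(
        {
            "roi_i": i[keep],
            "roi_j": j[keep],
            "weight": w[keep],
            "sign": np.sign(w[keep]).astype(int),
        }
    )
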