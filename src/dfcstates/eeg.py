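"""EEG processing chain: gradient-artifact template subtraction, filtering and
epoching, spectral depth-of-anesthesia markers, and nonparametric group
comparison with FDR control.

Markers follow the spectral family used to separate conscious from
unconscious recordings: normalized delta (1-4 Hz), theta (4-8 Hz) and alpha
(8-13 Hz) power over a 1-25 Hz total band, the spectral entropy

    SE = -sum_i p_i log p_i / log(n_bins),  p = PSD / sum(PSD),

bounded in [0, 1] (1 for a flat spectrum), and the median spectral frequency
MSF, the frequency dividing the 1-25 Hz power spectrum into two equal areas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats as sp_stats
from scipy.integrate import cumulative_trapezoid
from statsmodels.stats.multitest import multipletests

from .synthetic import EEGRecording

__all__ = [
    "EpochSet",
    "SpectralConfig",
    "remove_gradient_artifact",
    "preprocess",
    "epoch",
    "psd_per_epoch",
    "band_power",
    "spectral_entropy",
    "spectral_entropy_from_psd",
    "median_spectral_frequency",
    "msf_from_psd",
    "marker_table",
    "compare_markers",
    "MARKER_BANDS",
]

#: Reported normalized bands (Hz); the residual 13-25 Hz completes the partition.
MARKER_BANDS = {"delta": (1.0, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 13.0)}


@dataclass
class EpochSet:
    """Fixed-length epochs cut from a continuous recording."""

    data: np.ndarray  # epochs x channels x samples
    fs: float
    onsets: np.ndarray  # seconds
    length: float
    channel_names: tuple[str, ...] = ()

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass
class SpectralConfig:
    """PSD-estimation parameters for the spectral markers.

    Averaged windowed periodogram (Welch) with Hann-tapered ``seg_len_s``-long
    segments at 50% overlap, zero-padded so the bin width does not exceed
    ``max_bin_width_hz``. Segments are truncated to the epoch length when the
    epoch is shorter. ``fmin``/``fmax`` bound the analysis band.
    """

    seg_len_s: float = 1.0
    overlap: float = 0.5
    max_bin_width_hz: float = 0.5
    fmin: float = 1.0
    fmax: float = 25.0


# ---------------------------------------------------------------------------
# gradient-artifact template subtraction
# ---------------------------------------------------------------------------

def remove_gradient_artifact(
    rec: EEGRecording,
    period: float | None = None,
    n_avg: int = 21,
    baseline: float = 0.2,
) -> EEGRecording:
    """Average-artifact template subtraction for a periodic scanner artifact.

    Each channel is segmented into consecutive occurrences of the artifact
    period. For occurrence i the correction template is the sliding average
    of the ``n_avg`` occurrences centred on i (truncated at the recording
    edges; the occurrence itself is included, as in the standard
    average-artifact approach). Both the occurrence and its template are
    baseline-corrected over the first ``baseline`` seconds before the
    template is subtracted in place. Samples after the last complete
    occurrence are left unchanged.

    Falls back to a single global template with a warning when fewer than
    ``n_avg`` occurrences are available.
    """
    if period is None:
        period = rec.artifact_period
    if period is None:
        raise ValueError("no artifact period given or recorded")
    p = int(round(period * rec.fs))
    if p < 2:
        raise ValueError("artifact period too short for the sampling rate")
    n_occ = rec.n_samples // p
    if n_occ < 1:
        raise ValueError("recording shorter than one artifact period")
    if n_occ < n_avg:
        warnings.warn(
            f"only {n_occ} artifact periods (< n_avg={n_avg}); using a global template",
            stacklevel=2,
        )

    data = rec.data.copy()
    occ = data[:, : n_occ * p].reshape(rec.n_channels, n_occ, p)
    b = max(1, min(p, int(round(baseline * rec.fs))))

    # truncated centred sliding mean over occurrences via prefix sums
    cs = np.concatenate(
        [np.zeros((rec.n_channels, 1, p)), np.cumsum(occ, axis=1)], axis=1
    )
    half = n_avg // 2
    idx = np.arange(n_occ)
    lo = np.maximum(0, idx - half)
    hi = np.minimum(n_occ, idx + half + 1)
    templates = (cs[:, hi, :] - cs[:, lo, :]) / (hi - lo)[None, :, None]

    occ_bl = occ[:, :, :b].mean(axis=2, keepdims=True)
    tmpl_bl = templates[:, :, :b].mean(axis=2, keepdims=True)
    cleaned = (occ - occ_bl) - (templates - tmpl_bl)
    data[:, : n_occ * p] = cleaned.reshape(rec.n_channels, n_occ * p)

    return EEGRecording(
        data=data,
        fs=rec.fs,
        channel_names=rec.channel_names,
        artifact_period=None,
        true_band_powers=rec.true_band_powers,
    )


# ---------------------------------------------------------------------------
# filtering / resampling / trimming / re-referencing
# ---------------------------------------------------------------------------

def preprocess(
    rec: EEGRecording,
    l_freq: float = 1.0,
    h_freq: float = 25.0,
    resample_to: float = 250.0,
    trim: float = 15.0,
) -> EEGRecording:
    """Band-pass, downsample, trim and average-reference a recording.

    Zero-phase Butterworth filtering (forward-backward; order-6 high-pass and
    order-8 low-pass sections, i.e. effective orders 12 and 16), polyphase
    resampling to ``resample_to`` Hz, removal of ``trim`` seconds at each
    end, and re-referencing of every sample to the across-channel mean.
    """
    if rec.duration <= 2 * trim:
        raise ValueError(f"recording must be longer than {2 * trim} s")
    hp = sp_signal.butter(6, l_freq, btype="highpass", fs=rec.fs, output="sos")
    lp = sp_signal.butter(8, h_freq, btype="lowpass", fs=rec.fs, output="sos")
    data = sp_signal.sosfiltfilt(hp, rec.data, axis=1)
    data = sp_signal.sosfiltfilt(lp, data, axis=1)

    if resample_to != rec.fs:
        frac = Fraction(resample_to / rec.fs).limit_denominator(1000)
        data = sp_signal.resample_poly(data, frac.numerator, frac.denominator, axis=1)
    fs = resample_to

    n_trim = int(round(trim * fs))
    data = data[:, n_trim : data.shape[1] - n_trim]
    data = data - data.mean(axis=0, keepdims=True)

    return EEGRecording(
        data=data,
        fs=fs,
        channel_names=rec.channel_names,
        artifact_period=rec.artifact_period,
        true_band_powers=rec.true_band_powers,
    )


def epoch(
    rec: EEGRecording,
    length: float = 0.8,
    jitter_range: tuple[float, float] = (0.55, 0.85),
    seed: int | None = None,
) -> EpochSet:
    """Cut fixed-length epochs whose onsets advance by uniform jitter.

    Onset-to-onset gaps are independent draws from
    ``Uniform(jitter_range)``; since the default gap range lies below the
    0.8-s epoch length, consecutive epochs may overlap. Deterministic given
    ``seed``.
    """
    if rec.duration <= length:
        raise ValueError("recording shorter than one epoch")
    rng = np.random.default_rng(seed)
    onsets = []
    t = 0.0
    while t + length <= rec.duration:
        onsets.append(t)
        t += rng.uniform(*jitter_range)
    onsets = np.asarray(onsets)
    n = int(round(length * rec.fs))
    starts = np.round(onsets * rec.fs).astype(int)
    starts = starts[starts + n <= rec.n_samples]
    data = np.stack([rec.data[:, s : s + n] for s in starts])
    return EpochSet(
        data=data,
        fs=rec.fs,
        onsets=starts / rec.fs,
        length=length,
        channel_names=rec.channel_names,
    )


# ---------------------------------------------------------------------------
# spectral markers
# ---------------------------------------------------------------------------

def psd_per_epoch(
    epochs: EpochSet, cfg: SpectralConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD per epoch and channel; returns (freqs, psd[e, c, f])."""
    cfg = cfg or SpectralConfig()
    n = epochs.data.shape[2]
    nperseg = min(n, int(round(cfg.seg_len_s * epochs.fs)))
    noverlap = int(round(cfg.overlap * nperseg))
    nfft = max(nperseg, int(np.ceil(epochs.fs / cfg.max_bin_width_hz)))
    freqs, psd = sp_signal.welch(
        epochs.data,
        fs=epochs.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        nfft=nfft,
        axis=2,
    )
    return freqs, psd


def _band_mask(freqs: np.ndarray, lo: float, hi: float, inclusive: bool) -> np.ndarray:
    return (freqs >= lo) & ((freqs <= hi) if inclusive else (freqs < hi))


def band_power(
    epochs: EpochSet,
    bands: dict[str, tuple[float, float]] | None = None,
    total_band: tuple[float, float] = (1.0, 25.0),
    cfg: SpectralConfig | None = None,
) -> pd.DataFrame:
    """Normalized band power per epoch and channel.

    Band fraction = band-integrated PSD / total-band-integrated PSD, with
    half-open band intervals (the upper edge of the total band inclusive) so
    bands tiling the total band partition the power exactly. Epochs with zero
    total power get NaN fractions and a ``zero_power`` flag.
    """
    bands = bands or MARKER_BANDS
    freqs, psd = psd_per_epoch(epochs, cfg)
    total_mask = _band_mask(freqs, total_band[0], total_band[1], inclusive=True)
    total = psd[:, :, total_mask].sum(axis=2)
    zero = total <= 0
    if zero.any():
        warnings.warn("zero total power in some epochs; markers undefined", stacklevel=2)
    rows = {"epoch": np.repeat(np.arange(epochs.n_epochs), epochs.n_channels),
            "channel": np.tile(np.arange(epochs.n_channels), epochs.n_epochs)}
    safe_total = np.where(zero, 1.0, total)
    for name, (lo, hi) in bands.items():
        inclusive = hi >= total_band[1]
        m = _band_mask(freqs, lo, hi, inclusive=inclusive) & total_mask
        frac = psd[:, :, m].sum(axis=2) / safe_total
        frac = np.where(zero, np.nan, frac)
        rows[f"{name}_norm"] = frac.ravel()
    rows["zero_power"] = zero.ravel()
    return pd.DataFrame(rows)


def spectral_entropy_from_psd(psd_bins: np.ndarray) -> float:
    """Shannon entropy of a normalized PSD, scaled to [0, 1] by log(n_bins)."""
    p = np.asarray(psd_bins, dtype=float)
    total = p.sum()
    if total <= 0:
        return np.nan
    p = p / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(p.size))


def spectral_entropy(
    epochs: EpochSet,
    band: tuple[float, float] = (1.0, 25.0),
    cfg: SpectralConfig | None = None,
) -> np.ndarray:
    """SE per epoch and channel over the analysis band; in [0, 1]."""
    freqs, psd = psd_per_epoch(epochs, cfg)
    m = _band_mask(freqs, band[0], band[1], inclusive=True)
    sub = psd[:, :, m]
    out = np.empty(sub.shape[:2])
    for e in range(sub.shape[0]):
        for c in range(sub.shape[1]):
            out[e, c] = spectral_entropy_from_psd(sub[e, c])
    return out


def msf_from_psd(freqs: np.ndarray, psd_bins: np.ndarray) -> float:
    """Frequency splitting the PSD (piecewise-linear) into two equal areas."""
    freqs = np.asarray(freqs, dtype=float)
    p = np.asarray(psd_bins, dtype=float)
    cum = cumulative_trapezoid(p, freqs, initial=0.0)
    total = cum[-1]
    if total <= 0:
        return np.nan
    return float(np.interp(total / 2.0, cum, freqs))


def median_spectral_frequency(
    epochs: EpochSet,
    band: tuple[float, float] = (1.0, 25.0),
    cfg: SpectralConfig | None = None,
) -> np.ndarray:
    """MSF (Hz) per epoch and channel over the analysis band."""
    freqs, psd = psd_per_epoch(epochs, cfg)
    m = _band_mask(freqs, band[0], band[1], inclusive=True)
    f = freqs[m]
    sub = psd[:, :, m]
    out = np.empty(sub.shape[:2])
    for e in range(sub.shape[0]):
        for c in range(sub.shape[1]):
            out[e, c] = msf_from_psd(f, sub[e, c])
    return out


def marker_table(
    epochs: EpochSet, cfg: SpectralConfig | None = None
) -> pd.DataFrame:
    """All spectral markers per epoch and channel.

    Columns: delta_norm, theta_norm, alpha_norm, se, msf. Session-level
    values are conventionally the mean across epochs, then channels.
    """
    df = band_power(epochs, cfg=cfg)
    df["se"] = spectral_entropy(epochs, cfg=cfg).ravel()
    df["msf"] = median_spectral_frequency(epochs, cfg=cfg).ravel()
    return df


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def compare_markers(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    markers: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mann-Whitney U per marker with Benjamini-Hochberg FDR correction.

    ``group_a``/``group_b`` hold one observation per row (e.g. session-level
    marker means) in identically named columns. Two-sided tests; all-tied
    markers get p = 1 with a warning. Adjusted p values use the BH step-up
    procedure for independent or positively correlated tests; the
    significance flag applies ``alpha`` (default 0.05) to the adjusted p.
    """
    if markers is None:
        markers = [c for c in group_a.columns if c in group_b.columns]
    rows = []
    for m in markers:
        a = np.asarray(group_a[m].dropna(), dtype=float)
        b = np.asarray(group_b[m].dropna(), dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError(f"marker {m!r}: need >= 2 observations per group")
        if np.ptp(np.concatenate([a, b])) == 0:
            warnings.warn(f"marker {m!r}: all values tied; p set to 1", stacklevel=2)
            u, p = a.size * b.size / 2.0, 1.0
        else:
            u, p = sp_stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append({"marker": m, "U": float(u), "p": float(p)})
    df = pd.DataFrame(rows)
    reject, p_adj, _, _ = multipletests(df["p"], alpha=alpha, method="fdr_bh")
    df["p_fdr"] = p_adj
    df["significant"] = reject
    return df
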