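"""Synthetic data generators for the brain-state analysis pipeline.

Provides ground-truth-bearing stand-ins for the three kinds of recordings the
analysis consumes:

* a weighted structural connectome with 3-D ROI coordinates,
* resting-state ROI time series whose windowed-connectivity dynamics follow a
  latent Markov chain over covariance templates with condition-dependent
  occupancy, and
* multichannel EEG built from band-limited noise with known relative band
  powers, optionally contaminated by an exactly periodic scanner-gradient
  artifact.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import squareform

__all__ = [
    "StructuralConnectome",
    "StateTemplate",
    "SyntheticSession",
    "GeneratorConfig",
    "EEGRecording",
    "EEG_CHANNELS",
    "EEG_BANDS",
    "make_structural_connectome",
    "make_state_templates",
    "simulate_session",
    "simulate_eeg",
    "default_occupancy_profiles",
]

# Default geometry mirrors the resting-state acquisitions the pipeline targets:
# 82 cortical ROIs, 500 volumes per run at TR = 1.25 s, seven brain states.
DEFAULT_N_ROIS = 82
DEFAULT_N_SCANS = 500
DEFAULT_N_STATES = 7
DEFAULT_TR = 1.25

#: The 11 scalp electrodes carrying signal in the emulated EEG montage.
EEG_CHANNELS = ("Fp1", "Fp2", "F3", "F4", "T3", "T4", "P3", "P4", "O1", "Oz", "O2")

#: Canonical analysis bands (Hz).
EEG_BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 25.0),
}

# Exponential-distance-rule length constant (mm) for synthetic tract weights.
_EDR_LAMBDA_MM = 20.0
# Mean shell radius (mm) for ROI coordinates, roughly a macaque cortical hull.
_SHELL_RADIUS_MM = 30.0


@dataclass
class StructuralConnectome:
    """Weighted anatomical connectivity with ROI coordinates.

    Attributes
    ----------
    weights : ndarray, shape (n_rois, n_rois)
        Symmetric, nonnegative tract strengths with zero diagonal.
    coords : ndarray, shape (n_rois, 3)
        ROI centroids in template space (mm).
    labels : list of str
        Region names, aligned with the matrix order.
    """

    weights: np.ndarray
    coords: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("weights must have a zero diagonal")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (w.shape[0], 3):
            raise ValueError("coords must be (n_rois, 3)")
        if not np.all(np.isfinite(c)):
            raise ValueError("coords must be finite")
        if len(self.labels) != w.shape[0]:
            raise ValueError("labels length must match n_rois")
        self.weights = w
        self.coords = c

    @property
    def n_rois(self) -> int:
        return self.weights.shape[0]


@dataclass
class StateTemplate:
    """Ground-truth covariance template for one latent brain state.

    ``mixing`` is the weight of the structure-derived covariance in the blend;
    templates built with higher mixing resemble the structural connectome more
    closely. ``ridge`` records any diagonal loading that was required to make
    the blend positive definite.
    """

    covariance: np.ndarray
    mixing: float
    ridge: float = 0.0

    def __post_init__(self) -> None:
        cov = np.asarray(self.covariance, dtype=float)
        if not np.allclose(cov, cov.T):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(cov)[0] <= 0:
            raise ValueError("covariance must be positive definite")
        if not 0.0 <= self.mixing <= 1.0:
            raise ValueError("mixing must lie in [0, 1]")
        self.covariance = cov

    @property
    def n_rois(self) -> int:
        return self.covariance.shape[0]


@dataclass
class SyntheticSession:
    """One simulated resting-state run with its latent state path."""

    timeseries: np.ndarray  # scans x n_rois
    tr: float
    condition: str
    true_states: np.ndarray  # per-scan latent state, 1-based
    seed: int | None = None
    session_id: str = "sim"


@dataclass
class GeneratorConfig:
    """Study-condition parameters for the resting-state simulator."""

    n_rois: int = DEFAULT_N_ROIS
    n_scans: int = DEFAULT_N_SCANS
    n_states: int = DEFAULT_N_STATES
    tr: float = DEFAULT_TR
    occupancy_profiles: dict[str, np.ndarray] = field(default_factory=dict)
    dwell_mean: float = 25.0
    observation_noise_sd: float = 0.25
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.dwell_mean < 1:
            raise ValueError("dwell_mean must be >= 1 scan")
        for cond, prof in self.occupancy_profiles.items():
            p = np.asarray(prof, dtype=float)
            if p.shape != (self.n_states,):
                raise ValueError(
                    f"occupancy profile for {cond!r} must have length {self.n_states}"
                )
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"occupancy profile for {cond!r} must sum to 1")
            if np.any(p < 0):
                raise ValueError(f"occupancy profile for {cond!r} must be nonnegative")
            self.occupancy_profiles[cond] = p


@dataclass
class EEGRecording:
    """Multichannel EEG (channels x samples, microvolts)."""

    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    artifact_period: float | None = None
    true_band_powers: dict[str, float] | None = None

    def __post_init__(self) -> None:
        d = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if d.shape[0] < 1:
            raise ValueError("need at least one channel")
        if not np.all(np.isfinite(d)):
            raise ValueError("samples must be finite")
        self.data = d

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def default_occupancy_profiles(n_states: int = DEFAULT_N_STATES) -> dict[str, np.ndarray]:
    """Canonical condition profiles over similarity-ordered states.

    * ``awake`` — uniform: the conscious brain visits its whole repertoire.
    * ``anesthesia`` — mass concentrated on the most structure-like state
      (the highest-similarity state is dominant, ~50% occupancy).
    * ``anesthesia+high CT-DBS`` — restored, near-awake repertoire with a
      mild residual tilt toward structure-like states.
    """
    uniform = np.ones(n_states) / n_states
    anes = np.linspace(1.0, 2.0, n_states)
    anes[-1] = 0.0
    anes = anes / anes.sum() * 0.5
    anes[-1] = 0.5
    dbs = uniform + np.linspace(-0.03, 0.03, n_states)
    return {
        "awake": uniform,
        "anesthesia": anes,
        "anesthesia+high CT-DBS": dbs / dbs.sum(),
    }


# ---------------------------------------------------------------------------
# structural connectome
# ---------------------------------------------------------------------------

def make_structural_connectome(
    n_rois: int = DEFAULT_N_ROIS,
    density: float = 0.3,
    seed: int | None = None,
) -> StructuralConnectome:
    """Generate a connected, distance-decaying weighted connectome.

    ROI coordinates are sampled on a jittered spherical shell so the pairwise
    distance distribution resembles a cortical parcellation; edge weights
    follow an exponential distance rule (strength ~ exp(-d / lambda)) with
    multiplicative log-normal variability. A random subset of pairs at the
    requested density is retained, and the Euclidean minimum spanning tree is
    always included so the graph is connected.

    Parameters
    ----------
    n_rois : int
        Number of regions (default 82).
    density : float
        Fraction of ROI pairs with a nonzero weight, in (0, 1].
    seed : int, optional
        Seed for reproducibility.
    """
    if n_rois < 4:
        raise ValueError("n_rois must be >= 4")
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    rng = np.random.default_rng(seed)

    # coordinates on a sphere-like shell
    direc = rng.normal(size=(n_rois, 3))
    direc /= np.linalg.norm(direc, axis=1, keepdims=True)
    radius = _SHELL_RADIUS_MM * (1.0 + 0.15 * rng.normal(size=n_rois))
    coords = direc * radius[:, None]

    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))

    base = np.exp(-dist / _EDR_LAMBDA_MM)
    jitter = np.exp(0.5 * rng.normal(size=(n_rois, n_rois)))
    jitter = np.sqrt(jitter * jitter.T)  # symmetrize multiplicatively
    weights = base * jitter
    np.fill_diagonal(weights, 0.0)

    # sparsify: keep a random `density` fraction of pairs ...
    n_pairs = n_rois * (n_rois - 1) // 2
    keep = np.zeros(n_pairs, dtype=bool)
    keep[rng.choice(n_pairs, size=max(1, int(round(density * n_pairs))), replace=False)] = True
    mask = squareform(keep).astype(bool)
    # ... but always include a spanning tree so the graph is connected
    mst = minimum_spanning_tree(dist).toarray()
    mask |= (mst > 0) | (mst.T > 0)

    weights = np.where(mask, weights, 0.0)
    weights = (weights + weights.T) / 2.0
    np.fill_diagonal(weights, 0.0)

    labels = [f"ROI{i + 1:03d}" for i in range(n_rois)]
    return StructuralConnectome(weights=weights, coords=coords, labels=labels)


# ---------------------------------------------------------------------------
# state templates
# ---------------------------------------------------------------------------

def _nearest_pd_ridge(mat: np.ndarray) -> tuple[np.ndarray, float]:
    """Add the smallest ridge from a fixed grid that makes ``mat`` PD."""
    eigmin = np.linalg.eigvalsh(mat)[0]
    shift = max(0.0, -eigmin)
    for ridge in (1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1):
        cand = mat + (shift + ridge) * np.eye(mat.shape[0])
        if np.linalg.eigvalsh(cand)[0] > 0:
            return cand, shift + ridge
    raise ValueError("could not regularize matrix to positive definite")


def _cov_to_corr(cov: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return (corr + corr.T) / 2.0


def _structure_covariance(sc: StructuralConnectome) -> tuple[np.ndarray, float]:
    """Positive-definite covariance whose off-diagonal is proportional to the
    structural weights (normalized by spectral radius, keeping the implied
    correlations strong)."""
    w = sc.weights / np.abs(np.linalg.eigvalsh(sc.weights)).max()
    cov, ridge = _nearest_pd_ridge(w)
    return _cov_to_corr(cov), ridge


def _random_covariance(
    n: int, rng: np.random.Generator, n_factors: int | None = None
) -> np.ndarray:
    """Random low-rank-dominated correlation matrix.

    Built from a small number of latent factors (default ~n/10) so the
    off-diagonal correlations are strong (sd ~0.3), mimicking the
    network-dominated covariance of resting-state FC patterns rather than the
    weak correlations a full-rank Wishart draw would give.
    """
    if n_factors is None:
        n_factors = max(4, round(n / 10))
    a = rng.normal(size=(n, n_factors))
    cov = a @ a.T / n_factors + 1e-4 * np.eye(n)
    return _cov_to_corr(cov)


def make_state_templates(
    sc: StructuralConnectome,
    n_states: int = DEFAULT_N_STATES,
    mixing_grid: np.ndarray | None = None,
    seed: int | None = None,
) -> list[StateTemplate]:
    """Build covariance templates with graded similarity to the structure.

    Template ``i`` is the convex blend ``m_i * C_struct + (1 - m_i) * C_rand_i``
    of a structure-derived correlation matrix and a template-specific random
    long-range correlation matrix, so the structure-function similarity of the
    templates increases strictly with the mixing grid.

    Parameters
    ----------
    sc : StructuralConnectome
    n_states : int
        Number of templates (default 7).
    mixing_grid : array-like, optional
        Strictly increasing mixing weights in [0, 1], one per state. Defaults
        to ``linspace(0, 1, n_states)``.
    seed : int, optional
    """
    if mixing_grid is None:
        # intermediate templates tile [0, 0.75] at gaps of 0.15; the final,
        # fully structural template sits at 1.0. The widest gap is placed at
        # the top because that pair's difference involves only one random
        # component (the m = 1 template has none), making it otherwise the
        # least distinct pair of the construction.
        mixing_grid = np.append(np.linspace(0.0, 0.75, n_states - 1), 1.0)
    mixing_grid = np.asarray(mixing_grid, dtype=float)
    if mixing_grid.shape != (n_states,):
        raise ValueError("mixing_grid must have length n_states")
    if np.any(np.diff(mixing_grid) <= 0):
        raise ValueError("mixing_grid must be strictly increasing")
    if mixing_grid[0] < 0 or mixing_grid[-1] > 1:
        raise ValueError("mixing_grid must lie in [0, 1]")

    from .brain_states import structure_similarity  # local import; no cycle

    c_struct, struct_ridge = _structure_covariance(sc)
    rng = np.random.default_rng(seed)

    for _attempt in range(10):
        templates: list[StateTemplate] = []
        for m in mixing_grid:
            c_rand = _random_covariance(sc.n_rois, rng)
            blend = m * c_struct + (1.0 - m) * c_rand
            ridge = 0.0
            if np.linalg.eigvalsh(blend)[0] <= 0:
                blend, ridge = _nearest_pd_ridge(blend)
            templates.append(
                StateTemplate(covariance=blend, mixing=float(m), ridge=ridge + (struct_ridge if m > 0 else 0.0))
            )
        sims = [structure_similarity(t.covariance, sc) for t in templates]
        if np.all(np.diff(sims) > 0):
            return templates
    raise RuntimeError(
        "failed to draw templates with strictly increasing structure similarity"
    )


# ---------------------------------------------------------------------------
# resting-state session simulator
# ---------------------------------------------------------------------------

def _sticky_transition_matrix(profile: np.ndarray, dwell_mean: float) -> np.ndarray:
    """Transition matrix P = p*I + (1-p) * 1 pi^T.

    Its stationary distribution is exactly ``profile`` for any profile. The
    stickiness p is calibrated so that, under a uniform profile over k states,
    the expected dwell time of every state equals ``dwell_mean`` scans.
    """
    k = profile.size
    if k == 1:
        return np.ones((1, 1))
    p = 1.0 - 1.0 / (dwell_mean * (1.0 - 1.0 / k))
    p = min(max(p, 0.0), 1.0 - 1e-12)
    return p * np.eye(k) + (1.0 - p) * np.tile(profile, (k, 1))


def simulate_session(
    templates: list[StateTemplate],
    config: GeneratorConfig,
    condition: str,
    seed: int | None = None,
    session_id: str = "sim",
) -> SyntheticSession:
    """Simulate one resting-state run under a condition's occupancy profile.

    The latent state path is a sticky first-order Markov chain whose
    stationary distribution equals the condition's occupancy profile; each
    scan's observation is a zero-mean multivariate Gaussian draw from the
    active template's covariance plus isotropic noise.
    """
    if condition not in config.occupancy_profiles:
        raise ValueError(f"no occupancy profile defined for condition {condition!r}")
    profile = config.occupancy_profiles[condition]
    k = len(templates)
    if profile.size != k:
        raise ValueError("profile length must equal number of templates")

    rng = np.random.default_rng(seed if seed is not None else config.seed)
    trans = _sticky_transition_matrix(profile, config.dwell_mean)

    states = np.empty(config.n_scans, dtype=np.int64)
    states[0] = rng.choice(k, p=profile)
    u = rng.random(config.n_scans - 1)
    cum = np.cumsum(trans, axis=1)
    for t in range(1, config.n_scans):
        states[t] = np.searchsorted(cum[states[t - 1]], u[t - 1], side="right")

    n = templates[0].n_rois
    noise_var = config.observation_noise_sd**2
    chols = [
        np.linalg.cholesky(tpl.covariance + noise_var * np.eye(n)) for tpl in templates
    ]
    raw = rng.normal(size=(config.n_scans, n))
    data = np.empty_like(raw)
    for s in range(k):
        m = states == s
        if m.any():
            data[m] = raw[m] @ chols[s].T

    return SyntheticSession(
        timeseries=data,
        tr=config.tr,
        condition=condition,
        true_states=states + 1,
        seed=seed,
        session_id=session_id,
    )


# ---------------------------------------------------------------------------
# EEG simulator
# ---------------------------------------------------------------------------

def _band_limited_noise(
    n: int, fs: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    lo, hi = band
    x = rng.normal(size=n)
    sos = sp_signal.butter(8, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = sp_signal.sosfiltfilt(sos, x)
    rms = np.sqrt(np.mean(y**2))
    return y / rms if rms > 0 else y


def _artifact_waveform(period_samples: int, fs: float) -> np.ndarray:
    """One period of a deterministic gradient-like transient burst."""
    t = np.arange(period_samples) / fs
    wave = (
        np.exp(-t / 0.03) * np.sin(2 * np.pi * 71.0 * t)
        + 0.5 * np.exp(-t / 0.08) * np.sin(2 * np.pi * 37.0 * t + 0.7)
    )
    return wave - wave.mean()


def simulate_eeg(
    channels: tuple[str, ...] = EEG_CHANNELS,
    fs: float = 500.0,
    duration: float = 120.0,
    band_amplitudes: dict[str, float] | None = None,
    artifact_params: dict | None = None,
    seed: int | None = None,
) -> EEGRecording:
    """Simulate multichannel EEG from band-limited noise components.

    Each channel is an independent sum of band-limited Gaussian noise
    components (unit RMS, scaled by the requested amplitude), so the
    ground-truth relative band power of band b is amplitude_b^2 / sum(a^2).
    Optionally adds an exactly periodic scanner-gradient artifact.

    Parameters
    ----------
    channels : tuple of str
        Channel names (default: the 11-electrode scalp montage).
    fs : float
        Sampling rate (Hz); must exceed twice the highest band edge.
    duration : float
        Recording length in seconds (> 30 so 15-s trims leave data).
    band_amplitudes : dict, optional
        RMS amplitude per band name from ``EEG_BANDS``; all must be positive.
        Default: delta-dominant spectrum {delta: 2, theta: 1, alpha: 0.7,
        beta: 0.4}.
    artifact_params : dict, optional
        ``{"period": seconds, "ratio": artifact-to-signal RMS ratio}``; when
        given, a periodic artifact waveform is added to every channel.
    seed : int, optional
    """
    if band_amplitudes is None:
        band_amplitudes = {"delta": 2.0, "theta": 1.0, "alpha": 0.7, "beta": 0.4}
    for name, amp in band_amplitudes.items():
        if name not in EEG_BANDS:
            raise ValueError(f"unknown band {name!r}")
        if amp <= 0:
            raise ValueError(f"band amplitude for {name!r} must be positive")
    highest = max(EEG_BANDS[b][1] for b in band_amplitudes)
    if fs <= 2 * highest:
        raise ValueError("fs must exceed twice the highest band edge")
    if duration <= 30:
        raise ValueError("duration must exceed 30 s")

    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    data = np.zeros((len(channels), n))
    for c in range(len(channels)):
        for band, amp in band_amplitudes.items():
            data[c] += amp * _band_limited_noise(n, fs, EEG_BANDS[band], rng)

    total = sum(a**2 for a in band_amplitudes.values())
    true_powers = {b: a**2 / total for b, a in band_amplitudes.items()}

    artifact_period = None
    if artifact_params is not None:
        period = float(artifact_params["period"])
        ratio = float(artifact_params.get("ratio", 10.0))
        p_samp = int(round(period * fs))
        if abs(p_samp - period * fs) > 1e-6:
            warnings.warn("artifact period is not an integer number of samples")
        wave = _artifact_waveform(p_samp, fs)
        signal_rms = np.sqrt(np.mean(data**2, axis=1))
        wave_rms = np.sqrt(np.mean(wave**2))
        reps = int(np.ceil(n / p_samp))
        tiled = np.tile(wave, reps)[:n]
        for c in range(len(channels)):
            data[c] += tiled * (ratio * signal_rms[c] / wave_rms)
        artifact_period = period

    return EEGRecording(
        data=data,
        fs=fs,
        channel_names=tuple(channels),
        artifact_period=artifact_period,
        true_band_powers=true_powers,
    )
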