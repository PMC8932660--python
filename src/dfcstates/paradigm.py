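"""Deterministic experiment schedules: thalamic DBS pulse trains and block
design, the local-global auditory oddball runs, and the clinical arousal
score.

All schedule arithmetic is exact: TR counts are integers, sound onsets sit on
a millisecond grid, and the series/TR commensurability identity
(24 trials x 1500 ms == 15 TR x 2400 ms) is validated at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DBSPulseTrain",
    "DBSBlockSchedule",
    "SoundEvent",
    "Trial",
    "RunSchedule",
    "ArousalExam",
    "make_pulse_train",
    "make_dbs_block_design",
    "make_trial",
    "make_series",
    "make_run",
    "arousal_score",
    "PITCHES_HZ",
]

#: Allowed tone pitches (Hz) in the local-global paradigm.
PITCHES_HZ = (800.0, 1600.0)


# ---------------------------------------------------------------------------
# DBS stimulation
# ---------------------------------------------------------------------------

@dataclass
class DBSPulseTrain:
    """Monopolar DBS pulse train."""

    frequency: float  # Hz
    pulse_width_us: float
    amplitude_v: float
    duration_s: float
    onsets_ms: np.ndarray = field(repr=False)

    @property
    def period_ms(self) -> float:
        return 1000.0 / self.frequency

    @property
    def n_pulses(self) -> int:
        return self.onsets_ms.size


def make_pulse_train(
    frequency: float = 130.208,
    pulse_width_us: float = 320.0,
    amplitude_v: float = 5.0,
    duration_s: float = 1.0,
) -> DBSPulseTrain:
    """Pulse train at the clinical stimulation frequency (default 130.208 Hz,
    period 7.68 ms); pulse count = floor(duration / period)."""
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    period_ms = 1000.0 / frequency
    if pulse_width_us >= period_ms * 1000.0:
        raise ValueError("pulse width must be shorter than the period")
    n = int(np.floor(duration_s * 1000.0 / period_ms + 1e-9))
    onsets = period_ms * np.arange(n)
    return DBSPulseTrain(
        frequency=frequency,
        pulse_width_us=pulse_width_us,
        amplitude_v=amplitude_v,
        duration_s=duration_s,
        onsets_ms=onsets,
    )


@dataclass
class DBSBlockSchedule:
    """Block design: baseline, then alternating DBS-ON / DBS-OFF blocks."""

    tr: float
    blocks: list[tuple[str, int]]  # (label, length in TR)

    @property
    def total_tr(self) -> int:
        return sum(n for _, n in self.blocks)

    @property
    def on_onsets_tr(self) -> list[int]:
        """1-based TR index of the first scan of each ON block."""
        onsets, pos = [], 0
        for label, n in self.blocks:
            if label == "ON":
                onsets.append(pos + 1)
            pos += n
        return onsets

    def labels_per_tr(self) -> list[str]:
        out: list[str] = []
        for label, n in self.blocks:
            out.extend([label] * n)
        return out


def make_dbs_block_design(
    baseline_tr: int = 50,
    n_cycles: int = 5,
    on_tr: int = 5,
    off_tr: int = 50,
    tr: float = 1.25,
) -> DBSBlockSchedule:
    """Default design: 50-TR baseline + 5 x (5 TR ON + 50 TR OFF) = 325 TR,
    with ON onsets at TRs 51, 106, 161, 216, 271 (1-based)."""
    blocks: list[tuple[str, int]] = [("baseline", baseline_tr)]
    for _ in range(n_cycles):
        blocks.append(("ON", on_tr))
        blocks.append(("OFF", off_tr))
    return DBSBlockSchedule(tr=tr, blocks=blocks)


# ---------------------------------------------------------------------------
# local-global auditory paradigm
# ---------------------------------------------------------------------------

@dataclass
class SoundEvent:
    onset_ms: float
    pitch_hz: float
    duration_ms: float = 50.0


@dataclass
class Trial:
    """Five-tone trial: 150-ms onset asynchrony, 650-ms sound span, 1500-ms
    footprint including the 850-ms inter-trial silence."""

    sounds: list[SoundEvent]
    global_label: str  # standard | deviant | habituation
    footprint_ms: float = 1500.0

    @property
    def local_deviant(self) -> bool:
        return self.sounds[4].pitch_hz != self.sounds[0].pitch_hz

    @property
    def sound_span_ms(self) -> float:
        last = self.sounds[-1]
        return last.onset_ms + last.duration_ms - self.sounds[0].onset_ms


_SOA_MS = 150.0
_GLOBAL_LABELS = ("standard", "deviant", "habituation")


def _pattern_pitches(pattern: str, base: float, alt: float) -> list[float]:
    if pattern == "xx":
        return [base] * 5
    if pattern == "xY":
        return [base] * 4 + [alt]
    raise ValueError("standard_pattern must be 'xx' or 'xY'")


def make_trial(
    global_kind: str = "standard",
    standard_pattern: str = "xx",
    base_pitch: float = 800.0,
    alt_pitch: float = 1600.0,
) -> Trial:
    """Build one trial.

    ``standard_pattern`` names the block's globally frequent pattern ('xx' =
    five identical tones, 'xY' = four tones plus a pitch change); a global
    deviant presents the other pattern. Habituation trials repeat the
    standard pattern.
    """
    for p in (base_pitch, alt_pitch):
        if p not in PITCHES_HZ:
            raise ValueError(f"invalid pitch {p}; allowed: {PITCHES_HZ}")
    if global_kind not in _GLOBAL_LABELS:
        raise ValueError(f"global_kind must be one of {_GLOBAL_LABELS}")
    pattern = standard_pattern
    if global_kind == "deviant":
        pattern = "xY" if standard_pattern == "xx" else "xx"
    pitches = _pattern_pitches(pattern, base_pitch, alt_pitch)
    sounds = [SoundEvent(onset_ms=i * _SOA_MS, pitch_hz=p) for i, p in enumerate(pitches)]
    return Trial(sounds=sounds, global_label=global_kind)


def make_series(
    standard_pattern: str = "xx",
    seed: int | None = None,
    n_habituation: int = 4,
    n_post: int = 20,
    n_deviants: int = 4,
    base_pitch: float = 800.0,
    alt_pitch: float = 1600.0,
) -> list[Trial]:
    """One 24-trial series: 4 habituation trials then 20 post-habituation
    trials with 4 global deviants at seeded pseudorandom positions (uniform
    without replacement) and 16 global standards."""
    rng = np.random.default_rng(seed)
    deviant_pos = set(rng.choice(n_post, size=n_deviants, replace=False).tolist())
    trials = [
        make_trial("habituation", standard_pattern, base_pitch, alt_pitch)
        for _ in range(n_habituation)
    ]
    for i in range(n_post):
        kind = "deviant" if i in deviant_pos else "standard"
        trials.append(make_trial(kind, standard_pattern, base_pitch, alt_pitch))
    return trials


@dataclass
class RunSchedule:
    """One local-global run on the 2.4-s TR grid."""

    tr: float
    blocks: list[tuple[str, int]]  # (label, length in TR)
    trials: list[Trial]
    trial_onsets_s: np.ndarray

    @property
    def total_tr(self) -> int:
        return sum(n for _, n in self.blocks)

    def event_table(self) -> pd.DataFrame:
        """Events as GLM-ready rows; time origin is the first TR onset."""
        rows = []
        for i, (t, trial) in enumerate(zip(self.trial_onsets_s, self.trials)):
            rows.append(
                {
                    "onset_s": float(t),
                    "duration_s": trial.sound_span_ms / 1000.0,
                    "trial_index": i,
                    "local_deviant": trial.local_deviant,
                    "global_label": trial.global_label,
                }
            )
        return pd.DataFrame(rows)


def make_run(
    standard_pattern: str = "xx",
    seed: int | None = None,
    tr: float = 2.4,
    rest_tr: int = 6,
    series_tr: int = 15,
    n_series: int = 5,
    trial_ms: float = 1500.0,
    trials_per_series: int = 24,
) -> RunSchedule:
    """Full run: 6-TR rest + 5 x (15-TR series of 24 trials + 6-TR rest),
    111 TR in total.

    Construction validates the commensurability identity
    ``trials_per_series * trial_ms == series_tr * tr * 1000`` so trials tile
    the series block exactly.
    """
    if abs(trials_per_series * trial_ms - series_tr * tr * 1000.0) > 1e-9:
        raise ValueError(
            "trial footprint does not tile the series block: "
            f"{trials_per_series} x {trial_ms} ms != {series_tr} x {tr * 1000} ms"
        )
    rng = np.random.default_rng(seed)
    blocks: list[tuple[str, int]] = [("rest", rest_tr)]
    trials: list[Trial] = []
    onsets: list[float] = []
    t = rest_tr * tr
    for s in range(n_series):
        series = make_series(
            standard_pattern, seed=int(rng.integers(2**31 - 1))
        )
        for i, trial in enumerate(series):
            trials.append(trial)
            onsets.append(t + i * trial_ms / 1000.0)
        blocks.append((f"series{s + 1}", series_tr))
        blocks.append(("rest", rest_tr))
        t += series_tr * tr + rest_tr * tr
    return RunSchedule(
        tr=tr, blocks=blocks, trials=trials, trial_onsets_s=np.asarray(onsets)
    )


# ---------------------------------------------------------------------------
# clinical arousal score
# ---------------------------------------------------------------------------

_EXAM_RANGES = {
    "exploration": 2,
    "spontaneous_movements": 2,
    "shaking_prodding": 2,
    "toe_pinch": 2,
    "eye_opening": 2,
    "corneal_reflex": 1,
}


@dataclass
class ArousalExam:
    """Six-item clinical arousal exam (total score 0-11)."""

    exploration: int = 0
    spontaneous_movements: int = 0
    shaking_prodding: int = 0
    toe_pinch: int = 0
    eye_opening: int = 0
    corneal_reflex: int = 0

    def __post_init__(self) -> None:
        for item, hi in _EXAM_RANGES.items():
            v = getattr(self, item)
            if not (isinstance(v, (int, np.integer)) and 0 <= v <= hi):
                raise ValueError(f"item {item!r} must be an integer in [0, {hi}]")


def arousal_score(exam: ArousalExam) -> int:
    """Total clinical arousal score: the sum of the six items (0-11)."""
    return int(sum(getattr(exam, item) for item in _EXAM_RANGES))
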