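"""Synthetic physiological study generator.

Emulates a music-listening psychophysiology session: each trial is 30 s of
white-noise baseline followed by a 40 s music excerpt, recorded on five
channels — skin conductance level (SCL), a photoplethysmogram-like cardiac
pulse (PPG), a respiration belt, and surface EMG over zygomaticus major and
corrugator supercilii.  Listeners rate felt valence and arousal of each
excerpt on 1–9 scales.

Effects are planted to mirror the canonical peripheral-physiology findings:
heart rate and respiration rate rise with arousal; skin conductance and
corrugator activity are elevated for negative valence; respiration and
zygomaticus are elevated for positive valence.  An optional "interaction
mode" carries the valence signal in SCL/corrugator scaled by the arousal
deviation, producing a link that is invisible to linear regression but
recoverable by a non-linear model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .errors import DesignError, GenerationError

QUADRANTS = ("Happy", "Agitated", "Sad", "Peaceful")
CHANNELS = ("scl", "ppg", "resp", "zyg", "corr")

#: Physiological plausibility bounds for planted rates.
HR_BOUNDS_BPM = (40.0, 180.0)
RESP_BOUNDS_BPM = (5.0, 60.0)


@dataclass(frozen=True)
class ExcerptSpec:
    """One music excerpt: its emotion quadrant and latent mean ratings."""

    id: str
    quadrant: str
    latent_valence: float
    latent_arousal: float

    def __post_init__(self) -> None:
        if self.quadrant not in QUADRANTS:
            raise DesignError(
                f"unknown quadrant {self.quadrant!r} for excerpt {self.id}; "
                f"expected one of {QUADRANTS}"
            )
        for name, v in (("valence", self.latent_valence), ("arousal", self.latent_arousal)):
            if not (1.0 <= v <= 9.0):
                raise DesignError(f"latent {name} {v} of excerpt {self.id} outside [1, 9]")
        v, a = self.latent_valence, self.latent_arousal
        ok = {
            "Happy": v >= 5 and a >= 5,
            "Agitated": v <= 5 and a >= 5,
            "Sad": v <= 5 and a <= 5,
            "Peaceful": v >= 5 and a <= 5,
        }[self.quadrant]
        if not ok:
            raise DesignError(
                f"excerpt {self.id}: latent (V={v}, A={a}) inconsistent with "
                f"quadrant {self.quadrant}"
            )


def default_excerpts() -> list[ExcerptSpec]:
    """The default 12-excerpt grid (3 per quadrant), latent values set to the
    study's mean per-excerpt valence/arousal ratings so that synthetic studies
    cover the valence-arousal plane the same way."""
    rows = [
        ("M1", "Agitated", 5.00, 6.35),
        ("M2", "Agitated", 3.35, 7.45),
        ("M3", "Agitated", 3.95, 7.15),
        ("M4", "Happy", 6.60, 6.35),
        ("M5", "Happy", 5.75, 6.25),
        ("M6", "Happy", 6.80, 7.50),
        ("M7", "Peaceful", 6.60, 2.85),
        ("M8", "Peaceful", 5.95, 2.65),
        ("M9", "Peaceful", 5.75, 2.80),
        ("M10", "Sad", 4.85, 2.55),
        ("M11", "Sad", 4.05, 4.15),
        ("M12", "Sad", 4.30, 3.75),
    ]
    return [ExcerptSpec(i, q, v, a) for i, q, v, a in rows]


@dataclass
class StudyDesign:
    """Session layout: who hears what, for how long, at what sampling rate."""

    n_participants: int = 20
    excerpts: list[ExcerptSpec] = field(default_factory=default_excerpts)
    sample_rate_hz: float = 100.0
    baseline_dur_s: float = 30.0
    music_dur_s: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise DesignError("n_participants must be >= 1")
        if self.baseline_dur_s < 20.0:
            raise DesignError("baseline_dur_s must be >= 20 (feature window requirement)")
        if self.music_dur_s <= 10.0:
            raise DesignError("music_dur_s must be > 10")
        if self.sample_rate_hz <= 0:
            raise DesignError("sample_rate_hz must be positive")
        ids = [e.id for e in self.excerpts]
        if len(set(ids)) != len(ids):
            raise DesignError("excerpt ids must be unique")

    @property
    def trial_dur_s(self) -> float:
        return self.baseline_dur_s + self.music_dur_s

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_dur_s * self.sample_rate_hz))


def _default_channel_noise() -> dict[str, float]:
    return {"scl": 0.05, "ppg": 0.05, "resp": 0.05, "zyg": 0.02, "corr": 0.02}


@dataclass
class EffectModel:
    """Planted effect sizes linking latent valence/arousal to physiology.

    Rate effects are in events/min per rating unit of deviation from the
    scale midpoint (5); SCL in conductance units per valence unit; EMG slopes
    modulate the music-window noise amplitude (relative units per valence
    unit) because the downstream feature rectifies EMG.
    """

    hr_base_bpm: float = 70.0
    hr_arousal_slope: float = 2.0
    resp_base: float = 15.0
    resp_arousal_slope: float = 0.8
    resp_valence_slope: float = 0.5
    scl_valence_slope: float = -0.10
    corr_valence_slope: float = -0.08
    zyg_valence_slope: float = 0.05
    rating_noise_sd: float = 1.8
    channel_noise_sd: dict[str, float] = field(default_factory=_default_channel_noise)
    # intrinsic physiological variability (present even at zero channel noise)
    ibi_jitter_cv: float = 0.03
    breath_jitter_cv: float = 0.05
    # per-participant random offsets; rate channels carry their own scales (bpm)
    participant_sd_frac: float = 0.5
    hr_participant_sd_bpm: float = 1.0
    resp_participant_sd_bpm: float = 0.5
    # when True, every valence drive (SCL, Corr, Zyg, Resp) is multiplied by
    # (A-5)/2.5: no single feature is linearly related to valence, but the
    # link is recoverable non-linearly from the joint feature pattern.
    valence_interaction: bool = False

    def __post_init__(self) -> None:
        if self.rating_noise_sd < 0:
            raise DesignError("rating_noise_sd must be >= 0")
        missing = [c for c in CHANNELS if c not in self.channel_noise_sd]
        if missing:
            raise DesignError(f"channel_noise_sd missing channels: {missing}")


@dataclass
class TrialRecording:
    """One participant x excerpt recording: five synchronous sample series."""

    participant: str
    excerpt: str
    t: np.ndarray
    channels: dict[str, np.ndarray]
    baseline_dur_s: float
    music_dur_s: float
    sample_rate_hz: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.t)
        for c, s in self.channels.items():
            if len(s) != n:
                raise GenerationError(f"channel {c} length {len(s)} != time axis {n}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.t, **{c: self.channels[c] for c in CHANNELS}})


@dataclass(frozen=True)
class RatingRecord:
    """A single 1-9 valence/arousal rating of one excerpt by one participant."""

    participant: str
    excerpt: str
    valence: int
    arousal: int

    def __post_init__(self) -> None:
        for name, v in (("valence", self.valence), ("arousal", self.arousal)):
            if v not in range(1, 10):
                raise DesignError(f"{name} rating {v} outside 1..9")


def sample_ratings(excerpt: ExcerptSpec, effects: EffectModel, rng: np.random.Generator,
                   participant: str = "P01") -> RatingRecord:
    """Draw one noisy integer rating pair around the excerpt's latent values.

    rating = round(clip(latent + Normal(0, rating_noise_sd), 1, 9)).
    """
    vals = {}
    for name, latent in (("valence", excerpt.latent_valence), ("arousal", excerpt.latent_arousal)):
        draw = latent + rng.normal(0.0, effects.rating_noise_sd)
        vals[name] = int(round(float(np.clip(draw, 1.0, 9.0))))
    return RatingRecord(participant, excerpt.id, vals["valence"], vals["arousal"])


# ---------------------------------------------------------------------------
# per-channel synthesis
# ---------------------------------------------------------------------------

def _event_train(rate_fn, total_dur: float, jitter_cv: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Event onset times for a point process with instantaneous rate
    ``rate_fn(t)`` events/min and independent per-interval jitter (CV)."""
    times = [float(rng.uniform(0.0, 60.0 / rate_fn(0.0)))]
    while times[-1] < total_dur:
        base = 60.0 / rate_fn(times[-1])
        iv = base * max(0.1, 1.0 + jitter_cv * rng.standard_normal())
        times.append(times[-1] + iv)
    return np.asarray(times)


def _pulse_waveform(t: np.ndarray, onsets: np.ndarray) -> np.ndarray:
    """Asymmetric raised-cosine pulse train: one peaked pulse per beat, peak
    at ~37% of the interbeat interval (fast rise, slower decay)."""
    idx = np.clip(np.searchsorted(onsets, t, side="right") - 1, 0, len(onsets) - 2)
    t0 = onsets[idx]
    iv = onsets[idx + 1] - onsets[idx]
    u = np.clip((t - t0) / iv, 0.0, 1.0)
    return ((1.0 - np.cos(2.0 * np.pi * u ** 0.7)) / 2.0) ** 3


def _breath_waveform(t: np.ndarray, onsets: np.ndarray) -> np.ndarray:
    """Quasi-sinusoidal belt displacement, continuous across breath onsets."""
    idx = np.clip(np.searchsorted(onsets, t, side="right") - 1, 0, len(onsets) - 2)
    u = np.clip((t - onsets[idx]) / (onsets[idx + 1] - onsets[idx]), 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * u))


def _band_noise(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance broadband noise band-limited to the EMG-like range."""
    white = rng.standard_normal(n)
    hi = min(45.0, 0.45 * fs)
    lo = min(15.0, 0.6 * hi)
    sos = _signal.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = _signal.sosfiltfilt(sos, white)
    return x / max(x.std(), 1e-12)


def _slow_noise(n: int, fs: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Low-frequency (< ~0.5 Hz) noise with standard deviation ``sd``."""
    if sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    sos = _signal.butter(2, 0.5, btype="lowpass", fs=fs, output="sos")
    x = _signal.sosfiltfilt(sos, white)
    return sd * x / max(x.std(), 1e-12)


def _valence_signal(excerpt: ExcerptSpec, effects: EffectModel) -> float:
    """Signed valence drive; in interaction mode it is scaled by the (signed,
    normalized) arousal deviation, hiding valence from linear models."""
    dv = excerpt.latent_valence - 5.0
    if effects.valence_interaction:
        return dv * (excerpt.latent_arousal - 5.0) / 2.5
    return dv


def _synthesize_trial(participant: str, excerpt: ExcerptSpec, design: StudyDesign,
                      effects: EffectModel, rng: np.random.Generator,
                      p_offsets: dict[str, float]) -> TrialRecording:
    fs = design.sample_rate_hz
    n = design.n_samples
    t = np.arange(n) / fs
    b = design.baseline_dur_s
    music = t >= b
    noise_sd = effects.channel_noise_sd
    dv = _valence_signal(excerpt, effects)
    da = excerpt.latent_arousal - 5.0

    # --- cardiac pulse ------------------------------------------------------
    hr_base = effects.hr_base_bpm + p_offsets["hr_bpm"]
    hr_music = hr_base + effects.hr_arousal_slope * da
    for label, r in (("baseline", hr_base), ("music", hr_music)):
        if not (HR_BOUNDS_BPM[0] <= r <= HR_BOUNDS_BPM[1]):
            raise GenerationError(
                f"channel ppg: planted {label} heart rate {r:.1f} bpm outside "
                f"{HR_BOUNDS_BPM} for excerpt {excerpt.id}"
            )
    beat_onsets = _event_train(lambda tt: hr_music if tt >= b else hr_base,
                               design.trial_dur_s + 2.0, effects.ibi_jitter_cv, rng)
    ppg = _pulse_waveform(t, beat_onsets)
    ppg = ppg + noise_sd["ppg"] * rng.standard_normal(n)

    # --- respiration belt ---------------------------------------------------
    resp_base = effects.resp_base + p_offsets["resp_bpm"]
    resp_music = resp_base + effects.resp_arousal_slope * da + effects.resp_valence_slope * dv
    for label, r in (("baseline", resp_base), ("music", resp_music)):
        if not (RESP_BOUNDS_BPM[0] <= r <= RESP_BOUNDS_BPM[1]):
            raise GenerationError(
                f"channel resp: planted {label} respiration rate {r:.1f} /min outside "
                f"{RESP_BOUNDS_BPM} for excerpt {excerpt.id}"
            )
    breath_onsets = _event_train(lambda tt: resp_music if tt >= b else resp_base,
                                 design.trial_dur_s + 4.0, effects.breath_jitter_cv, rng)
    resp = _breath_waveform(t, breath_onsets)
    resp = resp + noise_sd["resp"] * rng.standard_normal(n)

    # --- skin conductance ---------------------------------------------------
    # tonic level + always-on slow oscillation (keeps the channel non-degenerate
    # even in noise-free runs) + slow stochastic drift + planted music shift
    phase = rng.uniform(0, 2 * np.pi)
    scl = 5.0 + 0.05 * np.sin(2 * np.pi * 0.03 * t + phase)
    scl = scl + _slow_noise(n, fs, noise_sd["scl"], rng)
    scl_shift = effects.scl_valence_slope * dv + p_offsets["scl"]
    scl = scl + np.where(music, scl_shift, 0.0)

    # --- facial EMG ---------------------------------------------------------
    # amplitude-modulated band-limited noise; the valence effect rides on the
    # music-window amplitude because the feature stage rectifies EMG
    emg = {}
    for name, slope, drive in (("zyg", effects.zyg_valence_slope, dv),
                               ("corr", effects.corr_valence_slope, dv)):
        amp_music = max(0.05, 1.0 + slope * drive + p_offsets[name])
        carrier = _band_noise(n, fs, rng)
        amp = np.where(music, amp_music, 1.0)
        emg[name] = amp * carrier + noise_sd[name] * rng.standard_normal(n)

    meta = {
        "beat_times": beat_onsets[beat_onsets < design.trial_dur_s],
        "breath_times": breath_onsets[breath_onsets < design.trial_dur_s],
        "hr_baseline_bpm": hr_base, "hr_music_bpm": hr_music,
        "resp_baseline_bpm": resp_base, "resp_music_bpm": resp_music,
        "scl_shift": scl_shift,
    }
    return TrialRecording(
        participant=participant, excerpt=excerpt.id, t=t,
        channels={"scl": scl, "ppg": ppg, "resp": resp, "zyg": emg["zyg"], "corr": emg["corr"]},
        baseline_dur_s=design.baseline_dur_s, music_dur_s=design.music_dur_s,
        sample_rate_hz=fs, meta=meta,
    )


def _participant_offsets(effects: EffectModel, rng: np.random.Generator) -> dict[str, float]:
    f = effects.participant_sd_frac
    return {
        "hr_bpm": effects.hr_participant_sd_bpm * rng.standard_normal(),
        "resp_bpm": effects.resp_participant_sd_bpm * rng.standard_normal(),
        "scl": f * effects.channel_noise_sd["scl"] * rng.standard_normal(),
        "zyg": f * effects.channel_noise_sd["zyg"] * rng.standard_normal(),
        "corr": f * effects.channel_noise_sd["corr"] * rng.standard_normal(),
    }


def generate_study(design: StudyDesign, effects: EffectModel | None = None
                   ) -> tuple[list[TrialRecording], list[RatingRecord]]:
    """Generate all trials and ratings of a full synthetic study.

    Reproducible: the same (design, effects) pair, including ``design.seed``,
    yields bit-identical output regardless of generation order — every trial
    draws from an RNG substream keyed by (participant, excerpt).
    """
    effects = effects if effects is not None else EffectModel()
    trials: list[TrialRecording] = []
    ratings: list[RatingRecord] = []
    for p_idx in range(design.n_participants):
        pid = f"P{p_idx + 1:02d}"
        p_rng = np.random.default_rng(np.random.SeedSequence(design.seed, spawn_key=(1, p_idx)))
        offsets = _participant_offsets(effects, p_rng)
        for e_idx, exc in enumerate(design.excerpts):
            t_rng = np.random.default_rng(
                np.random.SeedSequence(design.seed, spawn_key=(2, p_idx, e_idx)))
            trials.append(_synthesize_trial(pid, exc, design, effects, t_rng, offsets))
            r_rng = np.random.default_rng(
                np.random.SeedSequence(design.seed, spawn_key=(3, p_idx, e_idx)))
            ratings.append(sample_ratings(exc, effects, r_rng, participant=pid))
    return trials, ratings


# ---------------------------------------------------------------------------
# disk round-trip
# ---------------------------------------------------------------------------

def write_study(out_dir: str | Path, design: StudyDesign, trials: list[TrialRecording],
                ratings: list[RatingRecord]) -> None:
    """Write one CSV per trial, a ratings table, and a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for tr in trials:
        tr.to_frame().to_csv(out / f"{tr.participant}_{tr.excerpt}.csv", index=False,
                             float_format="%.6g")
    pd.DataFrame([asdict(r) for r in ratings]).to_csv(out / "ratings.csv", index=False)
    manifest = {
        "n_participants": design.n_participants,
        "sample_rate_hz": design.sample_rate_hz,
        "baseline_dur_s": design.baseline_dur_s,
        "music_dur_s": design.music_dur_s,
        "seed": design.seed,
        "excerpts": [asdict(e) for e in design.excerpts],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_study(in_dir: str | Path) -> tuple[StudyDesign, list[TrialRecording], list[RatingRecord]]:
    """Read a study directory written by :func:`write_study`."""
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    design = StudyDesign(
        n_participants=manifest["n_participants"],
        excerpts=[ExcerptSpec(**e) for e in manifest["excerpts"]],
        sample_rate_hz=manifest["sample_rate_hz"],
        baseline_dur_s=manifest["baseline_dur_s"],
        music_dur_s=manifest["music_dur_s"],
        seed=manifest["seed"],
    )
    rdf = pd.read_csv(src / "ratings.csv")
    ratings = [RatingRecord(r.participant, r.excerpt, int(r.valence), int(r.arousal))
               for r in rdf.itertuples()]
    trials = []
    for p_idx in range(design.n_participants):
        pid = f"P{p_idx + 1:02d}"
        for exc in design.excerpts:
            df = pd.read_csv(src / f"{pid}_{exc.id}.csv")
            trials.append(TrialRecording(
                participant=pid, excerpt=exc.id, t=df["time_s"].to_numpy(),
                channels={c: df[c].to_numpy() for c in CHANNELS},
                baseline_dur_s=design.baseline_dur_s, music_dur_s=design.music_dur_s,
                sample_rate_hz=design.sample_rate_hz,
            ))
    return design, trials, ratings
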