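"""From raw 5-channel recordings to the excerpt x feature matrix.

The processing chain per participant:

1. filter each channel (zero-phase 2nd-order Butterworth, channel-specific
   cutoffs; SCL and respiration are unfiltered),
2. convert the cardiac and respiration channels to instantaneous rate
   series via peak detection with physiological min/max bounds,
3. full-wave rectify the filtered EMG channels,
4. z-score each derived channel using mean/SD pooled over all of that
   participant's trials,
5. per trial, feature = mean(z, music window) - mean(z, baseline window),
   where the baseline window is the final 20 s of white noise and the music
   window excludes the first 10 s of music (startle guard),
6. average features and ratings over participants, one row per excerpt.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .errors import SignalError
from .synthetic import CHANNELS, RatingRecord, TrialRecording

FEATURES = ("scl", "hr", "resp", "zyg", "corr")

#: raw channel feeding each feature
FEATURE_SOURCE = {"scl": "scl", "hr": "ppg", "resp": "resp", "zyg": "zyg", "corr": "corr"}


@dataclass(frozen=True)
class FilterSpec:
    """High-/low-pass cutoffs for one channel; ``None`` disables a side."""

    channel: str
    hp_hz: float | None = None
    lp_hz: float | None = None


DEFAULT_FILTERS: dict[str, FilterSpec] = {
    "scl": FilterSpec("scl"),
    "resp": FilterSpec("resp"),
    "hr": FilterSpec("hr", hp_hz=0.5, lp_hz=3.0),
    "zyg": FilterSpec("zyg", hp_hz=1.0, lp_hz=500.0),
    "corr": FilterSpec("corr", hp_hz=1.0, lp_hz=500.0),
}


@dataclass(frozen=True)
class RateBounds:
    """Accepted event-rate range (events/minute) for a rate channel."""

    channel: str
    min_per_min: float
    max_per_min: float


DEFAULT_BOUNDS: dict[str, RateBounds] = {
    "hr": RateBounds("hr", 40.0, 180.0),
    "resp": RateBounds("resp", 5.0, 180.0),
}


def apply_filter(series: np.ndarray, spec: FilterSpec, sample_rate_hz: float) -> np.ndarray:
    """Zero-phase Butterworth band-pass per ``spec``; pass-through when both
    cutoffs are ``None``.  A low-pass cutoff at or above Nyquist is clamped to
    0.45 x sample rate with a warning."""
    series = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(series)):
        raise SignalError(f"channel {spec.channel}: non-finite samples")
    hp, lp = spec.hp_hz, spec.lp_hz
    if hp is None and lp is None:
        return series.copy()
    nyq = sample_rate_hz / 2.0
    if lp is not None and lp >= nyq:
        lp = 0.45 * sample_rate_hz
        warnings.warn(
            f"channel {spec.channel}: low-pass cutoff {spec.lp_hz} Hz >= Nyquist "
            f"({nyq} Hz); clamped to {lp} Hz", stacklevel=2)
    if hp is not None and lp is not None:
        sos = _signal.butter(2, [hp, lp], btype="bandpass", fs=sample_rate_hz, output="sos")
    elif hp is not None:
        sos = _signal.butter(2, hp, btype="highpass", fs=sample_rate_hz, output="sos")
    else:
        sos = _signal.butter(2, lp, btype="lowpass", fs=sample_rate_hz, output="sos")
    return _signal.sosfiltfilt(sos, series)


def detect_rate_series(series: np.ndarray, bounds: RateBounds, sample_rate_hz: float
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Peak-detect a periodic channel and convert it to an events/min series.

    Local maxima are required to be at least ``60 / max_per_min`` seconds
    apart.  Inter-event intervals implying rates outside [min, max]/min are
    rejected; the rate series is linearly interpolated across rejected spans
    (interval rates are placed at interval midpoints, held constant at the
    edges).  Returns ``(event_times_s, rate_series)`` with the rate series on
    the sample grid.

    Raises :class:`SignalError` when fewer than two events survive.
    """
    series = np.asarray(series, dtype=float)
    n = len(series)
    min_dist = max(1, int(round(sample_rate_hz * 60.0 / bounds.max_per_min)))
    prominence = 0.25 * (np.percentile(series, 95) - np.percentile(series, 5))
    peaks, _ = _signal.find_peaks(series, distance=min_dist, prominence=prominence)
    if len(peaks) < 2:
        raise SignalError(
            f"channel {bounds.channel}: fewer than 2 events detected over "
            f"{n / sample_rate_hz:.1f} s window")
    event_times = peaks / sample_rate_hz
    intervals = np.diff(event_times)
    rates = 60.0 / intervals
    ok = (rates >= bounds.min_per_min) & (rates <= bounds.max_per_min)
    if ok.sum() < 1:
        lo = rates.min()
        raise SignalError(
            f"channel {bounds.channel}: no accepted inter-event intervals over "
            f"{n / sample_rate_hz:.1f} s window (implied rates {lo:.1f}"
            f"-{rates.max():.1f}/min outside [{bounds.min_per_min}, {bounds.max_per_min}])")
    mid = (event_times[:-1] + event_times[1:]) / 2.0
    t_grid = np.arange(n) / sample_rate_hz
    rate_series = np.interp(t_grid, mid[ok], rates[ok])
    return event_times, rate_series


def process_trial(trial: TrialRecording,
                  filters: dict[str, FilterSpec] | None = None,
                  bounds: dict[str, RateBounds] | None = None) -> dict[str, np.ndarray]:
    """Derive the five per-sample feature series of one trial (pre-z-scoring):
    SCL as-is, HR and respiration as rate series, EMG band-passed and
    full-wave rectified."""
    filters = filters if filters is not None else DEFAULT_FILTERS
    bounds = bounds if bounds is not None else DEFAULT_BOUNDS
    fs = trial.sample_rate_hz
    out: dict[str, np.ndarray] = {}
    with warnings.catch_warnings():
        # the 500 Hz EMG low-pass is routinely clamped at desk sampling rates
        warnings.simplefilter("ignore")
        filtered = {f: apply_filter(trial.channels[FEATURE_SOURCE[f]], filters[f], fs)
                    for f in FEATURES}
    out["scl"] = filtered["scl"]
    for f in ("hr", "resp"):
        _, out[f] = detect_rate_series(filtered[f], bounds[f], fs)
    for f in ("zyg", "corr"):
        out[f] = np.abs(filtered[f])
    return out


def standardize_participant(processed: list[dict[str, np.ndarray]]
                            ) -> list[dict[str, np.ndarray]]:
    """Z-score each channel with mean/SD pooled across all trials of one
    participant, so the pooled series has mean 0 and SD 1 per channel."""
    if not processed:
        raise SignalError("no trials to standardize")
    z: list[dict[str, np.ndarray]] = [dict() for _ in processed]
    for f in FEATURES:
        pooled = np.concatenate([p[f] for p in processed])
        mu, sd = pooled.mean(), pooled.std()
        if sd == 0 or not np.isfinite(sd):
            raise SignalError(f"channel {f}: zero pooled SD (degenerate channel)")
        for zi, p in zip(z, processed):
            zi[f] = (p[f] - mu) / sd
    return z


@dataclass(frozen=True)
class FeatureVector:
    """Baseline-corrected music-window response of one trial, in z-units."""

    scl: float
    hr: float
    resp: float
    zyg: float
    corr: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in FEATURES])


#: feature windows relative to segment onsets, seconds
BASELINE_WINDOW = (10.0, 30.0)   # final 20 s of a 30 s baseline
MUSIC_WINDOW = (10.0, 40.0)      # music with the first 10 s excluded


def extract_feature(ztrial: dict[str, np.ndarray], baseline_dur_s: float,
                    music_dur_s: float, sample_rate_hz: float) -> FeatureVector:
    """feature = mean(z, music window) - mean(z, baseline window)."""
    if BASELINE_WINDOW[1] > baseline_dur_s:
        raise SignalError(
            f"baseline window {BASELINE_WINDOW} extends past the "
            f"{baseline_dur_s} s baseline segment")
    if MUSIC_WINDOW[1] > music_dur_s:
        raise SignalError(
            f"music window {MUSIC_WINDOW} extends past the {music_dur_s} s music segment")
    fs = sample_rate_hz
    b0 = int(round(BASELINE_WINDOW[0] * fs))
    b1 = int(round(BASELINE_WINDOW[1] * fs))
    m0 = int(round((baseline_dur_s + MUSIC_WINDOW[0]) * fs))
    m1 = int(round((baseline_dur_s + MUSIC_WINDOW[1]) * fs))
    vals = {}
    for f in FEATURES:
        z = ztrial[f]
        if len(z) < m1:
            raise SignalError(f"channel {f}: series too short for music window [{m0}, {m1})")
        vals[f] = float(z[m0:m1].mean() - z[b0:b1].mean())
        if not np.isfinite(vals[f]):
            raise SignalError(f"channel {f}: non-finite feature")
    return FeatureVector(**vals)


def feature_window_sample_counts(baseline_dur_s: float, sample_rate_hz: float
                                 ) -> tuple[int, int]:
    """(baseline, music) sample counts entering each feature — 20 s and 30 s
    worth of samples by construction."""
    fs = sample_rate_hz
    b = int(round(BASELINE_WINDOW[1] * fs)) - int(round(BASELINE_WINDOW[0] * fs))
    m0 = int(round((baseline_dur_s + MUSIC_WINDOW[0]) * fs))
    m1 = int(round((baseline_dur_s + MUSIC_WINDOW[1]) * fs))
    return b, m1 - m0


def build_feature_matrix(trials: list[TrialRecording], ratings: list[RatingRecord],
                         filters: dict[str, FilterSpec] | None = None,
                         bounds: dict[str, RateBounds] | None = None) -> pd.DataFrame:
    """Participant-averaged feature matrix: one row per excerpt with columns
    ``scl, hr, resp, zyg, corr, mean_valence, mean_arousal``.

    Only participants with a complete set of trials (every excerpt present)
    enter the average; an excerpt with no complete participant raises
    :class:`SignalError`.
    """
    by_participant: dict[str, list[TrialRecording]] = {}
    for tr in trials:
        by_participant.setdefault(tr.participant, []).append(tr)
    # preserve first-seen excerpt order
    seen: list[str] = []
    for tr in trials:
        if tr.excerpt not in seen:
            seen.append(tr.excerpt)
    excerpt_ids = seen

    rows: dict[str, list[np.ndarray]] = {e: [] for e in excerpt_ids}
    for pid, ptrials in by_participant.items():
        if {tr.excerpt for tr in ptrials} != set(excerpt_ids):
            continue  # incomplete participant: excluded from averaging
        processed = [process_trial(tr, filters, bounds) for tr in ptrials]
        z = standardize_participant(processed)
        for tr, zt in zip(ptrials, z):
            fv = extract_feature(zt, tr.baseline_dur_s, tr.music_dur_s, tr.sample_rate_hz)
            rows[tr.excerpt].append(fv.as_array())
    for e in excerpt_ids:
        if not rows[e]:
            raise SignalError(f"excerpt {e}: no complete participants")

    rdf = pd.DataFrame([(r.participant, r.excerpt, r.valence, r.arousal) for r in ratings],
                       columns=["participant", "excerpt", "valence", "arousal"])
    mean_ratings = rdf.groupby("excerpt")[["valence", "arousal"]].mean()

    data = []
    for e in excerpt_ids:
        feats = np.mean(rows[e], axis=0)
        data.append([e, *feats, mean_ratings.loc[e, "valence"], mean_ratings.loc[e, "arousal"]])
    df = pd.DataFrame(data, columns=["excerpt", *FEATURES, "mean_valence", "mean_arousal"])
    return df.set_index("excerpt")
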