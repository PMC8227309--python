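"""Synthetic EEG cohort generator.

Emulates the two-modality learning study: each participant contributes
one session (EC/EO baselines + three 150-s learning tasks at 256 Hz on
the 8-channel montage) and three test scores.  Signals are a 1/f
("pink") Gaussian background plus band-limited sinusoidal oscillations
at band-center frequencies, whose amplitudes depend on group, segment
and band, with per-participant trait variability and per-segment state
variability.  Scores are a known linear function of designated spectral
features plus Gaussian noise, so the downstream selection and
regression stages can be tested for parameter recovery.

Everything is a pure function of ``(spec, seed, indices)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bands import BANDS
from .recording import (
    CHANNELS,
    GROUPS,
    EEGRecording,
    ScoreRecord,
    SegmentAnnotation,
    default_annotations,
)

logger = logging.getLogger(__name__)

#: Per-band scalp topography gains (channel order FP2,FP1,C4,C3,P8,P7,O2,O1):
#: slow bands dominate frontally, alpha posteriorly -- the textbook pattern.
DEFAULT_TOPOGRAPHY: dict[str, tuple[float, ...]] = {
    "delta": (1.2, 1.2, 1.0, 1.0, 0.9, 0.9, 0.8, 0.8),
    "theta": (1.1, 1.1, 1.0, 1.0, 1.0, 1.0, 0.9, 0.9),
    "alpha": (0.7, 0.7, 0.9, 0.9, 1.1, 1.1, 1.3, 1.3),
    "beta": (1.0, 1.0, 1.1, 1.1, 1.0, 1.0, 0.9, 0.9),
    "gamma": (1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0),
}


def default_band_amplitudes() -> dict[str, dict[str, dict[str, float]]]:
    """Base oscillation amplitudes in microvolts per (group, segment, band).

    EC shows the classic posterior alpha surge; during the learning task
    the video group sits at a higher alpha/theta working point than the
    text group (lower mental-fatigue index), which is what links EEG
    features to the generated scores.
    """
    common_ec = {"delta": 8.0, "theta": 5.0, "alpha": 14.0, "beta": 3.0, "gamma": 1.5}
    common_eo = {"delta": 8.0, "theta": 5.0, "alpha": 7.0, "beta": 3.5, "gamma": 1.5}
    lt_text = {"delta": 8.0, "theta": 6.0, "alpha": 7.0, "beta": 4.0, "gamma": 2.0}
    lt_video = {"delta": 7.5, "theta": 5.5, "alpha": 8.5, "beta": 4.0, "gamma": 2.0}
    return {
        "text": {"EC": dict(common_ec), "EO": dict(common_eo), "LT": lt_text},
        "video": {"EC": dict(common_ec), "EO": dict(common_eo), "LT": lt_video},
    }


@dataclass
class ScoreModel:
    """Linear link from named spectral features to test scores."""

    feature_names: tuple[str, ...] = ("C3_alpha/theta", "FP1_delta")
    coefficients: tuple[float, ...] = (6.0, -30.0)
    intercept: float = 60.0
    noise_sd: float = 5.0

    def __post_init__(self) -> None:
        if len(self.feature_names) != len(self.coefficients):
            raise ValueError("one coefficient per feature required")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort.

    ``band_amplitudes[group][segment][band]`` is the base oscillation
    amplitude in microvolts; a scalar is spread over channels by
    ``topography``, or an explicit 8-vector may be given instead.
    Between-participant (trait) and within-session (state) variability
    are lognormal multipliers layered from coarse to fine, all shared
    across segments except the state terms: ``amplitude_jitter_global``
    scales every band and channel together (overall amplitude differs
    between heads); ``amplitude_jitter_trait`` is a per-band residual
    and ``amplitude_jitter_trait_channel`` a per-band-per-channel
    residual (no two channels are exact copies of each other);
    ``amplitude_jitter_state`` / ``amplitude_jitter_state_channel``
    fluctuate per segment, which is what baseline-normalized power
    picks up.
    """

    n_text: int = 10
    n_video: int = 10
    seed: int = 0
    fs: float = 256.0
    band_amplitudes: dict = field(default_factory=default_band_amplitudes)
    topography: dict = field(default_factory=lambda: {k: v for k, v in DEFAULT_TOPOGRAPHY.items()})
    noise_exponent: float = 1.0
    background_rms: float = 10.0
    amplitude_jitter_global: float = 0.20
    amplitude_jitter_trait: float = 0.06
    amplitude_jitter_trait_channel: float = 0.08
    amplitude_jitter_state: float = 0.05
    amplitude_jitter_state_channel: float = 0.10
    artifact_rate: float = 0.0
    artifact_amplitude: float = 30.0
    score_model: ScoreModel = field(default_factory=ScoreModel)

    def __post_init__(self) -> None:
        if self.n_text < 1 or self.n_video < 1:
            raise ValueError("participant counts must be >= 1")
        if self.background_rms <= 0:
            raise ValueError("background_rms must be positive")
        if self.artifact_rate < 0:
            raise ValueError("artifact_rate must be >= 0")

    def amplitude_vector(self, group: str, segment_label: str, band_name: str) -> np.ndarray:
        """Resolve the per-channel amplitude vector for one (group, segment, band)."""
        amp = self.band_amplitudes[group][segment_label][band_name]
        amp = np.asarray(amp, dtype=float)
        if amp.ndim == 0:
            topo = np.asarray(self.topography.get(band_name, np.ones(len(CHANNELS))), dtype=float)
            return float(amp) * topo
        if amp.shape != (len(CHANNELS),):
            raise ValueError(
                f"amplitude for ({group},{segment_label},{band_name}) must be scalar or "
                f"{len(CHANNELS)}-vector"
            )
        return amp


_GROUP_CODE = {"text": 1, "video": 2}


def participant_id(group: str, participant_index: int) -> str:
    prefix = "Pt" if group == "text" else "Pv"
    return f"{prefix}{participant_index + 1}"


def _pink_background(rng: np.random.Generator, n_channels: int, n_samples: int,
                     fs: float, exponent: float, rms: float) -> np.ndarray:
    """1/f-shaped Gaussian noise: white noise whose FFT magnitudes are
    weighted by f**(-exponent/2), rescaled to the requested per-channel RMS."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    weight = np.empty_like(freqs)
    weight[0] = 0.0  # no DC
    weight[1:] = freqs[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spec * weight[None, :], n=n_samples, axis=1)
    sd = shaped.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped * (rms / sd)


def generate_recording(spec: CohortSpec, participant_index: int, group: str) -> EEGRecording:
    """Generate one participant's full session.

    Deterministic given ``(spec.seed, participant_index, group)``: the
    same call twice returns bit-identical data.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    rng = np.random.default_rng([spec.seed, _GROUP_CODE[group], participant_index, 11])
    annotations = default_annotations(spec.fs)
    n_samples = annotations[-1].end_sample
    data = _pink_background(
        rng, len(CHANNELS), n_samples, spec.fs, spec.noise_exponent, spec.background_rms
    )

    # stable per-participant trait multipliers: a global amplitude scale,
    # a per-band residual and a per-band-per-channel residual
    global_scale = np.exp(rng.normal(0.0, spec.amplitude_jitter_global))
    trait_band = np.exp(rng.normal(0.0, spec.amplitude_jitter_trait, size=len(BANDS)))
    trait_chan = np.exp(
        rng.normal(0.0, spec.amplitude_jitter_trait_channel, size=(len(BANDS), len(CHANNELS)))
    )

    t_axis = np.arange(n_samples) / spec.fs
    for ann in annotations:
        sl = slice(ann.start_sample, ann.end_sample)
        t = t_axis[sl]
        for bi, band in enumerate(BANDS):
            state = np.exp(rng.normal(0.0, spec.amplitude_jitter_state))
            state_chan = np.exp(
                rng.normal(0.0, spec.amplitude_jitter_state_channel, size=len(CHANNELS))
            )
            amp = (
                spec.amplitude_vector(group, ann.label, band.name)
                * global_scale * trait_band[bi] * trait_chan[bi] * state * state_chan
            )
            phases = rng.uniform(0.0, 2.0 * np.pi, size=len(CHANNELS))
            data[:, sl] += amp[:, None] * np.sin(
                2.0 * np.pi * band.center * t[None, :] + phases[:, None]
            )

    return EEGRecording(
        data=data,
        fs=spec.fs,
        annotations=annotations,
        participant_id=participant_id(group, participant_index),
        group=group,
    )


def generate_cohort_recordings(spec: CohortSpec) -> list[EEGRecording]:
    """All recordings of the cohort: text participants first, then video."""
    recs = [generate_recording(spec, i, "text") for i in range(spec.n_text)]
    recs += [generate_recording(spec, i, "video") for i in range(spec.n_video)]
    return recs


#: Mean exam time (s) per repetition and the video-group speed-up used
#: when generating exam times; tests get longer as difficulty grows.
_EXAM_TIME_BASE = {1: 40.0, 2: 55.0, 3: 90.0}
_EXAM_TIME_VIDEO_FACTOR = 0.82
_EXAM_TIME_LOG_SD = 0.15


def generate_scores(spec: CohortSpec, features: pd.DataFrame) -> list[ScoreRecord]:
    """Draw scores for every (participant, repetition) row of a feature matrix.

    ``score = intercept + sum(coef * feature) + N(0, noise_sd)``, clipped
    to [0, 100].  Exam times are lognormal around a repetition-dependent
    base, faster for the video group.  Deterministic given ``spec.seed``.
    """
    model = spec.score_model
    missing = [n for n in model.feature_names if n not in features.columns]
    if missing:
        raise KeyError(f"score_model features not in matrix: {missing}")

    rng = np.random.default_rng([spec.seed, 3, 17])
    rows = features.sort_values(["participant_id", "repetition"]).reset_index(drop=True)
    out: list[ScoreRecord] = []
    for _, row in rows.iterrows():
        linear = model.intercept + sum(
            c * float(row[name]) for c, name in zip(model.coefficients, model.feature_names)
        )
        score = float(np.clip(linear + rng.normal(0.0, model.noise_sd), 0.0, 100.0))
        rep = int(row["repetition"])
        base = _EXAM_TIME_BASE[rep]
        if row["group"] == "video":
            base *= _EXAM_TIME_VIDEO_FACTOR
        exam_time = float(base * np.exp(rng.normal(0.0, _EXAM_TIME_LOG_SD)))
        out.append(
            ScoreRecord(
                participant_id=str(row["participant_id"]),
                group=str(row["group"]),
                repetition=rep,
                score=score,
                exam_time_s=exam_time,
            )
        )
    return out


@dataclass(frozen=True)
class ArtifactEvent:
    """Injected transient: sample interval and affected channel indices."""

    start_sample: int
    end_sample: int
    channels: tuple[int, ...]


def inject_artifacts(
    rec: EEGRecording,
    rate: float,
    amplitude: float,
    seed: int,
    segment_labels: tuple[str, ...] = ("LT",),
) -> tuple[EEGRecording, list[ArtifactEvent]]:
    """Add high-amplitude transients and return their positions.

    ``rate`` is events per minute within each targeted segment;
    ``amplitude`` scales the per-channel EO-segment standard deviation
    (the cleaning stage's calibration scale).  Each event is a raised-
    cosine bump of 100-300 ms on a random non-empty channel subset.
    Baselines are left clean by default so ASR calibration stays valid.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    out = rec.copy_with(rec.data)
    events: list[ArtifactEvent] = []
    if rate == 0:
        return out, events

    rng = np.random.default_rng([seed, 167])
    calib_sd = rec.segment_data("EO").std(axis=1)
    for ann in rec.annotations:
        if ann.label not in segment_labels:
            continue
        duration_min = ann.n_samples / rec.fs / 60.0
        n_events = rng.poisson(rate * duration_min)
        for _ in range(n_events):
            dur = int(round(rng.uniform(0.1, 0.3) * rec.fs))
            start = int(rng.integers(ann.start_sample, max(ann.start_sample + 1, ann.end_sample - dur)))
            stop = min(start + dur, ann.end_sample)
            picks = np.flatnonzero(rng.random(len(CHANNELS)) < 0.5)
            if picks.size == 0:
                picks = np.array([rng.integers(0, len(CHANNELS))])
            bump = np.hanning(stop - start)
            sign = rng.choice([-1.0, 1.0])
            for ch in picks:
                out.data[ch, start:stop] += sign * amplitude * calib_sd[ch] * bump
            events.append(ArtifactEvent(start, stop, tuple(int(c) for c in picks)))
    return out, events
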