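"""Windowed FFT band power, eyes-open baseline normalization, power
ratios, and assembly of the 200-column feature matrix.

Power is estimated per non-overlapping 1-s rectangular window by plain
FFT periodogram; the one-sided scaling is chosen so a pure sinusoid of
amplitude A at an integer frequency contributes exactly A**2/2 to its
band.  Learning-task power is normalized to the eyes-open baseline,

    P_N(t) = (P_LT(t) - mean(P_EO)) / mean(P_EO),

per channel and band; band-power ratios are taken on RAW (unnormalized)
learning-task power.  The feature matrix has one row per (participant,
repetition) and 200 named columns: 40 time-averaged normalized band
powers ("<CH>_<band>") followed by 160 time-averaged raw-power ratios
("<CH>_<num>/<den>").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bands import BAND_NAMES, BANDS, RATIOS, BandDefinition, RatioDescriptor
from .recording import CHANNELS, EEGRecording, ScoreRecord

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ("participant_id", "group", "repetition", "score", "exam_time_s")


def feature_names(
    channels: tuple[str, ...] = CHANNELS,
    bands: tuple[BandDefinition, ...] = BANDS,
    ratios: tuple[RatioDescriptor, ...] = RATIOS,
) -> list[str]:
    """The fixed 200-name column grammar: channels x bands, then channels x ratios."""
    names = [f"{ch}_{b.name}" for ch in channels for b in bands]
    names += [f"{ch}_{r.name}" for ch in channels for r in ratios]
    return names


@dataclass
class BandPowerSeries:
    """Per-window, per-channel, per-band power: ``values[window, channel, band]``.

    Raw values are in microvolt**2; normalized values are dimensionless
    deviations from the eyes-open baseline (>= -1 by construction).
    """

    values: np.ndarray
    band_names: tuple[str, ...]
    window_s: float = 1.0
    normalized: bool = False

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    def mean_over_windows(self) -> np.ndarray:
        return self.values.mean(axis=0)


def window_band_power(
    segment_data: np.ndarray,
    fs: float,
    bands: tuple[BandDefinition, ...] = BANDS,
    window_s: float = 1.0,
) -> BandPowerSeries:
    """Periodogram band power over non-overlapping rectangular windows.

    A trailing partial window is discarded.  Frequency bins are assigned
    to bands by bin-center frequency on the half-open interval
    ``[low, high)``; bins in the inter-band gaps belong to no band.
    """
    data = np.asarray(segment_data, dtype=float)
    if data.ndim != 2:
        raise ValueError("segment_data must be channels x samples")
    win = int(round(window_s * fs))
    n_win = data.shape[1] // win
    if n_win < 1:
        raise ValueError(
            f"segment of {data.shape[1]} samples is shorter than one {window_s}-s window"
        )
    windows = data[:, : n_win * win].reshape(data.shape[0], n_win, win)
    spec = np.fft.rfft(windows, axis=2)
    # one-sided periodogram: sinusoid amplitude A at an integer bin -> A^2/2
    power = (np.abs(spec) ** 2) * (2.0 / win**2)
    power[:, :, 0] /= 2.0
    if win % 2 == 0:
        power[:, :, -1] /= 2.0
    freqs = np.fft.rfftfreq(win, d=1.0 / fs)
    band_power = np.empty((n_win, data.shape[0], len(bands)))
    for bi, band in enumerate(bands):
        mask = (freqs >= band.low) & (freqs < band.high)
        band_power[:, :, bi] = power[:, :, mask].sum(axis=2).T
    return BandPowerSeries(
        values=band_power,
        band_names=tuple(b.name for b in bands),
        window_s=window_s,
        normalized=False,
    )


def normalize_power(lt: BandPowerSeries, eo: BandPowerSeries) -> BandPowerSeries:
    """Baseline-normalize learning-task power to the eyes-open mean."""
    if lt.normalized or eo.normalized:
        raise ValueError("normalize_power expects raw band-power series")
    if eo.n_windows < 1:
        raise ValueError("eyes-open series has no windows")
    eo_mean = eo.values.mean(axis=0)  # (channel, band)
    zero = np.argwhere(eo_mean == 0)
    if zero.size:
        ch_i, b_i = zero[0]
        raise ValueError(
            f"eyes-open mean power is zero at channel {CHANNELS[ch_i]}, "
            f"band {eo.band_names[b_i]}; cannot normalize"
        )
    return BandPowerSeries(
        values=(lt.values - eo_mean[None, :, :]) / eo_mean[None, :, :],
        band_names=lt.band_names,
        window_s=lt.window_s,
        normalized=True,
    )


@dataclass
class RatioSeries:
    """Per-window, per-channel ratio of two bands' raw power.

    Windows with a zero denominator are dropped (NaN) per channel and
    counted in ``n_dropped``.
    """

    values: np.ndarray  # (window, channel), NaN where dropped
    descriptor: RatioDescriptor
    n_dropped: int = 0

    def mean_over_windows(self) -> np.ndarray:
        return np.nanmean(self.values, axis=0)


MAX_DROPPED_FRACTION = 0.10


def power_ratio(lt: BandPowerSeries, descriptor: RatioDescriptor) -> RatioSeries:
    """Elementwise per-window band-power ratio on RAW learning-task power."""
    if lt.normalized:
        raise ValueError("power ratios are defined on raw (unnormalized) power")
    num_i = lt.band_names.index(descriptor.numerator)
    den_i = lt.band_names.index(descriptor.denominator)
    num = lt.values[:, :, num_i]
    den = lt.values[:, :, den_i]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    n_dropped = int(np.isnan(ratio).sum())
    dropped_frac = np.isnan(ratio).mean(axis=0)
    if np.any(dropped_frac > MAX_DROPPED_FRACTION):
        ch = CHANNELS[int(np.argmax(dropped_frac))]
        raise ValueError(
            f"ratio {descriptor.name}: more than {MAX_DROPPED_FRACTION:.0%} of windows "
            f"dropped for zero denominator at channel {ch}"
        )
    if n_dropped:
        logger.info("ratio %s: dropped %d zero-denominator windows", descriptor.name, n_dropped)
    return RatioSeries(values=ratio, descriptor=descriptor, n_dropped=n_dropped)


def participant_features(
    rec: EEGRecording,
    bands: tuple[BandDefinition, ...] = BANDS,
    ratios: tuple[RatioDescriptor, ...] = RATIOS,
    window_s: float = 1.0,
) -> dict[int, dict[str, float]]:
    """Per-repetition feature vectors for one recording.

    Returns ``{repetition: {feature_name: value}}`` with the 40
    normalized-power features and 160 ratio features per repetition.
    """
    eo = window_band_power(rec.segment_data("EO"), rec.fs, bands, window_s)
    out: dict[int, dict[str, float]] = {}
    for ann in rec.lt_segments():
        lt = window_band_power(
            rec.data[:, ann.start_sample : ann.end_sample], rec.fs, bands, window_s
        )
        feats: dict[str, float] = {}
        norm_mean = normalize_power(lt, eo).mean_over_windows()  # (channel, band)
        for ci, ch in enumerate(rec.channel_labels):
            for bi, band in enumerate(bands):
                feats[f"{ch}_{band.name}"] = float(norm_mean[ci, bi])
        ratio_means = {r.name: power_ratio(lt, r).mean_over_windows() for r in ratios}
        for ci, ch in enumerate(rec.channel_labels):
            for r in ratios:
                feats[f"{ch}_{r.name}"] = float(ratio_means[r.name][ci])
        out[ann.repetition] = feats
    return out


def build_feature_matrix(
    recordings: list[EEGRecording],
    scores: list[ScoreRecord] | None = None,
    bands: tuple[BandDefinition, ...] = BANDS,
    ratios: tuple[RatioDescriptor, ...] = RATIOS,
    window_s: float = 1.0,
) -> pd.DataFrame:
    """Assemble the cohort feature matrix: one row per (participant, repetition).

    When ``scores`` is given, rows without a matching score record are
    omitted and logged (mirroring discarded participants); when None,
    the score/exam-time columns are left NaN so that scores can be
    generated from the features afterwards.
    """
    columns = feature_names(tuple(CHANNELS), bands, ratios)
    score_lookup: dict[tuple[str, int], ScoreRecord] = {}
    if scores is not None:
        score_lookup = {(s.participant_id, s.repetition): s for s in scores}

    rows: list[dict] = []
    for rec in recordings:
        try:
            per_rep = participant_features(rec, bands, ratios, window_s)
        except (KeyError, ValueError) as exc:
            logger.warning("participant %s omitted: %s", rec.participant_id, exc)
            continue
        for rep, feats in sorted(per_rep.items()):
            meta: dict[str, object] = {
                "participant_id": rec.participant_id,
                "group": rec.group,
                "repetition": rep,
                "score": np.nan,
                "exam_time_s": np.nan,
            }
            if scores is not None:
                key = (rec.participant_id, rep)
                if key not in score_lookup:
                    logger.warning("row %s omitted: no score record", key)
                    continue
                meta["score"] = score_lookup[key].score
                meta["exam_time_s"] = score_lookup[key].exam_time_s
            meta.update(feats)
            rows.append(meta)

    fm = pd.DataFrame(rows, columns=list(METADATA_COLUMNS) + columns)
    if scores is not None and fm[columns].isna().any().any():
        raise AssertionError("feature matrix contains missing feature values")
    return fm


def attach_scores(fm: pd.DataFrame, scores: list[ScoreRecord]) -> pd.DataFrame:
    """Fill the score/exam-time metadata columns from score records."""
    lookup = {(s.participant_id, s.repetition): s for s in scores}
    out = fm.copy()
    keep = []
    for i, row in out.iterrows():
        key = (row["participant_id"], int(row["repetition"]))
        if key in lookup:
            out.loc[i, "score"] = lookup[key].score
            out.loc[i, "exam_time_s"] = lookup[key].exam_time_s
            keep.append(i)
        else:
            logger.warning("row %s dropped: no score record", key)
    return out.loc[keep].reset_index(drop=True)
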