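"""In-memory containers for multi-channel EEG recordings and test scores.

A recording session holds one eyes-closed (EC) and one eyes-open (EO)
30-s baseline plus three 150-s learning-task (LT) repetitions, all at a
common sampling rate on the 8-channel dry-electrode montage
FP2, FP1, C4, C3, P8, P7, O2, O1 (10-20 positions).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Headset channel order (10-20 labels), fixed for the whole pipeline.
CHANNELS: tuple[str, ...] = ("FP2", "FP1", "C4", "C3", "P8", "P7", "O2", "O1")

GROUPS: tuple[str, ...] = ("text", "video")

SEGMENT_LABELS: tuple[str, ...] = ("EC", "EO", "LT")

#: Protocol segment durations in seconds.
EC_DURATION_S = 30.0
EO_DURATION_S = 30.0
LT_DURATION_S = 150.0
N_REPETITIONS = 3


@dataclass(frozen=True)
class SegmentAnnotation:
    """Half-open sample interval ``[start_sample, end_sample)`` with a label.

    ``repetition`` is 1-3 for LT segments and None for baselines.
    """

    label: str
    start_sample: int
    end_sample: int
    repetition: int | None = None

    def __post_init__(self) -> None:
        if self.label not in SEGMENT_LABELS:
            raise ValueError(f"unknown segment label {self.label!r}; expected one of {SEGMENT_LABELS}")
        if self.end_sample <= self.start_sample:
            raise ValueError("empty or inverted segment interval")
        if self.label == "LT":
            if self.repetition not in (1, 2, 3):
                raise ValueError("LT segments need repetition 1-3")
        elif self.repetition is not None:
            raise ValueError(f"{self.label} segments carry no repetition")

    @property
    def n_samples(self) -> int:
        return self.end_sample - self.start_sample


@dataclass
class EEGRecording:
    """One participant's session: ``data`` is channels x samples in microvolts."""

    data: np.ndarray
    fs: float
    annotations: list[SegmentAnnotation]
    participant_id: str
    group: str
    channel_labels: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"data must be {len(self.channel_labels)} channels x T samples, got {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        for ann in self.annotations:
            if ann.end_sample > self.data.shape[1]:
                raise ValueError(f"annotation {ann} exceeds recording length {self.data.shape[1]}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def segment(self, label: str, repetition: int | None = None) -> SegmentAnnotation:
        """Return the unique annotation with this label (and repetition for LT)."""
        matches = [
            a
            for a in self.annotations
            if a.label == label and (repetition is None or a.repetition == repetition)
        ]
        if not matches:
            raise KeyError(f"no {label!r} segment (repetition={repetition}) in recording")
        if len(matches) > 1:
            raise KeyError(f"ambiguous segment request {label!r} (repetition={repetition})")
        return matches[0]

    def segment_data(self, label: str, repetition: int | None = None) -> np.ndarray:
        ann = self.segment(label, repetition)
        return self.data[:, ann.start_sample : ann.end_sample]

    def lt_segments(self) -> list[SegmentAnnotation]:
        return sorted(
            (a for a in self.annotations if a.label == "LT"), key=lambda a: a.repetition
        )

    def copy_with(self, data: np.ndarray) -> "EEGRecording":
        return replace(self, data=np.array(data, dtype=float))


@dataclass(frozen=True)
class ScoreRecord:
    """One test outcome: score on a 0-100 scale and exam time in seconds."""

    participant_id: str
    group: str
    repetition: int
    score: float
    exam_time_s: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 100.0:
            raise ValueError(f"score {self.score} outside [0, 100]")
        if self.exam_time_s <= 0:
            raise ValueError("exam time must be positive")
        if self.repetition not in (1, 2, 3):
            raise ValueError("repetition must be 1-3")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")


def default_annotations(fs: float) -> list[SegmentAnnotation]:
    """The standard session layout: EC, EO, then three LT repetitions."""
    out: list[SegmentAnnotation] = []
    cursor = 0
    for label, dur, rep in (
        ("EC", EC_DURATION_S, None),
        ("EO", EO_DURATION_S, None),
        ("LT", LT_DURATION_S, 1),
        ("LT", LT_DURATION_S, 2),
        ("LT", LT_DURATION_S, 3),
    ):
        n = int(round(dur * fs))
        out.append(SegmentAnnotation(label, cursor, cursor + n, rep))
        cursor += n
    return out
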