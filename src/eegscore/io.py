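"""Disk formats: EDF+ and plain CSV for recordings, CSV for scores.

Two recording dialects are supported losslessly enough for the
pipeline:

* **EDF+C** -- one file per participant, 8 EEG signals in microvolts
  (16-bit quantized against a symmetric per-file physical range) plus
  an annotations signal carrying the EC/EO/LT segment boundaries.
  Writing is implemented here directly against the EDF byte layout;
  reading goes through :func:`mne.io.read_raw_edf`, which also serves
  as an independent check of the writer in the test suite.
* **CSV** -- a sample x channel table (exact round trip) with
  ``# key=value`` metadata header lines and a companion
  ``<stem>.annotations.csv`` with columns
  ``label,repetition,start_sample,end_sample``.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import CHANNELS, EEGRecording, ScoreRecord, SegmentAnnotation


# --------------------------------------------------------------------------
# CSV dialect
# --------------------------------------------------------------------------

def annotations_path(data_path: Path) -> Path:
    data_path = Path(data_path)
    return data_path.with_name(data_path.stem + ".annotations.csv")


def write_recording_csv(rec: EEGRecording, path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# participant_id={rec.participant_id}\n")
        fh.write(f"# group={rec.group}\n")
        fh.write(f"# fs={rec.fs!r}\n")
        fh.write(",".join(rec.channel_labels) + "\n")
        np.savetxt(fh, rec.data.T, delimiter=",", fmt="%.17g")
    ann = pd.DataFrame(
        [
            {
                "label": a.label,
                "repetition": "" if a.repetition is None else a.repetition,
                "start_sample": a.start_sample,
                "end_sample": a.end_sample,
            }
            for a in rec.annotations
        ]
    )
    ann.to_csv(annotations_path(path), index=False)
    return path


def read_recording_csv(path: Path) -> EEGRecording:
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        header = [c.strip() for c in line.strip().split(",")]
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    unknown = [c for c in header if c not in CHANNELS]
    if unknown or list(header) != list(CHANNELS):
        raise ValueError(
            f"unexpected channel header {header}; expected montage {list(CHANNELS)}"
        )
    ann_path = annotations_path(path)
    if not ann_path.exists():
        raise FileNotFoundError(f"missing annotation file {ann_path}")
    ann_df = pd.read_csv(ann_path)
    annotations = [
        SegmentAnnotation(
            label=str(r["label"]),
            start_sample=int(r["start_sample"]),
            end_sample=int(r["end_sample"]),
            repetition=None if pd.isna(r["repetition"]) else int(r["repetition"]),
        )
        for _, r in ann_df.iterrows()
    ]
    return EEGRecording(
        data=data.T,
        fs=float(meta.get("fs", 256.0)),
        annotations=annotations,
        participant_id=meta.get("participant_id", path.stem),
        group=meta.get("group", "text"),
    )


def write_scores_csv(records: list[ScoreRecord], path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "group": r.group,
                "repetition": r.repetition,
                "score": r.score,
                "exam_time_s": r.exam_time_s,
            }
            for r in records
        ]
    ).to_csv(path, index=False)
    return path


def read_scores_csv(path: Path) -> list[ScoreRecord]:
    df = pd.read_csv(path)
    return [
        ScoreRecord(
            participant_id=str(r["participant_id"]),
            group=str(r["group"]),
            repetition=int(r["repetition"]),
            score=float(r["score"]),
            exam_time_s=float(r["exam_time_s"]),
        )
        for _, r in df.iterrows()
    ]


# --------------------------------------------------------------------------
# EDF+C writer / mne-based reader
# --------------------------------------------------------------------------

def _pad(text: str, width: int) -> bytes:
    raw = text.encode("ascii", errors="replace")[:width]
    return raw + b" " * (width - len(raw))


def write_recording_edf(rec: EEGRecording, path: Path) -> Path:
    """Write an EDF+C file: 8 EEG signals plus one annotations signal.

    Record duration is 1 s, so the sampling rate must be an integer.
    Samples are quantized to int16 over a symmetric physical range just
    above the data's absolute maximum.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_channels = rec.data.shape[0]
    n_records = int(np.ceil(rec.n_samples / fs))
    padded = np.zeros((n_channels, n_records * fs))
    padded[:, : rec.n_samples] = rec.data

    phys_max = max(1.0, float(np.abs(rec.data).max()) * 1.0001)
    phys_min = -phys_max
    dig_max, dig_min = 32767, -32768
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((padded - phys_min) * scale + dig_min).astype("<i2")

    # Annotation TALs: one per segment, distributed over the first records.
    tals: list[bytes] = []
    for a in rec.annotations:
        onset = a.start_sample / fs
        dur = a.n_samples / fs
        label = a.label if a.repetition is None else f"{a.label}{a.repetition}"
        tals.append(f"+{onset:g}\x15{dur:g}\x14{label}\x14\x00".encode("ascii"))
    ann_samples = 64  # 128 bytes per record, ample for one timestamp + one TAL
    ann_records = []
    for ri in range(n_records):
        chunk = f"+{ri}\x14\x14\x00".encode("ascii")
        if ri < len(tals):
            chunk += tals[ri]
        if len(chunk) > 2 * ann_samples:
            raise ValueError("annotation TAL too long for record")
        ann_records.append(chunk + b"\x00" * (2 * ann_samples - len(chunk)))
    if len(tals) > n_records:
        raise ValueError("more annotations than data records")

    ns = n_channels + 1
    header = b"".join(
        [
            _pad("0", 8),
            _pad(f"X X X {rec.participant_id}", 80),
            _pad(f"Startdate 01-JAN-2020 X X group={rec.group}", 80),
            _pad("01.01.20", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * (ns + 1)), 8),
            _pad("EDF+C", 44),
            _pad(str(n_records), 8),
            _pad("1", 8),
            _pad(str(ns), 4),
        ]
    )
    labels = [f"EEG {ch}" for ch in rec.channel_labels] + ["EDF Annotations"]
    signal_fields = [
        (labels, 16),
        (["" for _ in range(ns)], 80),  # transducer
        (["uV"] * n_channels + [""], 8),  # physical dimension
        ([f"{phys_min:.8g}"[:8]] * n_channels + ["-1"], 8),
        ([f"{phys_max:.8g}"[:8]] * n_channels + ["1"], 8),
        ([str(dig_min)] * ns, 8),
        ([str(dig_max)] * ns, 8),
        (["" for _ in range(ns)], 80),  # prefiltering
        ([str(fs)] * n_channels + [str(ann_samples)], 8),
        (["" for _ in range(ns)], 32),
    ]
    for values, width in signal_fields:
        header += b"".join(_pad(v, width) for v in values)

    with open(path, "wb") as fh:
        fh.write(header)
        for ri in range(n_records):
            fh.write(digital[:, ri * fs : (ri + 1) * fs].tobytes())
            fh.write(ann_records[ri])
    return path


_ANNOT_RE = re.compile(r"^(EC|EO|LT)(\d)?$")


def read_recording_edf(path: Path) -> EEGRecording:
    """Read an EDF recording (ours or compatible) via mne."""
    import mne

    path = Path(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    data = raw.get_data() * 1e6  # mne stores Volts for uV-dimensioned EEG
    names = [n.removeprefix("EEG ").strip() for n in raw.ch_names]
    if list(names) != list(CHANNELS):
        raise ValueError(f"unexpected channel labels {names}; expected montage {list(CHANNELS)}")

    with open(path, "rb") as fh:
        head = fh.read(168)
    patient = head[8:88].decode("ascii").strip()
    recording_field = head[88:168].decode("ascii").strip()
    participant = patient.split()[-1] if patient else path.stem
    m = re.search(r"group=(\w+)", recording_field)
    group = m.group(1) if m else "text"

    annotations = []
    n_samples_known = None
    for onset, duration, desc in zip(
        raw.annotations.onset, raw.annotations.duration, raw.annotations.description
    ):
        m = _ANNOT_RE.match(desc)
        if not m:
            continue
        start = int(round(onset * fs))
        end = start + int(round(duration * fs))
        annotations.append(
            SegmentAnnotation(
                label=m.group(1),
                start_sample=start,
                end_sample=end,
                repetition=int(m.group(2)) if m.group(2) else None,
            )
        )
        n_samples_known = max(n_samples_known or 0, end)
    if n_samples_known is not None and n_samples_known < data.shape[1]:
        data = data[:, :n_samples_known]  # strip zero padding of the last record
    return EEGRecording(
        data=data,
        fs=fs,
        annotations=annotations,
        participant_id=participant,
        group=group,
        channel_labels=tuple(names),
    )
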