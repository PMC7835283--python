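"""Reading, writing and windowing of multichannel intracranial EEG.

Recordings live in European Data Format (EDF) files; seizure-event
annotations (seizure id, phase, extent, involved contacts) are supplied as a
sidecar JSON file so that event definitions are deterministic and
format-independent.  All times are seconds from the start of the recording;
sample windows are 0-based and half-open.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np


class Phase(str, enum.Enum):
    """Clinically delineated stages of a seizure.

    ``baseline`` is the pre-ictal normative period; ``onset`` the electrographic
    seizure onset; ``ictal1``..``ictal3`` the successive propagation phases.
    """

    baseline = "baseline"
    onset = "onset"
    ictal1 = "ictal1"
    ictal2 = "ictal2"
    ictal3 = "ictal3"


@dataclass(frozen=True)
class EventAnnotation:
    """One clinically defined event: a labelled time window within a recording."""

    seizure_id: int
    phase: Phase
    start_s: float
    end_s: float
    involved_contacts: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.start_s < self.end_s:
            raise ValueError(f"start_s ({self.start_s}) must be < end_s ({self.end_s})")
        object.__setattr__(self, "phase", Phase(self.phase))
        object.__setattr__(self, "involved_contacts", frozenset(self.involved_contacts))

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class Recording:
    """Multichannel signal block: ``samples[i]`` is channel ``channel_labels[i]`` in µV."""

    channel_labels: list
    fs: float
    samples: np.ndarray
    start_time: float = 0.0

    def __post_init__(self):
        self.channel_labels = [str(c) for c in self.channel_labels]
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a channels x time matrix")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel_labels unique violated")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        return self.samples[self.channel_labels.index(label)]


@dataclass
class SegmentSet:
    """A group of fixed-duration consecutive windows cut from one recording."""

    segments: list  # of (source_id, offset_s, duration_s, samples)
    segment_duration_s: float
    segments_per_set: int


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: Recording, path) -> None:
    """Write a Recording as a single-record EDF file (16-bit, physical µV).

    Physical minima/maxima are chosen per channel to cover the signal range, so
    the quantisation step is (max-min)/65535 per channel.
    """
    path = Path(path)
    ns = rec.n_channels
    n_samp = rec.n_samples
    dig_min, dig_max = -32768, 32767
    phys_min = rec.samples.min(axis=1)
    phys_max = rec.samples.max(axis=1)
    flat = phys_max - phys_min <= 0
    phys_min = np.where(flat, phys_min - 1.0, phys_min)
    phys_max = np.where(flat, phys_max + 1.0, phys_max)

    header_bytes = 256 + 256 * ns
    record_duration = n_samp / rec.fs
    with open(path, "wb") as f:
        f.write(_edf_field("0", 8))
        f.write(_edf_field("X X X X", 80))
        f.write(_edf_field("Startdate 01-JAN-2000 X X X", 80))
        f.write(_edf_field("01.01.00", 8))
        f.write(_edf_field("00.00.00", 8))
        f.write(_edf_field(header_bytes, 8))
        f.write(_edf_field("", 44))
        f.write(_edf_field(1, 8))  # one data record holding the full signal
        f.write(_edf_field(f"{record_duration:.6g}", 8))
        f.write(_edf_field(ns, 4))
        for lab in rec.channel_labels:
            f.write(_edf_field(lab, 16))
        for _ in range(ns):
            f.write(_edf_field("", 80))  # transducer
        for _ in range(ns):
            f.write(_edf_field("uV", 8))
        for v in phys_min:
            f.write(_edf_field(f"{v:.6g}", 8))
        for v in phys_max:
            f.write(_edf_field(f"{v:.6g}", 8))
        for _ in range(ns):
            f.write(_edf_field(dig_min, 8))
        for _ in range(ns):
            f.write(_edf_field(dig_max, 8))
        for _ in range(ns):
            f.write(_edf_field("", 80))  # prefiltering
        for _ in range(ns):
            f.write(_edf_field(n_samp, 8))
        for _ in range(ns):
            f.write(_edf_field("", 32))
        # re-read the text header's phys range so scaling matches what a reader sees
        pmin = np.array([float(f"{v:.6g}") for v in phys_min])
        pmax = np.array([float(f"{v:.6g}") for v in phys_max])
        scale = (dig_max - dig_min) / (pmax - pmin)
        for i in range(ns):
            dig = np.round((rec.samples[i] - pmin[i]) * scale[i]) + dig_min
            dig = np.clip(dig, dig_min, dig_max).astype("<i2")
            f.write(dig.tobytes())


def _scan_edf_header(path):
    """Light pass over the EDF text header: labels and samples-per-record."""
    with open(path, "rb") as f:
        head = f.read(256)
        if len(head) < 256:
            raise ValueError(f"malformed header in {path}: file too short")
        try:
            ns = int(head[252:256].decode("ascii").strip())
            n_records = int(head[236:244].decode("ascii").strip())
            rec_dur = float(head[244:252].decode("ascii").strip())
        except ValueError as e:
            raise ValueError(f"malformed header in {path}: {e}") from None
        sig = f.read(256 * ns)
        if len(sig) < 256 * ns:
            raise ValueError(f"malformed header in {path}: truncated signal header")
    labels = [sig[16 * i:16 * (i + 1)].decode("ascii", "replace").strip() for i in range(ns)]
    # signal header layout: label 16, transducer 80, dim 8, phys min/max 8+8,
    # dig min/max 8+8, prefilter 80 -> samples-per-record starts at 216*ns
    off = 216 * ns
    spr = [int(sig[off + 8 * i: off + 8 * (i + 1)].decode("ascii").strip())
           for i in range(ns)]
    return labels, spr, n_records, rec_dur


def read_edf(path, allow_resample: bool = False) -> Recording:
    """Read an EDF/EDF+ file into a Recording (amplitudes in µV).

    All signals must share one sampling rate unless ``allow_resample`` is set,
    in which case slower channels are resampled to the fastest rate by the
    reader backend.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    labels, spr, _, rec_dur = _scan_edf_header(path)
    if len(set(labels)) != len(labels):
        raise ValueError("channel_labels unique violated in EDF header")
    if len(set(spr)) > 1 and not allow_resample:
        raise ValueError(
            "mixed per-channel sampling rates; pass allow_resample=True to resample"
        )
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data(units="uV")
    return Recording(
        channel_labels=list(raw.ch_names),
        fs=float(raw.info["sfreq"]),
        samples=data,
    )


# ---------------------------------------------------------------------------
# Annotations sidecar
# ---------------------------------------------------------------------------

def read_annotations(path) -> list:
    """Read the sidecar JSON event list (keys: seizure_id, phase, start_s, end_s, contacts)."""
    with open(path) as f:
        raw = json.load(f)
    return [
        EventAnnotation(
            seizure_id=int(d["seizure_id"]),
            phase=Phase(d["phase"]),
            start_s=float(d["start_s"]),
            end_s=float(d["end_s"]),
            involved_contacts=frozenset(d.get("contacts", [])),
        )
        for d in raw
    ]


def write_annotations(annotations: Sequence[EventAnnotation], path) -> None:
    payload = [
        {
            "seizure_id": a.seizure_id,
            "phase": a.phase.value,
            "start_s": a.start_s,
            "end_s": a.end_s,
            "contacts": sorted(a.involved_contacts),
        }
        for a in annotations
    ]
    with open(path, "w") as f:
        json.dump(payload, f, indent=1)


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------

def segment_recording(rec: Recording, segment_duration_s: float,
                      segments_per_set: int | None = None,
                      source_id: str = "recording") -> list:
    """Cut a recording into consecutive non-overlapping fixed-duration segments.

    A trailing partial window is dropped.  Segments are grouped into sets of at
    most ``segments_per_set`` (all in one set when ``None``).
    """
    if not segment_duration_s > 0:
        raise ValueError("segment_duration_s must be positive")
    seg_len = int(round(segment_duration_s * rec.fs))
    n_segments = rec.n_samples // seg_len
    if n_segments == 0:
        warnings.warn("segment longer than recording; returning empty segment set")
        return [SegmentSet([], segment_duration_s, segments_per_set or 0)]
    segments = []
    for k in range(n_segments):
        sl = rec.samples[:, k * seg_len:(k + 1) * seg_len]
        segments.append((source_id, k * seg_len / rec.fs, segment_duration_s, sl))
    per = segments_per_set if segments_per_set else n_segments
    return [
        SegmentSet(segments[i:i + per], segment_duration_s, per)
        for i in range(0, n_segments, per)
    ]


def extract_event(rec: Recording, ann: EventAnnotation) -> Recording:
    """Slice a recording to an event window; channel set is unchanged."""
    i0 = int(round(ann.start_s * rec.fs))
    i1 = int(round(ann.end_s * rec.fs))
    if ann.start_s < 0 or i1 > rec.n_samples:
        raise ValueError(
            f"annotation [{ann.start_s}, {ann.end_s}] s outside recording "
            f"extent [0, {rec.duration_s}] s"
        )
    return Recording(
        channel_labels=list(rec.channel_labels),
        fs=rec.fs,
        samples=rec.samples[:, i0:i1].copy(),
        start_time=rec.start_time + ann.start_s,
    )
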