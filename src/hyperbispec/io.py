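"""Reading and writing recordings, session containers and annotations.

Supported recording dialects: EDF and BrainVision (.vhdr/.eeg/.vmrk),
both read through MNE after a light structural validation pass (readers
reject rather than guess: truncated data files and malformed headers
raise :class:`FormatError` instead of returning partial recordings).

A whole :class:`~hyperbispec.types.HyperscanSession` round-trips through
a single hierarchical HDF5 container losslessly.

Annotation tables are CSV with columns ``event_type, time, annotation``;
times may be ``mm:ss`` (as annotators write them) or plain seconds, and
are anchored to the start of their trial — :func:`to_session_clock`
converts them onto the session clock via the design table.
"""

from __future__ import annotations

import json
import logging
import os
import re

import h5py
import numpy as np
import pandas as pd

from .errors import FormatError, UnsupportedFormatError
from .types import (
    EEG,
    EOG,
    BaselineBlock,
    EventAnnotation,
    HyperscanSession,
    MultichannelRecording,
    SegmentDesign,
)

__all__ = ["read_recording", "write_session", "read_session",
           "read_annotations", "write_annotations", "to_session_clock",
           "mask_missing"]

logger = logging.getLogger(__name__)

CONTAINER_FORMAT = "hyperbispec.session"
CONTAINER_VERSION = 1


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------

def _validate_edf(path):
    """Structural check of an EDF file before handing it to MNE."""
    size = os.path.getsize(path)
    if size < 256:
        raise FormatError(f"{path}: EDF header truncated ({size} < 256 bytes)")
    with open(path, "rb") as f:
        hdr = f.read(256)
    try:
        header_bytes = int(hdr[184:192].decode("ascii").strip())
        n_records = int(hdr[236:244].decode("ascii").strip())
        n_signals = int(hdr[252:256].decode("ascii").strip())
    except (UnicodeDecodeError, ValueError) as e:
        raise FormatError(f"{path}: malformed EDF header fields "
                          f"(header-bytes/records/signals): {e}") from None
    if n_signals <= 0 or n_records < 0:
        raise FormatError(f"{path}: EDF header declares {n_signals} signals, "
                          f"{n_records} records")
    if size < header_bytes:
        raise FormatError(f"{path}: file shorter than declared header "
                          f"({size} < {header_bytes})")
    with open(path, "rb") as f:
        f.seek(256 + n_signals * 216)
        raw = f.read(n_signals * 8)
    try:
        samples = [int(raw[i * 8:(i + 1) * 8].decode("ascii").strip())
                   for i in range(n_signals)]
    except (UnicodeDecodeError, ValueError) as e:
        raise FormatError(f"{path}: malformed samples-per-record field: {e}") from None
    expected = header_bytes + n_records * sum(samples) * 2
    if size < expected:
        raise FormatError(f"{path}: EDF data truncated "
                          f"({size} bytes, expected {expected})")


_REF_RE = re.compile(r"Reference\s*Channel\s*Name\s*[=:]\s*(\S+)", re.I)


def _validate_brainvision(path):
    """Check the .vhdr triplet and extract reference metadata."""
    text = open(path, "r", encoding="utf-8", errors="replace").read()
    meta = {}
    m = _REF_RE.search(text)
    if m:
        meta["reference"] = m.group(1)
    fields = dict(re.findall(r"^\s*([A-Za-z]+)\s*=\s*(.+?)\s*$", text, re.M))
    for req in ("DataFile", "NumberOfChannels", "SamplingInterval"):
        if req not in fields:
            raise FormatError(f"{path}: missing required field {req}")
    data_file = os.path.join(os.path.dirname(path), fields["DataFile"])
    if not os.path.exists(data_file):
        raise FormatError(f"{path}: data file {fields['DataFile']} not found")
    nch = int(fields["NumberOfChannels"])
    fmt = fields.get("BinaryFormat", "IEEE_FLOAT_32").strip()
    itemsize = {"IEEE_FLOAT_32": 4, "INT_16": 2, "INT_32": 4}.get(fmt)
    if itemsize is None:
        raise FormatError(f"{path}: unsupported BinaryFormat {fmt}")
    size = os.path.getsize(data_file)
    if size % (nch * itemsize) != 0:
        raise FormatError(f"{data_file}: truncated data ({size} bytes is not "
                          f"a whole number of {nch}-channel frames)")
    return meta


def read_recording(path, dialect, participant_id=None, eog_labels=()):
    """Read one participant's recording.

    Parameters
    ----------
    dialect
        ``"edf"`` or ``"brainvision"``.
    eog_labels
        Channels to mark as EOG kind.  EOG identity is metadata, not a
        label convention: several 10-10 labels are physically repurposed
        as EOG sensors, so callers must say which.
    """
    import mne

    path = os.fspath(path)
    meta = {}
    if dialect == "edf":
        _validate_edf(path)
        try:
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        except Exception as e:
            raise FormatError(f"{path}: EDF parse failed: {e}") from None
    elif dialect == "brainvision":
        meta.update(_validate_brainvision(path))
        try:
            raw = mne.io.read_raw_brainvision(path, preload=True,
                                              verbose="error")
        except Exception as e:
            raise FormatError(f"{path}: BrainVision parse failed: {e}") from None
    else:
        raise UnsupportedFormatError(f"unknown dialect {dialect!r}")

    labels = list(raw.ch_names)
    eogset = set(eog_labels)
    kinds = [EOG if (lab in eogset or t == "eog") else EEG
             for lab, t in zip(labels, raw.get_channel_types())]
    data = raw.get_data() * 1e6  # volts -> microvolts
    pid = participant_id or os.path.splitext(os.path.basename(path))[0]
    return MultichannelRecording(pid, labels, kinds, float(raw.info["sfreq"]),
                                 data, meta=meta)


# ---------------------------------------------------------------------------
# session container (HDF5)
# ---------------------------------------------------------------------------

def write_session(session: HyperscanSession, path):
    """Serialize a session to one hierarchical HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["format"] = CONTAINER_FORMAT
        f.attrs["version"] = CONTAINER_VERSION
        f.attrs["meta"] = json.dumps(session.meta)
        f.attrs["design"] = json.dumps(
            [[d.trial, d.segment, sorted(d.active_set), list(d.interval)]
             for d in session.design])
        f.attrs["baselines"] = json.dumps(
            [[b.phase, b.kind, list(b.interval)] for b in session.baselines])
        f.attrs["annotations"] = json.dumps(
            [[a.event_type, a.time, a.label] for a in session.annotations])
        f.attrs["masked"] = json.dumps([list(m) for m in session.masked])
        grp = f.create_group("recordings")
        for i, rec in enumerate(session.recordings):
            g = grp.create_group(f"{i:03d}")
            g.attrs["participant_id"] = rec.participant_id
            g.attrs["fs"] = rec.fs
            g.attrs["start_time"] = rec.start_time
            g.attrs["meta"] = json.dumps(rec.meta)
            g.create_dataset("data", data=rec.data)
            g.create_dataset("labels",
                             data=np.array(rec.channel_labels, dtype="S"))
            g.create_dataset("kinds",
                             data=np.array(rec.channel_kinds, dtype="S"))


def read_session(path) -> HyperscanSession:
    """Read a session container written by :func:`write_session`."""
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != CONTAINER_FORMAT:
            raise FormatError(f"{path}: not a {CONTAINER_FORMAT} container")
        if int(f.attrs.get("version", -1)) != CONTAINER_VERSION:
            raise FormatError(
                f"{path}: container version {f.attrs.get('version')} "
                f"!= supported {CONTAINER_VERSION}")
        try:
            design = [SegmentDesign(t, s, frozenset(act), tuple(iv))
                      for t, s, act, iv in json.loads(f.attrs["design"])]
        except (KeyError, ValueError, TypeError) as e:
            raise FormatError(f"{path}: corrupted design table: {e}") from None
        baselines = [BaselineBlock(p, k, tuple(iv))
                     for p, k, iv in json.loads(f.attrs.get("baselines", "[]"))]
        if "annotations" in f.attrs:
            annotations = [EventAnnotation(t, tm, lab) for t, tm, lab
                           in json.loads(f.attrs["annotations"])]
        else:
            logger.warning("%s: no annotations block; assuming none", path)
            annotations = []
        masked = [tuple(m) for m in json.loads(f.attrs.get("masked", "[]"))]
        meta = json.loads(f.attrs.get("meta", "{}"))
        recordings = []
        for key in sorted(f["recordings"]):
            g = f["recordings"][key]
            recordings.append(MultichannelRecording(
                g.attrs["participant_id"],
                [s.decode() for s in g["labels"][()]],
                [s.decode() for s in g["kinds"][()]],
                float(g.attrs["fs"]), g["data"][()],
                float(g.attrs["start_time"]), json.loads(g.attrs["meta"])))
    return HyperscanSession(recordings, design, baselines, annotations,
                            masked, meta)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def _parse_time(value, row):
    s = str(value).strip()
    if re.fullmatch(r"\d+:\d{1,2}(\.\d+)?", s):
        mm, ss = s.split(":")
        return int(mm) * 60.0 + float(ss)
    try:
        return float(s)
    except ValueError:
        raise FormatError(f"row {row}: unparseable time {value!r}") from None


def read_annotations(path):
    """Read an SP/DP event table (columns event_type, time, annotation).

    ``event_type`` entries like ``SP_1`` are normalized to their SP/DP
    prefix; times (``mm:ss`` or seconds) are returned in seconds with
    input ordering preserved.
    """
    df = pd.read_csv(path)
    need = {"event_type", "time"}
    if not need <= set(df.columns):
        raise FormatError(f"{path}: annotation CSV needs columns {sorted(need)}")
    out = []
    for row, rec in enumerate(df.itertuples(index=False), start=1):
        etype = str(rec.event_type).strip().split("_")[0].upper()
        if etype not in ("SP", "DP"):
            raise FormatError(f"row {row}: unknown event type "
                              f"{rec.event_type!r}")
        t = _parse_time(rec.time, row)
        label = str(getattr(rec, "annotation", "") or "")
        out.append(EventAnnotation(etype, t, label))
    return out


def write_annotations(annotations, path):
    pd.DataFrame([{"event_type": a.event_type, "time": a.time,
                   "annotation": a.label} for a in annotations]
                 ).to_csv(path, index=False)


def to_session_clock(annotations, session: HyperscanSession, trial: int):
    """Shift trial-anchored annotation times onto the session clock."""
    starts = [d.interval[0] for d in session.design if d.trial == trial]
    if not starts:
        raise KeyError(f"trial {trial} not in session design")
    t0 = min(starts)
    return [EventAnnotation(a.event_type, a.time + t0, a.label)
            for a in annotations]


# ---------------------------------------------------------------------------
# masking
# ---------------------------------------------------------------------------

def mask_missing(session: HyperscanSession, interval) -> HyperscanSession:
    """Flag ``[start, end)`` as invalid.

    Downstream window extraction drops windows overlapping the span and
    peri-event extraction rejects events inside it.  An empty interval is
    a no-op.  Fully masking a segment makes later window extraction raise
    an explicit empty-segment error.
    """
    t0, t1 = interval
    if t1 <= t0:
        return session
    for d in session.design:
        if t0 <= d.interval[0] and d.interval[1] <= t1:
            logger.warning("mask [%s, %s) covers entire segment t%ds%d",
                           t0, t1, d.trial, d.segment)
    return HyperscanSession(session.recordings, session.design,
                            session.baselines, session.annotations,
                            list(session.masked) + [(float(t0), float(t1))],
                            dict(session.meta))
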