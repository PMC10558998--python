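"""Shared fixtures: tiny synthetic sessions and minimal on-disk EEG files.

The EDF and BrainVision writers below produce deliberately minimal but
standard-conforming files so reader tests need no binary fixtures in the
repository; everything is generated at test time.
"""

from __future__ import annotations

import numpy as np
import pytest

from hyperbispec.synthetic import SyntheticConfig, generate_session
from hyperbispec.types import EEG, MultichannelRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(data, fs=250.0, labels=None, kinds=None, pid="P1",
                   start_time=0.0, meta=None):
    data = np.asarray(data, float)
    n = data.shape[0]
    labels = labels or [f"ch{i}" for i in range(n)]
    kinds = kinds or [EEG] * n
    return MultichannelRecording(pid, labels, kinds, fs, data, start_time,
                                 meta or {})


@pytest.fixture
def small_coupled_session():
    """Two participants, 16 channels, one 60 s active-active segment with
    gamma-band coupling at rho = 0.8."""
    cfg = SyntheticConfig(
        n_participants=2, n_eeg_channels=16, fs=250.0,
        trial_layout=[(1, 1, {"P1", "P2"}, 60.0)],
        coupling_strength=0.8, blink_rate=0.0, seed=7)
    return generate_session(cfg)


@pytest.fixture
def null_session():
    """Same layout, no coupling anywhere."""
    cfg = SyntheticConfig(
        n_participants=2, n_eeg_channels=16, fs=250.0,
        trial_layout=[(1, 1, {"P1", "P2"}, 60.0)],
        coupling_strength=0.0, blink_rate=0.0, seed=11)
    return generate_session(cfg)


# ---------------------------------------------------------------------------
# minimal standard-format writers (test-only)
# ---------------------------------------------------------------------------

def write_edf(path, data, fs, labels):
    """Write a minimal EDF file (one data record per second, int16)."""
    data = np.asarray(data, float)
    n_ch, n_samp = data.shape
    n_records = int(n_samp / fs)
    spr = int(fs)
    phys_min, phys_max = -250.0, 250.0
    dig_min, dig_max = -32768, 32767

    def pad(s, n):
        return str(s)[:n].ljust(n).encode("ascii")

    hdr = b"".join([
        pad("0", 8), pad("X", 80), pad("X", 80), pad("01.01.24", 8),
        pad("00.00.00", 8), pad(256 * (n_ch + 1), 8), pad("", 44),
        pad(n_records, 8), pad("1", 8), pad(n_ch, 4),
    ])
    sig = b"".join(pad(lab, 16) for lab in labels)
    sig += b"".join(pad("", 80) for _ in labels)
    sig += b"".join(pad("uV", 8) for _ in labels)
    sig += b"".join(pad(phys_min, 8) for _ in labels)
    sig += b"".join(pad(phys_max, 8) for _ in labels)
    sig += b"".join(pad(dig_min, 8) for _ in labels)
    sig += b"".join(pad(dig_max, 8) for _ in labels)
    sig += b"".join(pad("", 80) for _ in labels)
    sig += b"".join(pad(spr, 8) for _ in labels)
    sig += b"".join(pad("", 32) for _ in labels)

    gain = (dig_max - dig_min) / (phys_max - phys_min)
    body = b""
    for r in range(n_records):
        for ch in range(n_ch):
            chunk = data[ch, r * spr:(r + 1) * spr]
            dig = np.clip((chunk - phys_min) * gain + dig_min,
                          dig_min, dig_max).astype("<i2")
            body += dig.tobytes()
    with open(path, "wb") as f:
        f.write(hdr + sig + body)
    return path


def write_brainvision(basepath, data, fs, labels, reference="FCz"):
    """Write a minimal BrainVision .vhdr/.eeg/.vmrk triplet (float32)."""
    data = np.asarray(data, np.float32)
    stem = basepath.name if hasattr(basepath, "name") else basepath
    vhdr = basepath.with_suffix(".vhdr")
    eeg = basepath.with_suffix(".eeg")
    vmrk = basepath.with_suffix(".vmrk")
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "[Common Infos]",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={data.shape[0]}",
        f"SamplingInterval={1e6 / fs:.0f}",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "[Channel Infos]",
    ]
    lines += [f"Ch{i + 1}={lab},,1" for i, lab in enumerate(labels)]
    lines += ["[Comment]", f"Reference Channel Name = {reference}"]
    vhdr.write_text("\n".join(lines) + "\n")
    vmrk.write_text("\n".join([
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "[Common Infos]",
        f"DataFile={eeg.name}",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,20240101000000000000",
    ]) + "\n")
    with open(eeg, "wb") as f:
        f.write(np.asarray(data.T, np.float32).tobytes())
    return vhdr
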