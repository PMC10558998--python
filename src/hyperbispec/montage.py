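"""Electrode montages and channel-role bookkeeping.

The default montage is a 64-electrode 10-10 cap referenced online to FCz
(FCz itself is therefore not a data channel).  Four of the 64 recorded
channels are physically repurposed as electro-oculogram (EOG) sensors:
TP9/TP10 sit on the temples (horizontal eye movement) and PO9/PO10 above
and below one eye (vertical eye movement / blinks).  Because of that
repurposing, EOG channels must always be identified through explicit
role metadata, never by montage label.

Removing the four EOG-role channels leaves the 60 scalp channels that all
channel-combination scans run over.
"""

from __future__ import annotations

from .errors import MissingChannelError

# 64 recorded channels (10-10 labels, FCz excluded as the online reference).
DEFAULT_64 = (
    "Fp1", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP9", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "TP10",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO9", "PO7", "PO3", "POz", "PO4", "PO8", "PO10",
    "O1", "Oz", "O2", "Iz",
)

#: Channels repurposed as EOG sensors and their roles.
DEFAULT_EOG_ROLES = {"TP9": "heog", "TP10": "heog", "PO9": "veog", "PO10": "veog"}

#: Default analysis exclusion list: the online reference (not recorded here,
#: kept for montage variants that do record it) plus the EOG-role channels.
DEFAULT_EXCLUDE = ("FCz", "TP9", "TP10", "PO9", "PO10")

#: Compact 16-channel profile for desk-scale runs; spans frontal through
#: occipital sites so spatial (ROI) analyses stay meaningful.
SMALL_16 = (
    "Fp1", "Fp2", "F3", "Fz", "F4", "T7", "C3", "Cz", "C4", "T8",
    "P7", "Pz", "P8", "O1", "Oz", "O2",
)

# Approximate anterior->posterior position per label prefix, used for the
# frontally weighted blink mixing vector (1 = most frontal).
_FRONTAL_WEIGHT = {
    "Fp": 1.0, "AF": 0.8, "FT": 0.35, "FC": 0.45, "F": 0.6,
    "TP": 0.1, "CP": 0.12, "C": 0.25, "T": 0.15,
    "PO": 0.04, "P": 0.08, "O": 0.02, "I": 0.02,
}


def scalp_channels(labels, exclude=DEFAULT_EXCLUDE):
    """Return analysis (scalp EEG) channels: ``labels`` minus ``exclude``."""
    excl = set(exclude)
    return tuple(lab for lab in labels if lab not in excl)


def _prefix(label: str) -> str:
    p = ""
    for ch in label:
        if ch.isalpha():
            p += ch
        else:
            break
    # longest matching prefix key ("FC" before "F", etc.)
    for k in sorted(_FRONTAL_WEIGHT, key=len, reverse=True):
        if p.startswith(k):
            return k
    raise MissingChannelError(label)


def frontal_weight(label: str) -> float:
    """Blink-propagation weight for an EEG label (frontal sites highest)."""
    return _FRONTAL_WEIGHT[_prefix(label)]
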