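"""Region-of-interest aggregation of significant channel combinations.

Electrodes are grouped into 13 scalp regions: anterior frontal (AF),
left/midline/right fronto-central (LFC, MFC, RFC), left/midline/right
centro-parietal (LCP, MCP, RCP), left/middle/right parieto-occipital
(LPO, MPO, RPO), left and right temporal (LT, RT) and occipital (O).

The shipped default membership table partitions the 60 analyzed 10-10
labels into those regions by geometric sector (anterior-posterior row and
laterality of each label); it is user-overridable via a two-column CSV
(label, region).

Significant channel combinations are pooled across dyads and trials per
performance condition, and because the scalp maps draw undirected links,
(r1, r2) and (r2, r1) increment the same cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MissingChannelError
from .types import HyperscanSession

__all__ = ["REGIONS", "ROIMap", "default_roi_map", "load_roi_map",
           "save_roi_map", "assign_roi", "aggregate", "ROISyncMap"]

REGIONS = ("AF", "LFC", "MFC", "RFC", "LCP", "MCP", "RCP",
           "LPO", "MPO", "RPO", "LT", "RT", "O")

_DEFAULT_MEMBERSHIP = {
    # anterior frontal
    "Fp1": "AF", "Fp2": "AF", "AF7": "AF", "AF3": "AF", "AFz": "AF",
    "AF4": "AF", "AF8": "AF",
    # fronto-central rows
    "F7": "LFC", "F5": "LFC", "F3": "LFC", "FC5": "LFC", "FC3": "LFC",
    "F1": "MFC", "Fz": "MFC", "F2": "MFC", "FC1": "MFC", "FC2": "MFC",
    "F4": "RFC", "F6": "RFC", "F8": "RFC", "FC4": "RFC", "FC6": "RFC",
    # temporal chains
    "FT7": "LT", "T7": "LT", "TP7": "LT",
    "FT8": "RT", "T8": "RT", "TP8": "RT",
    # centro-parietal rows
    "C5": "LCP", "C3": "LCP", "CP5": "LCP", "CP3": "LCP",
    "C1": "MCP", "Cz": "MCP", "C2": "MCP", "CP1": "MCP", "CPz": "MCP",
    "CP2": "MCP",
    "C4": "RCP", "C6": "RCP", "CP4": "RCP", "CP6": "RCP",
    # parieto-occipital rows
    "P7": "LPO", "P5": "LPO", "P3": "LPO", "PO7": "LPO", "PO3": "LPO",
    "P1": "MPO", "Pz": "MPO", "P2": "MPO", "POz": "MPO",
    "P4": "RPO", "P6": "RPO", "P8": "RPO", "PO4": "RPO", "PO8": "RPO",
    # occipital
    "O1": "O", "Oz": "O", "O2": "O", "Iz": "O",
}


@dataclass(frozen=True)
class ROIMap:
    """Electrode label -> region membership over the 13 named regions."""

    membership: dict
    regions: tuple = REGIONS

    def __post_init__(self):
        bad = set(self.membership.values()) - set(self.regions)
        if bad:
            raise ValueError(f"unknown regions in membership: {sorted(bad)}")

    def region_index(self, region: str) -> int:
        return self.regions.index(region)


def default_roi_map() -> ROIMap:
    """The shipped 60-electrode geometric-sector partition."""
    return ROIMap(dict(_DEFAULT_MEMBERSHIP))


def load_roi_map(path) -> ROIMap:
    """Read an editable membership CSV with columns ``label, region``."""
    df = pd.read_csv(path)
    if not {"label", "region"} <= set(df.columns):
        raise ValueError("ROI CSV needs columns 'label' and 'region'")
    return ROIMap(dict(zip(df["label"].astype(str), df["region"].astype(str))))


def save_roi_map(roi_map: ROIMap, path):
    pd.DataFrame(sorted(roi_map.membership.items()),
                 columns=["label", "region"]).to_csv(path, index=False)


def assign_roi(channel_label: str, roi_map: ROIMap) -> str:
    """Region of one electrode label; unknown labels raise."""
    try:
        return roi_map.membership[channel_label]
    except KeyError:
        raise MissingChannelError(channel_label) from None


@dataclass
class ROISyncMap:
    """Condition-wise ROI-to-ROI synchronization counts.

    ``counts`` is a symmetric 13 x 13 matrix; the diagonal holds
    within-region counts.  ``shading`` normalizes by the maximum cell.
    """

    condition: str | None
    band: str | None
    regions: tuple
    counts: np.ndarray

    @property
    def total(self) -> int:
        """Number of aggregated significant combinations (off-diagonal
        cells count once despite the symmetric storage)."""
        return int(np.triu(self.counts).sum())

    @property
    def within(self) -> np.ndarray:
        return np.diag(self.counts)

    @property
    def shading(self) -> np.ndarray:
        m = self.counts.max()
        return self.counts / m if m > 0 else self.counts.astype(float)

    def cell(self, r1: str, r2: str) -> int:
        i = self.regions.index(r1)
        j = self.regions.index(r2)
        return int(self.counts[i, j])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (region_a, region_b, count, shading)."""
        rows = []
        sh = self.shading
        for i, r1 in enumerate(self.regions):
            for j in range(i, len(self.regions)):
                rows.append({"region_a": r1, "region_b": self.regions[j],
                             "count": int(self.counts[i, j]),
                             "shading": float(sh[i, j])})
        return pd.DataFrame(rows)


def aggregate(results, roi_map: ROIMap, condition=None, band=None,
              session: HyperscanSession | None = None) -> ROISyncMap:
    """Pool significant channel combinations into an ROI-to-ROI map.

    ``results`` are :class:`~hyperbispec.stats.SignificanceResult`
    records; non-significant entries are ignored.  When ``condition`` is
    given, ``session`` is required to derive each result's dyad condition
    from the segment design.  Pooling is symmetric: a T7 -> Oz combination
    increments the LT-O cell regardless of direction.
    """
    n = len(roi_map.regions)
    counts = np.zeros((n, n), int)
    seg_by_key = None
    if condition is not None:
        if session is None:
            raise ValueError("session required for condition filtering")
        seg_by_key = {(d.trial, d.segment): d for d in session.design}
    for r in results:
        if not r.significant:
            continue
        if band is not None and r.band != band:
            continue
        if condition is not None:
            seg = seg_by_key[(r.trial, r.segment)]
            if seg.condition(r.dyad) != condition:
                continue
        i = roi_map.region_index(assign_roi(r.channel_pair[0], roi_map))
        j = roi_map.region_index(assign_roi(r.channel_pair[1], roi_map))
        counts[i, j] += 1
        if i != j:
            counts[j, i] += 1
    return ROISyncMap(condition, band, roi_map.regions, counts)
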