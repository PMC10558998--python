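"""Mass discovery of synchronized channel combinations.

For every ordered channel combination (one channel of participant *a*,
one of participant *b*) the per-bin band values of the segment
representation are compared against the paired per-bin values of the
pre-trial eyes-open rest representation with a right-tailed Wilcoxon
signed-rank test (alternative: segment > rest).  The paired samples are
the native 0.25 Hz bins inside the band, so n = 16 for delta and theta,
20 for alpha, 68 for beta and 82 for gamma.

Bonferroni control is applied within one family = the full channel
combination scan of a single (trial, segment, dyad, band): with the
default 60-channel montage that is 60^2 = 3600 tests at alpha_corrected =
0.05 / 3600.  Sweeping all 3 trials x 3 segments x 3 dyads x 5 bands
yields 27 x 5 families and 486,000 tests in total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .bispectrum import BANDS, band_bins, pairwise_representations
from .errors import AlignmentError
from .types import HyperscanSession

__all__ = [
    "SignificanceResult", "ScanPlan", "wilcoxon_right", "scan_plan",
    "scan_combinations", "scan_all", "summarize", "top_k", "results_to_frame",
]

ALPHA = 0.05


@dataclass(frozen=True)
class SignificanceResult:
    """Outcome of one channel-combination test."""

    dyad: tuple
    channel_pair: tuple
    trial: int
    segment: int
    band: str
    p_value: float
    n_samples: int
    alpha_corrected: float
    significant: bool
    median_diff: float = float("nan")
    degenerate: bool = False


@dataclass(frozen=True)
class ScanPlan:
    """Bookkeeping of the full scan: family structure and test counts."""

    n_channels: int
    n_trials: int
    n_segments: int
    n_dyads: int
    n_bands: int

    @property
    def tests_per_family(self) -> int:
        return self.n_channels ** 2

    @property
    def n_families(self) -> int:
        return self.n_trials * self.n_segments * self.n_dyads * self.n_bands

    @property
    def total_tests(self) -> int:
        return self.tests_per_family * self.n_families


def scan_plan(n_channels=60, n_trials=3, n_segments=3, n_dyads=3,
              bands=tuple(BANDS)) -> ScanPlan:
    """Construct the scan bookkeeping for a montage/design."""
    return ScanPlan(n_channels, n_trials, n_segments, n_dyads, len(bands))


def wilcoxon_right(seg_values, rest_values):
    """Right-tailed Wilcoxon signed-rank p for "segment > rest".

    Zero differences are dropped (standard convention); if every
    difference is zero the test is degenerate and ``(1.0, True)`` is
    returned, else ``(p, False)``.
    """
    seg = np.asarray(seg_values, float)
    rest = np.asarray(rest_values, float)
    if seg.shape != rest.shape:
        raise AlignmentError("paired vectors have different lengths")
    if seg.size < 5:
        raise ValueError("need at least 5 paired samples")
    d = seg - rest
    if np.all(d == 0):
        return 1.0, True
    res = sps.wilcoxon(seg, rest, alternative="greater", zero_method="wilcox")
    return float(res.pvalue), False


def scan_combinations(session: HyperscanSession, trial, segment, dyad,
                      band, channels=None, alpha=ALPHA,
                      _cache=None) -> list:
    """Test every ordered channel combination of one (trial, segment,
    dyad, band) family against the pre-trial EO rest.

    ``channels`` defaults to the scalp (EEG-kind) channels shared by both
    participants; ``alpha_corrected = alpha / len(channels)**2``.
    """
    band = BANDS[band] if isinstance(band, str) else band
    rec_a = session.recording(dyad[0])
    if channels is None:
        channels = rec_a.eeg_labels
    channels = list(channels)
    n_comb = len(channels) ** 2
    alpha_c = alpha / n_comb

    key_seg = (tuple(dyad), trial, segment)
    key_eo = (tuple(dyad), "pre-EO")
    if _cache is None:
        _cache = {}
    if key_seg not in _cache:
        seg_iv = session.segment(trial, segment).interval
        _cache[key_seg] = pairwise_representations(
            session, dyad, channels, channels, seg_iv, f"t{trial}s{segment}")
    if key_eo not in _cache:
        eo_iv = session.baseline("pre", "EO").interval
        _cache[key_eo] = pairwise_representations(
            session, dyad, channels, channels, eo_iv, "pre-EO")
    freqs, seg_vals, _ = _cache[key_seg]
    _, eo_vals, _ = _cache[key_eo]
    return tests_from_arrays(freqs, seg_vals, eo_vals, channels, dyad,
                             trial, segment, band, alpha_c)


def tests_from_arrays(freqs, seg_vals, eo_vals, channels, dyad, trial,
                      segment, band, alpha_corrected) -> list:
    """Wilcoxon tests for one family from precomputed pairwise arrays
    (shape ``(n_a, n_b, n_bins)``)."""
    band = BANDS[band] if isinstance(band, str) else band
    bmask = band_bins(freqs, band)
    n = int(bmask.sum())
    results = []
    for i, ch_a in enumerate(channels):
        for j, ch_b in enumerate(channels):
            s = seg_vals[i, j, bmask]
            r = eo_vals[i, j, bmask]
            p, degen = wilcoxon_right(s, r)
            results.append(SignificanceResult(
                dyad=tuple(dyad), channel_pair=(ch_a, ch_b), trial=trial,
                segment=segment, band=band.name, p_value=p, n_samples=n,
                alpha_corrected=alpha_corrected, significant=bool(p < alpha_corrected),
                median_diff=float(np.median(s - r)), degenerate=degen))
    return results


def scan_all(session: HyperscanSession, bands=tuple(BANDS), channels=None,
             dyads=None, alpha=ALPHA) -> list:
    """Sweep all trials, segments, dyads and bands; returns a flat list."""
    if dyads is None:
        dyads = session.dyads()
    results = []
    for dyad in dyads:
        cache = {}
        trialsegs = sorted({(d.trial, d.segment) for d in session.design})
        for trial, segment in trialsegs:
            for band in bands:
                results.extend(scan_combinations(
                    session, trial, segment, dyad, band,
                    channels=channels, alpha=alpha, _cache=cache))
    return results


def results_to_frame(results) -> pd.DataFrame:
    """Tidy results table (dyad, chan_a, chan_b, trial, segment, band, n,
    p, significant)."""
    return pd.DataFrame([{
        "dyad": "-".join(r.dyad), "chan_a": r.channel_pair[0],
        "chan_b": r.channel_pair[1], "trial": r.trial, "segment": r.segment,
        "band": r.band, "n": r.n_samples, "p": r.p_value,
        "alpha_corrected": r.alpha_corrected, "significant": r.significant,
        "median_diff": r.median_diff,
    } for r in results])


def summarize(results, group_by, session: HyperscanSession | None = None
              ) -> pd.DataFrame:
    """Count significant combinations per group.

    ``group_by`` entries may be any of ``band``, ``dyad``, ``trial``,
    ``segment``, ``n_active`` (number of active musicians in the segment;
    requires ``session``) or ``condition`` (dyad condition; requires
    ``session``).
    """
    if not results:
        raise ValueError("results must be non-empty")
    allowed = {"band", "dyad", "trial", "segment", "n_active", "condition"}
    bad = set(group_by) - allowed
    if bad:
        raise ValueError(f"unknown grouping keys: {sorted(bad)}")
    df = results_to_frame(results)
    if "n_active" in group_by or "condition" in group_by:
        if session is None:
            raise ValueError("session required to derive activity grouping")
        seg_by_key = {(d.trial, d.segment): d for d in session.design}
        df["n_active"] = [len(seg_by_key[(r.trial, r.segment)].active_set)
                          for r in results]
        df["condition"] = [seg_by_key[(r.trial, r.segment)].condition(r.dyad)
                           for r in results]
    out = (df.groupby(list(group_by), sort=True)["significant"].sum()
           .rename("n_significant").reset_index())
    return out


def top_k(results, k: int) -> list:
    """The k most significant results (significant only), p ascending.

    Ties broken by larger median paired difference, then lexicographic
    channel labels, so ranking is deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sig = [r for r in results if r.significant]
    sig.sort(key=lambda r: (r.p_value, -r.median_diff,
                            r.channel_pair[0], r.channel_pair[1]))
    return sig[:k]
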