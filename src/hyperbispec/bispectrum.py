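"""Windowed diagonal cross-bispectrum estimation and rest normalization.

The inter-brain synchrony feature is the diagonal cross-bispectrum between
one channel of participant *a* and one channel of participant *b*::

    B(f | t, s, P_ab) = (1/L) * sum_l  X_al(f) * X_bl(f) * conj(X_bl(2 f))

where ``X_.l`` is the DFT of the *l*-th four-second window (rectangular
taper, windows advanced in 1 s steps, i.e. 75 % overlap) and ``L`` the
number of windows in the interval.  The magnitude of the complex average
is reported.  The estimator detects quadratic phase coupling between the
two signals at the bifrequency (f, f): phase-locked components add
coherently over windows (the phase closure f + f - 2 f = 0 cancels any
common time shift), while independent — in particular Gaussian — activity
averages out at a 1/sqrt(L) rate.

Factor convention: one factor from the "sender" channel of participant
*a* at f, and both the f factor and the conjugated 2 f closure from the
"receiver" channel of participant *b*.  The convention is asymmetric, so
ordered dyads (a, b) and (b, a) are distinct and both are scanned.

Each segment's representation is normalized to the pre-trial eyes-open
(EO) rest block of the same channel combination::

    BS_N = (BS_seg - BS_EO) / BS_EO

a dimensionless relative change (0.3 = 30 % above rest).

Frequency axes: the native diagonal grid is 0.25 Hz (4 s windows),
1.00-50.00 Hz inclusive = 197 bins.  Band averages are taken over the
native grid: delta [1, 5), theta [4, 8), alpha [8, 13), beta [13, 30),
gamma [29.75, 50.25) -> 16/16/20/68/82 bins.  A coarse 50-bin 1-Hz
summary grid (bin c = native bins in [c - 0.5, c + 0.5)) is available for
display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from numpy.fft import rfft, rfftfreq

from .errors import AlignmentError, EmptyWindowError
from .types import HyperscanSession, MultichannelRecording

__all__ = [
    "BANDS", "BandDefinition", "SpectralWindowSet", "BispectralRepresentation",
    "NormalizedBispectrum", "TemporalBispectrumTrace",
    "extract_windows", "window_starts", "diagonal_cross_bispectrum",
    "segment_representation", "baseline_representation", "normalize",
    "band_average", "band_bins", "summary_grid", "temporal_series",
    "diagonal_bins", "pairwise_representations",
]

WINDOW_LENGTH = 4.0   # s
WINDOW_STEP = 1.0     # s
DIAG_LOW = 1.0        # Hz, first diagonal bin
DIAG_HIGH = 50.0      # Hz, last diagonal bin


@dataclass(frozen=True)
class BandDefinition:
    """Half-open frequency band [low, high) sampled on the native grid."""

    name: str
    low: float
    high: float


#: Canonical EEG bands.  Printed ranges are delta 1-4, theta 4-7, alpha
#: 8-12, beta 13-29 and gamma 30-50 Hz; the half-open sampling intervals
#: below are the unique readings that yield 16/16/20/68/82 native bins
#: (note the one-bin delta/theta and beta/gamma overlaps this implies).
BANDS = {
    "delta": BandDefinition("delta", 1.0, 5.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 13.0),
    "beta": BandDefinition("beta", 13.0, 30.0),
    "gamma": BandDefinition("gamma", 29.75, 50.25),
}


@dataclass
class SpectralWindowSet:
    """DFTs of sliding windows of one channel.

    ``spectra`` has shape ``(L, n_freq)``; ``starts`` are absolute window
    start times (s, session clock); ``freqs`` the rfft frequency axis.
    """

    participant_id: str
    channel: str
    starts: np.ndarray
    spectra: np.ndarray
    freqs: np.ndarray
    fs: float
    window_length: float = WINDOW_LENGTH
    step: float = WINDOW_STEP

    @property
    def L(self) -> int:
        return self.spectra.shape[0]

    def aligned_with(self, other: "SpectralWindowSet") -> bool:
        return (self.L == other.L and self.fs == other.fs
                and np.allclose(self.starts, other.starts)
                and len(self.freqs) == len(other.freqs))


@dataclass
class BispectralRepresentation:
    """Diagonal cross-bispectrum magnitudes for one dyad/channel pair/interval."""

    dyad: tuple
    channel_pair: tuple
    interval_id: str            # e.g. "t1s2" or "pre-EO"
    freqs: np.ndarray           # diagonal bifrequencies f (= f_i = f_j), Hz
    values: np.ndarray          # |B(f)| >= 0
    L: int


@dataclass
class NormalizedBispectrum:
    """Relative change of a segment representation vs the EO rest block."""

    dyad: tuple
    channel_pair: tuple
    interval_id: str
    baseline_id: str
    freqs: np.ndarray
    values: np.ndarray          # BS_N, NaN where invalid
    valid: np.ndarray           # False where the baseline was below the floor


@dataclass
class TemporalBispectrumTrace:
    """Band-averaged normalized bispectrum per sliding window."""

    dyad: tuple
    channel_pair: tuple
    band: str
    times: np.ndarray           # window centers, s (session clock)
    values: np.ndarray
    gaps: list = field(default_factory=list)  # masked window starts


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def window_starts(interval, window_length=WINDOW_LENGTH, step=WINDOW_STEP,
                  masked=()):
    """Start times of sliding windows inside half-open ``interval``,
    excluding windows that overlap any masked span."""
    t0, t1 = interval
    n = int(np.floor((t1 - t0 - window_length) / step + 1e-9)) + 1
    if n < 1:
        return np.empty(0), np.empty(0)
    starts = t0 + step * np.arange(n)
    keep = np.ones(n, bool)
    for m0, m1 in masked:
        if m1 <= m0:
            continue
        keep &= (starts + window_length <= m0) | (starts >= m1)
    return starts[keep], starts[~keep]


def extract_windows(recording: MultichannelRecording, channel: str,
                    window_length=WINDOW_LENGTH, step=WINDOW_STEP,
                    interval=None, masked=()):
    """Rectangular-taper DFTs of sliding windows of one channel.

    Raises :class:`EmptyWindowError` if the interval is shorter than one
    window or fully masked.
    """
    if interval is None:
        interval = (recording.start_time, recording.start_time + recording.duration)
    if interval[1] - interval[0] < window_length - 1e-9:
        raise EmptyWindowError(
            f"interval of {interval[1] - interval[0]:.3f} s is shorter than "
            f"one {window_length} s window")
    starts, dropped = window_starts(interval, window_length, step, masked)
    if starts.size == 0:
        raise EmptyWindowError("all windows masked in interval")
    fs = recording.fs
    nwin = int(round(window_length * fs))
    x = recording.get_channel(channel)
    idx0 = np.round((starts - recording.start_time) * fs).astype(int)
    segs = np.stack([x[i:i + nwin] for i in idx0])
    spectra = rfft(segs, axis=1)
    return SpectralWindowSet(recording.participant_id, channel, starts,
                             spectra, rfftfreq(nwin, 1.0 / fs), fs,
                             window_length, step)


# ---------------------------------------------------------------------------
# bispectrum
# ---------------------------------------------------------------------------

def diagonal_bins(freqs, low=DIAG_LOW, high=DIAG_HIGH, fs=None):
    """Indices (i_f, i_2f) of diagonal bins with ``low <= f <= high``.

    Bins whose doubled frequency exceeds the spectral axis are excluded
    with a warning.  Returns ``(diag_freqs, idx_f, idx_2f)``.
    """
    freqs = np.asarray(freqs)
    df = freqs[1] - freqs[0]
    sel = (freqs >= low - 1e-9) & (freqs <= high + 1e-9)
    fvals = freqs[sel]
    idx_f = np.nonzero(sel)[0]
    idx_2f = np.round(2 * fvals / df).astype(int)
    ok = idx_2f < len(freqs)
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} diagonal bins excluded: 2f above Nyquist")
    return fvals[ok], idx_f[ok], idx_2f[ok]


def diagonal_cross_bispectrum(windows_a: SpectralWindowSet,
                              windows_b: SpectralWindowSet,
                              low=DIAG_LOW, high=DIAG_HIGH,
                              interval_id="") -> BispectralRepresentation:
    """Magnitude of the window-averaged diagonal cross-bispectrum.

    ``value(f) = | (1/L) sum_l X_al(f) X_bl(f) conj(X_bl(2f)) |``.
    """
    if not windows_a.aligned_with(windows_b):
        raise AlignmentError("window sets are not time-aligned")
    fvals, i_f, i_2f = diagonal_bins(windows_a.freqs, low, high)
    triple = (windows_a.spectra[:, i_f] * windows_b.spectra[:, i_f]
              * np.conj(windows_b.spectra[:, i_2f]))
    values = np.abs(triple.mean(axis=0))
    return BispectralRepresentation(
        dyad=(windows_a.participant_id, windows_b.participant_id),
        channel_pair=(windows_a.channel, windows_b.channel),
        interval_id=interval_id, freqs=fvals, values=values,
        L=windows_a.L)


def segment_representation(session: HyperscanSession, dyad, channel_pair,
                           trial, segment,
                           window_length=WINDOW_LENGTH, step=WINDOW_STEP):
    """Per-bin bispectrum averaged over all windows of one (trial, segment)."""
    seg = session.segment(trial, segment)
    wa = extract_windows(session.recording(dyad[0]), channel_pair[0],
                         window_length, step, seg.interval, session.masked)
    wb = extract_windows(session.recording(dyad[1]), channel_pair[1],
                         window_length, step, seg.interval, session.masked)
    return diagonal_cross_bispectrum(wa, wb, interval_id=f"t{trial}s{segment}")


def baseline_representation(session: HyperscanSession, dyad, channel_pair,
                            phase="pre", kind="EO",
                            window_length=WINDOW_LENGTH, step=WINDOW_STEP):
    """Bispectral representation of a resting baseline block."""
    blk = session.baseline(phase, kind)
    wa = extract_windows(session.recording(dyad[0]), channel_pair[0],
                         window_length, step, blk.interval, session.masked)
    wb = extract_windows(session.recording(dyad[1]), channel_pair[1],
                         window_length, step, blk.interval, session.masked)
    return diagonal_cross_bispectrum(wa, wb, interval_id=f"{phase}-{kind}")


def normalize(bs_seg: BispectralRepresentation,
              bs_eo: BispectralRepresentation,
              eps_factor=1e-12) -> NormalizedBispectrum:
    """Relative change of a segment vs the EO rest representation.

    Bins whose baseline magnitude falls below ``eps_factor`` times the
    median baseline magnitude are flagged invalid (NaN) instead of being
    divided.
    """
    if (len(bs_seg.freqs) != len(bs_eo.freqs)
            or not np.allclose(bs_seg.freqs, bs_eo.freqs)):
        raise AlignmentError("segment and baseline frequency axes differ")
    if bs_seg.channel_pair != bs_eo.channel_pair or bs_seg.dyad != bs_eo.dyad:
        raise AlignmentError("segment and baseline channel combinations differ")
    floor = eps_factor * np.median(bs_eo.values)
    valid = bs_eo.values > floor
    values = np.full_like(bs_seg.values, np.nan)
    values[valid] = (bs_seg.values[valid] - bs_eo.values[valid]) / bs_eo.values[valid]
    return NormalizedBispectrum(bs_seg.dyad, bs_seg.channel_pair,
                                bs_seg.interval_id, bs_eo.interval_id,
                                bs_seg.freqs.copy(), values, valid)


# ---------------------------------------------------------------------------
# band summaries
# ---------------------------------------------------------------------------

def band_bins(freqs, band) -> np.ndarray:
    """Boolean mask of native bins inside a band's half-open interval."""
    if isinstance(band, str):
        band = BANDS[band]
    freqs = np.asarray(freqs)
    return (freqs >= band.low - 1e-9) & (freqs < band.high - 1e-9)


def band_average(norm: NormalizedBispectrum, band) -> float:
    """Mean BS_N over the valid native bins of one band (NaN if none)."""
    mask = band_bins(norm.freqs, band) & norm.valid
    if not mask.any():
        return float("nan")
    return float(np.mean(norm.values[mask]))


def summary_grid(freqs, values, low=1, high=50):
    """Average native bins onto the coarse 1-Hz display grid.

    Bin ``c`` (c = 1..50) collects native bins in ``[c - 0.5, c + 0.5)``.
    Returns ``(centers, coarse_values)`` with 50 bins.
    """
    freqs = np.asarray(freqs)
    centers = np.arange(low, high + 1, dtype=float)
    out = np.full(centers.shape, np.nan)
    for k, c in enumerate(centers):
        m = (freqs >= c - 0.5) & (freqs < c + 0.5)
        if m.any():
            out[k] = np.nanmean(values[m])
    return centers, out


# ---------------------------------------------------------------------------
# temporal series
# ---------------------------------------------------------------------------

def temporal_series(session: HyperscanSession, dyad, channel_pair, band,
                    interval=None,
                    window_length=WINDOW_LENGTH, step=WINDOW_STEP
                    ) -> TemporalBispectrumTrace:
    """Sliding-window (L = 1) normalized band bispectrum over time.

    Each window's single-window representation is normalized to the
    pre-trial EO baseline representation and band averaged; masked windows
    are dropped and recorded as gaps.
    """
    bs_eo = baseline_representation(session, dyad, channel_pair,
                                    window_length=window_length, step=step)
    if interval is None:
        lo = min(d.interval[0] for d in session.design)
        hi = max(d.interval[1] for d in session.design)
        interval = (lo, hi)
    wa = extract_windows(session.recording(dyad[0]), channel_pair[0],
                         window_length, step, interval, session.masked)
    wb = extract_windows(session.recording(dyad[1]), channel_pair[1],
                         window_length, step, interval, session.masked)
    _, gaps = window_starts(interval, window_length, step, session.masked)
    fvals, i_f, i_2f = diagonal_bins(wa.freqs)
    triple = (wa.spectra[:, i_f] * wb.spectra[:, i_f]
              * np.conj(wb.spectra[:, i_2f]))
    mags = np.abs(triple)                      # (L, n_bins), per-window L=1
    floor = 1e-12 * np.median(bs_eo.values)
    valid = bs_eo.values > floor
    bmask = band_bins(fvals, band) & valid
    bsn = (mags[:, bmask] - bs_eo.values[bmask]) / bs_eo.values[bmask]
    values = bsn.mean(axis=1)
    times = wa.starts + window_length / 2.0
    return TemporalBispectrumTrace(tuple(dyad), tuple(channel_pair),
                                   band if isinstance(band, str) else band.name,
                                   times, values, gaps=list(gaps))


# ---------------------------------------------------------------------------
# batched pairwise computation (used by the statistical scan)
# ---------------------------------------------------------------------------

def pairwise_representations(session: HyperscanSession, dyad, channels_a,
                             channels_b, interval, interval_id,
                             window_length=WINDOW_LENGTH, step=WINDOW_STEP):
    """Bispectral representations for all (channel_a, channel_b) pairs.

    Returns ``(freqs, values, L)`` where ``values`` has shape
    ``(len(channels_a), len(channels_b), n_bins)``.  One einsum replaces
    the per-pair loop; identical to calling
    :func:`diagonal_cross_bispectrum` pair by pair.
    """
    rec_a, rec_b = session.recording(dyad[0]), session.recording(dyad[1])
    wa = [extract_windows(rec_a, ch, window_length, step, interval,
                          session.masked) for ch in channels_a]
    wb = [extract_windows(rec_b, ch, window_length, step, interval,
                          session.masked) for ch in channels_b]
    fvals, i_f, i_2f = diagonal_bins(wa[0].freqs)
    A = np.stack([w.spectra[:, i_f] for w in wa])                 # (na, L, F)
    B = np.stack([w.spectra[:, i_f] * np.conj(w.spectra[:, i_2f])
                  for w in wb])                                   # (nb, L, F)
    L = A.shape[1]
    values = np.abs(np.einsum("alf,blf->abf", A, B)) / L
    return fvals, values, L
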