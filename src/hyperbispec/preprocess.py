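"""Preprocessing: resampling, filtering, referencing, ocular-artifact removal.

The stage order is fixed and logged in each recording's history:
resample -> bandpass -> line-noise removal -> robust average reference ->
H-infinity EOG cancellation.  Every operation is pure: it returns a new
recording and leaves its input untouched.

Notes on individual stages
--------------------------
* Filtering is zero-phase (forward-backward second-order sections), so
  event timing is preserved for the peri-event analyses.
* Line-noise removal is a narrow zero-phase notch at the line frequency
  and its harmonics below Nyquist — a deliberately simple stand-in for a
  full reference-pipeline cleanup; external tools (PREP, ASR, ICA) can be
  run outside and their output ingested instead.
* The "average" reference is a per-sample median across EEG channels, a
  robust approximation to a true average reference that resists single-
  channel artifacts; EOG channels never enter the reference.
* Ocular artifacts are removed with an adaptive-noise-cancelling
  H-infinity filter: per EEG channel a weight vector over the EOG
  reference channels plus a constant bias term is updated recursively;
  the robustness bound gamma caps the worst-case energy amplification and
  the drift parameter q lets weights track slow changes (defaults
  gamma = 1.15, q = 1e-10).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .errors import InfeasibleFilterError
from .types import EEG, HyperscanSession, MultichannelRecording

__all__ = ["FilterConfig", "HInfConfig", "resample", "bandpass",
           "remove_line_noise", "average_reference", "hinf_eog_removal",
           "preprocess_recording", "preprocess_session"]


@dataclass(frozen=True)
class FilterConfig:
    """Band-pass / resampling parameters."""

    band: tuple = (0.1, 100.0)
    order: int = 4
    resample_to: float = 250.0
    line_freq: float = 60.0

    def __post_init__(self):
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        lo, hi = self.band
        if not 0 < lo < hi < self.resample_to / 2:
            raise ValueError("band must lie inside (0, resample_to/2)")


@dataclass(frozen=True)
class HInfConfig:
    """H-infinity canceller parameters.

    gamma > 1 bounds the worst-case error amplification (smaller is more
    aggressive; too small loses positive-definiteness), q > 0 is the
    random-walk drift of the weights, p0 the initial weight covariance.
    """

    gamma: float = 1.15
    q: float = 1e-10
    p0: float = 0.5
    use_bias: bool = True

    def __post_init__(self):
        if self.gamma <= 1:
            raise ValueError("gamma must exceed 1")
        if self.q <= 0 or self.p0 <= 0:
            raise ValueError("q and p0 must be positive")


def resample(recording: MultichannelRecording, target_fs: float
             ) -> MultichannelRecording:
    """Anti-aliased polyphase downsampling; upsampling is not supported."""
    if target_fs > recording.fs:
        raise ValueError("upsampling is not supported")
    if target_fs == recording.fs:
        return recording.with_data(recording.data, note="resample(identity)")
    frac = Fraction(target_fs / recording.fs).limit_denominator(1000)
    out = signal.resample_poly(recording.data, frac.numerator,
                               frac.denominator, axis=1)
    rec = recording.with_data(out, note=f"resample({recording.fs}->{target_fs})")
    rec.fs = float(target_fs)
    return rec


def bandpass(recording: MultichannelRecording, config: FilterConfig
             ) -> MultichannelRecording:
    """Zero-phase Butterworth band-pass."""
    nyq = recording.fs / 2
    lo, hi = config.band
    if not 0 < lo < hi < nyq:
        raise ValueError(f"band {config.band} outside (0, {nyq}) Hz")
    sos = signal.butter(config.order, [lo, hi], btype="bandpass",
                        fs=recording.fs, output="sos")
    out = signal.sosfiltfilt(sos, recording.data, axis=1)
    return recording.with_data(
        out, note=f"bandpass({lo}-{hi} Hz, order {config.order})")


def remove_line_noise(recording: MultichannelRecording, line_freq=60.0,
                      notch_bw=0.5) -> MultichannelRecording:
    """Zero-phase notch at the line frequency and harmonics below Nyquist.

    The -3 dB notch width is ``notch_bw`` Hz, narrow enough to leave
    bins +-2 Hz away essentially untouched.
    """
    nyq = recording.fs / 2
    if line_freq >= nyq:
        raise ValueError("line_freq must be below Nyquist")
    out = recording.data
    f = line_freq
    while f < nyq:
        b, a = signal.iirnotch(f, f / notch_bw, fs=recording.fs)
        out = signal.filtfilt(b, a, out, axis=1)
        f += line_freq
    return recording.with_data(out, note=f"remove_line_noise({line_freq} Hz)")


def average_reference(obj):
    """Subtract the per-sample median of the EEG channels (robust average
    reference).  EOG channels are excluded from the reference and left
    unchanged.  Accepts a recording or a whole session."""
    if isinstance(obj, HyperscanSession):
        recs = [average_reference(r) for r in obj.recordings]
        return HyperscanSession(recs, obj.design, obj.baselines,
                                obj.annotations, list(obj.masked),
                                dict(obj.meta))
    recording = obj
    eeg = recording.eeg_indices
    if len(eeg) < 2:
        raise ValueError("average reference needs >= 2 EEG channels")
    data = recording.data.copy()
    ref = np.median(data[eeg], axis=0)
    data[eeg] -= ref
    return recording.with_data(data, note="average_reference(median)")


def hinf_eog_removal(recording: MultichannelRecording,
                     config: HInfConfig = HInfConfig(),
                     return_weights=True):
    """Adaptive H-infinity cancellation of EOG references from EEG.

    Per EEG channel a weight vector ``w`` over [EOG references, 1] is
    updated sample by sample with the time-varying H-infinity estimator
    (state w constant up to drift q, measurement s_k = h_k^T w + noise)::

        P~_k   = P_k (I - gamma^-2 P_k + h_k h_k^T P_k)^-1
        K_k    = P~_k h_k
        w_k+1  = w_k + K_k (s_k - h_k^T w_k)
        P_k+1  = P~_k + q I

    cleaned = EEG - w^T [references, 1].  The gain matrix ``P`` is shared
    across EEG channels (it depends only on the references), so the
    per-channel update vectorizes.  Loss of positive-definiteness (gamma
    too small) raises :class:`InfeasibleFilterError` naming the first
    failing sample.

    Returns ``(cleaned recording, weight trajectories)`` with weights of
    shape ``(n_samples, n_refs + bias, n_eeg)``; pass
    ``return_weights=False`` to skip storing the (large) trajectory.
    """
    eog = recording.eog_indices
    eeg = recording.eeg_indices
    if len(eog) == 0:
        w = np.zeros((recording.n_samples, int(config.use_bias), len(eeg)))
        return recording.with_data(recording.data,
                                   note="hinf(no EOG references)"), w
    refs = recording.data[eog]                       # (n_refs, n)
    target = recording.data[eeg]                     # (n_eeg, n)
    nr = len(eog) + (1 if config.use_bias else 0)
    n = recording.n_samples
    g2 = config.gamma ** -2
    eye = np.eye(nr)
    P = config.p0 * eye
    W = np.zeros((nr, len(eeg)))
    traj = np.empty((n, nr, len(eeg))) if return_weights else None
    cleaned = np.empty_like(target)
    for k in range(n):
        h = refs[:, k]
        if config.use_bias:
            h = np.append(h, 1.0)
        A = eye - g2 * P + np.outer(h, h) @ P
        try:
            Pt = P @ np.linalg.inv(A)
            Pt = 0.5 * (Pt + Pt.T)
            np.linalg.cholesky(Pt)
        except np.linalg.LinAlgError:
            raise InfeasibleFilterError(k) from None
        K = Pt @ h
        est = h @ W                                  # (n_eeg,)
        cleaned[:, k] = target[:, k] - est
        W = W + np.outer(K, target[:, k] - est)
        if return_weights:
            traj[k] = W
        P = Pt + config.q * eye
        if not np.all(np.isfinite(W)):
            raise InfeasibleFilterError(k, f"weights diverged at sample {k}")
    data = recording.data.copy()
    data[eeg] = cleaned
    out = recording.with_data(
        data, note=f"hinf(gamma={config.gamma}, q={config.q})")
    return out, traj


def preprocess_recording(recording, filt: FilterConfig = FilterConfig(),
                         hinf: HInfConfig | None = HInfConfig(),
                         line=True, reference=True):
    """Run the full fixed-order pipeline on one recording."""
    rec = resample(recording, filt.resample_to)
    rec = bandpass(rec, filt)
    if line:
        rec = remove_line_noise(rec, filt.line_freq)
    if reference:
        rec = average_reference(rec)
    if hinf is not None:
        rec, _ = hinf_eog_removal(rec, hinf, return_weights=False)
    return rec


def preprocess_session(session: HyperscanSession,
                       filt: FilterConfig = FilterConfig(),
                       hinf: HInfConfig | None = HInfConfig(),
                       line=True, reference=True) -> HyperscanSession:
    """Apply :func:`preprocess_recording` to every participant."""
    recs = [preprocess_recording(r, filt, hinf, line, reference)
            for r in session.recordings]
    return HyperscanSession(recs, session.design, session.baselines,
                            session.annotations, list(session.masked),
                            dict(session.meta))
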