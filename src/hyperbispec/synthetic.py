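"""Synthetic hyperscanning sessions with known ground-truth coupling.

The generator emulates the structure of a three-musician improvisation
session: pre/post eyes-open (EO) and eyes-closed (EC) resting baselines,
three trials of three segments each with staggered entry of the "active"
musicians, and annotated synchronized-performance (SP) / desynchronized-
performance (DP) events.

Signal model
------------
* Background activity is independent 1/f^alpha ("pink") noise per channel.
* Inter-brain coupling is quadratic phase coupling (QPC), the canonical
  structure detected by the diagonal bispectrum: for each analysis epoch
  (default 4 s) a phase ``phi_l`` is drawn; participant *a* receives a tone
  at ``f0`` with phase ``phi_l`` while participant *b* receives a tone at
  ``f0`` with the *shared* phase and a tone at ``2 f0`` with phase
  ``2 phi_l``.  Both of *b*'s components are scaled by the coupling
  strength ``rho`` and complemented by amplitude-matched incoherent tones
  scaled by ``1 - rho``, so ``rho = 0`` leaves the participants
  statistically independent and ``rho = 1`` is fully phase-locked.
* A single QPC tone concentrates evidence in one frequency bin; to emulate
  band-wide synchrony (what band-level statistics respond to) the session
  generator plants a comb of QPC tones across a configurable frequency
  range (default: the gamma band).
* Oscillatory power on the coupled channels is stationary: the tone comb
  runs through the *entire* session (baselines included) and only the
  phase coupling ``rho(t)`` switches on when both dyad members are
  active.  This matters because the bispectrum magnitude responds to any
  power increase over rest in any of its three factors; keeping power
  stationary makes the segment-vs-rest contrast specific to phase
  coupling, which is the quantity under study.
* Blinks are stereotyped ~300 ms biphasic pulses on the vertical EOG
  channels, propagated to EEG channels through a frontally weighted mixing
  vector.

Coupling is active only in segments where both members of a dyad are
active.  SP events raise ``rho`` starting ``lead_time`` seconds before the
annotated time (anticipatory coupling); DP events lower it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.fft import irfft, rfft, rfftfreq

from . import montage as _montage
from .errors import MissingChannelError
from .types import (
    EEG,
    EOG,
    BaselineBlock,
    EventAnnotation,
    HyperscanSession,
    MultichannelRecording,
    SegmentDesign,
)

__all__ = [
    "SyntheticConfig",
    "EventSpec",
    "GroundTruth",
    "generate_participant_noise",
    "inject_coupled_component",
    "inject_eog_artifacts",
    "generate_session",
    "default_trial_layout",
]


@dataclass(frozen=True)
class EventSpec:
    """A scheduled SP/DP event.

    ``time`` is in the session clock; the coupling change of size
    ``rho_delta`` (positive for SP, negative for DP) starts ``lead_time``
    seconds *before* ``time`` and lasts ``duration`` seconds.

    ``amp_delta`` is the fractional change of the coupled-component
    amplitude over the same span (raised for SP, lowered for DP).  It
    exists because a single-window bispectrum magnitude is the product of
    its factor magnitudes and therefore blind to pure phase re-coupling;
    event-locked traces (one window at a time) can only reflect events
    that also modulate the coupled oscillatory power, which is how
    synchronized-performance episodes are modeled here.
    """

    event_type: str            # "SP" | "DP"
    time: float                # s, session clock
    rho_delta: float = 0.4
    lead_time: float = 3.0
    duration: float = 20.0
    amp_delta: float = 0.5
    label: str = ""


#: Temporal/parietal senders coupled into distinct occipital receivers,
#: mirroring the temporo-occipital placement of the strongest inter-brain
#: links.  Pairs are channel-disjoint so no channel carries two tone sets
#: (stacked tones would raise the incoherent bispectral floor of every
#: combination the channel enters and dilute its coherent fraction).
_COUPLED_PAIRS_60 = (("T7", "Oz"), ("TP7", "O1"), ("T8", "O2"),
                     ("TP8", "Iz"), ("FT7", "PO7"))
_COUPLED_PAIRS_16 = (("T7", "Oz"), ("T8", "O1"), ("P7", "O2"),
                     ("P8", "Pz"), ("C3", "C4"))


def default_coupled_pairs(labels):
    """Disjoint coupled channel pairs available in ``labels``."""
    labels = set(labels)
    for pairs in (_COUPLED_PAIRS_60, _COUPLED_PAIRS_16):
        if all(a in labels and b in labels for a, b in pairs):
            return pairs
    # fall back: pair the first channels with the last ones
    ordered = sorted(labels)
    k = min(5, len(ordered) // 2)
    return tuple((ordered[i], ordered[-1 - i]) for i in range(k))


def default_trial_layout(participants=("P1", "P2", "P3"), segment_duration=300.0,
                         n_trials=3):
    """Staggered-entry layout: per trial one musician starts, the others
    join one segment at a time; the entry order rotates so each participant
    is first exactly once."""
    p = list(participants)
    layout = []
    for t in range(n_trials):
        # trial 1: P3 first, then P1, then P2; subsequent trials rotate.
        order = p[(2 + t) % len(p):] + p[:(2 + t) % len(p)]
        for s in range(len(p)):
            active = frozenset(order[: s + 1])
            layout.append((t + 1, s + 1, active, segment_duration))
    return layout


@dataclass
class SyntheticConfig:
    """Study-condition defaults for the synthetic session generator.

    ``coupling_freqs`` lists the QPC tone frequencies f0; every f0 must
    satisfy ``2 f0 <= 50 Hz``-compatible analysis (i.e. below the Nyquist
    frequency after resampling).  ``coupling_variance_fraction`` caps the
    total coupled-component variance relative to background variance.
    """

    n_participants: int = 3
    n_eeg_channels: int = 60          # scalp channels (64-ch cap minus EOG roles)
    n_eog_channels: int = 4
    fs: float = 1000.0
    trial_layout: list = None         # list of (trial, segment, active_set, duration)
    baseline_duration: float = 60.0
    inter_trial_pause: float = 0.0
    coupling_strength: float = 0.8    # base rho in active-active intervals
    coupling_freqs: tuple = tuple(np.arange(30.0, 50.01, 0.5))
    coupled_channel_pairs: tuple = None   # resolved per montage; see below
    noise_exponent: float = 1.0
    noise_scale: float = 10.0         # background rms, microvolts
    coupling_variance_fraction: float = 0.1
    epoch_length: float = 4.0
    blink_rate: float = 12.0          # events / minute
    event_schedule: tuple = ()        # EventSpec entries
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must lie in [0, 1]")
        if self.baseline_duration <= 0 or self.fs <= 0:
            raise ValueError("durations and fs must be positive")
        if self.trial_layout is None:
            parts = [f"P{i + 1}" for i in range(self.n_participants)]
            self.trial_layout = default_trial_layout(parts)
        if self.coupled_channel_pairs is None:
            self.coupled_channel_pairs = default_coupled_pairs(self.eeg_labels())
        seen = {}
        for a, b in self.coupled_channel_pairs:
            for ch, role in ((a, "sender"), (b, "receiver")):
                if seen.setdefault(ch, role) != role or sum(
                        ch in p for p in self.coupled_channel_pairs) > 1:
                    raise ValueError(
                        f"channel {ch} reused across coupled pairs; pairs "
                        "must be disjoint so tone sets do not stack")

    @property
    def participants(self):
        """All participant ids: the P1..Pn roster plus anyone named in the
        trial layout (a participant may stay passive throughout)."""
        ids = {f"P{i + 1}" for i in range(self.n_participants)}
        for _, _, active, _ in self.trial_layout:
            ids |= set(active)
        return sorted(ids)

    def eeg_labels(self):
        scalp = _montage.scalp_channels(_montage.DEFAULT_64)
        if self.n_eeg_channels == len(_montage.SMALL_16):
            return list(_montage.SMALL_16)
        if self.n_eeg_channels > len(scalp):
            raise ValueError("montage has only %d scalp labels" % len(scalp))
        return list(scalp[: self.n_eeg_channels])

    def eog_labels(self):
        roles = list(_montage.DEFAULT_EOG_ROLES)
        return roles[: self.n_eog_channels]

    def tone_amplitude(self):
        """Per-tone amplitude keeping total coupled variance at the
        configured fraction of background variance."""
        n = max(len(self.coupling_freqs), 1)
        return math.sqrt(2.0 * self.coupling_variance_fraction
                         * self.noise_scale ** 2 / n)


@dataclass
class GroundTruth:
    """What the generator actually planted."""

    coupling: list = field(default_factory=list)  # (dyad, start, end, rho)
    events: list = field(default_factory=list)    # EventSpec
    coupled_pairs: list = field(default_factory=list)  # (chan_a, chan_b)
    blink_times: dict = field(default_factory=dict)    # participant -> array
    blink_mixing: dict = field(default_factory=dict)   # participant -> {label: w}

    def rho_at(self, dyad, t: float) -> float:
        dyad = tuple(sorted(dyad))
        for d, a, b, rho in self.coupling:
            if tuple(sorted(d)) == dyad and a <= t < b:
                return rho
        return 0.0

    def rho_steps(self, dyad):
        dyad = tuple(sorted(dyad))
        return sorted((a, rho) for d, a, b, rho in self.coupling
                      if tuple(sorted(d)) == dyad)


# ---------------------------------------------------------------------------
# primitive generators
# ---------------------------------------------------------------------------

def generate_participant_noise(n_channels, duration_s, fs, noise_exponent,
                               seed, scale=1.0):
    """Zero-mean channel noise with power spectral density ~ 1/f^exponent.

    Shaped in the frequency domain: white Gaussian noise is filtered by
    ``f**(-exponent/2)`` (DC removed), then rescaled to ``scale`` rms.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    white = rng.standard_normal((n_channels, n))
    spec = rfft(white, axis=1)
    freqs = rfftfreq(n, 1.0 / fs)
    shaping = np.ones_like(freqs)
    if noise_exponent != 0:
        shaping[1:] = freqs[1:] ** (-noise_exponent / 2.0)
    shaping[0] = 0.0  # zero mean
    x = irfft(spec * shaping, n=n, axis=1)
    x -= x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd * scale


def inject_coupled_component(recordings, dyad, channel_pair, f0, rho, interval,
                             seed, amplitude=1.0, epoch_length=4.0):
    """Add one quadratically phase-coupled tone pair to a dyad, in place.

    Participant ``dyad[0]`` receives ``A cos(2 pi f0 t + phi_l)`` on
    ``channel_pair[0]``; ``dyad[1]`` receives, on ``channel_pair[1]``, the
    phase-locked pair ``rho * [A cos(2 pi f0 t + phi_l) +
    A cos(2 pi 2 f0 t + 2 phi_l)]`` plus amplitude-matched incoherent tones
    scaled by ``1 - rho``.  ``phi_l`` is redrawn per ``epoch_length``
    epoch (epochs anchored at ``interval[0]``), so bispectral evidence can
    only accumulate through the phase coupling itself.

    ``rho`` may be a scalar or a callable ``rho(t_mid)`` evaluated at each
    epoch midpoint.  The arrays inside ``recordings`` are modified in place
    and the list is returned.
    """
    rec_by_id = {r.participant_id: r for r in recordings}
    try:
        rec_a, rec_b = rec_by_id[dyad[0]], rec_by_id[dyad[1]]
    except KeyError as e:
        raise MissingChannelError(f"participant {e.args[0]} not in recordings") from None
    ia = rec_a.channel_index(channel_pair[0])
    ib = rec_b.channel_index(channel_pair[1])
    fs = rec_a.fs
    if 2 * f0 >= fs / 2:
        raise ValueError(f"2*f0 = {2 * f0} Hz is not below Nyquist ({fs / 2} Hz)")
    t0, t1 = interval
    if t0 < rec_a.start_time or t1 > rec_a.start_time + rec_a.duration or t1 <= t0:
        raise IndexError(f"interval {interval} outside recording")
    rho_fn = rho if callable(rho) else (lambda _t, _r=float(rho): _r)
    amp_fn = amplitude if callable(amplitude) else (
        lambda _t, _a=float(amplitude): _a)
    rng = np.random.default_rng(seed)
    n_epochs = int(math.ceil((t1 - t0) / epoch_length))
    for l in range(n_epochs):
        e0 = t0 + l * epoch_length
        e1 = min(e0 + epoch_length, t1)
        r = float(rho_fn(0.5 * (e0 + e1)))
        amp = float(amp_fn(0.5 * (e0 + e1)))
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"rho(t) = {r} outside [0, 1]")
        phi, psi, chi = rng.uniform(0.0, 2 * np.pi, size=3)
        s0 = int(round((e0 - rec_a.start_time) * fs))
        s1 = int(round((e1 - rec_a.start_time) * fs))
        t = np.arange(s0, s1) / fs
        w1, w2 = 2 * np.pi * f0 * t, 2 * np.pi * (2 * f0) * t
        rec_a.data[ia, s0:s1] += amp * np.cos(w1 + phi)
        rec_b.data[ib, s0:s1] += amp * (
            r * np.cos(w1 + phi) + (1.0 - r) * np.cos(w1 + psi)
            + r * np.cos(w2 + 2.0 * phi) + (1.0 - r) * np.cos(w2 + chi)
        )
    return recordings


def blink_template(fs, duration=0.3, amp=150.0):
    """Stereotyped biphasic blink: a dominant positive lobe followed by a
    smaller negative rebound, ~300 ms total."""
    t = np.arange(int(round(duration * fs))) / fs
    return (amp * np.exp(-((t - 0.10) / 0.04) ** 2)
            - 0.3 * amp * np.exp(-((t - 0.22) / 0.06) ** 2))


def inject_eog_artifacts(recording, blink_rate, seed, eeg_gain=0.4):
    """Add Poisson-timed blinks to vertical EOG channels and, frontally
    weighted, to EEG channels.  Pure: returns a new recording plus the
    mixing ground truth ``({eeg_label: weight}, blink_onsets_s)``.

    Within the vertical EOG pair the second channel (below the eye) sees
    the blink with inverted polarity.
    """
    if blink_rate < 0:
        raise ValueError("blink_rate must be non-negative")
    roles = recording.meta.get("eog_roles", {})
    veog = [i for i in recording.eog_indices
            if roles.get(recording.channel_labels[i], "veog") == "veog"]
    if len(veog) == 0:
        raise ValueError("recording has no vertical EOG channels")
    data = recording.data.copy()
    rng = np.random.default_rng(seed)
    n_blinks = rng.poisson(blink_rate / 60.0 * recording.duration)
    tpl = blink_template(recording.fs)
    onsets = np.sort(rng.uniform(0.0, recording.duration - len(tpl) / recording.fs,
                                 size=n_blinks))
    mixing = {lab: eeg_gain * _montage.frontal_weight(lab)
              for lab in recording.eeg_labels}
    for onset in onsets:
        s0 = int(round(onset * recording.fs))
        sl = slice(s0, s0 + len(tpl))
        for k, i in enumerate(veog):
            data[i, sl] += tpl if k % 2 == 0 else -tpl
        for i in recording.eeg_indices:
            data[i, sl] += mixing[recording.channel_labels[i]] * tpl
    out = recording.with_data(data, note=f"inject_eog_artifacts(rate={blink_rate})")
    return out, mixing, onsets


# ---------------------------------------------------------------------------
# session assembly
# ---------------------------------------------------------------------------

def _session_timeline(config):
    """Lay out baselines, trials/segments and pauses on the session clock."""
    t = 0.0
    baselines, design = [], []
    for kind in ("EO", "EC"):
        baselines.append(BaselineBlock("pre", kind, (t, t + config.baseline_duration)))
        t += config.baseline_duration
    trials = sorted({tr for tr, _, _, _ in config.trial_layout})
    for k, trial in enumerate(trials):
        if k > 0:
            t += config.inter_trial_pause
        for tr, seg, active, dur in config.trial_layout:
            if tr != trial:
                continue
            design.append(SegmentDesign(tr, seg, frozenset(active), (t, t + dur)))
            t += dur
    for kind in ("EO", "EC"):
        baselines.append(BaselineBlock("post", kind, (t, t + config.baseline_duration)))
        t += config.baseline_duration
    return baselines, design, t


def _rho_profile(base_rho, events, active_intervals):
    """Piecewise rho(t): ``base_rho`` while the dyad is active-active
    (0 elsewhere), stepped by the event schedule, clipped to [0, 1]."""
    def rho(t):
        r = base_rho if any(a <= t < b for a, b in active_intervals) else 0.0
        for ev in events:
            start = ev.time - ev.lead_time
            if start <= t < start + ev.duration:
                r += ev.rho_delta if ev.event_type == "SP" else -abs(ev.rho_delta)
        return min(max(r, 0.0), 1.0)
    return rho


def _amp_profile(base_amp, events):
    """Coupled-component amplitude over time: ``base_amp`` scaled up by SP
    events and down by DP events (floored at 0)."""
    def amp(t):
        g = 1.0
        for ev in events:
            start = ev.time - ev.lead_time
            if start <= t < start + ev.duration:
                g += ev.amp_delta if ev.event_type == "SP" else -abs(ev.amp_delta)
        return base_amp * max(g, 0.0)
    return amp


def generate_session(config: SyntheticConfig):
    """Build a full synthetic session and its ground truth.

    Returns ``(HyperscanSession, GroundTruth)``.  Identical configs
    (including ``seed``) produce bitwise-identical sessions.
    """
    baselines, design, total = _session_timeline(config)
    for ev in config.event_schedule:
        if not 0.0 <= ev.time < total:
            raise IndexError(f"event at {ev.time} s outside session [0, {total})")
    participants = config.participants
    eeg_labels, eog_labels = config.eeg_labels(), config.eog_labels()
    labels = eeg_labels + eog_labels
    kinds = [EEG] * len(eeg_labels) + [EOG] * len(eog_labels)
    roles = {lab: _montage.DEFAULT_EOG_ROLES.get(lab, "veog") for lab in eog_labels}

    root = np.random.SeedSequence(config.seed)
    # fixed spawn order => deterministic regardless of later code paths
    noise_seeds = root.spawn(len(participants))
    blink_seeds = root.spawn(len(participants))
    coupling_root = root.spawn(1)[0]

    truth = GroundTruth(events=list(config.event_schedule),
                        coupled_pairs=list(config.coupled_channel_pairs))
    recordings = []
    for pid, nseed, bseed in zip(participants, noise_seeds, blink_seeds):
        data = generate_participant_noise(
            len(labels), total, config.fs, config.noise_exponent,
            nseed, scale=config.noise_scale)
        rec = MultichannelRecording(pid, list(labels), list(kinds), config.fs,
                                    data, meta={"eog_roles": dict(roles)})
        if config.blink_rate > 0:
            rec, mixing, onsets = inject_eog_artifacts(rec, config.blink_rate, bseed)
            truth.blink_mixing[pid] = mixing
            truth.blink_times[pid] = onsets
        recordings.append(rec)

    dyads = [(a, b) for i, a in enumerate(participants) for b in participants[i + 1:]]
    amp = config.tone_amplitude()
    if config.coupling_strength > 0 and config.coupled_channel_pairs:
        for d_i, dyad in enumerate(dyads):
            active = [seg.interval for seg in design
                      if seg.condition(dyad) == "active-active"]
            rho_fn = _rho_profile(config.coupling_strength,
                                  config.event_schedule, active)
            amp_fn = _amp_profile(amp, config.event_schedule)
            # tones run through the whole session; only rho(t) (and, around
            # events, the component amplitude) varies
            for p_i, pair in enumerate(config.coupled_channel_pairs):
                for f_i, f0 in enumerate(config.coupling_freqs):
                    child = np.random.SeedSequence(
                        entropy=coupling_root.entropy,
                        spawn_key=coupling_root.spawn_key + (d_i, p_i, f_i))
                    inject_coupled_component(
                        recordings, dyad, pair, f0, rho_fn, (0.0, total),
                        child, amplitude=amp_fn,
                        epoch_length=config.epoch_length)
            pieces = []
            _record_rho_pieces(pieces, (0.0, total), rho_fn,
                               config.event_schedule, active)
            truth.coupling.extend((dyad, a, b, r) for a, b, r in pieces)
    else:
        for dyad in dyads:
            truth.coupling.append((dyad, 0.0, total, 0.0))

    annotations = [EventAnnotation(ev.event_type, ev.time, ev.label or
                                   f"synthetic {ev.event_type} event")
                   for ev in config.event_schedule]
    session = HyperscanSession(recordings, design, baselines, annotations,
                               meta={"synthetic": True, "seed": config.seed})
    return session, truth


def _record_rho_pieces(acc, interval, rho_fn, events, active_intervals):
    """Break one interval at every rho step; append (a, b, rho) pieces
    that tile ``interval`` without overlap."""
    cuts = {interval[0], interval[1]}
    for a, b in active_intervals:
        cuts.update((a, b))
    for ev in events:
        for c in (ev.time - ev.lead_time, ev.time - ev.lead_time + ev.duration):
            cuts.add(c)
    cuts = sorted(c for c in cuts if interval[0] <= c <= interval[1])
    for a, b in zip(cuts, cuts[1:]):
        acc.append((a, b, rho_fn(0.5 * (a + b))))
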