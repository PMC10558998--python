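"""Event-locked analysis of temporal bispectrum traces.

SP (synchronized) and DP (desynchronized) performance events are analyzed
by cutting a two-minute trace (-60 to +60 s, annotation time = 0 s) out
of the band-limited temporal bispectrum series of a chosen channel
combination, baseline-correcting each trace by its pre-event (-60 to 0 s)
mean, and comparing the SP and DP groups at every time point.

The SP and DP groups generally have unequal sizes, so the per-timepoint
comparison is an unpaired two-sample rank test (Wilcoxon rank-sum /
Mann-Whitney U) with alternative SP > DP, masked at pointwise p < 0.05.
For onset estimation a sustained-significance criterion (a run of
``min_run`` consecutive significant points) is available, since a single
pointwise exceedance at 5 % is expected by chance over a 121-point grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .bispectrum import TemporalBispectrumTrace
from .errors import AlignmentError
from .types import EventAnnotation, HyperscanSession

__all__ = [
    "EventLockedTrace", "GroupComparison", "extract_peri_event",
    "baseline_correct", "compare_groups", "significance_onset",
    "split_by_condition", "collect_event_traces",
]


@dataclass
class EventLockedTrace:
    """One event's peri-event trace on the common relative time grid."""

    event: EventAnnotation
    dyad: tuple
    channel_pair: tuple
    condition: str | None       # dyad condition at event time (None: unassigned)
    times: np.ndarray           # relative s, -pre .. +post
    values: np.ndarray
    baseline_corrected: bool = False


@dataclass
class GroupComparison:
    """Per-timepoint SP-vs-DP comparison."""

    times: np.ndarray
    p_values: np.ndarray
    mask: np.ndarray            # p < alpha
    n_sp: int
    n_dp: int
    alpha: float = 0.05
    degenerate: bool = False
    note: str = ""


def extract_peri_event(trace: TemporalBispectrumTrace, event: EventAnnotation,
                       session: HyperscanSession | None = None,
                       pre=60.0, post=60.0, grid_step=1.0,
                       tol=0.501) -> EventLockedTrace:
    """Cut the (-pre, +post) window around an event out of a trace.

    The trace is sampled onto the relative grid by nearest-neighbour
    matching within ``tol`` seconds.  Raises ``ValueError`` if the window
    leaves the trace or crosses a masked gap (callers batching events
    should skip and log such events); events inside masked session spans
    are rejected outright.
    """
    if session is not None:
        for m0, m1 in session.masked:
            if m0 <= event.time < m1:
                raise ValueError(
                    f"event at {event.time} s lies in masked span [{m0}, {m1})")
    rel = np.arange(-pre, post + grid_step / 2, grid_step)
    want = event.time + rel
    if want[0] < trace.times[0] - tol or want[-1] > trace.times[-1] + tol:
        raise ValueError(
            f"event at {event.time} s: +-{pre:.0f}/{post:.0f} s window exceeds trace")
    idx = np.searchsorted(trace.times, want)
    idx = np.clip(idx, 0, len(trace.times) - 1)
    left = np.clip(idx - 1, 0, len(trace.times) - 1)
    choose_left = (np.abs(trace.times[left] - want)
                   < np.abs(trace.times[idx] - want))
    idx[choose_left] = left[choose_left]
    if np.any(np.abs(trace.times[idx] - want) > tol):
        raise ValueError(
            f"event at {event.time} s: window crosses a gap in the trace")
    condition = None
    if session is not None:
        seg = session.segment_at(event.time)
        condition = seg.condition(trace.dyad) if seg is not None else None
    return EventLockedTrace(event, trace.dyad, trace.channel_pair, condition,
                            rel, trace.values[idx].copy())


def baseline_correct(elt: EventLockedTrace) -> EventLockedTrace:
    """Subtract the pre-event (-60 to 0 s) mean from the whole trace.

    Idempotent; raises ``ValueError`` if the baseline span holds no valid
    sample.  Values stay in relative BS_N units (multiply by 100 to read
    as "BS change (%)").
    """
    base = elt.values[(elt.times >= elt.times[0]) & (elt.times < 0)]
    base = base[np.isfinite(base)]
    if base.size == 0:
        raise ValueError("empty pre-event baseline")
    return EventLockedTrace(elt.event, elt.dyad, elt.channel_pair,
                            elt.condition, elt.times.copy(),
                            elt.values - base.mean(),
                            baseline_corrected=True)


def compare_groups(sp_traces, dp_traces, alpha=0.05) -> GroupComparison:
    """Per-timepoint two-sample rank test, alternative SP > DP.

    Group sizes may differ.  Single-trace groups cannot be rank-tested:
    a degenerate comparison (no p-values) is returned.
    """
    if len(sp_traces) == 0 or len(dp_traces) == 0:
        return GroupComparison(np.empty(0), np.empty(0), np.empty(0, bool),
                               len(sp_traces), len(dp_traces), alpha,
                               degenerate=True, note="a group is empty")
    times = sp_traces[0].times
    for t in list(sp_traces) + list(dp_traces):
        if len(t.times) != len(times) or not np.allclose(t.times, times):
            raise AlignmentError("traces are not on a common time grid")
    if len(sp_traces) < 2 or len(dp_traces) < 2:
        return GroupComparison(times.copy(), np.empty(0), np.empty(0, bool),
                               len(sp_traces), len(dp_traces), alpha,
                               degenerate=True, note="single-trace group")
    sp = np.stack([t.values for t in sp_traces])
    dp = np.stack([t.values for t in dp_traces])
    p = np.ones(len(times))
    for k in range(len(times)):
        a, b = sp[:, k], dp[:, k]
        if np.all(a[0] == a) and np.all(b[0] == b) and a[0] == b[0]:
            continue  # identical constants: no evidence either way
        p[k] = sps.mannwhitneyu(a, b, alternative="greater").pvalue
    return GroupComparison(times.copy(), p, p < alpha, len(sp_traces),
                           len(dp_traces), alpha)


def significance_onset(comparison: GroupComparison, min_run=3):
    """Earliest time at which ``min_run`` consecutive points are
    significant; None if never.  ``min_run=1`` is the raw pointwise mask."""
    if comparison.degenerate or comparison.mask.size == 0:
        return None
    m = comparison.mask
    run = 0
    for k, flag in enumerate(m):
        run = run + 1 if flag else 0
        if run >= min_run:
            return float(comparison.times[k - min_run + 1])
    return None


def split_by_condition(events, session: HyperscanSession, dyads=None):
    """Assign each (event, dyad) to its performance condition.

    Returns ``(groups, unassigned)`` where ``groups`` maps
    passive-passive / passive-active / active-active to lists of
    ``(event, dyad)`` and ``unassigned`` holds events outside any segment
    (e.g. inter-trial pauses).
    """
    if dyads is None:
        dyads = session.dyads()
    groups = {"passive-passive": [], "passive-active": [], "active-active": []}
    unassigned = []
    for ev in events:
        seg = session.segment_at(ev.time)
        if seg is None:
            unassigned.append(ev)
            continue
        for dyad in dyads:
            groups[seg.condition(dyad)].append((ev, tuple(dyad)))
    return groups, unassigned


def collect_event_traces(session, traces_by_dyad, events=None, pre=60.0,
                         post=60.0, condition=None):
    """Baseline-corrected event-locked traces grouped into SP and DP.

    ``traces_by_dyad`` maps a dyad tuple to its representative
    :class:`TemporalBispectrumTrace` (in the study: the dyad's most
    significant gamma-band channel combination).  Events whose window
    leaves the trace or that fall in masked spans are skipped and
    reported in the returned ``skipped`` list.
    """
    if events is None:
        events = session.annotations
    sp, dp, skipped = [], [], []
    for ev in events:
        for dyad, trace in traces_by_dyad.items():
            try:
                elt = extract_peri_event(trace, ev, session, pre, post)
            except ValueError as exc:
                skipped.append((ev, dyad, str(exc)))
                continue
            if condition is not None and elt.condition != condition:
                continue
            elt = baseline_correct(elt)
            (sp if ev.event_type == "SP" else dp).append(elt)
    return sp, dp, skipped
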