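"""End-to-end orchestration from a single validated configuration.

Stages (each re-runnable from its cached predecessor under the output
directory): simulate/ingest -> preprocess -> features (pairwise
bispectral representations) -> stats -> events -> roi.  All artifacts are
CSV except the session container and the features cache (HDF5); a
provenance record (config hash, stage parameters, package version)
accompanies every run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__, io as hio
from .bispectrum import BANDS, pairwise_representations, temporal_series
from .errors import ConfigError
from .events import collect_event_traces, compare_groups, significance_onset
from .preprocess import FilterConfig, HInfConfig, preprocess_session
from .roi import aggregate, default_roi_map, load_roi_map
from .stats import results_to_frame, summarize, tests_from_arrays, top_k
from .synthetic import EventSpec, SyntheticConfig, default_trial_layout, generate_session
from .types import PASSIVE_ACTIVE, ACTIVE_ACTIVE, PASSIVE_PASSIVE

logger = logging.getLogger(__name__)

_SCHEMA = {
    "seed": int,
    "output": str,
    "input": {"session": (str, type(None))},
    "synthetic": {
        "n_participants": int, "n_eeg_channels": int, "n_eog_channels": int,
        "fs": (int, float), "segment_duration": (int, float), "n_trials": int,
        "baseline_duration": (int, float), "coupling_strength": (int, float),
        "coupling_band": list, "coupled_channel_pairs": list,
        "noise_exponent": (int, float), "noise_scale": (int, float),
        "blink_rate": (int, float), "events": list,
    },
    "preprocess": {
        "enabled": bool, "resample_to": (int, float), "band": list,
        "order": int, "line_freq": (int, float),
        "hinf": {"gamma": (int, float), "q": (int, float)},
    },
    "windows": {"length": (int, float), "step": (int, float)},
    "stats": {"alpha": (int, float), "bands": list, "channels": (list, type(None))},
    "events": {"pre": (int, float), "post": (int, float), "band": str},
    "roi": {"table": (str, type(None))},
}


def _check(section, schema, prefix=""):
    for key, val in section.items():
        if key not in schema:
            raise ConfigError(f"unknown config key {prefix}{key!r}")
        rule = schema[key]
        if isinstance(rule, dict):
            if not isinstance(val, dict):
                raise ConfigError(f"{prefix}{key} must be a mapping")
            _check(val, rule, prefix=f"{prefix}{key}.")
        elif not isinstance(val, rule):
            raise ConfigError(f"{prefix}{key} has wrong type "
                              f"({type(val).__name__})")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``_SCHEMA`` for keys)."""

    raw: dict = field(default_factory=dict)

    def __post_init__(self):
        _check(self.raw, _SCHEMA)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as f:
            return cls(yaml.safe_load(f) or {})

    def get(self, *keys, default=None):
        node = self.raw
        for k in keys:
            if not isinstance(node, dict) or k not in node:
                return default
            node = node[k]
        return node

    @property
    def seed(self):
        return self.get("seed", default=0)

    def config_hash(self):
        blob = json.dumps(self.raw, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def synthetic_config(self, seed=None):
        s = dict(self.get("synthetic", default={}) or {})
        n_part = s.get("n_participants", 3)
        parts = [f"P{i+1}" for i in range(n_part)]
        layout = default_trial_layout(parts,
                                      s.get("segment_duration", 300.0),
                                      s.get("n_trials", 3))
        band = s.get("coupling_band", [30.0, 50.0, 0.5])
        freqs = tuple(np.arange(band[0], band[1] + band[2] / 2, band[2]))
        events = tuple(EventSpec(*e) if isinstance(e, (list, tuple))
                       else EventSpec(**e) for e in s.get("events", []))
        kwargs = dict(
            n_participants=n_part,
            n_eeg_channels=s.get("n_eeg_channels", 16),
            n_eog_channels=s.get("n_eog_channels", 4),
            fs=s.get("fs", 250.0),
            trial_layout=layout,
            baseline_duration=s.get("baseline_duration", 60.0),
            coupling_strength=s.get("coupling_strength", 0.8),
            coupling_freqs=freqs,
            noise_exponent=s.get("noise_exponent", 1.0),
            noise_scale=s.get("noise_scale", 10.0),
            blink_rate=s.get("blink_rate", 12.0),
            event_schedule=events,
            seed=self.seed if seed is None else seed,
        )
        if "coupled_channel_pairs" in s:
            kwargs["coupled_channel_pairs"] = tuple(
                tuple(p) for p in s["coupled_channel_pairs"])
        return SyntheticConfig(**kwargs)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def simulate_stage(config: PipelineConfig, outdir, seed=None):
    session, truth = generate_session(config.synthetic_config(seed))
    os.makedirs(outdir, exist_ok=True)
    hio.write_session(session, os.path.join(outdir, "session.h5"))
    with open(os.path.join(outdir, "ground_truth.json"), "w") as f:
        json.dump({"coupling": [[list(d), a, b, r]
                                for d, a, b, r in truth.coupling],
                   "coupled_pairs": [list(p) for p in truth.coupled_pairs],
                   "events": [asdict(e) for e in truth.events]}, f, indent=1)
    return session, truth


def load_session(config: PipelineConfig, outdir):
    path = config.get("input", "session") or os.path.join(outdir, "session.h5")
    return hio.read_session(path)


def preprocess_stage(config: PipelineConfig, session, outdir):
    if not config.get("preprocess", "enabled", default=False):
        return session
    p = config.get("preprocess", default={})
    filt = FilterConfig(band=tuple(p.get("band", (0.1, 100.0))),
                        order=p.get("order", 4),
                        resample_to=p.get("resample_to", 250.0),
                        line_freq=p.get("line_freq", 60.0))
    h = p.get("hinf")
    hinf = HInfConfig(**h) if h else None
    out = preprocess_session(session, filt, hinf)
    hio.write_session(out, os.path.join(outdir, "preprocessed.h5"))
    return out


def features_stage(config: PipelineConfig, session, outdir):
    """Cache pairwise bispectral representations per dyad/interval."""
    channels = config.get("stats", "channels") or session.recordings[0].eeg_labels
    path = os.path.join(outdir, "features.h5")
    with h5py.File(path, "w") as f:
        f.attrs["channels"] = json.dumps(list(channels))
        for dyad in session.dyads():
            g = f.create_group("-".join(dyad))
            freqs, eo, _ = pairwise_representations(
                session, dyad, channels, channels,
                session.baseline("pre", "EO").interval, "pre-EO")
            g.attrs["freqs"] = freqs
            g.create_dataset("pre-EO", data=eo)
            for d in session.design:
                _, vals, _ = pairwise_representations(
                    session, dyad, channels, channels, d.interval,
                    f"t{d.trial}s{d.segment}")
                g.create_dataset(f"t{d.trial}s{d.segment}", data=vals)
    return path


def stats_stage(config: PipelineConfig, session, features_path, outdir):
    alpha = config.get("stats", "alpha", default=0.05)
    bands = config.get("stats", "bands", default=list(BANDS))
    results = []
    with h5py.File(features_path, "r") as f:
        channels = json.loads(f.attrs["channels"])
        alpha_c = alpha / len(channels) ** 2
        for dyad in session.dyads():
            g = f["-".join(dyad)]
            freqs = np.asarray(g.attrs["freqs"])
            eo = g["pre-EO"][()]
            for d in session.design:
                seg = g[f"t{d.trial}s{d.segment}"][()]
                for band in bands:
                    results.extend(tests_from_arrays(
                        freqs, seg, eo, channels, dyad, d.trial, d.segment,
                        band, alpha_c))
    df = results_to_frame(results)
    df.to_csv(os.path.join(outdir, "significance.csv"), index=False)
    summarize(results, ["band", "condition"], session).to_csv(
        os.path.join(outdir, "summary_band_condition.csv"), index=False)
    summarize(results, ["n_active"], session).to_csv(
        os.path.join(outdir, "summary_n_active.csv"), index=False)
    return results


def events_stage(config: PipelineConfig, session, results, outdir):
    """Event-locked SP/DP comparison per condition.

    Uses, per dyad, the most significant channel combination in the
    configured band (falling back to the smallest p if nothing survives
    correction)."""
    band = config.get("events", "band", default="gamma")
    pre = config.get("events", "pre", default=60.0)
    post = config.get("events", "post", default=60.0)
    if not session.annotations:
        return {}
    traces = {}
    for dyad in session.dyads():
        cand = [r for r in results if r.dyad == dyad and r.band == band]
        if not cand:
            continue
        best = (top_k(cand, 1) or
                [min(cand, key=lambda r: r.p_value)])[0]
        traces[dyad] = temporal_series(session, dyad, best.channel_pair, band)
    rows, comparisons = [], {}
    for condition in (PASSIVE_PASSIVE, PASSIVE_ACTIVE, ACTIVE_ACTIVE):
        sp, dp, skipped = collect_event_traces(session, traces, pre=pre,
                                               post=post, condition=condition)
        comp = compare_groups(sp, dp)
        comparisons[condition] = comp
        if comp.degenerate:
            continue
        onset = significance_onset(comp, min_run=3)
        for t, p, m in zip(comp.times, comp.p_values, comp.mask):
            rows.append({"condition": condition, "time_s": t, "p": p,
                         "significant": m, "n_sp": comp.n_sp,
                         "n_dp": comp.n_dp, "onset_s": onset})
    if rows:
        pd.DataFrame(rows).to_csv(os.path.join(outdir, "event_comparison.csv"),
                                  index=False)
    return comparisons


def roi_stage(config: PipelineConfig, session, results, outdir):
    table = config.get("roi", "table")
    roi_map = load_roi_map(table) if table else default_roi_map()
    frames = []
    for condition in (PASSIVE_PASSIVE, PASSIVE_ACTIVE, ACTIVE_ACTIVE):
        for band in config.get("stats", "bands", default=list(BANDS)):
            m = aggregate(results, roi_map, condition=condition, band=band,
                          session=session)
            df = m.to_frame()
            df.insert(0, "band", band)
            df.insert(0, "condition", condition)
            frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(os.path.join(outdir, "roi_maps.csv"), index=False)
    return out


def run(config: PipelineConfig, outdir=None, seed=None):
    """Execute the whole pipeline; returns a dict of stage artifacts."""
    outdir = outdir or config.get("output", default="hyperbispec_out")
    os.makedirs(outdir, exist_ok=True)
    provenance = {"version": __version__, "config_hash": config.config_hash(),
                  "config": config.raw, "seed": seed if seed is not None
                  else config.seed}
    stage = "simulate/ingest"
    try:
        if config.get("input", "session"):
            session = load_session(config, outdir)
        else:
            session, _ = simulate_stage(config, outdir, seed)
        stage = "preprocess"
        session = preprocess_stage(config, session, outdir)
        stage = "features"
        features = features_stage(config, session, outdir)
        stage = "stats"
        results = stats_stage(config, session, features, outdir)
        stage = "events"
        comparisons = events_stage(config, session, results, outdir)
        stage = "roi"
        roi_maps = roi_stage(config, session, results, outdir)
    except Exception:
        logger.error("pipeline failed in stage %r; partial artifacts kept "
                     "under %s", stage, outdir)
        raise
    with open(os.path.join(outdir, "provenance.json"), "w") as f:
        json.dump(provenance, f, indent=1, sort_keys=True)
    return {"session": session, "results": results,
            "comparisons": comparisons, "roi": roi_maps, "outdir": outdir}
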