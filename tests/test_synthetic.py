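"""Synthetic-data generator: spectra, determinism, coupling, artifacts."""

import numpy as np
import pytest
from numpy.fft import rfft, rfftfreq
from scipy import stats as sps

from hyperbispec.bispectrum import diagonal_cross_bispectrum, extract_windows
from hyperbispec.synthetic import (
    EventSpec,
    SyntheticConfig,
    default_trial_layout,
    generate_participant_noise,
    generate_session,
    inject_coupled_component,
    inject_eog_artifacts,
)
from hyperbispec.types import MultichannelRecording


def spectral_slope(x, fs, fmin=2.0, fmax=40.0):
    """Log-log periodogram slope averaged over channels."""
    X = np.abs(rfft(x, axis=1)) ** 2
    f = rfftfreq(x.shape[1], 1.0 / fs)
    sel = (f >= fmin) & (f <= fmax)
    return np.polyfit(np.log(f[sel]), np.log(X[:, sel].mean(axis=0)), 1)[0]


class TestParticipantNoise:
    def test_white_limit_flat_spectrum(self):
        x = generate_participant_noise(8, 60.0, 250.0, 0.0, seed=0)
        assert abs(spectral_slope(x, 250.0)) < 0.1

    def test_pink_slope_near_minus_one(self):
        x = generate_participant_noise(8, 60.0, 250.0, 1.0, seed=0)
        assert spectral_slope(x, 250.0) == pytest.approx(-1.0, abs=0.2)

    def test_zero_mean_and_scale(self):
        x = generate_participant_noise(4, 30.0, 250.0, 1.0, seed=3, scale=10.0)
        assert np.allclose(x.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(x.std(axis=1), 10.0, rtol=1e-6)

    def test_same_seed_bitwise_identical(self):
        a = generate_participant_noise(4, 10.0, 250.0, 1.0, seed=42)
        b = generate_participant_noise(4, 10.0, 250.0, 1.0, seed=42)
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("dur,fs", [(0.0, 250.0), (10.0, 0.0), (-1.0, 250.0)])
    def test_invalid_arguments(self, dur, fs):
        with pytest.raises(ValueError):
            generate_participant_noise(2, dur, fs, 1.0, seed=0)


def _tone_pair(rho, seed, T=60.0, fs=250.0, f0=35.0, noise=0.0):
    rng = np.random.default_rng(seed)
    n = int(T * fs)
    recs = [MultichannelRecording(p, ["c"], ["EEG"], fs,
                                  noise * rng.standard_normal((1, n)))
            for p in ("a", "b")]
    inject_coupled_component(recs, ("a", "b"), ("c", "c"), f0, rho,
                             (0.0, T), seed, amplitude=1.0)
    return recs


def _b_at(recs, f0=35.0):
    wa = extract_windows(recs[0], "c")
    wb = extract_windows(recs[1], "c")
    rep = diagonal_cross_bispectrum(wa, wb)
    return rep.values[np.argmin(np.abs(rep.freqs - f0))]


class TestCoupledComponent:
    def test_full_coupling_single_window_matches_triple_product(self):
        """L=1, pure tones: |B(f0)| equals the product of the three DFT
        magnitudes at f0, f0, 2f0."""
        fs, T, f0 = 250.0, 4.0, 10.0
        recs = _tone_pair(1.0, seed=5, T=T, fs=fs, f0=f0)
        wa = extract_windows(recs[0], "c")
        wb = extract_windows(recs[1], "c")
        rep = diagonal_cross_bispectrum(wa, wb)
        i = np.argmin(np.abs(rep.freqs - f0))
        i2 = np.argmin(np.abs(wa.freqs - 2 * f0))
        i1 = np.argmin(np.abs(wa.freqs - f0))
        expected = (np.abs(wa.spectra[0, i1]) * np.abs(wb.spectra[0, i1])
                    * np.abs(wb.spectra[0, i2]))
        assert rep.values[i] == pytest.approx(expected, rel=1e-9)

    def test_uncoupled_decays_like_noise_floor(self):
        """rho=0 gives an incoherent 1/sqrt(L) floor: it shrinks as the
        record grows, while the fully coupled value does not."""
        b0_short = np.mean([_b_at(_tone_pair(0.0, s, T=24.0)) for s in range(6)])
        b0_long = np.mean([_b_at(_tone_pair(0.0, s, T=240.0)) for s in range(6)])
        b1_long = np.mean([_b_at(_tone_pair(1.0, s, T=240.0)) for s in range(6)])
        assert b0_long < 0.55 * b0_short       # floor decays with L
        assert b0_long < 0.3 * b1_long         # coupled value persists

    def test_monotone_in_rho_rank_test(self):
        """Mean |B(f0,f0)| increases with rho (Kendall rank test over a
        grid of rho values, many short realizations)."""
        rhos = [0.0, 0.25, 0.5, 0.75, 1.0]
        xs, ys = [], []
        for rho in rhos:
            vals = [_b_at(_tone_pair(rho, seed=100 + r, T=24.0))
                    for r in range(20)]
            xs += [rho] * len(vals)
            ys += vals
            if rho > 0:
                assert np.mean(vals) > prev_mean or rho <= 0.25
            prev_mean = np.mean(vals)
        tau = sps.kendalltau(xs, ys)
        assert tau.statistic > 0
        assert tau.pvalue < 0.01

    def test_interval_and_nyquist_validation(self):
        recs = _tone_pair(0.5, seed=0, T=10.0)
        with pytest.raises(IndexError):
            inject_coupled_component(recs, ("a", "b"), ("c", "c"), 10.0,
                                     0.5, (5.0, 20.0), 0)
        with pytest.raises(ValueError):
            inject_coupled_component(recs, ("a", "b"), ("c", "c"), 80.0,
                                     0.5, (0.0, 10.0), 0)

    def test_missing_channel(self):
        recs = _tone_pair(0.5, seed=0, T=10.0)
        with pytest.raises(KeyError):
            inject_coupled_component(recs, ("a", "b"), ("c", "nope"), 10.0,
                                     0.5, (0.0, 10.0), 0)


class TestEogArtifacts:
    def _recording(self, seed=0, T=60.0, fs=250.0):
        labels = ["Fp1", "Fz", "Oz", "PO9", "PO10"]
        kinds = ["EEG", "EEG", "EEG", "EOG", "EOG"]
        rng = np.random.default_rng(seed)
        rec = MultichannelRecording(
            "P1", labels, kinds, fs, 2.0 * rng.standard_normal((5, int(T * fs))),
            meta={"eog_roles": {"PO9": "veog", "PO10": "veog"}})
        return rec

    def test_zero_rate_is_identity(self):
        rec = self._recording()
        out, mixing, onsets = inject_eog_artifacts(rec, 0.0, seed=1)
        assert np.array_equal(out.data, rec.data)
        assert len(onsets) == 0

    def test_blink_count_poisson_consistent(self):
        """Threshold-detected blink count on the vertical EOG channel
        matches the Poisson draw recorded in the ground truth."""
        rec = self._recording()
        out, _, onsets = inject_eog_artifacts(rec, 12.0, seed=2)
        v = out.data[3] - rec.data[3]
        above = v > 75.0
        n_pulses = np.sum(np.diff(above.astype(int)) == 1)
        assert n_pulses == len(onsets)
        assert 12 - 4 * np.sqrt(12) <= len(onsets) <= 12 + 4 * np.sqrt(12)

    def test_frontal_mixing_exceeds_occipital(self):
        rec = self._recording()
        out, mixing, onsets = inject_eog_artifacts(rec, 20.0, seed=3)
        assert mixing["Fp1"] > mixing["Oz"]
        art = out.data - rec.data
        assert np.sum(art[0] ** 2) > np.sum(art[2] ** 2)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            inject_eog_artifacts(self._recording(), -1.0, seed=0)


class TestSession:
    def test_default_layout_design(self):
        """Default design: 9 (trial, segment) intervals, each participant
        first-active exactly once, active sets growing within a trial."""
        layout = default_trial_layout()
        assert len(layout) == 9
        first = [sorted(active)[0] if len(active) == 1 else None
                 for _, seg, active, _ in layout if seg == 1]
        firsts = [sorted(a)[0] for t, s, a, _ in layout if s == 1]
        assert sorted(firsts) == ["P1", "P2", "P3"]
        for trial in (1, 2, 3):
            sizes = [len(a) for t, s, a, _ in layout if t == trial]
            assert sizes == [1, 2, 3]

    def test_event_step_at_lead_time(self):
        """An SP event at 320 s with lead_time 3 steps rho at 317 s."""
        ev = EventSpec("SP", 320.0, rho_delta=0.2, lead_time=3.0,
                       duration=10.0)
        cfg = SyntheticConfig(
            n_participants=2, n_eeg_channels=16, fs=250.0,
            trial_layout=[(1, 1, {"P1", "P2"}, 300.0)],
            coupling_strength=0.5, blink_rate=0.0,
            event_schedule=(ev,), seed=0)
        session, truth = generate_session(cfg)
        d = ("P1", "P2")
        assert truth.rho_at(d, 316.9) == pytest.approx(0.5)
        assert truth.rho_at(d, 317.1) == pytest.approx(0.7)
        assert truth.rho_at(d, 327.1) == pytest.approx(0.5)

    def test_event_outside_session_rejected(self):
        ev = EventSpec("SP", 1e6)
        cfg = SyntheticConfig(n_participants=2, n_eeg_channels=16, fs=250.0,
                              trial_layout=[(1, 1, {"P1", "P2"}, 60.0)],
                              event_schedule=(ev,), seed=0)
        with pytest.raises(IndexError):
            generate_session(cfg)

    def test_determinism_same_config_same_bytes(self):
        cfg = dict(n_participants=2, n_eeg_channels=16, fs=250.0,
                   trial_layout=[(1, 1, {"P1", "P2"}, 20.0)],
                   baseline_duration=8.0, coupling_strength=0.6,
                   blink_rate=10.0, seed=99)
        s1, _ = generate_session(SyntheticConfig(**cfg))
        s2, _ = generate_session(SyntheticConfig(**cfg))
        for r1, r2 in zip(s1.recordings, s2.recordings):
            assert np.array_equal(r1.data, r2.data)

    def test_null_session_cross_correlation(self):
        """With rho(t)=0 everywhere (here: no active-active segment, so the
        tone combs stay incoherent), cross-participant channels satisfy the
        3/sqrt(N) correlation bound at the tested lags.  White background is
        used so the bound's independence sampling theory applies."""
        cfg = SyntheticConfig(n_participants=2, n_eeg_channels=16, fs=250.0,
                              trial_layout=[(1, 1, {"P1"}, 30.0)],
                              baseline_duration=10.0, coupling_strength=0.5,
                              noise_exponent=0.0, blink_rate=0.0, seed=5)
        session, truth = generate_session(cfg)
        assert truth.rho_at(("P1", "P2"), 25.0) == 0.0
        ia = session.recordings[0].channel_index("T7")
        ib = session.recordings[1].channel_index("Oz")
        x = session.recordings[0].data[ia]
        y = session.recordings[1].data[ib]
        n = len(x)
        bound = 3.0 / np.sqrt(n)
        for lag in (0, 10, 100):
            r = np.corrcoef(x[: n - lag], y[lag:])[0, 1]
            assert abs(r) < bound

    def test_ground_truth_tiles_session(self):
        cfg = SyntheticConfig(n_participants=3, n_eeg_channels=16, fs=250.0,
                              trial_layout=default_trial_layout(
                                  segment_duration=20.0),
                              baseline_duration=8.0, coupling_strength=0.7,
                              blink_rate=0.0, seed=1)
        session, truth = generate_session(cfg)
        for dyad in session.dyads():
            pieces = sorted((a, b) for d, a, b, _ in truth.coupling
                            if tuple(sorted(d)) == tuple(sorted(dyad)))
            assert pieces[0][0] == 0.0
            assert pieces[-1][1] == pytest.approx(session.duration)
            for (a0, a1), (b0, b1) in zip(pieces, pieces[1:]):
                assert a1 == pytest.approx(b0)

    def test_reused_coupled_channel_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_participants=2, n_eeg_channels=16,
                            coupled_channel_pairs=(("T7", "Oz"),
                                                   ("T7", "O1")))
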