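"""Diagonal cross-bispectrum estimator: oracle equivalence, invariances,
normalization identities and band bookkeeping."""

import numpy as np
import pytest
from numpy.fft import rfft, rfftfreq

from hyperbispec.bispectrum import (
    BANDS,
    band_average,
    band_bins,
    baseline_representation,
    diagonal_cross_bispectrum,
    extract_windows,
    normalize,
    pairwise_representations,
    segment_representation,
    summary_grid,
    temporal_series,
    window_starts,
)
from hyperbispec.errors import AlignmentError, EmptyWindowError
from hyperbispec.synthetic import SyntheticConfig, generate_session

from conftest import make_recording


def naive_diagonal_bispectrum(xa, xb, fs, window_s=4.0, step_s=1.0,
                              low=1.0, high=50.0):
    """Three-nested-loop reference implementation of the windowed diagonal
    cross-bispectrum (independent oracle for the vectorized estimator)."""
    nwin = int(round(window_s * fs))
    step = int(round(step_s * fs))
    freqs = rfftfreq(nwin, 1.0 / fs)
    starts = list(range(0, len(xa) - nwin + 1, step))
    sel = [k for k, f in enumerate(freqs)
           if low - 1e-9 <= f <= high + 1e-9 and 2 * k < len(freqs)]
    out = np.zeros(len(sel))
    for m, k in enumerate(sel):
        acc = 0.0 + 0.0j
        for s in starts:
            Xa = rfft(xa[s:s + nwin])
            Xb = rfft(xb[s:s + nwin])
            acc += Xa[k] * Xb[k] * np.conj(Xb[2 * k])
        out[m] = abs(acc / len(starts))
    return np.array([freqs[k] for k in sel]), out


class TestWindows:
    @pytest.mark.parametrize("T,expected", [(300.0, 297), (4.0, 1), (5.0, 2)])
    def test_window_count(self, T, expected):
        starts, dropped = window_starts((0.0, T))
        assert len(starts) == expected

    def test_masked_windows_dropped(self):
        starts, dropped = window_starts((0.0, 30.0), masked=[(10.0, 12.0)])
        kept = set(np.round(starts).astype(int))
        # windows overlapping [10, 12) start anywhere in (6, 12)
        assert kept == set(range(27)) - {7, 8, 9, 10, 11}
        assert len(dropped) == 5

    def test_zero_length_mask_is_noop(self):
        a, _ = window_starts((0.0, 30.0))
        b, _ = window_starts((0.0, 30.0), masked=[(10.0, 10.0)])
        assert np.array_equal(a, b)

    def test_short_interval_raises(self, rng):
        rec = make_recording(rng.standard_normal((1, 500)))
        with pytest.raises(EmptyWindowError):
            extract_windows(rec, "ch0")

    def test_tone_peaks_at_its_bin(self, rng):
        fs, f0 = 250.0, 10.0
        t = np.arange(int(20 * fs)) / fs
        rec = make_recording([np.cos(2 * np.pi * f0 * t)], fs=fs)
        ws = extract_windows(rec, "ch0")
        peak_bins = np.abs(ws.spectra).argmax(axis=1)
        assert np.all(ws.freqs[peak_bins] == f0)


class TestEstimator:
    def test_zero_signals_give_zero(self):
        rec_a = make_recording(np.zeros((1, 2000)), pid="A")
        rec_b = make_recording(np.zeros((1, 2000)), pid="B")
        rep = diagonal_cross_bispectrum(extract_windows(rec_a, "ch0"),
                                        extract_windows(rec_b, "ch0"))
        assert np.all(rep.values == 0)

    def test_matches_naive_oracle(self, rng):
        """Vectorized estimator equals the three-loop oracle to 1e-10
        relative on short noise signals."""
        fs = 128.0  # 512-sample windows
        xa = rng.standard_normal(int(10 * fs))
        xb = rng.standard_normal(int(10 * fs))
        f_o, v_o = naive_diagonal_bispectrum(xa, xb, fs)
        rep = diagonal_cross_bispectrum(
            extract_windows(make_recording([xa], fs=fs, pid="A"), "ch0"),
            extract_windows(make_recording([xb], fs=fs, pid="B"), "ch0"))
        keep = np.isin(np.round(rep.freqs * 8), np.round(f_o * 8))
        assert np.allclose(rep.values[keep], v_o, rtol=1e-10)

    def test_pairwise_matches_per_pair(self, small_coupled_session):
        session, _ = small_coupled_session
        seg = session.segment(1, 1)
        chans = ["T7", "Oz", "Fz"]
        freqs, vals, L = pairwise_representations(
            session, ("P1", "P2"), chans, chans, seg.interval, "t1s1")
        for i, ca in enumerate(chans):
            for j, cb in enumerate(chans):
                rep = segment_representation(session, ("P1", "P2"),
                                             (ca, cb), 1, 1)
                assert np.allclose(vals[i, j], rep.values, rtol=1e-12)

    def test_time_shift_invariance(self, rng):
        """Circularly shifting both periodic signals by the same lag leaves
        every diagonal magnitude unchanged (phase closure f + f - 2f = 0)."""
        fs = 250.0
        n = int(12 * fs)
        # periodic signals: sum of on-grid tones so circular shift is exact
        t = np.arange(n) / fs
        xa = sum(np.cos(2 * np.pi * f * t + p)
                 for f, p in [(10, 0.3), (17, 1.1), (35, 2.0)])
        xb = sum(np.cos(2 * np.pi * f * t + p)
                 for f, p in [(10, 0.9), (20, 0.2), (34, 1.7)])
        shift = 250  # 1 s: window set maps onto itself for periodic input
        rep0 = diagonal_cross_bispectrum(
            extract_windows(make_recording([xa], fs=fs, pid="A"), "ch0"),
            extract_windows(make_recording([xb], fs=fs, pid="B"), "ch0"))
        rep1 = diagonal_cross_bispectrum(
            extract_windows(make_recording([np.roll(xa, shift)], fs=fs,
                                           pid="A"), "ch0"),
            extract_windows(make_recording([np.roll(xb, shift)], fs=fs,
                                           pid="B"), "ch0"))
        np.testing.assert_allclose(rep1.values, rep0.values, rtol=1e-9,
                                   atol=1e-9 * rep0.values.max())

    def test_scaling_laws(self, rng):
        """Scaling participant a by alpha scales |B| by alpha; scaling
        participant b by beta scales |B| by beta^2 (declared convention)."""
        fs = 250.0
        xa = rng.standard_normal(int(8 * fs))
        xb = rng.standard_normal(int(8 * fs))
        def rep_of(a, b):
            return diagonal_cross_bispectrum(
                extract_windows(make_recording([a], fs=fs, pid="A"), "ch0"),
                extract_windows(make_recording([b], fs=fs, pid="B"), "ch0")
            ).values
        base = rep_of(xa, xb)
        np.testing.assert_allclose(rep_of(3.0 * xa, xb), 3.0 * base,
                                   rtol=1e-9)
        np.testing.assert_allclose(rep_of(xa, 2.0 * xb), 4.0 * base,
                                   rtol=1e-9)

    def test_dyad_order_matters(self, small_coupled_session):
        """The factor convention is asymmetric: (a,b) and (b,a) differ."""
        session, _ = small_coupled_session
        r_ab = segment_representation(session, ("P1", "P2"), ("T7", "Oz"), 1, 1)
        r_ba = segment_representation(session, ("P2", "P1"), ("T7", "Oz"), 1, 1)
        assert not np.allclose(r_ab.values, r_ba.values)

    def test_misaligned_windows_rejected(self, rng):
        fs = 250.0
        ra = make_recording(rng.standard_normal((1, int(8 * fs))), fs=fs, pid="A")
        rb = make_recording(rng.standard_normal((1, int(12 * fs))), fs=fs, pid="B")
        with pytest.raises(AlignmentError):
            diagonal_cross_bispectrum(extract_windows(ra, "ch0"),
                                      extract_windows(rb, "ch0"))

    def test_gaussian_floor_below_coupled_value(self, rng):
        """Independent Gaussian inputs give a mean magnitude well below a
        fully phase-coupled signal of the same power."""
        fs, f0, T = 250.0, 20.0, 104.0
        t = np.arange(int(T * fs)) / fs
        xa = np.cos(2 * np.pi * f0 * t)
        xb = np.cos(2 * np.pi * f0 * t) + np.cos(2 * np.pi * 2 * f0 * t)
        coupled = diagonal_cross_bispectrum(
            extract_windows(make_recording([xa], fs=fs, pid="A"), "ch0"),
            extract_windows(make_recording([xb], fs=fs, pid="B"), "ch0"))
        i = np.argmin(np.abs(coupled.freqs - f0))
        ga = np.std(xa) * rng.standard_normal(len(t))
        gb = np.std(xb) * rng.standard_normal(len(t))
        gauss = diagonal_cross_bispectrum(
            extract_windows(make_recording([ga], fs=fs, pid="A"), "ch0"),
            extract_windows(make_recording([gb], fs=fs, pid="B"), "ch0"))
        assert gauss.values[i] < 0.1 * coupled.values[i]


class TestNormalization:
    def test_identity_when_equal(self, small_coupled_session):
        session, _ = small_coupled_session
        eo = baseline_representation(session, ("P1", "P2"), ("T7", "Oz"))
        norm = normalize(eo, eo)
        assert np.allclose(norm.values[norm.valid], 0.0)

    def test_thirty_percent_change(self, small_coupled_session):
        """BS_seg = 1.3 x BS_EO reads as +0.3 on the normalized scale."""
        import copy
        session, _ = small_coupled_session
        eo = baseline_representation(session, ("P1", "P2"), ("T7", "Oz"))
        seg = copy.deepcopy(eo)
        seg.values = 1.3 * seg.values
        norm = normalize(seg, eo)
        assert np.allclose(norm.values[norm.valid], 0.3)
        for band in BANDS:
            assert band_average(norm, band) == pytest.approx(0.3)

    def test_zero_baseline_bins_flagged_not_divided(self, small_coupled_session):
        import copy
        session, _ = small_coupled_session
        eo = baseline_representation(session, ("P1", "P2"), ("T7", "Oz"))
        eo0 = copy.deepcopy(eo)
        eo0.values = eo0.values.copy()
        eo0.values[5] = 0.0
        norm = normalize(eo, eo0)
        assert not norm.valid[5]
        assert np.isnan(norm.values[5])
        assert np.isfinite(norm.values[norm.valid]).all()

    def test_axis_mismatch_rejected(self, small_coupled_session):
        session, _ = small_coupled_session
        eo = baseline_representation(session, ("P1", "P2"), ("T7", "Oz"))
        other = baseline_representation(session, ("P1", "P2"), ("T7", "O1"))
        with pytest.raises(AlignmentError):
            normalize(other, eo)


class TestBands:
    def test_native_bin_counts_match_band_widths(self):
        """16/16/20/68/82 native 0.25 Hz bins for delta..gamma."""
        freqs = np.arange(1.0, 50.0 + 1e-9, 0.25)
        assert len(freqs) == 197
        counts = {name: int(band_bins(freqs, name).sum()) for name in BANDS}
        assert counts == {"delta": 16, "theta": 16, "alpha": 20,
                          "beta": 68, "gamma": 82}

    def test_summary_grid_has_fifty_bins(self):
        freqs = np.arange(1.0, 50.0 + 1e-9, 0.25)
        centers, coarse = summary_grid(freqs, np.ones_like(freqs))
        assert len(centers) == 50
        assert centers[0] == 1.0 and centers[-1] == 50.0
        assert np.allclose(coarse, 1.0)

    def test_uniform_value_averages_to_itself(self):
        freqs = np.arange(1.0, 50.0 + 1e-9, 0.25)
        from hyperbispec.bispectrum import NormalizedBispectrum
        norm = NormalizedBispectrum(("a", "b"), ("x", "y"), "s", "eo",
                                    freqs, np.full(197, 0.17),
                                    np.ones(197, bool))
        for band in BANDS:
            assert band_average(norm, band) == pytest.approx(0.17)


class TestTemporalSeries:
    def test_time_axis_step_and_span(self, small_coupled_session):
        session, _ = small_coupled_session
        trace = temporal_series(session, ("P1", "P2"), ("T7", "Oz"), "gamma")
        assert np.allclose(np.diff(trace.times), 1.0)
        seg = session.segment(1, 1)
        assert trace.times[0] == pytest.approx(seg.interval[0] + 2.0)

    def test_rho_step_raises_trace_mean(self):
        """Stepping the coupled-component amplitude mid-segment separates
        the before/after trace means."""
        from hyperbispec.synthetic import EventSpec
        ev = EventSpec("SP", 240.0, rho_delta=0.5, lead_time=3.0,
                       duration=100.0, amp_delta=0.8)
        cfg = SyntheticConfig(
            n_participants=2, n_eeg_channels=16, fs=250.0,
            trial_layout=[(1, 1, {"P1", "P2"}, 240.0)],
            coupling_strength=0.3, coupled_channel_pairs=(("T7", "Oz"),),
            event_schedule=(ev,), blink_rate=0.0, seed=3)
        session, _ = generate_session(cfg)
        trace = temporal_series(session, ("P1", "P2"), ("T7", "Oz"), "gamma")
        before = trace.values[trace.times < 230.0]
        after = trace.values[trace.times > 245.0]
        assert after.mean() > before.mean()

    def test_trace_mean_tracks_segment_estimate(self, small_coupled_session):
        """For stationary input the trace fluctuates around a stable level:
        halves of the trace agree within Monte-Carlo tolerance."""
        session, _ = small_coupled_session
        trace = temporal_series(session, ("P1", "P2"), ("T7", "Oz"), "gamma")
        h = len(trace.values) // 2
        m1, m2 = trace.values[:h].mean(), trace.values[h:].mean()
        spread = trace.values.std()
        assert abs(m1 - m2) < spread
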