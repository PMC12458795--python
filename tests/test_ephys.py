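"""Slice-ephys metrics: spikes, resistance, clustering, dip, PSC detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hierkit import ephys, synthio
from hierkit._dip import dip_statistic


# ---------------------------------------------------------------------------
# FI curves and input resistance
# ---------------------------------------------------------------------------


def spike_train_mV(rate_hz, duration_s, fs, width_ms=1.0, rest=-65.0, peak=30.0):
    """Regular spiking voltage trace crossing 0 mV at the given rate."""
    v = np.full(int(duration_s * fs), rest)
    w = int(width_ms / 1000 * fs)
    for t in np.arange(0, duration_s, 1.0 / rate_hz):
        i = int(t * fs)
        v[i : i + w] = peak
    return v


class TestFICurve:
    def test_subthreshold_sweeps_all_zero(self):
        fs = 20_000.0
        sweeps = [np.full(int(0.5 * fs), -60.0) for _ in range(3)]
        df = ephys.fi_curve([0, 50, 100], sweeps, fs)
        assert (df["rate_hz"] == 0).all()

    def test_regular_spiker_rate_recovered(self):
        fs = 20_000.0
        v = spike_train_mV(40.0, 0.5, fs)
        df = ephys.fi_curve([100.0], [v], fs)
        assert df["rate_hz"].iloc[0] == pytest.approx(40.0, abs=2.0)

    def test_rate_invariant_to_step_duration(self):
        fs = 20_000.0
        short = spike_train_mV(40.0, 0.5, fs)
        long = spike_train_mV(40.0, 1.0, fs)
        df = ephys.fi_curve([100.0, 100.0], [short, long], fs)
        assert df["rate_hz"].iloc[0] == pytest.approx(df["rate_hz"].iloc[1], abs=1.0)

    def test_refractory_guard_blocks_double_counting(self):
        fs = 20_000.0
        v = np.full(2000, -65.0)
        v[100:105] = 30.0
        v[108:112] = 30.0  # bounce within 2 ms refractory
        assert ephys.count_spikes(v, fs) == 1

    def test_empty_protocol_rejected(self):
        with pytest.raises(ValueError):
            ephys.fi_curve([], [], 10_000.0)


class TestInputResistance:
    def _trace(self, delta_i_pA, fs=20_000.0, tau_s=0.0):
        i = np.zeros(int(0.06 * fs))
        step = slice(int(0.02 * fs), int(0.04 * fs))
        t = np.arange(int(0.02 * fs)) / fs
        transient = np.exp(-t / tau_s) if tau_s > 0 else np.zeros_like(t)
        i[step] = delta_i_pA * (1 + 3 * transient)
        return i

    @pytest.mark.parametrize("di, expected", [(-20.0, 500.0), (-100.0, 100.0)])
    def test_ohms_law(self, di, expected):
        r = ephys.input_resistance(
            self._trace(di), 20_000.0, (0.02, 0.04), (0.0, 0.02), delta_v_mV=-10.0
        )
        assert r == pytest.approx(expected)

    def test_rc_cell_recovered_within_two_percent(self):
        # simulated RC response: capacitive transient decays before plateau
        r = ephys.input_resistance(
            self._trace(-20.0, tau_s=0.002), 20_000.0, (0.02, 0.04), (0.0, 0.02),
            delta_v_mV=-10.0,
        )
        assert r == pytest.approx(500.0, rel=0.02)

    def test_open_circuit_rejected(self):
        with pytest.raises(ValueError, match="open circuit"):
            ephys.input_resistance(np.zeros(1200), 20_000.0, (0.02, 0.04), (0.0, 0.02))


# ---------------------------------------------------------------------------
# excitability clustering and bimodality
# ---------------------------------------------------------------------------


class TestClusterNeurons:
    def _blobs(self, n1=37, n2=23, seed=0):
        rng = np.random.default_rng(seed)
        rates = np.concatenate([rng.normal(40, 5, n1), rng.normal(90, 5, n2)])
        rins = np.concatenate([rng.normal(300, 30, n1), rng.normal(700, 30, n2)])
        return rates, rins

    def test_separated_blobs_perfectly_assigned(self):
        rates, rins = self._blobs()
        labels, ratio = ephys.cluster_neurons(rates, rins, seed=0)
        assert (labels[:37] == 1).all() and (labels[37:] == 2).all()
        assert ratio == pytest.approx(23 / 37)

    def test_cluster_one_is_low_resistance_by_definition(self):
        rates, rins = self._blobs(seed=3)
        labels, _ = ephys.cluster_neurons(rates, rins, seed=5)
        assert rins[labels == 1].mean() < rins[labels == 2].mean()

    def test_assignment_invariant_to_feature_scaling(self):
        rates, rins = self._blobs(seed=1)
        l1, _ = ephys.cluster_neurons(rates, rins, seed=0)
        l2, _ = ephys.cluster_neurons(rates * 1000, rins * 0.001, seed=0)
        np.testing.assert_array_equal(l1, l2)

    def test_identical_features_degenerate(self):
        labels, ratio = ephys.cluster_neurons(np.full(5, 40.0), np.full(5, 300.0))
        assert (labels == 1).all() and ratio == 0.0

    def test_nonfinite_features_rejected(self):
        with pytest.raises(ValueError):
            ephys.cluster_neurons([40, np.nan], [300, 400])


def dip_lp_oracle(x):
    """Direct LP minimization of sup|F_n - G| over unimodal CDFs.

    Independent re-derivation used to validate the packaged statistic on
    small samples: for each candidate mode support, build the convex/concave
    piece constraints explicitly and minimize the error bound with HiGHS.
    """
    from scipy.optimize import linprog

    n = len(x)
    xs_all = np.sort(np.asarray(x, float))
    xs, first = np.unique(xs_all, return_index=True)
    counts = np.diff(np.append(first, n))
    a = first / n
    b = (first + counts) / n
    m = len(xs)
    if m == 1:
        return 0.0
    best = np.inf
    for s in range(m):
        nL = s + 1
        nv = nL + (m - s) + 1
        ie = nv - 1
        rows, ub = [], []

        def add(coefs, rhs):
            row = np.zeros(nv)
            for v, c in coefs:
                row[v] += c
            rows.append(row)
            ub.append(rhs)

        for k in range(s + 1):  # left piece tube (junction: left ecdf limit)
            hi = a[k] if k < s else a[s]
            lo = b[k] if k < s else a[s]
            add([(k, 1), (ie, -1)], hi)
            add([(k, -1), (ie, -1)], -lo)
        for k in range(s, m):  # right piece tube (junction: right ecdf value)
            hi = a[k] if k > s else b[s]
            add([(nL + k - s, 1), (ie, -1)], hi)
            add([(nL + k - s, -1), (ie, -1)], -b[k])
        for k in range(s):
            add([(k, 1), (k + 1, -1)], 0)
        add([(s, 1), (nL, -1)], 0)  # mode atom jumps up only
        for k in range(s, m - 1):
            add([(nL + k - s, 1), (nL + k + 1 - s, -1)], 0)
        for k in range(1, s):  # convexity
            d1, d2 = xs[k] - xs[k - 1], xs[k + 1] - xs[k]
            add([(k - 1, -d2), (k, d1 + d2), (k + 1, -d1)], 0)
        for k in range(s + 1, m - 1):  # concavity
            d1, d2 = xs[k] - xs[k - 1], xs[k + 1] - xs[k]
            add([(nL + k - 1 - s, d2), (nL + k - s, -(d1 + d2)), (nL + k + 1 - s, d1)], 0)
        c = np.zeros(nv)
        c[ie] = 1.0
        res = linprog(c, A_ub=np.array(rows), b_ub=np.array(ub),
                      bounds=[(0, 1)] * nv, method="highs")
        if res.success:
            best = min(best, res.fun)
    return best


class TestDip:
    def test_equally_spaced_sample_gives_half_over_n(self):
        for n in (8, 20, 50):
            assert dip_statistic(np.arange(n) / n) == pytest.approx(1 / (2 * n))

    def test_two_point_masses_approach_quarter(self):
        x = np.array([0.0] * 50 + [1.0] * 50)
        assert dip_statistic(x) == pytest.approx(0.25)

    def test_constant_sample_is_unimodal(self):
        assert dip_statistic(np.ones(8)) == 0.0

    def test_matches_lp_oracle_on_small_samples(self):
        rng = np.random.default_rng(0)
        for trial in range(24):
            n = int(rng.integers(4, 16))
            kind = trial % 4
            if kind == 0:
                x = rng.normal(size=n)
            elif kind == 1:
                x = np.concatenate([rng.normal(-4, 0.5, n // 2), rng.normal(4, 0.5, n - n // 2)])
            elif kind == 2:
                x = rng.uniform(size=n)
            else:
                x = np.round(rng.normal(size=n) * 2) / 2  # ties
            assert dip_statistic(x) == pytest.approx(dip_lp_oracle(x), abs=1e-9)

    def test_invariant_to_affine_rescaling(self):
        # the dip is invariant to location/scale changes of the values (a
        # nonlinear monotone map changes spacings, hence the dip)
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        d = dip_statistic(x)
        assert dip_statistic(3 * x - 7) == pytest.approx(d, abs=1e-12)
        assert dip_statistic(-x) == pytest.approx(d, abs=1e-12)

    def test_unimodal_sample_not_flagged(self):
        rng = np.random.default_rng(2)
        d, p = ephys.dip_bimodality(rng.normal(size=60), n_boot=200, seed=3)
        assert p > 0.1

    def test_well_separated_mixture_flagged(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(-3, 1, 30), rng.normal(3, 1, 30)])
        d, p = ephys.dip_bimodality(x, n_boot=200, seed=5)
        assert p < 0.01

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            dip_statistic(np.array([1.0, 2.0, 3.0]))


# ---------------------------------------------------------------------------
# PSC detection and charge
# ---------------------------------------------------------------------------


class TestPSCDetection:
    def test_noiseless_single_event_exact(self):
        fs = 20_000.0
        trace = np.zeros(int(1.0 * fs))
        kern = synthio.psc_kernel(fs, 0.5, 2.0)
        i0 = int(0.4 * fs)
        trace[i0 : i0 + len(kern)] -= 15.0 * kern  # excitatory, negative-going
        events = ephys.detect_psc_events(trace, fs, apply_filters=False)
        assert len(events) == 1
        assert events[0].time_s == pytest.approx(0.4, abs=5e-4)
        assert events[0].amplitude_pA == pytest.approx(15.0, rel=0.02)

    def test_recall_and_amplitude_at_high_snr(self):
        trace, truth = synthio.simulate_psc_trace(
            duration_s=60.0, fs=20_000.0, event_rate=2.0, amp_mean=20.0, amp_sd=2.0,
            noise_sd=2.0, seed=0)
        events = ephys.detect_psc_events(trace, 20_000.0)
        det = np.array([e.time_s for e in events])
        matched, amp_err = 0, []
        for t, a in zip(truth.event_times, truth.event_amplitudes):
            if len(det) and np.min(np.abs(det - t)) < 0.005:
                matched += 1
                amp_err.append(events[int(np.argmin(np.abs(det - t)))].amplitude_pA / a)
        assert matched / len(truth.event_times) >= 0.95
        assert abs(np.mean(amp_err) - 1.0) < 0.10  # amplitude bias < 10%

    def test_false_positive_rate_below_one_per_minute(self):
        minutes, fp = 0.0, 0
        for seed in range(30):
            noise, _ = synthio.simulate_psc_trace(
                duration_s=10.0, fs=20_000.0, event_rate=0.0, noise_sd=2.0, seed=seed)
            fp += len(ephys.detect_psc_events(noise, 20_000.0))
            minutes += 10.0 / 60.0
        assert fp / minutes < 1.0

    def test_amplitudes_scale_linearly(self):
        trace, _ = synthio.simulate_psc_trace(duration_s=10.0, fs=20_000.0, seed=3)
        e1 = ephys.detect_psc_events(trace, 20_000.0)
        e2 = ephys.detect_psc_events(2.0 * trace, 20_000.0)
        a1 = np.array(sorted(e.amplitude_pA for e in e1))
        a2 = np.array(sorted(e.amplitude_pA for e in e2))
        if len(a1) == len(a2):
            np.testing.assert_allclose(a2, 2.0 * a1, rtol=0.05)

    def test_template_longer_than_trace_rejected(self):
        with pytest.raises(ValueError, match="template"):
            ephys.detect_psc_events(np.zeros(10), 20_000.0)

    def test_inhibitory_polarity_uses_positive_events(self):
        trace, truth = synthio.simulate_psc_trace(
            duration_s=20.0, fs=20_000.0, polarity="inhibitory",
            rise_ms=1.0, decay_ms=3.0, seed=4)
        events = ephys.detect_psc_events(trace, 20_000.0, polarity="inhibitory")
        assert len(events) >= 0.9 * len(truth.event_times)
        assert all(e.amplitude_pA > 0 for e in events)


class TestCharge:
    def test_rectangular_pulse_charge(self):
        # 10 pA for 100 ms -> 1 pC
        fs = 10_000.0
        trace = np.zeros(int(fs))
        trace[: int(0.1 * fs)] = 10.0
        assert ephys.trace_charge(trace, fs) == pytest.approx(1.0)

    def test_no_events_all_zero_series(self):
        df = ephys.charge_transfer([], duration_s=180.0)
        assert (df["charge_pC"] == 0).all() and (df["cumulative_pC"] == 0).all()

    def test_event_charges_match_trace_integral(self):
        trace, _ = synthio.simulate_psc_trace(
            duration_s=30.0, fs=20_000.0, event_rate=1.0, noise_sd=0.0, seed=5)
        events = ephys.detect_psc_events(trace, 20_000.0, apply_filters=False)
        total_events = sum(e.charge_pC for e in events)
        total_trace = ephys.trace_charge(trace, 20_000.0)
        assert total_events == pytest.approx(total_trace, rel=0.15)

    def test_cumulative_is_running_sum(self):
        ev = [ephys.PSCEvent(10.0, 5.0, 0.5, "excitatory"),
              ephys.PSCEvent(70.0, 5.0, 0.7, "excitatory")]
        df = ephys.charge_transfer(ev, 120.0)
        assert df["cumulative_pC"].tolist() == pytest.approx([0.5, 1.2])


# ---------------------------------------------------------------------------
# paired pulse, TRPM3, IV, white noise
# ---------------------------------------------------------------------------


class TestPairedPulse:
    def test_facilitation_example(self):
        pp = ephys.paired_pulse([100, 120, 130, 135, 140])
        assert pp.ratios == pytest.approx([1, 1.2, 1.3, 1.35, 1.4])
        assert pp.regime == "facilitation"

    def test_depression_example(self):
        pp = ephys.paired_pulse([100, 80, 70, 65, 60])
        assert pp.ratios == pytest.approx([1, 0.8, 0.7, 0.65, 0.6])
        assert pp.regime == "depression"

    def test_equal_amplitudes_boundary_flagged(self):
        pp = ephys.paired_pulse([50.0] * 5)
        assert pp.regime == "mixed"
        assert pp.ratios == pytest.approx([1.0] * 5)

    @given(st.lists(st.floats(0.1, 1e4), min_size=5, max_size=5))
    @settings(max_examples=100, derandomize=True)
    def test_first_ratio_always_exactly_one(self, amps):
        assert ephys.paired_pulse(amps).ratios[0] == 1.0

    def test_wrong_length_or_zero_rejected(self):
        with pytest.raises(ValueError):
            ephys.paired_pulse([1.0, 2.0])
        with pytest.raises(ValueError):
            ephys.paired_pulse([0.0, 1, 1, 1, 1])


class TestTRPM3:
    @pytest.mark.parametrize("c, a, expected", [(100, 75, 0.25), (80, 80, 0.0), (60, 0, 1.0)])
    def test_formula(self, c, a, expected):
        assert ephys.trpm3_fraction(c, a) == pytest.approx(expected)

    def test_potentiation_gives_negative_fraction(self):
        assert ephys.trpm3_fraction(100, 120) == pytest.approx(-0.2)

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError):
            ephys.trpm3_fraction(0.0, 10.0)


class TestIVPeak:
    GRID = np.arange(-110, 31, 5.0)

    def _ohmic(self, fs=10_000.0, g=0.5):
        traces = []
        for v in self.GRID:
            i = np.full(int(0.05 * fs), g * (v - -70.0))
            i[:5] += 500.0  # capacitive transient inside blanking window
            traces.append(i)
        return traces

    def test_ohmic_model_linear(self):
        iv = ephys.iv_peak(self.GRID, self._ohmic(), 10_000.0)
        slope = np.polyfit(iv.voltages_mV, iv.peaks_pA, 1)[0]
        assert slope == pytest.approx(0.5, rel=1e-6)

    def test_planted_conductance_peak_found(self):
        # voltage-gated conductance with reversal at +30 mV: activation rises
        # with depolarization while driving force falls, peaking near -10 mV
        fs = 10_000.0
        traces = []
        for v in self.GRID:
            act = 1.0 / (1.0 + np.exp(-(v + 20.0) / 5.0))
            traces.append(np.full(int(0.05 * fs), -5.0 * act * (30.0 - v)))
        iv = ephys.iv_peak(self.GRID, traces, fs)
        peak_v = iv.voltages_mV[np.argmax(np.abs(iv.peaks_pA))]
        assert peak_v == pytest.approx(-10.0, abs=10.0)

    def test_planted_block_fraction_recovered(self):
        control = ephys.iv_peak(self.GRID, self._ohmic(g=0.8), 10_000.0, condition="control")
        block = ephys.iv_peak(self.GRID, self._ohmic(g=0.6), 10_000.0, condition="antagonist")
        f = ephys.trpm3_fraction(np.max(np.abs(control.peaks_pA)), np.max(np.abs(block.peaks_pA)))
        assert f == pytest.approx(0.25, abs=1e-9)

    def test_missing_steps_flagged(self):
        grid = np.array([-110.0, -100.0, 30.0])
        iv = ephys.iv_peak(grid, self._ohmic()[:3], 10_000.0, expected_grid=self.GRID)
        assert -105.0 in iv.missing_steps


class TestWhiteNoise:
    def test_prefilter_sd_matches_sigma(self):
        wn = ephys.white_noise_stimuli(n_patterns=50, n_select=50, duration_s=0.5, seed=0)
        assert wn.raw.std() == pytest.approx(50.0, rel=0.02)

    def test_autocorrelation_time_near_alpha(self):
        wn = ephys.white_noise_stimuli(n_patterns=20, n_select=20, duration_s=1.0, alpha_ms=2.0, seed=1)
        x = wn.filtered[0] - wn.filtered[0].mean()
        ac = np.correlate(x, x, mode="full")[len(x) - 1 :]
        ac /= ac[0]
        # exp-autocorrelation time constant: first crossing of 1/e
        tau_samples = np.argmax(ac < 1 / np.e)
        tau_ms = tau_samples / 10_000.0 * 1000.0
        assert 1.0 < tau_ms < 6.0

    def test_selection_deterministic(self):
        a = ephys.white_noise_stimuli(n_patterns=30, n_select=10, duration_s=0.2, seed=2)
        b = ephys.white_noise_stimuli(n_patterns=30, n_select=10, duration_s=0.2, seed=2)
        assert len(a.selected) == 10
        np.testing.assert_array_equal(a.selected, b.selected)
        np.testing.assert_array_equal(a.stimuli, b.stimuli)

    def test_select_bounded_by_patterns(self):
        with pytest.raises(ValueError):
            ephys.white_noise_stimuli(n_patterns=10, n_select=20)
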