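"""Capacitance extraction, de-embedding and peak-time readout."""

import dataclasses

import numpy as np
import pytest

from cvpheno import (
    CapacitanceTrace,
    CVTrace,
    SuspensionModel,
    VoltageProgram,
    capacitance_at,
    deembed,
    estimate_dvdt,
    extract_capacitance,
    find_peak_time,
    simulate_trace,
)
from cvpheno.capacitance import MaskingError, SupportError

from conftest import pure_capacitor


def make_ctrace(time, values, valid=None, **meta):
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.ones(values.size, dtype=bool)
    return CapacitanceTrace(np.asarray(time, float), values, valid, meta=meta)


class TestEstimateDvdt:
    def test_triangle_slope_on_descending_branch(self, paper_program):
        trace = simulate_trace(pure_capacitor(1e-6), paper_program)
        dvdt = estimate_dvdt(trace)
        assert dvdt[400] == pytest.approx(-0.04, rel=1e-9)  # mid descending branch
        assert dvdt[1400] == pytest.approx(0.04, rel=1e-9)  # mid ascending branch

    def test_constant_voltage_gives_zero(self):
        trace = CVTrace(np.arange(5) * 0.1, np.full(5, 0.3), np.zeros(5))
        np.testing.assert_allclose(estimate_dvdt(trace), 0.0, atol=1e-12)

    def test_polynomial_matches_analytic_derivative(self):
        # quadratic voltage: central differences are exact in the interior
        t = np.arange(50) * 0.01
        v = 0.3 * t**2 - 0.2 * t + 0.05
        trace = CVTrace(t, v, np.zeros_like(t))
        dvdt = estimate_dvdt(trace)
        np.testing.assert_allclose(dvdt[1:-1], (0.6 * t - 0.2)[1:-1], rtol=1e-9)

class TestExtractCapacitance:
    def test_pure_capacitor_inversion(self, paper_program):
        trace = simulate_trace(pure_capacitor(1e-6), paper_program)
        ctrace = extract_capacitance(trace)
        vals = ctrace.capacitance[ctrace.valid]
        np.testing.assert_allclose(vals, 1e-6, rtol=1e-3)
        # oracle inversion is much tighter than the 0.1% contract in practice
        np.testing.assert_allclose(vals, 1e-6, rtol=1e-9)

    def test_zero_current_gives_zero_capacitance(self, paper_program):
        trace = simulate_trace(pure_capacitor(1e-6), paper_program)
        zero = CVTrace(trace.time, trace.voltage, np.zeros_like(trace.current))
        ctrace = extract_capacitance(zero)
        np.testing.assert_array_equal(ctrace.capacitance[ctrace.valid], 0.0)

    def test_faradaic_peak_bias_is_bounded_and_one_sided(self, paper_program):
        c_tot, peak_i = 1e-6, 2e-8
        model = pure_capacitor(c_tot, faradaic_peak_i=peak_i)
        trace = simulate_trace(model, paper_program)
        ctrace = extract_capacitance(trace, smooth_window=0)
        err = ctrace.capacitance - c_tot
        bound = peak_i * np.exp(-0.5 * ((trace.voltage + 0.2) / 0.05) ** 2) / 0.04
        ok = ctrace.valid
        assert np.all(err[ok] <= bound[ok] + 1e-18)
        # equality at the peak centre on the descending branch
        centre = int(np.argmin(np.abs(trace.voltage[:900] + 0.2)))
        assert err[centre] == pytest.approx(peak_i / 0.04, rel=1e-9)
        # anodic (ascending) branch is unbiased
        ascending = np.arange(len(trace)) > 900
        np.testing.assert_allclose(err[ok & ascending], 0.0, atol=1e-18)

    @pytest.mark.parametrize("s_rate", [0.004, 0.04, 0.4])
    def test_scan_rate_invariance(self, s_rate):
        program = VoltageProgram(s_rate=s_rate)
        trace = simulate_trace(pure_capacitor(1e-6), program)
        ctrace = extract_capacitance(trace)
        np.testing.assert_allclose(ctrace.capacitance[ctrace.valid], 1e-6, rtol=1e-3)

    def test_positivity_for_passive_suspensions(self, paper_program):
        model = SuspensionModel(n_cells=5000, a_cell=1e-8, r_series=100.0, seed=2)
        trace = simulate_trace(model, paper_program)
        ctrace = extract_capacitance(trace)
        assert np.all(ctrace.capacitance[ctrace.valid] > 0)

    def test_all_masked_raises_with_parameters_named(self, paper_program):
        trace = simulate_trace(pure_capacitor(1e-6), paper_program)
        with pytest.raises(MaskingError, match="vertex_exclusion=2000"):
            extract_capacitance(trace, vertex_exclusion=2000)

    def test_even_smooth_window_rejected(self, paper_program):
        trace = simulate_trace(pure_capacitor(1e-6), paper_program)
        with pytest.raises(ValueError, match="odd"):
            extract_capacitance(trace, smooth_window=4)


class TestDeembed:
    def test_media_against_itself_is_one(self, paper_program):
        trace = simulate_trace(pure_capacitor(0.8e-6), paper_program)
        ctrace = extract_capacitance(trace)
        de = deembed(ctrace, ctrace)
        np.testing.assert_array_equal(de.ratio[de.valid], 1.0)

    def test_double_capacitance_gives_ratio_two(self, paper_program):
        media = extract_capacitance(simulate_trace(pure_capacitor(0.8e-6), paper_program))
        sample = extract_capacitance(simulate_trace(pure_capacitor(1.6e-6), paper_program))
        de = deembed(sample, media)
        np.testing.assert_allclose(de.ratio[de.valid], 2.0, rtol=1e-9)
        # rescaled restores farad units against the media reference
        np.testing.assert_allclose(de.rescaled[de.valid], 1.6e-6, rtol=1e-9)

    def test_noisy_ratio_within_propagated_uncertainty(self, paper_program):
        """Quotient noise propagation: ≥99% of valid samples within 3 s.d."""
        c_s, c_m = 1.0e-6, 0.8e-6
        noise_sd = 0.02 * c_m * paper_program.s_rate
        sigma_c = noise_sd / paper_program.s_rate  # per-sample capacitance s.d.
        true_ratio = c_s / c_m
        sigma_ratio = true_ratio * np.sqrt((sigma_c / c_s) ** 2 + (sigma_c / c_m) ** 2)
        within = total = 0
        for seed in range(100):
            sm = pure_capacitor(c_s, noise_sd=noise_sd, seed=seed)
            mm = pure_capacitor(c_m, noise_sd=noise_sd, seed=seed + 5000)
            sample = extract_capacitance(simulate_trace(sm, paper_program), smooth_window=0)
            media = extract_capacitance(simulate_trace(mm, paper_program), smooth_window=0)
            de = deembed(sample, media)
            err = np.abs(de.ratio[de.valid] - true_ratio)
            within += int(np.sum(err <= 3 * sigma_ratio))
            total += int(de.valid.sum())
        assert within / total >= 0.99

    def test_disjoint_support_rejected(self, paper_program):
        trace = simulate_trace(pure_capacitor(0.8e-6), paper_program)
        ctrace = extract_capacitance(trace)
        # media valid only on the first branch, sample only on the second
        early = ctrace.time < 40.0
        late = ctrace.time > 50.0
        media = CapacitanceTrace(ctrace.time, ctrace.capacitance, ctrace.valid & early)
        sample = CapacitanceTrace(ctrace.time, ctrace.capacitance, ctrace.valid & late)
        with pytest.raises(SupportError):
            deembed(sample, media)

    def test_media_floor_rejected(self, paper_program):
        trace = simulate_trace(pure_capacitor(0.8e-6), paper_program)
        ctrace = extract_capacitance(trace)
        near_zero = CapacitanceTrace(ctrace.time, np.full(len(ctrace), 1e-16),
                                     ctrace.valid)
        with pytest.raises(ValueError, match="below floor"):
            deembed(ctrace, near_zero)


class TestPeakReadout:
    def test_injected_peak_at_canonical_time(self):
        # reference behaviour: a capacitance maximum at 29.2 s is read back
        time = np.arange(1801) * 0.05
        values = np.full(time.size, 0.8e-6)
        values[584] = 1.0e-6  # grid sample at t = 29.2 s
        ctrace = make_ctrace(time, values)
        assert find_peak_time(ctrace) == pytest.approx(29.2, abs=1e-9)

    def test_constant_trace_ties_break_earliest(self):
        time = np.arange(100) * 0.05
        valid = time >= 1.0
        ctrace = make_ctrace(time, np.full(100, 0.5e-6), valid)
        assert find_peak_time(ctrace) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_argmax_matches_linear_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        time = np.arange(200) * 0.05
        values = rng.normal(1e-6, 1e-7, size=200)
        valid = rng.random(200) < 0.7
        valid[0] = True
        ctrace = make_ctrace(time, values, valid)
        best_t, best_v = None, -np.inf
        for t, v, ok in zip(time, values, valid):
            if ok and v > best_v:
                best_t, best_v = t, v
        assert find_peak_time(ctrace) == pytest.approx(best_t)

    def test_capacitance_at_nearest_rule(self):
        time = np.arange(10) * 0.5
        values = np.arange(10, dtype=float)
        ctrace = make_ctrace(time, values)
        assert capacitance_at(ctrace, 2.0) == 4.0  # exact grid time
        assert capacitance_at(ctrace, 2.2) == 4.0  # nearer to 2.0 than 2.5
        assert capacitance_at(ctrace, 2.3) == 5.0  # nearer to 2.5

    @pytest.mark.parametrize("seed", range(3))
    def test_capacitance_at_matches_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        time = np.arange(300) * 0.05
        values = rng.normal(size=300)
        valid = rng.random(300) < 0.5
        valid[-1] = True
        ctrace = make_ctrace(time, values, valid)
        for t_query in rng.uniform(0, 15, size=20):
            best = min(((abs(t - t_query), v) for t, v, ok in zip(time, values, valid) if ok),
                       key=lambda pair: pair[0])
            assert capacitance_at(ctrace, t_query, tolerance=np.inf) == best[1]

    def test_capacitance_at_tolerance_enforced(self):
        ctrace = make_ctrace([0.0, 1.0, 2.0], [1.0, 2.0, 3.0],
                             np.array([True, False, False]))
        with pytest.raises(ValueError, match="no valid sample"):
            capacitance_at(ctrace, 2.0, tolerance=0.5)


class TestParameterRecovery:
    @pytest.mark.parametrize("c_tot_uF", [0.5, 0.83, 1.01, 2.0])
    def test_median_recovers_configured_capacitance(self, paper_program, c_tot_uF):
        """Noisy, resistive, redox-peaked traces recover C_tot within 5%."""
        c_tot = c_tot_uF * 1e-6
        noise_sd = 0.02 * c_tot * paper_program.s_rate
        medians = []
        for seed in range(10):
            model = pure_capacitor(c_tot, r_series=100.0, noise_sd=noise_sd,
                                   faradaic_peak_i=1e-8, seed=seed)
            ctrace = extract_capacitance(simulate_trace(model, paper_program))
            medians.append(np.median(ctrace.capacitance[ctrace.valid]))
        assert np.median(medians) == pytest.approx(c_tot, rel=0.05)
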