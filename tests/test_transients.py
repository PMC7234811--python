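"""Transient phase analysis: exponential fits, model selection, phase laws."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinbind import (
    FretCalibration,
    RateConstants,
    TitrationDesign,
    fast_phase_fit,
    fit_exponentials,
    generate_titration,
    select_model,
    slow_phase_fit,
    summarize,
)
from kinbind.exceptions import (
    DegeneratePhasesWarning,
    IllDeterminedWarning,
    InsufficientDataError,
)


def _trace(t, amps, rates, offset):
    y = np.full_like(t, offset, dtype=float)
    for a, k in zip(amps, rates):
        y = y + a * np.exp(-k * t)
    return y


class TestFitExponentials:
    def test_single_exponential_exact_recovery(self):
        t = np.linspace(0, 1, 400)
        y = _trace(t, [1.0], [10.0], 0.2)
        fit = fit_exponentials(t, y, 1)
        assert fit.kobs[0] == pytest.approx(10.0, rel=1e-6)
        assert fit.amplitudes[0] == pytest.approx(1.0, rel=1e-6)
        assert fit.offset == pytest.approx(0.2, rel=1e-6)

    def test_biexponential_recovery(self):
        t = np.linspace(0, 0.5, 600)
        y = _trace(t, [0.6, 0.4], [200.0, 20.0], 0.1)
        fit = fit_exponentials(t, y, 2)
        assert fit.kobs[0] == pytest.approx(200.0, rel=1e-4)
        assert fit.kobs[1] == pytest.approx(20.0, rel=1e-4)
        assert fit.amplitudes[0] == pytest.approx(0.6, rel=1e-4)
        assert fit.amplitudes[1] == pytest.approx(0.4, rel=1e-4)

    def test_phases_reported_fast_to_slow(self):
        t = np.linspace(0, 0.5, 400)
        y = _trace(t, [0.3, 0.7], [15.0, 300.0], 0.0)
        fit = fit_exponentials(t, y, 2)
        assert fit.kobs[0] > fit.kobs[1]

    def test_overfit_single_exponential_warns_degenerate(self):
        t = np.linspace(0, 1, 400)
        y = _trace(t, [1.0], [12.0], 0.0)
        with pytest.warns(DegeneratePhasesWarning):
            fit_exponentials(t, y, 2)

    def test_insufficient_samples_rejected(self):
        t = np.linspace(0, 1, 10)
        with pytest.raises(InsufficientDataError):
            fit_exponentials(t, np.exp(-t), 2)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        k_slow=st.floats(1.0, 50.0),
        ratio=st.floats(3.0, 50.0),
        a1=st.floats(0.2, 2.0),
        a2=st.floats(0.2, 2.0),
    )
    def test_noiseless_recovery_property(self, k_slow, ratio, a1, a2):
        # any separation >= 3x must be recovered to 1e-4 relative
        k_fast = k_slow * ratio
        t = np.linspace(0, 5.0 / k_slow, 700)
        y = _trace(t, [a1, a2], [k_fast, k_slow], 0.5)
        fit = fit_exponentials(t, y, 2)
        assert fit.kobs[0] == pytest.approx(k_fast, rel=1e-4)
        assert fit.kobs[1] == pytest.approx(k_slow, rel=1e-4)


class TestSelectModel:
    def test_prefers_single_phase_for_single_exponential(self):
        t = np.linspace(0, 1, 300)
        rng = np.random.default_rng(0)
        y = _trace(t, [1.0], [8.0], 0.3) + rng.normal(0, 0.005, t.size)
        fit = select_model(t, y, max_phases=3)
        assert fit.n_phases == 1

    def test_scheme_transient_is_multiphasic(self, published_rates,
                                             acceptor3_calib):
        # 10 uM titrant, published constants: the noiseless model curve is
        # resolvably multi-exponential (binding phase plus minor modes)
        design = TitrationDesign(seed=21, titrant_multiples=(100.0,),
                                 duration=0.5, sample_rate=5000.0,
                                 noise_sigma=0.0)
        s = generate_titration(published_rates, acceptor3_calib, design)
        fit = select_model(s.time, s.transients[0], max_phases=3)
        assert fit.n_phases >= 2

    def test_flat_trace_selects_single_phase_with_tiny_amplitude(self):
        t = np.linspace(0, 1, 200)
        y = np.full(t.size, 0.7)
        fit = select_model(t, y, max_phases=2)
        assert np.sum(np.abs(fit.amplitudes)) < 1e-6


class TestFastPhase:
    def test_published_constants_line(self):
        # hand-derived from kobs = kon [L] + koff with kon = 1.88e7, koff = 13
        conc = np.array([1, 2, 5, 10, 20]) * 1e-6
        kobs = np.array([31.8, 50.6, 107.0, 201.0, 389.0])
        fit = fast_phase_fit(conc, kobs)
        assert fit.kon == pytest.approx(1.88e7, rel=1e-6)
        assert fit.koff == pytest.approx(13.0, rel=1e-6)
        assert fit.kd_app == pytest.approx(13.0 / 1.88e7, rel=1e-6)

    def test_kd_is_ratio_by_construction(self):
        rng = np.random.default_rng(1)
        conc = np.linspace(1e-6, 2e-5, 8)
        kobs = 2e7 * conc + 5 + rng.normal(0, 3, 8)
        fit = fast_phase_fit(conc, kobs)
        assert fit.kd_app == fit.koff / fit.kon

    def test_constant_kobs_flagged(self):
        with pytest.warns(IllDeterminedWarning):
            fit = fast_phase_fit([1e-6, 2e-6, 4e-6], [7.0, 7.0, 7.0])
        assert fit.kon == 0.0
        assert np.isnan(fit.kd_app)

    def test_two_points_exact_with_undefined_errors(self):
        fit = fast_phase_fit([1e-6, 3e-6], [30.0, 70.0])
        assert fit.kon == pytest.approx(2e7)
        assert fit.koff == pytest.approx(10.0)
        assert np.isnan(fit.kon_se)

    def test_single_point_rejected(self):
        with pytest.raises(InsufficientDataError):
            fast_phase_fit([1e-6], [30.0])


class TestSlowPhase:
    def test_noiseless_recovery(self):
        conc = np.array([0.5, 1, 2, 5, 10, 20, 50]) * 1e-6
        kobs = 24.0 * conc / (2.4e-6 + conc)
        fit = slow_phase_fit(conc, kobs)
        assert fit.kslow == pytest.approx(24.0, rel=1e-4)
        assert fit.k0_5 == pytest.approx(2.4e-6, rel=1e-4)

    def test_saturated_design_flags_k05(self):
        conc = np.array([50, 100, 200, 400]) * 1e-6
        kobs = 24.0 * conc / (2.4e-6 + conc)
        with pytest.warns(IllDeterminedWarning):
            fit = slow_phase_fit(conc, kobs)
        assert fit.kslow == pytest.approx(np.mean(kobs), rel=0.05)

    def test_single_concentration_rejected(self):
        with pytest.raises(InsufficientDataError):
            slow_phase_fit([1e-6], [10.0])


class TestSummarize:
    def test_fast_phase_slope_matches_preequilibrium_prediction(self):
        # fast pre-equilibrium regime, kr = 0: slope of the (only) phase
        # equals kb * k1 / (k1 + k_minus1) within 5%
        r = RateConstants(k1=1.9e6, k_minus1=1.5e6, kb=1.5e7, k_minusb=10.0,
                          kr=0.0, k_minusr=0.0)
        calib = FretCalibration(c=1.0, c_star=1.0, sc=-0.8, baseline=1.0)
        design = TitrationDesign(seed=31,
                                 titrant_multiples=(50.0, 100.0, 150.0, 250.0),
                                 duration=0.2, sample_rate=10_000.0,
                                 noise_sigma=0.0)
        series = generate_titration(r, calib, design)
        summary = summarize(series, max_phases=1)
        slope_pred = r.kb * r.competent_fraction
        assert summary.kon == pytest.approx(slope_pred, rel=0.05)

    def test_generated_series_recovers_effective_on_rate(
            self, noiseless_series, published_rates):
        # dominant-phase slope of the full scheme equals the effective
        # association rate kb * phi within 5% on noiseless data
        summary = summarize(noiseless_series, max_phases=2)
        amp = summary.amplitudes
        # dominant phase per transient: highest relative amplitude
        k_dom = [
            row[f"kobs_{int(np.argmax([row.get('rel_amp_1', 0), row.get('rel_amp_2', 0)])) + 1}"]
            for _, row in amp.iterrows()
        ]
        fit = fast_phase_fit(amp["concentration_M"], k_dom)
        pred = published_rates.kb * published_rates.competent_fraction
        assert fit.kon == pytest.approx(pred, rel=0.05)

    def test_empty_series_rejected(self, published_rates, acceptor3_calib):
        design = TitrationDesign(seed=41, titrant_multiples=(0.0,),
                                 duration=0.1, noise_sigma=0.0)
        series = generate_titration(published_rates, acceptor3_calib, design)
        with pytest.raises(InsufficientDataError):
            summarize(series)
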