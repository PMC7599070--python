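"""Dilution design, standard curves and single-timepoint MM fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import holophos as hp


class TestDilutionSeries:
    def test_default_single_step(self):
        series = hp.DilutionSeries(n_steps=1)
        assert hp.final_concentrations(series) == pytest.approx([800.0])

    def test_default_three_steps(self):
        series = hp.DilutionSeries(n_steps=3)
        assert hp.final_concentrations(series) == pytest.approx(
            [800.0, 533.33, 355.56], abs=0.01)

    def test_without_mix_dilution(self):
        series = hp.DilutionSeries(n_steps=2, mix_factor=1.0)
        assert hp.final_concentrations(series) == pytest.approx(
            [1000.0, 666.67], abs=0.01)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            hp.DilutionSeries(fold=1.0)
        with pytest.raises(ValueError):
            hp.DilutionSeries(mix_factor=0.0)
        with pytest.raises(ValueError):
            hp.final_concentrations(hp.DilutionSeries(n_steps=0))


class TestStandardCurve:
    def test_blank_reading_maps_to_zero(self):
        curve = hp.StandardCurve(slope=0.01, intercept=0.05)
        p, n = hp.absorbance_to_phosphate(0.05, curve)
        assert p == 0.0 and n == 0

    def test_linear_inversion(self):
        curve = hp.StandardCurve(slope=0.01, intercept=0.05)
        p, _ = hp.absorbance_to_phosphate(0.15, curve)
        assert p == pytest.approx(10.0)

    def test_sub_blank_clamped_with_warning(self):
        curve = hp.StandardCurve(slope=0.01, intercept=0.05)
        p, n = hp.absorbance_to_phosphate([0.01, 0.15], curve)
        assert p[0] == 0.0 and n == 1

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            hp.StandardCurve(slope=0.0)

    def test_fit_standard_curve_recovers_line(self):
        pi = np.linspace(0, 100, 8)
        curve = hp.fit_standard_curve(pi, 0.04 + 0.012 * pi)
        assert curve.slope == pytest.approx(0.012)
        assert curve.intercept == pytest.approx(0.04)


class TestSingleTimepointFit:
    CONC = hp.final_concentrations(hp.DilutionSeries())

    def test_noise_free_recovery(self):
        product = hp.mm_product(self.CONC, 15.0, 1.0, 0.5, 30.0)
        fit = hp.fit_single_timepoint_mm(self.CONC, product, 15.0, 1.0)
        assert fit.km == pytest.approx(30.0, rel=1e-4)
        assert fit.kcat_over_km == pytest.approx(0.5, rel=1e-4)
        assert fit.km_reliable

    def test_half_maximal_product_at_km(self):
        # model identity: P(C = KM) = t*E*kcat/2
        km, kcat_over_km = 30.0, 0.5
        kcat = kcat_over_km * km
        assert hp.mm_product(km, 15.0, 1.0, kcat_over_km, km) == \
            pytest.approx(15.0 * kcat / 2.0)

    def test_km_beyond_range_flagged_unreliable(self):
        """KM far above the highest concentration: the assay only sees
        the linear regime, so kcat/KM is recovered but KM is not."""
        product = hp.mm_product(self.CONC, 15.0, 1.0, 0.5, 5000.0)
        fit = hp.fit_single_timepoint_mm(self.CONC, product, 15.0, 1.0)
        assert not fit.km_reliable
        assert fit.kcat_over_km == pytest.approx(0.5, rel=0.02)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            hp.fit_single_timepoint_mm([1, 2, 3], [1, 2, 3], 15.0, 1.0)
        with pytest.raises(ValueError):
            hp.fit_single_timepoint_mm(self.CONC,
                                       np.zeros_like(self.CONC), 15.0, 1.0)
        product = hp.mm_product(self.CONC, 15.0, 1.0, 0.5, 30.0)
        with pytest.raises(ValueError):
            hp.fit_single_timepoint_mm(self.CONC, product, 0.0, 1.0)

    @given(km=st.floats(5.0, 200.0), a=st.floats(0.01, 2.0))
    @settings(deadline=None, max_examples=25)
    def test_round_trip_property(self, km, a):
        product = hp.mm_product(self.CONC, 15.0, 1.0, a, km)
        fit = hp.fit_single_timepoint_mm(self.CONC, product, 15.0, 1.0)
        assert fit.km == pytest.approx(km, rel=1e-3)
        assert fit.kcat_over_km == pytest.approx(a, rel=1e-3)

    def test_model_monotone_in_concentration(self):
        c = np.linspace(0.1, 1000, 500)
        p = hp.mm_product(c, 15.0, 1.0, 0.5, 30.0)
        assert np.all(np.diff(p) > 0)

    def test_reparameterization_consistency(self):
        """Predictions in (kcat/KM, KM) and (Vmax, KM) coordinates agree."""
        product = hp.mm_product(self.CONC, 15.0, 1.0, 0.5, 30.0)
        fit = hp.fit_single_timepoint_mm(self.CONC, product, 15.0, 1.0)
        via_specificity = hp.mm_product(self.CONC, 15.0, 1.0,
                                        fit.kcat_over_km, fit.km)
        vmax = fit.kcat_per_unit  # kcat per unit = (kcat/KM) * KM
        via_vmax = 15.0 * 1.0 * vmax * self.CONC / (self.CONC + fit.km)
        assert np.sum((via_specificity - via_vmax) ** 2) < 1e-10

    def test_noisy_bias_is_small(self):
        """2% multiplicative noise, 200 replicates: median relative bias
        of kcat/KM below 5% at KM = 30."""
        rng = np.random.default_rng(23)
        truth = 0.5
        estimates = []
        for _ in range(200):
            product = hp.mm_product(self.CONC, 15.0, 1.0, truth, 30.0)
            noisy = product * rng.normal(1.0, 0.02, size=product.shape)
            fit = hp.fit_single_timepoint_mm(self.CONC, noisy, 15.0, 1.0)
            estimates.append(fit.kcat_over_km)
        bias = np.median(np.abs(np.array(estimates) - truth) / truth)
        assert bias < 0.05


class TestActivityCalibration:
    def test_unit_definition(self):
        assert hp.calibrate_activity(15.0) == pytest.approx(1.0)

    def test_linearity(self):
        assert hp.calibrate_activity(30.0) == pytest.approx(2.0)
        assert hp.calibrate_activity(0.0) == 0.0
        alpha = 3.7
        assert hp.calibrate_activity(alpha * 15.0) == \
            pytest.approx(alpha * hp.calibrate_activity(15.0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            hp.calibrate_activity(-1.0)


class TestPnpp:
    CONC_MM = 100.0 / 2.0 ** np.arange(8)  # 2-fold dilution from 100 mM

    def test_noise_free_hyperbola_recovery(self):
        signal = 1.8 * self.CONC_MM / (self.CONC_MM + 12.0)
        fit = hp.fit_pnpp(self.CONC_MM, signal)
        assert fit.vmax == pytest.approx(1.8, rel=1e-4)
        assert fit.km_mm == pytest.approx(12.0, rel=1e-4)

    def test_fitted_curve_monotone(self):
        signal = 1.8 * self.CONC_MM / (self.CONC_MM + 12.0)
        fit = hp.fit_pnpp(self.CONC_MM, signal)
        c = np.linspace(0.1, 200, 100)
        assert np.all(np.diff(fit.predict(c)) > 0)

    def test_duplicates_averaged(self):
        conc = np.concatenate([self.CONC_MM, self.CONC_MM])
        base = 1.8 * self.CONC_MM / (self.CONC_MM + 12.0)
        signal = np.concatenate([base * 0.99, base * 1.01])
        fit = hp.fit_pnpp(conc, signal)
        ref = hp.fit_pnpp(self.CONC_MM, base)
        assert fit.km_mm == pytest.approx(ref.km_mm, rel=1e-6)


class TestEfficiencyFold:
    def _fit(self, a, km=30.0):
        conc = hp.final_concentrations(hp.DilutionSeries())
        product = hp.mm_product(conc, 15.0, 1.0, a, km)
        return hp.fit_single_timepoint_mm(conc, product, 15.0, 1.0)

    def test_identical_fits_fold_one(self):
        fit = self._fit(0.5)
        assert hp.efficiency_fold(fit, fit) == 1.0

    def test_hundredfold_efficiency_contrast(self):
        """Two enzymes generated at efficiencies 0.5 and 0.005 recover a
        100-fold catalytic-efficiency ratio."""
        fold = hp.efficiency_fold(self._fit(0.5), self._fit(0.005))
        assert fold == pytest.approx(100.0, rel=0.02)

    def test_zero_reference_rejected(self):
        fit = self._fit(0.5)
        zero = hp.KineticFit(kcat_over_km=0.0, km=30.0, km_reliable=False,
                             residual_sse=0.0)
        with pytest.raises(ValueError):
            hp.efficiency_fold(fit, zero)
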