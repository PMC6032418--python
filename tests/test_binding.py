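"""One-site binding isotherm fits and difference-spectrum typing."""

import numpy as np
import pytest

from hemedist import (
    BindingIsotherm,
    DifferenceSpectrum,
    InputError,
    classify_difference_spectrum,
    fit_binding_constant,
    gen_isotherm,
)

WT_CONCS = np.array([1.0, 3.0, 10.0, 17.1, 30.0, 60.0, 120.0, 200.0])


def make_isotherm(ks=17.1, bmax=0.05, concs=WT_CONCS):
    return BindingIsotherm(
        substrate_conc=concs,
        delta_A=bmax * concs / (ks + concs),
        enzyme_label="test",
    )


class TestFitBindingConstant:
    def test_noiseless_recovery(self):
        fit = fit_binding_constant(make_isotherm())
        assert fit.ks == pytest.approx(17.1, rel=1e-6)
        assert fit.bmax == pytest.approx(0.05, rel=1e-6)
        assert fit.fit_diagnostics["rss"] < 1e-12 * 0.05**2

    def test_half_saturation_identity(self):
        fit = fit_binding_constant(make_isotherm())
        assert fit.predict(np.array([fit.ks]))[0] == pytest.approx(
            fit.bmax / 2.0, rel=1e-12
        )

    def test_noisy_tight_binder_within_3se(self):
        iso, spec = gen_isotherm(ks=0.7, bmax=0.05, noise_sd=0.02 * 0.05,
                                 seed=5)
        fit = fit_binding_constant(iso)
        assert abs(fit.ks - spec.ground_truth["ks"]) < 3.0 * fit.ks_se

    def test_rescaling_delta_a_rescales_bmax_only(self):
        base = fit_binding_constant(make_isotherm())
        iso = make_isotherm()
        scaled = BindingIsotherm(
            substrate_conc=iso.substrate_conc,
            delta_A=3.0 * iso.delta_A,
            enzyme_label="scaled",
        )
        fit = fit_binding_constant(scaled)
        assert fit.ks == pytest.approx(base.ks, rel=1e-8)
        assert fit.bmax == pytest.approx(3.0 * base.bmax, rel=1e-8)

    @pytest.mark.parametrize("ks_true", [0.7, 3.5, 10.2, 17.1])
    def test_recovery_bias_below_5_percent(self, ks_true):
        """Mean fitted Ks over 200 noisy titrations stays within 5%."""
        rng = np.random.default_rng(815)
        fits = []
        for _ in range(200):
            iso, _ = gen_isotherm(ks=ks_true, bmax=0.05,
                                  noise_sd=0.02 * 0.05, seed=rng)
            fits.append(fit_binding_constant(iso).ks)
        assert abs(np.mean(fits) - ks_true) < 0.05 * ks_true

    def test_unsaturated_titration_is_flagged(self):
        # titration stops far below Ks: plateau unconstrained
        concs = np.array([0.1, 0.2, 0.4, 0.8, 1.6])
        iso = BindingIsotherm(
            substrate_conc=concs,
            delta_A=0.05 * concs / (500.0 + concs),
            enzyme_label="weak",
        )
        fit = fit_binding_constant(iso)
        assert fit.warnings
        assert "10x" in fit.warnings[0]

    def test_too_few_points_rejected(self):
        with pytest.raises(InputError, match=">= 5"):
            make_isotherm(concs=np.array([1.0, 3.0, 10.0, 30.0]))

    def test_non_increasing_concentrations_rejected(self):
        with pytest.raises(InputError, match="strictly increase"):
            BindingIsotherm(
                substrate_conc=np.array([1.0, 3.0, 3.0, 10.0, 30.0]),
                delta_A=np.zeros(5),
            )


def gaussian(w, center, fwhm, height):
    sigma = fwhm / 2.3548200450309493
    return height * np.exp(-((w - center) ** 2) / (2 * sigma**2))


def difference_spectrum(peak_nm, trough_nm, amp=0.03):
    w = np.arange(360.0, 460.5, 1.0)
    d = gaussian(w, peak_nm, 20.0, amp) - gaussian(w, trough_nm, 20.0, amp)
    return DifferenceSpectrum(wavelengths=w, delta_absorbance=d)


class TestClassifyDifferenceSpectrum:
    def test_type_i_peak_390_trough_420(self):
        cls = classify_difference_spectrum(difference_spectrum(390.0, 420.0))
        assert cls.spectrum_type == "type I"
        assert cls.lambda_max == pytest.approx(390.0, abs=1.0)
        assert cls.lambda_min == pytest.approx(420.0, abs=1.0)

    def test_flat_spectrum_is_indeterminate(self):
        w = np.arange(360.0, 460.5, 1.0)
        cls = classify_difference_spectrum(
            DifferenceSpectrum(wavelengths=w, delta_absorbance=np.zeros_like(w))
        )
        assert cls.spectrum_type == "indeterminate"

    def test_type_ii_mirrored_bands(self):
        cls = classify_difference_spectrum(difference_spectrum(430.0, 400.0))
        assert cls.spectrum_type == "type II"

    def test_out_of_window_extrema_are_indeterminate(self):
        cls = classify_difference_spectrum(difference_spectrum(370.0, 440.0))
        assert cls.spectrum_type == "indeterminate"
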