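"""Analytic factors, the rotational expansion, convolution, and the full
forward model."""

import numpy as np
import pytest
from scipy.special import spherical_jn

from aquadyn.qens_model import (
    HBAR_UEV_PS,
    binned_lorentzian,
    ModelParams,
    ResolutionFunction,
    SpectrumGrid,
    convolve_resolution,
    debye_waller,
    forward_model,
    lorentzian,
    profile_fwhm,
    rotational_eisf,
    sears_quasielastic_weights,
    symmetric_energy_grid,
    translational_hwhm,
)
from aquadyn import synthetic as syn


def j0_series(x, terms=40):
    """Independent power-series evaluation of the spherical Bessel j0."""
    from math import factorial
    return sum((-1) ** n * x ** (2 * n) / factorial(2 * n + 1)
               for n in range(terms))


class TestElementaryFactors:
    @pytest.mark.parametrize("q,u2,expected", [
        (0.0, 0.5, 1.0),
        (1.3, 0.0, 1.0),
        (1.0, 0.1, np.exp(-0.1)),
    ])
    def test_debye_waller_values(self, q, u2, expected):
        assert debye_waller(q, u2) == pytest.approx(expected, rel=1e-12)

    def test_debye_waller_rejects_negative(self):
        with pytest.raises(ValueError):
            debye_waller(1.0, -0.1)

    def test_rotational_eisf_limits(self):
        assert rotational_eisf(0.0, 0.98) == pytest.approx(1.0)
        assert rotational_eisf(np.pi / 0.98, 0.98) == pytest.approx(0.0, abs=1e-12)

    def test_rotational_eisf_against_power_series(self):
        # independent oracle: truncated power series of j0 at qb = 1.6268
        q, b = 1.66, 0.98
        expected = float(j0_series(q * b)) ** 2
        assert expected == pytest.approx(0.37668, abs=1e-4)
        assert rotational_eisf(q, b) == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("q,lam", [(0.5, 2.0), (1.0, 1.6), (1.66, 0.5)])
    def test_translational_hwhm_scaling(self, q, lam):
        g1 = translational_hwhm(q, 0.01, lam)
        g2 = translational_hwhm(2 * q, 0.01, lam)
        assert g2 / g1 == pytest.approx(2 ** lam, rel=1e-12)

    def test_translational_hwhm_q1_normalization(self):
        # at q = 1 the width is hbar * D_t for any exponent
        for lam in (0.7, 1.6, 2.0):
            assert translational_hwhm(1.0, 0.01, lam) == pytest.approx(
                HBAR_UEV_PS * 0.01, rel=1e-12)
        assert translational_hwhm(1.0, 0.01, 2.0) == pytest.approx(6.582119)

    def test_translational_hwhm_rejects_bad_exponent(self):
        for lam in (0.0, -1.0, 2.5):
            with pytest.raises(ValueError):
                translational_hwhm(1.0, 0.01, lam)

    def test_lorentzian_peak_and_halfwidth(self):
        assert lorentzian(0.0, 1.0) == pytest.approx(1 / np.pi)
        assert lorentzian(2.5, 2.5) == pytest.approx(lorentzian(0.0, 2.5) / 2)

    def test_lorentzian_unit_area(self):
        # tail beyond +-X*hwhm carries 2/(pi*X); X=1000 brings it below 1e-3
        hwhm = 0.8
        E = np.arange(-1000 * hwhm, 1000 * hwhm, hwhm / 50)
        area = np.trapezoid(lorentzian(E, hwhm), E)
        assert area == pytest.approx(1.0, abs=1e-3)

    def test_lorentzian_rejects_nonpositive_width(self):
        with pytest.raises(ValueError):
            lorentzian(0.0, 0.0)


class TestSearsExpansion:
    def test_weights_vanish_at_q_zero(self):
        assert np.allclose(sears_quasielastic_weights(0.0, 0.98, 5), 0.0)

    @pytest.mark.parametrize("x", np.linspace(0.05, 2.0, 9).tolist())
    def test_completeness_to_l20(self, x):
        total = spherical_jn(0, x) ** 2 + \
            sears_quasielastic_weights(x, 1.0, 20).sum()
        assert total == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("q", np.linspace(0.46, 1.66, 7).tolist())
    def test_five_terms_carry_99_percent(self, q):
        b = 0.98
        quasi_total = 1.0 - rotational_eisf(q, b)
        assert sears_quasielastic_weights(q, b, 5).sum() >= 0.99 * quasi_total

    def test_rejects_l_max_below_one(self):
        with pytest.raises(ValueError):
            sears_quasielastic_weights(1.0, 0.98, 0)


class TestConvolution:
    def test_spike_is_identity(self):
        dE = 0.05
        E = symmetric_energy_grid(10.0, dE)
        spike = np.zeros_like(E)
        spike[E.size // 2] = 1.0 / dE          # unit-area single channel
        profile = np.exp(-0.5 * (E / 1.3) ** 2)
        out = convolve_resolution(profile, spike, dE)
        assert np.allclose(out, profile, atol=1e-12)

    def test_gaussian_convolution_closed_form(self):
        s1, s2 = 0.8, 0.5
        dE = 0.02
        E = symmetric_energy_grid(20 * max(s1, s2), dE)

        def gauss(E, s):
            return np.exp(-0.5 * (E / s) ** 2) / (s * np.sqrt(2 * np.pi))

        out = convolve_resolution(gauss(E, s1), gauss(E, s2), dE)
        expected = gauss(E, np.hypot(s1, s2))
        assert np.sqrt(np.mean((out - expected) ** 2)) < 1e-4

    def test_area_is_conserved(self):
        dE = 0.02
        E = symmetric_energy_grid(30.0, dE)     # >> 10 FWHM of padding
        res = np.exp(-0.5 * (E / 0.3) ** 2)
        res /= res.sum() * dE
        profile = lorentzian(E, 0.9)
        out = convolve_resolution(profile, res, dE)
        assert out.sum() * dE == pytest.approx(profile.sum() * dE, abs=1e-4)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            convolve_resolution(np.zeros(10), np.zeros(11), 0.1)


class TestForwardModel:
    def test_null_model_is_zero(self, small_grid, small_resolution):
        params = ModelParams(u2=0.1, A_i=0, A_t=0, A_r=0, D_t=0.01, lam=1.6,
                             Gamma_r=0.5, k=np.zeros(small_grid.n_q))
        out = forward_model(params, small_grid, small_resolution)
        assert np.allclose(out.intensity, 0.0)

    def test_purely_elastic_sample_returns_resolution(self, small_grid,
                                                      small_resolution):
        params = ModelParams(u2=0.0, A_i=1, A_t=0, A_r=0, D_t=0.0, lam=2.0,
                             Gamma_r=0.5, k=np.zeros(small_grid.n_q))
        out = forward_model(params, small_grid, small_resolution)
        assert np.allclose(out.intensity, small_resolution.profiles, atol=1e-12)

    def test_integrated_intensity_matches_amplitudes(self, wide_grid):
        res = syn.generate_resolution(wide_grid)
        params = syn.default_qens_truth(n_q=wide_grid.n_q)
        out = forward_model(params, wide_grid, res)
        areas = (out.intensity - params.k[:, None]).sum(axis=1) * wide_grid.dE
        expected = debye_waller(wide_grid.q_values, params.u2) * \
            params.amplitude_sum()
        assert np.allclose(areas, expected, rtol=0.01)

    def test_linearity_in_amplitudes_and_background(self, small_grid,
                                                    small_resolution,
                                                    small_truth):
        doubled = ModelParams(u2=small_truth.u2, A_i=2 * small_truth.A_i,
                              A_t=2 * small_truth.A_t, A_r=2 * small_truth.A_r,
                              D_t=small_truth.D_t, lam=small_truth.lam,
                              Gamma_r=small_truth.Gamma_r, k=2 * small_truth.k)
        one = forward_model(small_truth, small_grid, small_resolution)
        two = forward_model(doubled, small_grid, small_resolution)
        assert np.allclose(two.intensity, 2 * one.intensity, rtol=1e-12)

    def test_brownian_limit_matches_independent_model(self, small_grid,
                                                      small_resolution):
        """lam=2 output equals an independently coded Brownian-diffusion
        model with Gamma = hbar * D * q^2."""
        params = ModelParams(u2=0.05, A_i=0.4, A_t=0.4, A_r=0.2, D_t=0.008,
                             lam=2.0, Gamma_r=0.7, k=np.full(small_grid.n_q, 2e-3))
        out = forward_model(params, small_grid, small_resolution)

        # independent implementation, Brownian widths hard-coded
        E, dE = small_grid.E_values, small_grid.dE
        pad = int(np.ceil(10 * small_resolution.fwhm() / dE))
        E_ext = np.concatenate([E[0] - dE * np.arange(pad, 0, -1), E,
                                E[-1] + dE * np.arange(1, pad + 1)])
        expected = np.empty_like(out.intensity)
        for iq, q in enumerate(small_grid.q_values):
            R = small_resolution.profiles[iq]
            dw = np.exp(-q ** 2 * params.u2)
            x = q * params.b
            gamma_t = HBAR_UEV_PS * params.D_t * q ** 2
            quasi = params.A_t * binned_lorentzian(E_ext, gamma_t, dE)
            for l in range(1, 6):
                quasi += params.A_r * (2 * l + 1) * spherical_jn(l, x) ** 2 * \
                    binned_lorentzian(E_ext, l * (l + 1) * params.Gamma_r, dE)
            conv = np.convolve(quasi, R, mode="same")[pad:pad + E.size] * dE
            elastic = (params.A_i + params.A_r * spherical_jn(0, x) ** 2) * R
            expected[iq] = dw * (elastic + conv) + params.k[iq]
        assert np.allclose(out.intensity, expected, atol=1e-10)

    def test_variants_coincide_as_translation_freezes(self, small_grid,
                                                      small_resolution):
        kwargs = dict(u2=0.05, A_i=0.4, A_t=0.3, A_r=0.3, lam=2.0,
                      Gamma_r=0.6, k=np.zeros(small_grid.n_q))
        slow = ModelParams(D_t=1e-9, **kwargs)
        add = forward_model(slow, small_grid, small_resolution, "additive")
        conv = forward_model(slow, small_grid, small_resolution, "convolved")
        assert np.allclose(add.intensity, conv.intensity, atol=1e-5)

    def test_unknown_variant_rejected(self, small_grid, small_resolution,
                                      small_truth):
        with pytest.raises(ValueError):
            forward_model(small_truth, small_grid, small_resolution, "hybrid")


class TestGridAndParamValidation:
    def test_grid_rejects_nonuniform_energy(self):
        with pytest.raises(ValueError):
            SpectrumGrid(q_values=[0.5], E_values=[-1.0, 0.0, 1.1])

    def test_grid_rejects_asymmetric_window(self):
        with pytest.raises(ValueError):
            SpectrumGrid(q_values=[0.5], E_values=np.arange(0.0, 5.0, 0.1))

    def test_grid_rejects_unsorted_q(self):
        E = symmetric_energy_grid(1.0, 0.1)
        with pytest.raises(ValueError):
            SpectrumGrid(q_values=[1.0, 0.5], E_values=E)

    @pytest.mark.parametrize("field,value", [
        ("A_i", -0.1), ("lam", 2.5), ("lam", 0.0), ("Gamma_r", 0.0),
        ("D_t", -1e-3), ("u2", -0.2), ("b", 0.0),
    ])
    def test_params_invariants(self, field, value):
        good = dict(u2=0.1, A_i=0.5, A_t=0.3, A_r=0.2, D_t=0.01, lam=1.6,
                    Gamma_r=0.5, k=[0.0], b=0.98)
        good[field] = value
        with pytest.raises(ValueError):
            ModelParams(**good)

    def test_resolution_must_be_normalized(self, small_grid):
        bad = np.ones((small_grid.n_q, small_grid.n_E))
        with pytest.raises(ValueError):
            ResolutionFunction(grid=small_grid, profiles=bad)
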