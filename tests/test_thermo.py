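"""Constant-heat-capacity decomposition of multi-temperature PMFs."""

import numpy as np
import pytest

import chainfel as cf
from chainfel.errors import NumericalError
from chainfel.oracles import RISModel, ris_enumerate, ris_sample
from chainfel.sampling import REFERENCE_LADDER
from chainfel.thermo import (
    MultiTemperaturePMF, T0_DEFAULT, decompose_pmf_pipeline, enthalpy_entropy,
    fit_gibbs_helmholtz,
)
from chainfel.wham import KB, BiasedHistogramSet

LADDER = np.array(REFERENCE_LADDER)
T0 = T0_DEFAULT


def surface_from_coeffs(a, b, c, temps=LADDER):
    """G(T) = A + B(T-T0) + C T ln(T/T0) evaluated per bin."""
    t = temps[:, None]
    return a[None, :] + b[None, :] * (t - T0) + c[None, :] * t * np.log(t / T0)


class TestFitRecovery:
    def test_temperature_independent_g_gives_zero_entropy(self):
        r = np.arange(5.0)
        g = np.tile(np.array([1.0, 0.0, 2.0, 5.0, 3.0]), (len(LADDER), 1))
        fit = fit_gibbs_helmholtz(
            MultiTemperaturePMF(LADDER, r, g), T0=T0,
        )
        np.testing.assert_allclose(fit.B, 0.0, atol=1e-10)
        np.testing.assert_allclose(fit.C, 0.0, atol=1e-10)
        np.testing.assert_allclose(fit.A, g[0], atol=1e-10)
        np.testing.assert_allclose(fit.H0, g[0], atol=1e-9)
        np.testing.assert_allclose(fit.minus_TS0, 0.0, atol=1e-9)

    def test_exact_recovery_of_known_coefficients(self):
        rng = np.random.default_rng(21)
        n_bins = 30
        a = rng.uniform(-5, 10, n_bins)
        b = rng.uniform(-0.05, 0.05, n_bins)
        c = rng.uniform(-0.1, 0.1, n_bins)
        fit = fit_gibbs_helmholtz(
            MultiTemperaturePMF(LADDER, np.arange(n_bins, dtype=float),
                                surface_from_coeffs(a, b, c)), T0=T0,
        )
        np.testing.assert_allclose(fit.A, a, atol=1e-9)
        np.testing.assert_allclose(fit.B, b, atol=1e-9)
        np.testing.assert_allclose(fit.C, c, atol=1e-9)
        np.testing.assert_allclose(fit.residual_rms, 0.0, atol=1e-9)

    def test_noise_recovery_matches_sampling_theory(self):
        # 100 random coefficient triples under sigma = 0.05 kJ/mol noise;
        # oracle: H(T0) = v'coef with v = (1, -T0, -T0), so its OLS
        # standard error is sigma * sqrt(v' (X'X)^-1 v) and the median
        # absolute error of a Gaussian is 0.6745 standard errors
        rng = np.random.default_rng(4)
        sigma = 0.05
        n_bins = 100
        a = rng.uniform(-5, 10, n_bins)
        b = rng.uniform(-0.05, 0.05, n_bins)
        c = rng.uniform(-0.1, 0.1, n_bins)
        g = surface_from_coeffs(a, b, c) + rng.normal(0, sigma, (len(LADDER), n_bins))
        fit = fit_gibbs_helmholtz(
            MultiTemperaturePMF(LADDER, np.arange(n_bins, dtype=float), g), T0=T0,
        )
        h_true = a - (b + c) * T0
        median_err = np.median(np.abs(fit.H0 - h_true))
        t = LADDER
        design = np.column_stack([np.ones_like(t), t - T0, t * np.log(t / T0)])
        v = np.array([1.0, -T0, -T0])
        se_h0 = sigma * np.sqrt(v @ np.linalg.inv(design.T @ design) @ v)
        expected_median = 0.6745 * se_h0
        assert 0.6 * expected_median < median_err < 1.5 * expected_median

    def test_added_quadratic_term_not_supported_by_three_term_data(self):
        # refitting with an extra (T - T0)^2 column on data generated from
        # the 3-term model returns a negligible extra coefficient
        rng = np.random.default_rng(8)
        a, b, c = rng.uniform(-3, 3, (3, 20))
        g = surface_from_coeffs(a, b, c)
        t = LADDER
        design = np.column_stack([
            np.ones_like(t), t - T0, t * np.log(t / T0), (t - T0) ** 2,
        ])
        extra = np.array([
            np.linalg.lstsq(design, g[:, i], rcond=None)[0][3]
            for i in range(20)
        ])
        np.testing.assert_allclose(extra, 0.0, atol=1e-10)

    def test_duplicate_temperatures_rejected(self):
        temps = np.array([298.15, 298.15, 350.0])
        with pytest.raises(NumericalError, match="duplicate"):
            MultiTemperaturePMF(temps, np.arange(3.0), np.zeros((3, 3)))

    def test_fewer_than_three_temperatures_rejected(self):
        with pytest.raises(ValueError, match="3 temperatures"):
            MultiTemperaturePMF(np.array([300.0, 400.0]), np.arange(3.0),
                                np.zeros((2, 3)))


class TestDerivedProfiles:
    @pytest.fixture(scope="class")
    def fit(self):
        rng = np.random.default_rng(5)
        a, b, c = rng.uniform(-2, 4, (3, 12))
        return fit_gibbs_helmholtz(
            MultiTemperaturePMF(LADDER, np.arange(12.0),
                                surface_from_coeffs(a, b, c)), T0=T0,
        )

    def test_reference_temperature_identities(self, fit):
        np.testing.assert_allclose(fit.G0, fit.A, atol=1e-12)
        np.testing.assert_allclose(
            fit.minus_TS0, (fit.B + fit.C) * T0, atol=1e-12,
        )
        h, minus_ts = enthalpy_entropy(fit, T0)
        np.testing.assert_allclose(h, fit.H0, atol=1e-9)
        np.testing.assert_allclose(minus_ts, fit.minus_TS0, atol=1e-9)

    @pytest.mark.parametrize("t", [298.15, 320.0, 400.0, 500.0])
    def test_gibbs_helmholtz_identity_everywhere(self, fit, t):
        h, minus_ts = enthalpy_entropy(fit, t)
        np.testing.assert_allclose(h + minus_ts, fit.gibbs(t), atol=1e-9)

    def test_heat_capacity_constant_minus_c(self, fit):
        dt = 1e-3
        h_lo, _ = enthalpy_entropy(fit, 350.0 - dt)
        h_hi, _ = enthalpy_entropy(fit, 350.0 + dt)
        np.testing.assert_allclose(
            (h_hi - h_lo) / (2 * dt), -fit.C, atol=1e-6,
        )
        np.testing.assert_allclose(fit.heat_capacity, -fit.C)

    def test_nonpositive_temperature_rejected(self, fit):
        with pytest.raises(ValueError):
            enthalpy_entropy(fit, -1.0)


class TestAgainstEnumerationOracle:
    def test_fitted_enthalpy_matches_finite_difference(self):
        # exact G(T, r) enumerated at the ten ladder temperatures; the
        # oracle is a centered finite difference of the same exact data,
        # H = -T^2 d(G/T)/dT = G - T dG/dT at T0; agreement is judged as
        # an RMS over well-populated bins (>= 0.1% of the population)
        model = RISModel(cf.ChainTopology(9))
        delta = 0.5

        def raw_g(temps):
            ex = ris_enumerate(model, temps)
            t = np.atleast_1d(temps)[:, None]
            with np.errstate(divide="ignore"):
                return ex.P, np.where(
                    ex.P > 0, -KB * t * np.log(np.where(ex.P > 0, ex.P, 1.0)),
                    np.nan,
                )

        p, g = raw_g(LADDER)
        fit = fit_gibbs_helmholtz(
            MultiTemperaturePMF(LADDER, np.zeros(g.shape[1]), g), T0=T0,
        )
        _, g_fd = raw_g(np.array([T0 - delta, T0, T0 + delta]))
        h_fd = g_fd[1] - T0 * (g_fd[2] - g_fd[0]) / (2 * delta)
        well = (p[0] >= 1e-3) & np.isfinite(fit.H0) & np.isfinite(h_fd)
        assert well.sum() > 10
        rms = np.sqrt(np.mean((fit.H0[well] - h_fd[well]) ** 2))
        assert rms < 0.1


class TestPipeline:
    def test_temperature_independent_toy_has_flat_entropy(self):
        # histograms drawn from one T-independent distribution at every
        # temperature: the fit must attribute everything to enthalpy
        rng = np.random.default_rng(17)
        edges = np.linspace(0.0, 5.0, 26)
        base = rng.multinomial(200_000, np.full(25, 1 / 25.0))
        sets = [
            BiasedHistogramSet(
                bin_edges=edges, counts=base[None, :], bias_k=np.zeros(1),
                bias_r0=np.zeros(1), temperature=t,
            )
            for t in (298.15, 350.0, 400.0, 450.0, 500.0)
        ]
        # energy-dominated limit: G(T) = -kT ln p is linear in T, which the
        # form absorbs into B with C = 0 -> -TS = (B+C)T is the -kT ln p
        # shape itself; a genuinely T-independent *free energy* instead
        # requires identical G rows, tested in TestFitRecovery; here we
        # check the pipeline plumbing returns finite profiles end to end
        thermo, profiles = decompose_pmf_pipeline(sets)
        assert len(profiles) == 5
        assert np.isfinite(thermo.A).all()

    def test_stage_errors_are_named(self):
        edges = np.linspace(0.0, 3.0, 4)
        disconnected = BiasedHistogramSet(
            bin_edges=edges,
            counts=np.array([[5, 0, 0], [0, 0, 5]]),
            bias_k=np.array([50.0, 50.0]),
            bias_r0=np.array([0.5, 2.5]),
            temperature=298.15,
        )
        sets = [disconnected] * 3
        with pytest.raises(NumericalError, match=r"wham @ 298.15"):
            decompose_pmf_pipeline(sets)

    def test_sampled_ris_ladder_matches_enumeration_decomposition(self, warm_kernels):
        # full route: discrete sampling at each ladder temperature ->
        # Boltzmann inversion -> fit, against the same fit on exact G
        model = RISModel(cf.ChainTopology(9))
        exact = ris_enumerate(model, LADDER)
        edges = exact.bin_edges
        sets = []
        for i, t in enumerate(LADDER):
            r_samp, _, _ = ris_sample(
                model, temperature=t, n_steps=4_000_000, seed=100 + i,
            )
            counts, _ = np.histogram(r_samp, bins=edges)
            sets.append(BiasedHistogramSet(
                bin_edges=edges, counts=counts[None, :], bias_k=np.zeros(1),
                bias_r0=np.zeros(1), temperature=t,
            ))
        thermo_sampled, _ = decompose_pmf_pipeline(sets)
        thermo_exact = fit_gibbs_helmholtz(
            MultiTemperaturePMF(LADDER, exact.r, exact.G), T0=T0,
        )
        well = exact.P.min(axis=0) >= 1e-2
        h_s, mts_s = enthalpy_entropy(thermo_sampled, T0)
        h_e, mts_e = enthalpy_entropy(thermo_exact, T0)
        ok = well & np.isfinite(h_s) & np.isfinite(h_e)
        assert ok.sum() >= 10
        assert np.sqrt(np.mean((h_s[ok] - h_e[ok]) ** 2)) < 0.2
        assert np.sqrt(np.mean((mts_s[ok] - mts_e[ok]) ** 2)) < 0.2
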