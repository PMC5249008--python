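"""Unit tests for the log2CPM transform and the gamma-normal mixture EM."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize_scalar
from scipy.special import digamma

from coactive.mixture import (
    EMConfig,
    InsufficientCellsError,
    build_ternary_matrix,
    classify_cells,
    e_step,
    fit_gamma_normal,
    gamma_log_density,
    inverse_digamma,
    log2cpm,
    m_step,
    normal_log_density,
)
from coactive.synthetic import sample_mixture


def _df(values, genes=None, cells=None):
    values = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=cells)


class TestLog2CPM:
    def test_printed_formula_single_cell(self):
        y = log2cpm(_df([[0], [0], [4]]))
        expected = np.log2(1 + 1e6)
        assert y.iloc[2, 0] == pytest.approx(expected, abs=1e-12)
        assert y.iloc[0, 0] == 0.0 and y.iloc[1, 0] == 0.0
        assert expected == pytest.approx(19.9316, abs=1e-4)

    def test_library_size_normalisation(self):
        y = log2cpm(_df([[1], [1], [2]]))
        assert y.iloc[0, 0] == pytest.approx(np.log2(1 + 250000))
        assert y.iloc[1, 0] == pytest.approx(np.log2(1 + 250000))
        assert y.iloc[2, 0] == pytest.approx(np.log2(1 + 500000))

    def test_zero_pattern_conserved(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 20, size=(30, 10))
        counts[:, 0] = np.maximum(counts[:, 0], 1)  # no dead cell
        y = log2cpm(_df(counts))
        assert ((y.to_numpy() == 0) == (counts == 0)).all()

    def test_zero_total_cell_is_named_in_error(self):
        with pytest.raises(ValueError, match="c1"):
            log2cpm(_df([[1, 0], [2, 0]], cells=["c0", "c1"]))


class TestDensities:
    def test_exponential_special_case(self):
        assert gamma_log_density(1.0, 1.0, 1.0) == pytest.approx(-1.0, abs=1e-12)

    def test_standard_normal_mode(self):
        assert normal_log_density(3.0, 3.0, 1.0) == pytest.approx(
            -0.5 * np.log(2 * np.pi), abs=1e-12
        )

    def test_gamma_against_scipy(self):
        # independent evaluation through scipy's parameterisation (scale=1/rate)
        for x, a, b in [(2.0, 3.0, 1.5), (0.3, 0.7, 4.0), (11.0, 9.0, 0.8)]:
            assert gamma_log_density(x, a, b) == pytest.approx(
                stats.gamma.logpdf(x, a, scale=1.0 / b), abs=1e-12
            )

    def test_gamma_rejects_nonpositive_x(self):
        with pytest.raises(ValueError):
            gamma_log_density(0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            gamma_log_density(-1.0, 1.0, 1.0)


class TestInverseDigamma:
    @pytest.mark.parametrize("w", [0.1, 0.5, 1.0, 2.0, 10.0, 100.0])
    def test_round_trip(self, w):
        assert inverse_digamma(digamma(w)) == pytest.approx(w, rel=1e-9)

    def test_euler_mascheroni(self):
        assert inverse_digamma(-0.5772156649) == pytest.approx(1.0, abs=1e-8)

    def test_residual_across_magnitudes(self):
        shapes = np.logspace(-3, 3, 61)
        y = digamma(shapes)
        resid = np.abs(digamma(inverse_digamma(y)) - y)
        assert resid.max() < 1e-10

    def test_monotone(self):
        ys = np.linspace(-20, 10, 200)
        ws = inverse_digamma(ys)
        assert (np.diff(ws) > 0).all()


class TestEStep:
    def test_symmetric_posterior(self):
        # at the crossing point of the two densities with rho=0.5, z=0.5
        a, b, mu, s2 = 2.0, 1.0, 8.0, 1.0
        f = lambda x: gamma_log_density(x, a, b) - normal_log_density(x, mu, s2)
        from scipy.optimize import brentq

        x_eq = brentq(f, 1.0, 8.0)
        z = e_step(np.array([x_eq]), a, b, mu, s2, 0.5)
        assert z[0] == pytest.approx(0.5, abs=1e-9)

    def test_degenerate_mixing_weights(self):
        x = np.array([1.0, 5.0, 9.0])
        assert (e_step(x, 2, 1, 8, 1, 1.0) == 1.0).all()
        assert (e_step(x, 2, 1, 8, 1, 0.0) == 0.0).all()

    def test_matches_direct_density_ratio(self):
        # logistic form vs the two-density posterior computed without it
        rng = np.random.default_rng(42)
        for _ in range(50):
            x = rng.uniform(0.05, 15.0, size=20)
            a, b = rng.uniform(0.5, 10), rng.uniform(0.2, 5)
            mu, s2 = rng.uniform(2, 12), rng.uniform(0.2, 4)
            rho = rng.uniform(0.05, 0.95)
            z = e_step(x, a, b, mu, s2, rho)
            fn = np.exp(normal_log_density(x, mu, s2))
            fg = np.exp(gamma_log_density(x, a, b))
            direct = rho * fn / (rho * fn + (1 - rho) * fg)
            assert np.abs(z - direct).max() < 1e-12


class TestMStep:
    def test_all_weight_on_normal(self):
        x = np.array([2.0, 4.0, 9.0, 5.0])
        alpha, beta, mu, s2, rho = m_step(x, np.ones(4))
        assert mu == pytest.approx(x.mean())
        assert s2 == pytest.approx(x.var())  # population variance
        assert rho == 1.0

    def test_mixing_weight_is_mean_posterior(self):
        x = np.array([1.0, 2.0, 3.0, 10.0])
        *_, rho = m_step(x, np.full(4, 0.5))
        assert rho == pytest.approx(0.5)

    def test_weighted_gamma_mle_consistency(self):
        # oracle: generic numeric maximisation of the gamma log-likelihood
        rng = np.random.default_rng(3)
        x = rng.gamma(shape=3.0, scale=0.5, size=10_000)  # rate 2
        alpha, beta, *_ = m_step(x, np.zeros(x.size))
        assert abs(alpha - 3.0) / 3.0 < 0.05
        assert abs(beta - 2.0) / 2.0 < 0.05

        def nll(a):
            b = a / x.mean()  # profile rate
            return -np.sum(gamma_log_density(x, a, b))

        res = minimize_scalar(nll, bounds=(0.1, 20), method="bounded")
        assert alpha == pytest.approx(res.x, rel=1e-4)


class TestFitGammaNormal:
    def test_all_zero_input_is_insufficient(self):
        with pytest.raises(InsufficientCellsError):
            fit_gamma_normal(np.zeros(50), EMConfig())

    def test_too_few_nonzero_cells(self):
        x = np.zeros(100)
        x[:3] = [5.0, 6.0, 7.0]
        with pytest.raises(InsufficientCellsError):
            fit_gamma_normal(x, EMConfig(min_nonzero_cells=10))

    def test_parameter_recovery(self):
        errs_mu, errs_rho, errs_s2, accs = [], [], [], []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x, comp = sample_mixture(1000, 2.0, 2.0, 8.0, 1.0, 0.4, rng)
            fit = fit_gamma_normal(x, EMConfig(seed=100 + seed))
            errs_mu.append(abs(fit.mu - 8.0))
            errs_rho.append(abs(fit.rho - 0.4))
            errs_s2.append(abs(fit.sigma2 - 1.0))
            accs.append((classify_cells(fit) == comp).mean())
        assert np.median(errs_mu) < 0.15
        assert np.median(errs_rho) < 0.05
        assert np.median(errs_s2) < 0.2
        assert np.median(accs) > 0.95

    def test_loglik_monotone(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x, _ = sample_mixture(300, 2.0, 2.0, 8.0, 1.0, 0.4, rng)
            fit = fit_gamma_normal(x, EMConfig(seed=seed))
            assert (np.diff(fit.loglik_trace) >= -1e-8).all()

    def test_z_length_and_range(self):
        rng = np.random.default_rng(5)
        x_all = np.concatenate([np.zeros(40), rng.gamma(2, 2, 60)])
        fit = fit_gamma_normal(x_all, EMConfig(seed=1))
        assert fit.n_used == 60
        assert fit.z.shape == (60,)
        assert ((fit.z >= 0) & (fit.z <= 1)).all()

    def test_orientation_gamma_below_normal(self):
        # components must come out with the gamma (low) mean below the normal
        for seed in range(8):
            rng = np.random.default_rng(seed)
            x, _ = sample_mixture(400, 8.0, 1.5, 13.0, 0.5, 0.5, rng)
            fit = fit_gamma_normal(x, EMConfig(seed=seed))
            if fit.single_component is None:
                assert fit.alpha / fit.beta < fit.mu


class TestClassifyCells:
    def test_inclusive_boundary(self):
        fit = _fake_fit(z=[0.5, 0.49, 1.0, 0.0])
        assert list(classify_cells(fit, 0.5)) == [2, 1, 2, 1]

    def test_threshold_monotone(self):
        fit = _fake_fit(z=np.linspace(0, 1, 21))
        lo = classify_cells(fit, 0.3)
        hi = classify_cells(fit, 0.7)
        # raising the threshold can only move labels 2 -> 1
        assert ((hi <= lo)).all()

    def test_idempotent_on_degenerate_posteriors(self):
        fit = _fake_fit(z=np.ones(5))
        assert (classify_cells(fit) == 2).all()


def _fake_fit(z):
    from coactive.mixture import MixtureFit

    z = np.asarray(z, dtype=float)
    return MixtureFit(
        alpha=2.0,
        beta=2.0,
        mu=8.0,
        sigma2=1.0,
        rho=0.5,
        z=z,
        loglik_trace=np.array([0.0]),
        converged=True,
        n_used=z.size,
        n_iter=1,
    )


class TestBuildTernaryMatrix:
    def test_all_zero_gene_stays_zero(self):
        df = _df(np.zeros((1, 20)))
        tern, fits = build_ternary_matrix(df, EMConfig())
        assert (tern.to_numpy() == 0).all()
        assert not fits

    def test_sparse_gene_becomes_na(self):
        values = np.zeros((1, 30))
        values[0, :2] = [5.0, 6.0]
        tern, _ = build_ternary_matrix(_df(values), EMConfig(min_nonzero_cells=10))
        assert tern.iloc[0, :2].isna().all()
        assert (tern.iloc[0, 2:] == 0).all()

    def test_well_separated_bimodal_gene(self):
        rng = np.random.default_rng(0)
        low = rng.normal(2.0, 0.3, 100).clip(0.1)
        high = rng.normal(10.0, 0.3, 100)
        values = np.concatenate([low, high])[None, :]
        tern, _ = build_ternary_matrix(_df(values), EMConfig(seed=4))
        assert (tern.iloc[0, :100] == 1).all()
        assert (tern.iloc[0, 100:] == 2).all()

    def test_zero_pattern_conserved(self, planted_dataset):
        y = planted_dataset["logexpr"].to_numpy()
        t = planted_dataset["ternary"].to_numpy()
        assert ((t == 0) == (y == 0)).all()
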