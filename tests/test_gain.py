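"""GAIN construction: correlation difference z-test and interaction GLMs.

dcGAIN is checked against hand arithmetic and an independent straight-line
per-pair recomputation; reGAIN against per-pair statsmodels GLM fits.
"""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from netgain import dcgain, fisher_z, groupwise_correlation, regain
from netgain.gain import GainMatrix

from conftest import make_dataset


def brute_force_dcgain(data):
    """Independent per-pair recomputation with scipy primitives only."""
    cases = np.flatnonzero(data.phenotype == 1)
    controls = np.flatnonzero(data.phenotype == 0)
    m1, m0 = len(cases), len(controls)
    n = data.n_genes
    w = np.zeros((n, n))
    denom = np.sqrt(1 / (m1 - 3) + 1 / (m0 - 3))
    for i in range(n):
        for j in range(i + 1, n):
            r1 = stats.pearsonr(data.matrix[i, cases], data.matrix[j, cases])[0]
            r0 = stats.pearsonr(data.matrix[i, controls], data.matrix[j, controls])[0]
            z1 = np.arctanh(np.clip(r1, -1 + 1e-7, 1 - 1e-7))
            z0 = np.arctanh(np.clip(r0, -1 + 1e-7, 1 - 1e-7))
            w[i, j] = w[j, i] = abs(z1 - z0) / denom
    for i in range(n):
        w[i, i] = stats.ttest_ind(
            data.matrix[i, cases], data.matrix[i, controls], equal_var=False
        ).statistic
    return w


class TestGroupwiseCorrelation:
    def test_copy_and_negation(self, rng):
        x = rng.standard_normal(12)
        mat = np.vstack([x, x, -x, rng.standard_normal(12)])
        data = make_dataset(mat, [1] * 6 + [0] * 6)
        r = groupwise_correlation(data, 1)
        assert r[0, 1] == pytest.approx(1.0)
        assert r[0, 2] == pytest.approx(-1.0)

    def test_hand_computed_toy(self):
        # Gi=(1,2,3,4), Gj=(1,2,4,3): cov=4/3, sd_i=sd_j=sqrt(5/3) -> r=0.8
        mat = np.array([[1, 2, 3, 4, 0, 0, 0, 0], [1, 2, 4, 3, 0, 0, 0, 0]], dtype=float)
        mat[:, 4:] = np.random.default_rng(1).standard_normal((2, 4))
        data = make_dataset(mat, [1] * 4 + [0] * 4)
        assert groupwise_correlation(data, 1)[0, 1] == pytest.approx(0.8)

    def test_flat_gene_gets_zero(self, rng):
        mat = rng.standard_normal((3, 10))
        mat[1] = 5.0
        data = make_dataset(mat, [1] * 5 + [0] * 5)
        r = groupwise_correlation(data, 1)
        assert r[1, 0] == 0.0 and r[1, 2] == 0.0 and r[1, 1] == 1.0

    def test_small_group_rejected(self, rng):
        data = make_dataset(rng.standard_normal((3, 6)), [1, 1, 1, 0, 0, 0])
        with pytest.raises(ValueError, match="at least 4"):
            groupwise_correlation(data, 1)


class TestFisherZ:
    def test_fixed_point_and_reference_value(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.9) == pytest.approx(0.5 * np.log(19), abs=1e-12)

    def test_boundary_clamped_finite(self):
        assert np.isfinite(fisher_z(0.999999))
        assert np.isfinite(fisher_z(1.0))
        assert np.isfinite(fisher_z(-1.0))

    def test_domain_error(self):
        with pytest.raises(ValueError):
            fisher_z(1.5)

    def test_absolute_variant_discards_sign(self):
        assert fisher_z(-0.9, absolute=True) == pytest.approx(fisher_z(0.9))
        assert fisher_z(-0.9) == pytest.approx(-fisher_z(0.9))

    def test_odd_and_monotone(self):
        rs = np.linspace(-0.99, 0.99, 21)
        zs = fisher_z(rs)
        assert np.allclose(zs, -fisher_z(-rs))
        assert (np.diff(zs) > 0).all()


class TestDcgain:
    def test_identical_groups_zero_offdiagonal(self, rng):
        half = rng.standard_normal((5, 10))
        data = make_dataset(np.hstack([half, half]), [1] * 10 + [0] * 10)
        g = dcgain(data)
        off = g.off_diagonal()
        assert np.abs(off).max() == pytest.approx(0.0, abs=1e-12)
        # equal group means/variances -> null t on the diagonal too
        assert np.abs(np.diag(g.weights)).max() == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic_strong_vs_null_pair(self):
        # r1 = 0.9, r0 = 0, m1 = m0 = 20 -> Z = atanh(0.9)/sqrt(2/17)
        expected = np.arctanh(0.9) / np.sqrt(2 / 17)
        assert expected == pytest.approx(4.2922, abs=5e-4)

    def test_group_label_swap_invariance(self, interaction_sim):
        data = interaction_sim.expression
        swapped = data.with_phenotype(1 - np.asarray(data.phenotype))
        a = dcgain(data).off_diagonal()
        b = dcgain(swapped).off_diagonal()
        assert np.allclose(a, b, atol=1e-12)

    def test_matches_brute_force(self, rng):
        data = make_dataset(rng.standard_normal((20, 10)), [1] * 5 + [0] * 5)
        fast = dcgain(data).weights
        slow = brute_force_dcgain(data)
        assert np.allclose(fast, slow, atol=1e-12)

    def test_offdiagonals_nonnegative_and_symmetric(self, interaction_sim):
        g = dcgain(interaction_sim.expression)
        assert (g.off_diagonal() >= 0).all()
        assert np.allclose(g.weights, g.weights.T)

    def test_small_groups_raise(self, rng):
        data = make_dataset(rng.standard_normal((4, 7)), [1, 1, 1, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="m1-3"):
            dcgain(data)


class TestRegain:
    def _toy(self, n=6, m=60, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((n, m))
        logit = 0.8 * x[0] * x[1] + 0.5 * x[2]
        y = rng.binomial(1, 1 / (1 + np.exp(-logit)))
        if y.sum() in (0, m):
            y[0] = 1 - y[0]
        return make_dataset(x, y)

    def test_matches_statsmodels_glm(self):
        """Batched IRLS equals per-pair statsmodels fits (Wald z)."""
        data = self._toy()
        g = regain(data, stat="wald")
        xs = (data.matrix - data.matrix.mean(1, keepdims=True)) / data.matrix.std(
            1, ddof=1, keepdims=True
        )
        y = np.asarray(data.phenotype, dtype=float)
        m = data.n_samples
        for i in range(data.n_genes):
            design = np.column_stack([np.ones(m), xs[i]])
            fit = sm.GLM(y, design, family=sm.families.Binomial()).fit()
            assert g.weights[i, i] == pytest.approx(fit.params[1] / fit.bse[1], abs=1e-6)
            for j in range(i + 1, data.n_genes):
                design = np.column_stack([np.ones(m), xs[i], xs[j], xs[i] * xs[j]])
                fit = sm.GLM(y, design, family=sm.families.Binomial()).fit()
                assert g.weights[i, j] == pytest.approx(
                    fit.params[3] / fit.bse[3], abs=1e-6
                )

    def test_gaussian_family_matches_ols(self, rng):
        x = rng.standard_normal((4, 50))
        y = 0.5 * x[0] + rng.standard_normal(50)
        data = make_dataset(x, y)
        g = regain(data, family="gaussian", stat="wald")
        xs = (x - x.mean(1, keepdims=True)) / x.std(1, ddof=1, keepdims=True)
        design = np.column_stack([np.ones(50), xs[1], xs[2], xs[1] * xs[2]])
        fit = sm.OLS(y, design).fit()
        assert g.weights[1, 2] == pytest.approx(fit.params[3] / fit.bse[3], abs=1e-6)

    def test_beta_stat_returns_coefficient(self):
        data = self._toy()
        g = regain(data, stat="beta")
        xs = (data.matrix - data.matrix.mean(1, keepdims=True)) / data.matrix.std(
            1, ddof=1, keepdims=True
        )
        y = np.asarray(data.phenotype, dtype=float)
        design = np.column_stack(
            [np.ones(data.n_samples), xs[0], xs[1], xs[0] * xs[1]]
        )
        fit = sm.GLM(y, design, family=sm.families.Binomial()).fit()
        assert g.weights[0, 1] == pytest.approx(fit.params[3], abs=1e-6)

    def test_null_wald_statistics_are_standard_normal(self):
        """Phenotype independent of all genes: ~5% of |z| exceed 1.96."""
        rng = np.random.default_rng(42)
        x = rng.standard_normal((30, 300))
        y = rng.binomial(1, 0.5, 300)
        data = make_dataset(x, y)
        g = regain(data, stat="wald")
        z = g.weights[np.triu_indices(30, 1)]
        frac = np.mean(np.abs(z) > 1.96)
        assert frac == pytest.approx(0.05, abs=0.025)
        assert np.std(z) == pytest.approx(1.0, abs=0.12)

    def test_separated_fit_falls_back_not_crashes(self):
        # a gene that perfectly separates classes at tiny M
        rng = np.random.default_rng(3)
        x = rng.standard_normal((5, 20))
        y = np.array([1] * 10 + [0] * 10)
        x[0] = y * 2.0 - 1.0 + 0.01 * rng.standard_normal(20)
        data = make_dataset(x, y)
        g = regain(data)
        assert np.isfinite(g.weights).all()

    def test_covariate_adjustment_changes_fit(self):
        import pandas as pd

        data = self._toy(seed=5)
        sex = pd.DataFrame({"sex": np.tile([0, 1], data.n_samples // 2)})
        with_cov = make_dataset(data.matrix, data.phenotype, covariates=sex)
        g0 = regain(data)
        g1 = regain(with_cov)
        assert g1.info["n_covariates"] == 1
        assert not np.allclose(g0.weights, g1.weights)

    def test_rejects_bad_inputs(self, rng):
        data = make_dataset(rng.standard_normal((3, 10)), rng.standard_normal(10))
        with pytest.raises(ValueError):
            regain(data, family="binomial")  # quantitative phenotype
        with pytest.raises(ValueError):
            regain(data, family="poisson")


class TestGainMatrix:
    def test_symmetry_enforced(self):
        w = np.array([[1.0, 2.0], [3.0, 1.0]])
        with pytest.raises(ValueError):
            GainMatrix(weights=w, gene_ids=["a", "b"], method="dcgain", signed=False)

    def test_frame_round_trip(self, rng):
        w = rng.standard_normal((3, 3))
        w = (w + w.T) / 2
        g = GainMatrix(weights=w, gene_ids=list("abc"), method="regain", signed=True)
        assert np.allclose(g.to_frame().to_numpy(), w)
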