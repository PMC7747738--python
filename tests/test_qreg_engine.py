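"""Quantile-regression engine: exactness, invariances, bootstrap behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import qherit as q
from qherit.qreg_engine import _fit_lp
from qherit.sibpairs import SibPairSet


def pairs_from_xy(x, y, family_id=None):
    """Wrap raw (x, y) points as a pair set for direct engine testing."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    fam = np.asarray(family_id) if family_id is not None \
        else np.array([f"f{i}" for i in range(n)])
    ids = np.array([f"p{i}" for i in range(n)])
    return SibPairSet(family_id=fam, dep_id=ids, dep_value=y, indep_id=ids,
                      indep_value=x, dep_sex_filter="all",
                      effective_df=max(n // 2, 1))


class TestQuantileGrid:
    def test_default_is_5_to_95(self):
        g = q.QuantileGrid.default()
        assert len(g) == 91
        assert g.taus[0] == 5 and g.taus[-1] == 95
        assert g.is_equally_spaced()

    @pytest.mark.parametrize("taus", [[0, 50], [50, 100], [50, 40], []])
    def test_invalid_grids_rejected(self, taus):
        with pytest.raises(ValueError):
            q.QuantileGrid(np.asarray(taus, dtype=float))


class TestFitQuantile:
    def test_binary_predictor_median_fit(self):
        """Check loss separates by group; each group's fit is its median."""
        x = [0, 0, 0, 1, 1, 1]
        y = [1, 2, 3, 2, 4, 6]
        a, b = q.fit_quantile(pairs_from_xy(x, y), 50)
        assert a == pytest.approx(2.0, abs=1e-9)
        assert b == pytest.approx(2.0, abs=1e-9)

    def test_pinball_loss_is_minimised_at_the_median(self):
        """With no slope, the intercept minimising the check loss is the median."""
        x = np.zeros(3)
        y = np.array([1.0, 2.0, 3.0])
        at_median = q.pinball_loss(x, y, 2.0, 0.0, 0.5)
        for a in (1.5, 1.9, 2.1, 2.5):
            assert at_median <= q.pinball_loss(x, y, a, 0.0, 0.5) + 1e-12

    def test_identity_data_gives_unit_slope_everywhere(self):
        v = np.array([1.0, 2.0, 5.0, 9.0, 12.0])
        pairs = pairs_from_xy(v, v)
        for tau in (10, 50, 90):
            a, b = q.fit_quantile(pairs, tau)
            assert b == pytest.approx(1.0, abs=1e-9)
            assert a == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_basis_search(self, rng):
        """An optimal 2-parameter fit interpolates >= 2 points; enumerate them."""
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        pairs = pairs_from_xy(x, y)
        a, b = q.fit_quantile(pairs, 25)
        best = np.inf
        for i in range(12):
            for j in range(i + 1, 12):
                if x[i] == x[j]:
                    continue
                bb = (y[j] - y[i]) / (x[j] - x[i])
                aa = y[i] - bb * x[i]
                best = min(best, q.pinball_loss(x, y, aa, bb, 0.25))
        assert q.pinball_loss(x, y, a, b, 0.25) == pytest.approx(best, abs=1e-9)

    def test_constant_predictor_is_an_error(self):
        with pytest.raises(ValueError, match="constant"):
            q.fit_quantile(pairs_from_xy([1, 1, 1], [1, 2, 3]), 50)

    def test_irls_agrees_with_exact_lp(self, flat_null_pairs):
        pairs, _ = flat_null_pairs
        for tau in (30, 50, 80):
            a_lp, b_lp = q.fit_quantile(pairs, tau, method="exact")
            a_ir, b_ir = q.fit_quantile(pairs, tau, method="irls")
            assert b_ir == pytest.approx(b_lp, abs=5e-4)
            assert a_ir == pytest.approx(a_lp, abs=5e-3)

    def test_matches_statsmodels_quantreg(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        x = rng.normal(size=500)
        y = 1.0 + 0.4 * x + rng.standard_t(df=4, size=500)
        a, b = q.fit_quantile(pairs_from_xy(x, y), 50)
        ref = sm.QuantReg(y, np.column_stack([np.ones(500), x])).fit(q=0.5)
        assert b == pytest.approx(ref.params[1], abs=1e-4)
        assert a == pytest.approx(ref.params[0], abs=1e-4)

    @given(c=st.floats(0.1, 50.0), tau=st.sampled_from([20, 50, 80]))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_scale_equivariance(self, c, tau):
        rng = np.random.default_rng(7)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        a1, b1 = q.fit_quantile(pairs_from_xy(x, y), tau)
        a2, b2 = q.fit_quantile(pairs_from_xy(c * x, c * y), tau)
        assert b2 == pytest.approx(b1, abs=1e-7)
        assert a2 == pytest.approx(c * a1, rel=1e-6, abs=1e-7)

    def test_optimality_against_random_perturbations(self, rng):
        x = rng.normal(size=80)
        y = 0.3 * x + rng.normal(size=80)
        a, b = q.fit_quantile(pairs_from_xy(x, y), 40)
        loss = q.pinball_loss(x, y, a, b, 0.40)
        da, db = rng.normal(size=(2, 1000)) * 0.05
        for i in range(1000):
            assert loss <= q.pinball_loss(x, y, a + da[i], b + db[i], 0.40) + 1e-12


class TestFitGrid:
    def test_null_slopes_near_zero_when_sibs_independent(self):
        cfg = q.SyntheticConfig(n_families=1500, family_size_probs={2: 1.0},
                                sib_correlation=0.0, seed=99)
        cohort, _ = q.generate(cfg)
        pv = cohort.phenotype("leptin")
        pairs = q.build_pairs(cohort, pv, pv)
        qsf = q.bootstrap_vcv(pairs, q.QuantileGrid.coarse(10), n_boot=100,
                              seed=7)
        assert np.all(np.abs(qsf.slopes) < 3 * qsf.boot_se)

    def test_grid_order_and_df_carried(self, two_family_pairs):
        grid = q.QuantileGrid(np.array([25.0, 50.0, 75.0]))
        qsf = q.fit_grid(two_family_pairs, grid)
        assert qsf.slopes.shape == (3,)
        assert qsf.effective_df == two_family_pairs.effective_df

    def test_crossings_counted_not_fatal(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        qsf = q.fit_grid(pairs_from_xy(x, y), q.QuantileGrid.coarse(10))
        assert qsf.crossings >= 0  # diagnostic only

    def test_few_crossings_on_well_behaved_data(self, flat_null_pairs):
        pairs, _ = flat_null_pairs
        qsf = q.fit_grid(pairs, q.QuantileGrid.coarse(5), method="irls")
        assert qsf.crossings == 0

    def test_slope_interpolation_refuses_extrapolation(self, two_family_pairs):
        qsf = q.fit_grid(two_family_pairs, q.QuantileGrid(np.array([25.0, 75.0])))
        assert np.isnan(qsf.slope_at(10.0))
        assert not np.isnan(qsf.slope_at(50.0))


class TestBootstrap:
    def test_fixed_seed_is_bit_identical(self, two_family_pairs, rng):
        cfg = q.SyntheticConfig(n_families=60, sib_correlation=0.4, seed=4)
        cohort, _ = q.generate(cfg)
        pv = cohort.phenotype("leptin")
        pairs = q.build_pairs(cohort, pv, pv)
        grid = q.QuantileGrid.coarse(20)
        q1 = q.bootstrap_vcv(pairs, grid, n_boot=60, seed=5)
        q2 = q.bootstrap_vcv(pairs, grid, n_boot=60, seed=5)
        assert np.array_equal(q1.vcv, q2.vcv)
        assert np.array_equal(q1.replicates, q2.replicates)

    def test_growing_n_boot_extends_replicates(self):
        cfg = q.SyntheticConfig(n_families=60, sib_correlation=0.4, seed=4)
        cohort, _ = q.generate(cfg)
        pv = cohort.phenotype("leptin")
        pairs = q.build_pairs(cohort, pv, pv)
        grid = q.QuantileGrid.coarse(20)
        q1 = q.bootstrap_vcv(pairs, grid, n_boot=50, seed=5)
        q2 = q.bootstrap_vcv(pairs, grid, n_boot=70, seed=5)
        np.testing.assert_array_equal(q2.replicates[:50], q1.replicates)

    def test_vcv_is_symmetric_psd_with_matching_diagonal(self, skewed_qsf):
        vcv = skewed_qsf.vcv
        np.testing.assert_allclose(vcv, vcv.T, atol=1e-14)
        eigs = np.linalg.eigvalsh(vcv)
        assert eigs.min() > -1e-12
        np.testing.assert_allclose(np.diag(vcv),
                                   skewed_qsf.replicates.var(axis=0, ddof=1),
                                   rtol=1e-10)

    def test_sibship_unit_widens_se_under_clustering(self):
        cfg = q.SyntheticConfig(n_families=400, family_size_probs={3: 0.5, 4: 0.5},
                                sib_correlation=0.6, seed=21)
        cohort, _ = q.generate(cfg)
        pv = cohort.phenotype("leptin")
        pairs = q.build_pairs(cohort, pv, pv)
        grid = q.QuantileGrid.coarse(10)
        se_sib = q.bootstrap_vcv(pairs, grid, n_boot=100, unit="sibship",
                                 seed=31).boot_se
        se_pair = q.bootstrap_vcv(pairs, grid, n_boot=100, unit="pair",
                                  seed=31).boot_se
        assert se_sib.mean() > se_pair.mean()

    def test_bootstrap_se_tracks_sampling_variability(self):
        """Bootstrap SE of the median slope within 1.5x of the re-simulation SE."""
        def one_cohort(seed):
            cfg = q.SyntheticConfig(n_families=250, family_size_probs={2: 1.0},
                                    sib_correlation=0.3, seed=seed)
            cohort, _ = q.generate(cfg)
            pv = cohort.phenotype("leptin")
            return q.build_pairs(cohort, pv, pv)

        grid = q.QuantileGrid(np.array([50.0]))
        qsf = q.bootstrap_vcv(one_cohort(0), grid, n_boot=200, seed=77)
        resim = [q.fit_grid(one_cohort(s), grid, method="irls").slopes[0]
                 for s in range(1, 121)]
        ratio = qsf.boot_se[0] / np.std(resim, ddof=1)
        assert 1 / 1.5 < ratio < 1.5

    def test_requires_seed_and_minimum_replicates(self, two_family_pairs):
        with pytest.raises(ValueError, match="seed"):
            q.bootstrap_vcv(two_family_pairs, n_boot=50)
        with pytest.raises(ValueError, match="50"):
            q.bootstrap_vcv(two_family_pairs, n_boot=10, seed=1)
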