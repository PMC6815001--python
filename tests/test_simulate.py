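import numpy as np
import pandas as pd
import pytest

from pleioscore import simulate
from pleioscore.simulate import SimulationConfig


class TestLdStructure:
    def test_no_ld_gives_unit_scores(self):
        prof = simulate.make_ld_structure(20, block_size=1, rho=0.0)
        np.testing.assert_allclose(prof.scores, 1.0)
        assert prof.zero_variance

    def test_middle_of_block_of_three(self):
        prof = simulate.make_ld_structure(3, block_size=3, rho=0.9)
        # middle variant: 1 + 2 * 0.81
        assert prof.scores.iloc[1] == pytest.approx(2.62)

    def test_interior_limit_of_long_block(self):
        rho = 0.8
        prof = simulate.make_ld_structure(200, block_size=200, rho=rho)
        limit = 1 + 2 * rho**2 / (1 - rho**2)
        assert prof.scores.iloc[100] == pytest.approx(limit, rel=1e-4)

    def test_variable_block_pattern_covers_all_variants(self):
        prof = simulate.make_ld_structure(37, block_size=[2, 5, 10], rho=0.5)
        assert len(prof.scores) == 37
        assert prof.pairwise.block_sizes.sum() == 37

    def test_pairwise_r2_matches_ar1(self):
        prof = simulate.make_ld_structure(10, block_size=5, rho=0.6)
        assert prof.pairwise.r2("v0", "v2") == pytest.approx(0.6**4)
        assert prof.pairwise.r2("v4", "v5") == 0.0  # across blocks


class TestAssignCausal:
    def test_empty_architecture(self):
        cfg = SimulationConfig(n_variants=100, n_traits=5, prop_pleio=0,
                               prop_nonpleio=0, nu=2, seed=0)
        truth = simulate.assign_causal(cfg)
        assert not truth.pleiotropic.any() and not truth.causal_mask.any()

    def test_pleiotropic_count_is_exact(self):
        cfg = SimulationConfig(n_variants=8000, n_traits=10, prop_pleio=0.001,
                               nu=3, seed=1)
        truth = simulate.assign_causal(cfg)
        assert truth.pleiotropic.sum() == 8

    def test_each_pleiotropic_variant_hits_nu_traits(self):
        cfg = SimulationConfig(n_variants=1000, n_traits=20, prop_pleio=0.01,
                               nu=10, seed=2)
        truth = simulate.assign_causal(cfg)
        counts = truth.causal_mask[truth.pleiotropic].sum(axis=1)
        assert (counts == 10).all()

    def test_nonpleiotropic_selected_per_trait(self):
        cfg = SimulationConfig(n_variants=1000, n_traits=4, prop_pleio=0.0,
                               prop_nonpleio=0.05, nu=1, seed=3)
        truth = simulate.assign_causal(cfg)
        assert (truth.causal_mask.sum(axis=0) == 50).all()
        # independent draws per trait: the four columns are not identical
        assert len({tuple(np.flatnonzero(truth.causal_mask[:, j]))
                    for j in range(4)}) > 1

    def test_infeasible_config_rejected(self):
        cfg = SimulationConfig(n_variants=10, n_traits=2, prop_pleio=1.0,
                               prop_nonpleio=0.5, nu=1, seed=0)
        with pytest.raises(ValueError):
            simulate.assign_causal(cfg)

    def test_reproducible(self):
        cfg = SimulationConfig(n_variants=500, n_traits=5, prop_pleio=0.01,
                               nu=2, seed=11)
        a = simulate.assign_causal(cfg)
        b = simulate.assign_causal(cfg)
        np.testing.assert_array_equal(a.causal_mask, b.causal_mask)


class TestSimulateZscores:
    def test_null_no_ld_is_standard_normal(self):
        cfg = SimulationConfig(n_variants=100_000, n_traits=2, prop_pleio=0,
                               prop_nonpleio=0, nu=1, seed=4)
        m, truth, _ = simulate.simulate_dataset(cfg)
        assert abs(m.z.mean(axis=0)).max() < 0.015
        assert np.all((m.z.var(axis=0) > 0.98) & (m.z.var(axis=0) < 1.02))

    def test_null_with_ld_correlates_neighbours(self):
        cfg = SimulationConfig(n_variants=50_000, n_traits=2, prop_pleio=0,
                               prop_nonpleio=0, nu=1, ld_block_size=2,
                               ld_rho=0.9, seed=5)
        m, _, _ = simulate.simulate_dataset(cfg)
        pairs = m.z[0::2, 0], m.z[1::2, 0]
        assert np.corrcoef(pairs[0], pairs[1])[0, 1] == pytest.approx(0.9, abs=0.02)
        # marginal variance still 1
        assert m.z[:, 0].var() == pytest.approx(1.0, abs=0.03)

    def test_causal_noncentrality_convention(self):
        # all variants causal for the single trait with effective_n*h2 = 20:
        # E[Z^2] = 1 + 20
        cfg = SimulationConfig(n_variants=20_000, n_traits=1, prop_pleio=0.0,
                               prop_nonpleio=1.0, nu=1, h2=0.002,
                               effective_n=10_000, seed=6)
        m, truth, _ = simulate.simulate_dataset(cfg)
        assert truth.causal_mask.all()
        assert (m.z**2).mean() == pytest.approx(21.0, rel=0.05)

    def test_literal_mode_reproduces_small_causal_variance(self):
        cfg = SimulationConfig(n_variants=20_000, n_traits=1, prop_pleio=0.0,
                               prop_nonpleio=1.0, nu=1, h2=0.2, literal=True,
                               seed=7)
        m, truth, _ = simulate.simulate_dataset(cfg)
        # causal Z drawn from N(0, h2): quieter than the null
        assert (m.z**2).mean() == pytest.approx(0.2, rel=0.05)

    def test_factor_model_mixes_traits(self):
        cfg = SimulationConfig(n_variants=30_000, n_traits=10, prop_pleio=0,
                               prop_nonpleio=0, nu=1,
                               trait_corr="factor_model", n_factors=2, seed=8)
        m, _, _ = simulate.simulate_dataset(cfg)
        corr = np.corrcoef(m.z, rowvar=False)
        off = np.abs(corr[~np.eye(10, dtype=bool)])
        assert off.max() > 0.2  # factor structure induces real correlation
        assert np.allclose(np.diag(corr), 1.0, atol=0.05)

    def test_bit_identical_under_fixed_seed(self):
        cfg = SimulationConfig(n_variants=500, n_traits=4, prop_pleio=0.01,
                               nu=2, ld_block_size=5, ld_rho=0.5, seed=9)
        a, _, _ = simulate.simulate_dataset(cfg)
        b, _, _ = simulate.simulate_dataset(cfg)
        np.testing.assert_array_equal(a.z, b.z)


class TestEvaluateDetection:
    def _truth(self, n, pleio_idx):
        pleio = np.zeros(n, dtype=bool)
        pleio[pleio_idx] = True
        mask = np.zeros((n, 2), dtype=bool)
        mask[pleio_idx] = True
        return simulate.SimulationTruth(pleio, mask, 1.0)

    def _table(self, p):
        return pd.DataFrame({"variant_id": [f"v{i}" for i in range(len(p))],
                             "p_m": p})

    def test_all_p_one_detects_nothing(self):
        truth = self._truth(10, [0])
        out = simulate.evaluate_detection(
            self._table(np.ones(10)), truth, p_columns=("p_m",)
        )
        assert out["power"].iloc[0] == 0.0 and out["fpr"].iloc[0] == 0.0

    def test_perfect_separation(self):
        truth = self._truth(10, [0, 1])
        p = np.ones(10)
        p[:2] = 1e-10
        out = simulate.evaluate_detection(self._table(p), truth,
                                          p_columns=("p_m",))
        assert out["power"].iloc[0] == 1.0 and out["fpr"].iloc[0] == 0.0

    def test_null_uniform_p_gives_alpha_fpr(self, rng):
        n = 50_000
        truth = self._truth(n, [])
        out = simulate.evaluate_detection(
            self._table(rng.uniform(size=n)), truth, alpha=0.05,
            p_columns=("p_m",),
        )
        assert out["fpr"].iloc[0] == pytest.approx(0.05, abs=0.005)
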