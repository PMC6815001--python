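import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from pleioscore import gwps, simulate, whitening
from pleioscore.gwps import Locus
from pleioscore.ld import SparseLD
from pleioscore.pipeline import score_summary_matrix
from pleioscore.simulate import SimulationConfig
from tests.conftest import make_matrix


def _score_frame(p, pos=None, chrom="1"):
    n = len(p)
    return pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(n)],
        "chr": chrom,
        "pos": pos if pos is not None else np.arange(1, n + 1) * 1000,
        "p_m": p,
    })


def clump_oracle_check(loci, table, pairwise, p_index, p_member, r2_min, window):
    """Verify every defining constraint of the greedy clumping procedure."""
    df = table.set_index("variant_id")
    assigned = {}
    for lo in loci:
        for v in lo.member_variants:
            assert v not in assigned, "variant in two loci"
            assigned[v] = lo.index_variant
    # every variant at or below the index threshold is assigned somewhere
    for v, row in df.iterrows():
        if row["p_m"] <= p_index:
            assert v in assigned
    for lo in loci:
        idx = lo.index_variant
        assert df.loc[idx, "p_m"] <= p_index
        assert lo.index_p == df.loc[idx, "p_m"]
        for v in lo.member_variants:
            if v == idx:
                continue
            assert df.loc[v, "p_m"] <= p_member
            assert abs(df.loc[v, "pos"] - df.loc[idx, "pos"]) <= window
            assert pairwise.r2(idx, v) >= r2_min
    # indices processed in ascending P: a locus index cannot satisfy the
    # membership constraints of an earlier (smaller-P) locus index
    order = sorted(loci, key=lambda lo: lo.index_p)
    for i, lo in enumerate(order):
        for prev in order[:i]:
            pidx = prev.index_variant
            close = abs(df.loc[lo.index_variant, "pos"] - df.loc[pidx, "pos"]) <= window
            linked = pairwise.r2(pidx, lo.index_variant) >= r2_min
            assert not (close and linked and df.loc[lo.index_variant, "p_m"] <= p_member)


class TestClump:
    def test_no_significant_variants_yields_no_loci(self):
        table = _score_frame([0.5, 0.2, 1e-6])
        assert gwps.clump(table, SparseLD()) == []

    def test_hand_traced_three_variant_example(self):
        table = _score_frame([1e-12, 1e-10, 1e-9], pos=[200_000, 1_000, 1_500])
        ld = SparseLD({("v1", "v2"): 0.5})
        loci = gwps.clump(table, ld)
        assert len(loci) == 2
        assert loci[0].index_variant == "v0" and loci[0].member_variants == ["v0"]
        assert loci[1].index_variant == "v1"
        assert set(loci[1].member_variants) == {"v1", "v2"}

    def test_distance_threshold_splits_linked_pair(self):
        table = _score_frame([1e-10, 1e-9], pos=[1_000, 201_000])
        ld = SparseLD({("v0", "v1"): 0.9})
        assert len(gwps.clump(table, ld)) == 2

    def test_greedy_agrees_with_constraint_oracle(self, rng):
        for trial in range(10):
            n = 50
            p = 10.0 ** (-rng.uniform(0, 12, size=n))
            pos = np.sort(rng.integers(1, 500_000, size=n))
            table = _score_frame(p, pos=pos)
            pairs = {}
            ld = SparseLD()
            for _ in range(120):
                i, j = rng.integers(0, n, size=2)
                if i != j:
                    ld.add(f"v{i}", f"v{j}", float(rng.uniform()))
            loci = gwps.clump(table, ld, p_index=1e-6, p_member=0.05)
            clump_oracle_check(loci, table, ld, 1e-6, 0.05, 0.1, 100_000)

    def test_bed_output_is_half_open(self):
        loci = [Locus("v1", "2", 100, 250, ["v1", "v2"], 1e-9)]
        bed = gwps.loci_to_bed(loci)
        assert bed.loc[0, "start"] == 99 and bed.loc[0, "end"] == 250


def _meta(maf, categories):
    idx = pd.Index([f"v{i}" for i in range(len(maf))], name="variant_id")
    return pd.DataFrame({"maf": maf, "categories": categories}, index=idx)


class TestEnrichment:
    def test_shifted_query_detected(self, rng):
        n = 10_000
        maf = rng.uniform(0.01, 0.5, size=n)
        labels = [{"coding"} if i < n // 5 else {"noncoding"} for i in range(n)]
        score = rng.normal(10, 1, size=n)
        score[: n // 5] += 0.5
        table = _score_frame(np.ones(n)).assign(pm_ld=score)
        res = gwps.enrichment_test(table, _meta(maf, labels), "coding",
                                   "noncoding", seed=0)
        assert res.delta_mean == pytest.approx(0.5, abs=0.1)
        assert res.p < 1e-10
        assert res.n_query == n // 5 and res.n_reference == n // 5

    def test_identical_query_and_reference_sets(self, rng):
        n = 200
        maf = rng.uniform(0.05, 0.5, size=n)
        labels = [{"a", "b"}] * n  # every variant in both categories
        table = _score_frame(np.ones(n)).assign(pm_ld=rng.normal(size=n))
        res = gwps.enrichment_test(table, _meta(maf, labels), "a", "b",
                                   n_maf_bins=10, seed=1)
        assert res.delta_mean == pytest.approx(0.0, abs=1e-12)

    def test_null_p_values_are_uniform_across_seeds(self, rng):
        n = 400
        maf = rng.uniform(0.01, 0.5, size=n)
        labels = [{"q"} if i < n // 2 else {"r"} for i in range(n)]
        score = rng.normal(size=n)
        table = _score_frame(np.ones(n)).assign(pm_ld=score)
        meta = _meta(maf, labels)
        ps = []
        for seed in range(200):
            perm = rng.permutation(n)
            table2 = table.assign(pm_ld=score[perm])
            ps.append(gwps.enrichment_test(table2, meta, "q", "r",
                                           n_maf_bins=5, seed=seed).p)
        assert st.kstest(ps, "uniform").pvalue > 1e-3

    def test_missing_maf_rejected(self, rng):
        meta = _meta([0.1, np.nan], [{"q"}, {"r"}])
        table = _score_frame(np.ones(2)).assign(pm_ld=[1.0, 2.0])
        with pytest.raises(ValueError, match="MAF"):
            gwps.enrichment_test(table, meta, "q", "r")


class TestReplication:
    def _whitened(self, rng, n=2000, l=10):
        m = make_matrix(rng.normal(size=(n, l)))
        model = whitening.TraitCorrelationModel(np.eye(l), m.trait_ids)
        return whitening.whiten(m, model)

    def test_identical_discovery_replicates_fully(self, rng):
        w = self._whitened(rng)
        res = score_summary_matrix(make_matrix(w.z))
        p = res.table.set_index("variant_id")["p_m"]
        strong = p.nsmallest(20)
        loci = [Locus(v, "1", 1, 1, [v], pv) for v, pv in strong.items()]
        out = gwps.replication_analysis(loci, p, w, alpha=max(strong) * 1.01,
                                        n_null_permutations=2, seed=0)
        assert out["observed_fraction"] == 1.0

    def test_null_replication_fraction_near_alpha(self, rng):
        w = self._whitened(rng, n=4000, l=20)
        res = score_summary_matrix(make_matrix(w.z))
        p = res.table.set_index("variant_id")["p_m"]
        chosen = rng.choice(p.index.to_numpy(), size=200, replace=False)
        loci = [Locus(v, "1", 1, 1, [v], 1e-9) for v in chosen]
        out = gwps.replication_analysis(loci, p, w, alpha=0.05,
                                        n_null_permutations=10, seed=1)
        assert out["null_fraction"] == pytest.approx(0.05, abs=0.015)

    def test_zero_loci_reported_missing(self, rng):
        w = self._whitened(rng, n=100)
        out = gwps.replication_analysis([], pd.Series(dtype=float), w)
        assert np.isnan(out["observed_fraction"]) and out["n_loci"] == 0


class TestGeneAverage:
    def test_means_and_ranking(self):
        table = _score_frame(np.ones(3)).assign(pm=[10.0, 20.0, 7.0])
        mapping = {"v0": "G1", "v1": "G1", "v2": "G2"}
        out = gwps.gene_average(table, mapping, score_columns=("pm",))
        assert out.loc["G1", "pm"] == pytest.approx(15.0)
        assert out.loc["G2", "pm"] == pytest.approx(7.0)
        assert list(out.index) == ["G1", "G2"]
        assert out.loc["G1", "n_variants"] == 2

    def test_unmapped_genes_excluded(self):
        table = _score_frame(np.ones(2)).assign(pm=[1.0, 2.0])
        out = gwps.gene_average(table, {"v0": "G1", "vX": "G9"},
                                score_columns=("pm",))
        assert list(out.index) == ["G1"]


class TestTraitContribution:
    def test_trait_equal_to_score_has_unit_correlation(self, rng):
        n = 100
        score = rng.uniform(5, 50, size=n)
        z = np.column_stack([score, rng.normal(size=n)])
        m = make_matrix(z)
        table = _score_frame(np.full(n, 1e-10)).assign(pm_ld=score)
        out = gwps.trait_contribution(table, m)
        assert out["t0"] == pytest.approx(1.0)
        assert abs(out["t1"]) < 0.5

    def test_independent_trait_has_near_zero_correlation(self, rng):
        n = 10_000
        score = rng.uniform(size=n)
        m = make_matrix(rng.normal(size=(n, 1)))
        table = _score_frame(np.full(n, 1e-10)).assign(pm_ld=score)
        out = gwps.trait_contribution(table, m)
        assert abs(out["t0"]) < 0.03

    def test_constant_trait_reported_missing(self, rng):
        n = 10
        m = make_matrix(np.ones((n, 1)))
        table = _score_frame(np.full(n, 1e-10)).assign(pm_ld=rng.uniform(size=n))
        assert np.isnan(gwps.trait_contribution(table, m)["t0"])

    def test_too_few_significant_variants_rejected(self, rng):
        m = make_matrix(rng.normal(size=(10, 1)))
        table = _score_frame(np.ones(10)).assign(pm_ld=1.0)
        with pytest.raises(ValueError):
            gwps.trait_contribution(table, m)
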