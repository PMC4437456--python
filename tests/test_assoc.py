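import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import panphen as pp
from panphen.pangenome import PhyloProfile, profile_id_for_pattern
from panphen.phylo import BMCovariance


def make_profile(pattern):
    pattern = tuple(int(v) for v in pattern)
    return PhyloProfile(profile_id_for_pattern(pattern), pattern, ("cX",))


def make_trait(values, strains, name="t"):
    return pp.BinaryTrait(name, pd.Series(values, index=strains,
                                          dtype=float))


class TestBinarize:
    def test_default_rule_any_positive(self):
        table = pp.PhenotypeTable(pd.DataFrame(
            {"t": [1.0, 0.75, 0.0, np.nan]}, index=list("abcd")))
        bt = pp.binarize_phenotype(table, "t")
        assert list(bt.values[:3]) == [1.0, 1.0, 0.0]
        assert np.isnan(bt.values["d"])
        assert bt.documented_strains == ["a", "b", "c"]

    def test_strict_rule(self):
        table = pp.PhenotypeTable(pd.DataFrame(
            {"t": [1.0, 0.75, 0.0, np.nan]}, index=list("abcd")))
        bt = pp.binarize_phenotype(table, "t", rule="strict")
        assert list(bt.values[:3]) == [1.0, 0.0, 0.0]

    def test_lactose_fixture_17_positive_4_negative(self, api50ch_table):
        bt = pp.binarize_phenotype(api50ch_table, "lactose")
        assert bt.n_positive == 17
        assert bt.n_negative == 4
        assert bt.testable

    def test_untestable_trait_flagged(self):
        table = pp.PhenotypeTable(pd.DataFrame(
            {"t": [1.0, 0.0, 0.0, 0.0]}, index=list("abcd")))
        assert not pp.binarize_phenotype(table, "t").testable

    def test_unknown_trait_and_rule(self, api50ch_table):
        with pytest.raises(KeyError):
            pp.binarize_phenotype(api50ch_table, "nope")
        with pytest.raises(ValueError):
            pp.binarize_phenotype(api50ch_table, "lactose", rule="bogus")


def fisher_oracle(a, b, c, d):
    """Full enumeration over all tables with the observed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    obs = math.comb(r1, a) * math.comb(r2, c) / math.comb(n, c1)
    total = 0.0
    for aa in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = math.comb(r1, aa) * math.comb(r2, c1 - aa) / math.comb(n, c1)
        if p <= obs * (1 + 1e-12):
            total += p
    return total


class TestFisher:
    def test_perfect_match_9_of_22(self):
        strains = [f"s{i}" for i in range(22)]
        values = [1.0] * 9 + [0.0] * 13
        trait = make_trait(values, strains)
        res = pp.fisher_association(trait, make_profile(values), strains)
        assert res.p_value == pytest.approx(1 / 497420, rel=1e-9)

    def test_degenerate_profile_p_one(self):
        strains = list("abcd")
        trait = make_trait([1, 1, 0, 0], strains)
        res = pp.fisher_association(trait, make_profile([1, 1, 1, 1]),
                                    strains)
        assert res.p_value == 1.0 and res.degenerate

    def test_matches_enumeration_oracle_on_random_tables(self, rng):
        strains = [f"s{i}" for i in range(16)]
        for _ in range(500):
            y = rng.integers(0, 2, size=16).astype(float)
            x = rng.integers(0, 2, size=16)
            trait = make_trait(y, strains)
            res = pp.fisher_association(trait, make_profile(x), strains)
            if res.degenerate:
                continue
            a = int(((y == 1) & (x == 1)).sum())
            b = int(((y == 1) & (x == 0)).sum())
            c = int(((y == 0) & (x == 1)).sum())
            d = int(((y == 0) & (x == 0)).sum())
            assert res.p_value == pytest.approx(fisher_oracle(a, b, c, d),
                                                abs=1e-12)

    def test_invariant_to_joint_permutation(self, rng):
        strains = [f"s{i}" for i in range(14)]
        y = rng.integers(0, 2, size=14).astype(float)
        x = rng.integers(0, 2, size=14)
        p1 = pp.fisher_association(make_trait(y, strains),
                                   make_profile(x), strains).p_value
        order = rng.permutation(14)
        strains2 = [strains[i] for i in order]
        p2 = pp.fisher_association(make_trait(y[order], strains2),
                                   make_profile(x[order]), strains2).p_value
        assert p1 == pytest.approx(p2, abs=1e-15)

    def test_missing_scores_reduce_n(self):
        strains = list("abcdef")
        trait = make_trait([1, 1, 0, 0, np.nan, np.nan], strains)
        res = pp.fisher_association(trait, make_profile([1, 1, 0, 0, 1, 0]),
                                    strains)
        assert res.n_used == 4


def ols_oracle(y, x):
    """Plain OLS slope t-test (the GLS must reduce to this when V = I)."""
    import statsmodels.api as sm

    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return fit.params[1], fit.tvalues[1], fit.pvalues[1]


class TestGLS:
    def test_reduces_to_ols_with_identity_covariance(self, rng):
        n = 12
        strains = [f"s{i}" for i in range(n)]
        V = BMCovariance(strains, np.eye(n))
        for _ in range(10):
            x = rng.integers(0, 2, size=n)
            if x.min() == x.max():
                continue
            y = 0.4 * x + rng.normal(size=n)
            y = (y > np.median(y)).astype(float)
            trait = make_trait(y, strains)
            res = pp.gls_association(trait, make_profile(x), V)
            if res.degenerate or not np.isfinite(res.statistic):
                continue
            b1, t, p = ols_oracle(y, x.astype(float))
            assert res.coefficient == pytest.approx(b1, abs=1e-10)
            assert res.statistic == pytest.approx(t, abs=1e-10)
            assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_four_taxon_matrix_inversion_oracle(self):
        strains = list("ABCD")
        V = BMCovariance(strains, np.array(
            [[2.0, 1.0, 0.0, 0.0], [1.0, 2.0, 0.0, 0.0],
             [0.0, 0.0, 2.0, 1.0], [0.0, 0.0, 1.0, 2.0]]))
        x = np.array([1.0, 0.0, 1.0, 0.0])
        y = np.array([1.0, 1.0, 0.0, 0.0])
        res = pp.gls_association(make_trait(y, strains), make_profile(x), V)
        # explicit hand computation with matrix inversion
        X = np.column_stack([np.ones(4), x])
        Vi = np.linalg.inv(V.values)
        beta = np.linalg.inv(X.T @ Vi @ X) @ X.T @ Vi @ y
        resid = y - X @ beta
        s2 = resid @ Vi @ resid / 2
        se = math.sqrt(s2 * np.linalg.inv(X.T @ Vi @ X)[1, 1])
        t = beta[1] / se
        p = 2 * stats.t.sf(abs(t), 2)
        assert res.coefficient == pytest.approx(beta[1], abs=1e-12)
        assert res.statistic == pytest.approx(t, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_perfect_separation_gives_unit_slope_zero_p(self):
        strains = list("ABCD")
        V = BMCovariance(strains, np.array(
            [[2.0, 1.0, 0.0, 0.0], [1.0, 2.0, 0.0, 0.0],
             [0.0, 0.0, 2.0, 1.0], [0.0, 0.0, 1.0, 2.0]]))
        y = np.array([1.0, 1.0, 0.0, 0.0])
        res = pp.gls_association(make_trait(y, strains), make_profile(y), V)
        assert res.coefficient == pytest.approx(1.0)
        assert res.p_value == 0.0

    def test_invariant_to_covariance_rescaling(self):
        t = pp.simulate_tree(10, seed=8)
        V = pp.bm_covariance(t)
        strains = V.strains
        rng = np.random.default_rng(1)
        x = rng.integers(0, 2, size=10)
        y = rng.integers(0, 2, size=10).astype(float)
        trait = make_trait(y, strains)
        res1 = pp.gls_association(trait, make_profile(x), V)
        V37 = BMCovariance(strains, 37.0 * V.values)
        res2 = pp.gls_association(trait, make_profile(x), V37)
        assert res1.p_value == pytest.approx(res2.p_value, abs=1e-9)
        assert res1.statistic == pytest.approx(res2.statistic, abs=1e-9)

    def test_degenerate_profile_flagged(self):
        strains = list("ABCD")
        V = BMCovariance(strains, np.eye(4))
        trait = make_trait([1, 1, 0, 0], strains)
        res = pp.gls_association(trait, make_profile([1, 1, 1, 1]), V)
        assert res.degenerate and res.p_value == 1.0


def _null_setup(seed=303):
    tree = pp.simulate_tree(22, seed=seed)
    V = pp.bm_covariance(tree)
    # x: a clade profile of intermediate size
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        leaves = {lf.taxon.label for lf in node.leaf_iter()}
        if 6 <= len(leaves) <= 16:
            x = np.array([1.0 if s in leaves else 0.0 for s in V.strains])
            return tree, V, x
    raise AssertionError("no mid-size clade in the fixture tree")


def _bm_draws(V, n_reps, seed):
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(V.values + 1e-10 * np.eye(len(V.strains)))
    return L @ rng.standard_normal((len(V.strains), n_reps))


def _accessory_profiles(tree, strains, n, seed):
    """Independent gain/loss gene patterns used as null genotypes."""
    pa = pp.simulate_gene_content(tree, n_core=0, gain_rate=1.0,
                                  loss_rate=1.0, seed=seed, n_accessory=n)
    cols = pa.presence[pa.cluster_ids].to_numpy()
    return [make_profile(cols[[pa.strains.index(s) for s in strains], j])
            for j in range(n)]


class TestNullCalibration:
    def test_p_uniform_under_continuous_bm_null(self):
        tree, V, x = _null_setup()
        ys = _bm_draws(V, 1000, seed=99)
        profile = make_profile(x)
        ps = []
        for k in range(ys.shape[1]):
            trait = pp.BinaryTrait("y", pd.Series(ys[:, k], index=V.strains))
            ps.append(pp.gls_association(trait, profile, V).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_type_one_error_with_thresholded_null(self):
        # each replicate pairs an independent thresholded BM trait with an
        # independently simulated accessory-gene profile, mirroring what
        # the scan actually tests; the 5%-level rejection rate must sit in
        # the [0.03, 0.07] band
        tree, V, _ = _null_setup()
        ys = _bm_draws(V, 1000, seed=100)
        rejections = tested = 0
        profiles = _accessory_profiles(tree, V.strains, 1000, seed=556)
        for k in range(ys.shape[1]):
            y = (ys[:, k] > np.median(ys[:, k])).astype(float)
            trait = pp.BinaryTrait("y", pd.Series(y, index=V.strains))
            res = pp.gls_association(trait, profiles[k], V)
            if res.degenerate:
                continue
            tested += 1
            rejections += res.p_value < 0.05
        assert tested > 900
        assert 0.03 <= rejections / tested <= 0.07

    def test_gls_corrects_where_fisher_inflates(self):
        # thresholded BM traits carry pure phylogenetic signal; against a
        # clade-shaped profile, Fisher p-values should be systematically
        # smaller (anti-conservative) than the phylogeny-aware GLS ones
        tree, V, x = _null_setup()
        ys = _bm_draws(V, 200, seed=101)
        profile = make_profile(x)
        fisher_ps, gls_ps = [], []
        for k in range(ys.shape[1]):
            y = (ys[:, k] > np.median(ys[:, k])).astype(float)
            trait = pp.BinaryTrait("y", pd.Series(y, index=V.strains))
            fisher_ps.append(
                pp.fisher_association(trait, profile, V.strains).p_value)
            gls_ps.append(pp.gls_association(trait, profile, V).p_value)
        assert np.median(fisher_ps) < np.median(gls_ps)


class TestScan:
    def test_perfect_profile_attains_minimum_gls_p(self, small_panel):
        pa, truth = small_panel.pa, small_panel.truth
        profiles = pp.dedup_profiles(pa)
        V = pp.bm_covariance(small_panel.tree, strains=pa.strains)
        report = pp.run_association_scan(profiles, small_panel.phenotypes,
                                         V, strains=pa.strains)
        sub = report.results[report.results.trait == "island_trait"]
        best = sub.sort_values("gls_p").iloc[0]
        causal_pattern = tuple(int(s in truth.strains_with_island)
                               for s in pa.strains)
        assert best.profile_id == profile_id_for_pattern(causal_pattern)
        assert best.gls_p == sub.gls_p.min()

    def test_strain_mismatch_reported(self, small_panel):
        profiles = pp.dedup_profiles(small_panel.pa)
        V = pp.bm_covariance(small_panel.tree,
                             strains=small_panel.pa.strains)
        bad = pp.PhenotypeTable(pd.DataFrame(
            {"t": [1, 1, 0, 0]}, index=["zz1", "zz2", "zz3", "zz4"]))
        with pytest.raises(ValueError, match="zz1"):
            pp.run_association_scan(profiles, bad, V,
                                    strains=small_panel.pa.strains)

    def test_untestable_traits_skipped_cleanly(self, small_panel):
        pa = small_panel.pa
        profiles = pp.dedup_profiles(pa)
        V = pp.bm_covariance(small_panel.tree, strains=pa.strains)
        table = pp.PhenotypeTable(pd.DataFrame(
            {"all_on": [1.0] * pa.n_strains}, index=pa.strains))
        report = pp.run_association_scan(profiles, table, V,
                                         strains=pa.strains)
        assert report.untestable_traits == ["all_on"]
        assert len(report.results) == 0
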