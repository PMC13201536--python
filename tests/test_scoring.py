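import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from skinarch.scoring import (
    GeneSet,
    SignatureWeights,
    aucell,
    build_signature,
    gsea_batch,
    module_score,
    preranked_gsea,
    pseudobulk,
    ulm_score,
    ulm_scores,
)

from .conftest import make_norm


def deg(genes, log2fc, padj):
    return pd.DataFrame({"gene": genes, "log2fc": log2fc, "padj": padj})


class TestBuildSignature:
    def test_padj_cutoff(self):
        table = deg(list("abcd"), [1, 2, 3, 4], [0.01, 0.06, 0.04, 0.001])
        sig = build_signature(table)
        assert set(sig.weights.index) == {"a", "c", "d"}

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            build_signature(deg([], [], []))

    def test_duplicate_gene_named(self):
        table = deg(["a", "a", "b"], [1, 2, 3], [0.01] * 3)
        with pytest.raises(ValueError, match="a"):
            build_signature(table)

    def test_too_few_genes(self):
        with pytest.raises(ValueError, match="at least 3"):
            build_signature(deg(list("abc"), [1, 2, 3], [0.01, 0.01, 0.9]))


def random_sig(rng, genes):
    return SignatureWeights(pd.Series(rng.normal(size=len(genes)), index=genes))


class TestUlmScore:
    def test_orthogonal_profile_near_zero(self, rng):
        n = 50
        w = rng.normal(size=n)
        wc = w - w.mean()
        y = rng.normal(size=n)
        y = y - y.mean() - (y @ wc) / (wc @ wc) * wc  # exactly orthogonal
        genes = [f"g{i}" for i in range(n)]
        sig = SignatureWeights(pd.Series(w, index=genes))
        score, sat = ulm_score(pd.Series(y, index=genes), sig)
        assert abs(score) < 1e-8
        assert not sat

    def test_perfect_fit_saturates_positive(self, rng):
        w = rng.normal(size=20)
        genes = [f"g{i}" for i in range(20)]
        sig = SignatureWeights(pd.Series(w, index=genes))
        score, sat = ulm_score(pd.Series(2 * w, index=genes), sig)
        assert sat and score > 1e5

    def test_matches_statsmodels_oracle(self, rng):
        genes = [f"g{i}" for i in range(20)]
        for _ in range(20):
            w = rng.normal(size=20)
            y = rng.normal(size=20)
            sig = SignatureWeights(pd.Series(w, index=genes))
            score, _ = ulm_score(pd.Series(y, index=genes), sig)
            fit = sm.OLS(y, sm.add_constant(w)).fit()
            assert score == pytest.approx(fit.tvalues[1], abs=1e-8)

    def test_affine_weight_invariance(self, rng):
        genes = [f"g{i}" for i in range(15)]
        w = rng.normal(size=15)
        y = pd.Series(rng.normal(size=15), index=genes)
        s0, _ = ulm_score(y, SignatureWeights(pd.Series(w, index=genes)))
        s1, _ = ulm_score(y, SignatureWeights(pd.Series(3.7 * w + 2.0, index=genes)))
        s2, _ = ulm_score(y, SignatureWeights(pd.Series(-w, index=genes)))
        assert s1 == pytest.approx(s0, abs=1e-9)
        assert s2 == pytest.approx(-s0, abs=1e-9)

    def test_vectorized_matches_scalar(self, rng):
        genes = [f"g{i}" for i in range(12)]
        sig = random_sig(rng, genes)
        values = rng.normal(size=(8, 12))
        norm = make_norm(values, features=genes)
        table = ulm_scores(norm, sig)
        for i, cid in enumerate(norm.cell_ids):
            s, _ = ulm_score(pd.Series(values[i], index=genes), sig)
            assert table.loc[cid, "score"] == pytest.approx(s, abs=1e-10)

    def test_zero_weight_variance_errors(self):
        genes = list("abcd")
        sig = SignatureWeights(pd.Series([1.0] * 4, index=genes))
        with pytest.raises(ValueError, match="variance"):
            ulm_score(pd.Series([1.0, 2, 3, 4], index=genes), sig)

    def test_insufficient_overlap(self, rng):
        sig = random_sig(rng, ["x", "y", "z"])
        with pytest.raises(ValueError, match="shared"):
            ulm_score(pd.Series([1.0], index=["x"]), sig)


class TestModuleScore:
    def test_null_construction_near_zero(self, rng):
        # set genes statistically identical to their bin-mates
        values = rng.normal(5.0, 1.0, (100, 60))
        norm = make_norm(values)
        score = module_score(norm, GeneSet("s", frozenset(["g0", "g1", "g2"])), seed=0)
        assert abs(score.mean()) < 0.15

    def test_additive_shift_recovered(self, rng):
        values = rng.normal(0.0, 0.01, (50, 60))
        values[:, :5] += 1.0  # set genes shifted +1 in every cell
        norm = make_norm(values)
        gene_set = GeneSet("s", frozenset([f"g{j}" for j in range(5)]))
        score = module_score(norm, gene_set, n_bins=2, seed=0)
        # controls from the set genes' own bin include set genes; at 5/30
        # contamination the expected score is (1 - 5/30) * 1
        assert score.mean() == pytest.approx(1.0, abs=0.25)

    def test_empty_overlap_errors(self, rng):
        norm = make_norm(rng.normal(size=(5, 10)))
        with pytest.raises(ValueError, match="overlap"):
            module_score(norm, GeneSet("s", frozenset(["nope"])))

    def test_small_bin_warns(self, rng):
        norm = make_norm(rng.normal(size=(5, 10)))
        with pytest.warns(UserWarning, match="replacement"):
            module_score(norm, GeneSet("s", frozenset(["g0"])), n_bins=5, n_ctrl=100)

    def test_deterministic(self, rng):
        norm = make_norm(rng.normal(size=(20, 40)))
        gs = GeneSet("s", frozenset(["g0", "g5"]))
        a = module_score(norm, gs, seed=4)
        b = module_score(norm, gs, seed=4)
        pd.testing.assert_series_equal(a, b)


def brute_aucell(profile, members, top_fraction):
    order = sorted(profile.index, key=lambda g: (-profile[g], g))
    max_rank = int(np.ceil(top_fraction * len(order)))
    raw = best = 0.0
    hits = 0
    for k in range(max_rank):
        if order[k] in members:
            hits += 1
        raw += hits
        best += min(k + 1, len(members))
    return raw / best


class TestAucell:
    def test_top_ranked_set_scores_one(self):
        genes = [f"g{i:03d}" for i in range(100)]
        profile = pd.Series(np.arange(100, 0, -1, dtype=float), index=genes)
        assert aucell(profile, GeneSet("s", frozenset(genes[:3]))) == 1.0

    def test_bottom_set_scores_zero(self):
        genes = [f"g{i:03d}" for i in range(100)]
        profile = pd.Series(np.arange(100, 0, -1, dtype=float), index=genes)
        assert aucell(profile, GeneSet("s", frozenset(genes[-3:]))) == 0.0

    def test_matches_brute_force_oracle(self, rng):
        genes = [f"g{i:03d}" for i in range(100)]
        for _ in range(10):
            profile = pd.Series(rng.normal(size=100), index=genes)
            members = frozenset(rng.choice(genes, 10, replace=False))
            expected = brute_aucell(profile, members, 0.2)
            assert aucell(profile, GeneSet("s", members), 0.2) == pytest.approx(expected)

    def test_monotone_adding_top_gene(self, rng):
        genes = [f"g{i:03d}" for i in range(100)]
        profile = pd.Series(rng.normal(size=100), index=genes)
        top_gene = profile.idxmax()
        members = frozenset(rng.choice([g for g in genes if g != top_gene], 8, replace=False))
        base = aucell(profile, GeneSet("s", members))
        assert aucell(profile, GeneSet("s", members | {top_gene})) >= base

    def test_set_larger_than_panel_errors(self):
        profile = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError, match="larger"):
            aucell(profile, GeneSet("s", frozenset("abcde")))


def walk_es(stats_sorted, member, p):
    """Independent step-by-step running-sum oracle."""
    absp = np.abs(stats_sorted) ** p
    nh = absp[member].sum()
    nm = (~member).sum()
    run, best = 0.0, 0.0
    for x, m in zip(absp, member):
        run += x / nh if m else -1.0 / nm
        if abs(run) > abs(best):
            best = run
    return best


class TestPrerankedGsea:
    def test_top_ranks_hand_walk(self):
        # set at ranks 1-2 of 100, p=0: running sum peaks at 1.0
        genes = [f"g{i:03d}" for i in range(100)]
        ranked = pd.Series(np.arange(100, 0, -1, dtype=float), index=genes)
        member = np.zeros(100, bool)
        member[[0, 1]] = True
        expected = walk_es(ranked.to_numpy(), member, 0.0)
        res = preranked_gsea(ranked, GeneSet("s", frozenset(genes[:2])), weight_p=0.0,
                             n_perm=100, seed=0)
        assert res.es == pytest.approx(expected)
        assert res.es == pytest.approx(1.0)

    def test_interior_ranks_hand_walk(self):
        # set at ranks 2-3 of 100, p=0: one miss step of 1/98 precedes the hits
        genes = [f"g{i:03d}" for i in range(100)]
        ranked = pd.Series(np.arange(100, 0, -1, dtype=float), index=genes)
        res = preranked_gsea(ranked, GeneSet("s", frozenset(genes[1:3])), weight_p=0.0,
                             n_perm=100, seed=0)
        assert res.es == pytest.approx(1.0 - 1.0 / 98.0)

    def test_reversed_ranking_negates_es_at_p0(self, rng):
        genes = [f"g{i:03d}" for i in range(60)]
        vals = np.sort(rng.normal(size=60))[::-1]
        ranked = pd.Series(vals, index=genes)
        members = frozenset(rng.choice(genes, 8, replace=False))
        es_fwd = preranked_gsea(ranked, GeneSet("s", members), weight_p=0.0,
                                n_perm=100, seed=0).es
        rev = pd.Series(-vals[::-1], index=genes[::-1])
        es_rev = preranked_gsea(rev, GeneSet("s", members), weight_p=0.0,
                                n_perm=100, seed=0).es
        assert es_rev == pytest.approx(-es_fwd)

    def test_matches_hand_walk_on_random_fixture(self, rng):
        genes = [f"g{i:03d}" for i in range(80)]
        ranked = pd.Series(rng.normal(size=80), index=genes)
        members = frozenset(rng.choice(genes, 10, replace=False))
        res = preranked_gsea(ranked, GeneSet("s", members), n_perm=100, seed=1)
        order = sorted(range(80), key=lambda i: (-ranked.iloc[i], genes[i]))
        stats_sorted = ranked.to_numpy()[order]
        member_mask = np.array([genes[i] in members for i in order])
        assert res.es == pytest.approx(walk_es(stats_sorted, member_mask, 1.0))

    def test_es_bounds_and_p_floor(self, rng):
        genes = [f"g{i:03d}" for i in range(50)]
        ranked = pd.Series(rng.normal(size=50), index=genes)
        res = preranked_gsea(ranked, GeneSet("s", frozenset(genes[:5])),
                             n_perm=200, seed=0)
        assert -1.0 <= res.es <= 1.0
        assert res.pvalue >= 1.0 / (200 + 1)
        assert np.sign(res.nes) == np.sign(res.es)

    def test_constant_statistics_error(self):
        ranked = pd.Series(np.ones(20), index=[f"g{i}" for i in range(20)])
        with pytest.raises(ValueError, match="equal"):
            preranked_gsea(ranked, GeneSet("s", frozenset(["g0", "g1"])), n_perm=100)

    def test_batch_fdr_in_range(self, rng):
        genes = [f"g{i:03d}" for i in range(60)]
        ranked = pd.Series(rng.normal(size=60), index=genes)
        sets = [
            GeneSet(f"s{j}", frozenset(rng.choice(genes, 6, replace=False)))
            for j in range(4)
        ]
        for res in gsea_batch(ranked, sets, n_perm=100, seed=0):
            assert 0.0 <= res.fdr_q <= 1.0


class TestPseudobulk:
    def test_single_cell_group(self, rng):
        norm = make_norm(rng.normal(size=(3, 4)))
        groups = pd.Series(["a", "b", "c"], index=norm.cell_ids)
        out = pseudobulk(norm, groups)
        np.testing.assert_allclose(out.loc["b"].to_numpy(), norm.values[1])

    def test_mean_of_two(self):
        norm = make_norm(np.array([[0.0], [2.0]]))
        groups = pd.Series(["g", "g"], index=norm.cell_ids)
        assert pseudobulk(norm, groups).iloc[0, 0] == 1.0

    def test_matrix_product_oracle(self, rng):
        values = rng.normal(size=(12, 5))
        norm = make_norm(values)
        labels = rng.choice(["a", "b", "c"], 12)
        groups = pd.Series(labels, index=norm.cell_ids)
        out = pseudobulk(norm, groups)
        for g in "abc":
            sel = labels == g
            expected = (sel.astype(float) @ values) / sel.sum()
            np.testing.assert_allclose(out.loc[g].to_numpy(), expected, rtol=1e-12)

    def test_missing_group_errors(self, rng):
        norm = make_norm(rng.normal(size=(2, 2)))
        with pytest.raises(ValueError):
            pseudobulk(norm, pd.Series({"c0": "a"}))
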