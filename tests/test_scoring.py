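"""QC, normalisation, signature scoring, hurdle DE, GSEA, HVGs, cluster merge."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats

import fibrokine as fk
from fibrokine.scoring import (
    ExpressionMatrix,
    cluster_state_merge,
    hurdle_de,
    normalize_log,
    preranked_gsea,
    qc_filter_cells,
    score_signature,
    select_hvgs,
    _running_es,
)


def _em(values, gene_ids=None, obs=None, **kw):
    values = np.asarray(values)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[1])]
    obs = obs if obs is not None else pd.DataFrame(index=[f"c{i}" for i in range(values.shape[0])])
    return ExpressionMatrix(values=values, obs=obs, gene_ids=pd.Index(gene_ids), **kw)


class TestQcFilter:
    def test_boundary_semantics(self):
        """1,024 molecules kept (strict <); mito fraction exactly 0.20 kept (strict >)."""
        genes = ["MT-0", "g1", "g2"]
        rows = [
            [0, 512, 512],     # exactly 1024 -> kept
            [0, 500, 523],     # 1023 -> removed (low depth)
            [400, 800, 800],   # mito 0.20 exactly -> kept
            [500, 800, 700],   # mito 0.25 -> removed
        ]
        em = _em(rows, gene_ids=genes)
        filt, report = qc_filter_cells(em, mito_max=0.20, libsize_min=1024)
        assert list(filt.obs.index) == ["c0", "c2"]
        assert report["n_removed_libsize"] == 1
        assert report["n_removed_mito"] == 1

    def test_disabled_thresholds_are_identity(self, two_state_cells):
        em, _ = two_state_cells
        filt, report = qc_filter_cells(em, mito_max=1.0, libsize_min=0)
        assert report["n_removed"] == 0
        assert filt.n_obs == em.n_obs

    def test_no_survivors_is_error(self):
        em = _em([[1, 1, 1]], gene_ids=["MT-0", "g1", "g2"])
        with pytest.raises(ValueError, match="survive"):
            qc_filter_cells(em, mito_max=0.2, libsize_min=10**6)


class TestNormalizeLog:
    def test_single_gene_closed_form(self):
        em = _em([[0, 7, 0]])
        norm = normalize_log(em, scale=1e5)
        assert norm.dense()[0, 1] == pytest.approx(np.log1p(1e5))
        assert norm.dense()[0, 0] == 0

    def test_depth_invariance(self):
        row = np.array([3, 0, 9, 1])
        em = _em(np.vstack([row, 2 * row]))
        norm = normalize_log(em)
        assert np.allclose(norm.dense()[0], norm.dense()[1])

    def test_inverse_recovers_proportions(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(5, size=(10, 50)) + (np.arange(50) == 0)
        em = _em(counts)
        norm = normalize_log(em, scale=1e5)
        back = np.expm1(norm.dense()) / 1e5
        props = counts / counts.sum(axis=1, keepdims=True)
        assert np.allclose(back, props, atol=1e-10)

    def test_median_scale_mode(self):
        em = _em([[10, 0], [0, 30]])
        norm = normalize_log(em, scale="median")
        assert norm.scale_factor == 20.0

    def test_zero_count_observation_named(self):
        em = _em([[1, 2], [0, 0]])
        with pytest.raises(ValueError, match="c1"):
            normalize_log(em)


class TestScoreSignature:
    def test_all_gene_signature_scores_vanish_pre_final_z(self, two_state_norm):
        norm, _ = two_state_norm
        sig = fk.GeneSignature("all", up=set(norm.gene_ids))
        raw = score_signature(norm, sig, final_z=False)
        assert np.abs(raw.to_numpy()).max() < 1e-8

    def test_constant_matrix_returns_zeros_with_warning(self):
        em = _em(np.full((8, 30), 2.0), kind="lognorm", scale_factor=1.0)
        sig = fk.GeneSignature("s", up={"g0", "g1", "g2"})
        with pytest.warns(UserWarning, match="constant"):
            s = score_signature(em, sig)
        assert np.allclose(s, 0)

    def test_planted_program_separates_states(self, two_state_norm):
        norm, _ = two_state_norm
        genes = list(norm.gene_ids)
        sig = fk.GeneSignature("prog", up=set(genes[50:100]))
        s = score_signature(norm, sig, seed=3)
        grp = norm.obs["state"].to_numpy()
        assert s[grp == "activated"].mean() - s[grp == "resting"].mean() > 1.0

    def test_final_column_is_standardised(self, two_state_norm):
        norm, _ = two_state_norm
        sig = fk.GeneSignature("prog", up=set(list(norm.gene_ids)[50:100]))
        s = score_signature(norm, sig, seed=3)
        assert abs(s.mean()) < 1e-8
        assert abs(s.std(ddof=0) - 1) < 1e-8

    def test_invariant_to_gene_and_cell_order(self, two_state_norm):
        norm, _ = two_state_norm
        genes = list(norm.gene_ids)
        sig = fk.GeneSignature("prog", up=set(genes[50:80]), down=set(genes[100:120]))
        s1 = score_signature(norm, sig, seed=9)
        rng = np.random.default_rng(1)
        gperm = rng.permutation(norm.n_genes)
        operm = rng.permutation(norm.n_obs)
        shuffled = ExpressionMatrix(
            values=norm.dense()[operm][:, gperm],
            obs=norm.obs.iloc[operm],
            gene_ids=norm.gene_ids[gperm],
            kind="lognorm",
            scale_factor=norm.scale_factor,
        )
        s2 = score_signature(shuffled, sig, seed=9)
        assert np.allclose(s1.loc[s2.index], s2, atol=1e-10)

    def test_absent_signature_errors(self, two_state_norm):
        norm, _ = two_state_norm
        sig = fk.GeneSignature("gone", up={"nope1", "nope2"})
        with pytest.raises(ValueError, match="no gene"):
            score_signature(norm, sig)


class TestHurdleDe:
    def test_null_split_has_no_bonferroni_hits(self):
        states = [fk.StateSpec("one", [], n_cells=400)]
        em, _ = fk.simulate.generate_single_cell(states, n_genes=300, seed=55)
        norm = fk.scoring.normalize_log(em)
        rng = np.random.default_rng(0)
        grp = rng.permutation(np.repeat(["a", "b"], 200))
        de = hurdle_de(norm, grp)
        assert (de["p_bonf"] < 0.05).sum() == 0

    def test_planted_program_sensitivity(self, two_state_norm):
        norm, _ = two_state_norm
        de = hurdle_de(norm, norm.obs["state"].to_numpy())
        planted = {list(norm.gene_ids)[i] for i in range(50, 100)}
        hits = set(de.index[de["p_bonf"] < 0.05])
        assert len(hits & planted) / len(planted) >= 0.8

    def test_undetected_gene_skipped(self):
        vals = np.zeros((60, 3))
        vals[:, 0] = np.random.default_rng(0).poisson(3, 60)
        vals[:30, 1] = 1.0
        em = _em(np.log1p(vals), kind="lognorm", scale_factor=1.0)
        grp = np.repeat(["a", "b"], 30)
        de = hurdle_de(em, grp)
        assert "g2" not in de.index  # never detected

    def test_small_groups_rejected(self, two_state_norm):
        norm, _ = two_state_norm
        grp = np.array(["a"] * 5 + ["b"] * (norm.n_obs - 5))
        with pytest.raises(ValueError, match=">= 20"):
            hurdle_de(norm, grp)

    def test_null_pvalues_not_anticonservative(self):
        """Hurdle p-values under the null are uniform or super-uniform."""
        states = [fk.StateSpec("one", [], n_cells=300)]
        em, _ = fk.simulate.generate_single_cell(states, n_genes=700, seed=66)
        norm = fk.scoring.normalize_log(em)
        grp = np.random.default_rng(3).permutation(np.repeat(["a", "b"], 150))
        de = hurdle_de(norm, grp)
        p = de["p"].to_numpy()
        # empirical CDF never exceeds uniform by more than KS band
        ks = stats.kstest(p, "uniform", alternative="greater").statistic
        assert ks < 0.05 or (p < 0.05).mean() <= 0.06


class TestPrerankedGsea:
    @pytest.fixture()
    def ranked20(self):
        rng = np.random.default_rng(12)
        vals = np.sort(rng.uniform(-2, 3, 20))[::-1]
        return pd.Series(vals, index=[f"g{i:02d}" for i in range(20)])

    def test_es_matches_bruteforce_enumeration(self, ranked20):
        """ES from the running-sum formula equals explicit enumeration."""
        gene_set = {"g00", "g03", "g04", "g11", "g17"}
        res = preranked_gsea(ranked20, {"set": gene_set}, n_perm=100, seed=0)
        # independent brute force: evaluate the running sum at every position
        order = np.argsort(-ranked20.to_numpy(), kind="stable")
        genes = np.asarray(ranked20.index)[order]
        w = np.abs(ranked20.to_numpy()[order])
        hit = np.array([g in gene_set for g in genes])
        best = 0.0
        ph = pm = 0.0
        for i in range(20):
            ph += w[i] / w[hit].sum() if hit[i] else 0.0
            pm += (not hit[i]) / (20 - hit.sum())
            if abs(ph - pm) > abs(best):
                best = ph - pm
        assert res["es"].iloc[0] == pytest.approx(best, abs=1e-12)

    def test_running_sum_endpoint_is_zero(self, ranked20):
        hit = np.zeros(20, dtype=bool)
        hit[[1, 5, 6, 13]] = True
        _, dev = _running_es(np.abs(ranked20.to_numpy()), hit)
        assert abs(dev[-1]) < 1e-10

    def test_reversed_ranks_negate_es(self, ranked20):
        gene_set = {"g00", "g01", "g02", "g03", "g04"}
        a = preranked_gsea(ranked20, {"s": gene_set}, n_perm=100, seed=0)
        b = preranked_gsea(-ranked20, {"s": gene_set}, n_perm=100, seed=0)
        assert a["es"].iloc[0] == pytest.approx(-b["es"].iloc[0])

    def test_permutation_floor(self, ranked20):
        res = preranked_gsea(
            ranked20, {"top": set(ranked20.index[:5])}, n_perm=2000, seed=1
        )
        assert res["p"].iloc[0] >= 1 / 2001

    def test_small_sets_skipped_with_warning(self, ranked20):
        with pytest.warns(UserWarning, match="skipped"):
            res = preranked_gsea(ranked20, {"tiny": {"g00", "g01"}}, n_perm=50, seed=0)
        assert len(res) == 0

    def test_random_set_pvalues_uniform(self):
        rng = np.random.default_rng(8)
        ranks = pd.Series(rng.normal(size=600), index=[f"G{i}" for i in range(600)])
        sets = {f"s{i}": set(rng.choice(ranks.index, 15, replace=False)) for i in range(150)}
        res = preranked_gsea(ranks, sets, n_perm=400, seed=2)
        ks = stats.kstest(res["p"], "uniform").statistic
        assert ks < 0.12


@pytest.fixture(scope="module")
def four_cluster_norm():
    """2+2 clusters from two disjoint strong programs."""
    pa = fk.CytokineProgram("A", up_genes=list(range(150)), down_genes=[], log2fc_up=3.0)
    pb = fk.CytokineProgram("B", up_genes=list(range(150, 300)), down_genes=[], log2fc_up=3.0)
    states = [
        fk.StateSpec("a1", [(pa, 1.0)], n_cells=100),
        fk.StateSpec("a2", [(pa, 0.9)], n_cells=100),
        fk.StateSpec("b1", [(pb, 1.0)], n_cells=100),
        fk.StateSpec("b2", [(pb, 0.9)], n_cells=100),
    ]
    em, _ = fk.simulate.generate_single_cell(states, n_genes=600, seed=7)
    return fk.scoring.normalize_log(em)


class TestHvgsAndClusterMerge:
    def test_constant_gene_never_selected(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(2, 1, size=(60, 40)).clip(0)
        vals[:, 0] = 1.7  # constant
        em = _em(vals, kind="lognorm", scale_factor=1.0)
        hv = select_hvgs(em, n_top=20)
        assert "g0" not in hv

    def test_planted_bimodal_genes_rank_high(self, two_state_norm):
        norm, _ = two_state_norm
        hv = select_hvgs(norm, n_top=80)
        planted = {list(norm.gene_ids)[i] for i in range(50, 100)}
        assert len(planted & set(hv)) / len(planted) > 0.6

    def test_batch_label_permutation_invariance(self, two_state_norm):
        norm, _ = two_state_norm
        batches = np.tile([0, 1], norm.n_obs // 2)
        hv1 = select_hvgs(norm, batches=batches, n_top=50)
        hv2 = select_hvgs(norm, batches=1 - batches, n_top=50)
        assert hv1 == hv2

    def test_masked_genes_excluded(self, two_state_norm):
        norm, _ = two_state_norm
        hv = select_hvgs(norm, n_top=100, mask={g for g in norm.gene_ids if g.startswith("MT-")})
        assert not any(g.startswith("MT-") for g in hv)

    def test_two_block_structure_recovered(self, four_cluster_norm):
        norm = four_cluster_norm
        hv = select_hvgs(norm, n_top=300)
        mapping, corr = cluster_state_merge(norm, norm.obs["state"].to_numpy(), hv)
        assert mapping["a1"] == mapping["a2"]
        assert mapping["b1"] == mapping["b2"]
        assert mapping["a1"] != mapping["b1"]
        assert len(set(mapping.values())) == 2

    def test_duplicated_cluster_merges(self, four_cluster_norm):
        norm = four_cluster_norm
        state = norm.obs["state"].to_numpy()
        clusters = state.copy().astype(object)
        half = np.arange(norm.n_obs) % 2 == 0
        clusters[(state == "a1") & half] = "a1_dup"
        hv = select_hvgs(norm, n_top=300)
        mapping, corr = cluster_state_merge(norm, clusters, hv)
        assert corr.loc["a1", "a1_dup"] > 0.98
        assert mapping["a1"] == mapping["a1_dup"]
        assert mapping["a1"] != mapping["b1"]

    def test_correlation_matrix_symmetric_unit_diag(self, two_state_norm):
        norm, _ = two_state_norm
        _, corr = cluster_state_merge(
            norm, norm.obs["state"].to_numpy(), list(norm.gene_ids)[:200]
        )
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)

    def test_single_cluster_rejected(self, two_state_norm):
        norm, _ = two_state_norm
        with pytest.raises(ValueError, match=">= 2"):
            cluster_state_merge(norm, np.zeros(norm.n_obs), list(norm.gene_ids)[:50])
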