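"""Bulk DE, signature derivation, and DLL4 dampening summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fibrokine as fk
from fibrokine._utils import bh_adjust
from fibrokine.bulk import estimate_size_factors


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = np.tile(np.array([[10], [20], [30]]), (1, 4))
        assert np.allclose(estimate_size_factors(counts), 1.0)

    def test_doubled_sample_hand_computation(self):
        """B = 2A elementwise -> factors (1/sqrt2, sqrt2)."""
        a = np.array([10.0, 20, 40, 80])
        counts = np.column_stack([a, 2 * a])
        f = estimate_size_factors(counts)
        assert np.allclose(f, [1 / np.sqrt(2), np.sqrt(2)], atol=1e-12)

    def test_gene_permutation_invariance(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(50, size=(30, 5)) + 1
        f1 = estimate_size_factors(counts)
        f2 = estimate_size_factors(counts[rng.permutation(30)])
        assert np.allclose(f1, f2)

    def test_all_zero_sample_named_in_error(self):
        counts = pd.DataFrame(
            np.column_stack([np.arange(1, 5), np.zeros(4)]), columns=["good", "dead"]
        )
        with pytest.raises(ValueError):
            estimate_size_factors(counts)


class TestNbWaldDe:
    def test_planted_power_and_fdp(self, planted_bulk):
        bulk, truth = planted_bulk
        de = fk.bulk.nb_wald_de(bulk, "TNF")
        sig = fk.bulk.derive_signature(de, alpha=0.05)
        planted = truth.de_genes_by_condition["TNF"]
        sens = len(sig.genes & planted.genes) / len(planted.genes)
        fdp = len(sig.genes - planted.genes) / max(len(sig.genes), 1)
        assert sens >= 0.9
        assert fdp <= 0.1

    def test_direction_agrees_with_truth(self, planted_bulk):
        bulk, truth = planted_bulk
        de = fk.bulk.nb_wald_de(bulk, "TNF")
        sig = fk.bulk.derive_signature(de, alpha=0.05)
        planted = truth.de_genes_by_condition["TNF"]
        assert not sig.up & planted.down
        assert not sig.down & planted.up

    def test_permuted_labels_center_lfc_on_zero(self):
        prog = fk.CytokineProgram("n", up_genes=[], down_genes=[], log2fc_up=1, log2fc_down=1)
        bulk, _ = fk.simulate.generate_bulk([prog], n_genes=1500, seed=21)
        de = fk.bulk.nb_wald_de(bulk, "n")
        assert abs(de["log2fc"].median()) < 0.05

    def test_wald_stats_null_distribution(self):
        """Label-exchangeable null Wald statistics are close to N(0,1)."""
        from scipy import stats

        prog = fk.CytokineProgram("n", up_genes=[], down_genes=[], log2fc_up=1, log2fc_down=1)
        bulk, _ = fk.simulate.generate_bulk([prog], n_genes=5000, seed=31)
        de = fk.bulk.nb_wald_de(bulk, "n")
        ks = stats.kstest(de["wald_stat"].dropna(), "norm").statistic
        assert ks < 0.05

    def test_bh_monotone_and_bounded(self, planted_bulk):
        bulk, _ = planted_bulk
        de = fk.bulk.nb_wald_de(bulk, "TNF").dropna(subset=["p_adj"]).sort_values("p")
        assert (de["p_adj"] >= de["p"] - 1e-15).all()
        assert de["p_adj"].between(0, 1).all()
        assert (np.diff(de["p_adj"].to_numpy()) >= -1e-12).all()

    def test_low_count_genes_excluded_from_bh_family(self):
        prog = fk.CytokineProgram("x", up_genes=[0], down_genes=[], log2fc_up=1)
        base = np.full(100, 50.0)
        base[90:] = 0.05  # below the mean-count floor
        bulk, _ = fk.simulate.generate_bulk([prog], n_genes=100, seed=2, baseline_mean=base)
        de = fk.bulk.nb_wald_de(bulk, "x")
        low = de.iloc[90:]
        assert low["p_adj"].isna().all()

    def test_unknown_condition_rejected(self, planted_bulk):
        bulk, _ = planted_bulk
        with pytest.raises(ValueError, match="not in design"):
            fk.bulk.nb_wald_de(bulk, "nope")


class TestDeriveSignature:
    def test_all_insignificant_gives_empty(self, planted_bulk):
        bulk, _ = planted_bulk
        de = fk.bulk.nb_wald_de(bulk, "TNF").copy()
        de["p_adj"] = 1.0
        with pytest.warns(UserWarning, match="empty"):
            sig = fk.bulk.derive_signature(de)
        assert len(sig) == 0

    def test_alpha_nesting(self, planted_bulk):
        bulk, _ = planted_bulk
        de = fk.bulk.nb_wald_de(bulk, "TNF")
        strict = fk.bulk.derive_signature(de, alpha=0.01)
        loose = fk.bulk.derive_signature(de, alpha=0.05)
        assert strict.up <= loose.up and strict.down <= loose.down

    def test_commutes_with_gene_relabeling(self, planted_bulk):
        bulk, _ = planted_bulk
        de = fk.bulk.nb_wald_de(bulk, "TNF")
        relabel = {g: f"X_{g}" for g in de.index}
        de2 = de.copy()
        de2.index = [relabel[g] for g in de.index]
        s1 = fk.bulk.derive_signature(de)
        s2 = fk.bulk.derive_signature(de2)
        assert {relabel[g] for g in s1.up} == s2.up
        assert {relabel[g] for g in s1.down} == s2.down


class TestRestrictSignature:
    @pytest.fixture()
    def table(self):
        return pd.DataFrame(
            {"FLS": [10.0, 5.0, 1.0, 8.0], "Tcell": [1.0, 6.0, 1.0, 0.0],
             "Mac": [0.5, 1.0, 1.0, 0.0]},
            index=["g_fls", "g_shared", "g_flat", "g_only"],
        )

    def test_zero_ratio_keeps_everything_present(self, table):
        sig = fk.GeneSignature("s", up={"g_fls", "g_shared", "g_flat", "g_only"})
        out = fk.bulk.restrict_signature(sig, table, "FLS", exclusivity_ratio=0.0)
        assert out.up == sig.up

    def test_exclusive_gene_always_kept(self, table):
        sig = fk.GeneSignature("s", up={"g_only"})
        out = fk.bulk.restrict_signature(sig, table, "FLS", exclusivity_ratio=100.0)
        assert out.up == {"g_only"}

    def test_known_exclusive_set_intersection(self, table):
        sig = fk.GeneSignature("s", up={"g_fls", "g_shared", "g_flat"}, down={"g_only"})
        out = fk.bulk.restrict_signature(sig, table, "FLS", exclusivity_ratio=2.0)
        assert out.up == {"g_fls"}  # 10 >= 2*1; shared 5 < 2*6; flat 1 < 2*1
        assert out.down == {"g_only"}

    def test_absent_gene_dropped_with_warning(self, table):
        sig = fk.GeneSignature("s", up={"g_fls", "missing"})
        with pytest.warns(UserWarning, match="absent"):
            out = fk.bulk.restrict_signature(sig, table, "FLS", exclusivity_ratio=0.0)
        assert out.up == {"g_fls"}


class TestDll4Shift:
    def test_identical_tables_no_dampening(self, planted_bulk):
        bulk, _ = planted_bulk
        de = fk.bulk.nb_wald_de(bulk, "TNF")
        sig = fk.bulk.derive_signature(de)
        out = fk.bulk.dll4_shift(de, de, sig)
        assert np.allclose(out["median_paired_diff"], 0)
        assert not out["dampened"].any()

    def test_planted_halving_recovered(self):
        prog = fk.CytokineProgram(
            "C", up_genes=list(range(25)), down_genes=list(range(25, 50)),
            log2fc_up=2.0, log2fc_down=2.0,
        )
        bulk, _ = fk.simulate.generate_bulk(
            [prog], n_genes=300, seed=77,
            baseline_mean=np.full(300, 150.0),
            combinations=[("C_DLL4", ["C"], 0.5)],
        )
        de_alone = fk.bulk.nb_wald_de(bulk, "C")
        de_dll4 = fk.bulk.nb_wald_de(bulk, "C_DLL4")
        sig = fk.bulk.derive_signature(de_alone)
        out = fk.bulk.dll4_shift(de_alone, de_dll4, sig)
        # both directions report positive shrinkage, ratio about one half
        assert out["dampened"].all()
        assert np.allclose(out["median_abs_ratio"], 0.5, atol=0.15)
        assert (out["median_shrinkage"] > 0).all()

    def test_too_few_shared_genes_rejected(self, planted_bulk):
        bulk, _ = planted_bulk
        de = fk.bulk.nb_wald_de(bulk, "TNF")
        sig = fk.GeneSignature("tiny", up=set(list(de.index[:2])))
        with pytest.raises(ValueError, match="shared"):
            fk.bulk.dll4_shift(de, de, sig)


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
def test_bh_adjust_properties(pvals):
    p = np.array(pvals)
    adj = bh_adjust(p)
    assert np.all(adj >= p - 1e-12)
    assert np.all((adj >= 0) & (adj <= 1))
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(adj[order]) >= -1e-12)
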