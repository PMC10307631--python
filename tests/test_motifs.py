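"""Motif accessibility deviations: expectation model, backgrounds, ranking."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats

import fibrokine as fk
from fibrokine.motifs import (
    DeviationResult,
    MotifMatch,
    PeakMatrix,
    compute_deviations,
    expected_counts,
    expression_gate,
    rank_motifs,
    sample_backgrounds,
)
from fibrokine.scoring import ExpressionMatrix


def _pm(binary, gc=None):
    binary = np.asarray(binary)
    P = binary.shape[0]
    coords = pd.DataFrame(
        {"chrom": "chr1", "start": np.arange(P) * 1000, "end": np.arange(P) * 1000 + 500}
    )
    gc = gc if gc is not None else np.full(P, 0.5)
    return PeakMatrix(binary=sp.csr_matrix(binary), peak_coords=coords, gc=gc)


def _mm(match, n_motifs=None):
    match = np.asarray(match)
    names = [f"m{i}" for i in range(match.shape[0])]
    return MotifMatch(
        match=sp.csr_matrix(match),
        motif_names=names,
        motif_to_tf={n: [f"TF{i}"] for i, n in enumerate(names)},
    )


class TestExpectedCounts:
    def test_hand_arithmetic_toy(self):
        """3 peaks x 2 cells, motif={p1,p2}: T=3, d=(2,2), D=4 -> E=(1.5,1.5)."""
        pm = _pm([[1, 0], [1, 1], [0, 1]])
        mm = _mm([[1, 1, 0]])
        E = expected_counts(pm, mm)
        assert np.allclose(E, [[1.5, 1.5]])

    def test_uniform_matrix_gives_zero_raw_deviation(self):
        pm = _pm(np.ones((6, 4)))
        mm = _mm([[1, 1, 0, 0, 1, 0]])
        bg = np.tile(np.arange(6)[:, None], (1, 10))  # self backgrounds
        dev = compute_deviations(pm, mm, bg)
        assert np.allclose(dev.raw.to_numpy(), 0.0)

    def test_expectation_conserves_motif_total(self, small_atac):
        pm, mm, _ = small_atac
        E = expected_counts(pm, mm)
        X = np.asarray(pm.binary.todense(), dtype=float)
        M = np.asarray(mm.match.todense(), dtype=float)
        T = (M @ X).sum(axis=1)
        assert np.allclose(E.sum(axis=1), T, atol=1e-8)


class TestSampleBackgrounds:
    def test_identical_covariates_uniform_draws(self):
        rng = np.random.default_rng(0)
        pm = _pm(rng.integers(0, 2, (100, 20)) | 1, gc=np.full(100, 0.4))
        # constant gc and constant mean accessibility -> uniform sampling
        bg = sample_backgrounds(pm, n_background=30, seed=1)
        assert bg.shape == (100, 30)
        assert bg.min() >= 0 and bg.max() < 100
        assert len(np.unique(bg)) > 50  # spread over most peaks

    def test_two_covariate_clusters_stay_within_cluster(self):
        rng = np.random.default_rng(1)
        P = 200
        gc = np.concatenate([np.full(100, 0.2), np.full(100, 0.8)])
        gc += rng.normal(0, 0.01, P)
        acc = np.concatenate([
            rng.integers(0, 2, (100, 40)),
            (rng.random((100, 40)) < 0.9).astype(int),
        ])
        acc[:, 0] = 1  # avoid empty cells
        pm = _pm(acc, gc=np.clip(gc, 0, 1))
        bg = sample_backgrounds(pm, n_background=50, seed=2)
        same_cluster = (bg < 100) == (np.arange(P) < 100)[:, None]
        assert same_cluster.mean() >= 0.99

    def test_seeded_determinism(self, small_atac):
        pm, _, _ = small_atac
        a = sample_backgrounds(pm, n_background=20, seed=9)
        b = sample_backgrounds(pm, n_background=20, seed=9)
        assert (a == b).all()


class TestComputeDeviations:
    def test_bruteforce_oracle_50x20x5(self):
        """z equals an independent direct-summation implementation to 1e-10."""
        rng = np.random.default_rng(123)
        X = (rng.random((50, 20)) < 0.3).astype(int)
        X[:, X.sum(axis=0) == 0] = 1
        gc = rng.beta(5, 5, 50)
        pm = _pm(X, gc=gc)
        match = (rng.random((5, 50)) < 0.25).astype(int)
        match[match.sum(axis=1) == 0, 0] = 1
        mm = _mm(match)
        bg = sample_backgrounds(pm, n_background=30, seed=4)
        dev = compute_deviations(pm, mm, bg)

        # independent brute force with explicit loops
        Xf = X.astype(float)
        d = Xf.sum(axis=0)
        D = d.sum()
        z_oracle = np.empty((5, 20))
        raw_oracle = np.empty((5, 20))
        for m in range(5):
            peaks = np.where(match[m] == 1)[0]
            for i in range(20):
                obs = sum(Xf[p, i] for p in peaks)
                T = sum(Xf[p, :].sum() for p in peaks)
                E = T * d[i] / D
                raw_oracle[m, i] = (obs - E) / E
            bdevs = np.empty((bg.shape[1], 20))
            for b in range(bg.shape[1]):
                bpeaks = [bg[p, b] for p in peaks]
                Tb = sum(Xf[p, :].sum() for p in bpeaks)
                for i in range(20):
                    obs_b = sum(Xf[p, i] for p in bpeaks)
                    E_b = Tb * d[i] / D
                    bdevs[b, i] = (obs_b - E_b) / E_b
            for i in range(20):
                mu = bdevs[:, i].mean()
                sd = bdevs[:, i].std(ddof=1)
                z_oracle[m, i] = (raw_oracle[m, i] - mu) / sd

        assert np.nanmax(np.abs(dev.raw.to_numpy() - raw_oracle)) < 1e-10
        assert np.nanmax(np.abs(dev.z.to_numpy() - z_oracle)) < 1e-10

    def test_unnormalised_deviation_sums_to_zero(self, small_atac):
        """Conservation: sum over cells of (obs - E) vanishes per motif."""
        pm, mm, _ = small_atac
        X = sp.csr_matrix(pm.binary, dtype=float)
        M = sp.csr_matrix(mm.match, dtype=float)
        obs = np.asarray((M @ X).todense())
        E = expected_counts(pm, mm)
        assert np.abs((obs - E).sum(axis=1)).max() < 1e-8

    def test_self_background_z_near_zero(self):
        rng = np.random.default_rng(5)
        X = (rng.random((40, 15)) < 0.4).astype(int)
        X[:, X.sum(axis=0) == 0] = 1
        pm = _pm(X)
        mm = _mm((rng.random((3, 40)) < 0.3).astype(int))
        bg = np.tile(np.arange(40)[:, None], (1, 25))
        dev = compute_deviations(pm, mm, bg)
        # background == motif peaks -> zero spread -> flagged, z missing
        assert set(dev.flagged) == set(dev.z.index)

    def test_planted_state_motif_recovered(self, small_atac):
        pm, mm, truth = small_atac
        bg = sample_backgrounds(pm, n_background=50, seed=3)
        dev = compute_deviations(pm, mm, bg)
        st = truth.state_of_cell
        z0 = dev.z.loc["motif_0"].to_numpy()
        assert np.nanmean(z0[st == 1]) - np.nanmean(z0[st == 0]) > 1.0

    def test_null_z_calibration(self):
        """Null motif z-scores have |mean| < 0.1-ish and sd near 1 at 50 backgrounds."""
        rng = np.random.default_rng(7)
        X = (rng.random((400, 80)) < 0.3).astype(int)
        X[:, X.sum(axis=0) == 0] = 1
        pm = _pm(X, gc=rng.beta(5, 5, 400))
        mm = _mm((rng.random((6, 400)) < 0.2).astype(int))
        bg = sample_backgrounds(pm, n_background=50, seed=8)
        dev = compute_deviations(pm, mm, bg)
        z = dev.z.to_numpy()
        assert np.abs(np.nanmean(z, axis=1)).max() < 0.35
        sds = np.nanstd(z, axis=1)
        assert (sds > 0.6).all() and (sds < 1.6).all()


class TestExpressionGate:
    def _expr(self, det_frac_by_state, n_cells_per_state=100):
        """Expression with TF0 detected at the given fraction per state."""
        states = np.repeat(np.arange(len(det_frac_by_state)), n_cells_per_state)
        vals = np.zeros((len(states), 1))
        for s, frac in enumerate(det_frac_by_state):
            idx = np.where(states == s)[0]
            k = int(round(frac * len(idx)))
            vals[idx[:k], 0] = 3
        em = ExpressionMatrix(
            values=vals, obs=pd.DataFrame(index=range(len(states))),
            gene_ids=pd.Index(["TF0"]), kind="counts",
        )
        return em, states

    def _single_motif(self):
        return MotifMatch(
            match=sp.csr_matrix(np.ones((1, 4))), motif_names=["m0"],
            motif_to_tf={"m0": ["TF0"]},
        )

    def _dev(self):
        z = pd.DataFrame(np.zeros((1, 200)), index=["m0"])
        return DeviationResult(raw=z, z=z, background_seed=0, n_background=1)

    def test_strict_threshold_boundary(self):
        """21% detection passes the >20% gate; exactly 20% fails."""
        mm = self._single_motif()
        em, states = self._expr([0.21, 0.20])
        gate = expression_gate(self._dev(), mm, em, states, min_frac=0.20)
        assert gate["0"] == {"m0"}
        assert gate["1"] == set()

    def test_never_detected_excluded_everywhere(self):
        mm = self._single_motif()
        em, states = self._expr([0.0, 0.0])
        gate = expression_gate(self._dev(), mm, em, states, min_frac=0.2)
        assert gate["0"] == set() and gate["1"] == set()

    def test_zero_threshold_admits_all_detected(self):
        mm = self._single_motif()
        em, states = self._expr([0.5, 0.1])
        gate = expression_gate(self._dev(), mm, em, states, min_frac=0.0)
        assert gate["0"] == {"m0"} and gate["1"] == {"m0"}

    def test_gate_monotone_in_threshold(self):
        mm = self._single_motif()
        em, states = self._expr([0.3, 0.6])
        gates = [
            expression_gate(self._dev(), mm, em, states, min_frac=f)
            for f in (0.0, 0.25, 0.5, 0.7)
        ]
        for lo, hi in zip(gates, gates[1:]):
            for s in lo:
                assert hi[s] <= lo[s]

    def test_missing_tf_motif_excluded_with_warning(self):
        mm = MotifMatch(
            match=sp.csr_matrix(np.ones((1, 4))), motif_names=["m0"],
            motif_to_tf={"m0": ["ABSENT"]},
        )
        em, states = self._expr([0.9, 0.9])
        with pytest.warns(UserWarning, match="excluded"):
            gate = expression_gate(self._dev(), mm, em, states, min_frac=0.0)
        assert gate["0"] == set()


class TestRankMotifs:
    def _dev_from_z(self, z):
        df = pd.DataFrame(z, index=[f"m{i}" for i in range(len(z))])
        return DeviationResult(raw=df, z=df, background_seed=0, n_background=1)

    def test_perfect_separation_ranks_first(self):
        states = np.repeat(["a", "b"], 10)
        z = np.vstack([(states == "a").astype(float), np.random.default_rng(0).normal(size=20)])
        out = rank_motifs(self._dev_from_z(z), states, n_top=6)
        top_a = out[(out.state == "a") & (out["rank"] == 1)]
        assert top_a["motif"].iloc[0] == "m0"

    def test_wilcoxon_matches_exhaustive_enumeration(self):
        """4 vs 4 distinct values: normal-score p agrees with the exact
        permutation distribution of the rank sum."""
        vals = np.array([1.0, 3.0, 5.0, 7.0, 2.0, 4.0, 6.0, 8.0])
        states = np.array(["a"] * 4 + ["b"] * 4)
        out = rank_motifs(self._dev_from_z([vals]), states, n_top=1)
        # exact enumeration of rank sums for group a
        ranks = stats.rankdata(vals)
        obs_r1 = ranks[:4].sum()
        all_sums = [sum(c) for c in itertools.combinations(ranks, 4)]
        mu = np.mean(all_sums)
        sd = np.std(all_sums)
        z_exact = (obs_r1 - mu) / sd
        score_a = out[out.state == "a"]["score"].iloc[0]
        assert score_a == pytest.approx(z_exact, abs=1e-6)

    def test_top_n_limit(self, small_atac):
        pm, mm, truth = small_atac
        bg = sample_backgrounds(pm, n_background=30, seed=1)
        dev = compute_deviations(pm, mm, bg)
        out = rank_motifs(dev, truth.state_of_cell, n_top=6)
        assert out.groupby("state").size().max() <= 6

    def test_single_state_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            rank_motifs(self._dev_from_z([np.arange(4.0)]), np.zeros(4), n_top=3)
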