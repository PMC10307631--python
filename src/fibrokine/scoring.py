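"""Single-cell / spot expression processing and signature scoring.

Covers the expression-side operations of the pipeline: QC filters on
mitochondrial fraction and library size, library-size log-normalisation,
bin-matched control-gene signature scoring (doubly z-scored), a two-part
hurdle differential-expression model with a detection-rate covariate,
preranked gene-set enrichment with a permutation null, dispersion-based
highly-variable-gene selection, and merging of expression clusters into
states by correlation of cluster mean profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from ._utils import bh_adjust, bonferroni
from .bulk import GeneSignature

MITO_PREFIX = "MT-"


@dataclass
class ExpressionMatrix:
    """Observations x genes expression values with per-observation metadata.

    ``kind`` tags the scale: ``"counts"`` for raw nonnegative integers,
    ``"lognorm"`` for ln(1 + scale * count / libsize) values with the scale
    factor recorded in ``scale_factor``.
    """

    values: sp.spmatrix | np.ndarray
    obs: pd.DataFrame
    gene_ids: pd.Index
    kind: str = "counts"
    scale_factor: float | None = None

    def __post_init__(self):
        self.gene_ids = pd.Index(self.gene_ids)
        if self.values.shape != (len(self.obs), len(self.gene_ids)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.obs)} obs x {len(self.gene_ids)} genes"
            )
        if self.kind == "counts":
            data = self.values.data if sp.issparse(self.values) else np.asarray(self.values)
            if data.size and (np.asarray(data) < 0).any():
                raise ValueError("raw counts must be nonnegative")
        if self.kind == "lognorm" and self.scale_factor is None:
            raise ValueError("normalized matrix must record its scale factor")

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        return self.values.toarray() if sp.issparse(self.values) else np.asarray(self.values)

    def subset_obs(self, mask) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        return ExpressionMatrix(
            values=self.values[mask],
            obs=self.obs.iloc[mask] if mask.dtype == bool else self.obs.iloc[mask],
            gene_ids=self.gene_ids,
            kind=self.kind,
            scale_factor=self.scale_factor,
        )


def mito_fraction(em: ExpressionMatrix, prefix: str = MITO_PREFIX) -> np.ndarray:
    is_mito = np.asarray(em.gene_ids.str.startswith(prefix))
    tot = np.asarray(em.values.sum(axis=1)).ravel()
    mito = np.asarray(em.values[:, is_mito].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(tot > 0, mito / np.maximum(tot, 1), 0.0)
    return frac


def qc_filter_cells(
    em: ExpressionMatrix,
    mito_max: float = 0.20,
    libsize_min: int = 1024,
    mito_prefix: str = MITO_PREFIX,
) -> tuple[ExpressionMatrix, dict]:
    """Remove cells failing mitochondrial-fraction or library-size QC.

    A cell fails when its mitochondrial fraction is strictly greater than
    ``mito_max`` or its total molecule count is strictly below
    ``libsize_min`` — so a cell at exactly 1,024 molecules, or at exactly the
    mitochondrial threshold, is kept.
    """
    if em.kind != "counts":
        raise ValueError("QC filters operate on raw counts")
    tot = np.asarray(em.values.sum(axis=1)).ravel()
    frac = mito_fraction(em, mito_prefix)
    fail_mito = frac > mito_max
    fail_lib = tot < libsize_min
    keep = ~(fail_mito | fail_lib)
    if keep.sum() == 0:
        raise ValueError("no cells survive QC")
    report = {
        "n_input": int(em.n_obs),
        "n_removed_mito": int(fail_mito.sum()),
        "n_removed_libsize": int(fail_lib.sum()),
        "n_removed": int((~keep).sum()),
        "n_kept": int(keep.sum()),
        "mito_max": mito_max,
        "libsize_min": libsize_min,
    }
    return em.subset_obs(keep), report


def normalize_log(em: ExpressionMatrix, scale: float | str = 1e5) -> ExpressionMatrix:
    """ln(1 + scale * count / libsize) normalisation.

    ``scale`` is the per-observation target total: 100,000 for single cells,
    or the string ``"median"`` to use the median of total counts across
    observations (the convention used for spatial spots).
    """
    if em.kind != "counts":
        raise ValueError("input must be raw counts")
    tot = np.asarray(em.values.sum(axis=1)).ravel()
    if (tot == 0).any():
        bad = list(em.obs.index[np.where(tot == 0)[0]][:5])
        raise ValueError(f"zero-count observation(s): {bad}")
    sf = float(np.median(tot)) if scale == "median" else float(scale)
    if sp.issparse(em.values):
        x = em.values.tocsr().astype(float, copy=True)
        x = sp.csr_matrix(x.multiply(sf / tot[:, None]))
        x.data = np.log1p(x.data)
    else:
        x = np.log1p(np.asarray(em.values, dtype=float) * (sf / tot)[:, None])
    return ExpressionMatrix(
        values=x, obs=em.obs, gene_ids=em.gene_ids, kind="lognorm", scale_factor=sf
    )


def _gene_zscores(dense: np.ndarray) -> np.ndarray:
    mu = dense.mean(axis=0)
    sd = dense.std(axis=0)
    z = np.zeros_like(dense)
    ok = sd > 0
    z[:, ok] = (dense[:, ok] - mu[ok]) / sd[ok]
    return z


def _expression_bins(means: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-occupancy bins of genes by mean expression (rank-based)."""
    order = np.argsort(means, kind="stable")
    bins = np.empty(len(means), dtype=int)
    bins[order] = (np.arange(len(means)) * n_bins) // len(means)
    return bins


def score_signature(
    em: ExpressionMatrix,
    sig: GeneSignature,
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
    final_z: bool = True,
    directed: bool = True,
) -> pd.Series:
    """Score a directed gene signature per observation with bin-matched controls.

    Procedure: (1) gene-wise z-score of the normalised matrix; (2) genes are
    binned into ``n_bins`` equal-occupancy bins by mean expression; (3) each
    signature gene is paired with a control set drawn from its bin (the whole
    bin when it holds <= ``n_ctrl`` genes, otherwise ``n_ctrl`` genes sampled
    without replacement, seeded); (4) the score is the signature-gene mean of
    z minus the matched control means, with downregulated genes entering with
    negative sign; (5) the score column is z-scored across observations.
    """
    if em.kind != "lognorm":
        raise ValueError("score_signature expects a normalised matrix")
    gene_pos = {g: i for i, g in enumerate(em.gene_ids)}
    sig_genes = [(g, 1.0) for g in sorted(sig.up)] + (
        [(g, -1.0 if directed else 1.0) for g in sorted(sig.down)]
    )
    present = [(g, s) for g, s in sig_genes if g in gene_pos]
    if not present:
        raise ValueError(f"no gene of signature {sig.name!r} present in the matrix")
    n_absent = len(sig_genes) - len(present)
    if n_absent:
        warnings.warn(
            f"signature {sig.name!r}: {n_absent} gene(s) absent from matrix",
            stacklevel=2,
        )

    dense = em.dense()
    z = _gene_zscores(dense)
    means = dense.mean(axis=0)
    bins = _expression_bins(means, n_bins)
    bin_members = {b: np.where(bins == b)[0] for b in np.unique(bins)}

    rng = np.random.default_rng(seed)
    contrib = np.zeros(em.n_obs)
    for g, s in present:
        gi = gene_pos[g]
        members = bin_members[bins[gi]]
        if len(members) <= n_ctrl:
            ctrl = members
        else:
            ctrl = rng.choice(members, size=n_ctrl, replace=False)
        contrib += s * (z[:, gi] - z[:, ctrl].mean(axis=1))
    raw = contrib / len(present)

    if not final_z:
        out = pd.Series(raw, index=em.obs.index, name=sig.name)
    else:
        sd = raw.std()
        if sd == 0:
            warnings.warn(
                f"signature {sig.name!r}: constant scores, final z-score undefined; "
                "returning zeros",
                stacklevel=2,
            )
            out = pd.Series(np.zeros_like(raw), index=em.obs.index, name=sig.name)
        else:
            out = pd.Series((raw - raw.mean()) / sd, index=em.obs.index, name=sig.name)
    out.attrs.update({"n_bins": n_bins, "n_ctrl": n_ctrl, "seed": seed})
    return out


def score_signatures(
    em: ExpressionMatrix,
    sigs: list[GeneSignature],
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
    **kw,
) -> pd.DataFrame:
    """Score several signatures; one column per signature, doubly z-scored."""
    cols = {
        s.name: score_signature(em, s, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed, **kw)
        for s in sigs
    }
    out = pd.DataFrame(cols, index=em.obs.index)
    out.attrs.update({"n_bins": n_bins, "n_ctrl": n_ctrl, "seed": seed})
    return out


# ---------------------------------------------------------------------------
# hurdle differential expression
# ---------------------------------------------------------------------------


def _logistic_fit(X: np.ndarray, y: np.ndarray, ridge: float = 1e-8, n_iter: int = 50):
    """Newton logistic regression; returns (beta, loglik, converged)."""
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(n_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1 - mu), 1e-10)
        grad = X.T @ (y - mu) - ridge * beta
        H = (X * w[:, None]).T @ X + ridge * np.eye(p)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return beta, -np.inf, False
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            eta = np.clip(X @ beta, -30, 30)
            ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
            return beta, ll, True
    eta = np.clip(X @ beta, -30, 30)
    ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
    return beta, ll, False


def _ols_loglik(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n = len(y)
    rss = float(resid @ resid)
    if rss <= 0:
        return beta, np.inf
    return beta, -0.5 * n * (np.log(2 * np.pi * rss / n) + 1)


def detection_rate_covariate(em: ExpressionMatrix) -> np.ndarray:
    """z-scored number of detected genes per cell (the 'cngeneson' covariate)."""
    det = np.asarray((em.values > 0).sum(axis=1)).ravel().astype(float)
    sd = det.std()
    return (det - det.mean()) / sd if sd > 0 else np.zeros_like(det)


def hurdle_de(
    em: ExpressionMatrix,
    groups: np.ndarray,
    min_cells: int = 5,
    min_group: int = 20,
) -> pd.DataFrame:
    """Two-part hurdle differential expression with a detection-rate covariate.

    Per gene: a logistic regression of detection (expression > 0) on
    ``condition + cngeneson`` and a Gaussian regression of positive
    log-expression on the same design.  The hurdle p-value combines the two
    likelihood-ratio components as a chi-square with one degree of freedom per
    estimable component (two when both parts carry the condition term).
    Genes detected in fewer than ``min_cells`` cells are skipped.  Perfect
    separation in the logistic part triggers a penalised refit and a flag.
    """
    if em.kind != "lognorm":
        raise ValueError("hurdle_de expects a normalised matrix")
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError("groups must be binary")
    cond = (groups == levels[1]).astype(float)
    if min(cond.sum(), (1 - cond).sum()) < min_group:
        raise ValueError(f"each group needs >= {min_group} cells")

    cn = detection_rate_covariate(em)
    Xf = np.column_stack([np.ones_like(cond), cond, cn])
    Xr = Xf[:, [0, 2]]
    dense = em.dense()

    rows = []
    for gi, gene in enumerate(em.gene_ids):
        yv = dense[:, gi]
        det = (yv > 0).astype(float)
        ndet = int(det.sum())
        if ndet < min_cells:
            continue
        flagged = False

        # discrete component
        if ndet == len(det):
            lrt_d, df_d, coef_d = 0.0, 0, np.nan
        else:
            bf, llf, okf = _logistic_fit(Xf, det)
            br, llr, okr = _logistic_fit(Xr, det)
            if not (okf and okr) or np.max(np.abs(bf)) > 12:
                bf, llf, _ = _logistic_fit(Xf, det, ridge=1.0)
                br, llr, _ = _logistic_fit(Xr, det, ridge=1.0)
                flagged = True
            lrt_d, df_d, coef_d = max(2 * (llf - llr), 0.0), 1, float(bf[1])

        # continuous component on expressing cells
        pos = yv > 0
        n_pos_by_group = (int((pos & (cond == 0)).sum()), int((pos & (cond == 1)).sum()))
        if min(n_pos_by_group) >= 2 and pos.sum() >= 4:
            bfc, llfc = _ols_loglik(Xf[pos], yv[pos])
            _, llrc = _ols_loglik(Xr[pos], yv[pos])
            lrt_c, df_c, coef_c = max(2 * (llfc - llrc), 0.0), 1, float(bfc[1])
        else:
            lrt_c, df_c, coef_c = 0.0, 0, np.nan

        df = df_d + df_c
        if df == 0:
            continue
        lrt = lrt_d + lrt_c
        # reported on the conventional 2-df scale of the combined hurdle test
        p = float(stats.chi2.sf(lrt, df))
        rows.append(
            {
                "gene": gene,
                "coef_disc": coef_d,
                "coef_cont": coef_c,
                "n_detected": ndet,
                "lrt": lrt,
                "df": df,
                "p": p,
                "flagged": flagged,
            }
        )

    out = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "coef_disc",
            "coef_cont",
            "n_detected",
            "lrt",
            "df",
            "p",
            "flagged",
        ],
    )
    if len(out):
        out = out.set_index("gene", drop=False)
        out["p_bonf"] = bonferroni(out["p"].to_numpy())
    else:
        out["p_bonf"] = []
    return out


# ---------------------------------------------------------------------------
# preranked GSEA
# ---------------------------------------------------------------------------


def rank_statistic(de: pd.DataFrame, p_col: str = "p") -> pd.Series:
    """Ranking statistic -log(p) * log fold change from a DE table.

    Uses ``log2fc`` (bulk tables) or ``coef_cont`` (hurdle tables), whichever
    is present.
    """
    for col in ("log2fc", "coef_cont", "coef_disc"):
        if col in de.columns and de[col].notna().any():
            lfc = de[col].fillna(0.0)
            break
    else:
        raise ValueError("no fold-change column found")
    p = np.clip(de[p_col].to_numpy(dtype=float), 1e-300, 1.0)
    stat = -np.log(p) * lfc.to_numpy(dtype=float)
    return pd.Series(stat, index=de.index, name="rank_stat")


def _running_es(weights_sorted: np.ndarray, hit_mask: np.ndarray) -> tuple[float, np.ndarray]:
    """Signed enrichment score from a weighted KS running sum (exponent 1)."""
    n = len(weights_sorted)
    s = hit_mask.sum()
    w_hits = np.where(hit_mask, weights_sorted, 0.0)
    denom = w_hits.sum()
    if denom == 0:  # all-zero weights in set: fall back to unweighted
        p_hit = np.cumsum(hit_mask) / s
    else:
        p_hit = np.cumsum(w_hits) / denom
    p_miss = np.cumsum(~hit_mask) / (n - s)
    dev = p_hit - p_miss
    es = float(dev[np.argmax(np.abs(dev))])
    return es, dev


def _null_es_for_size(
    weights_sorted: np.ndarray, size: int, n_perm: int, rng: np.random.Generator,
    chunk: int = 500,
) -> np.ndarray:
    """Null ES distribution for random gene sets of a given size (vectorised)."""
    n = len(weights_sorted)
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        # b random size-subsets of positions 0..n-1
        pick = np.argsort(rng.random((b, n)), axis=1)[:, :size]
        hits = np.zeros((b, n), dtype=bool)
        hits[np.arange(b)[:, None], pick] = True
        wh = np.where(hits, weights_sorted[None, :], 0.0)
        denom = wh.sum(axis=1)
        denom[denom == 0] = np.inf
        p_hit = np.cumsum(wh, axis=1) / denom[:, None]
        p_miss = np.cumsum(~hits, axis=1) / (n - size)
        dev = p_hit - p_miss
        idx = np.argmax(np.abs(dev), axis=1)
        out[done : done + b] = dev[np.arange(b), idx]
        done += b
    return out


def preranked_gsea(
    rank: pd.Series,
    gene_sets: dict[str, set],
    n_perm: int = 2000,
    seed: int = 0,
    min_size: int = 5,
) -> pd.DataFrame:
    """Preranked gene-set enrichment with a gene-label permutation null.

    ES is the extreme of the weighted Kolmogorov-Smirnov running sum (weight =
    |rank statistic|, exponent 1).  NES divides ES by the mean |null ES| of
    matching sign; the permutation p-value is the matching-sign tail fraction
    with +1 smoothing, BH-adjusted across gene sets.  Ties in the ranking are
    broken by stable gene-id order.
    """
    stat = rank.to_numpy(dtype=float)
    if not np.all(np.isfinite(stat)):
        raise ValueError("rank statistics must be finite")
    gene_ids = np.asarray(rank.index)
    order = np.lexsort((gene_ids, -stat))  # ties -> stable gene-id order
    genes_sorted = gene_ids[order]
    w = np.abs(stat[order])
    pos_of = {g: i for i, g in enumerate(genes_sorted)}
    rng = np.random.default_rng(seed)

    usable: list[tuple[str, np.ndarray]] = []
    for name, members in gene_sets.items():
        hit_idx = np.array(sorted(pos_of[g] for g in members if g in pos_of), dtype=int)
        if len(hit_idx) < min_size:
            warnings.warn(f"gene set {name!r}: <{min_size} ranked members, skipped", stacklevel=2)
            continue
        if len(hit_idx) >= len(genes_sorted):
            warnings.warn(f"gene set {name!r} covers all genes, skipped", stacklevel=2)
            continue
        usable.append((name, hit_idx))

    nulls: dict[int, np.ndarray] = {}
    rows = []
    for name, hit_idx in usable:
        size = len(hit_idx)
        if size not in nulls:
            nulls[size] = _null_es_for_size(w, size, n_perm, rng)
        null = nulls[size]
        hit_mask = np.zeros(len(genes_sorted), dtype=bool)
        hit_mask[hit_idx] = True
        es, _ = _running_es(w, hit_mask)
        same = null >= 0 if es >= 0 else null < 0
        n_same = int(same.sum())
        if n_same == 0:
            p = 1.0 / (n_perm + 1)
            nes = np.nan
        else:
            exceed = int((np.abs(null[same]) >= abs(es)).sum())
            p = (1 + exceed) / (1 + n_same)
            mean_same = float(np.abs(null[same]).mean())
            nes = es / mean_same if mean_same > 0 else np.nan
        rows.append({"pathway": name, "size": size, "es": es, "nes": nes, "p": p})

    out = pd.DataFrame(rows, columns=["pathway", "size", "es", "nes", "p"])
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
        out = out.set_index("pathway", drop=False)
    else:
        out["p_adj"] = []
    return out


# ---------------------------------------------------------------------------
# highly variable genes and cluster merging
# ---------------------------------------------------------------------------


def select_hvgs(
    em: ExpressionMatrix,
    batches: np.ndarray | None = None,
    n_top: int = 1000,
    n_bins: int = 20,
    mask: set | None = None,
) -> list[str]:
    """Dispersion-based highly-variable genes, batch-aware.

    Per batch the normalised dispersion (variance/mean of the log data,
    z-scored within mean-expression bins) is computed; genes are ranked by the
    number of batches in which they fall in that batch's top ``n_top``, then
    by median normalised dispersion.  ``mask`` genes (e.g. mitochondrial,
    ribosomal, MALAT1-like) are excluded.
    """
    if em.n_obs < 2:
        raise ValueError("need >= 2 observations")
    dense = em.dense()
    gene_ids = np.asarray(em.gene_ids)
    keep = np.ones(len(gene_ids), dtype=bool)
    if mask:
        keep &= ~np.isin(gene_ids, list(mask))
    if batches is None:
        batches = np.zeros(em.n_obs, dtype=int)
    batches = np.asarray(batches)

    if n_top > keep.sum():
        warnings.warn("n_top exceeds number of genes; returning all", stacklevel=2)

    per_batch_pass = np.zeros(len(gene_ids), dtype=int)
    disp_stack = []
    for b in pd.unique(batches):
        sub = dense[batches == b]
        mu = sub.mean(axis=0)
        var = sub.var(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            disp = np.where(mu > 0, var / mu, 0.0)
        nd = np.full(len(gene_ids), -np.inf)
        ok = keep & (mu > 0)
        if ok.sum() >= 2:
            bins = _expression_bins(mu[ok], min(n_bins, max(ok.sum() // 2, 1)))
            z = np.zeros(ok.sum())
            for bb in np.unique(bins):
                sel = bins == bb
                d = disp[ok][sel]
                sd = d.std()
                z[sel] = (d - d.mean()) / sd if sd > 0 else 0.0
            nd[ok] = z
        disp_stack.append(nd)
        top = np.argsort(-nd, kind="stable")[: min(n_top, int(keep.sum()))]
        passed = top[np.isfinite(nd[top])]
        per_batch_pass[passed] += 1

    med_disp = np.median(np.vstack(disp_stack), axis=0)
    med_disp[~np.isfinite(med_disp)] = -np.inf
    order = np.lexsort((gene_ids, -med_disp, -per_batch_pass))
    order = order[keep[order]]
    chosen = [g for g in gene_ids[order][:n_top]]
    return chosen


def cluster_state_merge(
    em: ExpressionMatrix,
    clusters: np.ndarray,
    hvgs: list[str],
    linkage_threshold: float = 0.7,
) -> tuple[dict, pd.DataFrame]:
    """Merge expression clusters into states by correlation of mean profiles.

    Pearson correlation of cluster mean expression over the highly-variable
    genes; average-linkage hierarchical grouping on 1 - r, cut at
    1 - ``linkage_threshold``.  Returns (cluster -> state map, correlation
    matrix).
    """
    clusters = np.asarray(clusters)
    labels = pd.unique(clusters)
    if len(labels) < 2:
        raise ValueError("need >= 2 clusters")
    gene_idx = [i for i, g in enumerate(em.gene_ids) if g in set(hvgs)]
    if not gene_idx:
        raise ValueError("no HVG present in the matrix")
    dense = em.dense()[:, gene_idx]
    means = []
    for lab in labels:
        sel = clusters == lab
        if sel.sum() < 3:
            warnings.warn(f"cluster {lab!r} has <3 cells; kept", stacklevel=2)
        means.append(dense[sel].mean(axis=0))
    M = np.vstack(means)
    corr = np.corrcoef(M)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    dist = squareform(1.0 - corr, checks=False)
    Z = hierarchy.linkage(dist, method="average")
    assign = hierarchy.fcluster(Z, t=1.0 - linkage_threshold, criterion="distance")
    mapping = {lab: f"state_{a}" for lab, a in zip(labels, assign)}
    corr_df = pd.DataFrame(corr, index=labels, columns=labels)
    return mapping, corr_df
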