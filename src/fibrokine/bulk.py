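"""Bulk stimulation differential expression and cytokine-response signatures.

Cultured fibroblasts stimulated in vitro with proinflammatory cytokines (TNF,
IFN-gamma, IL-1beta, alone or in combination, with or without the Notch ligand
DLL4) are profiled by bulk RNA-seq against unstimulated controls.  This module
derives directed response signatures from a negative-binomial Wald test per
condition, restricts them to genes expressed exclusively by a target cell
type, and quantifies the "dampening" of cytokine responses under Notch
co-stimulation as a paired shift of per-gene log2 fold changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _nbglm
from ._utils import bh_adjust

LN2 = np.log(2.0)


@dataclass
class GeneSignature:
    """A directed gene set: up- and downregulated members plus provenance."""

    name: str
    up: set = field(default_factory=set)
    down: set = field(default_factory=set)
    provenance: str = ""

    def __post_init__(self):
        self.up = set(self.up)
        self.down = set(self.down)
        overlap = self.up & self.down
        if overlap:
            raise ValueError(
                f"signature {self.name!r}: genes in both directions: {sorted(overlap)[:5]}"
            )
        if not self.up and not self.down:
            warnings.warn(f"signature {self.name!r} is empty", stacklevel=2)

    @property
    def genes(self) -> set:
        return self.up | self.down

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


@dataclass
class BulkCounts:
    """Genes x samples integer counts with a stimulation design.

    ``condition`` and ``replicate`` are per-sample (column-aligned) labels; a
    designated control condition must be present with >= 2 replicates, as must
    every stimulated condition.
    """

    counts: pd.DataFrame
    condition: pd.Series
    replicate: pd.Series
    control: str = "control"

    def __post_init__(self):
        if not self.counts.columns.equals(self.condition.index):
            self.condition = self.condition.reindex(self.counts.columns)
        if not self.counts.columns.equals(self.replicate.index):
            self.replicate = self.replicate.reindex(self.counts.columns)
        if self.condition.isna().any() or self.replicate.isna().any():
            raise ValueError("condition/replicate labels missing for some samples")
        vc = self.condition.value_counts()
        if self.control not in vc.index:
            raise ValueError(f"control condition {self.control!r} not found")
        low = vc[vc < 2]
        if len(low):
            raise ValueError(f"conditions with <2 replicates: {list(low.index)}")
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("negative counts")

    @property
    def conditions(self) -> list[str]:
        return list(pd.unique(self.condition))


def estimate_size_factors(counts) -> np.ndarray:
    """Median-of-ratios size factors.

    factor_j = median over genes (restricted to genes whose geometric mean
    across samples is positive) of count_gj / geometric-mean_g.
    """
    mat = np.asarray(counts, dtype=float)
    if mat.ndim != 2:
        raise ValueError("counts must be 2-D (genes x samples)")
    with np.errstate(divide="ignore"):
        logc = np.log(mat)
    finite_rows = np.isfinite(logc).all(axis=1)
    if finite_rows.sum() == 0:
        raise ValueError("no gene is nonzero in every sample; cannot form reference")
    log_geo = logc[finite_rows].mean(axis=1)
    ratios = logc[finite_rows] - log_geo[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    if not np.all(np.isfinite(factors) & (factors > 0)):
        bad = np.where(~(np.isfinite(factors) & (factors > 0)))[0]
        names = (
            list(counts.columns[bad]) if isinstance(counts, pd.DataFrame) else list(bad)
        )
        raise ValueError(f"degenerate size factor for sample(s) {names}")
    return factors


def nb_wald_de(
    bulk: BulkCounts,
    condition: str,
    shrink_lfc: bool = False,
    min_mean: float = 1.0,
) -> pd.DataFrame:
    """Negative-binomial Wald differential expression: ``condition`` vs control.

    Per gene an NB GLM with log link, design ``intercept + condition``,
    offsets = log median-of-ratios size factors (estimated on the full
    dataset).  Gene-wise dispersion MLEs are shrunk toward a parametric
    a/mu + b trend via a log-normal prior; the Wald test is on the condition
    coefficient with BH adjustment across genes passing an independent-filter
    floor on mean normalised count.  Genes below the floor, or with a
    non-convergent fit, are reported with ``p_adj`` missing and excluded from
    the BH family.

    With ``shrink_lfc`` the table gains a ``log2fc_shrunk`` column: the MAP
    estimate under a zero-centred normal prior on the condition coefficient
    (a ridge approximation of the moderated estimators used for effect-size
    plotting); the test itself always uses the MLE.
    """
    if condition not in bulk.conditions:
        raise ValueError(f"condition {condition!r} not in design")
    if condition == bulk.control:
        raise ValueError("condition equals the control")

    sf_all = estimate_size_factors(bulk.counts)
    keep = bulk.condition.isin([bulk.control, condition]).to_numpy()
    y = np.asarray(bulk.counts, dtype=float)[:, keep]
    x = (bulk.condition[keep] == condition).to_numpy().astype(float)
    offset = np.log(sf_all[keep])
    genes = np.asarray(bulk.counts.index)
    G, S = y.shape

    base_mean = (y / np.exp(offset)[None, :]).mean(axis=1)
    expressed = base_mean > 0

    alpha_mle = np.full(G, np.nan)
    alpha_mle[expressed] = _nbglm.estimate_dispersions_mle(
        y[expressed], x, offset
    )
    _, _, trend = _nbglm.fit_dispersion_trend(alpha_mle, base_mean)
    alpha_tr = trend(base_mean)
    log_resid = np.log(alpha_mle[expressed]) - np.log(alpha_tr[expressed])
    prior_var = _nbglm.dispersion_prior_var(log_resid, n_samples=S)

    alpha_map = np.full(G, np.nan)
    alpha_map[expressed] = _nbglm.estimate_dispersions_mle(
        y[expressed],
        x,
        offset,
        prior_mean=np.log(alpha_tr[expressed]),
        prior_var=prior_var,
    )

    b0 = np.full(G, np.nan)
    b1 = np.full(G, np.nan)
    se1 = np.full(G, np.nan)
    conv = np.zeros(G, dtype=bool)
    b0e, b1e, se1e, _, conve = _nbglm.irls_two_group(
        y[expressed], x, offset, alpha_map[expressed]
    )
    b0[expressed], b1[expressed], se1[expressed], conv[expressed] = b0e, b1e, se1e, conve

    with np.errstate(invalid="ignore", divide="ignore"):
        wald = b1 / se1
        p = 2.0 * stats.norm.sf(np.abs(wald))

    tested = expressed & conv & (base_mean >= min_mean) & np.isfinite(p)
    p_for_bh = np.where(tested, p, np.nan)
    p_adj = bh_adjust(p_for_bh)

    de = pd.DataFrame(
        {
            "gene": genes,
            "base_mean": base_mean,
            "log2fc": b1 / LN2,
            "se": se1 / LN2,
            "wald_stat": wald,
            "p": p,
            "p_adj": p_adj,
            "dispersion": alpha_map,
            "converged": conv,
        }
    ).set_index("gene", drop=False)

    if shrink_lfc:
        lfc_mle = b1[tested]
        prior_v = max(np.nanvar(lfc_mle) - np.nanmedian(se1[tested] ** 2), 0.05)
        ridge = 1.0 / prior_v
        _, b1s, _, _, _ = _nbglm.irls_two_group(
            y[expressed], x, offset, alpha_map[expressed], ridge=ridge
        )
        shrunk = np.full(G, np.nan)
        shrunk[expressed] = b1s
        de["log2fc_shrunk"] = shrunk / LN2

    de.attrs["condition"] = condition
    de.attrs["control"] = bulk.control
    return de


def derive_signature(de: pd.DataFrame, alpha: float = 0.05, name: str | None = None) -> GeneSignature:
    """Directed signature from a DE table: adjusted p < alpha, split by LFC sign."""
    if len(de) == 0:
        raise ValueError("empty DE table")
    sig_mask = (de["p_adj"] < alpha) & np.isfinite(de["p_adj"])
    up = set(de.index[sig_mask & (de["log2fc"] > 0)])
    down = set(de.index[sig_mask & (de["log2fc"] < 0)])
    cond = de.attrs.get("condition", "unknown")
    name = name or f"{cond}_response"
    with warnings.catch_warnings():
        if up or down:
            warnings.simplefilter("ignore")
        sig = GeneSignature(
            name=name,
            up=up,
            down=down,
            provenance=f"condition={cond} vs {de.attrs.get('control', '?')}, p_adj<{alpha}",
        )
    return sig


def restrict_signature(
    sig: GeneSignature,
    expr_by_celltype: pd.DataFrame,
    target: str,
    exclusivity_ratio: float = 2.0,
) -> GeneSignature:
    """Restrict a signature to genes expressed (near-)exclusively by one cell type.

    A gene is kept when its mean expression in ``target`` is at least
    ``exclusivity_ratio`` times the maximum mean expression among the other
    cell types in the table.  Genes absent from the table are dropped with a
    warning.
    """
    if target not in expr_by_celltype.columns:
        raise ValueError(f"target cell type {target!r} not in expression table")
    others = [c for c in expr_by_celltype.columns if c != target]

    def keep(genes: set) -> set:
        present = genes & set(expr_by_celltype.index)
        missing = genes - present
        if missing:
            warnings.warn(
                f"{len(missing)} signature gene(s) absent from cell-type table; dropped",
                stacklevel=3,
            )
        if not present:
            return set()
        sub = expr_by_celltype.loc[sorted(present)]
        tgt = sub[target].to_numpy()
        other_max = sub[others].to_numpy().max(axis=1) if others else np.zeros(len(sub))
        ok = tgt >= exclusivity_ratio * other_max
        return set(np.asarray(sub.index)[ok])

    up_kept = keep(sig.up)
    down_kept = keep(sig.down)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = GeneSignature(
            name=f"{sig.name}_restricted",
            up=up_kept,
            down=down_kept,
            provenance=sig.provenance
            + f"; restricted to {target} at ratio>={exclusivity_ratio}",
        )
    return out


def dll4_shift(
    de_alone: pd.DataFrame,
    de_with_dll4: pd.DataFrame,
    sig: GeneSignature,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired shift of per-gene log2 fold changes under Notch/DLL4 co-stimulation.

    For each signature gene the pair (lfc alone, lfc with DLL4) is formed from
    the two DE tables (shrunken estimates when available) and summarised
    separately for up- and downregulated genes.  "Dampening" is a shrinkage of
    |lfc| toward zero, reported with a positive sign for both directions:
    ``median_shrinkage = median(|lfc_alone| - |lfc_dll4|)``, with a Wilcoxon
    signed-rank test on the paired |lfc| values.
    """

    def lfc(de):
        col = "log2fc_shrunk" if "log2fc_shrunk" in de.columns else "log2fc"
        return de[col]

    rows = []
    for direction, genes in (("up", sig.up), ("down", sig.down)):
        shared = sorted(genes & set(de_alone.index) & set(de_with_dll4.index))
        if not genes:
            continue
        if len(shared) < 5:
            raise ValueError(
                f"only {len(shared)} shared {direction} signature genes; need >= 5"
            )
        a = lfc(de_alone).loc[shared].to_numpy(dtype=float)
        b = lfc(de_with_dll4).loc[shared].to_numpy(dtype=float)
        fin = np.isfinite(a) & np.isfinite(b)
        a, b = a[fin], b[fin]
        shrink = np.abs(a) - np.abs(b)
        if np.allclose(shrink, 0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(np.abs(a), np.abs(b)).pvalue)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.abs(b) / np.abs(a)
        rows.append(
            {
                "direction": direction,
                "n_genes": int(fin.sum()),
                "median_paired_diff": float(np.median(b - a)),
                "median_shrinkage": float(np.median(shrink)),
                "median_abs_ratio": float(np.median(ratio[np.isfinite(ratio)])),
                "wilcoxon_p": p,
                "dampened": bool(np.median(shrink) > 0 and p < alpha),
            }
        )
    return pd.DataFrame(rows).set_index("direction")
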