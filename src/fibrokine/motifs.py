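"""Per-cell TF-motif accessibility deviations with matched background peaks.

Implements the chromVAR model: for every motif, the observed accessibility of
its peaks in each cell is compared with the expectation under a purely
depth-driven null (cells draw accessible sites in proportion to their total
accessibility).  The raw deviation is normalised against the same statistic
computed on background peak sets matched on GC content and mean
accessibility, yielding a per-cell, per-motif z-score.  Downstream, motifs
are gated on paired RNA expression of their TFs and ranked per cell state by
a one-vs-rest Wilcoxon test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.spatial import cKDTree

from ._utils import bh_adjust
from .scoring import ExpressionMatrix


@dataclass
class PeakMatrix:
    """Binarised peaks x cells accessibility with peak intervals and GC content."""

    binary: sp.spmatrix | np.ndarray
    peak_coords: pd.DataFrame  # columns chrom, start, end (0-based half-open)
    gc: np.ndarray

    def __post_init__(self):
        self.gc = np.asarray(self.gc, dtype=float)
        P, C = self.binary.shape
        if len(self.gc) != P or len(self.peak_coords) != P:
            raise ValueError("peak annotation length mismatch")
        if not np.all(np.isfinite(self.gc)):
            raise ValueError("GC content must be finite")
        if ((self.gc < 0) | (self.gc > 1)).any():
            raise ValueError("GC content must lie in [0, 1]")
        cell_tot = np.asarray(self.binary.sum(axis=0)).ravel()
        if (cell_tot == 0).any():
            raise ValueError("all-zero cell(s) present; filter cells upstream")

    @property
    def n_peaks(self) -> int:
        return self.binary.shape[0]

    @property
    def n_cells(self) -> int:
        return self.binary.shape[1]


@dataclass
class MotifMatch:
    """Binary motifs x peaks match matrix plus motif -> TF gene mapping."""

    match: sp.spmatrix | np.ndarray
    motif_names: list[str]
    motif_to_tf: dict[str, list[str]]

    def __post_init__(self):
        if self.match.shape[0] != len(self.motif_names):
            raise ValueError("motif name / matrix mismatch")
        for m in self.motif_names:
            tfs = self.motif_to_tf.get(m)
            if not tfs:
                raise ValueError(f"motif {m!r} maps to no TF gene")
            if isinstance(tfs, str):
                self.motif_to_tf[m] = [tfs]
        per_motif = np.asarray(self.match.sum(axis=1)).ravel()
        empty = [self.motif_names[i] for i in np.where(per_motif == 0)[0]]
        if empty:
            warnings.warn(
                f"motif(s) with no matched peak kept: {empty[:5]} "
                "(deviations undefined downstream)",
                stacklevel=2,
            )


@dataclass
class DeviationResult:
    raw: pd.DataFrame  # motifs x cells
    z: pd.DataFrame
    background_seed: int
    n_background: int
    flagged: list[str] = field(default_factory=list)


def expected_counts(pm: PeakMatrix, mm: MotifMatch) -> np.ndarray:
    """Depth-proportional expected motif accessibility per cell.

    E_mi = T_m * d_i / D with T_m the total accessible counts in the motif's
    peaks over all cells, d_i the cell total and D the grand total.  Satisfies
    sum_i E_mi = T_m exactly.
    """
    X = sp.csr_matrix(pm.binary, dtype=float)
    M = sp.csr_matrix(mm.match, dtype=float)
    if M.shape[1] != X.shape[0]:
        raise ValueError("motif match / peak matrix dimension mismatch")
    obs = np.asarray((M @ X).todense())
    d = np.asarray(X.sum(axis=0)).ravel()
    D = d.sum()
    if D == 0:
        raise ValueError("empty accessibility matrix (grand total 0)")
    T = obs.sum(axis=1)
    return T[:, None] * d[None, :] / D


def sample_backgrounds(
    pm: PeakMatrix,
    n_background: int = 50,
    seed: int = 0,
    window: float = 0.02,
) -> np.ndarray:
    """Background peaks matched on (GC, log mean accessibility).

    Each peak draws ``n_background`` peaks (with replacement) from its
    Mahalanobis-nearest ``window`` quantile in the 2-D space of z-scored GC
    and z-scored log mean accessibility.  With a degenerate covariate
    covariance the matching falls back to rank-transformed coordinates; with
    fully identical covariates backgrounds are uniform draws from all peaks.
    """
    P = pm.n_peaks
    if P < n_background:
        raise ValueError("fewer peaks than requested backgrounds")
    rng = np.random.default_rng(seed)
    mean_acc = np.asarray(pm.binary.mean(axis=1)).ravel()
    cov1 = pm.gc.astype(float)
    cov2 = np.log(mean_acc + 1e-6)

    def zsc(v):
        sd = v.std()
        # relative tolerance: a constant vector has sd at round-off scale
        if sd <= 1e-12 * max(1.0, float(np.abs(v).max())):
            return np.zeros_like(v)
        return (v - v.mean()) / sd

    Z = np.column_stack([zsc(cov1), zsc(cov2)])
    if np.allclose(Z, 0):
        return rng.integers(0, P, size=(P, n_background))

    C = np.cov(Z.T)
    try:
        L = np.linalg.cholesky(C + 1e-12 * np.eye(2))
        white = np.linalg.solve(L, Z.T).T
        if not np.all(np.isfinite(white)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn("degenerate covariate covariance; rank-based matching", stacklevel=2)
        white = np.column_stack(
            [stats.rankdata(cov1) / P, stats.rankdata(cov2) / P]
        )

    k = max(int(np.ceil(window * P)), n_background, 2)
    k = min(k, P)
    tree = cKDTree(white)
    _, nn = tree.query(white, k=k)
    nn = np.atleast_2d(nn)
    draws = rng.integers(0, k, size=(P, n_background))
    return nn[np.arange(P)[:, None], draws]


def compute_deviations(
    pm: PeakMatrix,
    mm: MotifMatch,
    backgrounds: np.ndarray,
    cell_ids: list | None = None,
    seed: int = 0,
) -> DeviationResult:
    """chromVAR deviations: raw fractional deviation and background z-score.

    raw_mi = (obs_mi - E_mi) / E_mi; for each background replicate the same
    statistic is computed on the background peak sets, and
    z_mi = (raw_mi - mean_b bg_mib) / sd_b bg_mib.  Motifs whose background
    deviations have zero spread for a cell yield missing z there and are
    flagged.
    """
    X = sp.csr_matrix(pm.binary, dtype=float)
    M = sp.csr_matrix(mm.match, dtype=float)
    n_bg = backgrounds.shape[1]
    E = expected_counts(pm, mm)
    obs = np.asarray((M @ X).todense())
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(E > 0, (obs - E) / E, np.nan)

    d = np.asarray(X.sum(axis=0)).ravel()
    D = d.sum()
    bg_dev = np.empty((n_bg,) + raw.shape)
    for b in range(n_bg):
        idx = backgrounds[:, b]
        Xb = X[idx, :]
        obs_b = np.asarray((M @ Xb).todense())
        T_b = obs_b.sum(axis=1)
        E_b = T_b[:, None] * d[None, :] / D
        with np.errstate(divide="ignore", invalid="ignore"):
            bg_dev[b] = np.where(E_b > 0, (obs_b - E_b) / E_b, np.nan)

    bg_mean = np.nanmean(bg_dev, axis=0)
    bg_sd = np.nanstd(bg_dev, axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (raw - bg_mean) / bg_sd
    z[~np.isfinite(z)] = np.nan

    cells = list(cell_ids) if cell_ids is not None else list(range(pm.n_cells))
    raw_df = pd.DataFrame(raw, index=mm.motif_names, columns=cells)
    z_df = pd.DataFrame(z, index=mm.motif_names, columns=cells)
    flagged = [
        mm.motif_names[i]
        for i in range(len(mm.motif_names))
        if not np.all(np.isfinite(z[i]))
    ]
    return DeviationResult(
        raw=raw_df, z=z_df, background_seed=seed, n_background=n_bg, flagged=flagged
    )


def expression_gate(
    dev: DeviationResult,
    mm: MotifMatch,
    expr: ExpressionMatrix,
    states: np.ndarray,
    min_frac: float = 0.20,
) -> dict[str, set]:
    """Admit a motif for a state iff a mapped TF is detected in > ``min_frac``
    of that state's cells (strict inequality: a TF at exactly the threshold
    fails, one just above passes).

    Motifs whose TFs are all absent from the expression matrix are excluded
    everywhere, with a warning.
    """
    if expr.kind != "counts":
        raise ValueError("expression gate uses raw counts (detection = count > 0)")
    states = np.asarray(states)
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    detected = expr.values > 0
    if sp.issparse(detected):
        detected = np.asarray(detected.todense())

    out: dict[str, set] = {}
    missing: list[str] = []
    for state in pd.unique(states):
        sel = states == state
        if sel.sum() == 0:
            raise ValueError(f"state {state!r} has no cells")
        admitted = set()
        for motif in mm.motif_names:
            tfs = [t for t in mm.motif_to_tf[motif] if t in gene_pos]
            if not tfs:
                if motif not in missing:
                    missing.append(motif)
                continue
            fracs = [detected[sel, gene_pos[t]].mean() for t in tfs]
            if max(fracs) > min_frac:
                admitted.add(motif)
        out[str(state)] = admitted
    if missing:
        warnings.warn(
            f"{len(missing)} motif(s) with no expressed TF id in matrix; excluded",
            stacklevel=2,
        )
    return out


def _wilcoxon_one_vs_rest(values: np.ndarray, in_group: np.ndarray) -> tuple[float, float]:
    """Tie-corrected normal-approximation Wilcoxon rank-sum z and p."""
    fin = np.isfinite(values)
    v = values[fin]
    g = in_group[fin]
    n1 = int(g.sum())
    n2 = int((~g).sum())
    if n1 == 0 or n2 == 0:
        return np.nan, np.nan
    n = n1 + n2
    ranks = stats.rankdata(v)
    r1 = ranks[g].sum()
    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(v, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 0.0, 1.0
    zstat = (r1 - mu) / np.sqrt(var)
    return float(zstat), float(2.0 * stats.norm.sf(abs(zstat)))


def rank_motifs(
    dev: DeviationResult,
    states: np.ndarray,
    gate: dict[str, set] | None = None,
    n_top: int = 6,
) -> pd.DataFrame:
    """Per-state one-vs-rest Wilcoxon ranking of motif deviation z-scores.

    Within each state, BH adjustment across the gated motifs and the top
    ``n_top`` motifs by score (the Wilcoxon normal-approximation statistic)
    are returned.
    """
    states = np.asarray(states)
    if len(pd.unique(states)) < 2:
        raise ValueError("need >= 2 states")
    Z = dev.z.to_numpy()
    rows = []
    for state in pd.unique(states):
        sel = states == state
        allowed = gate.get(str(state)) if gate is not None else set(dev.z.index)
        scored = []
        for mi, motif in enumerate(dev.z.index):
            if motif not in allowed:
                continue
            vals = Z[mi]
            if not np.any(np.isfinite(vals)):
                continue
            score, p = _wilcoxon_one_vs_rest(vals, sel)
            if np.isnan(score):
                continue
            scored.append({"state": str(state), "motif": motif, "score": score, "p": p})
        if not scored:
            continue
        sdf = pd.DataFrame(scored)
        sdf["p_adj"] = bh_adjust(sdf["p"].to_numpy())
        sdf = sdf.sort_values(["score", "motif"], ascending=[False, True]).head(n_top)
        sdf["rank"] = np.arange(1, len(sdf) + 1)
        rows.append(sdf)
    if not rows:
        return pd.DataFrame(columns=["state", "motif", "score", "p", "p_adj", "rank"])
    return pd.concat(rows, ignore_index=True)
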