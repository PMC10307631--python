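"""Synthetic data generators with planted ground truth.

Every input kind the pipeline consumes can be generated here with known
truth, so each downstream stage is testable end-to-end without external
downloads:

* bulk stimulation RNA-seq: negative-binomial counts with planted
  per-condition cytokine programs (and optional attenuated combination
  conditions emulating Notch/DLL4 co-stimulation);
* multi-state single-cell counts whose states differ by multiplicative
  cytokine programs, with planted QC failures (high-mitochondrial and
  low-depth cells);
* spatial spots as Dirichlet-multinomial mixtures over topic-specific gene
  distributions on a hexagonal array;
* binarised peak x cell chromatin accessibility with motif-driven state
  effects and a GC covariate.

All generators are seed-deterministic.  The negative binomial is
parameterised by mean and dispersion with Var = mu + dispersion * mu**2;
per-cell library sizes are log-normal; mitochondrial genes carry a reserved
"MT-" name prefix so QC fractions are computable from names alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._utils import child_seeds, rng_from
from .bulk import BulkCounts, GeneSignature
from .hexgrid import axial_to_offset, hex_grid
from .motifs import MotifMatch, PeakMatrix
from .scoring import MITO_PREFIX, ExpressionMatrix


@dataclass
class CytokineProgram:
    """A directed transcriptional response program with log2 effect sizes."""

    name: str
    up_genes: list[int]
    down_genes: list[int]
    log2fc_up: float = 2.0
    log2fc_down: float = 2.0

    def __post_init__(self):
        if set(self.up_genes) & set(self.down_genes):
            raise ValueError(f"program {self.name!r}: up/down genes overlap")
        if not (
            np.isfinite(self.log2fc_up)
            and np.isfinite(self.log2fc_down)
            and self.log2fc_up > 0
            and self.log2fc_down > 0
        ):
            raise ValueError("effect sizes must be finite and positive")


@dataclass
class StateSpec:
    """A cell state: weighted cytokine programs over a baseline profile."""

    name: str
    programs: list[tuple[CytokineProgram, float]] = field(default_factory=list)
    baseline_mean: np.ndarray | None = None
    n_cells: int = 100

    def __post_init__(self):
        for _, w in self.programs:
            if not 0.0 <= w <= 1.0:
                raise ValueError("program weights must lie in [0, 1]")
        if self.baseline_mean is not None and (np.asarray(self.baseline_mean) < 0).any():
            raise ValueError("baseline_mean must be nonnegative")
        if self.n_cells <= 0:
            raise ValueError(f"state {self.name!r} has n_cells <= 0")


@dataclass
class SyntheticTruth:
    """Planted ground truth recorded by the generators."""

    seed: int
    de_genes_by_condition: dict = field(default_factory=dict)
    state_of_cell: np.ndarray | None = None
    omega_true: np.ndarray | None = None
    theta_true: np.ndarray | None = None
    motif_activity: np.ndarray | None = None
    qc_fail: pd.Series | None = None

    def __post_init__(self):
        if self.omega_true is not None and not np.allclose(
            self.omega_true.sum(axis=1), 1.0, atol=1e-12
        ):
            raise ValueError("omega_true rows must sum to 1")
        if self.theta_true is not None and not np.allclose(
            self.theta_true.sum(axis=1), 1.0, atol=1e-12
        ):
            raise ValueError("theta_true rows must sum to 1")


def make_gene_ids(n_genes: int, n_mito: int = 0) -> list[str]:
    """Gene identifiers; the first ``n_mito`` carry the mitochondrial prefix."""
    if n_mito > n_genes:
        raise ValueError("n_mito > n_genes")
    mito = [f"{MITO_PREFIX}{i}" for i in range(n_mito)]
    rest = [f"G{i:05d}" for i in range(n_genes - n_mito)]
    return mito + rest


def _signed_lfc(programs: list[tuple[CytokineProgram, float]], n_genes: int) -> np.ndarray:
    lfc = np.zeros(n_genes)
    for prog, w in programs:
        for g in prog.up_genes:
            lfc[g] += w * prog.log2fc_up
        for g in prog.down_genes:
            lfc[g] -= w * prog.log2fc_down
    return lfc


# ---------------------------------------------------------------------------
# bulk
# ---------------------------------------------------------------------------


def generate_bulk(
    programs: list[CytokineProgram],
    n_replicates: int = 3,
    n_genes: int = 2000,
    dispersion: float = 0.05,
    seed: int = 0,
    baseline_mean: np.ndarray | None = None,
    combinations: list[tuple[str, list[str], float]] | None = None,
) -> tuple[BulkCounts, SyntheticTruth]:
    """Negative-binomial bulk stimulation counts with planted condition effects.

    One control condition plus one condition per program; ``combinations``
    adds conditions formed by summing member-program effects scaled by a
    factor (a scale of 0.5 emulates DLL4-style dampening of every planted
    effect).  Counts are NB with mean = baseline * 2**(signed log2fc).
    """
    if n_replicates < 2:
        raise ValueError("need >= 2 replicates")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    for prog in programs:
        if prog.up_genes and max(prog.up_genes) >= n_genes:
            raise ValueError(f"program {prog.name!r} references gene >= n_genes")
        if prog.down_genes and max(prog.down_genes) >= n_genes:
            raise ValueError(f"program {prog.name!r} references gene >= n_genes")
    names = [p.name for p in programs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate program names")

    rng = rng_from(seed)
    if baseline_mean is None:
        baseline_mean = np.exp(rng.normal(np.log(100.0), 1.0, size=n_genes))
    baseline_mean = np.asarray(baseline_mean, dtype=float)

    by_name = {p.name: p for p in programs}
    cond_lfc: dict[str, np.ndarray] = {"control": np.zeros(n_genes)}
    for p in programs:
        cond_lfc[p.name] = _signed_lfc([(p, 1.0)], n_genes)
    for combo_name, members, scale in combinations or []:
        progs = [(by_name[m], 1.0) for m in members]
        up_all: set[int] = set()
        down_all: set[int] = set()
        for p, _ in progs:
            if (up_all & set(p.down_genes)) or (down_all & set(p.up_genes)):
                raise ValueError(
                    f"combination {combo_name!r}: conflicting up/down assignments"
                )
            up_all |= set(p.up_genes)
            down_all |= set(p.down_genes)
        cond_lfc[combo_name] = scale * _signed_lfc(progs, n_genes)

    gene_ids = make_gene_ids(n_genes)
    cols, cond_lab, rep_lab, blocks = [], [], [], []
    for cond, lfc in cond_lfc.items():
        mu = baseline_mean * np.power(2.0, lfc)
        shape = 1.0 / dispersion
        for r in range(n_replicates):
            lam = rng.gamma(shape, mu / shape)
            blocks.append(rng.poisson(lam))
            cols.append(f"{cond}_rep{r + 1}")
            cond_lab.append(cond)
            rep_lab.append(r + 1)
    counts = pd.DataFrame(np.column_stack(blocks), index=gene_ids, columns=cols)
    bulk = BulkCounts(
        counts=counts,
        condition=pd.Series(cond_lab, index=cols),
        replicate=pd.Series(rep_lab, index=cols),
    )

    de_truth = {}
    for cond, lfc in cond_lfc.items():
        if cond == "control":
            continue
        up = {gene_ids[g] for g in np.where(lfc > 0)[0]}
        down = {gene_ids[g] for g in np.where(lfc < 0)[0]}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            de_truth[cond] = GeneSignature(name=cond, up=up, down=down, provenance="planted")
    truth = SyntheticTruth(seed=seed, de_genes_by_condition=de_truth)
    return bulk, truth


# ---------------------------------------------------------------------------
# single cell
# ---------------------------------------------------------------------------


def generate_single_cell(
    states: list[StateSpec],
    n_genes: int = 2000,
    seed: int = 0,
    n_mito: int = 20,
    mito_baseline_frac: float = 0.03,
    libsize_median: float = 5000.0,
    libsize_sigma: float = 0.4,
    frac_low_depth: float = 0.0,
    frac_high_mito: float = 0.0,
    high_mito_frac: float = 0.35,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Multi-state single-cell counts with planted programs and QC failures.

    Each cell draws a log-normal library size and multinomial gene counts from
    its state's expected profile (baseline times 2**(weighted program lfc)).
    ``frac_low_depth`` cells get totals below 1,024 molecules and
    ``frac_high_mito`` cells get a mitochondrial fraction of
    ``high_mito_frac``, so QC filters can be validated by construction.
    """
    # single-state populations are legitimate (null-calibration designs)
    for st in states:
        if st.n_cells <= 0:
            raise ValueError(f"state {st.name!r} has no cells")

    rng = rng_from(seed)
    gene_ids = make_gene_ids(n_genes, n_mito=n_mito)
    shared_baseline = np.exp(rng.normal(0.0, 1.0, size=n_genes))
    # reserve a fixed fraction of expression for the mitochondrial block
    if n_mito:
        nonmito_sum = shared_baseline[n_mito:].sum()
        shared_baseline[:n_mito] = (
            mito_baseline_frac / (1 - mito_baseline_frac) * nonmito_sum / n_mito
        )

    profiles, labels = [], []
    for st in states:
        base = (
            np.asarray(st.baseline_mean, dtype=float)
            if st.baseline_mean is not None
            else shared_baseline
        )
        lfc = _signed_lfc(st.programs, n_genes)
        mean = base * np.power(2.0, lfc)
        profiles.append(mean / mean.sum())
        labels.append(st.name)

    n_cells = sum(st.n_cells for st in states)
    state_of_cell = np.repeat(labels, [st.n_cells for st in states])
    libsize = np.maximum(
        rng.lognormal(np.log(libsize_median), libsize_sigma, size=n_cells).astype(int),
        1100,
    )

    fail = np.array(["ok"] * n_cells, dtype=object)
    n_low = int(round(frac_low_depth * n_cells))
    n_hm = int(round(frac_high_mito * n_cells))
    planted = rng.choice(n_cells, size=n_low + n_hm, replace=False) if n_low + n_hm else []
    low_idx = np.asarray(planted[:n_low], dtype=int)
    hm_idx = np.asarray(planted[n_low : n_low + n_hm], dtype=int)
    libsize[low_idx] = rng.integers(200, 1024, size=n_low)
    fail[low_idx] = "low_depth"
    fail[hm_idx] = "high_mito"

    rows = []
    prof_by_state = dict(zip(labels, profiles))
    for i in range(n_cells):
        p = prof_by_state[state_of_cell[i]]
        if i in set(hm_idx):
            p = p.copy()
            p[:n_mito] = high_mito_frac * p[:n_mito] / p[:n_mito].sum()
            p[n_mito:] = (1 - high_mito_frac) * p[n_mito:] / p[n_mito:].sum()
        rows.append(rng.multinomial(libsize[i], p))
    values = sp.csr_matrix(np.vstack(rows))

    barcodes = [f"cell_{i:05d}" for i in range(n_cells)]
    obs = pd.DataFrame(
        {"state": state_of_cell, "qc_fail": fail}, index=pd.Index(barcodes, name="barcode")
    )
    em = ExpressionMatrix(values=values, obs=obs, gene_ids=pd.Index(gene_ids), kind="counts")
    truth = SyntheticTruth(
        seed=seed,
        state_of_cell=state_of_cell,
        qc_fail=pd.Series(fail, index=barcodes),
    )
    return em, truth


# ---------------------------------------------------------------------------
# spatial
# ---------------------------------------------------------------------------


def make_topics(
    K: int,
    n_genes: int,
    seed: int = 0,
    n_markers: int = 40,
    marker_mass: float = 0.6,
    n_shared: int = 0,
    shared_mass: float = 0.0,
    shared_background: bool = False,
) -> np.ndarray:
    """Well-separated topic gene distributions.

    Each topic concentrates ``marker_mass`` on its own exclusive marker block
    over a random background.  Optionally, ``n_shared`` genes (the last block)
    carry ``shared_mass`` with probabilities identical across topics, giving a
    gene set whose expression is independent of the topic mixture — useful for
    negative-control colocalization checks.  With ``shared_background`` the
    background profile is one draw common to all topics (topics then differ
    only in their marker blocks), making non-marker genes exchangeable across
    topics.
    """
    if K * n_markers + n_shared > n_genes:
        raise ValueError("too many marker/shared genes for n_genes")
    if not 0 <= shared_mass < 1 or marker_mass + shared_mass >= 1:
        raise ValueError("masses must satisfy 0 <= shared, marker+shared < 1")
    rng = rng_from(seed)
    bg_mass = 1.0 - marker_mass - shared_mass
    if shared_background:
        bg = rng.dirichlet(np.ones(n_genes))
        theta = np.tile(bg, (K, 1)) * bg_mass
    else:
        theta = rng.dirichlet(np.ones(n_genes), size=K) * bg_mass
    for k in range(K):
        block = slice(k * n_markers, (k + 1) * n_markers)
        theta[k, block] += marker_mass / n_markers
    if n_shared:
        theta[:, -n_shared:] = 0.0
        theta = theta * ((1.0 - shared_mass) / theta.sum(axis=1, keepdims=True))
        theta[:, -n_shared:] = shared_mass / n_shared
    return theta / theta.sum(axis=1, keepdims=True)


def generate_spatial(
    theta_true: np.ndarray,
    n_spots: int = 2000,
    depth: int | np.ndarray = 2000,
    alpha: np.ndarray | float = 0.5,
    seed: int = 0,
    gene_ids: list[str] | None = None,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Dirichlet-multinomial spatial spots on a hexagonal array.

    Per spot, mixing proportions omega ~ Dirichlet(alpha) and counts ~
    Multinomial(depth, omega @ theta).  Spot totals equal the requested depth
    exactly; coordinates are an axial hex grid stored in array row/col
    convention.
    """
    theta_true = np.asarray(theta_true, dtype=float)
    if not np.allclose(theta_true.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("theta_true rows must sum to 1")
    K, G = theta_true.shape
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), (K,))
    if (alpha <= 0).any():
        raise ValueError("Dirichlet concentration must be positive")
    depths = np.broadcast_to(np.asarray(depth, dtype=int), (n_spots,))
    if (depths <= 0).any():
        raise ValueError("depth must be positive")

    rng = rng_from(seed)
    omega = rng.dirichlet(alpha, size=n_spots)
    omega = omega / omega.sum(axis=1, keepdims=True)
    mix = omega @ theta_true
    counts = np.vstack([rng.multinomial(depths[i], mix[i]) for i in range(n_spots)])

    q, r = hex_grid(n_spots)
    row, col = axial_to_offset(q, r)
    barcodes = [f"spot_{i:05d}" for i in range(n_spots)]
    obs = pd.DataFrame(
        {"array_row": row, "array_col": col, "sample": "sim"},
        index=pd.Index(barcodes, name="barcode"),
    )
    gene_ids = gene_ids if gene_ids is not None else make_gene_ids(G)
    em = ExpressionMatrix(
        values=sp.csr_matrix(counts), obs=obs, gene_ids=pd.Index(gene_ids), kind="counts"
    )
    truth = SyntheticTruth(seed=seed, omega_true=omega, theta_true=theta_true)
    return em, truth


# ---------------------------------------------------------------------------
# ATAC
# ---------------------------------------------------------------------------


def make_motif_match(
    n_motifs: int,
    n_peaks: int,
    peaks_per_motif: int = 100,
    seed: int = 0,
) -> MotifMatch:
    """Random binary motif x peak match matrix; motif m maps to TF gene 'TF{m}'."""
    rng = rng_from(seed)
    match = np.zeros((n_motifs, n_peaks), dtype=np.int8)
    for m in range(n_motifs):
        idx = rng.choice(n_peaks, size=min(peaks_per_motif, n_peaks), replace=False)
        match[m, idx] = 1
    names = [f"motif_{m}" for m in range(n_motifs)]
    return MotifMatch(
        match=sp.csr_matrix(match),
        motif_names=names,
        motif_to_tf={f"motif_{m}": [f"TF{m}"] for m in range(n_motifs)},
    )


def generate_atac(
    n_peaks: int,
    n_cells: int,
    motif_match: MotifMatch,
    motif_activity: np.ndarray,
    gc: np.ndarray | None = None,
    seed: int = 0,
    state_of_cell: np.ndarray | None = None,
    base_rate: float = 0.05,
    intercept_sd: float = 0.5,
    depth_sd: float = 0.5,
    gc_coef: float = 1.0,
) -> tuple[PeakMatrix, SyntheticTruth]:
    """Bernoulli peak accessibility with motif-driven state effects.

    logit P(accessible) = peak intercept + cell depth offset + GC term +
    sum over motifs matching the peak of the motif's activity in the cell's
    state.  ``motif_activity`` is motifs x states; cells are assigned states
    evenly unless ``state_of_cell`` (integer state indices) is given.
    """
    motif_activity = np.atleast_2d(np.asarray(motif_activity, dtype=float))
    n_motifs, n_states = motif_activity.shape
    if n_motifs != len(motif_match.motif_names):
        raise ValueError("motif_activity rows must match motifs")
    rng = rng_from(seed)
    if gc is None:
        gc = rng.beta(5, 5, size=n_peaks)
    gc = np.asarray(gc, dtype=float)
    if ((gc < 0) | (gc > 1)).any():
        raise ValueError("gc must lie in [0, 1]")
    if state_of_cell is None:
        state_of_cell = np.arange(n_cells) % n_states
    state_of_cell = np.asarray(state_of_cell, dtype=int)

    match = np.asarray(
        motif_match.match.todense()
        if sp.issparse(motif_match.match)
        else motif_match.match,
        dtype=float,
    )
    intercept = np.log(base_rate / (1 - base_rate)) + rng.normal(0, intercept_sd, n_peaks)
    depth_off = rng.normal(0, depth_sd, n_cells)
    state_effect_per_peak = match.T @ motif_activity  # peaks x states
    logit = (
        intercept[:, None]
        + depth_off[None, :]
        + gc_coef * (gc - gc.mean())[:, None]
        + state_effect_per_peak[:, state_of_cell]
    )
    p = 1.0 / (1.0 + np.exp(-logit))
    X = (rng.random((n_peaks, n_cells)) < p).astype(np.int8)
    # guarantee the no-all-zero-cell invariant of PeakMatrix
    empty = np.where(X.sum(axis=0) == 0)[0]
    for c in empty:
        X[rng.integers(0, n_peaks), c] = 1

    coords = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n_peaks) * 1000,
            "end": np.arange(n_peaks) * 1000 + 500,
        }
    )
    pm = PeakMatrix(binary=sp.csr_matrix(X), peak_coords=coords, gc=gc)
    truth = SyntheticTruth(
        seed=seed, motif_activity=motif_activity, state_of_cell=state_of_cell
    )
    return pm, truth
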