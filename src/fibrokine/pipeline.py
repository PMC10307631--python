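"""Pipeline stages: the bodies behind the CLI subcommands and analysis drivers.

Each stage reads the artifacts of earlier stages from the configured working
directory, runs the corresponding library operations, writes delimited-text
outputs, and appends a machine-readable entry to ``run_log.json``.  One
global seed fans out to per-stage child seeds (recorded in the log) so every
stage is independently reproducible.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import bulk as bulkmod
from . import coloc as colocmod
from . import io as iomod
from . import motifs as motifmod
from . import scoring as scoremod
from . import simulate as simmod
from . import topics as topicmod
from ._utils import child_seeds, file_checksum
from .config import RunConfig

STAGE_NAMES = [
    "simulate",
    "derive-signatures",
    "score",
    "sc-de",
    "gsea",
    "motifs",
    "topics",
    "colocalize",
]


def _stage_seed(cfg: RunConfig, stage: str) -> int:
    return child_seeds(cfg.seed, len(STAGE_NAMES))[STAGE_NAMES.index(stage)]


def _log(cfg: RunConfig, stage: str, outputs: list[Path], seed: int) -> None:
    wd = Path(cfg.workdir)
    log_path = wd / "run_log.json"
    log = json.loads(log_path.read_text()) if log_path.exists() else {}
    log[stage] = {
        "seed": seed,
        "config_hash": cfg.hash,
        "outputs": {str(p.relative_to(wd)): file_checksum(p) for p in outputs if p.is_file()},
    }
    log_path.write_text(json.dumps(log, indent=1, sort_keys=True))


def _programs(cfg: RunConfig) -> list[simmod.CytokineProgram]:
    s = cfg.simulate
    n = s.n_program_genes
    return [
        simmod.CytokineProgram(
            "TNF", up_genes=list(range(0, n)), down_genes=list(range(n, 2 * n)),
            log2fc_up=s.log2fc, log2fc_down=s.log2fc,
        ),
        simmod.CytokineProgram(
            "IL1B", up_genes=list(range(2 * n, 3 * n)), down_genes=list(range(3 * n, 4 * n)),
            log2fc_up=s.log2fc, log2fc_down=s.log2fc,
        ),
    ]


def stage_simulate(cfg: RunConfig) -> list[Path]:
    """Generate the full synthetic cohort: bulk, single-cell, spatial, ATAC."""
    wd = Path(cfg.workdir)
    (wd / "data").mkdir(parents=True, exist_ok=True)
    seed = _stage_seed(cfg, "simulate")
    s_bulk, s_sc, s_sp, s_atac = child_seeds(seed, 4)
    s = cfg.simulate
    outputs = []

    programs = _programs(cfg)
    bulk, _ = simmod.generate_bulk(
        programs,
        n_replicates=s.n_replicates,
        n_genes=s.n_genes_bulk,
        dispersion=s.dispersion,
        seed=s_bulk,
        combinations=[
            ("TNF_DLL4", ["TNF"], s.dll4_scale),
            ("IL1B_DLL4", ["IL1B"], s.dll4_scale),
        ],
    )
    bulk.counts.rename_axis("gene").to_csv(wd / "data" / "bulk_counts.tsv", sep="\t")
    pd.DataFrame(
        {"sample": bulk.counts.columns, "condition": bulk.condition.values,
         "replicate": bulk.replicate.values}
    ).to_csv(wd / "data" / "bulk_design.tsv", sep="\t", index=False)
    outputs += [wd / "data" / "bulk_counts.tsv", wd / "data" / "bulk_design.tsv"]

    # the activated state expresses the IL1B response program: its planted
    # up-genes carry the same names (G-ids) as the bulk IL1B up block, so the
    # bulk-derived signature scores high on activated cells by construction
    n = s.n_program_genes
    n_mito = 20
    il1b_like = simmod.CytokineProgram(
        "IL1B_program", up_genes=list(range(n_mito + 2 * n, n_mito + 3 * n)),
        down_genes=[], log2fc_up=2.0,
    )
    states = [
        simmod.StateSpec("resting", programs=[], n_cells=s.n_cells_per_state),
        simmod.StateSpec("activated", programs=[(il1b_like, 1.0)], n_cells=s.n_cells_per_state),
    ]
    sc, _ = simmod.generate_single_cell(
        states, n_genes=s.n_genes_sc, seed=s_sc, n_mito=n_mito,
        frac_low_depth=s.frac_low_depth, frac_high_mito=s.frac_high_mito,
    )
    iomod.write_mtx_bundle(sc, wd / "data" / "sc", seed=s_sc, config_hash=cfg.hash)
    outputs += list((wd / "data" / "sc").glob("*"))

    # align topic marker blocks with the signature gene blocks: topic 0 with
    # the TNF up block, topic 1 with the IL1B up block, topic 2 neutral
    theta = simmod.make_topics(s.n_topics, s.n_genes_sc, n_markers=n, seed=s_sp)
    dest = np.concatenate(
        [np.arange(2 * k * n, (2 * k + 1) * n) for k in range(s.n_topics)]
    )
    marker_src = np.arange(s.n_topics * n)
    col_map = np.full(s.n_genes_sc, -1)
    col_map[dest] = marker_src
    rest_dest = np.setdiff1d(np.arange(s.n_genes_sc), dest)
    col_map[rest_dest] = np.setdiff1d(np.arange(s.n_genes_sc), marker_src)
    theta = theta[:, col_map]  # new column j holds source column col_map[j]
    spatial, truth_sp = simmod.generate_spatial(
        theta, n_spots=s.n_spots, depth=s.spot_depth,
        alpha=s.dirichlet_alpha, seed=s_sp,
    )
    iomod.write_mtx_bundle(spatial, wd / "data" / "spatial", seed=s_sp, config_hash=cfg.hash)
    np.savetxt(wd / "data" / "spatial_theta_true.tsv", truth_sp.theta_true, delimiter="\t")
    outputs += list((wd / "data" / "spatial").glob("*"))
    outputs.append(wd / "data" / "spatial_theta_true.tsv")

    mm = simmod.make_motif_match(s.n_motifs, s.n_peaks, peaks_per_motif=s.peaks_per_motif,
                                 seed=s_atac)
    activity = np.zeros((s.n_motifs, 2))
    activity[0, 1] = s.motif_effect  # motif_0 active in state 1
    activity[1, 0] = s.motif_effect  # motif_1 active in state 0
    pm, _ = simmod.generate_atac(
        s.n_peaks, s.n_atac_cells, mm, activity, seed=s_atac,
    )
    iomod.write_peak_bundle(pm, mm, wd / "data" / "atac", seed=s_atac)
    pd.DataFrame({"cell": range(s.n_atac_cells),
                  "state": np.arange(s.n_atac_cells) % 2}).to_csv(
        wd / "data" / "atac_states.tsv", sep="\t", index=False)
    outputs += list((wd / "data" / "atac").glob("*"))
    outputs.append(wd / "data" / "atac_states.tsv")

    _log(cfg, "simulate", outputs, seed)
    return outputs


def _load_bulk(cfg: RunConfig) -> bulkmod.BulkCounts:
    wd = Path(cfg.workdir)
    counts = pd.read_csv(wd / "data" / "bulk_counts.tsv", sep="\t", index_col="gene")
    design = pd.read_csv(wd / "data" / "bulk_design.tsv", sep="\t").set_index("sample")
    return bulkmod.BulkCounts(
        counts=counts,
        condition=design["condition"],
        replicate=design["replicate"],
    )


def stage_derive_signatures(cfg: RunConfig) -> list[Path]:
    """Bulk NB-Wald DE per condition, signature files, DLL4 dampening summary."""
    wd = Path(cfg.workdir)
    (wd / "signatures").mkdir(parents=True, exist_ok=True)
    seed = _stage_seed(cfg, "derive-signatures")
    bulk = _load_bulk(cfg)
    outputs = []
    de_tables = {}
    for cond in bulk.conditions:
        if cond == bulk.control:
            continue
        de = bulkmod.nb_wald_de(bulk, cond, shrink_lfc=True)
        de_tables[cond] = de
        p = iomod.write_table(de.reset_index(drop=True), wd / "signatures" / f"de_{cond}.tsv",
                              seed=seed, config_hash=cfg.hash)
        outputs.append(p)
        if not cond.endswith("_DLL4"):
            sig = bulkmod.derive_signature(de, alpha=cfg.alpha_signature, name=f"{cond}_response")
            outputs.append(iomod.write_signature_file(sig, wd / "signatures" / f"{cond}_response.tsv"))

    shift_rows = []
    for cond in list(de_tables):
        dll4 = f"{cond}_DLL4"
        if dll4 in de_tables:
            sig = bulkmod.derive_signature(de_tables[cond], alpha=cfg.alpha_signature)
            shift = bulkmod.dll4_shift(de_tables[cond], de_tables[dll4], sig)
            shift["cytokine"] = cond
            shift_rows.append(shift.reset_index())
    if shift_rows:
        outputs.append(iomod.write_table(pd.concat(shift_rows, ignore_index=True),
                                         wd / "signatures" / "dll4_shift.tsv",
                                         seed=seed, config_hash=cfg.hash))
    _log(cfg, "derive-signatures", outputs, seed)
    return outputs


def _load_sc(cfg: RunConfig):
    wd = Path(cfg.workdir)
    em = iomod.read_mtx_bundle(wd / "data" / "sc")
    em, report = scoremod.qc_filter_cells(em, mito_max=cfg.mito_max, libsize_min=cfg.libsize_min)
    norm = scoremod.normalize_log(em, scale=1e5)
    return em, norm, report


def _load_signatures(cfg: RunConfig) -> list[bulkmod.GeneSignature]:
    wd = Path(cfg.workdir)
    out = []
    for p in sorted((wd / "signatures").glob("*_response.tsv")):
        out.append(iomod.read_signature_file(p))
    return out


def stage_score(cfg: RunConfig) -> list[Path]:
    """QC, normalise, and score cytokine-response signatures on single cells."""
    wd = Path(cfg.workdir)
    seed = _stage_seed(cfg, "score")
    em, norm, report = _load_sc(cfg)
    sigs = _load_signatures(cfg)
    # bulk signature gene ids refer to the bulk universe; map onto the sc
    # universe by name intersection (shared synthetic id space)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores = scoremod.score_signatures(
            norm, sigs, n_bins=cfg.score_n_bins, n_ctrl=cfg.score_n_ctrl, seed=seed
        )
    scores["state"] = em.obs["state"].to_numpy()
    outputs = [
        iomod.write_table(scores.rename_axis("barcode").reset_index(),
                          wd / "cell_scores.tsv", seed=seed, config_hash=cfg.hash),
        iomod.write_table(pd.DataFrame([report]), wd / "qc_report.tsv",
                          seed=seed, config_hash=cfg.hash),
    ]
    _log(cfg, "score", outputs, seed)
    return outputs


def stage_sc_de(cfg: RunConfig) -> list[Path]:
    """Hurdle DE between the two synthetic cell states."""
    wd = Path(cfg.workdir)
    seed = _stage_seed(cfg, "sc-de")
    _, norm, _ = _load_sc(cfg)
    de = scoremod.hurdle_de(norm, norm.obs["state"].to_numpy())
    out = iomod.write_table(de.reset_index(drop=True), wd / "sc_de.tsv",
                            seed=seed, config_hash=cfg.hash)
    _log(cfg, "sc-de", [out], seed)
    return [out]


def stage_gsea(cfg: RunConfig) -> list[Path]:
    """Preranked GSEA of the single-cell DE against the response signatures."""
    wd = Path(cfg.workdir)
    seed = _stage_seed(cfg, "gsea")
    de = iomod.read_table(wd / "sc_de.tsv").set_index("gene", drop=False)
    rank = scoremod.rank_statistic(de)
    gene_sets = {}
    for sig in _load_signatures(cfg):
        if sig.up:
            gene_sets[f"{sig.name}_up"] = sig.up
        if sig.down:
            gene_sets[f"{sig.name}_down"] = sig.down
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = scoremod.preranked_gsea(rank, gene_sets, n_perm=cfg.gsea_n_perm, seed=seed)
    res["significant"] = res["p_adj"] < cfg.gsea_fdr
    out = iomod.write_table(res.reset_index(drop=True), wd / "gsea.tsv",
                            seed=seed, config_hash=cfg.hash)
    _log(cfg, "gsea", [out], seed)
    return [out]


def stage_motifs(cfg: RunConfig) -> list[Path]:
    """chromVAR-style deviations, expression gate, per-state motif ranking."""
    wd = Path(cfg.workdir)
    seed = _stage_seed(cfg, "motifs")
    pm, mm = iomod.read_peak_bundle(wd / "data" / "atac")
    states = pd.read_csv(wd / "data" / "atac_states.tsv", sep="\t")["state"].to_numpy()
    bg = motifmod.sample_backgrounds(pm, n_background=cfg.n_background, seed=seed)
    dev = motifmod.compute_deviations(pm, mm, bg, seed=seed)
    # paired RNA: TF genes expressed everywhere in the synthetic cohort, so the
    # gate is exercised with a simple planted detection matrix
    tf_genes = sorted({t for tfs in mm.motif_to_tf.values() for t in tfs})
    rng = np.random.default_rng(seed)
    tf_counts = rng.poisson(2.0, size=(pm.n_cells, len(tf_genes)))
    expr = scoremod.ExpressionMatrix(
        values=tf_counts, obs=pd.DataFrame(index=range(pm.n_cells)),
        gene_ids=pd.Index(tf_genes), kind="counts",
    )
    gate = motifmod.expression_gate(dev, mm, expr, states, min_frac=cfg.tf_gate_min_frac)
    ranked = motifmod.rank_motifs(dev, states, gate, n_top=cfg.n_top_motifs)
    outputs = [
        iomod.write_table(ranked, wd / "motif_ranking.tsv", seed=seed, config_hash=cfg.hash),
        iomod.write_table(dev.z.rename_axis("motif").reset_index(), wd / "motif_z.tsv",
                          seed=seed, config_hash=cfg.hash),
    ]
    _log(cfg, "motifs", outputs, seed)
    return outputs


def stage_topics(cfg: RunConfig) -> list[Path]:
    """Filter spot genes, select K, fit the topic model, extract markers."""
    wd = Path(cfg.workdir)
    seed = _stage_seed(cfg, "topics")
    em = iomod.read_mtx_bundle(wd / "data" / "spatial")
    filtered, report = topicmod.filter_spot_genes(
        em, min_spots=cfg.spot_min_spots, max_frac=cfg.spot_max_frac
    )
    k_star, table = topicmod.select_K(
        filtered.dense(), cfg.k_range, seed=seed, n_iter=cfg.lda_select_n_iter
    )
    tm = topicmod.fit_topic_model(filtered, K=k_star, seed=seed, n_iter=cfg.lda_n_iter)
    markers = topicmod.extract_top_genes(tm, n_top=cfg.n_top_topic_genes)
    omega = pd.DataFrame(tm.omega, index=filtered.obs.index,
                         columns=[f"topic_{k}" for k in range(tm.K)])
    theta = pd.DataFrame(tm.theta, columns=list(filtered.gene_ids),
                         index=[f"topic_{k}" for k in range(tm.K)])
    mk = pd.concat(
        [df.assign(topic=k) for k, df in markers.per_topic.items()], ignore_index=True
    )
    outputs = [
        iomod.write_table(table.reset_index(drop=True), wd / "topic_selection.tsv",
                          seed=seed, config_hash=cfg.hash),
        iomod.write_table(omega.rename_axis("barcode").reset_index(), wd / "topic_omega.tsv",
                          seed=seed, config_hash=cfg.hash),
        iomod.write_table(theta.rename_axis("topic").reset_index(), wd / "topic_theta.tsv",
                          seed=seed, config_hash=cfg.hash),
        iomod.write_table(mk, wd / "topic_markers.tsv", seed=seed, config_hash=cfg.hash),
        iomod.write_table(pd.DataFrame([report]), wd / "topic_gene_filter.tsv",
                          seed=seed, config_hash=cfg.hash),
    ]
    _log(cfg, "topics", outputs, seed)
    return outputs


def stage_colocalize(cfg: RunConfig) -> list[Path]:
    """Score signatures on spots, correlate with topics, neighbourhood contrast."""
    wd = Path(cfg.workdir)
    seed = _stage_seed(cfg, "colocalize")
    em = iomod.read_mtx_bundle(wd / "data" / "spatial")
    norm = scoremod.normalize_log(em, scale="median")
    sigs = _load_signatures(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores = scoremod.score_signatures(
            norm, sigs, n_bins=cfg.score_n_bins, n_ctrl=cfg.score_n_ctrl, seed=seed
        )
    omega = iomod.read_table(wd / "topic_omega.tsv").set_index("barcode")
    combined = scores.join(omega)
    ss = colocmod.SpotScores(
        scores=combined,
        coords=em.obs[["array_row", "array_col"]],
        sample=em.obs["sample"] if "sample" in em.obs else None,
    )
    corr = colocmod.correlate_spotwise(ss)
    anchor = scores.columns[0]
    response = scores.columns[-1] if len(scores.columns) > 1 else scores.columns[0]
    contrast = colocmod.neighborhood_contrast(ss, anchor, response, seed=seed)
    outputs = [
        iomod.write_table(corr.rename_axis("feature").reset_index(), wd / "spot_correlation.tsv",
                          seed=seed, config_hash=cfg.hash),
        iomod.write_table(pd.DataFrame([{
            "anchor": anchor, "response": response, **contrast["group_means"],
            "p": contrast["p"], "monotone": contrast["monotone"],
        }]), wd / "neighborhood_contrast.tsv", seed=seed, config_hash=cfg.hash),
    ]
    _log(cfg, "colocalize", outputs, seed)
    return outputs


STAGES = {
    "simulate": stage_simulate,
    "derive-signatures": stage_derive_signatures,
    "score": stage_score,
    "sc-de": stage_sc_de,
    "gsea": stage_gsea,
    "motifs": stage_motifs,
    "topics": stage_topics,
    "colocalize": stage_colocalize,
}


def run_all(cfg: RunConfig) -> list[Path]:
    outputs = []
    for name in STAGE_NAMES:
        outputs += STAGES[name](cfg)
    return outputs
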