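"""QC, score signatures on single cells, hurdle DE, and pathway enrichment.

Cells failing the mitochondrial (>20%) or library-size (<1,024) filters are
removed; the cytokine-response signatures from the bulk arm are scored per
cell with bin-matched controls; the two planted states are compared with the
hurdle model; and the derived signatures are tested for enrichment in the
state contrast by preranked GSEA.
"""

import argparse

import fibrokine.io as fio
from fibrokine.config import RunConfig
from fibrokine.pipeline import stage_gsea, stage_sc_de, stage_score


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--workdir", default="results/pipeline")
    args = ap.parse_args()

    cfg = RunConfig(seed=args.seed, workdir=args.workdir)
    stage_score(cfg)
    stage_sc_de(cfg)
    stage_gsea(cfg)

    qc = fio.read_table(f"{cfg.workdir}/qc_report.tsv").iloc[0]
    print(
        f"QC: kept {qc['n_kept']}/{qc['n_input']} cells "
        f"({qc['n_removed_mito']} high-mito, {qc['n_removed_libsize']} low-depth)"
    )
    scores = fio.read_table(f"{cfg.workdir}/cell_scores.tsv")
    for col in scores.columns:
        if col.endswith("_response"):
            by_state = scores.groupby("state")[col].mean()
            print(f"{col}: mean score per state -> {by_state.round(2).to_dict()}")
    de = fio.read_table(f"{cfg.workdir}/sc_de.tsv")
    print(f"hurdle DE: {(de['p_bonf'] < 0.05).sum()} genes at Bonferroni 0.05")
    gsea = fio.read_table(f"{cfg.workdir}/gsea.tsv")
    print(gsea[["pathway", "nes", "p_adj", "significant"]].to_string(index=False))


if __name__ == "__main__":
    main()
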