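"""Generate the synthetic study cohort.

Produces all four input kinds with planted ground truth under
results/pipeline/data/: bulk stimulation counts (control, TNF, IL1B, and the
two DLL4 co-stimulation conditions with halved effects), a two-state
single-cell matrix with planted QC failures, 3-topic spatial spots on a hex
array, and a binarised peak x cell accessibility matrix with two
state-specific motifs.
"""

import argparse

import pandas as pd

from fibrokine.config import RunConfig
from fibrokine.pipeline import stage_simulate


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--workdir", default="results/pipeline")
    args = ap.parse_args()

    cfg = RunConfig(seed=args.seed, workdir=args.workdir)
    outputs = stage_simulate(cfg)
    print(f"wrote {len(outputs)} data artifacts under {cfg.workdir}/data")

    design = pd.read_csv(f"{cfg.workdir}/data/bulk_design.tsv", sep="\t")
    print("bulk conditions:", ", ".join(design["condition"].unique()))
    counts = pd.read_csv(f"{cfg.workdir}/data/bulk_counts.tsv", sep="\t", index_col=0)
    print(f"bulk matrix: {counts.shape[0]} genes x {counts.shape[1]} samples")


if __name__ == "__main__":
    main()
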