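"""Derive cytokine-response signatures and quantify DLL4 dampening.

Per stimulation condition, a negative-binomial Wald test against control
defines the up/down signature at adjusted p < 0.05.  For each cytokine with a
DLL4 co-stimulation arm, the paired shift of per-gene log2 fold changes
measures how much Notch engagement blunts the response (planted attenuation:
a factor of one half).
"""

import argparse

import fibrokine.io as fio
from fibrokine.config import RunConfig
from fibrokine.pipeline import stage_derive_signatures


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--workdir", default="results/pipeline")
    args = ap.parse_args()

    cfg = RunConfig(seed=args.seed, workdir=args.workdir)
    stage_derive_signatures(cfg)

    for cond in ("TNF", "IL1B"):
        sig = fio.read_signature_file(f"{cfg.workdir}/signatures/{cond}_response.tsv")
        print(f"{cond}: {len(sig.up)} up / {len(sig.down)} down signature genes")
    shift = fio.read_table(f"{cfg.workdir}/signatures/dll4_shift.tsv")
    for _, row in shift.iterrows():
        print(
            f"DLL4 dampening [{row['cytokine']} {row['direction']}]: "
            f"median |lfc| ratio {row['median_abs_ratio']:.2f}, "
            f"Wilcoxon p {row['wilcoxon_p']:.2e}, dampened={row['dampened']}"
        )


if __name__ == "__main__":
    main()
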