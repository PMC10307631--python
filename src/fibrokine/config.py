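"""Run configuration: thresholds, seeds, masks, simulation sizes.

All analysis thresholds used across the pipeline live here with their
documented defaults: adjusted p < 0.05 for signature membership, Bonferroni
0.05 for single-cell DE, BH < 0.25 for GSEA, mitochondrial fraction 0.20 and
library-size floor 1,024 for QC, detection > 20% for the TF expression gate,
and the >= 10-spot / <= 95%-of-spots gene filter for topic modelling.
Configurations round-trip through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from ._utils import config_hash


@dataclass
class SimulateConfig:
    """Sizes and effects of the bundled synthetic cohort (smoke-test scale)."""

    n_genes_bulk: int = 600
    n_program_genes: int = 30
    log2fc: float = 2.0
    n_replicates: int = 3
    dispersion: float = 0.05
    dll4_scale: float = 0.5

    n_genes_sc: int = 600
    n_cells_per_state: int = 150
    frac_low_depth: float = 0.05
    frac_high_mito: float = 0.03

    n_topics: int = 3
    n_spots: int = 400
    spot_depth: int = 600
    dirichlet_alpha: float = 0.5

    n_peaks: int = 300
    n_atac_cells: int = 120
    n_motifs: int = 8
    peaks_per_motif: int = 40
    motif_effect: float = 1.5


@dataclass
class RunConfig:
    seed: int = 0
    alpha_signature: float = 0.05
    sc_de_alpha: float = 0.05
    gsea_fdr: float = 0.25
    gsea_n_perm: int = 2000
    mito_max: float = 0.20
    libsize_min: int = 1024
    tf_gate_min_frac: float = 0.20
    spot_min_spots: int = 10
    spot_max_frac: float = 0.95
    score_n_bins: int = 25
    score_n_ctrl: int = 50
    n_background: int = 50
    n_top_motifs: int = 6
    n_top_topic_genes: int = 30
    lda_n_iter: int = 400
    lda_select_n_iter: int = 150
    k_range: list = field(default_factory=lambda: [2, 3, 4])
    linkage_threshold: float = 0.7
    masked_genes: list = field(default_factory=list)
    workdir: str = "results/pipeline"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)

    def __post_init__(self):
        if isinstance(self.simulate, dict):
            self.simulate = SimulateConfig(**self.simulate)
        checks = [
            (0 < self.alpha_signature <= 1, "alpha_signature in (0, 1]"),
            (0 < self.sc_de_alpha <= 1, "sc_de_alpha in (0, 1]"),
            (0 < self.gsea_fdr <= 1, "gsea_fdr in (0, 1]"),
            (0 < self.mito_max <= 1, "mito_max in (0, 1]"),
            (self.libsize_min >= 0, "libsize_min >= 0"),
            (0 <= self.tf_gate_min_frac < 1, "tf_gate_min_frac in [0, 1)"),
            (self.spot_min_spots >= 0, "spot_min_spots >= 0"),
            (0 < self.spot_max_frac <= 1, "spot_max_frac in (0, 1]"),
            (all(2 <= k <= 20 for k in self.k_range), "k_range within [2, 20]"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: {msg}")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    @property
    def hash(self) -> str:
        """Hash of the scientific parameters only (paths excluded), so the
        same analysis in a different directory yields identical artifacts."""
        d = asdict(self)
        d.pop("workdir", None)
        return config_hash(d)
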