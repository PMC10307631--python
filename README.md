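# fibrokine

Attributing fibroblast activation states to cytokine exposures.

Fibroblast-like synoviocytes (FLS) in the inflamed joint adopt distinct
activation states — activated and resting flavours of the synovial lining and
sublining. `fibrokine` implements, as one tested pipeline, the computational
chain that connects those states to the inflammatory signals that plausibly
produce them:

1. **Cytokine-response signatures from bulk stimulation RNA-seq** — a
   negative-binomial Wald test per stimulation condition (TNF, IFN-γ, IL-1β,
   alone or with the Notch ligand DLL4) against unstimulated control defines
   directed up/down gene signatures at adjusted *p* < 0.05, and a paired-shift
   summary quantifies the *dampening* of cytokine responses under DLL4
   co-stimulation.
2. **Signature scoring on single cells and spatial spots** — library-size
   normalisation to a fixed target, gene-wise z-scoring, and per-signature
   scores against expression-bin-matched control genes, z-scored again across
   observations.
3. **Single-cell differential expression and enrichment** — a two-part hurdle
   model (logistic detection + Gaussian positive expression) with the
   detection-rate covariate `cngeneson`, Bonferroni correction, and preranked
   GSEA on −log(*p*) × log-fold-change ranks with a permutation null.
4. **TF-motif accessibility deviations** — the chromVAR model: per cell and
   motif, observed accessibility minus a depth-proportional expectation,
   z-scored against GC/accessibility-matched background peak sets, gated on
   paired RNA expression of the TF (>20% detection per state) and ranked
   per state by one-vs-rest Wilcoxon score (top six reported).
5. **Spatial topic models** — grade-of-membership LDA on raw spot counts by
   collapsed Gibbs sampling; each spot is a mixture ω over topics, each topic
   a gene distribution θ; K chosen by maximum approximate log Bayes factor;
   per-topic markers by a Poisson Kullback–Leibler discrimination score.
6. **Colocalization** — Pearson correlation of signature scores and topic
   proportions across spots, plus a hexagonal neighbourhood contrast testing
   whether response signatures are suppressed in and around anchor-high
   regions (the dampening halo).

Every input kind can be generated synthetically with planted ground truth
(`fibrokine.simulate`), so the whole chain is testable without any external
download.

## Worked example

The numbered drivers under `analysis/` run the pipeline on the bundled
synthetic cohort and write delimited-text tables under `results/pipeline/`:

```bash
python analysis/01_simulate_cohort.py --seed 0
python analysis/02_derive_signatures.py --seed 0
```

```
TNF: 29 up / 30 down signature genes
IL1B: 32 up / 32 down signature genes
DLL4 dampening [TNF up]: median |lfc| ratio 0.32, Wilcoxon p 3.73e-09, dampened=True
```

The planted TNF program has 30 up and 30 down genes at |log2fc| = 2; the
derived signature recovers essentially all of them. The DLL4 co-stimulation
conditions were simulated with every effect halved, and the paired-shift
summary reports significant shrinkage of |log2fc| in both directions (the
ratio is below the planted 0.5 because these are shrunken fold-change
estimates, which moderate the weaker DLL4 arm more strongly).

```bash
python analysis/03_score_states.py --seed 0
```

```
QC: kept 276.0/300.0 cells (9.0 high-mito, 15.0 low-depth)
IL1B_response: mean score per state -> {'activated': 0.96, 'resting': -0.96}
TNF_response: mean score per state -> {'activated': -0.1, 'resting': 0.1}
```

The synthetic activated state carries the IL1B program: its score separates
the states by ~2 z-units while the TNF signature stays flat. Continuing with
`04_motif_activity.py`, `05_spatial_topics.py` and `06_colocalization.py`:
the two planted state-specific motifs rank first in their states; the Bayes
factor selects the planted K = 3; and the spot-wise correlation matrix shows
each response signature colocalizing with exactly one topic (r ≈ 0.95) and
near-zero correlation elsewhere.

The same stages are exposed as a CLI
(`fibrokine all --seed 0 --workdir results/pipeline`, or per-stage
subcommands) with deterministic output checksums recorded in
`run_log.json`.

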