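# Methods

This note documents the statistical models implemented in `fibrokine`, the
choices made where the procedures admit more than one reasonable definition,
and what the synthetic-data generators do and do not emulate.

## Bulk differential expression and signatures

Counts for gene *g* in sample *j* are modelled as negative binomial with
mean μ_gj and dispersion α_g, Var = μ + αμ². The GLM uses a log link, design
`intercept + condition`, and per-sample offsets log s_j, where s_j are
median-of-ratios size factors (median over genes, restricted to genes with a
positive geometric mean across samples, of count/geometric-mean).

Dispersion estimation follows the standard shrinkage recipe for small
designs: (1) per-gene maximum likelihood in log α by vectorised
golden-section search, with the Cox–Reid adjustment −½ log det(XᵀWX) to
reduce small-sample bias; (2) a parametric trend α(μ) = a/μ + b fitted by
iteratively reweighted least squares with gamma-family weights and outlier
exclusion, falling back to the median dispersion when fewer than 20 usable
genes remain; (3) a second, MAP, pass with a log-normal prior centred on the
trend. The prior width is the MAD-based variance of log-dispersion residuals
minus the expected sampling variance trigamma((m−p)/2), floored at 0.25.

The Wald test uses the MLE condition coefficient and its Fisher-information
standard error; p-values are BH-adjusted within one family per
condition-vs-control contrast. Genes with mean normalised count below 1
(independent filtering) or a non-convergent fit are reported with missing
adjusted p and excluded from the family. Signatures take genes at adjusted
p < 0.05, split by the sign of the fold change.

An optional ridge estimator (zero-centred normal prior on the condition
coefficient, prior variance estimated as max(var(MLE lfc) − median SE², 0.05))
provides *shrunken* fold changes for effect-size displays and the DLL4
paired-shift summary; the test itself always uses the MLE. A consequence
worth knowing: the ridge moderates a weak-effect contrast more strongly than
a strong one, so shrunken-lfc attenuation ratios overstate dampening
slightly relative to the planted values (the unshrunken ratio recovers the
planted 0.5 to within simulation error; see `scripts/acceptance.py`).

Calibration at the 3-vs-3 design was verified by simulation: 5,000 null
genes give a raw p < 0.05 rate near 0.05 and Wald statistics within KS
distance 0.05 of N(0,1); planted |log2fc| = 2 at baseline 100 is recovered
with sensitivity ≥ 0.9 at an observed false-discovery proportion ≤ 0.1. An
independent NB-GLM implementation (pydeseq2) is used in the test suite as a
cross-check of size factors and fold changes, never as the implementation.

The DLL4 paired shift compares, per signature gene, the fold change under
cytokine alone with the fold change under cytokine + DLL4. Up- and
downregulated genes are summarised separately, with shrinkage reported
positive in both directions (median of |lfc_alone| − |lfc_DLL4|) and a
Wilcoxon signed-rank test on the paired |lfc|; "dampened" requires positive
median shrinkage at p < 0.05.

## QC, normalisation and signature scoring

Cells are removed when their mitochondrial fraction (genes with the reserved
`MT-` prefix) is strictly greater than 0.20 or their total molecule count is
strictly below 1,024 — the boundary cells (exactly 0.20, exactly 1,024) are
kept. Normalisation is ln(1 + S·c/total) with S = 100,000 for cells and the
median total for spatial spots.

Signature scores use bin-matched control genes: the normalised matrix is
z-scored per gene, genes are ranked into 25 equal-occupancy bins by mean
expression, and each signature gene is paired with up to 50 control genes
from its bin (n_bins = 25 and n_ctrl = 50 are the common defaults for this
family of scoring procedures). When a bin holds 50 or fewer genes the whole
bin serves as the control set; larger bins are sampled without replacement
with a recorded seed. This "exhaustive when small" rule is deliberate: it
makes the all-genes signature score exactly zero before the final transform
(each gene's control mean is its bin mean, and the gene-weighted mean of bin
means equals the grand mean), a useful identity for validation. Down-genes
enter with negative sign, so a directed signature distinguishes response
from dampening; the behaviour is reversible via the `directed` flag. The
final score column is z-scored across observations; a zero-variance column
returns zeros with a warning.

## Hurdle differential expression

Per gene, detection (expression > 0) follows a logistic regression and
positive log-expression a Gaussian regression, both on
`condition + cngeneson`, where cngeneson is the z-scored number of detected
genes per cell. The reported p combines the two likelihood-ratio components
as χ² with one degree of freedom per estimable component (two when both
parts carry the condition term; detection-saturated genes or genes with too
few expressing cells per group contribute one). Genes detected in fewer than
5 cells are skipped. Perfect separation in the logistic part triggers a
ridge-penalised refit (λ = 1) and a flag. Multiple testing is Bonferroni
over tested genes. Null calibration (random splits of a homogeneous
population, 200 vs 200 cells) yields zero Bonferroni hits in ≥ 95% of seeds
and p-values that are uniform to super-uniform.

## Preranked GSEA

Genes are ranked by −log(p) × log fold change; ties are broken by stable
gene-id order (recorded). The enrichment score is the extremum of the
weighted Kolmogorov–Smirnov running sum with weight |rank statistic|
(exponent 1); the running sum returns to zero at the end of the list. The
null permutes gene labels (equivalently, draws random sets of the same
size, shared across sets of equal size); NES divides ES by the mean |null
ES| of matching sign; the p-value is the matching-sign tail fraction with
+1 smoothing, so p ≥ 1/(n_perm + 1), and is BH-adjusted across gene sets.
Default 2,000 permutations with significance at BH < 0.25.

## HVGs and cluster-to-state merging

Highly variable genes use the normalised-dispersion recipe per batch
(variance/mean of the log data, z-scored within 20 mean-expression bins);
genes are ranked by the number of batches in which they reach that batch's
top-n, then by median normalised dispersion. Masked genes (mitochondrial,
ribosomal, MALAT1-like; supplied as a config list) never enter.

Clusters merge into states by average-linkage hierarchical grouping on
1 − r, where r is the Pearson correlation of cluster mean HVG expression,
cut at correlation 0.7 (exposed; merging by eye from a heatmap has no
canonical threshold). Note that correlations of mean profiles sit high
whenever states share a baseline: only programs that dominate the HVG
variance push cross-state correlation below the cut.

## Motif deviations

For motif *m* and cell *i*, the expected accessibility is
E_mi = T_m · d_i / D (motif total × cell share of the grand total), the raw
deviation (obs − E)/E, and the z-score normalises raw against the same
statistic on background peak sets: z = (raw − mean_b)/sd_b. Backgrounds
(default 50, the conventional count) are drawn with replacement from each
peak's nearest 2% quantile in the whitened 2-D space of z-scored GC and
z-scored log mean accessibility, with a rank-based fallback when the
covariate covariance degenerates and uniform draws when covariates are
constant. The exact conservation law holds for the unnormalised deviation:
Σ_i (obs_mi − E_mi) = 0 per motif; the ratio form weights cells by 1/E and
does not sum to zero, so conservation is asserted on obs − E. An additional
sequencing-depth bias term beyond the expected-fraction model is omitted:
background matching on mean accessibility covers the tested regime.

Motifs are admitted per state only when a mapped TF is detected in strictly
more than 20% of the state's cells; motifs whose TFs are absent from the
expression matrix are excluded everywhere (the conservative reading of the
filter). Ranking per state is one-vs-rest Wilcoxon on the z matrix with
tie-corrected normal approximation, BH within state, top six reported.

## Spatial topic model

Genes detected in fewer than 10 spots or more than 95% of spots are removed
(boundaries inclusive on the keep side). The model is standard LDA on raw
counts: ω_d ~ Dirichlet(α), token topics from ω_d, genes from θ_k. Fitting
is collapsed Gibbs sampling with symmetric priors α = 1/K and β = 0.1;
default 1,000 sweeps with the second half as burn-in and thinning 10, all
config-exposed. θ and ω are posterior means of the per-sample conditional
estimates; the per-sweep trace records the collapsed joint log-probability,
which rises in trend during burn-in (asserted as a 10-sweep moving average
that never drops by more than 1% of the trace range). The Gibbs kernel is
compiled with numba.

K is selected by an approximate log Bayes factor against the K = 1
multinomial null: 2·Δloglik − Δdf·ln(N_tokens) with df_K = K(G−1) + D(K−1),
a BIC-style penalty chosen because the reference Bayes factor is itself an
approximation; the approximation is isolated in `select_K` so alternatives
can be swapped. Ties go to the smallest K. On null (single-multinomial)
data all log BF values are negative and the smallest K wins; planted-K data
at adequate depth put the maximum at the true K.

Per-topic markers use the Poisson-KL score
min_{k'≠k} [θ_k'g − θ_kg + θ_kg ln(θ_kg/θ_k'g)] — discriminability of the
topic against its nearest competitor, with θ floored at 1e-12. The score is
nonnegative, zero iff the gene carries equal probability in some competing
topic, and degree-1 homogeneous in the θ pair.

All recovery comparisons match topics by Hungarian assignment on
Jensen–Shannon divergence (base 2) before comparing, to absorb label
switching. Multi-section datasets can be fitted individually or
concatenated with a retained section label.

## Colocalization

Signature scores and topic proportions are correlated across spots
(Pearson), combined across samples or per sample by flag; zero-variance
columns become missing with a warning. The neighbourhood contrast
partitions spots into anchor-high (top decile of the anchor score by
default), adjacent (hexagonal neighbours of anchor-high spots), and distal,
and tests the ordered trend with a Jonckheere–Terpstra statistic whose null
comes from Monte-Carlo label permutation (999 draws, seeded, two-sided).
Hex adjacency is the six neighbouring axial cells; coordinates are stored
in even-q offset ("array row/col") convention, and all neighbourhood logic
is invariant under lattice translations.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *first-order structure* each stage consumes:

- bulk: NB counts, constant dispersion per dataset (0.05 by default, a
  typical technical-replicate scale), log-normal baseline around 100
  counts, planted per-condition programs with |log2fc| = 2, triplicates,
  and scaled combination conditions (scale 0.5 emulates DLL4 dampening);
- single cell: multinomial sampling at log-normal library sizes (median
  5,000, σ = 0.4, matching the few-thousand-molecules regime of droplet
  data), multiplicative state programs, a reserved mitochondrial block at
  3% baseline share, and planted QC failures (low-depth cells below 1,024;
  high-mito cells at 35%);
- spatial: exact Dirichlet-multinomial spots on a hex lattice, with
  topic constructions exposing exclusive marker blocks, an optional
  topic-independent shared block, and an optional background common to all
  topics (the last two exist so that negative-control gene sets are
  *constructibly* independent of the mixture);
- ATAC: Bernoulli accessibility with peak intercepts, cell depth offsets,
  a GC covariate, and additive motif-by-state effects on the logit.

Not emulated: gene–gene correlation beyond program co-membership, doublets,
batch effects, ambient RNA, zero inflation beyond the sampling process,
spatial autocorrelation of the topic mixture, or realistic motif
co-occurrence. Passing tests therefore demonstrate correctness of the
procedures under their stated sampling assumptions, not robustness to every
artefact of real tissue data.

## Problem sizes

The validation suite and `scripts/acceptance.py` use sizes chosen to make
each property measurable with comfortable margin on a single CPU: 5,000
genes for DE calibration, 2,000 spots at depth 2,000 for topic recovery
(with 250 Gibbs sweeps; K selection over K = 2…6 uses 1,000 × 1,000 spots
at 120 sweeps), 20 seeds of 200-vs-200 cells for hurdle null calibration,
500 random sets for GSEA uniformity, and 50 peaks × 20 cells × 5 motifs for
the brute-force deviation oracle. The bundled pipeline configuration is
smaller still (hundreds of cells/spots) so the end-to-end run finishes in
well under a minute.

## Known limitations

- The NB trend fit assumes a monotone a/μ + b mean-dispersion relationship;
  datasets with non-monotone trends fall back poorly (the fallback is a
  flat median trend).
- The hurdle model's Gaussian part assumes homoscedastic positive
  log-expression; heavy-tailed positive components inflate the continuous
  LRT slightly.
- The Bayes-factor approximation penalises by total parameter count
  including all D(K−1) spot proportions, which is conservative for large
  D; it recovered planted K in all tested regimes but favours smaller K
  near the detection boundary.
- Background matching treats GC and mean accessibility as sufficient bias
  covariates; fragment-length or copy-number biases are out of scope.
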