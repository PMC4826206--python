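# fusemod

Multi-omics patient subtyping by similarity network fusion, with
network-module discovery of subtype-specific copy-number-altered genes.

`fusemod` implements, as a tested reusable pipeline, an integrative cancer
genomics analysis aimed at people studying molecular subtypes of a tumor
cohort (the motivating setting is high-grade serous ovarian cancer): it
fuses two expression views (mRNA and miRNA) into one patient similarity
network, clusters patients into survival-distinct subtypes, scores and
thresholds copy-number alterations within each subtype, and detects altered
network modules — with linker genes and two null models — on a curated
gene–gene interaction network.  A synthetic-data module generates cohorts
with planted ground truth so that every stage has a recovery test at desk
scale.

## The methods

**Similarity network fusion (SNF).**  For each omics view, patients i, j get
an affinity from a locally scaled exponential kernel,

    W(i,j) = exp( −ρ²(xᵢ,xⱼ) / (μ εᵢⱼ) ),
    εᵢⱼ = [ mean ρ(xᵢ,Nᵢ) + mean ρ(xⱼ,Nⱼ) + ρ(xᵢ,xⱼ) ] / 3,

with ρ the Euclidean distance and Nᵢ the k nearest neighbors of i.  Two
row-stochastic operators are derived per view — a full transition matrix P
(diagonal fixed at 1/2, off-diagonal mass normalized to 1/2) and a sparse
local operator S supported on each patient's k nearest neighbors — and the
views are fused by T rounds of cross-diffusion

    P⁽ᵛ⁾ ← S⁽ᵛ⁾ · ( Σ_{u≠v} P⁽ᵘ⁾ / (m−1) ) · S⁽ᵛ⁾ᵀ,

re-symmetrizing and re-normalizing after each round; the fused network is
the mean of the final per-view matrices.  Similarity supported in every view
is reinforced; view-specific noise decays.

**Subtype discovery.**  The fused matrix W is clustered through its
normalized Laplacian L = I − D^(−1/2) W D^(−1/2) (bottom-C eigenvectors,
row-normalized, k-means with 50 restarts — the standard relaxation of
min Trace(QᵀLQ) s.t. QᵀQ = I).  The number of subtypes C is chosen from a
candidate range as the partition with the smallest log-rank p-value on
overall survival.

**Alteration scoring.**  Gene-level GISTIC codes are binarized (only ±2,
homozygous deletion / high amplification, count).  Within a subtype, gene i
gets

    Cᵢ = Σⱼ xᵢⱼ / (Σ_g x_gⱼ),      pᵢ⁰ = Cᵢ / Σᵢ Cᵢ,

i.e. each alteration is weighted inversely by its sample's total alteration
load; genes with p⁰ ≥ 2×10⁻⁴ (inclusive) form the subtype's altered set.

**Module detection.**  On the interaction network, the subtype network keeps
altered–altered edges and admits *linker* genes: unaltered nodes adjacent to
≥ 2 altered genes whose neighborhoods are enriched for altered genes
(one-sided hypergeometric, Benjamini–Hochberg corrected).  The induced graph
is partitioned by greedy Newman-modularity agglomeration with deterministic
tie-breaking plus a local-move refinement.  Two null models judge the
result: 1000 degree-preserving rewirings give a modularity null and a
*scaled modularity* z-score (q_obs − mean)/sd; 1000 random draws of equally
many genes give a connectivity null for the largest component.

**Downstream statistics.**  Two-sample Wilcoxon rank-sum tests with a
fold-change filter (p < 0.01, FC > 1.2) define subtype-up-regulated miRNAs;
these are intersected with a strong-evidence miRNA→target table to nominate
candidate regulators (a curated RB1 table ships with the package); per-gene
copy-number–expression coupling is annotated by one-way ANOVA.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
cohort (60 patients, two planted subtypes, hazard ratio 3, planted 12-gene
modules on a 500-gene network):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_fuse_views.py
python analysis/03_cluster_subtypes.py
python analysis/04_score_alterations.py
python analysis/05_detect_modules.py
python analysis/06_differential_mirna.py
```

Output of the run at the default seed:

```
mRNA view alone: within/between affinity contrast 15919.96
miRNA view alone: within/between affinity contrast 23290.07
fused network:    within/between affinity contrast 487941663121.66
fusion sharpened the subtype block structure (20 iterations, last rel. change 8.1e-13)
model-selection scan (smaller log-rank p = stronger survival split):
 C  statistic  logrank_p
 2  19.928246   0.000008
 3  19.966730   0.000046
 4  21.317914   0.000090
 5  21.842522   0.000215
selected C = 2
agreement with planted subtypes: ARI = 1.000
subtype 1: 30 samples, 229 genes pass p0 >= 0.0002; planted-module genes retained 12/12
subtype 1: network 126 nodes (0 linkers), 26 modules, Q = 0.8079 vs null 0.7042 +/- 0.0137 -> scaled modularity 7.56
           largest component 65 (random-gene-set null p = 0.0010); best Jaccard vs planted module 0.75
9 / 200 miRNAs up-regulated in subtype 2 (p < 0.01, fold change > 1.2)
```

Reading the numbers: fusion multiplies the within-subtype over
between-subtype affinity contrast by orders of magnitude; the survival-
guided scan picks C = 2, which matches the planted labels exactly
(ARI = 1.0); the alteration filter keeps all 24 planted-module genes; the
detected modules overlap the planted ones (Jaccard 0.75) and the subtype
network is far more modular (z ≈ 7.6) and more connected (p ≈ 0.001) than
its degree-preserving and random-gene-set nulls.

The same stages are available as CLI subcommands
(`fusemod simulate|fuse|cluster|score|modules|downstream|run-all`) over the
plain TSV/SIF formats.

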