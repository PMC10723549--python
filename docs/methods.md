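# Methods

## Problem setting

A tumor–immune hybrid cell carries both a tumor lineage program and an
immune (here macrophage/monocyte) program inside **one** cell, and hence
one droplet library. An artifactual doublet — two cells captured together
— shows the same dual-lineage expression but is the *sum of two libraries*.
After depth normalization the two are nearly indistinguishable gene-wise;
the package's central claim is operational: genuine hybrid clusters are
(i) called by a dual module-score criterion and (ii) *not* consistently
elevated in simulation-based doublet scores, while true doublet clusters
are.

## Synthetic data model (`syndata`)

The generator emulates a primary uveal-melanoma biopsy at desk scale.

* **Populations** (defaults): tumor 1000, macrophage 400, T cell 150,
  stromal 150 cells; 1000 genes; one sample per run. The T-cell group is
  deliberately larger than the ligand–receptor module's 20-cell floor.
* **Programs**: every population has 50 marker genes whose baseline
  lognormal weight is multiplied by `marker_fold = 6` (log2 fold ≈ 2.6,
  typical of lineage markers). Canonical symbols are seeded into each
  program (MITF/MLANA/DCT/TYR/GP100/HTR2B/CD44… for tumor;
  CD45/CD14/CD163/APP… for macrophage) so marker-recovery and
  ligand–receptor tests can reference them.
* **Counts**: library size ~ lognormal(mean 5000, σ = 0.35); per-cell
  gamma perturbation of the program proportions with dispersion 0.3
  (negative-binomial-style overdispersion); multinomial draw of the
  library across genes. Fully reproducible from one integer seed.
* **Hybrids** (5% of singlets): mixing weight λ ~ U[0.3, 0.7], proportion
  vector λ·tumor + (1−λ)·macrophage at a **singlet** library size, plus a
  40-gene hybrid-specific program elevated 12-fold (TMSB10, CD74, GPX1,
  SEPP1, B2M, TYROBP, …). The extra program is essential, not cosmetic:
  real hybrid populations are transcriptionally distinct (dozens of
  strongly differential genes), and without it a hybrid is *by
  construction* the depth-normalized equal of a tumor+macrophage doublet —
  no expression-based method could, or should, separate them. It is also
  what the differential-expression recall and planted-axis tests recover.
* **Doublets** (rate 0.10): element-wise sums of two distinct randomly
  chosen singlet columns, parents recorded. No down-sampling — this
  matches the simulation used by the doublet scorers themselves and
  preserves the ~2× depth signature.

What the generator does **not** model: ambient RNA, batch effects, UMI
saturation, cell-cycle structure. Passing tests therefore demonstrate the
logic of the discrimination, not robustness to every real-data artifact.

The cyCIF generator draws per-cell marker intensities from per-population
lognormals (σ = 0.5 on the log scale) over the 11-marker panel
(CD45; MITF, TYR, MLANA, GP100, HTR2B; CD25, CD203c; TMSB10, CD74, GPX1),
with populations hybrid / tumor / leukocyte / basophil-like / treg-like.
In the peripheral-blood compartment hybrids carry elevated TMSB10/CD74/GPX1
(log-mean log 400 vs log 120 for circulating tumor cells); in tumor tissue
the two classes match (log 250), mirroring the tissue-vs-blood contrast the
quantification arm is meant to detect.

## Preprocessing choices

* **Normalization** is log1p counts-per-10k. A regularized-NB
  variance-stabilizing transform is deliberately not reimplemented: the
  hybrid logic consumes *relative lineage expression* and rank statistics,
  which are insensitive to the variance model. The scale factor is
  configurable.
* **HVG selection** is top-n by dispersion (var/mean of de-logged values);
  with ≤ 2000 genes all genes are used.
* **PC selection**: per-PC variance shares are renormalized over the
  computed PCs; the smallest prefix exceeding 95% cumulative share is
  restricted to PCs with individual share ≥ 5%. The two clauses conflict
  on most structured data (the prefix is long, the individual filter keeps
  only the top few PCs), so two guards apply: at least two PCs are always
  retained, and if no PC passes the individual filter the first
  min(10, max_pcs) PCs are used — consistent with the fixed 10-PC
  embedding of the doublet guard. On the synthetic defaults the rule
  retains 4 PCs, and the hybrid-specific program is strong enough to place
  the hybrid axis among them; with a weaker hybrid program the 5% filter
  silently discards exactly the dimension that separates hybrids from
  mixture doublets — a real failure mode users should know about.
* **Clustering**: Leiden (RB-configuration modularity, resolution 1.0,
  seeded) on the symmetrized unweighted Euclidean kNN graph (k = 20) in
  selected-PC space.

## Module scores and hybrid calling

The module score bins all genes into `nbin = 24` equal-size bins by
data-wide mean expression (ties broken by symbol for determinism), draws
`n_ctrl = 100` control genes per set gene uniformly without replacement
from the gene's bin (whole bin if smaller; draws independent across set
genes), and reports mean(set) − mean(pooled controls). Smaller samples may
need a smaller `nbin` (the error message suggests 12); scores are exactly
shift-invariant and zero for constant matrices.

Hybrid calling formalizes what is usually a manual read of per-cluster
score violins. Candidate h is hybrid iff tum_score(h) is stochastically
greater than that of *every* immune/stromal cluster and mac_score(h)
greater than that of *every* tumor cluster — one-sided Mann–Whitney,
BH-adjusted within each comparison family, all adjusted p ≤ α = 0.05.
Because the clusters were built from the same matrix the scores derive
from, rank tests between clusters of hundreds of cells reach significance
on trivial, noise-driven shifts (observed: a pure tumor cluster beating
all other tumor clusters on mac score at p ≤ 1e-9 with AUC ≈ 0.72). The
decision therefore also requires a material effect: **AUC ≥ 0.9 in every
comparison**, i.e. ≥ 90% of candidate-vs-comparison cell pairs ordered
correctly — the quantitative analogue of visibly disjoint violins. Both
tests and threshold are rank-based, so the decision is invariant to
monotone score transforms. Zero, one or several clusters may be called.

## Doublet guard

Artificial doublets are pair sums of observed libraries. For the pANN
variant their count is pN/(1−pN)·n_obs (artificial cells are pN = 25% of
the merged set); the other two scorers default to n_obs artificial cells.
All three operate on one joint log1p-CP10K + 10-PC embedding:

* **pANN** — artificial fraction among K = round(pK·n_merged) nearest
  neighbors, pK = 0.09;
* **kNN fraction** — artificial fraction f among k_sim = 50 neighbors,
  corrected for the simulation ratio r = n_art/n_obs:
  (f/r)/((f/r) + (1−f));
* **density ratio** — artificial vs observed density within the
  k_sim-th-neighbor radius, each normalized by population size; the query
  cell counts as observed so the ratio is always finite.

Cluster adjudication ranks cluster medians per method (percentile rank =
fraction of clusters with strictly smaller median, so ties share the lower
rank and identical clusters are never flagged); a cluster is a doublet
artifact when its rank exceeds 0.8 in ≥ 2 of 3 methods, and a hybrid call
on a flagged cluster is demoted with the reason recorded. The published
tools' expected-doublet count (`nExp`) is carried in the config for
compatibility but unused: the consensus is rank-based, matching the
"not consistently elevated" criterion rather than a hard count.

## Differential expression, panels, enrichment

DE is the two-sided Wilcoxon rank-sum on normalized expression with
Bonferroni adjustment (the convention of the standard single-cell toolkits;
exact enumeration for small tie-free groups via scipy) and Seurat-style
log2 fold change log2(mean(expm1)+1) ratios. Gene panels apply adjusted
p ≤ 0.05 and |lfc| ≥ 1.0 per sample, keep genes passing in ≥ 2 samples,
then narrow the crowded lists: top 10 by best adjusted p for
hybrid-vs-tumor up-regulated, and only lfc ≤ −2.0 for hybrid-vs-macrophage
down-regulated. Curated additions enter through an explicit include-list,
never silently. The pathway input list uses the looser |lfc| ≥ 0.58 tier.
Over-representation is the hypergeometric upper tail against user-supplied
GMT sets with BH across sets — a local, reproducible replacement for
web-service enrichment; the universe is the post-filter gene set of the
sample under test.

## Ligand–receptor inference

Cell types with < 20 cells are dropped; a pair×(sender, receiver) is
evaluated only when ligand and receptor are expressed in ≥ 10% of the
respective cells. The statistic is (mean ligand in sender + mean receptor
in receiver)/2; the null permutes cell-type labels 1,000 times (the same
permutations for every pair), p = #(permuted ≥ observed)/1000 without
smoothing, significance at p ≤ 0.05. Under a global null the measured
positive rate is ≈ 0.031–0.05 across ≥ 500 combinations (slightly
conservative because the planted lineage structure makes permuted means
heavy-tailed). Multi-subunit receptor complexes are out of scope; the
bundled pair table expresses the well-known axes as simple pairs.
Per-sample analysis with post-hoc intersection is the intended multi-sample
workflow.

## cyCIF quantification

Gating uses inclusive thresholds (≥) per marker; defaults are explicit
config values (200 across the default panel) and can be derived as a high
quantile of a negative-control table. Hybrid = CD45⁺ with ≥ 1 melanocyte
marker, except cells whose **only** melanocyte positivity is HTR2B and
which are CD25⁺ or CD203c⁺ — indistinguishable from basophil/Treg
populations, hence excluded. A stricter mode (`htr2b_only_exclusion=False`)
drops every CD25/CD203c-positive candidate. Tumor = melanocyte-positive
with CD45, CD25, CD203c all below threshold. Percent positive is
100·positive/total within a class and is an error (not zero) for an empty
class. Group comparisons use Welch's unequal-variance t-test with
Welch–Satterthwaite degrees of freedom, two-sided, significance read at
p ≤ 0.05.

## Numerical and engineering notes

* All stochastic steps (generator, control-gene draws, artificial
  doublets, permutations, Leiden) consume explicit integer seeds; equal
  config + seed gives bit-identical output.
* Mann–Whitney p-values switch to exact enumeration automatically for
  small tie-free groups (scipy); Bonferroni is used within DE tables, BH
  across comparison families and gene sets.
* Problem sizes in tests and the acceptance script (≈ 2,000 cells, 1,000
  genes, 5–10 seeds) were chosen so a full multi-seed evaluation completes
  in minutes on one CPU while keeping every population large enough for
  the rank tests to be meaningful.

## Known limitations

* The doublet scorers are contract-level implementations of the published
  family (pair-sum simulation → joint embedding → kNN statistic), not
  line-for-line ports; absolute score values differ from any specific tool
  even where ranks agree.
* Cluster-level calling cannot detect hybrids that co-cluster with their
  parent lineages; per-cell hybrid probabilities are out of scope.
* The AUC ≥ 0.9 floor trades recall for specificity: a genuine hybrid
  cluster heavily contaminated by doublets or parent cells may be missed.
* Real-data effects absent from the generator (ambient RNA, batch
  structure) can inflate both lineage scores and doublet scores; on real
  samples the guard's percentile ranks should be inspected, not only the
  binary flag.
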