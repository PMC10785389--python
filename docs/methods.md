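# Methods

This note documents the models, numerical choices and limitations of
`mdcapnet`, and what the synthetic benchmark does and does not show.

## Model overview and assumptions

The predictor is transductive: it scores every miRNA–disease pair in a
fixed universe from (a) how similar each miRNA is to miRNAs with known
causal links to a disease, and (b) how semantically close that disease is
to diseases the miRNA is known to cause. The driving assumption is
homophily — similar miRNAs associate causally with similar diseases. Both
the similarity networks and the label matrix are assumed incomplete, which
motivates the imputation stage.

## Similarity metrics

* **Levenshtein similarity** `1 − LD/(len1 + len2)` with the standard
  unit-cost (insert/delete/substitute) edit distance, computed by edlib.
  For equal-length strings `LD ≤ len`, so the score lies in [0.5, 1]; the
  0.5 floor is attained exactly by equal-length strings over disjoint
  alphabets. For very unequal lengths the score can drop below 0.5 — the
  [0.5, 1] range is a property of the equal-length subclass only. The cost
  scheme is fixed to the standard symmetric metric; asymmetric schemes
  would change the floor and are not supported.
* **Sequence fusion weights** 0.80/0.15/0.05 (precursor/mature/seed) ship
  as defaults; a seed sequence not supplied explicitly is derived as mature
  positions 2–8, the standard seed definition.
* **Binary profiles** are serialized in the fixed order of the feature
  vector, so the strings — and hence the similarity matrix — are
  reproducible run to run.
* **Expression normalization**: each cell-type column is divided by its
  total (removing per-column multiplicative factors) and log1p-transformed.
  All-zero columns carry no signal and are dropped with a warning.
* **Pathway features**: enrichment p-values become −log10(p) capped at 20
  (p = 10⁻²⁰ is well past any meaningful resolution); pathways with fewer
  than three miRNAs at p < 0.05 are discarded; missing pairs contribute 0.
* **GIP kernel** bandwidth follows the van Laarhoven convention
  γ = 1/mean‖IP‖² (scale factor 1). It is computed from the *training*
  association matrix only — computing it after imputation would leak the
  imputer's decisions into a "baseline" metric.

## Disease semantic similarity

Wang's measure with contribution factor Δ = 0.5 (configurable in (0, 1)).
T(D) is D plus its ancestor closure under parent→child edges; with
multiple parents a term's contribution is the maximum of Δ times any of
its children's contributions inside T(D), computed in one reverse
topological sweep. Diseases present in the association data but absent
from the DAG keep a diagonal 1 and off-diagonal 0 with a warning, rather
than being dropped along with their labels.

## Network imputation

Similarity matrices are binarized at per-metric thresholds ξ
(0.75/0.91/0.3/0.60/0.97/0.95, the published operating points; the
threshold test is inclusive, `sim ≥ ξ`). Each binary graph — and the
bipartite association graph over the joint miRNA+disease node set — is
embedded by biased second-order random walks (return parameter p, in-out
parameter q; p = q = 1 default, i.e. first-order walks) feeding a
skip-gram objective with negative sampling. The trainer is a compact
batched SGNS implementation in numpy; because graph vocabularies here are
tens to hundreds of nodes, each batch applies the *per-row mean* gradient
(a node recurring hundreds of times in a batch otherwise receives a summed
step that diverges). Negatives follow the corpus unigram distribution
raised to 3/4; the learning rate (default 0.25) decays linearly to 10%.

Link decision: a logistic classifier on Hadamard products of endpoint
embeddings, trained on observed edges versus an equal-sized seeded sample
of non-edges, scores every unobserved pair of the legal type
(miRNA–miRNA in similarity networks, miRNA–disease in the bipartite
network); candidates with probability ≥ π = 0.95 are added. Observed edges
are never removed, so imputation is monotone-additive. Networks with fewer
than 10 edges skip imputation (an untrainable classifier would add noise).
Held-out evaluation pairs can be passed as a holdout mask: they must not
be present as observed edges (this is checked and treated as leakage) and
are never imputed.

Walk defaults for standalone embedding are dimension 64, 20 walks per node
of length 40, window 5, 5 negatives, 5 epochs. The pipeline configuration
uses a lighter preset (dimension 32, 10 walks of length 20, 3 epochs):
the ~100-node graphs the pipeline builds carry far less structure than
the full parameter budget is sized for, and the planted-partition
recovery experiments show no ranking benefit from the larger setting at
this scale.

## Label propagation (IRLS)

Both spaces minimize
`Σ_ij W_ij ‖qⁱ − qʲ‖₂ + Tr((Q − Y)ᵀ U (Q − Y))` with U = μI (μ = 1
default, configurable per space). The graph term uses the *unsquared*
row-difference norm, which is exactly the form IRLS majorizes: at each
iteration the reweighted graph `G_ij = W_ij / (2·max(‖qⁱ − qʲ‖, ε))`
(ε = 10⁻⁸ smoothing floor) defines the linear system
`(2·L_G + U)·Q = U·Y`, solved in closed form; Q⁰ = Y. The objective is
non-increasing by the standard majorize–minimize argument and is asserted
so in tests on every run. Iteration stops when the relative Frobenius
change of Q falls below 10⁻⁶ or after 100 iterations; with μ > 0 the
system matrix is positive definite, so no singular solves arise. The
miRNA-space graph is the re-linked binary adjacency (imputed edges carry
weight 1 — the thresholds ξ were tuned in the binarized representation,
and mixing raw similarities with binary imputed edges would be
inconsistent); the disease-space graph is DS with its diagonal dropped.
Raw adjacencies are used by default; symmetric degree normalization is
available behind a config switch.

## Fusion and missing features

Per-metric score matrices combine with weights
0.15/0.1/0.05/0.25/0.2/0.25 (seq/expr/gip/pathway/gene/tf). A miRNA
lacking a feature block is excluded from that metric's similarity matrix;
in fusion its per-metric score contributes 0 and the remaining weights are
renormalized row-wise, so no similarity is ever fabricated for it. An
optional exhaustive simplex grid search (step 0.05 by default; ~53k points
for six metrics, so a coarser step is advisable there) re-optimizes the
weights against a validation split, with ties broken toward the
lexicographically smallest weight vector.

## Evaluation protocol

Known causal pairs are split into folds (or one 1/5 independent test
split) and removed from MD *before* similarity binarization and
imputation; a SHA-256 hash of the training matrix is recorded and the
absence of every test pair from it is asserted (and re-asserted against
imputed edges). Causal-vs-non-disease AUROC uses the rank (Mann–Whitney)
formula with half-credit ties; negatives default to *all* pairs with no
recorded association of any kind, with an optional fixed positive:negative
ratio (1:5 in the published comparison protocol) for subsampled runs.
Causal-vs-non-causal discrimination reuses the same score matrix without
any refit and adds a two-sided Wilcoxon rank-sum test (exact enumeration
when both groups have ≤ 8 tie-free values, tie-corrected normal
approximation otherwise). Cross-validation reports both the per-fold mean
AUROC and the pooled AUROC over all folds' scored pairs, since the two
conventions can differ.

## Synthetic benchmark

The generator plants the statistical structure the method assumes, not
biology. miRNAs belong to latent groups; each group has an ancestral
precursor (length 80) and mature (length 22) sequence that members mutate
at per-base rate (1 − signal)·0.3 (substitutions only, so lengths stay
equal and the 0.5 similarity floor applies inside fixtures), a 15-bit
block in a 100-bit binary regulator/target universe (group bits on with
probability `signal`, background bits at 0.02), and prototype expression
(137 dimensions, echoing the cell-type panel size of real expression
compendia) and pathway (60 dimensions) vectors with additive noise of
scale (1 − signal). Diseases live on a random tree whose top-level
subtrees map one-to-one onto the groups. Causal pairs are drawn at
probability 0.03 + 0.55·signal within matching blocks and 0.03 elsewhere
(the 3% background echoes the sparsity of real causality catalogs).
Non-causal pairs are within-block pairs that did not become causal,
relabeled at `noncausal_fraction` of the causal count.

What passing tests show — and what they do not: the pipeline recovers
*block-level* association structure from coherent multi-view features
(held-out AUROC ≥ 0.8 at signal 0.9 on 60×40 bundles; chance at signal 0;
monotone in between). Because non-causal pairs sit inside the same blocks
as causal ones and no pair-level signal is planted, causal-vs-non-causal
discrimination on the fixtures is at or below chance; on real data that
task is driven by pair-level evidence the generator deliberately omits.
Real catalogs also have heavy-tailed degree distributions, identifier
noise, and feature blocks missing non-randomly — none of which the
generator emulates.

`hide_edges` removes a uniform random ⌈fraction·positives⌉ of the ones,
redrawing up to 100 times to avoid emptying any row or column of all its
positives; when that is unavoidable the final draw is accepted *unchanged*
— preferring a "least bad" draw instead would systematically place hidden
pairs on high-degree entities and leak degree information into held-out
evaluation.

## Determinism

Every stochastic stage (walks, skip-gram batching and negatives, negative
sampling for the link classifier and for evaluation, splits, the
generator) draws from `numpy.random.Generator` instances derived from one
configured seed via `SeedSequence`; identical configurations produce
byte-identical outputs, which the test suite asserts.

## Problem sizes

Default experiment sizes were chosen for single-workstation runs:
synthetic bundles of 60 miRNAs × 40 diseases, planted-partition graphs of
60 nodes, and the light embedding preset above. A full pipeline run on a
60×40 bundle (seven embeddings, twelve IRLS solves) takes a few seconds on
one CPU core.

## Known limitations

* Scores are not calibrated probabilities; only their ranking is meaningful.
* Diseases with no training positives receive scores only through the
  disease-space graph; wholly novel diseases (absent from DS and MD) are
  out of reach of a transductive model.
* The link-decision rule (Hadamard features + logistic model + probability
  cutoff) is the standard embedding link-prediction recipe, chosen because
  the upstream literature leaves the rule unspecified; π, the walk
  parameters and the classifier are all configurable.
* Dense matrices throughout: comfortable to a few thousand nodes, not
  beyond.
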