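# Methods

`pathwalker` implements a multi-omics biomarker-discovery workflow that
links aberrant DNA methylation in gene regulatory regions to transcription
factor (TF) binding and to the topology of the upstream signaling network.
This note describes the models, their assumptions, the tunable parameters,
and the design choices made where the procedure was genuinely open.

## Site scoring (Match-style PWM scan)

A position weight matrix (PWM) of length L is built from a count matrix
with a per-cell pseudocount (default 0.25, guarding sparse count matrices
against degenerate zero frequencies). Position i contributes
`I(i) * f(i, b)` for observed base b, where `I(i) = sum_b f(i,b) ln(4 f(i,b))`
is the information content (0·ln 0 := 0). The raw window sum is min–max
normalized to [0, 1] so the consensus word scores exactly 1. Both strands
are scanned by default; minus-strand hits keep forward coordinates.
Windows containing N score 0 — conservative, no imputation. Core-score
pre-filtering and dinucleotide-dependency models are out of scope; plain
PWMs trade some per-site accuracy for complete motif coverage.

## Composite modules and the correlation fitness

A composite module (CM) is a set of PWMs with per-PWM score cutoffs
`q_cutoff` and top-match counts `kappa`, plus a width `sigma` (bp). For a
sequence s, matches below the module cutoff are discarded and only the
`kappa` best per PWM retained; the module score is

    cm_score(s) = max_x  sum_k sum_j  q_j^(k) * N(|x - c_j^(k)|; 0, sigma^2)

where `c` is the match-window center and N the normal *density*: sites
clustered near the anchor x contribute most, and sigma is the module's
effective width. Design choices:

- the density (not CDF) reading is the only one under which nearer sites
  contribute more;
- site position is the window center (`start + L//2`), symmetric under
  strand flips;
- x is scanned at 1-nt granularity over the whole sequence; ties break to
  the smallest x;
- a model of T modules scores additively, `reg_score = sum_t cm_score_t`;
  the reporting threshold `cm_score_cutoff` flags module matches but never
  enters the sum.

The model is fitted to a set of (sequence, value) pairs — values can be an
expression log-fold-change, a methylation–expression correlation, a ChIP
peak height — by maximizing

    fitness = - complexity^(-penalty) * log10(1 - |rho|)

where rho is the Spearman rank correlation (average ranks on ties) between
`reg_score` and the values, and complexity is the number of distinct PWMs
in the model. `lg` is log base 10; |rho| is clamped at 1 - 1e-12. The
penalty (default 1.0) trades correlation against model size.

### Genetic algorithm

Optimization is a seeded, mutation-only genetic algorithm with tournament
selection (size 3) and elitism (2), so the best-fitness trajectory is
non-decreasing and runs are bit-reproducible. Mutations add/drop a module
PWM (rates 0.2) and perturb cutoffs, sigma, and kappa (rates 0.3). Library
defaults are population 50 / 200 generations with two modules of up to 10
PWMs, sigma in [10, 150] bp (init 30) and kappa in [1, 3]. Each PWM is
scanned once per sequence at a score floor of 0.5 and cached; module
cutoffs are applied by slicing the cache, which is what makes the GA
affordable. The recovery experiments in `benchmarks` use a reduced
configuration (population 24, 30 generations, ≤ 3 PWMs per module, pool of
6 PWMs) — at the planted effect sizes the optimum is found reliably well
before the library defaults would.

## Motif enrichment (Yes/No cutoff optimization)

For each PWM the enrichment optimizer evaluates every distinct observed
match score (plus 1.0) as a candidate cutoff and keeps, among candidates
whose test p-value is ≤ alpha, the one maximizing the odds ratio
(Haldane-corrected); ties break toward smaller p, then smaller cutoff.
If no candidate is significant the minimum-p candidate is returned with a
not-significant flag. Two criteria exist: the *site* criterion tests the
Yes-set site density against the No-set density with an upper-tail
binomial test (continuity rate `(s+1)/(n+2)` when the No set has no
sites); the *sequence* criterion applies a one-sided Fisher exact test to
the 2×2 table of sequences with ≥ 1 site. Across PWMs the criterion
p-values at the optimized cutoffs are Benjamini–Hochberg adjusted; the
cutoff search itself is not corrected (per-matrix optimized thresholds are
reported as such).

The default criterion is *sequence*: the binomial site test conditions on
the No rate as if known and is therefore anti-conservative under the null,
while the Fisher test is exact and, with BH, keeps the realized false
discovery fraction below nominal even though cutoffs are optimized (the
discreteness of the exact test absorbs the selection). This calibration is
verified empirically in the benchmark suite.

## Methylation and expression preprocessing

Beta-values follow the standard intensity ratio `M / (U + M + 100)`.
Differential statistics use a Welch t-test per feature with BH adjustment
and a log2 fold change of group means (epsilon 1e-9 for expression; for
beta matrices the conventional 1.5 / 0.67 fold-change thresholds map to
±log2 1.5 ≈ ±0.585). A moderated-variance model would gain power at very
small n; the desk-scale fixtures use ≥ 5 samples per group where the plain
Welch test is well calibrated (verified: type-I ≈ 0.05).

CpG–gene links use the Spearman correlation across shared samples with the
large-sample critical value `z_{1-alpha/2} / sqrt(n - 1)`; at n ≈ 120 and
alpha 0.05 this reproduces the conventional 0.18 threshold. The sample
size is always explicit — the 0.18 value is not hard-coded. Probes are
paired with genes whose span ± 2 kb contains the probe when explicit pairs
are not given. Windows around CpGs (200 bp for enrichment sets, 500 bp for
composite-module sets) are half-open, clipped at zero, and merged when
overlapping or touching.

## Master regulators, context weighting, feedback loops

The signaling network is a directed graph with strictly positive edge
costs and ±1 signs. For each candidate node k, hop-bounded (radius,
default 10 edges) min-cost paths are computed by a layered Bellman–Ford
DP — the hop bound makes plain Dijkstra incorrect — and the node is scored

    score(k) = [ sum_{t in reached inputs} 1 / (1 + cost(k->t)) ] / total_reachable(k)

The numerator rewards many cheaply reached input TFs, the denominator
penalizes promiscuous hubs. The exact weighting of the original key-node
statistic is unpublished; this form is documented as the package's
interpretation and is validated by planted-regulator recovery. The
*context* variant multiplies the cost of every edge adjacent (either
endpoint) to an up-regulated gene product by a discount (default 0.5),
steering shortest paths through the active subnetwork. With TF→gene
regulatory edges and gene→protein closure edges present, simple cycles
through a key node that cross the regulation layer are enumerated
(bounded length, default 6); the edge-sign product classifies a loop as
positive (self-activating) or negative. On synthetic fixtures the context
discount makes an on-loop regulator outrank an off-loop twin with
identical input wiring — the testable core of the walking-pathways
rationale.

## Biomarker panels

Candidate markers are pruned greedily by pairwise Pearson correlation
(threshold 0.8): pairs are visited by descending |r| and the member with
the smaller univariate effect is dropped. Panels are evaluated by
repeated stratified random 50/50 splits (default 100) with a linear
soft-margin SVM (C = 1; kernel and C are unstated in comparable studies,
so the simplest classifier is the default and the factory is injectable).
Accuracy is the fraction correct; splits are stratified to avoid
degenerate class-empty draws at small n. Backward elimination drops the
probe whose removal least degrades mean accuracy, breaking exact ties by
the smallest univariate class separation.

## Synthetic data: what it does and does not emulate

The generators produce the statistical structure each stage assumes:
i.i.d. background DNA with consensus words planted inside a Gaussian
window (consensus planting gives unambiguous recovery targets; a
probabilistic sampling mode would make harder fixtures), values linearly
coupled to module presence plus Gaussian noise, two-class beta cohorts
with per-marker shifts, and toy signaling graphs where decoy nodes carry
deliberate extra fan-out so that reaching many inputs cheaply — not
merely having few neighbors — is what the planted regulator is rewarded
for. The end-to-end bundle couples all of these: hypermethylated CpGs
whose windows carry a planted two-PWM module, paired down-regulated
genes, up-regulated TF and regulator genes, and a feedback loop in the
network.

Not emulated: probe chemistry and array normalization artifacts, read
counts (expression is log-normal around group means), linkage between
neighboring CpGs, genome-scale motif background composition, and the
reaction-mechanism semantics of curated pathway databases. Passing the
recovery tests therefore demonstrates correctness and calibration of the
algorithms under their stated assumptions, not clinical performance on
patient cohorts.

## Problem sizes and numerical choices

Benchmark experiments use: 50 random instances for the module-score
oracle; 400 sequences × 200 bp for GA recovery (10 seeds, plus 10
permuted-null seeds); 200 + 200 sequences for planted enrichment and
100 + 100 × 50 PWMs × 20 seeds for the enrichment null; 50-node graphs
(10 fixtures) for regulator recovery; 12 + 12 cohorts × 100 splits for
panels; and 10 seeds of the full pipeline bundle (60 signal + 340
background CpGs, 20 + 20 tissue samples). Ties everywhere break
deterministically (smallest position/x, lexicographic ids); all
randomness flows from explicit seeds; TSV output uses 6 significant
digits.
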