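# pathwalker

Toolkit for finding candidate *causative* DNA-methylation biomarkers by
linking three layers of evidence: CpG loci whose methylation correlates
with gene expression, transcription-factor (TF) binding sites enriched in
the genomic windows around those loci, and master regulators upstream of
those TFs in the signaling network — with special attention to positive
feedback loops, where a regulator up-regulates its own gene through the
TFs it controls. It is aimed at computational biologists integrating
methylation arrays, RNA-seq, PWM motif libraries and curated pathway
networks, and it ships synthetic-data generators so every stage is
testable without access to patient data.

## What it computes

**Composite-module models correlated with a quantitative trait.** A
composite module is a set of PWMs with per-PWM score cutoffs
$q^{(k)}_{cutoff}$, top-match counts $\kappa^{(k)}$ and a width $\sigma$.
Its score on a sequence $s$ anchors a Gaussian at the best position $x$:

$$cm\\_score(s) = \max_x \sum_k \sum_{j=1}^{\kappa^{(k)}} q_j^{(k)}
\cdot \mathcal{N}\!\left(|x - \theta_j^{(k)}|;\, 0, \sigma^2\right)$$

with $\theta$ the site center and $q$ its normalized Match-style score.
A full model sums $T$ such modules. A genetic algorithm maximizes

$$fitness = -\,complexity^{-penalty}\,\lg\left(1 - |\rho|\right)$$

where $\rho$ is the Spearman correlation between model score and a
per-sequence value (expression logFC, methylation–expression correlation,
...) and *complexity* counts distinct PWMs.

**Motif enrichment** (Yes/No sets) optimizes a score cutoff per PWM —
binomial test on site density or one-sided Fisher exact test on
site-containing sequences — and BH-adjusts across PWMs.

**Master regulators** are nodes of a weighted signed signaling graph
scored by $\left[\sum_t 1/(1+cost(k \to t))\right] / reachable(k)$ over
hop-bounded cheapest paths to the input TFs; a context discount on edges
adjacent to up-regulated gene products steers the search toward active
subnetworks and positive feedback loops (TF → gene → protein closures
with positive sign product).

**Biomarker panels** are pruned by pairwise Pearson correlation and
evaluated with a linear SVM over repeated stratified 50/50 splits.

## Worked example

Plant a two-PWM module in half of 200 random promoters, couple a noisy
trait to module presence, then ask the toolkit to find the motifs and the
module again:

```python
import numpy as np
from pathwalker.synthetic import (consensus_pwm, random_pwm, gen_background,
                                  plant_module, gen_values)
from pathwalker.enrichment import fmatch
from pathwalker.cma_correl import GAConfig, FitnessParams, ga_optimize
from pathwalker.io_formats import SequenceSet, Sequence

rng = np.random.default_rng(0)
planted = [consensus_pwm("ATGCATACG", "TFA"), consensus_pwm("GCCATTAGG", "TFB")]
decoys = [random_pwm(9, f"DEC{i}", seed=rng) for i in range(4)]

seqs = gen_background(200, 200, seed=1)
with_module, truth = plant_module(seqs, planted, sigma=20, fraction=0.5, seed=1)
values = gen_values(truth, effect=0.6, noise_sd=0.2, seed=1, sequences=with_module)

yes = SequenceSet(s for s in with_module if truth.labels[s.id])
no = SequenceSet(Sequence("bg_" + s.id, s.residues)
                 for s in gen_background(200, 200, seed=2))
table = fmatch(planted + decoys, yes, no, criterion="sequence")
print(table[["pwm_id", "optimized_cutoff", "yes_seq_hits",
             "no_seq_hits", "p_adjusted"]].head(3).to_string(index=False))

model, trajectory, rho = ga_optimize(
    values, planted + decoys,
    GAConfig(population_size=24, generations=30, max_pwms_per_module=3, seed=0),
    FitnessParams(penalty=1.0))
print("model PWMs:", sorted({p for m in model.modules for p in m.pwm_ids}))
print(f"Spearman rho = {rho:.3f}")
```

Output:

```
pwm_id  optimized_cutoff  yes_seq_hits  no_seq_hits   p_adjusted
   TFB          1.000000           100            0 1.442914e-81
   TFA          1.000000           100            1 7.286717e-80
  DEC2          0.977751             9            0 7.917349e-05
model PWMs: ['TFA']
Spearman rho = 0.851
```

Both planted PWMs top the enrichment table at their exact consensus
cutoff (100/100 planted sequences hit, ~0 background hits), a decoy
trails ten orders of magnitude behind, and the optimized composite model
reaches rank correlation 0.85 with the planted trait — close to the
ceiling imposed by the trait's noise.

## Command line

`pathwalker` exposes each stage (`scan`, `fmatch`, `cma`, `keynodes`,
`prep-diff`, `prep-corr`, `prep-regions`, `panel`, `simulate`) and the
full workflow:

```sh
pathwalker simulate bundle --seed 1 --out bundle/
pathwalker pipeline --config bundle/config.yaml --out results/
```

The pipeline runs differential expression → differential methylation →
CpG–gene correlation → window construction → motif enrichment +
composite-module optimization → TF filtering → context-weighted
master-regulator search with feedback-loop detection → biomarker table →
panel decorrelation and SVM evaluation, writing one TSV per stage plus a
JSON summary and a run log.

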