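"""Planted-signal recovery and calibration experiments on synthetic data.

These are the package's own validation studies: each function generates a
fixture with known ground truth, runs the corresponding analysis, and
returns the recovery or calibration statistic. Problem sizes are chosen to
be informative at desk scale; the test suite and the acceptance script
both call these functions.
"""

from __future__ import annotations

import numpy as np

from .cma_correl import (
    CompositeModule,
    FitnessParams,
    GAConfig,
    ScoredDataset,
    cm_score,
    ga_optimize,
    gaussian_density,
    spearman,
)
from .enrichment import fmatch
from .io_formats import SampleMatrix, Sequence, SequenceSet
from .marker_selection import evaluate_panel
from .master_regulators import apply_context, keynode_search
from .omics_prep import critical_r, differential
from .pwm_scan import scan
from .synthetic import (
    consensus_pwm,
    gen_background,
    gen_cohort,
    gen_network,
    gen_values,
    plant_module,
    random_pwm,
)

PLANTED_WORD_A = "ATGCATACG"
PLANTED_WORD_B = "GCCATTAGG"


# ---------------------------------------------------------------------------
# Composite-module score: exhaustive oracle


def cm_score_oracle(matches_by_pwm, module, seq_length, pwm_lengths):
    """Literal per-position, per-match evaluation of the module score."""
    from .pwm_scan import top_matches

    sites = []
    for pid, cutoff, kappa in zip(module.pwm_ids, module.cutoffs, module.top_counts):
        kept = [m for m in matches_by_pwm.get(pid, []) if m.score >= cutoff]
        for m in top_matches(kept, kappa):
            sites.append((m.score, m.center(pwm_lengths[pid])))
    if not sites:
        return 0.0, 0
    best_score, best_x = -1.0, 0
    for x in range(seq_length):
        total = sum(
            q * float(gaussian_density(abs(x - c), module.sigma)) for q, c in sites
        )
        if total > best_score:
            best_score, best_x = total, x
    return best_score, best_x


def cm_score_oracle_max_delta(n_instances: int = 50, seed: int = 0) -> float:
    """Max |cm_score - oracle| over random (sequence, module) instances."""
    rng = np.random.default_rng(seed)
    max_delta = 0.0
    for i in range(n_instances):
        length = int(rng.integers(60, 501))
        seq = gen_background(1, length, seed=rng)[0]
        k = int(rng.integers(1, 4))
        pwms = [random_pwm(int(rng.integers(6, 10)), f"pwm{j}", seed=rng) for j in range(k)]
        module = CompositeModule(
            pwm_ids=tuple(p.id for p in pwms),
            cutoffs=tuple(float(rng.uniform(0.5, 0.9)) for _ in pwms),
            top_counts=tuple(int(rng.integers(1, 4)) for _ in pwms),
            sigma=float(rng.uniform(5, 50)),
        )
        matches = {p.id: scan(p, seq, cutoff=0.0) for p in pwms}
        lengths = {p.id: p.length for p in pwms}
        fast = cm_score(matches, module, length, lengths)
        slow = cm_score_oracle(matches, module, length, lengths)
        max_delta = max(max_delta, abs(fast[0] - slow[0]))
        assert fast[1] == slow[1], "x_max mismatch against oracle"
    return max_delta


# ---------------------------------------------------------------------------
# GA parameter recovery


def ga_fixture(seed: int, n_seqs: int = 400, length: int = 200):
    """Planted 2-PWM module in half the sequences, trait coupled to presence."""
    rng = np.random.default_rng(seed)
    planted = [
        consensus_pwm(PLANTED_WORD_A, "PLANT_A"),
        consensus_pwm(PLANTED_WORD_B, "PLANT_B"),
    ]
    decoys = [random_pwm(9, f"DECOY_{i}", seed=rng, concentration=0.7) for i in range(4)]
    seqs = gen_background(n_seqs, length, seed=rng)
    planted_seqs, truth = plant_module(seqs, planted, sigma=20.0, fraction=0.5, seed=rng)
    dataset = gen_values(truth, effect=0.6, noise_sd=0.2, seed=rng, sequences=planted_seqs)
    return dataset, planted + decoys, truth


def _experiment_ga_config(seed: int) -> GAConfig:
    return GAConfig(
        population_size=24,
        generations=30,
        n_modules=2,
        max_pwms_per_module=3,
        kappa_max=3,
        seed=seed,
    )


def ga_recovery(n_seeds: int = 10, base_seed: int = 0):
    """Fraction of seeded runs recovering a planted PWM with |rho| >= 0.5."""
    hits, rhos = 0, []
    for i in range(n_seeds):
        seed = base_seed + i
        dataset, pool, truth = ga_fixture(seed)
        model, _, rho = ga_optimize(
            dataset, pool, _experiment_ga_config(seed), FitnessParams(penalty=1.0)
        )
        model_pwms = {pid for m in model.modules for pid in m.pwm_ids}
        recovered = bool(model_pwms & set(truth.planted_pwm_ids))
        if recovered and abs(rho) >= 0.5:
            hits += 1
        rhos.append(abs(rho))
    return hits / n_seeds, rhos


def ga_null(n_seeds: int = 10, base_seed: int = 0):
    """Mean best |rho| when values are randomly permuted (no real signal)."""
    rhos = []
    for i in range(n_seeds):
        seed = base_seed + i
        dataset, pool, _ = ga_fixture(seed)
        rng = np.random.default_rng(seed + 10_000)
        values = dataset.values
        permuted = values[rng.permutation(values.size)]
        null_ds = ScoredDataset(
            [(s, float(v)) for (s, _), v in zip(dataset.entries, permuted)],
            value_semantics="permuted",
        )
        _, _, rho = ga_optimize(
            null_ds, pool, _experiment_ga_config(seed), FitnessParams(penalty=1.0)
        )
        rhos.append(abs(rho))
    return float(np.mean(rhos)), rhos


# ---------------------------------------------------------------------------
# F-Match calibration


def fmatch_planted_fixture(seed: int, n_yes: int = 200, n_no: int = 200,
                           length: int = 200, n_decoys: int = 20):
    """Motif planted in 60% of Yes and 5% of No sequences."""
    rng = np.random.default_rng(seed)
    planted = consensus_pwm(PLANTED_WORD_A, "PLANTED")
    decoys = [
        random_pwm(int(rng.integers(8, 11)), f"DECOY_{i:02d}", seed=rng, concentration=0.7)
        for i in range(n_decoys)
    ]
    yes, _ = plant_module(
        gen_background(n_yes, length, seed=rng), [planted], fraction=0.6, seed=rng
    )
    no, _ = plant_module(
        gen_background(n_no, length, seed=rng), [planted], fraction=0.05, seed=rng
    )
    no = SequenceSet(Sequence("no_" + s.id, s.residues) for s in no)
    return [planted] + decoys, yes, no


def fmatch_planted(seed: int = 0):
    """Rank and adjusted p of the planted PWM in the enrichment table."""
    pwms, yes, no = fmatch_planted_fixture(seed)
    table = fmatch(pwms, yes, no, criterion="sequence", alpha=0.05)
    rank = int(table.index[table["pwm_id"] == "PLANTED"][0]) + 1
    p_adj = float(table.loc[table["pwm_id"] == "PLANTED", "p_adjusted"].iloc[0])
    return rank, p_adj


def fmatch_null_fraction(n_seeds: int = 20, base_seed: int = 0, n_pwms: int = 50):
    """Mean fraction of PWMs called enriched when Yes and No share a null."""
    fractions = []
    for i in range(n_seeds):
        rng = np.random.default_rng(base_seed + i)
        pwms = [
            random_pwm(int(rng.integers(8, 11)), f"P{j:02d}", seed=rng, concentration=0.7)
            for j in range(n_pwms)
        ]
        yes = gen_background(100, 200, seed=rng)
        no = SequenceSet(
            Sequence("no_" + s.id, s.residues) for s in gen_background(100, 200, seed=rng)
        )
        table = fmatch(pwms, yes, no, criterion="sequence", alpha=0.05)
        called = ((table["p_adjusted"] < 0.05) & table["significant"]).sum()
        fractions.append(called / n_pwms)
    return float(np.mean(fractions)), fractions


# ---------------------------------------------------------------------------
# Key-node recovery


def keynode_recovery(n_fixtures: int = 10, base_seed: int = 0) -> float:
    """Fraction of random 50-node fixtures ranking the planted regulator first."""
    hits = 0
    for i in range(n_fixtures):
        graph, truth = gen_network(n_nodes=50, planted=True, n_inputs=5, seed=base_seed + i)
        results = keynode_search(graph, truth["inputs"], radius=3)
        if results and results[0].node == truth["regulator"]:
            hits += 1
    return hits / n_fixtures


def loop_context_advantage(n_fixtures: int = 10, base_seed: int = 0) -> float:
    """Fraction of fixtures where context discounting on loop nodes ranks the
    on-loop regulator above its topologically equivalent off-loop twin."""
    hits = 0
    for i in range(n_fixtures):
        graph, truth = gen_network(
            n_nodes=50, planted=True, feedback=True, n_inputs=5, seed=base_seed + i
        )
        weighted = apply_context(graph, truth["loop_nodes"], discount=0.5)
        results = keynode_search(weighted, truth["inputs"], radius=3)
        order = {r.node: rank for rank, r in enumerate(results)}
        if order.get(truth["regulator"], 10**9) < order.get(truth["twin"], 10**9):
            hits += 1
    return hits / n_fixtures


def star_graph_score() -> float:
    """Hand-checkable star graph: R -> T1, R -> T2 at unit cost, radius 1."""
    from .master_regulators import SignalingGraph

    g = SignalingGraph()
    g.add_node("T1", kind="TF", gene="g1")
    g.add_node("T2", kind="TF", gene="g2")
    g.add_edge("R", "T1", cost=1.0)
    g.add_edge("R", "T2", cost=1.0)
    results = keynode_search(g, ["T1", "T2"], radius=1)
    return next(r.score for r in results if r.node == "R")


# ---------------------------------------------------------------------------
# Statistical calibration


def differential_type1(n_seeds: int = 20, base_seed: int = 0, n_features: int = 100,
                       n_per_group: int = 10) -> float:
    """Raw-p type-I rate of the two-group differential test on null data."""
    rates = []
    for i in range(n_seeds):
        rng = np.random.default_rng(base_seed + i)
        import pandas as pd

        a = pd.DataFrame(
            rng.normal(100, 10, size=(n_features, n_per_group)),
            index=[f"f{j}" for j in range(n_features)],
            columns=[f"a{j}" for j in range(n_per_group)],
        )
        b = pd.DataFrame(
            rng.normal(100, 10, size=(n_features, n_per_group)),
            index=a.index,
            columns=[f"b{j}" for j in range(n_per_group)],
        )
        table = differential(SampleMatrix(a), SampleMatrix(b))
        rates.append(float((table["p"] < 0.05).mean()))
    return float(np.mean(rates))


def correlation_type1(n_seeds: int = 20, base_seed: int = 0, n_pairs: int = 100,
                      n_samples: int = 30) -> float:
    """Pass rate of the |rho| > critical_r filter on independent pairs."""
    crit = critical_r(n_samples, 0.05)
    rates = []
    for i in range(n_seeds):
        rng = np.random.default_rng(base_seed + i)
        passes = 0
        for _ in range(n_pairs):
            rho = spearman(rng.normal(size=n_samples), rng.normal(size=n_samples))
            passes += abs(rho) > crit
        rates.append(passes / n_pairs)
    return float(np.mean(rates))


# ---------------------------------------------------------------------------
# Panel evaluation


def panel_separable(seed: int = 0, n_splits: int = 100):
    """Mean accuracy on a linearly separable 12 + 12 cohort, 6 markers."""
    cohort, labels = gen_cohort(
        n_case=12, n_control=12, n_markers=6, effects=0.5, noise_sd=0.05, seed=seed
    )
    return evaluate_panel(cohort, labels, n_splits=n_splits, seed=seed)


def panel_null(seed: int = 0, n_splits: int = 100):
    """Mean accuracy with permuted labels on the same cohort."""
    cohort, labels = gen_cohort(
        n_case=12, n_control=12, n_markers=6, effects=0.5, noise_sd=0.05, seed=seed
    )
    rng = np.random.default_rng(seed + 777)
    permuted = labels.copy()
    permuted[:] = labels.to_numpy()[rng.permutation(len(labels))]
    return evaluate_panel(cohort, permuted, n_splits=n_splits, seed=seed)


# ---------------------------------------------------------------------------
# End-to-end pipeline recovery


def pipeline_recovery(n_seeds: int = 10, base_seed: int = 0, workdir=None) -> float:
    """Fraction of seeds whose final panel contains a planted biomarker CpG."""
    import tempfile
    from pathlib import Path

    from .pipeline import PipelineConfig, run_pipeline
    from .synthetic import gen_pipeline_bundle

    hits = 0
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        tmp = Path(tmp)
        for i in range(n_seeds):
            seed = base_seed + i
            info = gen_pipeline_bundle(tmp / f"bundle_{seed}", seed=seed)
            summary = run_pipeline(
                PipelineConfig.from_yaml(info["config"]), tmp / f"out_{seed}"
            )
            panel = set(summary["stages"]["panel"]["panel"])
            if panel & set(info["truth"]["planted_probes"]):
                hits += 1
    return hits / n_seeds
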