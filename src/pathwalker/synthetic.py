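"""Generators for synthetic fixtures with the statistical structure each
analysis stage assumes: background DNA with planted composite modules,
quantitative values coupled to module presence, toy signaling graphs with
a planted master regulator (optionally on a positive feedback loop), and
two-class beta-value cohorts.

Every generator is a pure function of its seed and parameters, and returns
a truth object sufficient to score recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cma_correl import ScoredDataset
from .io_formats import SampleMatrix, Sequence, SequenceSet
from .master_regulators import SignalingGraph
from .pwm_scan import PWM, build_pwm


@dataclass
class SyntheticTruth:
    """Ground truth of a planting experiment."""

    planted_pwm_ids: list[str] = field(default_factory=list)
    planted_positions: list[tuple[str, str, int]] = field(default_factory=list)
    labels: dict[str, bool] = field(default_factory=dict)
    effect: float = 0.0
    noise_sd: float = 0.0
    regulator: str | None = None
    seed: int = 0


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def gen_background(n: int, length: int, gc: float = 0.5, seed: int = 0) -> SequenceSet:
    """i.i.d. background sequences with P(G) = P(C) = gc/2."""
    if not 0 < gc < 1:
        raise ValueError("gc must lie in (0, 1)")
    rng = _rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    bases = np.array(list("ACGT"))
    out = SequenceSet()
    for i in range(n):
        draws = rng.choice(4, size=length, p=probs)
        out.add(Sequence(f"seq_{i:04d}", "".join(bases[draws])))
    return out


def consensus_pwm(word: str, pwm_id: str, weight: float = 20.0, pseudocount: float = 0.25) -> PWM:
    """A sharp PWM whose consensus is the given word."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    counts = np.zeros((len(word), 4))
    for i, base in enumerate(word.upper()):
        counts[i, idx[base]] = weight
    return build_pwm(counts, pseudocount=pseudocount, pwm_id=pwm_id)


def random_pwm(length: int, pwm_id: str, seed: int = 0, concentration: float = 0.5,
               total: float = 20.0) -> PWM:
    """A random PWM with Dirichlet-distributed position preferences."""
    rng = _rng(seed)
    freqs = rng.dirichlet([concentration] * 4, size=length)
    return build_pwm(np.round(freqs * total, 3), pwm_id=pwm_id)


def plant_module(
    seqs: SequenceSet,
    pwms: list[PWM],
    sigma: float = 20.0,
    fraction: float = 0.5,
    seed: int = 0,
    center_margin: int | None = None,
) -> tuple[SequenceSet, SyntheticTruth]:
    """Write one consensus word per PWM into a random subset of sequences.

    In each selected sequence a random module center is drawn and every
    PWM's consensus is placed at an offset within +/- sigma of it, avoiding
    overlap between planted words where possible. ``center_margin``
    restricts the module center to [margin, length - margin) so planted
    sites stay inside a central window (defaults to sigma + max word size).
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    rng = _rng(seed)
    words = [p.consensus() for p in pwms]
    max_w = max((len(w) for w in words), default=0)
    n = len(seqs)
    n_plant = int(np.ceil(fraction * n))
    chosen = set(rng.choice(n, size=n_plant, replace=False).tolist()) if n_plant else set()
    truth = SyntheticTruth(planted_pwm_ids=[p.id for p in pwms], seed=int(seed) if not isinstance(seed, np.random.Generator) else -1)
    out = SequenceSet()
    for i, seq in enumerate(seqs):
        residues = seq.residues
        if i in chosen:
            length = len(residues)
            margin = center_margin if center_margin is not None else int(sigma) + max_w
            if 2 * margin >= length:
                raise ValueError("sequence too short for module planting")
            center = int(rng.integers(margin, length - margin))
            placed: list[tuple[int, int]] = []
            chars = list(residues)
            for pwm, word in zip(pwms, words):
                L = len(word)
                for _attempt in range(50):
                    offset = int(np.round(rng.uniform(-sigma, sigma)))
                    start = min(max(center + offset - L // 2, 0), length - L)
                    if all(start + L <= s or start >= e for s, e in placed):
                        break
                placed.append((start, start + L))
                chars[start : start + L] = list(word)
                truth.planted_positions.append((seq.id, pwm.id, start))
            residues = "".join(chars)
        truth.labels[seq.id] = i in chosen
        out.add(Sequence(seq.id, residues))
    return out, truth


def gen_values(
    truth: SyntheticTruth,
    effect: float,
    noise_sd: float,
    seed: int = 0,
    clip_beta: bool = False,
    sequences: SequenceSet | None = None,
    semantics: str = "synthetic trait",
) -> ScoredDataset:
    """Per-sequence values = effect * module_present + Gaussian noise.

    When ``clip_beta`` is set, values are clipped to [0, 1] (beta-value
    emulation). ``sequences`` supplies the Sequence objects for the dataset
    entries (required to build a ScoredDataset usable by the optimizer).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = _rng(seed)
    entries = []
    for seq_id, present in truth.labels.items():
        value = effect * float(present) + rng.normal(0.0, noise_sd)
        if clip_beta:
            value = float(np.clip(value, 0.0, 1.0))
        seq = sequences[seq_id] if sequences is not None else Sequence(seq_id, "N")
        entries.append((seq, value))
    truth.effect = effect
    truth.noise_sd = noise_sd
    return ScoredDataset(entries, value_semantics=semantics)


def gen_network(
    n_nodes: int = 50,
    planted: bool = True,
    feedback: bool = False,
    n_inputs: int = 5,
    seed: int = 0,
) -> tuple[SignalingGraph, dict]:
    """A toy signaling graph with decoys and, optionally, a planted regulator.

    The planted regulator reaches every input TF within <= 2 steps; decoy
    "feeder" nodes reach at most 2 inputs and carry extra fan-out to inert
    "sink" nodes, so the regulator tops the key-node ranking. With
    ``feedback``, a TF -> gene -> regulator positive closure loop is added,
    together with an off-loop twin with identical input wiring.
    """
    if n_nodes < n_inputs + 2:
        raise ValueError("n_nodes must be >= n_inputs + 2")
    rng = _rng(seed)
    g = SignalingGraph()
    inputs = [f"TF_{i}" for i in range(n_inputs)]
    for tf in inputs:
        g.add_node(tf, kind="TF", gene=f"gene_{tf}")
    truth: dict = {"inputs": inputs, "regulator": None, "twin": None, "loop_nodes": []}

    used = n_inputs
    if planted:
        g.add_node("REG", kind="protein", gene="gene_REG")
        used += 1
        for tf in inputs:
            g.add_edge("REG", tf, sign=1, cost=1.0)
        truth["regulator"] = "REG"
        if feedback:
            g.add_node("TWIN", kind="protein", gene="gene_TWIN")
            used += 1
            for tf in inputs:
                g.add_edge("TWIN", tf, sign=1, cost=1.0)
            g.add_node("gene_REG", kind="gene")
            g.add_edge(inputs[0], "gene_REG", sign=1, cost=1.0)  # TF -> gene
            g.add_edge("gene_REG", "REG", sign=1, cost=1.0)  # gene -> product
            used += 1
            truth["twin"] = "TWIN"
            truth["loop_nodes"] = ["REG", inputs[0], "gene_REG"]

    n_decoys = max(n_nodes - used, 0)
    n_sinks = max(n_decoys // 2, 2) if n_decoys else 0
    sinks = [f"SINK_{i}" for i in range(n_sinks)]
    feeders = [f"DECOY_{i}" for i in range(n_decoys - n_sinks)]
    for s in sinks:
        g.add_node(s, kind="protein")
    for i, s in enumerate(sinks):
        for j in range(2):
            t = sinks[(i + j + 1) % len(sinks)]
            if t != s:
                g.add_edge(s, t, sign=1, cost=float(rng.uniform(0.8, 1.2)))
    for d in feeders:
        g.add_node(d, kind="protein")
        k_in = int(rng.integers(0, 3))  # 0..2 inputs
        for tf in rng.choice(n_inputs, size=k_in, replace=False):
            g.add_edge(d, inputs[int(tf)], sign=1, cost=float(rng.uniform(0.8, 1.2)))
        for s in rng.choice(len(sinks), size=min(3, len(sinks)), replace=False):
            g.add_edge(d, sinks[int(s)], sign=1, cost=float(rng.uniform(0.8, 1.2)))
    return g, truth


def gen_pipeline_bundle(
    outdir,
    seed: int = 0,
    n_signal: int = 60,
    n_background: int = 340,
    window: int = 500,
    n_case: int = 20,
    n_control: int = 20,
    cohort_case: int = 12,
    cohort_control: int = 12,
    n_decoy_pwms: int = 6,
) -> dict:
    """Write a complete synthetic input bundle for the end-to-end pipeline.

    The bundle emulates the study conditions at desk scale: hypermethylated
    CpG probes whose beta-values anticorrelate with expression of their
    paired (down-regulated) genes, 500 bp windows around those CpGs with a
    planted two-PWM composite module, up-regulated TF genes for the planted
    PWMs, a signaling network in which a master regulator reaches both TFs
    and sits on a TF -> gene -> protein positive feedback loop, and a
    separable two-class plasma cohort over all probes.

    Returns a dict with the config path and the ground truth.
    """
    import json
    from pathlib import Path

    import yaml

    from .io_formats import (
        write_fasta,
        write_matrix,
        write_network,
        write_pwm_jaspar,
    )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = _rng(seed)

    n_probes = n_signal + n_background
    signal_probes = [f"cg_sig_{i:03d}" for i in range(n_signal)]
    bg_probes = [f"cg_bg_{i:03d}" for i in range(n_background)]
    probes = signal_probes + bg_probes

    # --- PWMs: two planted + decoys -------------------------------------
    planted_words = ("ATGCATACG", "GCCATTAGG")
    pwm_a = consensus_pwm(planted_words[0], "PWM_TFA")
    pwm_b = consensus_pwm(planted_words[1], "PWM_TFB")
    decoys = [
        random_pwm(int(rng.integers(8, 11)), f"PWM_DEC{i}", seed=rng, concentration=0.7)
        for i in range(n_decoy_pwms)
    ]
    pwms = [pwm_a, pwm_b] + decoys
    write_pwm_jaspar(outdir / "pwms.jaspar", pwms)

    # --- sequences: 500 bp windows, module planted centrally in signal --
    margin = window // 2 - 40 - max(len(w) for w in planted_words)
    background = gen_background(n_probes, window, gc=0.5, seed=rng)
    all_seqs = SequenceSet(
        Sequence(p, background[i].residues) for i, p in enumerate(probes)
    )
    signal_set = SequenceSet(all_seqs[p] for p in signal_probes)
    planted_set, plant_truth = plant_module(
        signal_set, [pwm_a, pwm_b], sigma=20.0, fraction=1.0, seed=rng,
        center_margin=margin,
    )
    final = SequenceSet(
        planted_set[p] if p in planted_set else all_seqs[p] for p in probes
    )
    write_fasta(outdir / "sequences.fasta", final)

    # --- genes and expression -------------------------------------------
    sig_genes = [f"gene_sig_{i:03d}" for i in range(n_signal)]
    bg_genes = [f"gene_bg_{i:03d}" for i in range(60)]
    tf_genes = ["gene_TFA", "gene_TFB"]
    ctx_genes = [f"gene_CTX_{i}" for i in range(4)]
    mreg_gene = "gene_MREG"
    genes = sig_genes + bg_genes + tf_genes + ctx_genes + [mreg_gene]

    samples = [f"s{i:02d}" for i in range(n_case + n_control)]
    case_cols, ctrl_cols = samples[:n_case], samples[n_case:]
    group = np.array([1.0] * n_case + [0.0] * n_control)

    lfc = {g: 0.0 for g in genes}
    lfc.update({g: -2.5 for g in sig_genes})
    lfc.update({g: 2.0 for g in tf_genes})
    lfc.update({g: 2.5 for g in ctx_genes})
    lfc[mreg_gene] = 2.5
    expr = np.empty((len(genes), len(samples)))
    for gi, g in enumerate(genes):
        base = 100.0 * 2 ** (lfc[g] * group)
        expr[gi] = base * 2 ** rng.normal(0.0, 0.25, size=len(samples))
    expr_df = pd.DataFrame(expr, index=genes, columns=samples)
    write_matrix(outdir / "expr_case.tsv", SampleMatrix(expr_df[case_cols]))
    write_matrix(outdir / "expr_control.tsv", SampleMatrix(expr_df[ctrl_cols]))

    # --- methylation beta matrices --------------------------------------
    beta = np.clip(rng.normal(0.15, 0.05, size=(n_probes, len(samples))), 0.0, 0.99)
    beta[:n_signal] += 0.4 * group[None, :]
    beta = np.clip(beta, 0.0, 0.99)
    beta_df = pd.DataFrame(beta, index=probes, columns=samples)
    write_matrix(outdir / "meth_case.tsv", SampleMatrix(beta_df[case_cols], kind="beta"))
    write_matrix(outdir / "meth_control.tsv", SampleMatrix(beta_df[ctrl_cols], kind="beta"))

    # --- probe annotation ------------------------------------------------
    gene_of_probe = {}
    for i, p in enumerate(signal_probes):
        gene_of_probe[p] = sig_genes[i]
    for i, p in enumerate(bg_probes):
        gene_of_probe[p] = bg_genes[i % len(bg_genes)]
    ann = pd.DataFrame(
        {
            "probe": probes,
            "chrom": "chr1",
            "position": [5000 * (i + 1) for i in range(n_probes)],
            "gene": [gene_of_probe[p] for p in probes],
        }
    )
    ann.to_csv(outdir / "cpg_annotation.tsv", sep="\t", index=False)

    # --- signaling network with feedback loop ---------------------------
    g = SignalingGraph()
    g.add_node("TFA", kind="TF", gene="gene_TFA")
    g.add_node("TFB", kind="TF", gene="gene_TFB")
    g.add_node("REG", kind="protein", gene=mreg_gene)
    g.add_edge("REG", "TFA", sign=1, cost=1.0)
    g.add_edge("REG", "TFB", sign=1, cost=1.0)
    g.add_node("gene_MREG_locus", kind="gene")
    g.add_edge("TFA", "gene_MREG_locus", sign=1, cost=1.0)
    g.add_edge("gene_MREG_locus", "REG", sign=1, cost=1.0)
    for i, cg in enumerate(ctx_genes):
        node = f"CTX_{i}"
        g.add_node(node, kind="protein", gene=cg)
        g.add_edge(node, "REG", sign=1, cost=1.0)
    sinks = [f"SINK_{i}" for i in range(4)]
    for i, s in enumerate(sinks):
        g.add_node(s, kind="protein")
    for i, s in enumerate(sinks):
        g.add_edge(s, sinks[(i + 1) % len(sinks)], sign=1, cost=1.0)
    for i in range(6):
        d = f"DECOY_{i}"
        g.add_node(d, kind="protein", gene=bg_genes[i])
        g.add_edge(d, "TFA" if i % 2 == 0 else "TFB", sign=1,
                   cost=float(rng.uniform(0.8, 1.2)))
        for s in rng.choice(4, size=3, replace=False):
            g.add_edge(d, sinks[int(s)], sign=1, cost=float(rng.uniform(0.8, 1.2)))
    write_network(outdir / "network.tsv", g)
    nodes_rows = [
        {"node": n, "kind": g.kind(n), "gene": g.gene_of(n) or ""} for n in g.graph.nodes
    ]
    pd.DataFrame(nodes_rows).to_csv(outdir / "nodes.tsv", sep="\t", index=False)

    # --- PWM -> TF map ----------------------------------------------------
    pwm_tf_rows = [
        {"pwm_id": "PWM_TFA", "tf_gene": "gene_TFA", "tf_node": "TFA"},
        {"pwm_id": "PWM_TFB", "tf_gene": "gene_TFB", "tf_node": "TFB"},
    ]
    for i, p in enumerate(decoys):
        pwm_tf_rows.append(
            {"pwm_id": p.id, "tf_gene": bg_genes[10 + i], "tf_node": f"DECOY_TF_{i}"}
        )
    pd.DataFrame(pwm_tf_rows).to_csv(outdir / "pwm_tf_map.tsv", sep="\t", index=False)

    # --- plasma cohort ----------------------------------------------------
    effects = np.zeros(n_probes)
    effects[:n_signal] = 0.35
    cohort, labels = gen_cohort(
        n_case=cohort_case, n_control=cohort_control, n_markers=n_probes,
        effects=effects, noise_sd=0.05, baseline=0.1, seed=rng, marker_ids=probes,
    )
    write_matrix(outdir / "cohort_beta.tsv", cohort)
    labels.to_frame().to_csv(outdir / "cohort_labels.tsv", sep="\t", index_label="sample")

    # --- config and truth -------------------------------------------------
    config = {
        "seed": int(seed),
        "paths": {
            "expr_case": "expr_case.tsv",
            "expr_control": "expr_control.tsv",
            "meth_case": "meth_case.tsv",
            "meth_control": "meth_control.tsv",
            "annotation": "cpg_annotation.tsv",
            "sequences": "sequences.fasta",
            "pwms": "pwms.jaspar",
            "pwm_dialect": "jaspar",
            "pwm_tf_map": "pwm_tf_map.tsv",
            "network": "network.tsv",
            "nodes": "nodes.tsv",
            "cohort_beta": "cohort_beta.tsv",
            "cohort_labels": "cohort_labels.tsv",
        },
        "thresholds": {
            "deg_lfc": 1.5,
            "deg_alpha": 0.05,
            "meth_fold_change": 1.5,
            "meth_alpha": 1.0e-4,
            "corr_alpha": 0.05,
            "region_corr_threshold": 0.4,
            "cma_corr_threshold": 0.18,
            "window_enrichment": 200,
            "window_cma": 500,
            "fmatch_alpha": 0.05,
            "fmatch_criterion": "sequence",
            "tf_expr_lfc": 1.0,
            "tf_meth_lfc": 0.585,
            "context_lfc": 1.0,
            "keynode_radius": 10,
            "context_discount": 0.5,
            "keynode_top_n": 3,
            "loop_max_len": 6,
            "panel_corr_threshold": 0.8,
            "panel_splits": 100,
            "train_fraction": 0.5,
        },
        "ga": {
            "population_size": 16,
            "generations": 12,
            "n_modules": 2,
            "max_pwms_per_module": 3,
            "seed": int(seed),
        },
    }
    config_path = outdir / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    truth = {
        "planted_probes": signal_probes,
        "planted_pwms": ["PWM_TFA", "PWM_TFB"],
        "tf_genes": tf_genes,
        "regulator": "REG",
        "regulator_gene": mreg_gene,
        "loop_nodes": ["REG", "TFA", "gene_MREG_locus"],
        "seed": int(seed),
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return {"config": str(config_path), "truth": truth, "outdir": str(outdir)}


def gen_cohort(
    n_case: int = 12,
    n_control: int = 12,
    n_markers: int = 6,
    effects=0.5,
    noise_sd: float = 0.05,
    baseline: float = 0.1,
    seed: int = 0,
    marker_ids: list[str] | None = None,
) -> tuple[SampleMatrix, pd.Series]:
    """Two-class beta-value cohort: controls around ``baseline``, cases
    shifted by per-marker ``effects`` (hypermethylation), clipped to [0, 1].
    """
    rng = _rng(seed)
    effects = np.broadcast_to(np.asarray(effects, dtype=float), (n_markers,))
    probes = marker_ids if marker_ids is not None else [f"cg{i:05d}" for i in range(n_markers)]
    samples = [f"case_{i:02d}" for i in range(n_case)] + [
        f"ctrl_{i:02d}" for i in range(n_control)
    ]
    labels = pd.Series(["case"] * n_case + ["control"] * n_control, index=samples, name="label")
    base = rng.normal(baseline, noise_sd, size=(n_markers, n_case + n_control))
    base[:, :n_case] += effects[:, None]
    values = pd.DataFrame(np.clip(base, 0.0, 1.0), index=probes, columns=samples)
    return SampleMatrix(values, kind="beta"), labels
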