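"""End-to-end orchestration of the walking-pathways workflow.

Stages, in order: differential expression -> differential methylation ->
CpG-gene correlation (NEG/POS split by rho sign) -> region construction ->
motif enrichment (F-Match) + composite-module optimization (CMAcorrel) ->
TF candidate filtering -> context-weighted master-regulator search with
positive-feedback-loop detection -> candidate biomarker CpG table ->
marker decorrelation -> panel evaluation. Every stage writes a TSV; a run
log records seed and parameters; inputs are never mutated.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cma_correl import FitnessParams, GAConfig, ScoredDataset, ga_optimize, score_and_report
from .enrichment import fmatch
from .io_formats import (
    SampleMatrix,
    Sequence,
    SequenceSet,
    read_fasta,
    read_matrix,
    read_network,
    read_node_annotations,
    read_pwm_collection,
    write_bed,
    write_table,
)
from .marker_selection import decorrelate, evaluate_panel, marker_correlation
from .master_regulators import apply_context, find_feedback_loops, keynode_search, prioritize
from .omics_prep import cpg_gene_correlation, differential, filter_features, regions_around
from .pwm_scan import encode, window_scores

logger = logging.getLogger(__name__)

_REQUIRED_PATHS = (
    "expr_case", "expr_control", "meth_case", "meth_control", "annotation",
    "sequences", "pwms", "pwm_tf_map", "network", "nodes", "cohort_beta",
    "cohort_labels",
)

DEFAULT_THRESHOLDS = {
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
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (paths resolved against a base dir)."""

    paths: dict[str, Path]
    thresholds: dict = field(default_factory=dict)
    ga: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        self.thresholds = merged
        t = self.thresholds
        if not 0 < t["deg_alpha"] <= 1 or not 0 < t["meth_alpha"] <= 1:
            raise ValueError("alpha thresholds must lie in (0, 1]")
        if t["meth_fold_change"] <= 1:
            raise ValueError("meth_fold_change must be > 1")
        if not 0 < t["context_discount"] <= 1:
            raise ValueError("context_discount must lie in (0, 1]")
        if t["fmatch_criterion"] not in ("site", "sequence"):
            raise ValueError("fmatch_criterion must be 'site' or 'sequence'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = path.parent
        paths = {k: base / v for k, v in raw.get("paths", {}).items() if k != "pwm_dialect"}
        missing = [k for k in _REQUIRED_PATHS if k not in paths]
        if missing:
            raise ValueError(f"config missing input paths: {missing}")
        absent = [str(p) for k, p in paths.items() if not Path(p).exists()]
        if absent:
            raise FileNotFoundError(f"input files not found: {absent}")
        cfg = cls(
            paths=paths,
            thresholds=raw.get("thresholds", {}),
            ga=raw.get("ga", {}),
            seed=int(raw.get("seed", 0)),
        )
        cfg.pwm_dialect = raw.get("paths", {}).get("pwm_dialect", "jaspar")
        return cfg


def _central_slice(seq: Sequence, window: int) -> Sequence:
    length = len(seq.residues)
    if length <= window:
        return seq
    start = (length - window) // 2
    return Sequence(seq.id, seq.residues[start : start + window])


def _max_score(pwm, seq: Sequence) -> float:
    codes = encode(seq.residues)
    if codes.size < pwm.length:
        return 0.0
    return max(
        float(window_scores(pwm, codes, s).max()) for s in ("+", "-")
    )


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage; returns the JSON-ready summary dict.

    Any stage failure aborts with the stage name in the exception; partial
    outputs written so far are retained in ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t = config.thresholds
    seed = config.seed

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("pathwalker")
    root.addHandler(handler)
    old_level = root.level
    if root.getEffectiveLevel() > logging.INFO:
        root.setLevel(logging.INFO)
    summary: dict = {"version": __version__, "seed": seed, "thresholds": t, "stages": {}}
    stage = "load_inputs"
    try:
        logger.info("pipeline start: seed=%d thresholds=%s", seed, t)
        expr_case = read_matrix(config.paths["expr_case"], kind="expression")
        expr_ctrl = read_matrix(config.paths["expr_control"], kind="expression")
        meth_case = read_matrix(config.paths["meth_case"], kind="beta")
        meth_ctrl = read_matrix(config.paths["meth_control"], kind="beta")
        ann = pd.read_csv(config.paths["annotation"], sep="\t", dtype={"probe": str})
        seqs = read_fasta(config.paths["sequences"])
        pwms = read_pwm_collection(
            config.paths["pwms"], dialect=getattr(config, "pwm_dialect", "jaspar")
        )
        pwm_tf = pd.read_csv(config.paths["pwm_tf_map"], sep="\t")
        network = read_network(config.paths["network"])
        for node, info in read_node_annotations(config.paths["nodes"]).items():
            network.set_annotation(node, kind=info["kind"], gene=info["gene"])
        cohort = read_matrix(config.paths["cohort_beta"], kind="beta")
        labels = pd.read_csv(
            config.paths["cohort_labels"], sep="\t", index_col=0
        )["label"]

        stage = "differential_expression"
        deg = differential(expr_case, expr_ctrl)
        up, down = filter_features(deg, t["deg_lfc"], -t["deg_lfc"], t["deg_alpha"])
        write_table(outdir / "degs.tsv", deg, index_label="gene")
        summary["stages"][stage] = {"up": len(up), "down": len(down)}

        stage = "differential_methylation"
        meth_diff = differential(meth_case, meth_ctrl)
        lfc_cut = math.log2(t["meth_fold_change"])
        dm_up, dm_down = filter_features(meth_diff, lfc_cut, -lfc_cut, t["meth_alpha"])
        dm_probes = sorted(dm_up + dm_down)
        no_probes = [p for p in meth_diff.index if p not in set(dm_probes)]
        write_table(outdir / "meth_diff.tsv", meth_diff, index_label="probe")
        summary["stages"][stage] = {"hyper": len(dm_up), "hypo": len(dm_down)}

        stage = "cpg_gene_correlation"
        meth_all = SampleMatrix(
            pd.concat([meth_case.values, meth_ctrl.values], axis=1), kind="beta"
        )
        expr_all = SampleMatrix(
            pd.concat([expr_case.values, expr_ctrl.values], axis=1), kind="expression"
        )
        gene_of_probe = dict(zip(ann["probe"], ann["gene"]))
        pairs = [(p, gene_of_probe[p]) for p in dm_probes if p in gene_of_probe]
        records = cpg_gene_correlation(meth_all, expr_all, pairs, alpha=t["corr_alpha"])
        corr_df = pd.DataFrame(
            [
                {"probe": r.probe_id, "gene": r.gene_id, "rho": r.rho,
                 "n": r.n_samples, "passes": r.passes}
                for r in records
            ]
        ).set_index("probe")
        write_table(outdir / "correlations.tsv", corr_df, index_label="probe")
        rho_of = corr_df["rho"].to_dict()
        neg = [p for p in dm_probes if rho_of.get(p, 0.0) < -t["region_corr_threshold"]]
        pos = [p for p in dm_probes if rho_of.get(p, 0.0) > t["region_corr_threshold"]]
        cma_probes = [p for p in dm_probes if abs(rho_of.get(p, 0.0)) > t["cma_corr_threshold"]]
        summary["stages"][stage] = {"neg": len(neg), "pos": len(pos), "cma_set": len(cma_probes)}

        stage = "region_construction"
        pos_of = dict(zip(ann["probe"], zip(ann["chrom"], ann["position"])))
        for name, probe_list, window in (
            ("regions_neg.bed", neg, t["window_enrichment"]),
            ("regions_pos.bed", pos, t["window_enrichment"]),
            ("regions_cma.bed", cma_probes, t["window_cma"]),
        ):
            intervals = regions_around([pos_of[p] for p in probe_list if p in pos_of], window)
            write_bed(outdir / name, intervals)

        stage = "fmatch"
        rng = np.random.default_rng(seed)
        no_sample = list(no_probes)
        if len(no_sample) > 400:
            no_sample = sorted(rng.choice(no_sample, size=400, replace=False).tolist())
        no_set = SequenceSet(
            _central_slice(seqs[p], t["window_enrichment"]) for p in no_sample if p in seqs
        )
        enriched_pwms: dict[str, float] = {}
        fmatch_tables = {}
        for label, probe_list in (("neg", neg), ("pos", pos)):
            yes_set = SequenceSet(
                _central_slice(seqs[p], t["window_enrichment"]) for p in probe_list if p in seqs
            )
            if len(yes_set) == 0 or len(no_set) == 0:
                fmatch_tables[label] = pd.DataFrame()
                continue
            table = fmatch(
                pwms, yes_set, no_set,
                criterion=t["fmatch_criterion"], alpha=t["fmatch_alpha"],
            )
            table.to_csv(outdir / f"fmatch_{label}.tsv", sep="\t", index=False,
                         float_format="%.6g")
            fmatch_tables[label] = table
            for _, row in table.iterrows():
                if row["p_adjusted"] < t["fmatch_alpha"] and row["significant"]:
                    prev = enriched_pwms.get(row["pwm_id"])
                    cut = float(row["optimized_cutoff"])
                    enriched_pwms[row["pwm_id"]] = min(prev, cut) if prev is not None else cut
        summary["stages"][stage] = {"enriched_pwms": sorted(enriched_pwms)}

        stage = "cma_correl"
        model_pwm_ids: list[str] = []
        cma_rho = None
        cma_values = [rho_of[p] for p in cma_probes if p in seqs]
        cma_seqs = [seqs[p] for p in cma_probes if p in seqs]
        if len(cma_seqs) >= 3 and len(set(cma_values)) > 1:
            dataset = ScoredDataset(
                list(zip(cma_seqs, cma_values)),
                value_semantics="methylation-expression Spearman rho",
            )
            ga_cfg = GAConfig(**{"seed": seed, **config.ga})
            model, trajectory, cma_rho = ga_optimize(dataset, pwms, ga_cfg, FitnessParams())
            model.to_json(outdir / "cma_model.json")
            report, _ = score_and_report(model, cma_seqs, pwms, dataset)
            report.to_csv(outdir / "cma_report.tsv", sep="\t", index=False,
                          float_format="%.6g")
            model_pwm_ids = sorted({pid for m in model.modules for pid in m.pwm_ids})
        summary["stages"][stage] = {"model_pwms": model_pwm_ids, "rho": cma_rho}

        stage = "tf_candidates"
        gene_meth_lfc: dict[str, float] = {}
        for probe, gene in gene_of_probe.items():
            if probe in meth_diff.index:
                lfc = abs(float(meth_diff.loc[probe, "logFC"]))
                gene_meth_lfc[gene] = max(gene_meth_lfc.get(gene, 0.0), lfc)
        candidate_pwms = set(enriched_pwms) | set(model_pwm_ids)
        tf_rows = []
        for _, row in pwm_tf.iterrows():
            if row["pwm_id"] not in candidate_pwms:
                continue
            gene = row["tf_gene"]
            e_lfc = float(deg.loc[gene, "logFC"]) if gene in deg.index else 0.0
            m_lfc = gene_meth_lfc.get(gene, 0.0)
            if abs(e_lfc) >= t["tf_expr_lfc"] or m_lfc >= t["tf_meth_lfc"]:
                tf_rows.append(
                    {"pwm_id": row["pwm_id"], "tf_gene": gene, "tf_node": row["tf_node"],
                     "expression_logFC": e_lfc, "methylation_logFC": m_lfc}
                )
        tf_table = pd.DataFrame(
            tf_rows, columns=["pwm_id", "tf_gene", "tf_node", "expression_logFC",
                              "methylation_logFC"]
        )
        tf_table.to_csv(outdir / "tf_candidates.tsv", sep="\t", index=False,
                        float_format="%.6g")
        summary["stages"][stage] = {"n_tfs": len(tf_table)}

        stage = "keynode_search"
        master_genes: list[str] = []
        keynode_table = pd.DataFrame()
        input_nodes = [n for n in tf_table["tf_node"] if n in network.graph]
        if input_nodes:
            up_context = deg.index[
                (deg["p_adjusted"] < t["deg_alpha"]) & (deg["logFC"] > t["context_lfc"])
            ]
            context_nodes = {
                n for n in network.graph.nodes if network.gene_of(n) in set(up_context)
            }
            weighted = apply_context(network, context_nodes, t["context_discount"])
            results = keynode_search(weighted, input_nodes, radius=t["keynode_radius"])
            keynode_table = pd.DataFrame(
                [
                    {"node": r.node, "gene": network.gene_of(r.node) or r.node,
                     "score": r.score, "n_inputs_reached": len(r.reached_inputs),
                     "total_reachable": r.total_reachable}
                    for r in results
                ]
            )
            keynode_table.to_csv(outdir / "keynodes.tsv", sep="\t", index=False,
                                 float_format="%.6g")
            loop_rows = []
            for r in results[: t["keynode_top_n"]]:
                for loop in find_feedback_loops(
                    network, r.node, max_len=t["loop_max_len"], context_nodes=context_nodes
                ):
                    loop_rows.append(
                        {"keynode": r.node, "cycle": "->".join(loop.nodes),
                         "positive": loop.positive,
                         "context_nodes": loop.context_nodes_on_loop}
                    )
            pd.DataFrame(
                loop_rows, columns=["keynode", "cycle", "positive", "context_nodes"]
            ).to_csv(outdir / "feedback_loops.tsv", sep="\t", index=False)
            gene_meth_table = pd.DataFrame(
                {"logFC": [gene_meth_lfc.get(g, 0.0) for g in deg.index]}, index=deg.index
            )
            mr_table = prioritize(
                results, deg, gene_meth_table, network,
                expression_lfc_threshold=t["tf_expr_lfc"],
                methylation_lfc_threshold=0.0,
            )
            mr_table.to_csv(outdir / "master_regulators.tsv", sep="\t", index=False,
                            float_format="%.6g")
            master_genes = mr_table["gene"].head(t["keynode_top_n"]).tolist()
        summary["stages"][stage] = {"n_keynodes": len(keynode_table),
                                    "master_genes": master_genes}

        stage = "biomarker_table"
        selected_pwm_cutoffs = {
            row["pwm_id"]: enriched_pwms.get(row["pwm_id"], 0.9)
            for _, row in tf_table.iterrows()
        }
        pwm_by_id = {p.id: p for p in pwms}
        bio_rows = []
        for probe in dm_probes:
            if abs(rho_of.get(probe, 0.0)) <= t["cma_corr_threshold"]:
                continue
            has_site = False
            if probe in seqs:
                win = _central_slice(seqs[probe], t["window_enrichment"])
                for pid, cutoff in selected_pwm_cutoffs.items():
                    if _max_score(pwm_by_id[pid], win) >= cutoff:
                        has_site = True
                        break
            gene = gene_of_probe.get(probe)
            is_master = gene in set(master_genes)
            if has_site or is_master:
                bio_rows.append(
                    {"probe": probe, "gene": gene,
                     "methylation_logFC": float(meth_diff.loc[probe, "logFC"]),
                     "rho": rho_of.get(probe), "tf_site": has_site,
                     "master_regulator_gene": is_master}
                )
        bio_table = pd.DataFrame(
            bio_rows, columns=["probe", "gene", "methylation_logFC", "rho", "tf_site",
                               "master_regulator_gene"]
        )
        bio_table.to_csv(outdir / "biomarkers.tsv", sep="\t", index=False,
                         float_format="%.6g")
        summary["stages"][stage] = {"n_biomarkers": len(bio_table)}

        stage = "panel"
        panel_probes: list[str] = []
        panel_mean = panel_sd = float("nan")
        candidates = [p for p in bio_table["probe"] if p in cohort.values.index]
        if len(candidates) >= 1:
            sub = cohort.subset(candidates)
            if len(candidates) >= 2:
                corr = marker_correlation(sub)
                effects = {
                    p: abs(float(meth_diff.loc[p, "logFC"])) for p in candidates
                }
                panel_probes = decorrelate(
                    candidates, corr, effects, threshold=t["panel_corr_threshold"]
                )
            else:
                panel_probes = candidates
            panel_mean, panel_sd, per_split = evaluate_panel(
                cohort.subset(panel_probes), labels,
                n_splits=t["panel_splits"], train_fraction=t["train_fraction"],
                seed=seed,
            )
            pd.DataFrame(
                {"split": range(1, len(per_split) + 1), "accuracy": per_split}
            ).to_csv(outdir / "panel_splits.tsv", sep="\t", index=False,
                     float_format="%.6g")
        pd.DataFrame({"probe": panel_probes}).to_csv(
            outdir / "panel.tsv", sep="\t", index=False
        )
        summary["stages"][stage] = {
            "panel": panel_probes, "mean_accuracy": panel_mean, "sd_accuracy": panel_sd,
        }

        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=str)
        logger.info("pipeline finished: %s", summary["stages"]["panel"])
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        root.setLevel(old_level)
        root.removeHandler(handler)
        handler.close()
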