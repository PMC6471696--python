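"""Master-regulator (key-node) search over weighted, signed signaling graphs.

A candidate node is ranked by how cheaply it reaches a given set of input
transcription factors within a bounded number of steps, normalized by how
many nodes it reaches overall:

    score(k) = sum_{t reached} 1 / (1 + cost(k -> t)) / total_reachable(k)

The "context" variant discounts edges adjacent to up-regulated gene
products, biasing shortest paths through active parts of the network and,
combined with TF -> gene -> protein closure edges, toward positive
feedback loops (self-activating circuits).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

NODE_KINDS = ("protein", "complex", "gene", "TF")


class SignalingGraph:
    """Directed, signed, strictly positively weighted reaction network."""

    def __init__(self) -> None:
        self.graph = nx.DiGraph()

    def add_node(self, node: str, kind: str = "protein", gene: str | None = None) -> None:
        if kind not in NODE_KINDS:
            raise ValueError(f"unknown node kind {kind!r}")
        self.graph.add_node(node, kind=kind, gene=gene)

    def add_edge(self, source: str, target: str, sign: int = 1, cost: float = 1.0) -> None:
        if cost <= 0:
            raise ValueError("edge cost must be > 0")
        if sign not in (1, -1):
            raise ValueError("edge sign must be +1 or -1")
        for n in (source, target):
            if n not in self.graph:
                self.graph.add_node(n, kind="protein", gene=None)
        self.graph.add_edge(source, target, sign=sign, cost=cost)

    def kind(self, node: str) -> str:
        return self.graph.nodes[node].get("kind", "protein")

    def gene_of(self, node: str) -> str | None:
        return self.graph.nodes[node].get("gene")

    def set_annotation(self, node: str, kind: str | None = None, gene: str | None = None) -> None:
        if node not in self.graph:
            self.graph.add_node(node)
        if kind is not None:
            if kind not in NODE_KINDS:
                raise ValueError(f"unknown node kind {kind!r}")
            self.graph.nodes[node]["kind"] = kind
        if gene is not None:
            self.graph.nodes[node]["gene"] = gene

    def copy(self) -> "SignalingGraph":
        clone = SignalingGraph()
        clone.graph = self.graph.copy()
        return clone

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def is_regulatory_edge(self, u: str, v: str) -> bool:
        """A TF -> gene edge (the transcription-regulation layer)."""
        return self.kind(u) == "TF" and self.kind(v) == "gene"


@dataclass
class KeyNodeResult:
    node: str
    score: float
    reached_inputs: dict[str, float]  # input TF -> min path cost
    total_reachable: int
    radius: int
    subnetwork: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class FeedbackLoop:
    nodes: list[str]  # closed walk, first == last
    sign_product: int
    contains_regulatory_edge: bool
    context_nodes_on_loop: int = 0

    @property
    def positive(self) -> bool:
        return self.sign_product == 1

    def __len__(self) -> int:
        return len(self.nodes) - 1


def apply_context(
    graph: SignalingGraph, context_nodes, discount: float
) -> SignalingGraph:
    """Multiply the cost of every edge adjacent to a context node by ``discount``.

    Context nodes are products of up-regulated genes; "adjacent" covers both
    incoming and outgoing edges. The input graph is not mutated. Unknown
    context ids are ignored with a warning.
    """
    if not 0 < discount <= 1:
        raise ValueError("discount must lie in (0, 1]")
    context = set(context_nodes)
    unknown = context - set(graph.graph.nodes)
    if unknown:
        logger.warning("ignoring %d unknown context nodes: %s", len(unknown), sorted(unknown)[:5])
        context -= unknown
    out = graph.copy()
    if discount == 1.0 or not context:
        return out
    for u, v, data in out.graph.edges(data=True):
        if u in context or v in context:
            data["cost"] = data["cost"] * discount
    return out


def _bounded_shortest_paths(graph: nx.DiGraph, source: str, radius: int, max_cost: float):
    """Min-cost paths from ``source`` using at most ``radius`` edges.

    Layered Bellman-Ford DP: ``dist[h][v]`` = min cost over paths of <= h
    edges, with per-layer parent pointers for path reconstruction.
    Returns (best_cost, path_reconstructor).
    """
    dist = [{source: 0.0}]
    parents: list[dict[str, str]] = [{}]
    for _ in range(radius):
        prev = dist[-1]
        curr = dict(prev)
        par = dict(parents[-1])
        for u, du in prev.items():
            for v, data in graph[u].items():
                d = du + data["cost"]
                if d <= max_cost and d < curr.get(v, float("inf")) - 1e-15:
                    curr[v] = d
                    par[v] = u
        dist.append(curr)
        parents.append(par)
        if curr == prev:
            break
    best = dist[-1]

    def path_to(v: str) -> list[str]:
        par = parents[-1]
        path = [v]
        while path[-1] != source:
            path.append(par[path[-1]])
        return path[::-1]

    return best, path_to


def keynode_search(
    graph: SignalingGraph,
    input_tfs,
    radius: int = 10,
    max_path_cost: float = float("inf"),
) -> list[KeyNodeResult]:
    """Rank every node by the weighted ratio of cheaply reached input TFs.

    Each candidate's min-cost paths (bounded by ``radius`` edges and
    ``max_path_cost``) to the input TFs are found; its score is the sum of
    1/(1 + cost) over reached inputs divided by the total number of other
    nodes it reaches. Nodes reaching no input are omitted. Sorted by
    descending score, ties to more reached inputs, then lexicographic id.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    inputs = list(dict.fromkeys(input_tfs))
    if not inputs:
        raise ValueError("input TF set must be non-empty")
    missing = [t for t in inputs if t not in graph.graph]
    if missing:
        raise ValueError(f"input TFs not in graph: {missing}")
    results = []
    for node in graph.graph.nodes:
        best, path_to = _bounded_shortest_paths(graph.graph, node, radius, max_path_cost)
        reached = {t: best[t] for t in inputs if t in best}
        if not reached:
            continue
        total_reachable = sum(1 for v in best if v != node)
        if total_reachable == 0:
            continue
        weight = sum(1.0 / (1.0 + cost) for cost in reached.values())
        subnet: list[tuple[str, str]] = []
        seen = set()
        for t in reached:
            path = path_to(t)
            for u, v in zip(path, path[1:]):
                if (u, v) not in seen:
                    seen.add((u, v))
                    subnet.append((u, v))
        results.append(
            KeyNodeResult(
                node=node,
                score=weight / total_reachable,
                reached_inputs=reached,
                total_reachable=total_reachable,
                radius=radius,
                subnetwork=subnet,
            )
        )
    results.sort(key=lambda r: (-r.score, -len(r.reached_inputs), r.node))
    return results


def find_feedback_loops(
    graph: SignalingGraph,
    keynode: str,
    max_len: int = 6,
    context_nodes=(),
) -> list[FeedbackLoop]:
    """All simple cycles through ``keynode`` (<= max_len edges) crossing the
    transcription-regulation layer (at least one TF -> gene edge).

    The sign product classifies each loop: +1 = positive (self-activating)
    feedback. Requires gene -> product closure edges to be present.
    """
    if max_len < 2:
        raise ValueError("max_len must be >= 2")
    context = set(context_nodes)
    loops = []
    for cycle in nx.simple_cycles(graph.graph, length_bound=max_len):
        if keynode not in cycle:
            continue
        # rotate so the cycle starts at the keynode
        i = cycle.index(keynode)
        cycle = cycle[i:] + cycle[:i]
        closed = cycle + [cycle[0]]
        sign = 1
        has_reg = False
        for u, v in zip(closed, closed[1:]):
            sign *= graph.graph[u][v]["sign"]
            if graph.is_regulatory_edge(u, v):
                has_reg = True
        if not has_reg:
            continue
        loops.append(
            FeedbackLoop(
                nodes=closed,
                sign_product=sign,
                contains_regulatory_edge=True,
                context_nodes_on_loop=len(context & set(cycle)),
            )
        )
    loops.sort(key=lambda l: (len(l), l.nodes))
    return loops


def prioritize(
    results: list[KeyNodeResult],
    expression: pd.DataFrame,
    methylation: pd.DataFrame,
    graph: SignalingGraph,
    expression_lfc_threshold: float = 1.0,
    methylation_lfc_threshold: float = 0.0,
) -> pd.DataFrame:
    """Filter ranked key nodes by differential expression / methylation of
    their genes; aggregate isoform nodes to genes (best score kept).

    ``expression`` / ``methylation`` are DiffResult tables indexed by gene id
    with a ``logFC`` column. Rows without a joinable gene are dropped with a
    warning. Output mirrors the master-regulator summary: score, expression
    logFC, methylation logFC, number of reached input TFs.
    """
    rows = []
    for res in results:
        gene = graph.gene_of(res.node) or res.node
        if gene not in expression.index or gene not in methylation.index:
            logger.warning("dropping key node %s: gene %s not joinable", res.node, gene)
            continue
        e_lfc = float(expression.loc[gene, "logFC"])
        m_lfc = float(methylation.loc[gene, "logFC"])
        if abs(e_lfc) < expression_lfc_threshold:
            continue
        if abs(m_lfc) < methylation_lfc_threshold:
            continue
        rows.append(
            {
                "node": res.node,
                "gene": gene,
                "score": res.score,
                "expression_logFC": e_lfc,
                "methylation_logFC": m_lfc,
                "n_target_tfs": len(res.reached_inputs),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["node", "gene", "score", "expression_logFC", "methylation_logFC", "n_target_tfs"],
    )
    if table.empty:
        return table
    table = table.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
    table = table.groupby("gene", sort=False).first().reset_index()
    return table.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort").reset_index(drop=True)
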