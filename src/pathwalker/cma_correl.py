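"""Composite-module models whose score correlates with a quantitative trait.

A composite module (CM) is a set of PWMs with per-PWM score cutoffs and
top-match counts, plus a Gaussian width sigma. Its score on a sequence is
the maximum over anchor positions x of the sum of site scores weighted by
a normal density of the site-center distance to x — sites clustered around
a common position contribute most. A full regulatory model sums the scores
of T modules. Model parameters are optimized by a genetic algorithm whose
fitness is a complexity-penalized transform of the Spearman rank
correlation between model scores and per-sequence quantitative values
(expression log-fold-change, methylation-expression correlation, ...):

    fitness = -complexity^(-penalty) * log10(1 - |rho|)
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence as TSequence

import numpy as np
from scipy import stats

from .io_formats import Sequence
from .pwm_scan import PWM, SiteMatch, encode, top_matches, window_scores

SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class CompositeModule:
    """A duplet of PWM ids and parameters (cutoffs, top counts, width sigma)."""

    pwm_ids: tuple[str, ...]
    cutoffs: tuple[float, ...]
    top_counts: tuple[int, ...]
    sigma: float

    def __post_init__(self) -> None:
        k = len(self.pwm_ids)
        if k < 1:
            raise ValueError("a composite module needs at least one PWM")
        if len(self.cutoffs) != k or len(self.top_counts) != k:
            raise ValueError("cutoffs and top_counts must align with pwm_ids")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if any(t < 1 for t in self.top_counts):
            raise ValueError("top counts must be >= 1")


@dataclass(frozen=True)
class RegulatoryModel:
    """An ordered list of composite modules plus a reporting threshold."""

    modules: tuple[CompositeModule, ...]
    cm_score_cutoff: float = 0.0

    def __post_init__(self) -> None:
        if len(self.modules) < 1:
            raise ValueError("a model needs at least one module")

    @property
    def complexity(self) -> int:
        """Number of distinct PWM ids across all modules."""
        return len({pid for m in self.modules for pid in m.pwm_ids})

    def to_dict(self) -> dict:
        return {
            "cm_score_cutoff": self.cm_score_cutoff,
            "modules": [
                {
                    "pwm_ids": list(m.pwm_ids),
                    "cutoffs": list(m.cutoffs),
                    "top_counts": list(m.top_counts),
                    "sigma": m.sigma,
                }
                for m in self.modules
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RegulatoryModel":
        modules = tuple(
            CompositeModule(
                tuple(m["pwm_ids"]), tuple(m["cutoffs"]), tuple(m["top_counts"]), m["sigma"]
            )
            for m in data["modules"]
        )
        return cls(modules, data.get("cm_score_cutoff", 0.0))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass
class ScoredDataset:
    """Pairs (sequence, value) linking regulatory regions to a trait."""

    entries: list[tuple[Sequence, float]]
    value_semantics: str = "value"

    def __post_init__(self) -> None:
        if len(self.entries) < 3:
            raise ValueError("need at least 3 entries for fitness evaluation")
        values = [v for _, v in self.entries]
        if len(set(values)) == 1:
            raise ValueError("values must not all be identical")

    @property
    def sequences(self) -> list[Sequence]:
        return [s for s, _ in self.entries]

    @property
    def values(self) -> np.ndarray:
        return np.asarray([v for _, v in self.entries], dtype=float)


@dataclass(frozen=True)
class FitnessParams:
    penalty: float = 1.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.penalty) or self.penalty < 0:
            raise ValueError("penalty must be finite and >= 0")


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm hyperparameters (all exposed, seeded)."""

    population_size: int = 50
    generations: int = 200
    rate_add_pwm: float = 0.2
    rate_drop_pwm: float = 0.2
    rate_perturb_cutoff: float = 0.3
    rate_perturb_sigma: float = 0.3
    rate_perturb_kappa: float = 0.3
    elitism: int = 2
    tournament_size: int = 3
    n_modules: int = 2
    max_pwms_per_module: int = 10
    sigma_bounds: tuple[float, float] = (10.0, 150.0)
    sigma_init: float = 30.0
    kappa_max: int = 3
    cutoff_floor: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        rates = (
            self.rate_add_pwm, self.rate_drop_pwm, self.rate_perturb_cutoff,
            self.rate_perturb_sigma, self.rate_perturb_kappa,
        )
        if any(not 0 <= r <= 1 for r in rates):
            raise ValueError("mutation rates must lie in [0, 1]")
        if self.population_size < self.elitism:
            raise ValueError("population_size must be >= elitism")
        if self.sigma_bounds[0] <= 0 or self.sigma_bounds[0] > self.sigma_bounds[1]:
            raise ValueError("invalid sigma bounds")


def gaussian_density(d, sigma: float):
    """Normal density N(0, sigma^2) evaluated at distance d."""
    d = np.asarray(d, dtype=float)
    return np.exp(-0.5 * (d / sigma) ** 2) / (sigma * SQRT_2PI)


def cm_score(
    matches_by_pwm: dict[str, list[SiteMatch]],
    module: CompositeModule,
    seq_length: int,
    pwm_lengths: dict[str, int],
) -> tuple[float, int]:
    """Module score of one sequence: max over x of the Gaussian-weighted site sum.

    For each module PWM, matches below the module cutoff are discarded and
    only the top-kappa highest-scoring kept; each retained match contributes
    score * N(0, sigma^2) at its window-center distance from x. Ties in x
    break to the smallest position. No retained matches => (0.0, 0).
    """
    qs: list[float] = []
    cs: list[int] = []
    for pid, cutoff, kappa in zip(module.pwm_ids, module.cutoffs, module.top_counts):
        kept = [m for m in matches_by_pwm.get(pid, []) if m.score >= cutoff]
        for m in top_matches(kept, kappa):
            qs.append(m.score)
            cs.append(m.center(pwm_lengths[pid]))
    if not qs:
        return 0.0, 0
    x = np.arange(seq_length)
    total = np.zeros(seq_length)
    for q, c in zip(qs, cs):
        total += q * gaussian_density(np.abs(x - c), module.sigma)
    x_max = int(np.argmax(total))  # first maximum = smallest x on ties
    return float(total[x_max]), x_max


def reg_score(
    model: RegulatoryModel,
    matches_by_pwm: dict[str, list[SiteMatch]],
    seq_length: int,
    pwm_lengths: dict[str, int],
) -> float:
    """Additive model score: the sum of the T module scores."""
    return sum(
        cm_score(matches_by_pwm, module, seq_length, pwm_lengths)[0]
        for module in model.modules
    )


def spearman(xs, ys) -> float:
    """Spearman rank correlation (average ranks on ties)."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.ndim != 1:
        raise ValueError("inputs must be 1-D and of equal length")
    if xs.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("spearman undefined for constant input")
    return float(stats.spearmanr(xs, ys).statistic)


def fitness_value(rho: float, complexity: int, penalty: float) -> float:
    """-complexity^(-penalty) * log10(1 - |rho|), with |rho|=1 clamped."""
    r = min(abs(rho), 1.0 - 1e-12)
    return -(complexity ** (-penalty)) * math.log10(1.0 - r)


# ---------------------------------------------------------------------------
# Match cache: each PWM is scanned once per sequence at a global score floor;
# module-level cutoffs and top counts are applied by slicing the cache.


class MatchCache:
    """Per-(PWM, sequence) match arrays sorted like ``top_matches`` output."""

    def __init__(self, pwms: TSequence[PWM], sequences: TSequence[Sequence],
                 floor: float = 0.5, both_strands: bool = True):
        self.pwm_ids = [p.id for p in pwms]
        self.pwm_lengths = {p.id: p.length for p in pwms}
        self.seq_lengths = np.asarray([len(s) for s in sequences])
        self.max_len = int(self.seq_lengths.max()) if len(sequences) else 0
        self.floor = floor
        # entries[pwm_index][seq_index] = (neg_scores_sorted, centers)
        self.entries: list[list[tuple[np.ndarray, np.ndarray]]] = []
        for pwm in pwms:
            per_seq = []
            half = pwm.length // 2
            for seq in sequences:
                codes = encode(seq.residues)
                if codes.size < pwm.length:
                    per_seq.append((np.empty(0), np.empty(0, dtype=int)))
                    continue
                pos_list, strand_list, score_list = [], [], []
                strands = ("+", "-") if both_strands else ("+",)
                for si, strand in enumerate(strands):
                    scores = window_scores(pwm, codes, strand)
                    keep = np.flatnonzero(scores >= floor)
                    pos_list.append(keep)
                    strand_list.append(np.full(keep.size, si))
                    score_list.append(scores[keep])
                pos = np.concatenate(pos_list)
                strand_idx = np.concatenate(strand_list)
                score = np.concatenate(score_list)
                order = np.lexsort((strand_idx, pos, -score))
                per_seq.append((-score[order], pos[order] + half))
            self.entries.append(per_seq)

    def module_scores(self, pwm_indices, cutoffs, kappas, sigma: float) -> np.ndarray:
        """cm_score of one module for every cached sequence (vectorized core)."""
        n = len(self.seq_lengths)
        out = np.zeros(n)
        off = self.max_len - 1
        ext = gaussian_density(np.abs(np.arange(-off, self.max_len)), sigma)
        for s in range(n):
            length = int(self.seq_lengths[s])
            acc = None
            for pi, cutoff, kappa in zip(pwm_indices, cutoffs, kappas):
                neg_q, centers = self.entries[pi][s]
                cnt = int(np.searchsorted(neg_q, -cutoff, side="right"))
                cnt = min(cnt, kappa)
                for j in range(cnt):
                    c = int(centers[j])
                    view = ext[off - c : off - c + length]
                    if acc is None:
                        acc = -neg_q[j] * view
                    else:
                        acc = acc + (-neg_q[j]) * view
            if acc is not None:
                out[s] = acc.max()
        return out


# ---------------------------------------------------------------------------
# Genetic algorithm


def _genome_key(genome) -> tuple:
    return tuple(
        (mod[0], tuple(round(c, 6) for c in mod[1]), mod[2], round(mod[3], 4))
        for mod in genome
    )


class _GA:
    """Mutation-only GA with tournament selection and elitism."""

    def __init__(self, dataset: ScoredDataset, pwms: TSequence[PWM],
                 config: GAConfig, fit: FitnessParams):
        self.cfg = config
        self.fit = fit
        self.pwms = list(pwms)
        self.values = dataset.values
        self.cache = MatchCache(self.pwms, dataset.sequences, floor=config.cutoff_floor)
        self.rng = np.random.default_rng(config.seed)
        self._memo: dict[tuple, tuple[float, float]] = {}

    # genome: tuple of modules, each (pwm_idx_tuple, cutoffs, kappas, sigma)

    def _random_module(self):
        cfg = self.cfg
        idx = int(self.rng.integers(len(self.pwms)))
        cutoff = float(self.rng.uniform(cfg.cutoff_floor, 0.95))
        kappa = int(self.rng.integers(1, cfg.kappa_max + 1))
        return ((idx,), (cutoff,), (kappa,), cfg.sigma_init)

    def _random_genome(self):
        return tuple(self._random_module() for _ in range(self.cfg.n_modules))

    def _mutate_module(self, mod):
        cfg, rng = self.cfg, self.rng
        idxs, cutoffs, kappas, sigma = list(mod[0]), list(mod[1]), list(mod[2]), mod[3]
        if rng.random() < cfg.rate_add_pwm and len(idxs) < min(cfg.max_pwms_per_module, len(self.pwms)):
            choices = [i for i in range(len(self.pwms)) if i not in idxs]
            if choices:
                i = choices[int(rng.integers(len(choices)))]
                idxs.append(i)
                cutoffs.append(float(rng.uniform(cfg.cutoff_floor, 0.95)))
                kappas.append(int(rng.integers(1, cfg.kappa_max + 1)))
        if rng.random() < cfg.rate_drop_pwm and len(idxs) > 1:
            j = int(rng.integers(len(idxs)))
            del idxs[j], cutoffs[j], kappas[j]
        if rng.random() < cfg.rate_perturb_cutoff:
            j = int(rng.integers(len(idxs)))
            cutoffs[j] = float(np.clip(cutoffs[j] + rng.normal(0, 0.1), cfg.cutoff_floor, 1.0))
        if rng.random() < cfg.rate_perturb_sigma:
            sigma = float(np.clip(sigma + rng.normal(0, 10.0), *cfg.sigma_bounds))
        if rng.random() < cfg.rate_perturb_kappa:
            j = int(rng.integers(len(idxs)))
            kappas[j] = int(np.clip(kappas[j] + rng.choice([-1, 1]), 1, cfg.kappa_max))
        order = np.argsort(idxs, kind="stable")
        return (
            tuple(idxs[o] for o in order),
            tuple(cutoffs[o] for o in order),
            tuple(kappas[o] for o in order),
            sigma,
        )

    def _evaluate(self, genome) -> tuple[float, float]:
        key = _genome_key(genome)
        hit = self._memo.get(key)
        if hit is not None:
            return hit
        scores = np.zeros(len(self.values))
        for mod in genome:
            scores += self.cache.module_scores(*mod)
        if np.ptp(scores) == 0:
            result = (0.0, 0.0)
        else:
            rho = spearman(scores, self.values)
            complexity = len({i for mod in genome for i in mod[0]})
            result = (fitness_value(rho, complexity, self.fit.penalty), rho)
        self._memo[key] = result
        return result

    def run(self):
        cfg = self.cfg
        population = [self._random_genome() for _ in range(cfg.population_size)]
        fitnesses = [self._evaluate(g) for g in population]
        trajectory = []
        for _ in range(cfg.generations):
            order = sorted(
                range(len(population)),
                key=lambda i: (-fitnesses[i][0], _genome_key(population[i])),
            )
            trajectory.append(fitnesses[order[0]][0])
            elites = [population[i] for i in order[: cfg.elitism]]
            new_pop = list(elites)
            while len(new_pop) < cfg.population_size:
                contenders = self.rng.integers(len(population), size=cfg.tournament_size)
                winner = max(contenders, key=lambda i: fitnesses[i][0])
                child = tuple(self._mutate_module(m) for m in population[winner])
                new_pop.append(child)
            population = new_pop
            fitnesses = [self._evaluate(g) for g in population]
        order = sorted(
            range(len(population)),
            key=lambda i: (-fitnesses[i][0], _genome_key(population[i])),
        )
        best = population[order[0]]
        best_fit, best_rho = fitnesses[order[0]]
        trajectory.append(best_fit)
        return best, trajectory, best_rho

    def to_model(self, genome, cm_score_cutoff: float = 0.0) -> RegulatoryModel:
        modules = tuple(
            CompositeModule(
                tuple(self.pwms[i].id for i in mod[0]), mod[1], mod[2], mod[3]
            )
            for mod in genome
        )
        return RegulatoryModel(modules, cm_score_cutoff)


def fitness(
    model: RegulatoryModel,
    dataset: ScoredDataset,
    pwms: TSequence[PWM],
    params: FitnessParams,
) -> float:
    """Fitness of a fixed model on a dataset (scans once, then scores)."""
    pwm_by_id = {p.id: p for p in pwms}
    pwm_lengths = {p.id: p.length for p in pwms}
    from .pwm_scan import scan

    scores = []
    for seq, _ in dataset.entries:
        matches = {
            pid: scan(pwm_by_id[pid], seq, cutoff=0.0)
            for pid in {p for m in model.modules for p in m.pwm_ids}
        }
        scores.append(reg_score(model, matches, len(seq), pwm_lengths))
    if np.ptp(scores) == 0:
        return 0.0
    rho = spearman(scores, dataset.values)
    return fitness_value(rho, model.complexity, params.penalty)


def ga_optimize(
    dataset: ScoredDataset,
    pwm_pool: TSequence[PWM],
    ga: GAConfig = GAConfig(),
    fit: FitnessParams = FitnessParams(),
) -> tuple[RegulatoryModel, list[float], float]:
    """Optimize a regulatory model by a seeded genetic algorithm.

    Returns the best model, the per-generation best-fitness trajectory
    (non-decreasing thanks to elitism) and the final Spearman rho.
    """
    if not pwm_pool:
        raise ValueError("PWM pool must be non-empty")
    engine = _GA(dataset, pwm_pool, ga, fit)
    best_genome, trajectory, best_rho = engine.run()
    return engine.to_model(best_genome), trajectory, best_rho


def score_and_report(
    model: RegulatoryModel,
    sequences: TSequence[Sequence],
    pwms: TSequence[PWM],
    dataset: ScoredDataset | None = None,
    scan_floor: float = 0.0,
):
    """Per-sequence score table (reg_score, per-module cm_score / x_max / flag).

    The module-match flag compares each cm_score against the model's
    cm_score_cutoff (reporting only; the cutoff never enters reg_score).
    Returns (table, rho) where rho is the Spearman correlation between
    reg_score and the dataset values (None without a dataset).
    """
    import pandas as pd

    from .pwm_scan import scan

    pwm_by_id = {p.id: p for p in pwms}
    pwm_lengths = {p.id: p.length for p in pwms}
    needed = {pid for m in model.modules for pid in m.pwm_ids}
    rows = []
    for seq in sequences:
        matches = {pid: scan(pwm_by_id[pid], seq, cutoff=scan_floor) for pid in needed}
        row: dict = {"sequence_id": seq.id}
        total = 0.0
        for t, module in enumerate(model.modules, start=1):
            score, x_max = cm_score(matches, module, len(seq), pwm_lengths)
            total += score
            row[f"cm{t}_score"] = score
            row[f"cm{t}_x_max"] = x_max
            row[f"cm{t}_match"] = score > model.cm_score_cutoff
        row["reg_score"] = total
        rows.append(row)
    table = pd.DataFrame(rows)
    rho = None
    if dataset is not None:
        values = dataset.values
        scores = table["reg_score"].to_numpy()
        if np.ptp(scores) > 0:
            rho = spearman(scores, values)
    return table, rho
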