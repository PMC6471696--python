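import math

import numpy as np
import pytest

from pathwalker import cma_correl as cc
from pathwalker.benchmarks import cm_score_oracle, ga_fixture
from pathwalker.pwm_scan import SiteMatch
from pathwalker.synthetic import consensus_pwm


def _module(pwm_ids, sigma=10.0, cutoff=0.5, kappa=3):
    return cc.CompositeModule(
        tuple(pwm_ids), (cutoff,) * len(pwm_ids), (kappa,) * len(pwm_ids), sigma
    )


class TestCmScore:
    def test_single_match_closed_form(self):
        # one site q = 0.9 centered at 50, sigma = 10: peak q / (sigma sqrt(2 pi))
        matches = {"p": [SiteMatch("p", "s", 49, "+", 0.9)]}  # center = 49 + 2//2 = 50
        score, x_max = cc.cm_score(matches, _module(["p"]), 100, {"p": 2})
        assert x_max == 50
        assert score == pytest.approx(0.9 / (10 * math.sqrt(2 * math.pi)))
        assert score == pytest.approx(0.035905, abs=1e-6)

    def test_no_matches_above_cutoff(self):
        matches = {"p": [SiteMatch("p", "s", 10, "+", 0.3)]}
        assert cc.cm_score(matches, _module(["p"], cutoff=0.5), 100, {"p": 2}) == (0.0, 0)

    def test_two_matches_symmetric_peak(self):
        # q = 0.8 at centers 50 and 60: peak at the midpoint, smallest tie kept
        matches = {
            "p": [SiteMatch("p", "s", 49, "+", 0.8), SiteMatch("p", "s", 59, "+", 0.8)]
        }
        module = _module(["p"])
        score, x_max = cc.cm_score(matches, module, 120, {"p": 2})
        o_score, o_x = cm_score_oracle(matches, module, 120, {"p": 2})
        assert x_max == o_x == 55
        assert score == pytest.approx(o_score, abs=1e-12)

    def test_translation_equivariance(self):
        module = _module(["p"], sigma=8.0)
        base = [SiteMatch("p", "s", 30, "+", 0.9), SiteMatch("p", "s", 44, "-", 0.7)]
        shifted = [
            SiteMatch("p", "s", m.position + 15, m.strand, m.score) for m in base
        ]
        s1, x1 = cc.cm_score({"p": base}, module, 200, {"p": 2})
        s2, x2 = cc.cm_score({"p": shifted}, module, 200, {"p": 2})
        assert s2 == pytest.approx(s1, rel=1e-9)
        assert x2 == x1 + 15

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            _module(["p"], sigma=0.0)


class TestRegScore:
    def _matches(self):
        return {"p": [SiteMatch("p", "s", 20, "+", 0.9)]}

    def test_single_module_equals_cm_score(self):
        model = cc.RegulatoryModel((_module(["p"]),))
        expected, _ = cc.cm_score(self._matches(), model.modules[0], 100, {"p": 2})
        assert cc.reg_score(model, self._matches(), 100, {"p": 2}) == pytest.approx(expected)

    def test_duplicate_module_doubles(self):
        m = _module(["p"])
        model = cc.RegulatoryModel((m, m))
        single, _ = cc.cm_score(self._matches(), m, 100, {"p": 2})
        assert cc.reg_score(model, self._matches(), 100, {"p": 2}) == pytest.approx(2 * single)

    def test_two_distinct_modules_additive(self):
        m1, m2 = _module(["p"], sigma=10), _module(["p"], sigma=25)
        model = cc.RegulatoryModel((m1, m2))
        s1, _ = cc.cm_score(self._matches(), m1, 100, {"p": 2})
        s2, _ = cc.cm_score(self._matches(), m2, 100, {"p": 2})
        assert cc.reg_score(model, self._matches(), 100, {"p": 2}) == pytest.approx(s1 + s2)


def spearman_rank_oracle(xs, ys):
    """Explicit average-rank formula: cov(rg_X, rg_Y) / (sd_rgX sd_rgY)."""

    def ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        r = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sorted_v[j] == sorted_v[i]:
                j += 1
            r[order[i:j]] = (i + j - 1) / 2.0 + 1.0  # average of ranks i+1..j
            i = j
        return r

    rx, ry = ranks(xs), ranks(ys)
    cov = np.mean((rx - rx.mean()) * (ry - ry.mean()))
    return cov / (rx.std() * ry.std())


class TestSpearman:
    def test_monotone_is_one(self):
        assert cc.spearman([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        assert cc.spearman([1, 2, 3], [30, 20, 10]) == pytest.approx(-1.0)

    def test_ties_match_rank_formula(self):
        xs, ys = [1, 2, 2, 4], [3, 1, 4, 5]
        assert cc.spearman(xs, ys) == pytest.approx(spearman_rank_oracle(xs, ys), rel=1e-12)

    def test_random_data_matches_rank_formula(self):
        rng = np.random.default_rng(2)
        xs = rng.integers(0, 5, size=40).astype(float)  # heavy ties
        ys = rng.normal(size=40)
        assert cc.spearman(xs, ys) == pytest.approx(spearman_rank_oracle(xs, ys), rel=1e-12)

    def test_constant_input_signalled(self):
        with pytest.raises(ValueError, match="constant"):
            cc.spearman([1.0, 1.0, 1.0], [1, 2, 3])


class TestFitness:
    def test_zero_rho_zero_fitness(self):
        assert cc.fitness_value(0.0, 5, 1.0) == 0.0

    def test_closed_forms(self):
        assert cc.fitness_value(0.9, 2, 0.0) == pytest.approx(1.0)
        assert cc.fitness_value(0.9, 10, 1.0) == pytest.approx(0.1)

    def test_perfect_rho_clamped_finite(self):
        assert math.isfinite(cc.fitness_value(1.0, 2, 0.0))

    def test_monotone_in_rho_and_complexity(self):
        rhos = np.linspace(0, 0.99, 25)
        f = [cc.fitness_value(r, 3, 1.0) for r in rhos]
        assert all(b > a for a, b in zip(f, f[1:]))
        by_complexity = [cc.fitness_value(0.8, c, 1.0) for c in range(1, 10)]
        assert all(b < a for a, b in zip(by_complexity, by_complexity[1:]))


class TestGaOptimize:
    def test_forced_composition_single_pwm(self):
        dataset, pool, _ = ga_fixture(0, n_seqs=60, length=120)
        cfg = cc.GAConfig(
            population_size=8, generations=5, n_modules=1, max_pwms_per_module=1, seed=0
        )
        model, trajectory, _ = cc.ga_optimize(dataset, [pool[0]], cfg, cc.FitnessParams())
        assert model.modules[0].pwm_ids == (pool[0].id,)
        assert len(model.modules) == 1

    def test_reproducible_and_monotone_trajectory(self):
        dataset, pool, _ = ga_fixture(1, n_seqs=60, length=120)
        cfg = cc.GAConfig(population_size=10, generations=8, seed=42)
        out1 = cc.ga_optimize(dataset, pool, cfg, cc.FitnessParams())
        out2 = cc.ga_optimize(dataset, pool, cfg, cc.FitnessParams())
        assert out1[0].to_dict() == out2[0].to_dict()
        assert out1[1] == out2[1]
        assert out1[2] == out2[2]
        traj = out1[1]
        assert all(b >= a - 1e-12 for a, b in zip(traj, traj[1:]))

    def test_empty_pool_rejected(self):
        dataset, _, _ = ga_fixture(0, n_seqs=60, length=120)
        with pytest.raises(ValueError):
            cc.ga_optimize(dataset, [], cc.GAConfig(), cc.FitnessParams())


class TestScoreAndReport:
    @pytest.fixture()
    def setup(self):
        dataset, pool, _ = ga_fixture(3, n_seqs=40, length=120)
        pwms = pool[:2]
        module = cc.CompositeModule(
            (pwms[0].id, pwms[1].id), (0.9, 0.9), (1, 1), 20.0
        )
        return dataset, pwms, module

    def test_zero_cutoff_flags_everything_with_sites(self, setup):
        dataset, pwms, module = setup
        model = cc.RegulatoryModel((module,), cm_score_cutoff=0.0)
        table, _ = cc.score_and_report(model, dataset.sequences, pwms, dataset)
        has_site = table["cm1_score"] > 0
        assert (table.loc[has_site, "cm1_match"]).all()

    def test_high_cutoff_flags_nothing(self, setup):
        dataset, pwms, module = setup
        model = cc.RegulatoryModel((module,), cm_score_cutoff=1e9)
        table, _ = cc.score_and_report(model, dataset.sequences, pwms, dataset)
        assert not table["cm1_match"].any()

    def test_rho_consistent_with_reported_columns(self, setup):
        dataset, pwms, module = setup
        model = cc.RegulatoryModel((module,))
        table, rho = cc.score_and_report(model, dataset.sequences, pwms, dataset)
        scores = table["reg_score"].to_numpy()
        if np.ptp(scores) > 0:
            assert rho == pytest.approx(cc.spearman(scores, dataset.values))


class TestScoredDataset:
    def test_too_few_entries_rejected(self):
        from pathwalker.io_formats import Sequence

        with pytest.raises(ValueError):
            cc.ScoredDataset([(Sequence("a", "ACGT"), 1.0)])

    def test_constant_values_rejected(self):
        from pathwalker.io_formats import Sequence

        entries = [(Sequence(f"s{i}", "ACGT"), 2.0) for i in range(5)]
        with pytest.raises(ValueError):
            cc.ScoredDataset(entries)
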