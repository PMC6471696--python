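import math

import numpy as np
import pytest

from pathwalker import enrichment as en
from pathwalker.io_formats import Sequence, SequenceSet
from pathwalker.synthetic import consensus_pwm, gen_background, plant_module


def binom_tail_oracle(k, n, p):
    """Exact summation of the upper binomial tail P(X >= k)."""
    return sum(math.comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1))


def fisher_oracle(yes_hits, yes_total, no_hits, no_total):
    """One-sided Fisher p by exhaustive hypergeometric enumeration."""
    N = yes_total + no_total
    K = yes_hits + no_hits
    total = 0.0
    for x in range(max(0, K - no_total), min(K, yes_total) + 1):
        if x >= yes_hits:
            total += math.comb(K, x) * math.comb(N - K, yes_total - x)
    return total / math.comb(N, yes_total)


class TestSiteOverrep:
    def test_zero_yes_sites_gives_one(self):
        assert en.site_overrep_pvalue(0, 1000, 5, 1000) == 1.0

    def test_exact_tail_oracle(self):
        p = en.site_overrep_pvalue(10, 1000, 2, 1000)
        assert p == pytest.approx(binom_tail_oracle(10, 1000, 2 / 1000), rel=1e-9)

    def test_continuity_rate_when_no_sites_zero(self):
        p = en.site_overrep_pvalue(3, 1000, 0, 1000)
        assert p == pytest.approx(binom_tail_oracle(3, 1000, 1 / 1002), rel=1e-9)

    def test_equal_rates_not_significant(self):
        p = en.site_overrep_pvalue(50, 1000, 50, 1000)
        assert p >= 0.05

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            en.site_overrep_pvalue(5, 0, 1, 10)
        with pytest.raises(ValueError):
            en.site_overrep_pvalue(11, 10, 1, 10)


class TestSeqOverrep:
    @pytest.mark.parametrize(
        "yh,yt,nh,nt",
        [(8, 10, 2, 10), (5, 10, 5, 10), (10, 10, 0, 10), (3, 12, 7, 15), (0, 8, 4, 8)],
    )
    def test_matches_enumeration_oracle(self, yh, yt, nh, nt):
        assert en.seq_overrep_pvalue(yh, yt, nh, nt) == pytest.approx(
            fisher_oracle(yh, yt, nh, nt), rel=1e-9
        )

    def test_no_enrichment_at_least_half(self):
        assert en.seq_overrep_pvalue(5, 10, 5, 10) >= 0.5

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            en.seq_overrep_pvalue(-1, 10, 0, 10)


class TestBhAdjust:
    def test_step_up_hand_computation(self):
        # m = 3: p_(i) * m / i = [0.03, 0.03, 0.03] after monotone step-up
        np.testing.assert_allclose(en.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(en.bh_adjust([0.2]), [0.2])

    def test_dominates_input_and_capped(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=40)
        adj = en.bh_adjust(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            en.bh_adjust([0.5, 1.5])


def brute_force_optimize(pwm, yes, no, criterion, alpha, scan_floor=0.5):
    """Literal search over every distinct observed score (plus 1.0)."""
    yes_sites, yes_max, yes_pos = en._scan_set(pwm, yes, scan_floor, True)
    no_sites, no_max, no_pos = en._scan_set(pwm, no, scan_floor, True)
    candidates = sorted(set(yes_sites) | set(no_sites) | {1.0})
    rows = []
    for c in candidates:
        ys = int((yes_sites >= c).sum())
        ns = int((no_sites >= c).sum())
        yh = int((yes_max >= c).sum())
        nh = int((no_max >= c).sum())
        if criterion == "sequence":
            p = en.seq_overrep_pvalue(yh, len(yes), nh, len(no))
            odds = ((yh + 0.5) * (len(no) - nh + 0.5)) / ((len(yes) - yh + 0.5) * (nh + 0.5))
        else:
            p = en.site_overrep_pvalue(ys, yes_pos, ns, no_pos)
            odds = ((ys + 0.5) * (no_pos - ns + 0.5)) / ((yes_pos - ys + 0.5) * (ns + 0.5))
        rows.append((c, p, odds))
    sig = [r for r in rows if r[1] <= alpha]
    if sig:
        best = min(sig, key=lambda r: (-r[2], r[1], r[0]))
        return best[0], best[2], True
    best = min(rows, key=lambda r: (r[1], r[0]))
    return best[0], best[2], False


@pytest.fixture(scope="module")
def planted_fixture():
    rng = np.random.default_rng(7)
    pwm = consensus_pwm("ATGCATACG", "PLANTED")
    yes, _ = plant_module(gen_background(60, 200, seed=rng), [pwm], fraction=0.6, seed=rng)
    no_raw, _ = plant_module(gen_background(60, 200, seed=rng), [pwm], fraction=0.05, seed=rng)
    no = SequenceSet(Sequence("no_" + s.id, s.residues) for s in no_raw)
    return pwm, yes, no


class TestOptimizeCutoff:
    def test_planted_motif_isolated(self, planted_fixture):
        pwm, yes, no = planted_fixture
        cutoff, res = en.optimize_cutoff(pwm, yes, no, criterion="sequence")
        assert res.significant
        assert res.p_fisher < 1e-6
        assert res.yes_seq_hits >= 30

    def test_yes_equals_no_not_significant(self, planted_fixture):
        pwm, yes, _ = planted_fixture
        no = SequenceSet(Sequence("copy_" + s.id, s.residues) for s in yes)
        _, res = en.optimize_cutoff(pwm, yes, no, criterion="sequence")
        assert not res.significant

    @pytest.mark.parametrize("criterion", ["sequence", "site"])
    def test_equals_brute_force(self, planted_fixture, criterion):
        pwm, yes, no = planted_fixture
        cutoff, res = en.optimize_cutoff(pwm, yes, no, criterion=criterion)
        bf_cutoff, bf_odds, bf_sig = brute_force_optimize(pwm, yes, no, criterion, 0.05)
        assert cutoff == pytest.approx(bf_cutoff)
        assert res.odds_ratio == pytest.approx(bf_odds)
        assert res.significant == bf_sig

    def test_order_invariance(self, planted_fixture):
        pwm, yes, no = planted_fixture
        shuffled = SequenceSet(list(yes)[::-1])
        c1, r1 = en.optimize_cutoff(pwm, yes, no)
        c2, r2 = en.optimize_cutoff(pwm, shuffled, no)
        assert c1 == c2 and r1.p_fisher == r2.p_fisher


class TestFmatch:
    def test_empty_pwm_list(self, planted_fixture):
        _, yes, no = planted_fixture
        assert en.fmatch([], yes, no).empty

    def test_planted_ranked_first(self, planted_fixture, random_pwms):
        pwm, yes, no = planted_fixture
        table = en.fmatch([pwm] + random_pwms, yes, no, criterion="sequence")
        assert table.iloc[0]["pwm_id"] == "PLANTED"
        assert table.iloc[0]["p_adjusted"] < 0.01

    def test_no_bidirectional_enrichment(self, planted_fixture, random_pwms):
        """Label-swapped sets never flag the same PWM in both directions."""
        pwm, yes, no = planted_fixture
        fwd = en.fmatch([pwm] + random_pwms, yes, no)
        rev = en.fmatch([pwm] + random_pwms, no, yes)
        fwd_hits = set(fwd[(fwd["p_adjusted"] < 0.05) & fwd["significant"]]["pwm_id"])
        rev_hits = set(rev[(rev["p_adjusted"] < 0.05) & rev["significant"]]["pwm_id"])
        assert not (fwd_hits & rev_hits)
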