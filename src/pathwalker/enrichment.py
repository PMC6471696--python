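"""F-Match-style Yes/No binding-site enrichment with cutoff optimization.

For each PWM, a score threshold is chosen that maximizes the odds of a
predicted site (or a site-containing sequence) falling in the Yes set,
subject to a significance constraint: the site criterion applies an
upper-tail binomial test of the Yes site rate against the No rate, the
sequence criterion a one-sided Fisher exact test on the 2x2 table of
sequences with/without a site. Multiple testing across PWMs is controlled
by Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import SequenceSet
from .pwm_scan import PWM, encode, window_scores


@dataclass(frozen=True)
class EnrichmentResult:
    pwm_id: str
    optimized_cutoff: float
    yes_sites: int
    no_sites: int
    yes_seq_hits: int
    no_seq_hits: int
    yes_total: int
    no_total: int
    site_rate_yes: float
    site_rate_no: float
    odds_ratio: float
    p_binomial: float
    p_fisher: float
    significant: bool
    p_adjusted: float = float("nan")


def site_overrep_pvalue(
    yes_sites: int, yes_positions: int, no_sites: int, no_positions: int
) -> float:
    """Upper-tail binomial p-value for site overrepresentation in the Yes set.

    The Yes site count is tested against Binomial(yes_positions, rate_no)
    where rate_no is the No-set site density; a continuity rate
    (no_sites + 1) / (no_positions + 2) is used when no sites were seen in No.
    """
    if yes_positions <= 0:
        raise ValueError("yes_positions must be > 0")
    if no_positions <= 0:
        raise ValueError("no_positions must be > 0")
    if not (0 <= yes_sites <= yes_positions and 0 <= no_sites <= no_positions):
        raise ValueError("counts must satisfy 0 <= sites <= positions")
    if yes_sites == 0:
        return 1.0
    if no_sites == 0:
        rate_no = (no_sites + 1) / (no_positions + 2)
    else:
        rate_no = no_sites / no_positions
    return float(stats.binom.sf(yes_sites - 1, yes_positions, rate_no))


def seq_overrep_pvalue(yes_hits: int, yes_total: int, no_hits: int, no_total: int) -> float:
    """One-sided Fisher exact p (enrichment in Yes) on the 2x2 hit table."""
    if min(yes_hits, yes_total, no_hits, no_total) < 0:
        raise ValueError("negative counts")
    if yes_hits > yes_total or no_hits > no_total:
        raise ValueError("hits must not exceed totals")
    # P(X >= yes_hits) under the hypergeometric null with fixed margins
    return float(
        stats.hypergeom.sf(yes_hits - 1, yes_total + no_total, yes_hits + no_hits, yes_total)
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Haldane-corrected odds ratio of the table [[a, b], [c, d]]."""
    return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))


def _scan_set(pwm: PWM, seqs: SequenceSet, floor: float, both_strands: bool):
    """Per-sequence site scores >= floor and max window score, plus #positions."""
    site_scores, max_scores, n_positions = [], [], 0
    for seq in seqs:
        codes = encode(seq.residues)
        if codes.size < pwm.length:
            max_scores.append(0.0)
            continue
        strands = ("+", "-") if both_strands else ("+",)
        best = 0.0
        for strand in strands:
            scores = window_scores(pwm, codes, strand)
            n_positions += scores.size
            best = max(best, float(scores.max()))
            site_scores.append(scores[scores >= floor])
        max_scores.append(best)
    sites = np.concatenate(site_scores) if site_scores else np.empty(0)
    return np.sort(sites), np.asarray(max_scores), n_positions


def optimize_cutoff(
    pwm: PWM,
    yes: SequenceSet,
    no: SequenceSet,
    criterion: str = "sequence",
    alpha: float = 0.05,
    scan_floor: float = 0.5,
    both_strands: bool = True,
) -> tuple[float, EnrichmentResult]:
    """Find the score cutoff with optimal Yes-set overrepresentation.

    Candidate cutoffs are the distinct observed match scores (>= scan_floor)
    in yes + no, plus 1.0. Among candidates whose criterion p-value is
    <= alpha, the one maximizing the odds ratio is returned; if none is
    significant, the candidate with the smallest p-value is returned with
    ``significant=False``.
    """
    if len(yes) == 0 or len(no) == 0:
        raise ValueError("yes and no sets must be non-empty")
    if criterion not in ("site", "sequence"):
        raise ValueError(f"unknown criterion {criterion!r}")

    yes_sites, yes_max, yes_pos = _scan_set(pwm, yes, scan_floor, both_strands)
    no_sites, no_max, no_pos = _scan_set(pwm, no, scan_floor, both_strands)

    # candidate cutoffs: every distinct observed match score, plus 1.0
    observed = np.concatenate([yes_sites, no_sites])
    candidates = np.unique(np.concatenate([observed, [1.0]]))
    if candidates.size == 0:
        raise ValueError("empty candidate cutoff set")

    n_yes, n_no = len(yes), len(no)
    yes_hits_c = n_yes - np.searchsorted(np.sort(yes_max), candidates, side="left")
    no_hits_c = n_no - np.searchsorted(np.sort(no_max), candidates, side="left")
    yes_sites_c = yes_sites.size - np.searchsorted(yes_sites, candidates, side="left")
    no_sites_c = no_sites.size - np.searchsorted(no_sites, candidates, side="left")

    if criterion == "sequence":
        table = np.stack([yes_hits_c, no_hits_c], axis=1)
        uniq, inverse = np.unique(table, axis=0, return_inverse=True)
        p_uniq = stats.hypergeom.sf(
            uniq[:, 0] - 1, n_yes + n_no, uniq[:, 0] + uniq[:, 1], n_yes
        )
        pvals = p_uniq[inverse]
        odds = (
            (yes_hits_c + 0.5) * (n_no - no_hits_c + 0.5)
            / ((n_yes - yes_hits_c + 0.5) * (no_hits_c + 0.5))
        )
    else:
        table = np.stack([yes_sites_c, no_sites_c], axis=1)
        uniq, inverse = np.unique(table, axis=0, return_inverse=True)
        rate_no = np.where(
            uniq[:, 1] == 0, (uniq[:, 1] + 1) / (no_pos + 2), uniq[:, 1] / no_pos
        )
        p_uniq = np.where(
            uniq[:, 0] == 0, 1.0, stats.binom.sf(uniq[:, 0] - 1, yes_pos, rate_no)
        )
        pvals = p_uniq[inverse]
        odds = (
            (yes_sites_c + 0.5) * (no_pos - no_sites_c + 0.5)
            / ((yes_pos - yes_sites_c + 0.5) * (no_sites_c + 0.5))
        )

    sig = pvals <= alpha
    if sig.any():
        pool = np.flatnonzero(sig)
        # maximize odds; break ties toward smaller p, then smaller cutoff
        order = sorted(pool, key=lambda i: (-odds[i], pvals[i], candidates[i]))
        best = order[0]
        significant = True
    else:
        order = sorted(range(candidates.size), key=lambda i: (pvals[i], candidates[i]))
        best = order[0]
        significant = False

    cutoff = float(candidates[best])
    ys, ns = int(yes_sites_c[best]), int(no_sites_c[best])
    yh, nh = int(yes_hits_c[best]), int(no_hits_c[best])
    result = EnrichmentResult(
        pwm_id=pwm.id,
        optimized_cutoff=cutoff,
        yes_sites=ys,
        no_sites=ns,
        yes_seq_hits=yh,
        no_seq_hits=nh,
        yes_total=n_yes,
        no_total=n_no,
        site_rate_yes=ys / yes_pos if yes_pos else 0.0,
        site_rate_no=ns / no_pos if no_pos else 0.0,
        odds_ratio=float(odds[best]),
        p_binomial=site_overrep_pvalue(ys, yes_pos, ns, no_pos) if yes_pos and no_pos else 1.0,
        p_fisher=seq_overrep_pvalue(yh, n_yes, nh, n_no),
        significant=significant,
    )
    return cutoff, result


def fmatch(
    pwms,
    yes: SequenceSet,
    no: SequenceSet,
    criterion: str = "sequence",
    alpha: float = 0.05,
    scan_floor: float = 0.5,
    both_strands: bool = True,
) -> pd.DataFrame:
    """Per-PWM cutoff optimization plus BH adjustment across PWMs.

    Returns one row per PWM sorted by adjusted p-value; ``p_adjusted`` is
    the BH adjustment of the criterion p-values (Fisher for the sequence
    criterion, binomial for the site criterion) at the optimized cutoffs.
    """
    results = []
    for pwm in pwms:
        _, res = optimize_cutoff(pwm, yes, no, criterion, alpha, scan_floor, both_strands)
        results.append(res)
    if not results:
        return pd.DataFrame(
            columns=[
                "pwm_id", "optimized_cutoff", "yes_sites", "no_sites", "yes_seq_hits",
                "no_seq_hits", "yes_total", "no_total", "site_rate_yes", "site_rate_no",
                "odds_ratio", "p_binomial", "p_fisher", "significant", "p_adjusted",
            ]
        )
    crit_p = [r.p_fisher if criterion == "sequence" else r.p_binomial for r in results]
    adjusted = bh_adjust(crit_p)
    results = [replace(r, p_adjusted=float(a)) for r, a in zip(results, adjusted)]
    frame = pd.DataFrame([r.__dict__ for r in results])
    return frame.sort_values(
        ["p_adjusted", "p_fisher" if criterion == "sequence" else "p_binomial", "pwm_id"],
        kind="mergesort",
    ).reset_index(drop=True)
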