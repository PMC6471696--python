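"""Methylation / expression preprocessing.

Beta-values from probe intensities, two-group differential statistics
(Welch t-test with BH adjustment on log2 fold changes of group means),
CpG-gene Spearman correlation with a large-sample critical value, and
construction of merged windows around CpG positions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cma_correl import spearman
from .enrichment import bh_adjust
from .io_formats import GenomicInterval, SampleMatrix

logger = logging.getLogger(__name__)

EXPRESSION_EPS = 1e-9


@dataclass(frozen=True)
class MethylationRecord:
    probe_id: str
    chrom: str
    position: int
    methylated: float
    unmethylated: float

    @property
    def beta(self) -> float:
        return beta_value(self.methylated, self.unmethylated)


@dataclass(frozen=True)
class CorrelationRecord:
    probe_id: str
    gene_id: str
    rho: float
    n_samples: int
    passes: bool


def beta_value(methylated: float, unmethylated: float) -> float:
    """Methylation beta-value M / (U + M + 100) from probe intensities."""
    if methylated < 0 or unmethylated < 0:
        raise ValueError("intensities must be non-negative")
    return methylated / (unmethylated + methylated + 100.0)


def differential(group_a: SampleMatrix, group_b: SampleMatrix) -> pd.DataFrame:
    """Per-feature log2 fold change (A vs B) with Welch t-test and BH FDR.

    For expression matrices the fold change is of group means with a small
    epsilon; for beta matrices it is the fold change of mean beta-values
    (the conventional 1.5 / 0.67 thresholds map to +/- log2 1.5). Features
    with zero variance in both groups get p = 1.
    """
    shared = group_a.values.index.intersection(group_b.values.index)
    if len(shared) == 0:
        raise ValueError("no shared feature ids between groups")
    if group_a.values.shape[1] < 2 or group_b.values.shape[1] < 2:
        raise ValueError("need at least 2 samples per group")
    a = group_a.values.loc[shared].to_numpy(dtype=float)
    b = group_b.values.loc[shared].to_numpy(dtype=float)
    eps = EXPRESSION_EPS
    logfc = np.log2((a.mean(axis=1) + eps) / (b.mean(axis=1) + eps))
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # zero-variance features trigger a precision warning; their NaN p is
        # mapped to 1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        t = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isnan(t.pvalue), 1.0, t.pvalue)
    return pd.DataFrame(
        {"logFC": logfc, "p": p, "p_adjusted": bh_adjust(p)}, index=pd.Index(shared, name="feature")
    )


def filter_features(
    results: pd.DataFrame, lfc_hi: float, lfc_lo: float, alpha: float
) -> tuple[list[str], list[str]]:
    """Split features into up / down lists by adjusted p and logFC thresholds."""
    sig = results["p_adjusted"] < alpha
    up = results.index[sig & (results["logFC"] > lfc_hi)].tolist()
    down = results.index[sig & (results["logFC"] < lfc_lo)].tolist()
    return up, down


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Large-sample critical value of the Spearman coefficient.

    Normal approximation z_{1-alpha/2} / sqrt(n - 1); at n around 120 and
    alpha 0.05 this gives the conventional 0.18 threshold.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    return float(stats.norm.ppf(1 - alpha / 2) / math.sqrt(n - 1))


def cpg_gene_correlation(
    meth: SampleMatrix,
    expr: SampleMatrix,
    pairs: list[tuple[str, str]] | None = None,
    alpha: float = 0.05,
    probe_positions: dict[str, tuple[str, int]] | None = None,
    gene_spans: dict[str, tuple[str, int, int]] | None = None,
    max_distance: int = 2000,
) -> list[CorrelationRecord]:
    """Spearman correlation between CpG beta-values and gene expression.

    Samples are the intersection of the two matrices' columns (order taken
    from the methylation matrix). When explicit pairs are omitted, probes
    are paired with genes whose span, extended by ``max_distance`` bp both
    ways, contains the probe position. A pair passes when
    |rho| > critical_r(n, alpha).
    """
    shared = [s for s in meth.samples if s in set(expr.samples)]
    if len(shared) < 4:
        raise ValueError(f"need >= 4 shared samples, got {len(shared)}")
    if pairs is None:
        if probe_positions is None or gene_spans is None:
            raise ValueError("either pairs or probe_positions + gene_spans required")
        pairs = []
        for probe, (chrom, pos) in probe_positions.items():
            for gene, (g_chrom, start, end) in gene_spans.items():
                if chrom == g_chrom and start - max_distance <= pos < end + max_distance:
                    pairs.append((probe, gene))
    n = len(shared)
    crit = critical_r(n, alpha)
    m = meth.values[shared]
    e = expr.values[shared]
    records = []
    for probe, gene in pairs:
        if probe not in m.index or gene not in e.index:
            logger.warning("skipping pair (%s, %s): missing feature", probe, gene)
            continue
        xs = m.loc[probe].to_numpy(dtype=float)
        ys = e.loc[gene].to_numpy(dtype=float)
        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
            records.append(CorrelationRecord(probe, gene, float("nan"), n, False))
            continue
        rho = spearman(xs, ys)
        records.append(CorrelationRecord(probe, gene, rho, n, abs(rho) > crit))
    return records


def regions_around(
    cpg_positions: list[tuple[str, int]], window: int
) -> list[GenomicInterval]:
    """Merged half-open windows of ``window`` bp centered on CpG positions.

    Overlapping or touching windows on the same chromosome are merged;
    starts are clipped at 0; output is sorted by (chrom, start).
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if window % 2 != 0:
        raise ValueError("window must be even")
    half = window // 2
    raw = sorted((chrom, max(0, pos - half), pos + half) for chrom, pos in cpg_positions)
    merged: list[GenomicInterval] = []
    for chrom, start, end in raw:
        if merged and merged[-1].chrom == chrom and start <= merged[-1].end:
            last = merged.pop()
            merged.append(GenomicInterval(chrom, last.start, max(last.end, end)))
        else:
            merged.append(GenomicInterval(chrom, start, end))
    return merged
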