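"""Match-style PWM site prediction.

A PWM hit is scored with the classic matrix-similarity score: each position
contributes its information content times the frequency of the observed
base, and the raw sum is min-max normalized so the consensus word scores
1.0 and the worst word 0.0. Windows containing N score 0 (no imputation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import Sequence

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def encode(residues: str) -> np.ndarray:
    """Map a DNA string to integer codes (A=0, C=1, G=2, T=3, N=4)."""
    return _CODE[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]


def reverse_complement(residues: str) -> str:
    return residues.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PWM:
    """Position weight matrix with information-weighted score bounds.

    ``frequencies`` rows sum to 1; ``information[i] = sum_b f(i,b) ln(4 f(i,b))``
    (with 0 ln 0 := 0); ``min_raw``/``max_raw`` are the attainable raw-score
    bounds used for min-max normalization.
    """

    id: str
    counts: np.ndarray
    frequencies: np.ndarray
    information: np.ndarray
    min_raw: float
    max_raw: float

    @property
    def length(self) -> int:
        return self.frequencies.shape[0]

    @property
    def weights(self) -> np.ndarray:
        """Per-position, per-base raw score contributions I(i) * f(i, b)."""
        return self.information[:, None] * self.frequencies

    def consensus(self) -> str:
        return "".join("ACGT"[b] for b in np.argmax(self.frequencies, axis=1))


def build_pwm(counts, pseudocount: float = 0.25, pwm_id: str = "pwm") -> PWM:
    """Build a PWM from an L x 4 count matrix (columns A, C, G, T)."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 4 or counts.shape[0] < 1:
        raise ValueError("counts must be an L x 4 matrix with L >= 1")
    if (counts < 0).any():
        i, b = np.argwhere(counts < 0)[0]
        raise ValueError(f"negative count at position {i + 1}, base {'ACGT'[b]}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    rowsums = counts.sum(axis=1)
    if pseudocount == 0 and (rowsums == 0).any():
        raise ValueError("all-zero count row with pseudocount 0")
    freq = (counts + pseudocount) / (rowsums + 4 * pseudocount)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(freq > 0, freq * np.log(4 * freq), 0.0)
    info = terms.sum(axis=1)
    weights = info[:, None] * freq
    min_raw = float(weights.min(axis=1).sum())
    max_raw = float(weights.max(axis=1).sum())
    return PWM(pwm_id, counts, freq, info, min_raw, max_raw)


@dataclass(frozen=True, order=True)
class SiteMatch:
    """A scored PWM hit: window start (0-based, forward coords), strand, score."""

    pwm_id: str
    sequence_id: str
    position: int
    strand: str
    score: float

    def center(self, pwm_length: int) -> int:
        return self.position + pwm_length // 2


def match_score(pwm: PWM, word: str) -> float:
    """Normalized similarity score of a single L-mer (N anywhere => 0)."""
    if len(word) != pwm.length:
        raise ValueError(f"word length {len(word)} != PWM length {pwm.length}")
    codes = encode(word.upper())
    if (codes == 4).any():
        return 0.0
    raw = float(pwm.weights[np.arange(pwm.length), codes].sum())
    span = pwm.max_raw - pwm.min_raw
    if span <= 0:
        return 0.0
    return (raw - pwm.min_raw) / span


def _strand_scores(weights: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Raw window scores of one strand's weight matrix over all windows."""
    L = weights.shape[0]
    n_win = codes.size - L + 1
    w5 = np.hstack([weights, np.zeros((L, 1))])  # N column contributes 0
    raw = np.zeros(n_win)
    for i in range(L):
        raw += w5[i, codes[i : i + n_win]]
    return raw


def window_scores(pwm: PWM, codes: np.ndarray, strand: str = "+") -> np.ndarray:
    """Normalized scores for every window of an encoded sequence.

    The minus strand scores the reverse complement of each window while
    keeping forward coordinates (window start unchanged).
    """
    L = pwm.length
    if codes.size < L:
        return np.empty(0)
    weights = pwm.weights
    if strand == "-":
        weights = weights[::-1, ::-1]
    raw = _strand_scores(weights, codes)
    span = pwm.max_raw - pwm.min_raw
    if span <= 0:
        return np.zeros_like(raw)
    scores = (raw - pwm.min_raw) / span
    # windows containing N score 0
    has_n = np.convolve((codes == 4).astype(float), np.ones(L), mode="valid") > 0
    scores[has_n] = 0.0
    return scores


def scan(
    pwm: PWM,
    sequence: Sequence,
    cutoff: float = 0.75,
    both_strands: bool = True,
) -> list[SiteMatch]:
    """All matches with score >= cutoff, sorted by position then strand (+ first)."""
    import logging

    codes = encode(sequence.residues)
    if codes.size < pwm.length:
        logging.getLogger(__name__).warning(
            "sequence %s shorter than PWM %s (%d < %d)",
            sequence.id, pwm.id, codes.size, pwm.length,
        )
        return []
    matches = []
    strands = ("+", "-") if both_strands else ("+",)
    for strand in strands:
        scores = window_scores(pwm, codes, strand)
        for pos in np.flatnonzero(scores >= cutoff):
            matches.append(SiteMatch(pwm.id, sequence.id, int(pos), strand, float(scores[pos])))
    matches.sort(key=lambda m: (m.position, m.strand != "+"))
    return matches


def top_matches(matches: list[SiteMatch], kappa: int) -> list[SiteMatch]:
    """The kappa highest-scoring matches; ties to smaller position, then + strand."""
    if kappa < 1:
        raise ValueError("kappa must be >= 1")
    ranked = sorted(matches, key=lambda m: (-m.score, m.position, m.strand != "+"))
    return ranked[:kappa]
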