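"""Readers and writers for the external formats the toolkit touches.

Everything downstream works on the in-memory types defined here:
:class:`Sequence` / :class:`SequenceSet` for DNA, :class:`GenomicInterval`
for regions (0-based half-open, BED-native), :class:`SampleMatrix` for
feature-by-sample numeric tables, and edge lists for signaling networks.
Parsers reject structural errors; benign repairs (non-ACGT residues mapped
to N, duplicate network edges) are logged and counted rather than silent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO, motifs

logger = logging.getLogger(__name__)

DNA_ALPHABET = "ACGTN"


@dataclass(frozen=True)
class Sequence:
    """A named DNA sequence over the alphabet {A, C, G, T, N}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has empty residues")
        bad = set(self.residues) - set(DNA_ALPHABET)
        if bad:
            raise ValueError(f"sequence {self.id!r} contains invalid residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


class SequenceSet:
    """An ordered collection of sequences with unique ids."""

    def __init__(self, sequences: Iterable[Sequence] = ()):
        self._seqs: list[Sequence] = []
        self._index: dict[str, int] = {}
        for seq in sequences:
            self.add(seq)

    def add(self, seq: Sequence) -> None:
        if seq.id in self._index:
            raise ValueError(f"duplicate sequence id {seq.id!r}")
        self._index[seq.id] = len(self._seqs)
        self._seqs.append(seq)

    def __len__(self) -> int:
        return len(self._seqs)

    def __iter__(self) -> Iterator[Sequence]:
        return iter(self._seqs)

    def __getitem__(self, key: int | str) -> Sequence:
        if isinstance(key, str):
            return self._seqs[self._index[key]]
        return self._seqs[key]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._index

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self._seqs]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("interval start must be non-negative")
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class SampleMatrix:
    """Feature-by-sample numeric matrix with a value-kind flag.

    ``kind`` is ``"beta"`` (methylation fractions, all values in [0, 1]) or
    ``"expression"`` (non-negative abundances); the beta invariant is
    enforced on construction and on read.
    """

    values: pd.DataFrame
    kind: str = "expression"

    def __post_init__(self) -> None:
        if self.kind not in ("beta", "expression"):
            raise ValueError(f"unknown value kind {self.kind!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        vals = self.values.to_numpy()
        if self.kind == "beta" and ((vals < 0).any() or (vals > 1).any()):
            raise ValueError("beta matrix contains values outside [0, 1]")

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, features: Iterable[str]) -> "SampleMatrix":
        return SampleMatrix(self.values.loc[list(features)].copy(), kind=self.kind)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> SequenceSet:
    """Read a FASTA file; lowercase is uppercased, non-ACGT mapped to N.

    The number of repaired (N-mapped) residues is logged as a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out = SequenceSet()
    n_repaired = 0
    for record in SeqIO.parse(str(path), "fasta"):
        if not record.id:
            raise ValueError(f"{path}: FASTA record with empty id")
        residues = str(record.seq).upper()
        cleaned = "".join(c if c in "ACGTN" else "N" for c in residues)
        n_repaired += sum(1 for a, b in zip(residues, cleaned) if a != b)
        out.add(Sequence(record.id, cleaned))
    if n_repaired:
        logger.warning("%s: mapped %d non-ACGT residues to N", path, n_repaired)
    return out


def write_fasta(path: str | Path, seqs: SequenceSet, width: int = 70) -> None:
    with open(path, "w") as fh:
        for seq in seqs:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[GenomicInterval]:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line with < 3 columns")
            name = parts[3] if len(parts) > 3 else None
            intervals.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]), name))
    return intervals


def write_bed(path: str | Path, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None:
                cols.append(iv.name)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# PWM collections


def read_pwm_collection(path: str | Path, dialect: str = "jaspar", pseudocount: float = 0.25):
    """Parse a PWM collection (JASPAR PFM or TRANSFAC flat) into PWM objects.

    Count matrices are handed to :func:`pathwalker.pwm_scan.build_pwm` with
    the given pseudocount. Old-style TRANSFAC "PO" header rows are accepted
    as synonyms of "P0".
    """
    from .pwm_scan import build_pwm  # local import to avoid a cycle

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect not in ("jaspar", "transfac"):
        raise ValueError(f"unknown PWM dialect {dialect!r}")
    text = path.read_text()
    if dialect == "transfac":
        text = "\n".join(
            "P0" + line[2:] if line.startswith("PO") else line for line in text.splitlines()
        ) + "\n"
    from io import StringIO

    records = motifs.parse(StringIO(text), dialect)
    pwms = []
    for m in records:
        counts = [[float(m.counts[base][i]) for base in "ACGT"] for i in range(m.length)]
        for i, row in enumerate(counts):
            for base, c in zip("ACGT", row):
                if c < 0:
                    raise ValueError(
                        f"{path}: negative count {c} at position {i + 1}, base {base} "
                        f"in matrix {m.name or getattr(m, 'matrix_id', '?')}"
                    )
        pwm_id = getattr(m, "matrix_id", None) or m.name or f"pwm_{len(pwms) + 1}"
        pwms.append(build_pwm(counts, pseudocount=pseudocount, pwm_id=str(pwm_id)))
    return pwms


def write_pwm_jaspar(path: str | Path, pwms) -> None:
    """Write PWM count matrices in JASPAR PFM format."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.id} {pwm.id}\n")
            for bi, base in enumerate("ACGT"):
                row = " ".join(_fmt(c) for c in pwm.counts[:, bi])
                fh.write(f"{base} [ {row} ]\n")


# ---------------------------------------------------------------------------
# Signaling network edge lists


def read_network(path: str | Path):
    """Read a signed, weighted edge list into a SignalingGraph.

    Format: ``source<TAB>sign<TAB>target[<TAB>cost]`` with sign in {+1, -1}
    (``+``/``-`` accepted) and cost > 0 (default 1.0). The last duplicate of
    an edge wins, with a logged warning.
    """
    from .master_regulators import SignalingGraph

    graph = SignalingGraph()
    n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            source, sign_str, target = parts[0], parts[1], parts[2]
            if sign_str in ("+1", "+", "1"):
                sign = 1
            elif sign_str in ("-1", "-"):
                sign = -1
            else:
                raise ValueError(f"{path}:{lineno}: malformed sign {sign_str!r}")
            cost = float(parts[3]) if len(parts) > 3 and parts[3] != "" else 1.0
            if cost <= 0:
                raise ValueError(f"{path}:{lineno}: cost must be > 0, got {cost}")
            if graph.graph.has_edge(source, target):
                n_dup += 1
            graph.add_edge(source, target, sign=sign, cost=cost)
    if n_dup:
        logger.warning("%s: %d duplicate edges, last occurrence kept", path, n_dup)
    return graph


def write_network(path: str | Path, graph) -> None:
    with open(path, "w") as fh:
        for u, v, data in graph.graph.edges(data=True):
            fh.write(f"{u}\t{data['sign']:+d}\t{v}\t{_fmt(data['cost'])}\n")


def read_node_annotations(path: str | Path) -> dict[str, dict]:
    """Read a node annotation TSV: node, kind, gene (empty gene allowed)."""
    out: dict[str, dict] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            row = dict(zip(header, parts))
            out[row["node"]] = {
                "kind": row.get("kind", "protein"),
                "gene": row.get("gene") or None,
            }
    return out


# ---------------------------------------------------------------------------
# TSV matrices / tables


def _fmt(x: float) -> str:
    return f"{float(x):.6g}"


def read_matrix(path: str | Path, kind: str = "expression") -> SampleMatrix:
    """Read a TSV matrix (first column = feature ids, header = sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate feature ids {dups}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell in matrix") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return SampleMatrix(df, kind=kind)


def write_matrix(path: str | Path, matrix: SampleMatrix) -> None:
    write_table(path, matrix.values)


def write_table(path: str | Path, table: pd.DataFrame, index_label: str = "id") -> None:
    """Write a DataFrame as TSV with 6-significant-digit float formatting."""
    table.to_csv(path, sep="\t", float_format="%.6g", index_label=index_label)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
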