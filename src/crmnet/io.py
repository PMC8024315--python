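"""Readers, writers, and the domain types they traffic in.

Every on-disk dialect the package understands is decided here, once.  All
genomic coordinates are 0-based half-open throughout the package; text
citations of the form ``chr1:100-200`` found in the wild are treated as
already half-open when parsed by :func:`parse_region`.

Formats supported: BED3-5, chrom.sizes, JASPAR position frequency
matrices, FASTA (via pyfaidx), TSV expression matrices, TSV SNP tables,
TSV directed edge lists, and the TSV triplet serialization of consensus
networks (see :mod:`crmnet.networks`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    id: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end

    def region_string(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def parse_region(text: str) -> GenomicInterval:
    """Parse ``chrom:start-end`` into an interval (coordinates half-open)."""
    try:
        chrom, span = text.split(":")
        start, end = span.split("-")
        return GenomicInterval(chrom, int(start), int(end))
    except ValidationError:
        raise
    except Exception as exc:  # noqa: BLE001 - uniform parse error
        raise ParseError(f"cannot parse region {text!r}") from exc


class GenomeIndex:
    """Ordered map chromosome -> length in bases."""

    def __init__(self, lengths: Mapping[str, int]):
        seen: dict[str, int] = {}
        for chrom, length in lengths.items():
            if chrom in seen:
                raise ValidationError(f"duplicate chromosome {chrom!r}")
            if length <= 0:
                raise ValidationError(f"chromosome {chrom!r} has length {length}")
            seen[chrom] = int(length)
        self._lengths = seen

    def __getitem__(self, chrom: str) -> int:
        return self._lengths[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __iter__(self):
        return iter(self._lengths)

    def __len__(self) -> int:
        return len(self._lengths)

    def items(self):
        return self._lengths.items()

    @property
    def total_length(self) -> int:
        return sum(self._lengths.values())

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeIndex) and self._lengths == other._lengths


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values (FPKM-like, non-negative).

    ``normalization`` records what has been applied so downstream code can
    assert the convention (e.g. ``"raw"``, ``"log2p1"``).
    """

    values: pd.DataFrame
    normalization: str = "raw"

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()].unique()
            raise ValidationError(f"duplicate gene ids: {list(dup)!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, genes: Sequence[str]) -> np.ndarray:
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise ValidationError(f"genes absent from matrix: {missing!r}")
        return self.values.loc[list(genes)].to_numpy(dtype=float)

    def log2p1(self) -> "ExpressionMatrix":
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("negative expression values before log transform")
        return ExpressionMatrix(np.log2(self.values + 1.0), normalization="log2p1")


@dataclass
class PWM:
    """Position weight matrix as per-position base log-odds (A,C,G,T rows).

    ``threshold`` is the minimal log-odds score a scanning window must
    reach to count as a binding site; by convention it is a fraction of
    :meth:`max_score` chosen by the caller.
    """

    id: str
    matrix: np.ndarray  # shape (4, width), log2 odds
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    threshold: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4 or self.matrix.shape[1] < 1:
            raise ValidationError(f"PWM {self.id!r}: matrix must be 4 x width>=1")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValidationError(f"PWM {self.id!r}: background must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=0))

    def reverse_complement_matrix(self) -> np.ndarray:
        # complement = reverse row order (A<->T, C<->G), then reverse columns
        return self.matrix[::-1, ::-1]

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        counts: np.ndarray,
        background: np.ndarray | None = None,
        pseudocount: float = 1.0,
        threshold_frac: float = 0.0,
    ) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValidationError(f"PWM {motif_id!r}: counts must be 4 x width")
        if (counts < 0).any():
            raise ValidationError(f"PWM {motif_id!r}: negative counts")
        if (counts.sum(axis=0) == 0).any():
            raise ValidationError(f"PWM {motif_id!r}: all-zero column")
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        padded = counts + pseudocount
        probs = padded / padded.sum(axis=0, keepdims=True)
        matrix = np.log2(probs / bg[:, None])
        pwm = cls(motif_id, matrix, bg)
        pwm.threshold = threshold_frac * pwm.max_score
        return pwm


@dataclass(frozen=True)
class SnpRecord:
    """A variant with per-trait association p-values."""

    chrom: str
    pos: int  # 0-based
    rsid: str
    ref: str
    alt: str
    pvalues: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for trait, p in self.pvalues.items():
            if not (0.0 < p <= 1.0):
                raise ValidationError(
                    f"SNP {self.rsid}: p-value for {trait!r} is {p}, not in (0, 1]"
                )

    @property
    def min_pvalue(self) -> float:
        if not self.pvalues:
            raise ValidationError(f"SNP {self.rsid}: no trait p-values")
        return min(self.pvalues.values())


class EdgeList:
    """A set of directed (regulator, target) gene pairs with optional weights."""

    def __init__(
        self,
        edges: Iterable[tuple[str, str]] = (),
        weights: Mapping[tuple[str, str], float] | None = None,
        allow_self_loops: bool = False,
    ):
        self.edges: set[tuple[str, str]] = set()
        self.weights: dict[tuple[str, str], float] = {}
        weights = weights or {}
        for edge in edges:
            reg, tgt = edge
            if reg == tgt and not allow_self_loops:
                raise ValidationError(f"self-loop {reg!r} not allowed")
            self.edges.add((reg, tgt))
            if edge in weights:
                self.weights[edge] = float(weights[edge])

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, edge: tuple[str, str]) -> bool:
        return edge in self.edges

    def __iter__(self):
        return iter(sorted(self.edges))

    def restricted(self, universe: set[str]) -> "EdgeList":
        kept = {e for e in self.edges if e[0] in universe and e[1] in universe}
        return EdgeList(kept, self.weights, allow_self_loops=True)

    def genes(self) -> set[str]:
        return {g for e in self.edges for g in e}


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _data_lines(path: str | Path):
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def parse_bed(path: str | Path, expect_score: bool = False) -> list[GenomicInterval]:
    """Read a BED3/BED4/BED5 file into intervals, file order preserved.

    Column 4 becomes the interval id, column 5 the score when
    ``expect_score`` is set. Extra columns are ignored with a warning.
    """
    intervals: list[GenomicInterval] = []
    warned = False
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
        if len(fields) > 5 and not warned:
            log.warning("%s: columns beyond 5 ignored (first at line %d)", path, lineno)
            warned = True
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
        name = fields[3] if len(fields) >= 4 and fields[3] != "." else None
        score = None
        if expect_score:
            if len(fields) < 5:
                raise ParseError(f"{path}:{lineno}: score column requested but absent")
            try:
                score = float(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
        try:
            intervals.append(GenomicInterval(fields[0], start, end, name, score))
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.id is not None or iv.score is not None:
                fields.append(iv.id if iv.id is not None else ".")
            if iv.score is not None:
                fields.append(repr(iv.score))
            handle.write("\t".join(fields) + "\n")


def parse_chrom_sizes(path: str | Path) -> GenomeIndex:
    lengths: dict[str, int] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 'chrom<TAB>length'")
        try:
            lengths[fields[0]] = int(fields[1])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer length") from exc
    return GenomeIndex(lengths)


def write_chrom_sizes(genome: GenomeIndex, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for chrom, length in genome.items():
            handle.write(f"{chrom}\t{length}\n")


def parse_pwm(
    path: str | Path,
    background: np.ndarray | None = None,
    pseudocount: float = 1.0,
    threshold_frac: float = 0.0,
) -> list[PWM]:
    """Read JASPAR-format count matrices into log-odds PWMs.

    JASPAR blocks look like::

        >MA0001.1 NAME
        A  [ 0  3 79 ... ]
        C  [94 75  4 ... ]
        G  [ 1  0  3 ... ]
        T  [ 2 19 11 ... ]
    """
    pwms: list[PWM] = []
    motif_id: str | None = None
    rows: dict[str, list[float]] = {}

    def flush(lineno: int) -> None:
        nonlocal motif_id, rows
        if motif_id is None:
            return
        missing = [b for b in _BASES if b not in rows]
        if missing:
            raise ParseError(f"{path}:{lineno}: motif {motif_id!r} missing rows {missing}")
        counts = np.array([rows[b] for b in _BASES], dtype=float)
        try:
            pwms.append(
                PWM.from_counts(motif_id, counts, background, pseudocount, threshold_frac)
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: {exc}") from exc
        motif_id, rows = None, {}

    last_lineno = 0
    for lineno, line in _data_lines(path):
        last_lineno = lineno
        if line.startswith(">"):
            flush(lineno)
            motif_id = line[1:].split()[0]
            continue
        if motif_id is None:
            raise ParseError(f"{path}:{lineno}: count row before any '>' header")
        token = line.replace("[", " ").replace("]", " ").split()
        base = token[0].upper()
        if base not in _BASE_INDEX:
            raise ParseError(f"{path}:{lineno}: unknown base row {token[0]!r}")
        try:
            rows[base] = [float(x) for x in token[1:]]
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric count") from exc
    flush(last_lineno + 1)
    return pwms


def write_pwm_counts(pwms_counts: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Write raw count matrices (4 x width, ACGT order) in JASPAR layout."""
    with open(path, "w", encoding="utf-8") as handle:
        for motif_id, counts in pwms_counts.items():
            handle.write(f">{motif_id}\n")
            for base, row in zip(_BASES, np.asarray(counts)):
                cells = " ".join(f"{v:g}" for v in row)
                handle.write(f"{base} [ {cells} ]\n")


def parse_expression_matrix(
    path: str | Path, log_transform: bool = False
) -> ExpressionMatrix:
    """Read a TSV with gene ids in the first column, sample ids in the header."""
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"{path}: cannot read expression TSV: {exc}") from exc
    bad = frame.map(lambda v: not isinstance(v, (int, float)) or pd.isna(v))
    if bad.to_numpy().any():
        row, col = next(zip(*np.nonzero(bad.to_numpy())))
        raise ParseError(
            f"{path}: non-numeric cell at gene {frame.index[row]!r}, "
            f"sample {frame.columns[col]!r}"
        )
    frame = frame.astype(float)
    frame.index.name = None
    matrix = ExpressionMatrix(frame)
    return matrix.log2p1() if log_transform else matrix


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")


def parse_snp_table(path: str | Path, genome: GenomeIndex | None = None) -> list[SnpRecord]:
    """Read a SNP TSV: chrom, pos, rsid, ref, alt, then one p-value per trait.

    Missing p-values may be left as 'NA' and are simply absent from the record.
    """
    frame = pd.read_csv(path, sep="\t", comment="#")
    required = ["chrom", "pos", "rsid", "ref", "alt"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    traits = [c for c in frame.columns if c not in required]
    snps: list[SnpRecord] = []
    for row in frame.itertuples(index=False):
        pvals = {}
        for trait in traits:
            value = getattr(row, trait)
            if pd.notna(value):
                pvals[trait] = float(value)
        pos = int(row.pos)
        if genome is not None:
            if row.chrom not in genome or not (0 <= pos < genome[row.chrom]):
                raise ValidationError(
                    f"{path}: SNP {row.rsid} position {row.chrom}:{pos} outside genome"
                )
        snps.append(SnpRecord(str(row.chrom), pos, str(row.rsid), str(row.ref),
                              str(row.alt), pvals))
    return snps


def write_snp_table(snps: Sequence[SnpRecord], path: str | Path) -> None:
    traits = sorted({t for s in snps for t in s.pvalues})
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\t".join(["chrom", "pos", "rsid", "ref", "alt", *traits]) + "\n")
        for s in snps:
            cells = [s.chrom, str(s.pos), s.rsid, s.ref, s.alt]
            cells += [repr(s.pvalues[t]) if t in s.pvalues else "NA" for t in traits]
            handle.write("\t".join(cells) + "\n")


def parse_edge_list(path: str | Path) -> EdgeList:
    edges: list[tuple[str, str]] = []
    weights: dict[tuple[str, str], float] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 'regulator<TAB>target'")
        edge = (fields[0], fields[1])
        edges.append(edge)
        if len(fields) >= 3:
            try:
                weights[edge] = float(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric weight") from exc
    return EdgeList(edges, weights)


def write_edge_list(edges: EdgeList, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for edge in edges:
            if edge in edges.weights:
                handle.write(f"{edge[0]}\t{edge[1]}\t{edges.weights[edge]!r}\n")
            else:
                handle.write(f"{edge[0]}\t{edge[1]}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a (small) FASTA file into a dict of uppercase sequences."""
    from pyfaidx import Fasta

    with Fasta(str(path), as_raw=True, sequence_always_upper=True) as fasta:
        return {name: str(fasta[name][:]) for name in fasta.keys()}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for name, seq in sequences.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


# Network triplet TSV serialization lives logically here but depends on the
# network containers; re-exported for a single import surface.


def read_network(path: str | Path):
    from .networks import ConsensusNetwork

    return ConsensusNetwork.read_tsv(path)


def write_network(network, path: str | Path) -> None:
    network.write_tsv(path)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Sort and merge overlapping or adjacent intervals (ids/scores dropped)."""
    ordered = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ordered:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(len(iv) for iv in merge_intervals(intervals))
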