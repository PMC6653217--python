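"""Readers and writers for the text formats the pipeline touches.

Peak calls arrive as BED5/BED6/broadPeak-style lines, gene models as BED6
with the gene identifier in column 4, expression as a headed TSV, motifs as
JASPAR-style matrices and gene sets as GMT.  All genomic coordinates are
0-based, half-open (the BED convention); on the minus strand the TSS is the
last covered base (``end - 1``).

Also hosts the differential-expression filter applied upstream of every
other module: a gene is a DEG when its fold change is at least ``min_fc``
(or at most ``1/min_fc``) and its adjusted significance is below ``max_q``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

#: Histone-mark vocabulary used throughout the pipeline.
MARKS = ("H3K4me3", "H3K27ac", "H3K4me1", "H3K27me3", "H3K9me3")

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end - 1) / 2.0

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of bases shared with ``other`` (0 on different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def distance_to_point(self, pos: int) -> int:
        """Distance from the nearest covered base to ``pos`` (0 if inside)."""
        return max(self.start - pos, pos - (self.end - 1), 0)


@dataclass(frozen=True)
class Peak:
    """A called peak for one histone mark in one cell line."""

    interval: GenomicInterval
    mark: str
    tag_count: float
    score: float | None = None
    cell: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if self.tag_count < 0:
            raise ValueError("tag_count must be non-negative")


@dataclass(frozen=True)
class GeneModel:
    """A gene with its transcription start site and body interval."""

    gene_id: str
    tss: int
    strand: str
    interval: GenomicInterval

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass
class ExpressionRecord:
    """Per-gene abundance in two conditions with differential statistics.

    ``fc`` is the condition-B over condition-A fold change on the linear
    scale; ``q`` the multiple-testing-adjusted significance.  ``is_deg`` and
    ``direction`` are set by :func:`filter_degs`.
    """

    gene_id: str
    fpkm_a: float
    fpkm_b: float
    fc: float
    q: float | None = None
    is_deg: bool = False
    direction: str | None = None  # "up" / "down" once flagged

    def __post_init__(self) -> None:
        if self.fpkm_a < 0 or self.fpkm_b < 0:
            raise ValueError(f"negative abundance for {self.gene_id}")
        if self.fc <= 0:
            raise ValueError(f"fold change must be positive for {self.gene_id}")

    @property
    def log2fc(self) -> float:
        return float(np.log2(self.fc))


@dataclass(frozen=True)
class Pwm:
    """Position weight matrix over {A, C, G, T}.

    ``matrix`` has one row per motif position; each row is a probability
    distribution over the four bases (columns ordered A, C, G, T).
    """

    tf_name: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise ValueError("PWM matrix must be (width, 4) with width >= 1")
        if np.any(m < 0):
            raise ValueError("PWM probabilities must be non-negative")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each PWM position must sum to 1")
        object.__setattr__(self, "matrix", m)

    @property
    def width(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=1))

    @classmethod
    def from_counts(
        cls, tf_name: str, counts: np.ndarray, pseudocount: float = 0.0
    ) -> "Pwm":
        """Build a PWM from a (width, 4) count matrix, renormalizing columns."""
        c = np.asarray(counts, dtype=float) + pseudocount
        totals = c.sum(axis=1)
        if np.any(totals <= 0):
            raise ParseError(f"PWM {tf_name}: position with zero total count")
        return cls(tf_name, c / totals[:, None])


# ---------------------------------------------------------------------------
# parsers
# ---------------------------------------------------------------------------


def _data_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t") if "\t" in line else line.split()


def parse_peaks(
    path: str | Path,
    mark: str,
    cell: str = "",
    tag_column: int = 4,
) -> list[Peak]:
    """Parse a BED5+/broadPeak file into :class:`Peak` records.

    ``tag_column`` is the 0-based index of the column holding the tag count
    (4 for BED5 score, 6 for broadPeak signalValue).  Comment/track lines
    are skipped; malformed data lines raise :class:`ParseError` naming the
    line number.
    """
    peaks: list[Peak] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
        if start >= end:
            raise ParseError(f"{path}:{lineno}: start {start} >= end {end}")
        name = fields[3] if len(fields) > 3 else f"peak_{lineno}"
        tag = 0.0
        if len(fields) > tag_column:
            try:
                tag = float(fields[tag_column])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: tag count column {tag_column + 1} "
                    f"is not numeric"
                ) from exc
        try:
            peaks.append(
                Peak(GenomicInterval(fields[0], start, end), mark, tag, cell=cell,
                     name=name)
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_peaks(peaks: Sequence[Peak], path: str | Path) -> None:
    """Write peaks as BED6 with the tag count in the score column."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            name = p.name or f"peak_{i}"
            tag = int(p.tag_count) if float(p.tag_count).is_integer() else p.tag_count
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t"
                f"{name}\t{tag}\t{p.interval.strand}\n"
            )


def parse_gene_models(path: str | Path) -> list[GeneModel]:
    """Parse BED6 gene models; the TSS is ``start`` on '+' and ``end - 1`` on '-'."""
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for lineno, fields in _data_lines(path):
        if len(fields) < 6:
            raise ParseError(f"{path}:{lineno}: gene models need 6 BED columns")
        chrom, start, end, gene_id, _score, strand = fields[:6]
        if strand not in ("+", "-"):
            raise ParseError(f"{path}:{lineno}: unknown strand {strand!r}")
        if gene_id in seen:
            raise ParseError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        start, end = int(start), int(end)
        tss = start if strand == "+" else end - 1
        genes.append(GeneModel(gene_id, tss, strand, GenomicInterval(chrom, start, end, strand)))
    return genes


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.interval.chrom}\t{g.interval.start}\t{g.interval.end}\t"
                f"{g.gene_id}\t0\t{g.strand}\n"
            )


def parse_expression(path: str | Path, pseudocount: float = 1.0) -> list[ExpressionRecord]:
    """Parse a headed expression TSV (gene_id, fpkm_a, fpkm_b[, fc][, q]).

    When the fold-change column is absent it is computed as
    ``(fpkm_b + eps) / (fpkm_a + eps)`` with ``eps = pseudocount`` so that
    zero-abundance genes yield a finite ratio.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "fpkm_a", "fpkm_b"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}")
    records: list[ExpressionRecord] = []
    for row in df.itertuples(index=False):
        fpkm_a, fpkm_b = float(row.fpkm_a), float(row.fpkm_b)
        if fpkm_a < 0 or fpkm_b < 0:
            raise ParseError(f"{path}: negative abundance for {row.gene_id}")
        if "fc" in df.columns and not np.isnan(getattr(row, "fc")):
            fc = float(getattr(row, "fc"))
        else:
            fc = (fpkm_b + pseudocount) / (fpkm_a + pseudocount)
        q = None
        if "q" in df.columns and not np.isnan(getattr(row, "q")):
            q = float(getattr(row, "q"))
        records.append(ExpressionRecord(str(row.gene_id), fpkm_a, fpkm_b, fc, q))
    return records


def write_expression(records: Sequence[ExpressionRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tfpkm_a\tfpkm_b\tfc\tq\n")
        for r in records:
            q = "" if r.q is None else repr(r.q)
            fh.write(f"{r.gene_id}\t{r.fpkm_a!r}\t{r.fpkm_b!r}\t{r.fc!r}\t{q}\n")


def filter_degs(
    records: Sequence[ExpressionRecord],
    min_fc: float = 1.5,
    max_q: float = 0.05,
    use_q: bool = True,
) -> list[ExpressionRecord]:
    """Keep differentially expressed genes (>= ``min_fc`` fold, q < ``max_q``).

    Down-regulation is symmetric on the ratio scale (``fc <= 1/min_fc``).
    Returns flagged copies; the input records are left untouched.
    """
    if min_fc < 1:
        raise ValueError("min_fc must be >= 1")
    kept: list[ExpressionRecord] = []
    for r in records:
        if use_q:
            if r.q is None:
                raise ValueError(f"{r.gene_id}: q missing with the q-filter enabled")
            if not (r.q < max_q):
                continue
        if r.fc >= min_fc:
            kept.append(replace(r, is_deg=True, direction="up"))
        elif r.fc <= 1.0 / min_fc:
            kept.append(replace(r, is_deg=True, direction="down"))
    return kept


def parse_pwms(path: str | Path, pseudocount: float = 0.0) -> list[Pwm]:
    """Parse JASPAR-style matrices (counts or probabilities) into PWMs.

    Expects blocks of the form::

        >MA0001.1 TFNAME
        A [ 4 19  0 ]
        C [16  0 20 ]
        G [ 0  1  0 ]
        T [ 0  0  0 ]

    Brackets are optional.  Count matrices are converted to probabilities
    with ``pseudocount`` added to every cell and each position renormalized;
    a position whose total is zero raises :class:`ParseError`.
    """
    pwms: list[Pwm] = []
    name: str | None = None
    rows: dict[str, list[float]] = {}

    def _flush() -> None:
        nonlocal name, rows
        if name is None:
            return
        missing = [b for b in _BASES if b not in rows]
        if missing:
            raise ParseError(f"PWM {name}: missing rows for {missing}")
        widths = {len(v) for v in rows.values()}
        if len(widths) != 1:
            raise ParseError(f"PWM {name}: ragged matrix rows")
        counts = np.array([rows[b] for b in _BASES], dtype=float).T  # (width, 4)
        pwms.append(Pwm.from_counts(name, counts, pseudocount))
        name, rows = None, {}

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                tokens = line[1:].split()
                if not tokens:
                    raise ParseError(f"{path}: empty PWM header")
                name = tokens[1] if len(tokens) > 1 else tokens[0]
                continue
            if name is None:
                raise ParseError(f"{path}: matrix row before any header")
            base, _, rest = line.partition(" ")
            base = base.upper().rstrip(":")
            if base not in _BASE_INDEX:
                raise ParseError(f"{path}: unexpected matrix row {line!r}")
            rest = rest.replace("[", " ").replace("]", " ")
            rows[base] = [float(x) for x in rest.split()]
    _flush()
    return pwms


def write_pwms(pwms: Sequence[Pwm], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.tf_name} {p.tf_name}\n")
            for j, b in enumerate(_BASES):
                vals = " ".join(f"{v:.6f}" for v in p.matrix[:, j])
                fh.write(f"{b} [ {vals} ]\n")


def parse_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT file into ``{set_name: genes}`` (description column ignored)."""
    sets: dict[str, set[str]] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: GMT lines need name, desc, >=1 gene")
        name = fields[0]
        if name in sets:
            raise ParseError(f"{path}:{lineno}: duplicate gene set {name!r}")
        sets[name] = set(fields[2:])
    return sets


def write_gmt(sets: dict[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write(name + "\tna\t" + "\t".join(sorted(genes)) + "\n")
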