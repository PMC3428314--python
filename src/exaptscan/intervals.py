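"""Interval algebra, repeat-annotation parsing, CNEE derivation and
exaptation classification.

Coordinates are 0-based half-open internally (BED convention). RepeatMasker
``.out`` files (1-based inclusive) and SNP tables (1-based positions) are
converted at parse time.

An element is an *exaptation* when a strict majority (> 50%) of its bases
are annotated as deriving from a SINE, LINE, LTR or DNA-transposon
insertion.  The same strict-majority rule assigns the element to a family,
superfamily and class: a CNEE covered 45% by L1 and 45% by L2 is a LINE
exaptation but belongs to no single superfamily.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence, TextIO

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

MOBILE_CLASSES = ("LINE", "SINE", "DNA", "LTR")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open span ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersect(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.chrom, max(self.start, other.start), min(self.end, other.end), self.strand
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class RepeatHit:
    """A genomic repeat fragment with its alignment span on the family
    consensus.

    ``cons_start``/``cons_end`` are 1-based inclusive consensus coordinates
    with ``cons_start <= cons_end`` on both strands; ``cons_length`` is the
    full consensus length.  ``klass`` is one of LINE/SINE/DNA/LTR or
    ``"other"`` (excluded from exaptation analysis).
    """

    interval: GenomicInterval
    family: str
    superfamily: str
    klass: str
    cons_start: int
    cons_end: int
    cons_length: int

    def __post_init__(self) -> None:
        if not (1 <= self.cons_start <= self.cons_end <= self.cons_length):
            raise ValueError(
                f"inconsistent consensus coordinates {self.cons_start}-"
                f"{self.cons_end} on consensus of length {self.cons_length}"
            )


@dataclass
class CNEERecord:
    """A conserved non-exonic element with its exaptation annotation."""

    interval: GenomicInterval
    repeat_fraction: float = 0.0
    exapted: bool = False
    assigned_class: str | None = None
    assigned_superfamily: str | None = None
    assigned_family: str | None = None

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class ExaptationSummary:
    """Class/superfamily exaptation tabulation.

    ``table`` rows are keyed ``(class, superfamily)`` with superfamily
    ``""`` for class-level rows and ``("Total", "")`` for the grand total;
    ratio columns are the genomic/exapted quotients truncated (floored) to
    one decimal, or NaN where the exapted count is zero.
    """

    table: pd.DataFrame


# ---------------------------------------------------------------------------
# RepeatMasker .out parsing


def _parse_class_field(raw: str) -> tuple[str, str]:
    """Split a RepeatMasker class/family field like ``LINE/L1``.

    Returns (class, superfamily); classes outside the four mobile-element
    classes collapse to ``other``.
    """
    if "/" in raw:
        klass, superfamily = raw.split("/", 1)
    else:
        klass, superfamily = raw, raw
    # RepeatMasker suffixes like "SINE?" mark uncertain calls; keep the stem.
    klass = klass.rstrip("?")
    if klass not in MOBILE_CLASSES:
        return "other", superfamily
    return klass, superfamily


def parse_repeatmasker_out(stream: TextIO | str) -> list[RepeatHit]:
    """Parse RepeatMasker ``.out`` annotation (15-column dialect).

    Header lines are tolerated.  Strand ``C`` becomes ``-`` and the
    consensus columns are normalised so that ``cons_start <= cons_end`` on
    both strands: for ``+`` hits columns 12-14 are repStart, repEnd,
    (repLeft); for ``C`` hits they are (repLeft), repEnd, repStart.
    ``cons_length = cons_end + repLeft``.
    """
    if isinstance(stream, str):
        with open(stream) as fh:
            return parse_repeatmasker_out(fh)

    hits: list[RepeatHit] = []
    for lineno, line in enumerate(stream, start=1):
        fields = line.split()
        if not fields:
            continue
        # Standard headers start with "SW"/"score" or are the blank ruler line.
        if fields[0] in ("SW", "score") or not fields[0][0].isdigit():
            continue
        if len(fields) < 14:
            raise ValueError(f"malformed .out line {lineno}: expected >=14 fields")
        try:
            chrom = fields[4]
            qstart = int(fields[5])  # 1-based inclusive
            qend = int(fields[6])
            strand_raw = fields[8]
            family = fields[9]
            klass, superfamily = _parse_class_field(fields[10])
            c12, c13, c14 = fields[11], fields[12], fields[13]
            if strand_raw == "+":
                cons_start = int(c12)
                cons_end = int(c13)
                left = int(c14.strip("()"))
                strand = "+"
            elif strand_raw in ("C", "-"):
                left = int(c12.strip("()"))
                cons_end = int(c13)
                cons_start = int(c14)
                strand = "-"
            else:
                raise ValueError(f"unknown strand {strand_raw!r}")
        except ValueError as exc:
            raise ValueError(f"malformed .out line {lineno}: {exc}") from exc
        cons_length = cons_end + left
        if not (1 <= cons_start <= cons_end <= cons_length):
            raise ValueError(
                f"malformed .out line {lineno}: consensus coordinates "
                f"{cons_start}-{cons_end} inconsistent with length {cons_length}"
            )
        hits.append(
            RepeatHit(
                interval=GenomicInterval(chrom, qstart - 1, qend, strand),
                family=family,
                superfamily=superfamily,
                klass=klass,
                cons_start=cons_start,
                cons_end=cons_end,
                cons_length=cons_length,
            )
        )
    return hits


def write_repeatmasker_out(hits: Sequence[RepeatHit], path: str) -> None:
    """Emit hits in the 15-column ``.out`` dialect read back by
    :func:`parse_repeatmasker_out`."""
    with open(path, "w") as fh:
        fh.write(
            "   SW  perc perc perc  query     position in query    "
            "matching repeat          position in repeat\n"
            "score  div. del. ins.  sequence  begin end     (left) "
            "repeat  class/family    begin end (left) ID\n\n"
        )
        for i, h in enumerate(hits, start=1):
            left = h.cons_length - h.cons_end
            klass_field = (
                f"{h.klass}/{h.superfamily}" if h.klass != "other" else h.superfamily
            )
            if h.interval.strand == "-":
                rep_cols = f"({left}) {h.cons_end} {h.cons_start}"
                strand = "C"
            else:
                rep_cols = f"{h.cons_start} {h.cons_end} ({left})"
                strand = "+"
            fh.write(
                f"1000 0.0 0.0 0.0 {h.interval.chrom} {h.interval.start + 1} "
                f"{h.interval.end} (0) {strand} {h.family} {klass_field} "
                f"{rep_cols} {i}\n"
            )


# ---------------------------------------------------------------------------
# BED I/O


def read_bed(path: str) -> list[GenomicInterval]:
    """Read a BED3+ file into intervals (strand taken from column 6 if present)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    out = []
    for row in df.itertuples(index=False):
        strand = row[5] if len(row) > 5 and row[5] in ("+", "-") else "."
        out.append(GenomicInterval(str(row[0]), int(row[1]), int(row[2]), strand))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# CNEE derivation


def derive_cnees(
    conserved: Sequence[GenomicInterval],
    exonic_tracks: Sequence[Sequence[GenomicInterval]],
) -> list[CNEERecord]:
    """Remove conserved elements overlapping any exonic track.

    Removal is whole-element: an element overlapping >= 1 base of the union
    of the exonic tracks is dropped entirely (no trimming).  Survivors
    become :class:`CNEERecord` objects with exaptation fields unset.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for track in exonic_tracks:
        for iv in track:
            trees[iv.chrom].addi(iv.start, iv.end)
    survivors = []
    for iv in conserved:
        tree = trees.get(iv.chrom)
        if tree is not None and tree.overlap(iv.start, iv.end):
            continue
        survivors.append(CNEERecord(interval=iv))
    return survivors


# ---------------------------------------------------------------------------
# Exaptation classification


def _majority_taxon(cover: dict[str, int], length: int) -> str | None:
    """The taxon covering a strict majority of bases, if any."""
    for taxon, n in cover.items():
        if n * 2 > length:
            return taxon
    return None


def classify_exaptation(cnee: CNEERecord, hits: Sequence[RepeatHit]) -> CNEERecord:
    """Annotate one CNEE with its repeat-derived fraction and taxon.

    Per-base deduplication: a base covered by several hits counts once
    toward the union fraction, and once per distinct taxon at each level
    (family, superfamily, class).  ``exapted`` iff the union fraction is a
    strict majority; the taxon at each level is assigned only when a single
    taxon itself covers a strict majority of bases.
    """
    iv = cnee.interval
    L = iv.length
    union = np.zeros(L, dtype=bool)
    by_family: dict[str, np.ndarray] = {}
    by_superfamily: dict[str, np.ndarray] = {}
    by_class: dict[str, np.ndarray] = {}
    for hit in hits:
        if hit.klass not in MOBILE_CLASSES:
            continue
        inter = iv.intersect(hit.interval)
        if inter is None:
            continue
        lo, hi = inter.start - iv.start, inter.end - iv.start
        union[lo:hi] = True
        for key, pool in (
            (hit.family, by_family),
            (hit.superfamily, by_superfamily),
            (hit.klass, by_class),
        ):
            mask = pool.get(key)
            if mask is None:
                mask = pool[key] = np.zeros(L, dtype=bool)
            mask[lo:hi] = True

    frac = union.sum() / L
    exapted = frac > 0.5
    record = replace(
        cnee,
        repeat_fraction=float(frac),
        exapted=bool(exapted),
        assigned_class=None,
        assigned_superfamily=None,
        assigned_family=None,
    )
    if not exapted:
        return record
    counts = lambda pool: {k: int(v.sum()) for k, v in pool.items()}
    record.assigned_class = _majority_taxon(counts(by_class), L)
    record.assigned_superfamily = _majority_taxon(counts(by_superfamily), L)
    record.assigned_family = _majority_taxon(counts(by_family), L)
    # Nesting: a family majority implies its superfamily/class majorities,
    # but enforce the invariant explicitly for degenerate label collisions.
    if record.assigned_superfamily is None:
        record.assigned_family = None
    if record.assigned_class is None:
        record.assigned_superfamily = None
        record.assigned_family = None
    return record


def classify_all(
    cnees: Sequence[CNEERecord], hits: Sequence[RepeatHit]
) -> list[CNEERecord]:
    """Classify every CNEE against the hit set (interval-tree accelerated)."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for hit in hits:
        if hit.klass in MOBILE_CLASSES:
            trees[hit.interval.chrom].addi(hit.interval.start, hit.interval.end, hit)
    out = []
    for cnee in cnees:
        tree = trees.get(cnee.interval.chrom)
        local = (
            [n.data for n in tree.overlap(cnee.interval.start, cnee.interval.end)]
            if tree is not None
            else []
        )
        out.append(classify_exaptation(cnee, local))
    return out


# ---------------------------------------------------------------------------
# Summary table


def truncate_ratio(numerator: int, denominator: int) -> float:
    """Quotient truncated (floored) to one decimal; NaN when denominator 0.

    Integer arithmetic avoids float floor artefacts: 550/797 prints 0.6.
    """
    if denominator == 0:
        return float("nan")
    return (10 * numerator // denominator) / 10


def summarize_exaptation(
    cnees: Sequence[CNEERecord], hits: Sequence[RepeatHit]
) -> ExaptationSummary:
    """Tabulate exaptation counts and genomic prevalence per class and
    superfamily.

    ``exapted_bases`` counts all bases of each exapted CNEE, attributed to
    the majority taxon of the relevant level; genomic columns count every
    mobile-element hit of that taxon.  Ratio columns are
    genomic/exapted truncated to one decimal ("NA"/NaN on zero exapted).
    """
    ex_el: dict[tuple[str, str], int] = defaultdict(int)
    ex_b: dict[tuple[str, str], int] = defaultdict(int)
    for c in cnees:
        if not c.exapted:
            continue
        ex_el[("Total", "")] += 1
        ex_b[("Total", "")] += c.length
        if c.assigned_class:
            ex_el[(c.assigned_class, "")] += 1
            ex_b[(c.assigned_class, "")] += c.length
        if c.assigned_class and c.assigned_superfamily:
            ex_el[(c.assigned_class, c.assigned_superfamily)] += 1
            ex_b[(c.assigned_class, c.assigned_superfamily)] += c.length

    gen_el: dict[tuple[str, str], int] = defaultdict(int)
    gen_b: dict[tuple[str, str], int] = defaultdict(int)
    for h in hits:
        if h.klass not in MOBILE_CLASSES:
            continue
        for key in (("Total", ""), (h.klass, ""), (h.klass, h.superfamily)):
            gen_el[key] += 1
            gen_b[key] += h.interval.length

    keys = sorted(set(ex_el) | set(gen_el), key=lambda k: (k != ("Total", ""), k))
    rows = []
    for klass, superfamily in keys:
        k = (klass, superfamily)
        rows.append(
            {
                "class": klass,
                "superfamily": superfamily,
                "exapted_elements": ex_el.get(k, 0),
                "exapted_bases": ex_b.get(k, 0),
                "genomic_elements": gen_el.get(k, 0),
                "genomic_bases": gen_b.get(k, 0),
                "elements_per_exaptation": truncate_ratio(
                    gen_el.get(k, 0), ex_el.get(k, 0)
                ),
                "bases_per_exapted_base": truncate_ratio(
                    gen_b.get(k, 0), ex_b.get(k, 0)
                ),
            }
        )
    return ExaptationSummary(table=pd.DataFrame(rows))


def summary_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Recompute the ratio columns from a table of printed count columns.

    ``counts`` needs columns exapted_elements, exapted_bases,
    genomic_elements, genomic_bases; the two ratio columns are derived by
    one-decimal truncation of the genomic/exapted quotients.
    """
    out = counts.copy()
    out["elements_per_exaptation"] = [
        truncate_ratio(int(g), int(e))
        for g, e in zip(counts["genomic_elements"], counts["exapted_elements"])
    ]
    out["bases_per_exapted_base"] = [
        truncate_ratio(int(g), int(e))
        for g, e in zip(counts["genomic_bases"], counts["exapted_bases"])
    ]
    return out
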