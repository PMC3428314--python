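"""Reference-anchored alignment blocks and MAF I/O (via Bio.AlignIO)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass
class AlignmentBlock:
    """One reference-anchored alignment block.

    ``sequences`` maps species name to its aligned row (gaps ``-``); the
    reference row comes first by convention and ``start`` is the 0-based
    reference coordinate of its first non-gap base on ``chrom``.
    """

    chrom: str
    start: int
    reference: str
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        widths = {len(s) for s in self.sequences.values()}
        if len(widths) != 1:
            raise ValueError("ragged alignment block")
        if self.reference not in self.sequences:
            raise ValueError(f"reference row {self.reference!r} missing")

    @property
    def width(self) -> int:
        return len(self.sequences[self.reference])

    @property
    def ref_size(self) -> int:
        """Ungapped reference length of the block."""
        return sum(c != "-" for c in self.sequences[self.reference])

    @property
    def end(self) -> int:
        return self.start + self.ref_size

    def ref_columns(self) -> list[int]:
        """Column index for each reference base, in reference order."""
        return [i for i, c in enumerate(self.sequences[self.reference]) if c != "-"]


def write_maf(blocks: Iterable[AlignmentBlock], path: str, chrom_sizes: dict[str, int] | None = None) -> None:
    alignments = []
    for block in blocks:
        records = []
        ordered = [block.reference] + [s for s in block.sequences if s != block.reference]
        for sp in ordered:
            row = block.sequences[sp]
            size = sum(c != "-" for c in row)
            if sp == block.reference:
                src = f"{sp}.{block.chrom}"
                start = block.start
                src_size = (chrom_sizes or {}).get(block.chrom, block.end)
            else:
                src = f"{sp}.{block.chrom}"
                start = 0
                src_size = max(size, 1)
            rec = SeqRecord(Seq(row), id=src, name=src, description="")
            rec.annotations.update(
                {"start": start, "size": size, "strand": 1, "srcSize": src_size}
            )
            records.append(rec)
        alignments.append(MultipleSeqAlignment(records))
    with open(path, "w") as fh:
        AlignIO.write(alignments, fh, "maf")


def read_maf(path: str) -> list[AlignmentBlock]:
    """Parse a MAF file into blocks; the first row of each block is taken
    as the reference."""
    blocks = []
    with open(path) as fh:
        for aln in AlignIO.parse(fh, "maf"):
            sequences: dict[str, str] = {}
            reference = None
            chrom = None
            start = None
            for rec in aln:
                sp, _, chrom_part = rec.id.partition(".")
                sequences[sp] = str(rec.seq)
                if reference is None:
                    reference = sp
                    chrom = chrom_part or rec.id
                    start = int(rec.annotations.get("start", 0))
            blocks.append(
                AlignmentBlock(chrom=chrom, start=start, reference=reference, sequences=sequences)
            )
    return blocks
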