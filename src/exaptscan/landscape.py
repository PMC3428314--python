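"""Genomic-landscape comparisons.

Density tracks bin elements into fixed windows (1 Mb by default, element
assigned to the window containing its midpoint); similarity of two tracks
is quantified by the Pearson correlation of the first differences of their
normalised densities.  Gene-desert depletion compares, via a one-sided
hypergeometric test, how often exapted versus other elements lie more than
1 Mb from the closest transcription start site.  Fold enrichment against a
feature track is estimated against length-matched random placements, and
distribution shapes are compared with the two-sample Kolmogorov-Smirnov
test.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from exaptscan.intervals import CNEERecord, GenomicInterval

DESERT_DISTANCE = 1_000_000
DEFAULT_WINDOW = 1_000_000


@dataclass
class DensityTrack:
    """Windowed element counts per chromosome (windows tile each
    chromosome; the final partial window is kept)."""

    window: int
    counts: dict[str, np.ndarray]
    normalization: str = "raw"  # raw | fraction

    def normalized(self) -> "DensityTrack":
        total = sum(float(v.sum()) for v in self.counts.values())
        if total == 0:
            raise ValueError("cannot normalise an empty track")
        return DensityTrack(
            window=self.window,
            counts={c: v / total for c, v in self.counts.items()},
            normalization="fraction",
        )


def density_track(
    items: Sequence[GenomicInterval],
    genome_sizes: dict[str, int],
    window: int = DEFAULT_WINDOW,
) -> DensityTrack:
    """Count each element once, in the window containing its midpoint."""
    if window <= 0:
        raise ValueError("window must be > 0")
    counts = {
        chrom: np.zeros(-(-size // window)) for chrom, size in genome_sizes.items()
    }
    for iv in items:
        if iv.chrom not in genome_sizes:
            raise ValueError(f"unknown chromosome {iv.chrom}")
        if iv.end > genome_sizes[iv.chrom]:
            raise ValueError(f"element {iv} beyond chromosome length")
        mid = (iv.start + iv.end) // 2
        counts[iv.chrom][mid // window] += 1
    return DensityTrack(window=window, counts=counts)


def density_change_correlation(a: DensityTrack, b: DensityTrack) -> float:
    """Pearson r of the first differences of the two normalised tracks.

    Differences are taken within chromosomes (no cross-chromosome
    difference) and concatenated.
    """
    if a.window != b.window or set(a.counts) != set(b.counts):
        raise ValueError("tracks must share windows")
    a, b = a.normalized(), b.normalized()
    da, db = [], []
    for chrom in sorted(a.counts):
        if a.counts[chrom].shape != b.counts[chrom].shape:
            raise ValueError("tracks must share windows")
        da.append(np.diff(a.counts[chrom]))
        db.append(np.diff(b.counts[chrom]))
    da, db = np.concatenate(da), np.concatenate(db)
    if sum(v.size for v in a.counts.values()) < 3:
        raise ValueError("need at least 3 windows")
    return float(stats.pearsonr(da, db).statistic)


@dataclass(frozen=True)
class DesertTest:
    n_exapted: int
    n_exapted_far: int
    n_other: int
    n_other_far: int
    p_value: float

    def __post_init__(self) -> None:
        if self.n_exapted_far > self.n_exapted or self.n_other_far > self.n_other:
            raise ValueError("far counts cannot exceed totals")


def _nearest_tss_distance(
    midpoints: dict[str, np.ndarray], tss: Sequence[GenomicInterval]
) -> dict[str, np.ndarray]:
    by_chrom: dict[str, np.ndarray] = {}
    tss_pos: dict[str, list[int]] = defaultdict(list)
    for iv in tss:
        tss_pos[iv.chrom].append(iv.start)
    for chrom, mids in midpoints.items():
        pos = np.array(sorted(tss_pos.get(chrom, [])))
        if pos.size == 0:
            warnings.warn(f"no TSS on {chrom}; its elements are excluded")
            by_chrom[chrom] = np.full(mids.shape, np.nan)
            continue
        idx = np.searchsorted(pos, mids)
        left = np.where(idx > 0, np.abs(mids - pos[np.maximum(idx - 1, 0)]), np.inf)
        right = np.where(
            idx < pos.size, np.abs(pos[np.minimum(idx, pos.size - 1)] - mids), np.inf
        )
        by_chrom[chrom] = np.minimum(left, right)
    return by_chrom


def desert_depletion_test(
    cnees: Sequence[CNEERecord],
    tss: Sequence[GenomicInterval],
    distance: int = DESERT_DISTANCE,
) -> DesertTest:
    """One-sided hypergeometric test for depletion of exapted elements in
    gene deserts (element midpoint more than ``distance`` from the closest
    TSS).  The p-value is the probability of at most the observed number
    of far elements among the exapted draws from the pooled far/near
    population."""
    if not cnees:
        raise ValueError("empty element set")
    midpoints: dict[str, list[int]] = defaultdict(list)
    flags: dict[str, list[bool]] = defaultdict(list)
    for c in cnees:
        midpoints[c.interval.chrom].append((c.interval.start + c.interval.end) // 2)
        flags[c.interval.chrom].append(c.exapted)
    distances = _nearest_tss_distance(
        {c: np.array(v) for c, v in midpoints.items()}, tss
    )
    n_ex = n_ex_far = n_ot = n_ot_far = 0
    for chrom, d in distances.items():
        keep = ~np.isnan(d)
        far = d[keep] > distance
        exapted = np.array(flags[chrom])[keep]
        n_ex += int(exapted.sum())
        n_ex_far += int((far & exapted).sum())
        n_ot += int((~exapted).sum())
        n_ot_far += int((far & ~exapted).sum())
    population = n_ex + n_ot
    total_far = n_ex_far + n_ot_far
    p = float(stats.hypergeom.cdf(n_ex_far, population, total_far, n_ex))
    return DesertTest(
        n_exapted=n_ex,
        n_exapted_far=n_ex_far,
        n_other=n_ot,
        n_other_far=n_ot_far,
        p_value=p,
    )


@dataclass(frozen=True)
class FoldEnrichment:
    fold: float
    observed_fraction: float
    expected_fraction: float
    n_elements: int
    n_placements: int


def fold_enrichment(
    cnees: Sequence[GenomicInterval],
    features: Sequence[GenomicInterval],
    genome_sizes: dict[str, int],
    n_placements: int = 1000,
    seed: int = 0,
) -> FoldEnrichment:
    """Fraction of elements overlapping >= 1 feature base, relative to the
    expectation for length-matched intervals placed uniformly at random
    (``n_placements`` seeded randomisations).

    A zero expected fraction yields an infinite fold (flagged by the
    expected_fraction field).
    """
    if not cnees:
        raise ValueError("empty element set")
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for f in features:
        if f.chrom not in genome_sizes or f.end > genome_sizes[f.chrom]:
            raise ValueError(f"feature {f} outside genome")
        trees[f.chrom].addi(f.start, f.end)

    def frac_overlapping(items: Sequence[GenomicInterval]) -> float:
        hit = sum(
            1
            for iv in items
            if iv.chrom in trees and trees[iv.chrom].overlap(iv.start, iv.end)
        )
        return hit / len(items)

    observed = frac_overlapping(cnees)
    rng = np.random.default_rng(seed)
    chroms = sorted(genome_sizes)
    sizes = np.array([genome_sizes[c] for c in chroms], dtype=float)
    weights = sizes / sizes.sum()
    expected_sum = 0.0
    lengths = [iv.length for iv in cnees]
    for _ in range(n_placements):
        placed = []
        for length in lengths:
            ci = rng.choice(len(chroms), p=weights)
            start = int(rng.integers(0, max(1, genome_sizes[chroms[ci]] - length)))
            placed.append(GenomicInterval(chroms[ci], start, start + length))
        expected_sum += frac_overlapping(placed)
    expected = expected_sum / n_placements
    fold = float("inf") if expected == 0 else observed / expected
    return FoldEnrichment(
        fold=fold,
        observed_fraction=observed,
        expected_fraction=expected,
        n_elements=len(cnees),
        n_placements=n_placements,
    )


def ks_distribution_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and asymptotic p-value."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)
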