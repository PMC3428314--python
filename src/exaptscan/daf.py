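"""Derived-allele-frequency spectra and rank-shift significance testing.

A region set's DAF spectrum is the multiset of derived-allele frequencies
of segregating sites falling inside the region union.  A downward rank
shift of one spectrum against a neutral proxy indicates ongoing purifying
selection: deleterious derived alleles rarely reach high population
frequencies.  Significance comes from the two-sample Mann-Whitney U test,
computed by exact enumeration for small samples and by the tie-corrected
normal approximation otherwise.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from exaptscan.intervals import GenomicInterval

EXACT_LIMIT = 12  # exact enumeration when n_a + n_b <= this


@dataclass(frozen=True)
class DAFSite:
    """One segregating site (0 < derived_count < sample_size)."""

    position: GenomicInterval
    derived_count: int
    sample_size: int

    def __post_init__(self) -> None:
        if self.position.length != 1:
            raise ValueError("site position must have width 1")
        if not 0 < self.derived_count < self.sample_size:
            raise ValueError("site must be segregating")

    @property
    def frequency(self) -> float:
        return self.derived_count / self.sample_size


@dataclass
class DAFSpectrum:
    name: str
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.size and not ((f > 0) & (f < 1)).all():
            raise ValueError("frequencies must lie strictly in (0, 1)")
        self.frequencies = f

    def __len__(self) -> int:
        return self.frequencies.size


def read_sites_tsv(path: str) -> list[DAFSite]:
    """Read the SNP TSV dialect (chrom, 1-based pos, ancestral, derived,
    derived_count, sample_size); non-segregating rows are rejected."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        DAFSite(
            position=GenomicInterval(r.chrom, int(r.pos) - 1, int(r.pos)),
            derived_count=int(r.derived_count),
            sample_size=int(r.sample_size),
        )
        for r in df.itertuples()
    ]


def region_daf_spectrum(
    sites: Sequence[DAFSite],
    regions: Sequence[GenomicInterval],
    name: str = "",
) -> DAFSpectrum:
    """Spectrum of the sites whose position lies in the region union
    (half-open; duplicates preserved)."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for iv in regions:
        trees[iv.chrom].addi(iv.start, iv.end)
    freqs = [
        s.frequency
        for s in sites
        if s.position.chrom in trees
        and trees[s.position.chrom].overlaps_point(s.position.start)
    ]
    return DAFSpectrum(name=name, frequencies=np.array(freqs))


@dataclass(frozen=True)
class RankShiftResult:
    u_statistic: float  # U for spectrum a
    p_value: float
    lower_mean_rank: str  # name of the spectrum with the lower mean rank
    mean_rank_difference: float  # mean rank a - mean rank b
    method: str


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample a: #{a_i > b_j} + 0.5 #{a_i = b_j}."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt + 0.5 * eq)


def _exact_p(a: np.ndarray, b: np.ndarray, alternative: str) -> tuple[float, float]:
    """Exact Mann-Whitney by enumerating all label assignments of the
    pooled sample (ties handled naturally)."""
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    u_obs = _u_statistic(a, b)
    lower = higher = 0
    total = comb(n, na)
    for idx_a in combinations(range(n), na):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx_a)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        if u <= u_obs + 1e-12:
            lower += 1
        if u >= u_obs - 1e-12:
            higher += 1
    p_less = lower / total
    p_greater = higher / total
    if alternative == "less":
        return u_obs, p_less
    if alternative == "greater":
        return u_obs, p_greater
    return u_obs, min(1.0, 2 * min(p_less, p_greater))


def rank_shift_test(
    a: DAFSpectrum, b: DAFSpectrum, alternative: str = "two-sided"
) -> RankShiftResult:
    """Mann-Whitney rank-shift test between two spectra.

    ``alternative`` is ``two-sided`` or ``a-less`` (spectrum *a* shifted
    toward rarer derived alleles).  Exact enumeration is used when the
    pooled size is at most 12, the tie-corrected normal approximation
    otherwise; the result also reports which spectrum has the lower mean
    rank of frequencies in the pooled ranking.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both spectra must be non-empty")
    if alternative not in ("two-sided", "a-less"):
        raise ValueError("alternative must be 'two-sided' or 'a-less'")
    alt = "less" if alternative == "a-less" else "two-sided"
    pooled = np.concatenate([a.frequencies, b.frequencies])
    ranks = stats.rankdata(pooled)
    diff = float(ranks[: len(a)].mean() - ranks[len(a) :].mean())
    lower = a.name if diff < 0 else b.name if diff > 0 else "tie"
    if len(a) + len(b) <= EXACT_LIMIT:
        u, p = _exact_p(a.frequencies, b.frequencies, alt)
        method = "exact"
    else:
        res = stats.mannwhitneyu(
            a.frequencies, b.frequencies, alternative=alt, method="asymptotic"
        )
        u, p = float(res.statistic), float(res.pvalue)
        method = "normal-approximation"
    return RankShiftResult(
        u_statistic=u,
        p_value=p,
        lower_mean_rank=lower,
        mean_rank_difference=diff,
        method=method,
    )
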