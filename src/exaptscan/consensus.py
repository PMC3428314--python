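"""Repeat-consensus coordinate profiling, enrichment-peak calling and
paralog motif comparison.

Under neutral co-option, the chance that a consensus base ends up under
selection is directly proportional to how often that base occurs in
genomic copies of the repeat.  The per-position *fold* track — the exapted
base density divided by the genomic density, both normalised to sum to
one — tests that null: runs of positions with fold above 2, supported by
at least 40 distinct exaptation events, are called enrichment peaks.
Significance of the observed peak count is calibrated by randomly
re-placing the element set across the genome and re-running the whole
classification/profiling/peak-calling path.  The paralogous sequences
behind one peak can be stacked (consensus-anchored, consensus-oriented)
into a position weight matrix and compared against transcription-factor
binding profiles with a simple column-correlation scan; MEME/Tomtom remain
the external reference tools for real data.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from exaptscan.intervals import (
    CNEERecord,
    GenomicInterval,
    MOBILE_CLASSES,
    RepeatHit,
    classify_all,
)

FOLD_MIN = 2.0
SUPPORT_MIN = 40
_COMP = str.maketrans("ACGT", "TGCA")
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def map_to_consensus(sub: GenomicInterval, hit: RepeatHit) -> tuple[int, int]:
    """Project a genomic sub-interval of a repeat hit onto 1-based
    inclusive consensus coordinates by affine interpolation.

    On the minus strand the mapping is mirrored from ``cons_end``.  Real
    annotations may hide indels inside the hit, which the interpolation
    spreads evenly; the result is clipped to the hit's consensus span.
    """
    if not hit.interval.contains(sub):
        raise ValueError(f"{sub} not contained in hit {hit.interval}")
    g_start = hit.interval.start
    g_span = hit.interval.length
    cons_span = hit.cons_end - hit.cons_start + 1

    def project(g: int) -> int:
        frac = 0.0 if g_span == 1 else (g - g_start) * (cons_span - 1) / (g_span - 1)
        if hit.interval.strand == "-":
            c = hit.cons_end - _round_half_up(frac)
        else:
            c = hit.cons_start + _round_half_up(frac)
        return min(max(c, hit.cons_start), hit.cons_end)

    c1, c2 = project(sub.start), project(sub.end - 1)
    return (min(c1, c2), max(c1, c2))


def map_from_consensus(cons_lo: int, cons_hi: int, hit: RepeatHit) -> GenomicInterval:
    """Inverse affine projection of a 1-based inclusive consensus interval
    back to genomic coordinates within the hit."""
    if not (hit.cons_start <= cons_lo <= cons_hi <= hit.cons_end):
        raise ValueError("consensus interval escapes the hit span")
    g_start = hit.interval.start
    g_span = hit.interval.length
    cons_span = hit.cons_end - hit.cons_start + 1

    def unproject(c: int) -> int:
        if hit.interval.strand == "-":
            frac = hit.cons_end - c
        else:
            frac = c - hit.cons_start
        off = 0 if cons_span == 1 else frac * (g_span - 1) / (cons_span - 1)
        return g_start + _round_half_up(off)

    g1, g2 = unproject(cons_lo), unproject(cons_hi)
    lo, hi = min(g1, g2), max(g1, g2)
    return GenomicInterval(hit.interval.chrom, lo, hi + 1, hit.interval.strand)


@dataclass
class ConsensusProfile:
    """Per-consensus-position coverage of genomic and exapted copies.

    ``fold`` is the per-position share of exapted bases divided by the
    per-position share of genomic bases (NaN where the genomic coverage is
    zero); ``contributors`` records which exapted elements touch each
    position (for peak support counting).
    """

    family: str
    length: int
    genomic_cov: np.ndarray
    exapt_cov: np.ndarray
    contributors: list[set[str]] = field(repr=False, default_factory=list)

    def __post_init__(self) -> None:
        if len(self.genomic_cov) != self.length or len(self.exapt_cov) != self.length:
            raise ValueError("coverage vectors must match consensus length")
        if (self.genomic_cov < 0).any() or (self.exapt_cov < 0).any():
            raise ValueError("coverage counts must be >= 0")
        if not self.contributors:
            self.contributors = [set() for _ in range(self.length)]

    @property
    def is_empty(self) -> bool:
        return self.exapt_cov.sum() == 0

    @property
    def fold(self) -> np.ndarray:
        g_tot = self.genomic_cov.sum()
        e_tot = self.exapt_cov.sum()
        out = np.full(self.length, np.nan)
        if g_tot == 0 or e_tot == 0:
            return out
        g_density = self.genomic_cov / g_tot
        e_density = self.exapt_cov / e_tot
        defined = g_density > 0
        out[defined] = e_density[defined] / g_density[defined]
        return out


def _cnee_id(cnee: CNEERecord) -> str:
    iv = cnee.interval
    return f"{iv.chrom}:{iv.start}-{iv.end}"


def build_profile(
    family: str,
    hits: Sequence[RepeatHit],
    exapted_cnees: Sequence[CNEERecord],
    cons_length: int | None = None,
) -> ConsensusProfile:
    """Accumulate genomic and exapted coverage for one repeat family.

    Genomic coverage increments over every hit's consensus span; exapted
    coverage increments over the consensus projection of each exapted
    element's intersection with a hit, de-duplicated per element.
    """
    fam_hits = [h for h in hits if h.family == family]
    if cons_length is None:
        if not fam_hits:
            raise ValueError(f"no hits for family {family!r}")
        cons_length = fam_hits[0].cons_length
    genomic = np.zeros(cons_length, dtype=int)
    exapt = np.zeros(cons_length, dtype=int)
    contributors: list[set[str]] = [set() for _ in range(cons_length)]
    for h in fam_hits:
        genomic[h.cons_start - 1 : h.cons_end] += 1

    for cnee in exapted_cnees:
        if not cnee.exapted:
            continue
        positions: set[int] = set()
        for h in fam_hits:
            inter = cnee.interval.intersect(h.interval)
            if inter is None:
                continue
            lo, hi = map_to_consensus(inter, h)
            positions.update(range(lo - 1, hi))
        if positions:
            cid = _cnee_id(cnee)
            for p in positions:
                exapt[p] += 1
                contributors[p].add(cid)
    profile = ConsensusProfile(
        family=family,
        length=cons_length,
        genomic_cov=genomic,
        exapt_cov=exapt,
        contributors=contributors,
    )
    if profile.is_empty:
        warnings.warn(f"no exapted bases mapped onto {family!r}; fold undefined")
    return profile


@dataclass(frozen=True)
class EnrichmentPeak:
    """A maximal run of consensus positions exapted more than
    ``fold_min`` times oftener than genomic prevalence predicts."""

    family: str
    cons_start: int  # 1-based inclusive
    cons_end: int
    min_fold: float
    supporting_events: int

    @property
    def width(self) -> int:
        return self.cons_end - self.cons_start + 1


def call_peaks(
    profile: ConsensusProfile,
    fold_min: float = FOLD_MIN,
    support_min: int = SUPPORT_MIN,
) -> list[EnrichmentPeak]:
    """Maximal runs of positions with defined fold > ``fold_min``; a run
    is emitted only when at least ``support_min`` distinct exapted
    elements contribute a base to it."""
    fold = profile.fold
    qualifying = np.where(np.isfinite(fold) & (fold > fold_min))[0]
    peaks: list[EnrichmentPeak] = []
    if qualifying.size == 0:
        return peaks
    run_start = prev = qualifying[0]
    runs = []
    for idx in qualifying[1:]:
        if idx != prev + 1:
            runs.append((run_start, prev))
            run_start = idx
        prev = idx
    runs.append((run_start, prev))
    for lo, hi in runs:
        support: set[str] = set()
        for p in range(lo, hi + 1):
            support |= profile.contributors[p]
        if len(support) >= support_min:
            peaks.append(
                EnrichmentPeak(
                    family=profile.family,
                    cons_start=lo + 1,
                    cons_end=hi + 1,
                    min_fold=float(np.nanmin(fold[lo : hi + 1])),
                    supporting_events=len(support),
                )
            )
    return peaks


# ---------------------------------------------------------------------------
# Permutation null


@dataclass
class PeakNull:
    observed_peaks: int
    trial_counts: np.ndarray
    mean_per_genome: float
    exceedance: float  # fraction of trials with count >= observed


def _random_placement(
    lengths: Sequence[int],
    genome_sizes: dict[str, int],
    rng: np.random.Generator,
) -> list[GenomicInterval]:
    """Uniform non-overlapping placement preserving the length multiset."""
    chroms = sorted(genome_sizes)
    sizes = np.array([genome_sizes[c] for c in chroms], dtype=float)
    weights = sizes / sizes.sum()
    placed: dict[str, list[tuple[int, int]]] = defaultdict(list)
    out = []
    for length in sorted(lengths, reverse=True):
        for attempt in range(500):
            ci = rng.choice(len(chroms), p=weights)
            chrom = chroms[ci]
            limit = genome_sizes[chrom] - length
            if limit <= 0:
                continue
            start = int(rng.integers(0, limit))
            end = start + length
            if any(start < e and s < end for s, e in placed[chrom]):
                continue
            placed[chrom].append((start, end))
            out.append(GenomicInterval(chrom, start, end))
            break
        else:
            raise RuntimeError("genome too small to place all elements")
    return out


def _count_all_peaks(
    cnees: Sequence[CNEERecord],
    hits: Sequence[RepeatHit],
    fold_min: float,
    support_min: int,
) -> int:
    classified = classify_all(cnees, hits)
    exapted = [c for c in classified if c.exapted]
    families = sorted(
        {h.family: h.cons_length for h in hits if h.klass in MOBILE_CLASSES}.items()
    )
    total = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for family, cons_length in families:
            profile = build_profile(family, hits, exapted, cons_length)
            total += len(call_peaks(profile, fold_min, support_min))
    return total


def permutation_peak_null(
    cnees: Sequence[CNEERecord],
    genome_sizes: dict[str, int],
    hits: Sequence[RepeatHit],
    n_trials: int = 1000,
    seed: int = 0,
    fold_min: float = FOLD_MIN,
    support_min: int = SUPPORT_MIN,
) -> PeakNull:
    """Calibrate the observed peak count against random element placement.

    Each trial re-places the element length multiset uniformly (without
    overlap) across the genome and re-runs classification, profiling and
    peak calling; the summary reports the per-trial counts, their mean and
    the empirical exceedance of the observed count.
    """
    observed = _count_all_peaks(cnees, hits, fold_min, support_min)
    lengths = [c.interval.length for c in cnees]
    rng = np.random.default_rng(seed)
    counts = np.zeros(n_trials, dtype=int)
    for t in range(n_trials):
        placement = _random_placement(lengths, genome_sizes, rng)
        trial_cnees = [CNEERecord(interval=iv) for iv in placement]
        counts[t] = _count_all_peaks(trial_cnees, hits, fold_min, support_min)
    return PeakNull(
        observed_peaks=observed,
        trial_counts=counts,
        mean_per_genome=float(counts.mean()),
        exceedance=float((counts >= observed).mean()),
    )


# ---------------------------------------------------------------------------
# Paralogs and motifs


def extract_paralogs(
    peak: EnrichmentPeak,
    hits: Sequence[RepeatHit],
    genome: dict[str, str],
    exapted_cnees: Sequence[CNEERecord],
) -> list[tuple[str, str]]:
    """Genomic sequences of the peak region from every supporting element,
    oriented to the consensus strand.

    Returns (header, sequence) pairs; headers record the source
    coordinates.  Elements whose projection misses the peak after clipping
    and hits whose consensus span does not cover the peak are skipped.
    """
    if peak.supporting_events < 2:
        raise ValueError("peak must be supported by at least 2 events")
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for cnee in exapted_cnees:
        if not cnee.exapted or _cnee_id(cnee) in seen:
            continue
        seen.add(_cnee_id(cnee))
        for h in hits:
            if h.family != peak.family:
                continue
            inter = cnee.interval.intersect(h.interval)
            if inter is None:
                continue
            lo, hi = map_to_consensus(inter, h)
            if hi < peak.cons_start or lo > peak.cons_end:
                continue  # projection misses the peak
            if not (h.cons_start <= peak.cons_start and peak.cons_end <= h.cons_end):
                warnings.warn(
                    f"hit {h.interval} does not span peak "
                    f"{peak.cons_start}-{peak.cons_end}; skipped"
                )
                continue
            g = map_from_consensus(peak.cons_start, peak.cons_end, h)
            seq = genome[g.chrom][g.start : g.end]
            if h.interval.strand == "-":
                seq = seq.translate(_COMP)[::-1]
            header = f"{_cnee_id(cnee)}|{g.chrom}:{g.start}-{g.end}({h.interval.strand})"
            out.append((header, seq))
            break
    return out


@dataclass
class PWMProfile:
    """Position probability matrix (rows = positions, columns = ACGT)."""

    probabilities: np.ndarray
    pseudocount: float
    n_sequences: int

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4:
            raise ValueError("probabilities must be (width, 4)")
        if not np.allclose(p.sum(axis=1), 1, atol=1e-8):
            raise ValueError("columns must sum to 1")
        self.probabilities = p

    @property
    def width(self) -> int:
        return self.probabilities.shape[0]

    def reverse_complement(self) -> "PWMProfile":
        return PWMProfile(
            probabilities=self.probabilities[::-1, ::-1].copy(),
            pseudocount=self.pseudocount,
            n_sequences=self.n_sequences,
        )


def build_pwm(sequences: Sequence[str], pseudocount: float = 0.5) -> PWMProfile:
    """Stack equal-length (consensus-anchored) sequences into a PWM with
    additive smoothing: p = (count + pc) / (n + 4 pc)."""
    if not sequences:
        raise ValueError("no sequences")
    width = len(sequences[0])
    if any(len(s) != width for s in sequences):
        raise ValueError("sequences must have equal length")
    counts = np.zeros((width, 4))
    for seq in sequences:
        for i, ch in enumerate(seq.upper()):
            j = _BASE_INDEX.get(ch)
            if j is not None:
                counts[i, j] += 1
    n = len(sequences)
    probs = (counts + pseudocount) / (n + 4 * pseudocount)
    # columns containing non-ACGT characters renormalise over observed counts
    probs = probs / probs.sum(axis=1, keepdims=True)
    return PWMProfile(probabilities=probs, pseudocount=pseudocount, n_sequences=n)


@dataclass(frozen=True)
class PWMMatch:
    offset: int
    orientation: str  # "+" or "-"
    score: float  # column-averaged Pearson r over the overlap
    p_value: float
    n_overlap: int


def _column_r(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _best_alignment(a: np.ndarray, b: np.ndarray, min_overlap: int):
    best = (-np.inf, 0, 0)
    wa, wb = a.shape[0], b.shape[0]
    for offset in range(-(wb - min_overlap), wa - min_overlap + 1):
        lo_a, hi_a = max(0, offset), min(wa, offset + wb)
        if hi_a - lo_a < min_overlap:
            continue
        cols_a = a[lo_a:hi_a]
        cols_b = b[lo_a - offset : hi_a - offset]
        score = float(
            np.mean([_column_r(x, y) for x, y in zip(cols_a, cols_b)])
        )
        if score > best[0]:
            best = (score, offset, hi_a - lo_a)
    return best


def compare_pwm(
    a: PWMProfile,
    b: PWMProfile,
    n_permutations: int = 10_000,
    seed: int = 0,
    min_overlap: int = 4,
) -> PWMMatch:
    """Column-correlation comparison of two PWMs.

    All offsets and both orientations of ``b`` are scanned; the score is
    the mean per-column Pearson r over the best overlap (>= ``min_overlap``
    columns).  The p-value is the rank of the observed score among scores
    of column-shuffled versions of ``b`` (seeded); Bonferroni correction
    across multiple comparisons is left to the caller.  This is a
    simplified internal comparator; Tomtom is the external reference tool.
    """
    if a.width < 4 or b.width < 4:
        raise ValueError("motif width must be >= 4")
    fwd = _best_alignment(a.probabilities, b.probabilities, min_overlap)
    rev = _best_alignment(
        a.probabilities, b.reverse_complement().probabilities, min_overlap
    )
    if fwd[0] >= rev[0]:
        score, offset, n_overlap, orientation = *fwd, "+"
    else:
        score, offset, n_overlap, orientation = *rev, "-"
    if not np.isfinite(score):
        raise ValueError(f"no alignment with >= {min_overlap} overlapping columns")
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = b.probabilities[rng.permutation(b.width)]
        shuffled = PWMProfile(perm, b.pseudocount, b.n_sequences)
        s_fwd = _best_alignment(a.probabilities, shuffled.probabilities, min_overlap)[0]
        s_rev = _best_alignment(
            a.probabilities, shuffled.reverse_complement().probabilities, min_overlap
        )[0]
        if max(s_fwd, s_rev) >= score:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return PWMMatch(
        offset=offset, orientation=orientation, score=score, p_value=p, n_overlap=n_overlap
    )


def write_pwm(pwm: PWMProfile, path: str, name: str = "motif") -> None:
    """MEME minimal motif format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write(f"MOTIF {name}\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {pwm.width} "
            f"nsites= {pwm.n_sequences} E= 0\n"
        )
        for row in pwm.probabilities:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
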