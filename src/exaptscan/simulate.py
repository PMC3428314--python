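"""Synthetic genomes with known exaptation truth.

The generator emulates the study system end to end: a small
multi-chromosome genome is seeded with non-overlapping repeat insertions
copied from a consensus library (known family, consensus span, strand and
branch of origin on a supplied phylogeny); a fraction of insertions carry a
constrained sub-interval, the synthetic counterpart of an exapted CNEE;
alignments are evolved under a time-reversible model at the neutral rate
outside constrained intervals and at a reduced rate ``constraint_scale``
inside them; segregating sites get derived-allele frequencies drawn from a
low-mean Beta inside constrained intervals and a flat Beta elsewhere,
mimicking the downward frequency shift of sites under purifying selection.

Reproducibility contract: every stage draws from its own child stream of
``numpy.random.default_rng`` keyed ``(seed, stage)`` with stages genome=0,
insertions=1, annotations=2, alignment=3, daf=4 — a fixed seed yields
byte-identical fixtures regardless of which stages are invoked.

No indels are simulated inside insertions, so the genomic-to-consensus
mapping is exactly affine; lineages that diverged before an insertion's
origin branch show the insertion as all-gap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm

from exaptscan.alignio import AlignmentBlock, write_maf
from exaptscan.dating import SpeciesLadder
from exaptscan.intervals import (
    GenomicInterval,
    RepeatHit,
    write_bed,
    write_repeatmasker_out,
)
from exaptscan.phylo import BASES, PhyloModel

_STAGE_GENOME, _STAGE_INSERTIONS, _STAGE_ANNOT, _STAGE_ALIGN, _STAGE_DAF = range(5)

_COMP = str.maketrans("ACGT", "TGCA")

#: Default phylogeny: a 12-leaf ladderised tree with the reference ``ref``
#: and outgroup clades of decreasing divergence, branch lengths in
#: substitutions/site.
DEFAULT_TREE = (
    "((((((((ref:0.05,sp1:0.05):0.05,(sp2:0.04,sp3:0.04):0.06):0.05,"
    "sp4:0.15):0.05,(sp5:0.1,sp6:0.1):0.1):0.05,sp7:0.25):0.05,"
    "(sp8:0.2,sp9:0.2):0.1):0.05,sp10:0.35):0.05,sp11:0.4);"
)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(BASES))[rng.choice(4, size=length, p=p)])


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def default_consensus_library() -> dict[str, tuple[str, str, str]]:
    """Three-family library (LINE/SINE/DNA) with fixed sequences."""
    rng = np.random.default_rng(714025)
    return {
        "L1sim": (_random_seq(rng, 900, 0.40), "L1", "LINE"),
        "AluSim": (_random_seq(rng, 300, 0.55), "Alu", "SINE"),
        "CharlieSim": (_random_seq(rng, 220, 0.38), "hAT-Charlie", "DNA"),
    }


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic genome."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 100_000
    consensus_library: dict[str, tuple[str, str, str]] = field(
        default_factory=default_consensus_library
    )
    insertion_rate: float = 0.4  # insertions per kb
    constrained_fraction: float = 0.7
    constraint_scale: float = 0.30  # relative rate inside constrained intervals
    tree: str = DEFAULT_TREE
    reference: str = "ref"
    gc_content: float = 0.41
    min_insert_len: int = 120
    constrained_len_range: tuple[int, int] = (25, 160)
    flank: int = 60
    background_cnee_rate: float = 0.3  # non-exapted conserved elements per kb
    genes_per_chrom: int = 4
    daf_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"neutral": (1.0, 1.0), "constrained": (0.5, 3.0)}
    )
    n_sites: int = 5000
    sample_size: int = 120

    def __post_init__(self) -> None:
        if not 0 <= self.constrained_fraction <= 1:
            raise ValueError("constrained_fraction must lie in [0, 1]")
        if not 0 < self.constraint_scale <= 1:
            raise ValueError("constraint_scale must lie in (0, 1]")
        if self.insertion_rate < 0:
            raise ValueError("insertion_rate must be >= 0")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage])

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


@dataclass
class InsertionTruth:
    chrom: str
    start: int
    end: int
    strand: str
    family: str
    cons_start: int  # 1-based inclusive
    cons_end: int
    branch: str
    constrained: list[tuple[int, int]]  # genomic half-open sub-intervals

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


@dataclass
class TruthSet:
    """Ground truth for every simulated insertion and segregating site."""

    insertions: list[InsertionTruth] = field(default_factory=list)
    sites: list[dict] = field(default_factory=list)

    def validate(self, ladder: SpeciesLadder | None = None) -> None:
        for ins in self.insertions:
            for lo, hi in ins.constrained:
                if not (ins.start <= lo < hi <= ins.end):
                    raise ValueError("constrained interval escapes its insertion")
            if ins.cons_end - ins.cons_start + 1 != ins.end - ins.start:
                raise ValueError("consensus span length != genomic span length")
            if ladder is not None and ins.branch not in ladder.branch_labels:
                raise ValueError(f"unknown branch label {ins.branch!r}")

    def constrained_intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(ins.chrom, lo, hi)
            for ins in self.insertions
            for lo, hi in ins.constrained
        ]

    def to_json(self) -> str:
        return json.dumps(
            {
                "insertions": [vars(i) for i in self.insertions],
                "sites": self.sites,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthSet":
        raw = json.loads(text)
        insertions = [
            InsertionTruth(**{**d, "constrained": [tuple(c) for c in d["constrained"]]})
            for d in raw["insertions"]
        ]
        return cls(insertions=insertions, sites=raw["sites"])


# ---------------------------------------------------------------------------
# Genome + insertions


def simulate_insertion_genome(
    config: SimConfig,
) -> tuple[dict[str, str], list[RepeatHit], TruthSet]:
    """Seed a background genome with non-overlapping repeat insertions.

    Each insertion copies a contiguous consensus sub-sequence (uniform
    span, either strand) over the background; the returned hits carry the
    true consensus coordinates.  Raises when the requested density cannot
    be placed without overlap.
    """
    if not config.consensus_library:
        raise ValueError("consensus library is empty")
    rng_genome = config.rng(_STAGE_GENOME)
    rng_ins = config.rng(_STAGE_INSERTIONS)
    ladder = SpeciesLadder.from_newick(config.tree, config.reference)
    branch_labels = ladder.branch_labels

    genome: dict[str, str] = {}
    hits: list[RepeatHit] = []
    truth = TruthSet()
    families = sorted(config.consensus_library)
    n_per_chrom = int(round(config.insertion_rate * config.chrom_length / 1000))

    for chrom in config.chrom_names():
        seq = np.array(list(_random_seq(rng_genome, config.chrom_length, config.gc_content)))
        placed: list[tuple[int, int]] = []
        for _ in range(n_per_chrom):
            ok = False
            for _attempt in range(300):
                family = families[rng_ins.integers(len(families))]
                cons_seq, superfamily, klass = config.consensus_library[family]
                clen = len(cons_seq)
                min_len = min(config.min_insert_len, clen)
                ins_len = int(rng_ins.integers(min_len, clen + 1))
                cons_start = int(rng_ins.integers(1, clen - ins_len + 2))
                cons_end = cons_start + ins_len - 1
                strand = "+" if rng_ins.random() < 0.5 else "-"
                lo_bound = config.flank
                hi_bound = config.chrom_length - ins_len - config.flank
                if hi_bound <= lo_bound:
                    continue
                start = int(rng_ins.integers(lo_bound, hi_bound))
                end = start + ins_len
                if any(start < e and s < end for s, e in placed):
                    continue
                ok = True
                break
            if not ok:
                raise RuntimeError(
                    f"cannot place {n_per_chrom} insertions on {chrom} "
                    f"({config.chrom_length} bp) without overlap"
                )
            placed.append((start, end))
            fragment = cons_seq[cons_start - 1 : cons_end]
            if strand == "-":
                fragment = revcomp(fragment)
            seq[start:end] = list(fragment)

            constrained: list[tuple[int, int]] = []
            if rng_ins.random() < config.constrained_fraction:
                lo_c, hi_c = config.constrained_len_range
                clen_c = int(rng_ins.integers(min(lo_c, ins_len), min(hi_c, ins_len) + 1))
                off = int(rng_ins.integers(0, ins_len - clen_c + 1))
                constrained.append((start + off, start + off + clen_c))
            branch = branch_labels[rng_ins.integers(len(branch_labels))]

            hits.append(
                RepeatHit(
                    interval=GenomicInterval(chrom, start, end, strand),
                    family=family,
                    superfamily=superfamily,
                    klass=klass,
                    cons_start=cons_start,
                    cons_end=cons_end,
                    cons_length=len(cons_seq),
                )
            )
            truth.insertions.append(
                InsertionTruth(
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    family=family,
                    cons_start=cons_start,
                    cons_end=cons_end,
                    branch=branch,
                    constrained=constrained,
                )
            )
        genome[chrom] = "".join(seq)
    truth.validate(ladder)
    return genome, hits, truth


# ---------------------------------------------------------------------------
# Annotations: background conserved elements, genes, TSS


@dataclass
class Annotations:
    background_elements: list[GenomicInterval]
    exons: list[GenomicInterval]
    tss: list[GenomicInterval]  # width-1 intervals


def simulate_annotations(truth: TruthSet, config: SimConfig) -> Annotations:
    """Non-exapted conserved elements plus a sparse gene annotation.

    Background elements are placed outside insertions (they are the
    non-exapted CNEE population); genes contribute exon intervals (some of
    which will overlap conserved elements, exercising CNEE derivation) and
    transcription start sites.
    """
    rng = config.rng(_STAGE_ANNOT)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in config.chrom_names()}
    for ins in truth.insertions:
        occupied[ins.chrom].append((ins.start, ins.end))

    background: list[GenomicInterval] = []
    exons: list[GenomicInterval] = []
    tss: list[GenomicInterval] = []
    n_bg = int(round(config.background_cnee_rate * config.chrom_length / 1000))
    for chrom in config.chrom_names():
        for _ in range(n_bg):
            for _attempt in range(200):
                length = int(rng.integers(25, 161))
                start = int(rng.integers(0, config.chrom_length - length))
                if any(start < e and s < start + length for s, e in occupied[chrom]):
                    continue
                background.append(GenomicInterval(chrom, start, start + length))
                break
        for _ in range(config.genes_per_chrom):
            pos = int(rng.integers(0, config.chrom_length - 2000))
            tss.append(GenomicInterval(chrom, pos, pos + 1))
            cursor = pos
            for _exon in range(int(rng.integers(2, 5))):
                elen = int(rng.integers(80, 300))
                if cursor + elen >= config.chrom_length:
                    break
                exons.append(GenomicInterval(chrom, cursor, cursor + elen))
                cursor += elen + int(rng.integers(200, 800))
    return Annotations(background_elements=background, exons=exons, tss=tss)


# ---------------------------------------------------------------------------
# Alignment simulation


def evolve_sequence(
    parent: np.ndarray,
    t: float,
    rates: np.ndarray,
    Q: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Evolve integer-coded bases across one branch.

    ``rates`` gives the per-column rate multiplier; transition matrices are
    ``expm(rate * t * Q)`` per distinct rate.
    """
    child = parent.copy()
    for rate in np.unique(rates):
        idx = np.where(rates == rate)[0]
        P = expm(rate * t * Q)
        cum = np.cumsum(P, axis=1)
        u = rng.random(idx.size)
        child[idx] = (u[:, None] > cum[parent[idx]]).sum(axis=1)
    return child


def _simulate_leaves(
    ref_seq: np.ndarray,
    model: PhyloModel,
    rates: np.ndarray,
    reference: str,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Leaf sequences given the realised reference sequence.

    By time-reversibility the joint leaf law is unchanged when the tree is
    traversed from the reference leaf outward, which pins the reference row
    to the genome exactly.
    """
    tree = model.tree
    ref_node = None
    adjacency: dict[int, list[tuple[object, float]]] = {}
    nodes = list(tree.preorder_node_iter())
    for node in nodes:
        adjacency.setdefault(id(node), [])
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            adjacency[id(node)].append((child, t))
            adjacency.setdefault(id(child), []).append((node, t))
        if node.is_leaf() and node.taxon is not None:
            if node.taxon.label == reference:
                ref_node = node
    if ref_node is None:
        raise ValueError("reference leaf not found in model tree")

    seqs: dict[int, np.ndarray] = {id(ref_node): ref_seq}
    out: dict[str, np.ndarray] = {reference: ref_seq}
    stack = [ref_node]
    visited = {id(ref_node)}
    while stack:
        node = stack.pop()
        for neighbour, t in adjacency[id(node)]:
            if id(neighbour) in visited:
                continue
            visited.add(id(neighbour))
            seqs[id(neighbour)] = evolve_sequence(seqs[id(node)], t, rates, model.rate_matrix, rng)
            if neighbour.is_leaf() and neighbour.taxon is not None:
                out[neighbour.taxon.label] = seqs[id(neighbour)]
            stack.append(neighbour)
    return out


def simulate_alignment(
    genome: dict[str, str],
    model: PhyloModel,
    truth: TruthSet,
    config: SimConfig,
) -> list[AlignmentBlock]:
    """Evolve one reference-anchored block per insertion (plus flanks).

    Columns inside constrained intervals evolve at ``constraint_scale``
    times the neutral rate; species that diverged before the insertion's
    origin branch are all-gap across the insertion columns.
    """
    rng = config.rng(_STAGE_ALIGN)
    ladder = SpeciesLadder.from_tree(model.tree, config.reference)
    code = {b: i for i, b in enumerate(BASES)}

    blocks: list[AlignmentBlock] = []
    for ins in truth.insertions:
        if ins.branch not in ladder.presence:
            raise ValueError(f"unknown branch label {ins.branch!r}")
        present = ladder.presence[ins.branch]
        start = max(0, ins.start - config.flank)
        end = min(len(genome[ins.chrom]), ins.end + config.flank)
        ref = np.array([code[b] for b in genome[ins.chrom][start:end]])
        rates = np.ones(end - start)
        for lo, hi in ins.constrained:
            rates[lo - start : hi - start] = config.constraint_scale
        leaf_seqs = _simulate_leaves(ref, model, rates, config.reference, rng)
        ins_lo, ins_hi = ins.start - start, ins.end - start
        rows: dict[str, str] = {}
        for sp in [config.reference] + sorted(set(leaf_seqs) - {config.reference}):
            chars = [BASES[i] for i in leaf_seqs[sp]]
            if sp not in present:
                chars[ins_lo:ins_hi] = ["-"] * (ins_hi - ins_lo)
            rows[sp] = "".join(chars)
        blocks.append(
            AlignmentBlock(chrom=ins.chrom, start=start, reference=config.reference, sequences=rows)
        )
    return blocks


# ---------------------------------------------------------------------------
# Segregating sites


def simulate_daf_sites(truth: TruthSet, config: SimConfig) -> pd.DataFrame:
    """Segregating sites with class-dependent derived-allele frequencies.

    Site positions are uniform over the genome; a site falling inside a
    constrained interval draws its population frequency from the
    constrained Beta (lower mean), all others from the neutral Beta; the
    derived count is a Binomial(sample_size, freq) sample conditioned on
    segregating (0 < count < n).  Classes are appended to ``truth.sites``.
    """
    if config.sample_size < 2:
        raise ValueError("sample_size must be >= 2")
    a_n, b_n = config.daf_params["neutral"]
    a_c, b_c = config.daf_params["constrained"]
    if (a_c / (a_c + b_c)) >= (a_n / (a_n + b_n)):
        raise ValueError("constrained Beta mean must be below the neutral mean")
    rng = config.rng(_STAGE_DAF)
    constrained = {
        (iv.chrom, p)
        for iv in truth.constrained_intervals()
        for p in range(iv.start, iv.end)
    }
    chroms = config.chrom_names()
    records = []
    truth.sites = []
    for _ in range(config.n_sites):
        chrom = chroms[rng.integers(len(chroms))]
        pos = int(rng.integers(0, config.chrom_length))
        site_class = "constrained" if (chrom, pos) in constrained else "neutral"
        a, b = (a_c, b_c) if site_class == "constrained" else (a_n, b_n)
        while True:
            freq = rng.beta(a, b)
            count = rng.binomial(config.sample_size, freq)
            if 0 < count < config.sample_size:
                break
        anc = BASES[rng.integers(4)]
        der = BASES[(BASES.index(anc) + 1 + rng.integers(3)) % 4]
        records.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ancestral": anc,
                "derived": der,
                "derived_count": count,
                "sample_size": config.sample_size,
            }
        )
        truth.sites.append({"chrom": chrom, "pos": pos, "site_class": site_class})
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# Fixture bundle


@dataclass
class SimResult:
    config: SimConfig
    genome: dict[str, str]
    hits: list[RepeatHit]
    truth: TruthSet
    annotations: Annotations
    blocks: list[AlignmentBlock]
    sites: pd.DataFrame

    def conserved_elements(self) -> list[GenomicInterval]:
        """All conserved elements: constrained insert intervals plus
        background elements (sorted)."""
        return sorted(self.truth.constrained_intervals() + self.annotations.background_elements)

    def write(self, outdir: str) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "genome.fa"), "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        write_repeatmasker_out(self.hits, os.path.join(outdir, "repeats.out"))
        write_bed(self.conserved_elements(), os.path.join(outdir, "conserved.bed"))
        write_bed(self.annotations.exons, os.path.join(outdir, "exons.bed"))
        write_bed(self.annotations.tss, os.path.join(outdir, "tss.bed"))
        chrom_sizes = {c: len(s) for c, s in self.genome.items()}
        write_maf(self.blocks, os.path.join(outdir, "alignment.maf"), chrom_sizes)
        sites = self.sites.copy()
        sites["pos"] = sites["pos"] + 1  # TSV dialect is 1-based
        sites.to_csv(os.path.join(outdir, "sites.tsv"), sep="\t", index=False)
        with open(os.path.join(outdir, "tree.nwk"), "w") as fh:
            fh.write(self.config.tree + "\n")
        with open(os.path.join(outdir, "truth.json"), "w") as fh:
            fh.write(self.truth.to_json())
        with open(os.path.join(outdir, "chrom.sizes"), "w") as fh:
            for c, n in chrom_sizes.items():
                fh.write(f"{c}\t{n}\n")


def simulate_peak_fixture(
    seed: int,
    planted_fold: float = 3.0,
    cons_length: int = 200,
    peak_span: tuple[int, int] = (100, 110),
    background_cov: int = 20,
    peak_events: int | None = None,
):
    """Genome + hits + elements with exaptations concentrated on one
    consensus window.

    Every insertion carries the full consensus; ``background_cov`` layers
    of exapted elements tile the consensus uniformly (staggered offsets)
    while ``peak_events`` additional elements target exactly the peak
    window, so the planted per-position fold at the peak is approximately
    ``planted_fold``:  n_peak = L b (f - 1) / (L - f w)  for consensus
    length L, window width w.  Returns (genome, hits, elements, truth
    peak span, family name).
    """
    w = peak_span[1] - peak_span[0] + 1
    if peak_events is None:
        peak_events = int(round(
            cons_length * background_cov * (planted_fold - 1)
            / (cons_length - planted_fold * w)
        ))
    rng = np.random.default_rng([seed, 7])
    family = "PlantedFam"
    consensus = _random_seq(rng, cons_length, 0.45)
    gap = 80
    n_ins = max(peak_events, 40)
    chrom = "chr1"
    chrom_length = n_ins * (cons_length + gap) + 2 * gap
    background = list(_random_seq(rng, chrom_length, 0.41))

    hits: list[RepeatHit] = []
    starts = []
    for i in range(n_ins):
        start = gap + i * (cons_length + gap)
        strand = "+" if rng.random() < 0.5 else "-"
        fragment = consensus if strand == "+" else revcomp(consensus)
        background[start : start + cons_length] = list(fragment)
        starts.append((start, strand))
        hits.append(
            RepeatHit(
                interval=GenomicInterval(chrom, start, start + cons_length, strand),
                family=family,
                superfamily="L1",
                klass="LINE",
                cons_start=1,
                cons_end=cons_length,
                cons_length=cons_length,
            )
        )
    genome = {chrom: "".join(background)}

    def genomic_window(ins_idx: int, c_lo: int, c_hi: int) -> GenomicInterval:
        """Genomic interval of 1-based inclusive consensus span within
        insertion ``ins_idx`` (strand-aware)."""
        start, strand = starts[ins_idx]
        if strand == "+":
            lo = start + c_lo - 1
            hi = start + c_hi
        else:
            lo = start + cons_length - c_hi
            hi = start + cons_length - c_lo + 1
        return GenomicInterval(chrom, lo, hi)

    from exaptscan.intervals import CNEERecord

    elements: list[CNEERecord] = []
    for k in range(peak_events):
        elements.append(
            CNEERecord(interval=genomic_window(k % n_ins, peak_span[0], peak_span[1]))
        )
    for layer in range(background_cov):
        offset = layer % w
        pos = 1 + offset
        while pos <= cons_length:
            hi = min(pos + w - 1, cons_length)
            idx = int(rng.integers(n_ins))
            elements.append(CNEERecord(interval=genomic_window(idx, pos, hi)))
            pos += w
    return genome, hits, elements, peak_span, family


def simulate_all(config: SimConfig) -> SimResult:
    """Run every stage of the generator in the documented draw order."""
    genome, hits, truth = simulate_insertion_genome(config)
    annotations = simulate_annotations(truth, config)
    model = PhyloModel.jukes_cantor(config.tree)
    blocks = simulate_alignment(genome, model, truth, config)
    sites = simulate_daf_sites(truth, config)
    return SimResult(
        config=config,
        genome=genome,
        hits=hits,
        truth=truth,
        annotations=annotations,
        blocks=blocks,
        sites=sites,
    )
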