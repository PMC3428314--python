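import numpy as np
import pytest

from exaptscan.intervals import CNEERecord, GenomicInterval, RepeatHit
from exaptscan.simulate import SimConfig, simulate_all


@pytest.fixture(scope="session")
def sim_default():
    """A small default simulation shared across read-only tests."""
    return simulate_all(SimConfig(seed=11))


@pytest.fixture(scope="session")
def sim_config_default():
    return SimConfig(seed=11)


def make_hit(
    chrom="chr1",
    start=1000,
    end=1100,
    strand="+",
    family="L1MC4",
    superfamily="L1",
    klass="LINE",
    cons_start=100,
    cons_end=199,
    cons_length=500,
):
    return RepeatHit(
        interval=GenomicInterval(chrom, start, end, strand),
        family=family,
        superfamily=superfamily,
        klass=klass,
        cons_start=cons_start,
        cons_end=cons_end,
        cons_length=cons_length,
    )


def make_cnee(chrom="chr1", start=0, end=10):
    return CNEERecord(interval=GenomicInterval(chrom, start, end))


def brute_force_classify(cnee, hits):
    """Per-base oracle for exaptation classification (quadratic scan)."""
    iv = cnee.interval
    length = iv.length
    union = set()
    per = {"family": {}, "superfamily": {}, "klass": {}}
    for h in hits:
        if h.klass not in ("LINE", "SINE", "DNA", "LTR"):
            continue
        if h.interval.chrom != iv.chrom:
            continue
        for pos in range(iv.start, iv.end):
            if h.interval.start <= pos < h.interval.end:
                union.add(pos)
                for level, key in (
                    ("family", h.family),
                    ("superfamily", h.superfamily),
                    ("klass", h.klass),
                ):
                    per[level].setdefault(key, set()).add(pos)
    frac = len(union) / length
    exapted = frac > 0.5

    def majority(level):
        for key, positions in per[level].items():
            if 2 * len(positions) > length:
                return key
        return None

    assigned = {lvl: (majority(lvl) if exapted else None) for lvl in per}
    if assigned["klass"] is None:
        assigned["superfamily"] = assigned["family"] = None
    if assigned["superfamily"] is None:
        assigned["family"] = None
    return frac, exapted, assigned["klass"], assigned["superfamily"], assigned["family"]
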