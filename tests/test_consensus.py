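"""Consensus-coordinate profiling, peak calling and motif comparison."""

import numpy as np
import pytest

from exaptscan.consensus import (
    ConsensusProfile,
    build_profile,
    build_pwm,
    call_peaks,
    compare_pwm,
    extract_paralogs,
    map_from_consensus,
    map_to_consensus,
    permutation_peak_null,
)
from exaptscan.intervals import CNEERecord, GenomicInterval, classify_all
from exaptscan.simulate import revcomp, simulate_peak_fixture

from conftest import make_cnee, make_hit


class TestMapToConsensus:
    def test_equal_length_affine_plus(self):
        hit = make_hit(start=1000, end=1100, cons_start=100, cons_end=199)
        sub = GenomicInterval("chr1", 1050, 1060)
        assert map_to_consensus(sub, hit) == (150, 159)

    def test_minus_strand_mirrored(self):
        hit = make_hit(start=1000, end=1100, strand="-", cons_start=100, cons_end=199)
        sub = GenomicInterval("chr1", 1050, 1060)
        assert map_to_consensus(sub, hit) == (140, 149)

    def test_uncontained_sub_rejected(self):
        hit = make_hit(start=1000, end=1100)
        with pytest.raises(ValueError, match="not contained"):
            map_to_consensus(GenomicInterval("chr1", 990, 1010), hit)

    def test_interpolation_matches_linear_oracle_with_indels(self):
        """Genomic span 200 vs consensus span 100: interpolated positions
        agree with the exhaustive per-base linear map within one position."""
        hit = make_hit(start=0, end=200, cons_start=1, cons_end=100, cons_length=150)
        for g in range(0, 200):
            lo, hi = map_to_consensus(GenomicInterval("chr1", g, g + 1), hit)
            oracle = 1 + g * 99 / 199
            assert abs(lo - oracle) <= 1

    def test_inverse_mapping_round_trip(self):
        for strand in "+-":
            hit = make_hit(start=1000, end=1100, strand=strand, cons_start=100, cons_end=199)
            g = map_from_consensus(150, 159, hit)
            assert map_to_consensus(g, hit) == (150, 159)


class TestBuildProfile:
    def test_uniform_exaptation_gives_fold_one(self):
        hit = make_hit(start=0, end=100, cons_start=1, cons_end=100, cons_length=100)
        cnee = CNEERecord(interval=GenomicInterval("chr1", 0, 100), exapted=True)
        profile = build_profile("L1MC4", [hit], [cnee])
        assert np.allclose(profile.fold, 1.0)

    def test_concentrated_exaptation_raises_local_fold(self):
        hits = [
            make_hit(start=1000 * i, end=1000 * i + 200, cons_start=1,
                     cons_end=200, cons_length=200)
            for i in range(30)
        ]
        cnees = [
            CNEERecord(
                interval=GenomicInterval("chr1", 1000 * i + 49, 1000 * i + 60),
                exapted=True,
            )
            for i in range(30)
        ]
        profile = build_profile("L1MC4", hits, cnees)
        fold = profile.fold
        assert np.nanmin(fold[49:60]) > 1
        outside = np.concatenate([fold[:49], fold[60:]])
        assert np.nanmax(outside) < 1

    def test_no_exapted_elements_flagged(self):
        hit = make_hit(start=0, end=100, cons_start=1, cons_end=100, cons_length=100)
        with pytest.warns(UserWarning, match="fold undefined"):
            profile = build_profile("L1MC4", [hit], [])
        assert profile.is_empty
        assert np.isnan(profile.fold).all()

    def test_normalised_densities_sum_to_one(self, sim_default):
        classified = classify_all(
            [CNEERecord(interval=iv) for iv in sim_default.conserved_elements()],
            sim_default.hits,
        )
        exapted = [c for c in classified if c.exapted]
        profile = build_profile("AluSim", sim_default.hits, exapted)
        assert profile.genomic_cov.sum() > 0 and profile.exapt_cov.sum() > 0
        assert (profile.genomic_cov / profile.genomic_cov.sum()).sum() == pytest.approx(1)
        assert (profile.exapt_cov / profile.exapt_cov.sum()).sum() == pytest.approx(1)


def _profile_with_run(fold_positions, support, length=100):
    """Profile with uniform genomic coverage and exapted coverage raised
    on the given positions, contributor sets of the given size."""
    genomic = np.full(length, 50, dtype=int)
    exapt = np.full(length, 1, dtype=int)
    contributors = [{f"bg{i}"} for i in range(length)]
    for p in fold_positions:
        exapt[p] = 0  # set below
    base_total = exapt.sum()
    # choose coverage at run positions so fold > 2 there
    for p in fold_positions:
        exapt[p] = 10
        contributors[p] = {f"ev{i}" for i in range(support)}
    return ConsensusProfile(
        family="F", length=length, genomic_cov=genomic, exapt_cov=exapt,
        contributors=contributors,
    )


class TestCallPeaks:
    def test_uniform_fold_gives_no_peaks(self):
        profile = ConsensusProfile(
            family="F",
            length=50,
            genomic_cov=np.full(50, 10, dtype=int),
            exapt_cov=np.full(50, 5, dtype=int),
        )
        assert call_peaks(profile) == []

    def test_planted_eleven_bp_peak_recovered_exactly(self):
        genome, hits, elements, peak_span, family = simulate_peak_fixture(
            seed=1, planted_fold=3.0
        )
        classified = classify_all(elements, hits)
        exapted = [c for c in classified if c.exapted]
        assert len(exapted) == len(elements)  # all elements sit inside hits
        profile = build_profile(family, hits, exapted)
        peaks = call_peaks(profile, fold_min=2, support_min=40)
        assert len(peaks) == 1
        assert (peaks[0].cons_start, peaks[0].cons_end) == peak_span
        assert peaks[0].width == 11
        assert peaks[0].supporting_events >= 40
        assert peaks[0].min_fold > 2

    def test_support_boundary_thirty_nine_events_no_peak(self):
        profile = _profile_with_run(range(20, 31), support=39)
        assert call_peaks(profile, fold_min=2, support_min=40) == []
        profile40 = _profile_with_run(range(20, 31), support=40)
        assert len(call_peaks(profile40, fold_min=2, support_min=40)) == 1

    @pytest.mark.parametrize("planted_fold", [2.5, 3.0, 5.0])
    def test_planted_fold_recall_and_no_spurious_peaks(self, planted_fold):
        """Recall 1 with zero false peaks across seeds for planted folds
        of 2.5, 3 and 5."""
        for seed in range(5):
            genome, hits, elements, peak_span, family = simulate_peak_fixture(
                seed=seed, planted_fold=planted_fold
            )
            classified = classify_all(elements, hits)
            exapted = [c for c in classified if c.exapted]
            profile = build_profile(family, hits, exapted)
            peaks = call_peaks(profile, fold_min=2, support_min=40)
            assert len(peaks) == 1
            assert (peaks[0].cons_start, peaks[0].cons_end) == peak_span

    def test_invariant_to_input_order(self):
        genome, hits, elements, peak_span, family = simulate_peak_fixture(seed=2)
        classified = classify_all(elements, hits)
        exapted = [c for c in classified if c.exapted]
        p1 = call_peaks(build_profile(family, hits, exapted))
        p2 = call_peaks(build_profile(family, hits[::-1], exapted[::-1]))
        assert p1 == p2


class TestPermutationNull:
    def test_fixed_seed_reproducible(self):
        genome, hits, elements, _, _ = simulate_peak_fixture(seed=3)
        sizes = {c: len(s) for c, s in genome.items()}
        a = permutation_peak_null(elements, sizes, hits, n_trials=20, seed=5)
        b = permutation_peak_null(elements, sizes, hits, n_trials=20, seed=5)
        assert list(a.trial_counts) == list(b.trial_counts)
        assert a.observed_peaks == b.observed_peaks

    def test_planted_signal_exceeds_null(self):
        genome, hits, elements, _, _ = simulate_peak_fixture(seed=4)
        sizes = {c: len(s) for c, s in genome.items()}
        null = permutation_peak_null(elements, sizes, hits, n_trials=50, seed=6)
        assert null.observed_peaks >= 1
        assert (null.trial_counts < null.observed_peaks).all()
        assert null.exceedance == 0.0

    def test_too_small_genome_rejected(self):
        elements = [CNEERecord(interval=GenomicInterval("chr1", 0, 500))]
        with pytest.raises(RuntimeError, match="too small"):
            permutation_peak_null(elements, {"chr1": 400}, [], n_trials=1, seed=0)


class TestParalogs:
    def test_count_and_orientation(self):
        genome, hits, elements, peak_span, family = simulate_peak_fixture(seed=5)
        classified = classify_all(elements, hits)
        exapted = [c for c in classified if c.exapted]
        profile = build_profile(family, hits, exapted)
        (peak,) = call_peaks(profile, fold_min=2, support_min=40)
        seqs = extract_paralogs(peak, hits, genome, exapted)
        assert len(seqs) == peak.supporting_events
        # with no evolution every paralog equals the consensus window
        bodies = {s for _, s in seqs}
        assert len(bodies) == 1
        assert len(next(iter(bodies))) == peak.width

    def test_minus_strand_insertion_reverse_complemented(self):
        consensus = "ACGTTGCAAC" * 10
        hit = make_hit(start=0, end=100, strand="-", cons_start=1,
                       cons_end=100, cons_length=100)
        genome = {"chr1": revcomp(consensus)}
        cnee = CNEERecord(interval=GenomicInterval("chr1", 0, 100), exapted=True)
        from exaptscan.consensus import EnrichmentPeak

        peak = EnrichmentPeak(family="L1MC4", cons_start=11, cons_end=20,
                              min_fold=3.0, supporting_events=2)
        ((_, seq),) = extract_paralogs(peak, [hit], genome, [cnee])
        assert seq == consensus[10:20]


class TestPWM:
    def test_pseudocount_arithmetic(self):
        pwm = build_pwm(["ACGT"] * 4, pseudocount=0.5)
        assert pwm.probabilities[0, 0] == pytest.approx(4.5 / 6)
        single = build_pwm(["A"], pseudocount=0.5)
        assert single.probabilities[0, 0] == pytest.approx(1.5 / 3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            build_pwm(["ACGT", "ACG"])

    def test_random_sequences_near_uniform(self):
        rng = np.random.default_rng(12)
        seqs = ["".join(rng.choice(list("ACGT"), 8)) for _ in range(1000)]
        pwm = build_pwm(seqs)
        se = np.sqrt(0.25 * 0.75 / 1000)
        assert np.abs(pwm.probabilities - 0.25).max() < 3 * se + 0.001

    def test_self_comparison_scores_one(self):
        rng = np.random.default_rng(3)
        probs = rng.dirichlet([1, 1, 1, 1], size=10)
        pwm = build_pwm(["ACGTACGTAC"])  # any valid pwm shell
        from exaptscan.consensus import PWMProfile

        a = PWMProfile(probs, 0.5, 10)
        match = compare_pwm(a, a, n_permutations=100, seed=1)
        assert match.score == pytest.approx(1.0)
        assert match.offset == 0 and match.orientation == "+"

    def test_reverse_complement_detected(self):
        rng = np.random.default_rng(4)
        probs = rng.dirichlet([1, 1, 1, 1], size=12)
        from exaptscan.consensus import PWMProfile

        a = PWMProfile(probs, 0.5, 10)
        match = compare_pwm(a, a.reverse_complement(), n_permutations=100, seed=2)
        assert match.score == pytest.approx(1.0)
        assert match.orientation == "-"

    def test_column_shuffle_breaks_similarity(self):
        """A column-permuted motif scores below the motif itself and the
        permutation p-value reflects its rank among shuffles."""
        rng = np.random.default_rng(9)
        probs = rng.dirichlet([0.4, 0.4, 0.4, 0.4], size=12)
        from exaptscan.consensus import PWMProfile

        a = PWMProfile(probs, 0.5, 10)
        shuffled = PWMProfile(probs[rng.permutation(12)], 0.5, 10)
        self_match = compare_pwm(a, a, n_permutations=500, seed=3)
        cross = compare_pwm(a, shuffled, n_permutations=500, seed=3)
        assert cross.score < self_match.score
        assert self_match.p_value < 0.05

    def test_narrow_motif_rejected(self):
        from exaptscan.consensus import PWMProfile

        a = PWMProfile(np.full((3, 4), 0.25), 0.5, 1)
        b = PWMProfile(np.full((6, 4), 0.25), 0.5, 1)
        with pytest.raises(ValueError, match="width"):
            compare_pwm(a, b)
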