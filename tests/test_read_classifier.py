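"""Unit, oracle and property tests for the read classifier."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitocount import (
    PairingParams,
    RunCount,
    build_index,
    classify_pair,
    count_run,
    map_read,
    pileup_alleles,
)
from mitocount.errors import ParameterError
from mitocount.read_classifier import circular_insert_size, classify_run, Placement

from conftest import random_dna
from oracles import exhaustive_placements, rc


@pytest.fixture(scope="module")
def index(toy_circle):
    return build_index(toy_circle, 31)


def mutate(seq: str, positions, rng=None) -> str:
    out = list(seq)
    for i, p in enumerate(positions):
        out[p] = "ACGT"[("ACGT".index(out[p]) + 1 + i % 3) % 4]
    return "".join(out)


class TestBuildIndex:
    def test_circular_seed_count_equals_length(self, toy_circle):
        idx = build_index(toy_circle, 31)
        total = sum(len(v) for v in idx._table.values())
        assert total == 2000

    def test_self_lookup(self, toy_circle, index):
        seed = (toy_circle * 2)[137 : 137 + 31]
        assert 137 in index.lookup(seed)

    def test_wraparound_seed_indexed(self, toy_circle, index):
        seed = (toy_circle * 2)[1990 : 1990 + 31]
        assert 1990 in index.lookup(seed)

    def test_negative_lookup(self, toy_circle, index):
        rng = np.random.default_rng(3)
        doubled = toy_circle * 2
        checked = 0
        for _ in range(20):
            probe = random_dna(rng, 31)
            if probe not in doubled:
                assert index.lookup(probe) == []
                checked += 1
        assert checked > 0

    def test_seed_length_out_of_range(self, toy_circle):
        with pytest.raises(ParameterError):
            build_index(toy_circle, 7)
        with pytest.raises(ParameterError):
            build_index(toy_circle, 2001)


class TestMapRead:
    def test_exact_substring(self, toy_circle, index):
        read = toy_circle[100:200]
        placements = map_read(read, index, 5)
        assert placements[0] == Placement(100, "+", 0)

    def test_reverse_strand(self, toy_circle, index):
        read = rc(toy_circle[400:500])
        placements = map_read(read, index, 5)
        assert placements[0] == Placement(400, "-", 0)

    def test_wrapping_read(self, toy_circle, index):
        read = (toy_circle * 2)[1950:2050]
        placements = map_read(read, index, 5)
        assert placements[0] == Placement(1950, "+", 0)

    def test_at_and_beyond_mismatch_budget(self, toy_circle, index):
        base = toy_circle[600:700]
        # 5 mismatches clustered at the read start leave seeds at 31.. clean
        at_budget = mutate(base, [0, 2, 4, 6, 8])
        over = mutate(base, [0, 2, 4, 6, 8, 10])
        assert map_read(at_budget, index, 5) == [Placement(600, "+", 5)]
        assert map_read(over, index, 5) == []
        # oracle agrees
        assert exhaustive_placements(at_budget, toy_circle, 5) == [(600, "+", 5)]
        assert exhaustive_placements(over, toy_circle, 5) == []

    def test_random_read_unplaceable(self, toy_circle, index):
        rng = np.random.default_rng(8)
        for _ in range(10):
            read = random_dna(rng, 100)
            assert map_read(read, index, 5) == []
            assert exhaustive_placements(read, toy_circle, 5) == []

    def test_short_read_returns_empty(self, index):
        assert map_read("ACGTACGT", index, 2) == []

    @settings(max_examples=25, deadline=None)
    @given(
        start=st.integers(0, 1999),
        err_seed=st.integers(0, 10_000),
        n_err=st.integers(0, 5),
        reverse=st.booleans(),
    )
    def test_oracle_equivalence_stride_one(self, toy_circle, start, err_seed, n_err, reverse):
        # with stride 1 every seed-length window is probed, so equivalence
        # holds whenever at least one window of the read is error-free
        rng = np.random.default_rng(err_seed)
        read = (toy_circle * 2)[start : start + 100]
        positions = sorted(rng.choice(100, size=n_err, replace=False))
        read = mutate(read, positions)
        if reverse:
            read = rc(read)
        index = build_index(toy_circle, 31)
        clean_window = any(
            all(not (o <= p < o + 31) for p in positions) for o in range(0, 70)
        )
        got = {(p.position, p.strand, p.mismatches) for p in map_read(read, index, 5, stride=1)}
        expected = set(exhaustive_placements(read, toy_circle, 5))
        if clean_window:
            assert got == expected
        else:
            assert got <= expected


class TestInsertSizeAndClassify:
    def test_concordant_exact_pair(self, toy_circle, index):
        r1 = toy_circle[100:200]
        r2 = rc(toy_circle[300:400])  # insert 300
        verdict = classify_pair(r1, r2, index, PairingParams(insert_min=100, insert_max=600))
        assert verdict.is_mito
        assert verdict.insert_size == 300

    def test_single_mapped_mate_is_rejected(self, toy_circle, index):
        rng = np.random.default_rng(9)
        verdict = classify_pair(toy_circle[100:200], random_dna(rng, 100), index)
        assert not verdict.is_mito

    def test_insert_outside_window_rejected(self, toy_circle, index):
        r1 = toy_circle[0:100]
        r2 = rc(toy_circle[800:900])  # circular insert 900
        params = PairingParams(insert_min=100, insert_max=600)
        assert not classify_pair(r1, r2, index, params).is_mito
        # oracle: no placement combination is concordant
        pl1 = exhaustive_placements(r1, toy_circle, 5)
        pl2 = exhaustive_placements(r2, toy_circle, 5)
        for (p1, s1, _), (p2, s2, _) in [(a, b) for a in pl1 for b in pl2]:
            if s1 == s2:
                continue
            ins = circular_insert_size(
                Placement(p1, s1, 0), 100, Placement(p2, s2, 0), 100, 2000
            )
            assert not (100 <= ins <= 600)

    def test_same_strand_pair_rejected(self, toy_circle, index):
        r1 = toy_circle[100:200]
        r2 = toy_circle[300:400]  # both forward
        assert not classify_pair(r1, r2, index).is_mito

    def test_wrapping_pair_insert(self, toy_circle, index):
        # fragment 1950..2250 wraps the origin; circular insert is 300
        r1 = (toy_circle * 2)[1950:2050]
        r2 = rc((toy_circle * 2)[2150:2250])
        verdict = classify_pair(r1, r2, index, PairingParams(insert_min=100, insert_max=600))
        assert verdict.is_mito
        assert verdict.insert_size == 300

    def test_strand_symmetry(self, toy_circle, index, small_noisy_dataset):
        _, genome, reads = small_noisy_dataset
        idx = build_index(genome.mito_true, 31)
        for r1, r2 in list(zip(reads.r1, reads.r2))[:200]:
            v = classify_pair(r1, r2, idx)
            w = classify_pair(rc(r2), rc(r1), idx)
            assert v.is_mito == w.is_mito
            if v.is_mito:
                assert v.insert_size == w.insert_size

    def test_insert_size_function_symmetry(self):
        a = Placement(0, "+", 0)
        b = Placement(800, "-", 0)
        assert circular_insert_size(a, 100, b, 100, 2000) == circular_insert_size(
            b, 100, a, 100, 2000
        )


class TestCountRun:
    def test_empty_stream(self, index):
        count = count_run([], index, run_id="r0")
        assert (count.total_reads, count.mito_reads, count.all_bases, count.mt_bases) == (
            0, 0, 0, 0,
        )

    def test_simulator_truth_labels_are_the_oracle(self, toy_circle, index):
        # noiseless synthetic run: planted mito pairs counted exactly
        from mitocount import SimSpec, simulate_dataset

        spec = SimSpec(
            nuclear_length=100_000,
            mito_length=2000,
            true_k=4.0,
            n_pairs=1000,
            error_rate=0.0,
            seed=21,
        )
        genome, reads = simulate_dataset(spec)
        idx = build_index(genome.mito_true, 31)
        count = count_run(zip(reads.r1, reads.r2), idx, run_id="sim")
        planted = reads.truth.mito_pair_count
        assert count.mito_reads == 2 * planted
        assert count.mt_bases == 2 * planted * spec.read_length

    def test_saturated_run(self, toy_circle, index):
        pairs = [
            (toy_circle[s : s + 100], rc((toy_circle * 2)[s + 200 : s + 300]))
            for s in range(0, 1700, 100)
        ]
        count = count_run(pairs, index, run_id="all-mito")
        assert count.mt_bases == count.all_bases

    def test_orphan_reads_count_only_all_bases(self, toy_circle, index):
        count = count_run([(toy_circle[0:100], None)], index, run_id="orphans")
        assert count.all_bases == 100
        assert count.mt_bases == 0
        assert count.total_reads == 1

    def test_conservation_and_stream_additivity(self, small_noisy_dataset):
        _, genome, reads = small_noisy_dataset
        idx = build_index(genome.mito_true, 31)
        pairs = list(zip(reads.r1, reads.r2))
        whole = count_run(pairs, idx, run_id="whole")
        a = count_run(pairs[:700], idx, run_id="a")
        b = count_run(pairs[700:], idx, run_id="b")
        for c in (whole, a, b):
            assert 0 <= c.mt_bases <= c.all_bases
        assert a.mt_bases + b.mt_bases == whole.mt_bases
        assert a.all_bases + b.all_bases == whole.all_bases
        assert a.mito_reads + b.mito_reads == whole.mito_reads


class TestRunCountInvariants:
    def test_mt_bases_bounded(self):
        with pytest.raises(ValueError):
            RunCount("r", total_reads=10, mito_reads=0, all_bases=100, mt_bases=200)

    def test_zero_coupling(self):
        with pytest.raises(ValueError):
            RunCount("r", total_reads=10, mito_reads=2, all_bases=1000, mt_bases=0)


class TestPileup:
    def _classified(self, genome, reads, n=None):
        idx = build_index(genome.mito_true, 31)
        pairs = list(zip(reads.r1, reads.r2))
        if n:
            pairs = pairs[:n]
        return list(classify_run(pairs, idx)), idx

    def test_homoplasmic_input_no_flags(self, toy_circle):
        from mitocount import SimSpec, simulate_dataset

        spec = SimSpec(
            nuclear_length=50_000, mito_length=2000, true_k=100, n_pairs=1500,
            error_rate=0.0, seed=31,
        )
        genome, reads = simulate_dataset(spec)
        classified, _ = self._classified(genome, reads)
        counts, flagged = pileup_alleles(classified, genome.mito_true, 0.1)
        assert flagged == []
        assert counts.sum() > 0

    def test_heteroplasmic_site_recovered(self):
        from mitocount import SimSpec, simulate_dataset

        spec = SimSpec(
            nuclear_length=20_000, mito_length=2000, true_k=200, n_pairs=2000,
            error_rate=0.0, heteroplasmy_fraction=0.2, heteroplasmy_sites=1, seed=32,
        )
        genome, reads = simulate_dataset(spec)
        classified, _ = self._classified(genome, reads)
        counts, flagged = pileup_alleles(classified, genome.mito_true, 0.1)
        site = reads.truth.heteroplasmy_positions[0]
        flagged_positions = {p for p, _ in flagged}
        assert site in flagged_positions
        frac = dict(flagged)[site]
        cov = counts[:, site].sum()
        # binomial oracle: observed minor fraction within 3 sd of 0.2
        sd = (0.2 * 0.8 / cov) ** 0.5
        assert abs(frac - 0.2) <= 3 * sd

    def test_threshold_zero_flags_any_second_allele(self, toy_circle):
        idx = build_index(toy_circle, 31)
        r1 = toy_circle[0:100]
        r2 = rc(toy_circle[200:300])
        v = classify_pair(r1, r2, idx, PairingParams(insert_min=100, insert_max=600))
        # second copy of the pair with one substituted base in r1
        r1_mut = mutate(r1, [10])
        v2 = classify_pair(r1_mut, r2, idx, PairingParams(insert_min=100, insert_max=600))
        counts, flagged = pileup_alleles(
            [(r1, r2, v), (r1_mut, r2, v2)], toy_circle, 0.0
        )
        assert (10, 0.5) in flagged
        # positions covered with a single allele are not flagged
        assert all(p == 10 for p, _ in flagged)
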