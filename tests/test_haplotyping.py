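from __future__ import annotations

import random

import pytest

from haplomerge.haplotyping import (
    Diplotype,
    PhaseSetError,
    assemble_diplotype,
    build_phase_blocks,
    cohort_haplotype_frequencies,
    haplotype_sequence,
    percent_phased,
)
from haplomerge.io_vcf import Platform


class TestBuildPhaseBlocks:
    def test_genotype_transposition(self, make_call):
        calls = [
            make_call(pos=100, genotype=(0, 1), phased=True, phase_set=100),
            make_call(pos=200, genotype=(1, 0), phased=True, phase_set=100),
        ]
        (block,) = build_phase_blocks(calls)
        assert block.hap_a == [0, 1]
        assert block.hap_b == [1, 0]
        assert [s.pos for s in block.sites] == [100, 200]

    def test_homozygous_sites_join_every_block(self, make_call):
        calls = [
            make_call(pos=100, genotype=(0, 1), phased=True, phase_set=100),
            make_call(pos=150, genotype=(1, 1)),
            make_call(pos=200, genotype=(1, 0), phased=True, phase_set=100),
        ]
        (block,) = build_phase_blocks(calls)
        assert block.hap_a == [0, 1, 1]
        assert block.hap_b == [1, 1, 0]

    def test_unphased_het_excluded(self, make_call):
        calls = [
            make_call(pos=100, genotype=(0, 1), phased=True, phase_set=100),
            make_call(pos=200, genotype=(0, 1), phased=False),
        ]
        (block,) = build_phase_blocks(calls)
        assert [s.pos for s in block.sites] == [100]

    def test_two_phase_sets_two_blocks(self, make_call):
        calls = [
            make_call(pos=100, genotype=(0, 1), phased=True, phase_set=100),
            make_call(pos=300, genotype=(1, 0), phased=True, phase_set=300),
        ]
        blocks = build_phase_blocks(calls)
        assert [b.phase_set for b in blocks] == [100, 300]

    def test_missing_ps_with_other_blocks_rejected(self, make_call):
        calls = [
            make_call(pos=100, genotype=(0, 1), phased=True, phase_set=None),
            make_call(pos=300, genotype=(1, 0), phased=True, phase_set=300),
        ]
        with pytest.raises(PhaseSetError):
            build_phase_blocks(calls)

    def test_random_cohort_matches_groupby_oracle(self, make_call):
        rng = random.Random(31)
        calls = []
        for pos in range(100, 600, 10):
            gt = rng.choice([(0, 1), (1, 0), (1, 1)])
            ps = rng.choice([100, 300]) if gt != (1, 1) else None
            calls.append(
                make_call(pos=pos, genotype=gt, phased=ps is not None, phase_set=ps)
            )
        blocks = {b.phase_set: b for b in build_phase_blocks(calls)}
        for ps in (100, 300):
            expected = sorted(
                [c for c in calls if c.phase_set == ps or c.genotype == (1, 1)],
                key=lambda c: c.pos,
            )
            assert [s.pos for s in blocks[ps].sites] == [c.pos for c in expected]
            assert blocks[ps].hap_a == [c.genotype[0] for c in expected]
            assert blocks[ps].hap_b == [c.genotype[1] for c in expected]


class TestPercentPhased:
    def test_partial_phasing(self, make_call):
        calls = [
            make_call(pos=p, genotype=(0, 1), phased=p != 400, phase_set=100)
            for p in (100, 200, 300, 400)
        ]
        summary = percent_phased(calls)
        assert summary.percent == 75.0
        assert (summary.n_het, summary.n_het_phased) == (4, 3)
        assert not summary.vacuous

    def test_all_homozygous_is_vacuously_phased(self, make_call):
        summary = percent_phased([make_call(genotype=(1, 1))])
        assert summary.percent == 100.0 and summary.vacuous

    def test_cohort_mean_tracks_phasing_probability(self, make_call):
        """Bernoulli(0.9) phasing over many hets lands near 90%."""
        rng = random.Random(12)
        n_het = 400 * 30
        calls = [
            make_call(pos=100 + i, genotype=(0, 1), phased=rng.random() < 0.9,
                      phase_set=1)
            for i in range(n_het)
        ]
        summary = percent_phased(calls)
        se = 100 * (0.9 * 0.1 / n_het) ** 0.5
        assert abs(summary.percent - 90.0) < 3 * se


class TestHaplotypeSequence:
    def test_substitution_on_one_haplotype(self, make_call):
        calls = [
            make_call(pos=2, ref="C", alt="T", genotype=(1, 0), phased=True,
                      phase_set=1)
        ]
        (block,) = build_phase_blocks(calls)
        assert haplotype_sequence("ACGT", block, ref_start=1) == ("ATGT", "ACGT")

    def test_no_variants_returns_reference(self, make_call):
        calls = [make_call(pos=2, ref="C", alt="T", genotype=(0, 0))]
        blocks = build_phase_blocks(calls)
        assert blocks == []  # hom-ref carries nothing

    def test_deletion_applied_right_to_left(self, make_call):
        calls = [
            make_call(pos=1, ref="AC", alt="A", genotype=(1, 1)),
            make_call(pos=4, ref="T", alt="G", genotype=(1, 1)),
        ]
        (block,) = build_phase_blocks(calls)
        assert haplotype_sequence("ACGT", block, ref_start=1) == ("AGG", "AGG")

    def test_reference_mismatch_rejected(self, make_call):
        calls = [make_call(pos=2, ref="G", alt="T", genotype=(1, 1))]
        (block,) = build_phase_blocks(calls)
        with pytest.raises(ValueError, match="REF mismatch"):
            haplotype_sequence("ACGT", block, ref_start=1)

    def test_random_substitutions_match_per_base_oracle(self, make_call):
        rng = random.Random(77)
        bases = "ACGT"
        for _ in range(50):
            ref = "".join(rng.choice(bases) for _ in range(40))
            positions = sorted(rng.sample(range(1, 41), rng.randint(1, 8)))
            calls = []
            for pos in positions:
                r = ref[pos - 1]
                a = rng.choice([b for b in bases if b != r])
                gt = rng.choice([(0, 1), (1, 0), (1, 1)])
                calls.append(
                    make_call(pos=pos, ref=r, alt=a, genotype=gt,
                              phased=gt != (1, 1), phase_set=1)
                )
            (block,) = build_phase_blocks(calls)
            got = haplotype_sequence(ref, block, ref_start=1)
            for hap_index in (0, 1):
                expected = list(ref)
                for c in calls:
                    if c.genotype[hap_index] == 1:
                        expected[c.pos - 1] = c.alt
                assert got[hap_index] == "".join(expected)


class TestDiplotypesAndFrequencies:
    def test_hand_counted_frequencies(self):
        dips = [
            Diplotype("S1", "r", ("H1", "H2"), True),
            Diplotype("S2", "r", ("H1", "H1"), True),
            Diplotype("S3", "r", ("H1", "H2"), True),
        ]
        hap = cohort_haplotype_frequencies(dips, "haplotype")
        assert hap.rows == [("H1", 4, pytest.approx(4 / 6)),
                            ("H2", 2, pytest.approx(2 / 6))]
        dip = cohort_haplotype_frequencies(dips, "diplotype")
        assert dip.rows[0] == ("H1 / H2", 2, pytest.approx(2 / 3))
        assert dip.rows[1] == ("H1 / H1", 1, pytest.approx(1 / 3))

    def test_single_sample(self):
        (row_a, row_b) = cohort_haplotype_frequencies(
            [Diplotype("S1", "r", ("A", "B"), True)], "haplotype"
        ).rows
        assert row_a[1:] == (1, 0.5) and row_b[1:] == (1, 0.5)

    def test_incomplete_samples_excluded_and_counted(self):
        dips = [
            Diplotype("S1", "r", ("H1", "H2"), True),
            Diplotype("S2", "r", ("H1", "H3"), False),
        ]
        table = cohort_haplotype_frequencies(dips, "haplotype")
        assert table.n_excluded_incomplete == 1
        assert table.n_complete_samples == 1
        assert sum(c for _, c, _ in table.rows) == 2

    def test_random_multiset_matches_counting_oracle(self):
        rng = random.Random(50)
        haps = ["H1", "H2", "H3", "H4"]
        dips = [
            Diplotype(f"S{i}", "r", tuple(sorted(rng.sample(haps, 2))), True)
            for i in range(100)
        ]
        table = cohort_haplotype_frequencies(dips, "haplotype")
        oracle: dict[str, int] = {}
        for d in dips:
            for h in d.haplotype_pair:
                oracle[h] = oracle.get(h, 0) + 1
        assert {h: c for h, c, _ in table.rows} == oracle
        assert sum(f for _, _, f in table.rows) == pytest.approx(1.0, abs=1e-9)
        counts = [c for _, c, _ in table.rows]
        assert counts == sorted(counts, reverse=True)

    def test_split_blocks_flag_incomplete(self, make_call):
        calls = [
            make_call(pos=100, genotype=(0, 1), phased=True, phase_set=100),
            make_call(pos=300, genotype=(1, 0), phased=True, phase_set=300),
        ]
        dip = assemble_diplotype(calls, "r")
        assert not dip.complete

    def test_sample_without_calls_is_ref_ref(self):
        dip = assemble_diplotype([], "r", sample_id="S9")
        assert dip.haplotype_pair == ("REF", "REF")
        assert dip.complete and dip.sample_id == "S9"
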