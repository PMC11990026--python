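from __future__ import annotations

import random

import pytest

from haplomerge.concordance import (
    ConcordanceCategory as Cat,
    DuplicateCallError,
    classify_pair,
    merge_cohorts,
    records_to_frame,
    summarize,
)
from haplomerge.io_vcf import Platform, SiteKey


class TestClassifyPair:
    def test_equal_genotypes_agree(self, make_call):
        a = make_call(platform=Platform.ILLUMINA, genotype=(0, 1))
        b = make_call(platform=Platform.ONT, genotype=(0, 1))
        assert classify_pair(a, b) is Cat.AGREE

    def test_different_genotypes_discrepant(self, make_call):
        a = make_call(platform=Platform.ILLUMINA, genotype=(0, 1))
        b = make_call(platform=Platform.ONT, genotype=(1, 1))
        assert classify_pair(a, b) is Cat.DISCREPANT

    def test_one_sided_calls(self, make_call):
        ont = make_call(platform=Platform.ONT, genotype=(0, 1))
        ill = make_call(platform=Platform.ILLUMINA, genotype=(0, 1))
        assert classify_pair(None, ont) is Cat.ONT_ONLY
        assert classify_pair(ill, None) is Cat.ILLUMINA_ONLY

    def test_phase_order_ignored(self, make_call):
        a = make_call(platform=Platform.ILLUMINA, genotype=(0, 1), phased=True)
        b = make_call(platform=Platform.ONT, genotype=(1, 0), phased=True)
        assert classify_pair(a, b) is Cat.AGREE

    def test_both_absent_is_contract_violation(self):
        with pytest.raises(ValueError):
            classify_pair(None, None)

    def test_site_mismatch_rejected(self, make_call):
        a = make_call(platform=Platform.ILLUMINA, pos=100)
        b = make_call(platform=Platform.ONT, pos=101)
        with pytest.raises(ValueError):
            classify_pair(a, b)


class TestMergeCohorts:
    def test_single_agreeing_site(self, make_call):
        ill = [make_call(platform=Platform.ILLUMINA)]
        ont = [make_call(platform=Platform.ONT)]
        (rec,) = merge_cohorts(ill, ont)
        assert rec.category is Cat.AGREE
        assert rec.illumina_call and rec.ont_call

    def test_platform_only_sites(self, make_call):
        ill = [make_call(platform=Platform.ILLUMINA, pos=100)]
        ont = [make_call(platform=Platform.ONT, pos=200)]
        recs = merge_cohorts(ill, ont)
        assert [r.category for r in recs] == [Cat.ILLUMINA_ONLY, Cat.ONT_ONLY]

    def test_duplicate_within_platform_rejected(self, make_call):
        ill = [make_call(platform=Platform.ILLUMINA)] * 2
        with pytest.raises(DuplicateCallError):
            merge_cohorts(ill, [])

    def test_hom_ref_and_missing_are_not_reported(self, make_call):
        ill = [
            make_call(platform=Platform.ILLUMINA, genotype=(0, 0)),
            make_call(platform=Platform.ILLUMINA, pos=200, genotype=None),
        ]
        ont = [make_call(platform=Platform.ONT, genotype=(0, 1))]
        recs = merge_cohorts(ill, ont)
        assert [r.category for r in recs] == [Cat.ONT_ONLY]

    def test_random_cohorts_match_pairing_oracle(self, make_call):
        rng = random.Random(42)
        sites = [SiteKey("chr1", 100 + 10 * i, "A", "G") for i in range(30)]
        samples = [f"S{i:02d}" for i in range(20)]

        def cohort(platform):
            return [
                make_call(
                    sample_id=sid,
                    platform=platform,
                    pos=site.pos,
                    contig=site.contig,
                    genotype=rng.choice([(0, 1), (1, 0), (1, 1)]),
                )
                for sid in samples
                for site in sites
                if rng.random() < 0.5
            ]

        ill, ont = cohort(Platform.ILLUMINA), cohort(Platform.ONT)
        records = merge_cohorts(ill, ont)

        # brute-force pairing over the (sample, site) union
        ill_map = {(c.sample_id, c.site): c for c in ill}
        ont_map = {(c.sample_id, c.site): c for c in ont}
        expected = {}
        for key in set(ill_map) | set(ont_map):
            a, b = ill_map.get(key), ont_map.get(key)
            if a is None:
                expected[key] = Cat.ONT_ONLY
            elif b is None:
                expected[key] = Cat.ILLUMINA_ONLY
            elif sorted(a.genotype) == sorted(b.genotype):
                expected[key] = Cat.AGREE
            else:
                expected[key] = Cat.DISCREPANT
        assert {(r.sample_id, r.site): r.category for r in records} == expected
        # conservation: one record per (sample, site) in the union
        assert len(records) == len(expected)
        # sorted output
        keys = [(r.site.contig, r.site.pos, r.sample_id) for r in records]
        assert keys == sorted(keys)

    def test_platform_symmetry(self, make_call):
        rng = random.Random(13)
        ill = [
            make_call(sample_id=f"S{i}", platform=Platform.ILLUMINA, pos=p,
                      genotype=rng.choice([(0, 1), (1, 1)]))
            for i in range(5)
            for p in range(100, 150, 10)
            if rng.random() < 0.7
        ]
        ont = [
            make_call(sample_id=f"S{i}", platform=Platform.ONT, pos=p,
                      genotype=rng.choice([(0, 1), (1, 1)]))
            for i in range(5)
            for p in range(100, 150, 10)
            if rng.random() < 0.7
        ]
        fwd = {(r.sample_id, r.site): r.category for r in merge_cohorts(ill, ont)}
        swap_ill = [_relabel(c, Platform.ILLUMINA) for c in ont]
        swap_ont = [_relabel(c, Platform.ONT) for c in ill]
        rev = {
            (r.sample_id, r.site): r.category
            for r in merge_cohorts(swap_ill, swap_ont)
        }
        flip = {
            Cat.AGREE: Cat.AGREE,
            Cat.DISCREPANT: Cat.DISCREPANT,
            Cat.ILLUMINA_ONLY: Cat.ONT_ONLY,
            Cat.ONT_ONLY: Cat.ILLUMINA_ONLY,
        }
        assert rev == {k: flip[v] for k, v in fwd.items()}


def _relabel(call, platform):
    import dataclasses

    return dataclasses.replace(call, platform=platform)


class TestSummarize:
    def test_overall_frequencies_arithmetic(self, make_call):
        records = merge_cohorts(
            [
                make_call(sample_id=f"S{i}", platform=Platform.ILLUMINA, pos=100 + i)
                for i in range(99)
            ]
            + [make_call(sample_id="D", platform=Platform.ILLUMINA, pos=500,
                         genotype=(1, 1))],
            [
                make_call(sample_id=f"S{i}", platform=Platform.ONT, pos=100 + i)
                for i in range(98)
            ]
            + [make_call(sample_id="D", platform=Platform.ONT, pos=500,
                         genotype=(0, 1)),
               make_call(sample_id="O", platform=Platform.ONT, pos=600)],
        )
        (overall,) = summarize(records, "overall")
        assert overall.counts[Cat.AGREE] == 98
        assert overall.counts[Cat.DISCREPANT] == 1
        assert overall.counts[Cat.ILLUMINA_ONLY] == 1
        assert overall.counts[Cat.ONT_ONLY] == 1
        assert overall.frequencies[Cat.AGREE] == pytest.approx(98 / 101)
        assert sum(overall.frequencies.values()) == pytest.approx(1.0, abs=1e-9)

    def test_all_agree_frequency_one(self, make_call):
        records = merge_cohorts(
            [make_call(platform=Platform.ILLUMINA)],
            [make_call(platform=Platform.ONT)],
        )
        (overall,) = summarize(records)
        assert overall.frequencies[Cat.AGREE] == 1.0

    def test_empty_input_gives_empty_summary(self):
        assert summarize([], "overall") == []

    def test_per_position_counts_match_groupby_oracle(self, make_call):
        rng = random.Random(17)
        ill = [
            make_call(sample_id=f"S{i}", platform=Platform.ILLUMINA, pos=p,
                      genotype=rng.choice([(0, 1), (1, 1)]))
            for i in range(10)
            for p in (100, 200, 300)
            if rng.random() < 0.8
        ]
        ont = [
            make_call(sample_id=f"S{i}", platform=Platform.ONT, pos=p,
                      genotype=rng.choice([(0, 1), (1, 1)]))
            for i in range(10)
            for p in (100, 200, 300)
            if rng.random() < 0.8
        ]
        records = merge_cohorts(ill, ont)
        summaries = {s.key: s.counts for s in summarize(records, "per_position")}
        oracle: dict = {}
        for r in records:
            oracle.setdefault(r.site, {c: 0 for c in Cat})
            oracle[r.site][r.category] += 1
        assert summaries == oracle

    def test_export_frame_layout(self, make_call):
        records = merge_cohorts(
            [make_call(platform=Platform.ILLUMINA, phased=True, genotype=(1, 0))],
            [make_call(platform=Platform.ONT)],
        )
        frame = records_to_frame(records)
        assert list(frame["category"]) == ["AGREE"]
        assert list(frame["illumina_gt"]) == ["1|0"]
        assert list(frame["ont_gt"]) == ["0/1"]
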