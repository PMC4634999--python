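from collections import Counter, defaultdict

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mosaicscan import (
    PileupColumn,
    TierConfig,
    VariantCall,
    apply_orientation_filter,
    apply_panel_filter,
    build_pileup,
    call_candidates,
    call_sample,
    downsample_redundancy,
    filter_reads,
    random_reference,
)
from mosaicscan.simulate import SimulationProfile, VariantSpec, simulate_reads

from conftest import TRANSITION, make_read


def make_column(ref_base="C", alt="T", n_alt_f=0, n_alt_r=0, depth=100, pos=50):
    """Pileup column with given alt support on a ref background."""
    n_ref = depth - n_alt_f - n_alt_r
    col = PileupColumn(contig="c", position=pos, ref_base=ref_base)
    col.counts_forward[ref_base] = n_ref // 2
    col.counts_reverse[ref_base] = n_ref - n_ref // 2
    if n_alt_f:
        col.counts_forward[alt] = n_alt_f
    if n_alt_r:
        col.counts_reverse[alt] = n_alt_r
    return col


class TestFilterReads:
    def test_high_quality_reads_untouched(self, small_reference):
        reads = [make_read(small_reference, i + 1, read_id=f"r{i}") for i in range(5)]
        assert filter_reads(reads, TierConfig()) == reads

    def test_low_mapq_removed(self, small_reference):
        reads = [make_read(small_reference, 1, mapq=0), make_read(small_reference, 1, mapq=60)]
        kept = filter_reads(reads, TierConfig())
        assert len(kept) == 1 and kept[0].mapping_quality == 60

    def test_low_quality_bases_masked_not_dropped(self, small_reference):
        read = make_read(small_reference, 1, length=10)
        read.base_qualities[3] = 5
        (kept,) = filter_reads([read], TierConfig())
        assert kept.sequence[3] == "N"
        assert kept.sequence[:3] == read.sequence[:3] if read.sequence[3] == "N" else True
        assert len(kept.sequence) == 10

    def test_threshold_sweep_matches_recount_oracle(self, small_reference):
        rng = np.random.default_rng(17)
        reads = [
            make_read(small_reference, 1, read_id=f"r{i}", mapq=int(rng.integers(0, 61)))
            for i in range(1000)
        ]
        for threshold in (0, 10, 20, 40, 61):
            cfg = TierConfig(min_mapping_quality=threshold)
            expected = sum(1 for r in reads if r.mapping_quality >= threshold)
            assert len(filter_reads(reads, cfg)) == expected


class TestDownsampleRedundancy:
    def test_overfull_group_capped_at_50(self, small_reference):
        reads = [make_read(small_reference, 100 % 90 + 1, read_id=f"r{i:04d}") for i in range(120)]
        assert len(downsample_redundancy(reads, cap=50)) == 50

    def test_small_group_untouched(self, small_reference):
        reads = [make_read(small_reference, 1, read_id=f"r{i}") for i in range(30)]
        assert downsample_redundancy(reads, cap=50) == reads

    def test_per_group_sizes_match_groupby_oracle(self, small_reference):
        rng = np.random.default_rng(3)
        reads = [
            make_read(
                small_reference,
                int(rng.integers(1, 6)),
                orientation="forward" if rng.random() < 0.5 else "reverse",
                read_id=f"r{i}",
            )
            for i in range(400)
        ]
        cap = 50
        kept = downsample_redundancy(reads, cap=cap)
        orig = Counter((r.start, r.orientation) for r in reads)
        after = Counter((r.start, r.orientation) for r in kept)
        for group, n in orig.items():
            assert after[group] == min(n, cap)

    def test_selection_deterministic_and_mapq_ranked(self, small_reference):
        reads = [
            make_read(small_reference, 1, read_id=f"r{i:03d}", mapq=30 + (i % 3))
            for i in range(60)
        ]
        kept1 = downsample_redundancy(reads, cap=10)
        kept2 = downsample_redundancy(list(reversed(reads)), cap=10)
        assert {r.read_id for r in kept1} == {r.read_id for r in kept2}
        assert all(r.mapping_quality == 32 for r in kept1[:10])


class TestBuildPileup:
    def test_single_read_columns(self, small_reference):
        read = make_read(small_reference, 1, length=4, sequence="ACGT", cigar="4M")
        cols = build_pileup([read], small_reference)
        assert [c.position for c in cols] == [1, 2, 3, 4]
        assert all(c.depth_forward == 1 and c.depth_reverse == 0 for c in cols)
        assert cols[0].counts_forward["A"] == 1

    def test_orientation_split_bookkeeping(self, small_reference):
        pos, ref_base = 10, small_reference.base(10)
        alt = TRANSITION[ref_base]
        reads = []
        for i in range(6):
            r = make_read(small_reference, pos, length=5, read_id=f"f{i}")
            reads.append(make_read(small_reference, pos, length=5, read_id=f"f{i}",
                                   sequence=alt + r.sequence[1:]))
        for i in range(4):
            r = make_read(small_reference, pos, length=5, read_id=f"v{i}", orientation="reverse")
            reads.append(make_read(small_reference, pos, length=5, read_id=f"v{i}",
                                   orientation="reverse", sequence=alt + r.sequence[1:]))
        col = build_pileup(reads, small_reference, region=(pos, pos))[0]
        assert col.counts_forward[alt] == 6
        assert col.counts_reverse[alt] == 4

    def test_insertion_keyed_to_anchor(self, small_reference):
        seq = small_reference.sequence[9:14] + "TT" + small_reference.sequence[14:17]
        read = make_read(small_reference, 10, sequence=seq, cigar="5M2I3M")
        cols = {c.position: c for c in build_pileup([read], small_reference)}
        assert cols[14].indel_obs_forward["+TT"] == 1

    def test_deletion_keyed_to_anchor_with_length(self, small_reference):
        seq = small_reference.sequence[9:14] + small_reference.sequence[17:20]
        read = make_read(small_reference, 10, sequence=seq, cigar="5M3D3M")
        cols = {c.position: c for c in build_pileup([read], small_reference)}
        assert cols[14].indel_obs_forward["-3"] == 1
        # deleted positions contribute no base depth
        assert 15 not in cols or cols[15].depth_total == 0

    def test_overhanging_read_truncated(self, small_reference):
        L = len(small_reference)
        read = make_read(small_reference, L - 2, length=10,
                         sequence=small_reference.sequence[L - 3:] + "AAAAAAA")
        cols = build_pileup([read], small_reference)
        assert max(c.position for c in cols) == L

    def test_depths_match_naive_per_read_scan(self, small_reference):
        profile = SimulationProfile(depth=500, read_length=30, per_base_error=0.002, seed=11)
        reads = simulate_reads(small_reference, [], profile)
        cols = {c.position: c for c in build_pileup(reads, small_reference)}
        naive = defaultdict(int)
        for r in reads:
            for offset, base in enumerate(r.sequence):
                if base != "N":
                    naive[r.start + offset] += 1
        for pos, depth in naive.items():
            assert cols[pos].depth_total == depth

    def test_conservation_property(self, small_reference):
        """Sum of orientation-split counts equals quality-passing bases covering."""
        profile = SimulationProfile(depth=200, read_length=25, per_base_error=0.01, seed=23)
        reads = simulate_reads(small_reference, [], profile)
        cols = build_pileup(reads, small_reference)
        total_counted = sum(c.depth_total for c in cols)
        total_bases = sum(len(r.sequence) for r in reads)
        assert total_counted == total_bases  # no N bases in this error model


class TestCallCandidates:
    def test_af_arithmetic_low_fraction_snv(self):
        col = make_column(n_alt_f=6, n_alt_r=4, depth=1806)
        (call,) = call_candidates([col], tier="sensitive")
        assert call.af == pytest.approx(10 / 1806)
        assert round(call.af * 100, 2) == 0.55
        assert call.tier == "sensitive"

    def test_af_arithmetic_second_regime(self):
        col = make_column(n_alt_f=21, n_alt_r=20, depth=5745)
        (call,) = call_candidates([col], tier="sensitive")
        assert round(call.af * 100, 2) == 0.71

    def test_review_tier_requires_one_percent(self):
        col = make_column(n_alt_f=4, n_alt_r=4, depth=1000)  # 0.8%
        assert call_candidates([col], tier="review") == []
        assert len(call_candidates([col], tier="sensitive")) == 1

    def test_sensitive_snv_thresholds(self):
        called = call_candidates([make_column(n_alt_f=2, n_alt_r=1, depth=600)], tier="sensitive")
        assert len(called) == 1  # 0.5% with 3 reads
        not_called = call_candidates([make_column(n_alt_f=1, n_alt_r=1, depth=1000)], tier="sensitive")
        assert not_called == []  # 0.2% SNV below the 0.5% cut

    def test_indel_thresholds(self):
        col = make_column(depth=1000)
        col.indel_obs_forward["-2"] = 1
        col.indel_obs_reverse["-2"] = 1
        (call,) = call_candidates([col], tier="sensitive")  # 0.2%, 2 reads
        assert call.variant_type == "deletion_small"
        assert call.af == pytest.approx(0.002)

    def test_zero_depth_column_skipped(self):
        col = PileupColumn(contig="c", position=1, ref_base="A")
        assert call_candidates([col]) == []

    def test_monotonicity_lowering_thresholds_never_removes_calls(self):
        cols = [
            make_column(n_alt_f=3, n_alt_r=2, depth=400, pos=p) for p in range(1, 30)
        ]
        strict = {c.key for c in call_candidates(cols, TierConfig(), "sensitive")}
        loose_cfg = TierConfig(snv_af=0.002, indel_af=0.001)
        loose = {c.key for c in call_candidates(cols, loose_cfg, "sensitive")}
        assert strict <= loose

    def test_brute_force_enumeration_oracle(self, small_reference):
        """On small read sets, calls equal exhaustive allele/threshold enumeration."""
        rng = np.random.default_rng(31)
        pos, ref_base = 50, small_reference.base(50)
        reads = []
        for i in range(50):
            base = "ACGT"[rng.integers(0, 4)] if rng.random() < 0.3 else ref_base
            seq = small_reference.sequence[44:50] + base + small_reference.sequence[50:56]
            reads.append(make_read(small_reference, 45, sequence=seq, read_id=f"r{i}",
                                   orientation="forward" if rng.random() < 0.5 else "reverse"))
        cfg = TierConfig()
        calls = call_candidates(build_pileup(reads, small_reference, (pos, pos)), cfg, "sensitive")
        # oracle: direct tally over reads
        tally_f, tally_r = Counter(), Counter()
        for r in reads:
            b = r.sequence[pos - r.start]
            (tally_f if r.orientation == "forward" else tally_r)[b] += 1
        depth = sum(tally_f.values()) + sum(tally_r.values())
        expected = set()
        for b in "ACGT":
            if b == ref_base:
                continue
            support = tally_f[b] + tally_r[b]
            af = support / depth
            if support and (af >= cfg.review_af or (af >= cfg.snv_af and support >= cfg.snv_min_reads)):
                expected.add((pos, ref_base, b))
        assert {(c.position, c.ref, c.alt) for c in calls} == expected


class TestArtifactFilters:
    def _call(self, fwd, rev, sample="s1", pos=10):
        return VariantCall(
            contig="c", position=pos, ref="C", alt="T", variant_type="SNV",
            af=(fwd + rev) / 1000, support_forward=fwd, support_reverse=rev,
            depth_total=1000, tier="sensitive", sample_id=sample)

    def test_single_orientation_flagged(self):
        calls = apply_orientation_filter([self._call(5, 0)])
        assert calls[0].filters == {"single_orientation"}

    def test_minimal_both_orientation_passes(self):
        calls = apply_orientation_filter([self._call(1, 1)])
        assert calls[0].passes

    def test_strand_asymmetric_simulation_flag_rate(self, small_reference):
        """Every strand-confined call from an asymmetric-error run is flagged."""
        profile = SimulationProfile(
            depth=3000, read_length=75, per_base_error=0.004,
            strand_asymmetry=5.0, seed=41)
        reads = simulate_reads(small_reference, [], profile)
        calls = call_sample(reads, small_reference)
        confined = [c for c in calls if c.support_forward == 0 or c.support_reverse == 0]
        assert confined, "asymmetric error run should produce strand-confined candidates"
        assert all("single_orientation" in c.filters for c in confined)
        balanced = [c for c in calls if c.support_forward > 0 and c.support_reverse > 0]
        assert all("single_orientation" not in c.filters for c in balanced)

    def test_panel_recurrent_flagged_in_all_carriers(self):
        cohort = {f"s{i}": [self._call(3, 3, sample=f"s{i}")] for i in range(5)}
        cohort.update({f"t{i}": [] for i in range(7)})
        for sample, calls in cohort.items():
            apply_panel_filter(calls, cohort)
            for c in calls:
                assert "panel_recurrent" in c.filters

    def test_private_variant_passes(self):
        mine = [self._call(3, 3, sample="s1")]
        cohort = {"s1": mine, "s2": [], "s3": []}
        apply_panel_filter(mine, cohort)
        assert mine[0].passes

    def test_recurrent_artifact_flagged_true_mosaic_passes(self):
        """Injected recurrent artifact flagged; private 3% mosaic untouched."""
        artifact_pos, mosaic_pos = 10, 77
        cohort = {}
        for i in range(25):
            calls = []
            if i < 10:
                calls.append(self._call(4, 4, sample=f"s{i}", pos=artifact_pos))
            if i == 0:
                c = self._call(15, 15, sample="s0", pos=mosaic_pos)
                calls.append(c)
            cohort[f"s{i}"] = calls
        all_calls = [c for calls in cohort.values() for c in calls]
        apply_panel_filter(all_calls, cohort)
        for c in all_calls:
            if c.position == artifact_pos:
                assert "panel_recurrent" in c.filters
            else:
                assert c.passes


@settings(deadline=None, max_examples=25)
@given(
    n_alt_f=st.integers(0, 30),
    n_alt_r=st.integers(0, 30),
    depth=st.integers(60, 5000),
)
def test_call_af_invariant(n_alt_f, n_alt_r, depth):
    """Every emitted call satisfies af == support / depth_total and af in (0, 1]."""
    col = make_column(n_alt_f=n_alt_f, n_alt_r=n_alt_r, depth=depth)
    for call in call_candidates([col], tier="sensitive"):
        assert call.af == pytest.approx(call.support_total / call.depth_total)
        assert 0 < call.af <= 1
        assert (call.support_forward, call.support_reverse) == (n_alt_f, n_alt_r)
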