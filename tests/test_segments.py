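"""Curation rules: parsing, CN-LOH exclusion, proximity merging,
chromothripsis collapse, size/region filtering, aneuploidy, counting and
lesion calls."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_segments
from gcx.errors import (
    ConfigurationError,
    ContractViolation,
    ParseError,
    UndefinedResultError,
    ValidationError,
)
from gcx.segments import (
    MB,
    CNAEvent,
    ConcordanceResult,
    CurationParams,
    EventKind,
    GCClass,
    GC_ORDER,
    GCThresholds,
    RegionCatalog,
    Segment,
    SegState,
    apply_size_and_region_filter,
    call_canonical_lesions,
    classify_del13q_size,
    classify_gc,
    count_cna,
    curate_sample,
    detect_aneuploidy,
    detect_chromothripsis,
    exclude_cn_neutral_loh,
    fish_concordance,
    merge_proximal,
    read_seg,
)

P = CurationParams()


def seg(chrom, start, end, state=SegState.LOSS, sample="S1", flag=False):
    return Segment(sample_id=sample, chrom=chrom, start=start, end=end,
                   state=state, chromothripsis_flag=flag)


# ---------------------------------------------------------------- parsing

class TestReadSeg:
    def _write(self, tmp_path, rows, header="sample\tchrom\tstart\tend\tstate"):
        p = tmp_path / "in.seg"
        p.write_text(header + "\n" + "\n".join(rows) + "\n")
        return p

    def test_well_formed_rows_parse(self, tmp_path):
        p = self._write(
            tmp_path,
            ["S1\t1\t1001\t2000\tloss", "S1\t13\t500\t900\tgain", "S2\tX\t10\t20\tloss"],
        )
        segs = read_seg(p)
        assert len(segs) == 3
        assert all(s.end > s.start for s in segs)

    def test_one_based_inclusive_conversion(self, tmp_path):
        p = self._write(tmp_path, ["S1\t1\t1001\t2000\tloss"])
        (s,) = read_seg(p, dialect="seg_1based")
        assert (s.start, s.end, s.size_bp) == (1000, 2000, 1000)

    def test_bed_dialect_keeps_coordinates(self, tmp_path):
        p = self._write(tmp_path, ["S1\t1\t1000\t2000\tloss"])
        (s,) = read_seg(p, dialect="bed_0based")
        assert (s.start, s.end) == (1000, 2000)

    def test_unknown_chromosome_rejected(self, tmp_path):
        p = self._write(tmp_path, ["S1\tchr99\t100\t200\tloss"])
        with pytest.raises(ParseError, match="line 2"):
            read_seg(p)

    def test_unknown_state_rejected(self, tmp_path):
        p = self._write(tmp_path, ["S1\t1\t100\t200\tweird"])
        with pytest.raises(ParseError):
            read_seg(p)

    def test_copy_number_column_translated(self, tmp_path):
        p = self._write(
            tmp_path,
            ["S1\t1\t100\t200\t0", "S1\t2\t100\t200\t1", "S1\t3\t100\t200\t2",
             "S1\t4\t100\t200\t3"],
            header="sample\tchrom\tstart\tend\tcopy_number",
        )
        segs = read_seg(p)
        assert [s.state for s in segs] == [
            SegState.BIALLELIC_LOSS, SegState.LOSS, SegState.GAIN
        ]


# ----------------------------------------------------------- CN-LOH

class TestExcludeCnLoh:
    def test_loh_removed_others_kept_in_order(self):
        segs = [
            seg("1", 0, MB, SegState.LOSS),
            seg("2", 0, MB, SegState.CN_LOH),
            seg("3", 0, MB, SegState.GAIN),
        ]
        out = exclude_cn_neutral_loh(segs)
        assert [s.state for s in out] == [SegState.LOSS, SegState.GAIN]

    def test_identity_when_no_loh(self):
        segs = [seg("1", 0, MB), seg("2", 0, MB, SegState.GAIN)]
        assert exclude_cn_neutral_loh(segs) == segs

    def test_random_mix_count(self):
        rng = np.random.default_rng(0)
        segs = random_segments(rng, 6) + [
            seg("5", i * 10 * MB, i * 10 * MB + MB, SegState.CN_LOH) for i in range(4)
        ]
        assert len(exclude_cn_neutral_loh(segs)) == 6


# ----------------------------------------------------------- merging

class TestMergeProximal:
    def test_gap_within_5mb_merges(self):
        out = merge_proximal([seg("4", 0, 2 * MB), seg("4", 6 * MB, 8 * MB)], P)
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (0, 8 * MB)

    def test_gap_exactly_5mb_merges(self):
        out = merge_proximal([seg("4", 0, 2 * MB), seg("4", 7 * MB, 9 * MB)], P)
        assert len(out) == 1

    def test_gap_above_5mb_stays_separate(self):
        out = merge_proximal([seg("4", 0, 2 * MB), seg("4", 7 * MB + 1, 9 * MB)], P)
        assert len(out) == 2

    def test_opposite_directions_never_merge(self):
        out = merge_proximal(
            [seg("4", 0, 2 * MB, SegState.LOSS), seg("4", 3 * MB, 5 * MB, SegState.GAIN)], P
        )
        assert len(out) == 2

    def test_merge_is_transitive(self):
        segs = [seg("4", i * 6 * MB, i * 6 * MB + 2 * MB) for i in range(5)]
        assert len(merge_proximal(segs, P)) == 1

    def test_biallelic_member_dominates_kind(self):
        out = merge_proximal(
            [seg("13", 0, MB, SegState.BIALLELIC_LOSS), seg("13", 2 * MB, 3 * MB)], P
        )
        assert out[0].kind is EventKind.BIALLELIC_LOSS and out[0].weight == 2

    def test_mixed_samples_rejected(self):
        with pytest.raises(ContractViolation):
            merge_proximal([seg("1", 0, MB, sample="A"), seg("1", 0, MB, sample="B")], P)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        segs = random_segments(rng, 15)
        once = merge_proximal(segs, P)
        twice = merge_proximal(once, P)
        assert once == twice

    def test_matches_brute_force_oracle(self, catalog, merge_filter_oracle):
        rng = np.random.default_rng(11)
        for _ in range(400):
            segs = random_segments(rng, int(rng.integers(1, 21)))
            events = apply_size_and_region_filter(merge_proximal(segs, P), catalog, P)
            got = sorted((e.chrom, e.start, e.end, e.kind) for e in events)
            expected, count = merge_filter_oracle(segs, catalog, P)
            assert got == sorted(expected)
            assert count_cna(events) == count

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        segs = random_segments(rng, 12)
        base = merge_proximal(segs, P)
        for _ in range(10):
            perm = list(segs)
            rng.shuffle(perm)
            assert merge_proximal(perm, P) == base


# ----------------------------------------------------- chromothripsis

class TestChromothripsis:
    def test_oscillating_segments_collapse(self):
        segs = [seg("5", i * 2 * MB, i * 2 * MB + MB) for i in range(12)]
        clusters, remaining = detect_chromothripsis(segs, P)
        assert len(clusters) == 1 and clusters[0].kind is EventKind.CHROMOTHRIPSIS_CLUSTER
        assert remaining == []

    def test_few_segments_do_not_collapse(self):
        segs = [seg("5", i * 10 * MB, i * 10 * MB + MB) for i in range(3)]
        clusters, remaining = detect_chromothripsis(segs, P)
        assert clusters == [] and len(remaining) == 3

    def test_flag_override_wins_regardless_of_oscillation(self):
        segs = [seg("8", i * 10 * MB, i * 10 * MB + MB, flag=True) for i in range(5)]
        clusters, remaining = detect_chromothripsis(segs, P)
        assert len(clusters) == 1 and remaining == []

    def test_cluster_counts_once_through_pipeline(self, catalog, chrom_lengths):
        segs = [seg("5", i * 2 * MB, i * 2 * MB + MB) for i in range(12)]
        _, summary = curate_sample(segs, catalog, chrom_lengths)
        assert summary["cna_count"] == 1


# ------------------------------------------------------ size filter

class TestSizeRegionFilter:
    def test_small_deletion_in_known_region_retained(self, catalog):
        e = merge_proximal([seg("13", 50_100_000, 50_400_000)], P)  # 300 kb in 13q14
        out = apply_size_and_region_filter(e, catalog, P)
        assert len(out) == 1 and "13q14_MDR" in out[0].region_hits

    def test_tiny_7kb_in_region_retained(self, catalog):
        e = merge_proximal([seg("17", 7_570_000, 7_577_000)], P)  # 7 kb over TP53
        out = apply_size_and_region_filter(e, catalog, P)
        assert len(out) == 1

    def test_small_off_catalog_removed(self, catalog):
        e = merge_proximal([seg("9", 10 * MB, 13 * MB)], P)  # 3 Mb on 9p
        assert apply_size_and_region_filter(e, catalog, P) == []

    def test_5mb_inclusive_retained(self, catalog):
        e = merge_proximal([seg("9", 10 * MB, 15 * MB)], P)  # exactly 5 Mb
        assert len(apply_size_and_region_filter(e, catalog, P)) == 1

    def test_empty_catalog_rejected(self):
        with pytest.raises((ConfigurationError, TypeError)):
            apply_size_and_region_filter([], None, P)


# ------------------------------------------------------- aneuploidy

class TestAneuploidy:
    def test_95pct_chr12_gain_is_trisomy(self, chrom_lengths):
        span = int(0.95 * chrom_lengths["12"])
        e = CNAEvent("S1", "12", 0, span, EventKind.GAIN)
        (out,) = detect_aneuploidy([e], chrom_lengths, P)
        assert out.kind is EventKind.ANEUPLOIDY_GAIN

    def test_half_chr12_gain_stays_segmental(self, chrom_lengths):
        e = CNAEvent("S1", "12", 0, chrom_lengths["12"] // 2, EventKind.GAIN)
        (out,) = detect_aneuploidy([e], chrom_lengths, P)
        assert out.kind is EventKind.GAIN

    def test_whole_chr13_loss_counts_once(self, catalog, chrom_lengths):
        segs = [seg("13", 0, chrom_lengths["13"], SegState.LOSS)]
        events, summary = curate_sample(segs, catalog, chrom_lengths)
        assert events[0].kind is EventKind.ANEUPLOIDY_LOSS
        assert summary["cna_count"] == 1

    def test_missing_length_rejected(self):
        e = CNAEvent("S1", "12", 0, 10 * MB, EventKind.GAIN)
        with pytest.raises(ConfigurationError):
            detect_aneuploidy([e], {"1": 100}, P)


# ------------------------------------------------------- counting / GC

class TestCountAndGC:
    def test_biallelic_counts_two(self):
        e = CNAEvent("S1", "13", 50_000_000, 50_500_000, EventKind.BIALLELIC_LOSS)
        assert count_cna([e]) == 2

    def test_empty_is_zero(self):
        assert count_cna([]) == 0

    def test_mixed_weights(self):
        events = [
            CNAEvent("S1", "12", 0, 133_851_895, EventKind.ANEUPLOIDY_GAIN),
            CNAEvent("S1", "11", 100 * MB, 110 * MB, EventKind.LOSS),
            CNAEvent("S1", "13", 50_000_000, 50_500_000, EventKind.BIALLELIC_LOSS),
        ]
        assert count_cna(events) == 4

    @pytest.mark.parametrize(
        "count,expected",
        [(0, GCClass.LGC), (2, GCClass.LGC), (3, GCClass.IGC), (4, GCClass.IGC),
         (5, GCClass.HGC), (23, GCClass.HGC)],
    )
    def test_gc_boundaries(self, count, expected):
        assert classify_gc(count) is expected

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            classify_gc(-1)

    @given(st.integers(0, 40), st.integers(0, 40))
    @settings(max_examples=100, derandomize=True)
    def test_gc_monotone(self, a, b):
        lo, hi = sorted((a, b))
        assert GC_ORDER[classify_gc(lo)] <= GC_ORDER[classify_gc(hi)]


# -------------------------------------------------------- lesion calls

class TestLesionCalls:
    def test_tp53_loss_sets_del17p(self, catalog, chrom_lengths):
        segs = [seg("17", 7_000_000, 8_000_000)]
        _, summary = curate_sample(segs, catalog, chrom_lengths)
        assert summary["del17p"] is True

    def test_11q_loss_covering_atm_and_birc3(self, catalog, chrom_lengths):
        segs = [seg("11", 101 * MB, 109 * MB)]
        _, summary = curate_sample(segs, catalog, chrom_lengths)
        assert summary["del11q"] and summary["birc3_del"]

    def test_no_events_all_flags_false(self, catalog, chrom_lengths):
        _, summary = curate_sample([], catalog, chrom_lengths)
        assert not any(
            summary[f]
            for f in ("del17p", "del11q", "del13q_mono", "del13q_biallelic", "tri12", "birc3_del")
        )

    def test_missing_locus_in_catalog_rejected(self):
        cat = RegionCatalog([("13q", "13", 17_900_000, 115_000_000)])
        with pytest.raises(ConfigurationError):
            call_canonical_lesions([], cat)

    def test_biallelic_13q_flag_and_count(self, catalog, chrom_lengths):
        segs = [seg("13", 50_000_000, 50_600_000, SegState.BIALLELIC_LOSS)]
        _, summary = curate_sample(segs, catalog, chrom_lengths)
        assert summary["del13q_biallelic"] and not summary["del13q_mono"]
        assert summary["cna_count"] == 2


class TestDel13qClass:
    def test_small_is_class1(self):
        e = CNAEvent("S1", "13", 50 * MB, int(51.5 * MB), EventKind.LOSS)
        assert classify_del13q_size(e) == "ClassI"

    def test_large_is_class2(self):
        e = CNAEvent("S1", "13", 50 * MB, int(52.5 * MB), EventKind.LOSS)
        assert classify_del13q_size(e) == "ClassII"

    def test_exactly_2mb_is_class1(self):
        e = CNAEvent("S1", "13", 50 * MB, 52 * MB, EventKind.LOSS)
        assert classify_del13q_size(e) == "ClassI"

    def test_non_13q_rejected(self):
        e = CNAEvent("S1", "11", 0, MB, EventKind.LOSS)
        with pytest.raises(ContractViolation):
            classify_del13q_size(e)


# ----------------------------------------------------- FISH concordance

class TestFishConcordance:
    def test_perfect_agreement(self):
        calls = {f"S{i}": True for i in range(10)}
        res = fish_concordance(calls, calls, "del17p")
        assert res.percent_agreement == 100.0

    def test_half_agreement(self):
        gen = {f"S{i}": True for i in range(10)}
        fish = {f"S{i}": i < 5 for i in range(10)}
        assert fish_concordance(gen, fish, "tri12").percent_agreement == 50.0

    def test_missing_samples_excluded_from_denominator(self):
        gen = {f"S{i}": i % 2 == 0 for i in range(12)}
        fish = {f"S{i}": (i % 2 == 0) == (i >= 2) for i in range(10)}
        res = fish_concordance(gen, fish, "del13q")
        assert res.n_compared == 10 and res.n_agree == 8
        assert res.percent_agreement == 80.0

    def test_no_comparable_samples_undefined(self):
        with pytest.raises(UndefinedResultError):
            fish_concordance({"A": True}, {"B": True}, "del11q")


# --------------------------------------------------- pipeline invariants

class TestPipelineInvariants:
    def test_permuting_segments_never_changes_summary(self, catalog, chrom_lengths):
        rng = np.random.default_rng(21)
        for _ in range(20):
            segs = random_segments(rng, int(rng.integers(1, 15)))
            _, base = curate_sample(segs, catalog, chrom_lengths)
            perm = list(segs)
            rng.shuffle(perm)
            _, other = curate_sample(perm, catalog, chrom_lengths)
            assert base == other

    def test_removing_cnloh_never_increases_count(self, catalog, chrom_lengths):
        rng = np.random.default_rng(22)
        segs = random_segments(rng, 10)
        decoys = [seg("7", 10 * MB, 20 * MB, SegState.CN_LOH)]
        _, with_decoy = curate_sample(segs + decoys, catalog, chrom_lengths)
        _, without = curate_sample(segs, catalog, chrom_lengths)
        assert with_decoy["cna_count"] == without["cna_count"]

    def test_adding_isolated_biallelic_in_region_adds_two(self, catalog, chrom_lengths):
        rng = np.random.default_rng(23)
        segs = random_segments(rng, 8, chroms=("1", "9"))
        extra = seg("13", 50_000_000, 50_600_000, SegState.BIALLELIC_LOSS)
        _, base = curate_sample(segs, catalog, chrom_lengths)
        _, more = curate_sample(segs + [extra], catalog, chrom_lengths)
        assert more["cna_count"] == base["cna_count"] + 2
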