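"""Step 1 filters: quality thresholds, mate collapse, site filters, candidates."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panelsnv import (
    ContractViolation,
    FilterConfig,
    GenomicSite,
    call_raw_variants,
    deduplicate_overlapping_mates,
    filter_reads,
    matched_normal_filter,
    position_in_read_filter,
    SiteObservation,
)
from panelsnv.raw_caller import FILTER_NAMES

from conftest import make_read, pileup_row, stack_table, table_from_rows

CFG = FilterConfig()


class TestQualityFilters:
    @pytest.mark.parametrize("baseq,mapq,kept", [
        (29, 60, False),   # base quality just below the cut-off
        (60, 29, False),   # mapping quality just below the cut-off
        (30, 30, True),    # removals are "< 30": exactly 30 passes
        (35, 60, True),
    ])
    def test_phred_30_boundaries(self, site_c_a, baseq, mapq, kept):
        reads = filter_reads([make_read(site_c_a, baseq=baseq, mapq=mapq)], CFG)
        assert (len(reads) == 1) is kept

    def test_empty_input_and_order_preservation(self, site_c_a):
        assert filter_reads([], CFG) == []
        reads = [make_read(site_c_a, baseq=q) for q in (40, 10, 31, 33)]
        assert [r.base_quality for r in filter_reads(reads, CFG)] == [40, 31, 33]


class TestOverlappingMates:
    def test_higher_base_quality_mate_retained(self, site_c_a):
        r1 = make_read(site_c_a, base="A", baseq=35, fragment="F1")
        r2 = make_read(site_c_a, base="A", baseq=32, fragment="F1", strand="-")
        out = deduplicate_overlapping_mates([r1, r2])
        assert out == [r1]

    @pytest.mark.parametrize("b1,b2,expected_alt,expected_total", [
        # equal base quality: forward-strand mate retained; hand-enumerated
        # contribution of each base combination to (alt, total)
        ("C", "C", 0, 1),
        ("C", "A", 0, 1),   # forward mate is ref -> no alt contribution
        ("A", "C", 1, 1),   # forward mate is alt
        ("A", "A", 1, 1),
    ])
    def test_discordant_mates_count_once(self, site_c_a, b1, b2,
                                         expected_alt, expected_total):
        fwd = make_read(site_c_a, base=b1, baseq=33, strand="+", fragment="F1")
        rev = make_read(site_c_a, base=b2, baseq=33, strand="-", fragment="F1")
        out = deduplicate_overlapping_mates([rev, fwd])  # order must not matter
        obs = SiteObservation.from_reads(site_c_a, "s", out)
        assert (obs.alt_count, obs.total_count) == (expected_alt, expected_total)

    def test_no_shared_fragments_is_identity(self, site_c_a):
        reads = [make_read(site_c_a) for _ in range(4)]
        assert deduplicate_overlapping_mates(reads) == reads

    @given(st.lists(st.tuples(st.integers(0, 3), st.integers(20, 45),
                              st.booleans()), max_size=12))
    @settings(max_examples=100, derandomize=True)
    def test_idempotent_and_never_increases_counts(self, spec):
        site = GenomicSite("chr1", 100, "C", "A")
        reads = [
            make_read(site, base="A" if frag % 2 else "C", baseq=q,
                      strand="+" if fwd else "-", fragment=f"F{frag}")
            for frag, q, fwd in spec
        ]
        once = deduplicate_overlapping_mates(reads)
        assert deduplicate_overlapping_mates(once) == once
        assert len(once) == len({r.fragment_id for r in reads})
        n_pairs_collapsed = len(reads) - len(once)
        assert n_pairs_collapsed >= 0


class TestPositionInRead:
    def test_all_forward_alts_at_read_ends_fails(self, site_c_a):
        alts = [make_read(site_c_a, base="A", read_pos=p, read_len=101)
                for p in (2, 3, 101)]
        assert position_in_read_filter(alts, CFG) is False

    def test_either_strand_clause(self, site_c_a):
        # forward has a mid-read alt (fine) but the only reverse alt is
        # end-positioned -> the site still fails
        alts = [
            make_read(site_c_a, base="A", read_pos=2, strand="+"),
            make_read(site_c_a, base="A", read_pos=50, strand="+"),
            make_read(site_c_a, base="A", read_pos=3, strand="-"),
        ]
        assert position_in_read_filter(alts, CFG) is False

    def test_alt_just_outside_window_passes(self, site_c_a):
        alts = [make_read(site_c_a, base="A", read_pos=6, read_len=100)]
        assert position_in_read_filter(alts, CFG) is True
        # position 96 of 100 is the first end-window position on the 3' side
        assert position_in_read_filter(
            [make_read(site_c_a, base="A", read_pos=96, read_len=100)], CFG
        ) is False

    def test_empty_alt_reads_is_a_contract_violation(self):
        with pytest.raises(ContractViolation):
            position_in_read_filter([], CFG)


class TestMatchedNormal:
    @pytest.mark.parametrize("alt,passes", [(0, True), (1, True), (2, False)])
    def test_threshold_at_two_altered_reads(self, site_c_a, alt, passes):
        obs = SiteObservation(site_c_a, "n", [], alt_count=alt, total_count=30)
        assert matched_normal_filter(obs, CFG) is passes


class TestCallRawVariants:
    def test_two_alt_reads_from_one_fragment_never_a_candidate(self, site_c_a):
        rows = [pileup_row(base="C") for _ in range(20)]
        rows += [pileup_row(base="A", strand=s, fragment="PAIR")
                 for s in ("+", "-")]
        tumor = table_from_rows(rows, sample_id="s1")
        normal = stack_table("n1", site_c_a, n_ref=20, n_alt=0)
        assert call_raw_variants(tumor, normal) == []

    def test_low_af_variant_with_clean_normal_is_emitted(self, site_c_a):
        tumor = stack_table("s1", site_c_a, n_ref=89, n_alt=5)
        normal = stack_table("n1", site_c_a, n_ref=60, n_alt=0)
        (cand,) = call_raw_variants(tumor, normal)
        assert cand.site == site_c_a
        assert (cand.tumor.alt_count, cand.tumor.total_count) == (5, 94)
        assert cand.tumor.allelic_fraction == pytest.approx(5 / 94)
        assert cand.normal.alt_count == 0

    def test_all_reference_tumor_yields_no_candidates(self, site_c_a):
        tumor = stack_table("s1", site_c_a, n_ref=30, n_alt=0)
        normal = stack_table("n1", site_c_a, n_ref=30, n_alt=0)
        assert call_raw_variants(tumor, normal) == []

    def test_trace_covers_every_filter_in_order(self, site_c_a):
        tumor = stack_table("s1", site_c_a, n_ref=20, n_alt=4)
        normal = stack_table("n1", site_c_a, n_ref=20, n_alt=0)
        (cand,) = call_raw_variants(tumor, normal)
        assert tuple(name for name, _, _ in cand.filter_trace) == FILTER_NAMES
        assert cand.passed

    def test_emitted_candidates_satisfy_support_invariants(self, site_c_a):
        tumor = stack_table("s1", site_c_a, n_ref=50, n_alt=3)
        normal = stack_table("n1", site_c_a, n_ref=50, n_alt=1)
        (cand,) = call_raw_variants(tumor, normal)
        alt_frags = {r.fragment_id for r in cand.tumor.reads
                     if r.base == site_c_a.alt}
        assert cand.tumor.alt_count >= 2
        assert len(alt_frags) >= 2
        assert cand.normal.alt_count <= CFG.max_normal_alt

    def test_counts_match_brute_force_recount(self, site_c_a):
        # mixed-quality, mixed-fragment stack; oracle recount by hand rules
        rows = [
            pileup_row(base="A", baseq=35, fragment="f1"),
            pileup_row(base="A", baseq=29, fragment="f2"),   # fails baseq
            pileup_row(base="A", baseq=40, mapq=20, fragment="f3"),  # fails mapq
            pileup_row(base="A", baseq=35, fragment="f4", strand="+"),
            pileup_row(base="A", baseq=31, fragment="f4", strand="-"),  # mate
            pileup_row(base="C", baseq=35, fragment="f5"),
            pileup_row(base="C", baseq=35, fragment="f6"),
        ]
        tumor = table_from_rows(rows, sample_id="s1")
        normal = stack_table("n1", site_c_a, n_ref=30, n_alt=0)
        (cand,) = call_raw_variants(tumor, normal)
        # surviving: f1(A), f4 collapsed to one A, f5(C), f6(C)
        assert (cand.tumor.alt_count, cand.tumor.total_count) == (2, 4)
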