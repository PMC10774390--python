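"""Repeat-counting correctness: orientation, error-tolerant windowing,
the on-target filter, SNP genotyping, and the brute-force oracle."""

import edlib
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from c9quant import synthetic
from c9quant._util import revcomp
from c9quant.config import LocusConfig
from c9quant.repeatcall import (
    CcsRead,
    call_read,
    call_reads,
    classify_on_target,
    count_repeats,
    genotype_snps,
    orient_read,
)


@pytest.fixture(scope="module")
def locus():
    left, right = synthetic.make_reference_flanks(flank_len=60)
    return LocusConfig(left_flank=left, right_flank=right)


def _template(locus, k):
    return locus.left_flank + "GGGGCC" * k + locus.right_flank


class TestOrientation:
    def test_plus_read_unchanged(self, locus):
        t = _template(locus, 3)
        seq, strand = orient_read(CcsRead("r", t, 5), locus)
        assert (seq, strand) == (t, "+")

    def test_minus_read_flipped_back(self, locus):
        t = _template(locus, 3)
        seq, strand = orient_read(CcsRead("r", revcomp(t), 5), locus)
        assert (seq, strand) == (t, "-")

    def test_anchorless_read_flagged(self, locus):
        seq, strand = orient_read(CcsRead("r", "ATATATATAT" * 10, 5), locus)
        assert strand is None
        call = call_read(CcsRead("r", "ATATATATAT" * 10, 5), locus)
        assert not call.on_target and not call.anchor5_found


class TestCountRepeats:
    @pytest.mark.parametrize("k", [0, 1, 2, 10, 145, 200, 1400, 1491])
    def test_noiseless_exact_count(self, locus, k):
        r, e, t = count_repeats(_template(locus, k), locus)
        assert (r, e, t) == (k, 0, 6 * k)

    def test_single_substitution_window_still_counted(self, locus):
        # GGAGCC is edit distance 1 from the unit
        seq = locus.left_flank + "GGGGCC" + "GGAGCC" + "GGGGCC" + locus.right_flank
        r, e, t = count_repeats(seq, locus)
        assert r == 3
        assert e == 0

    def test_two_error_window_classified_error(self, locus):
        # middle unit carries two substitutions: excluded from the count,
        # recorded as one error window, tract continues past it
        seq = locus.left_flank + "GGGGCC" + "GTATCC" + "GGGGCC" * 3 + locus.right_flank
        r, e, t = count_repeats(seq, locus)
        assert r == 4
        assert e == 1
        assert t == 30

    def test_single_indel_preserves_frame(self, locus):
        # one deletion inside a unit: window matches at distance 1 with a
        # 5-nt advance, downstream units stay in frame
        seq = locus.left_flank + "GGGGC" + "GGGGCC" * 9 + locus.right_flank
        r, e, t = count_repeats(seq, locus)
        assert r == 10

    def test_empty_post_anchor_sequence(self, locus):
        r, e, t = count_repeats(locus.left_flank, locus)
        assert (r, e, t) == (0, 0, 0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(k=st.integers(min_value=0, max_value=60))
    def test_strand_invariance(self, locus, k):
        """A read and its reverse complement yield identical counts."""
        t = _template(locus, k)
        fwd = count_repeats(*orient_read(CcsRead("f", t, 5), locus)[:1], locus)
        rev = count_repeats(
            orient_read(CcsRead("r", revcomp(t), 5), locus)[0], locus
        )
        assert fwd == rev

    @pytest.mark.parametrize("k", [0, 1, 5, 17, 33, 60])
    def test_brute_force_oracle_equivalence(self, locus, k):
        """The window scanner agrees with exhaustive alignment of the
        tract against (unit)^j for all j, on clean templates and on
        templates where every third unit carries one substitution (one
        error per window is within the unit-match tolerance)."""
        def oracle(segment):
            best = min(
                range(0, 70),
                key=lambda j: (
                    edlib.align(segment, "GGGGCC" * j, task="distance")["editDistance"],
                    j,
                ),
            )
            return best

        clean = _template(locus, k)
        seg = clean[len(locus.left_flank) : len(clean) - len(locus.right_flank)]
        assert count_repeats(clean, locus)[0] == oracle(seg) == k

        units = ["GGGGCC"] * k
        for i in range(0, k, 3):
            units[i] = "GGGTCC"
        noisy_seg = "".join(units)
        noisy = locus.left_flank + noisy_seg + locus.right_flank
        assert count_repeats(noisy, locus)[0] == oracle(noisy_seg) == k

    def test_error_rate_monotonicity(self, locus):
        """Raising the substitution rate never increases the fraction of
        reads whose count equals truth (fixed seeds, regression grid)."""
        truth = 20
        t = _template(locus, truth)
        accs = []
        for sub in (0.0, 0.01, 0.03, 0.06):
            reads = synthetic.simulate_ccs_reads(
                t,
                synthetic.ReadSimParams(
                    n_reads=80, sub_rate=sub, ins_rate=0, del_rate=0, seed=123
                ),
            )
            calls = call_reads(reads, locus)
            accs.append(sum(c.repeat_count == truth for c in calls) / len(calls))
        assert accs[0] == 1.0
        assert all(b <= a for a, b in zip(accs, accs[1:]))


class TestOnTargetFilter:
    def test_two_passes_rejected(self, locus):
        assert not classify_on_target(True, True, 2, locus)

    def test_three_passes_boundary_accepted(self, locus):
        assert classify_on_target(True, True, 3, locus)

    def test_missing_anchor_rejected_at_high_passes(self, locus):
        assert not classify_on_target(True, False, 5, locus)

    def test_min_passes_configurable(self, locus):
        strict = locus.model_copy(update={"min_passes": 4})
        assert not classify_on_target(True, True, 3, strict)


@pytest.fixture(scope="module")
def snp_locus():
    return synthetic.make_locus(flank_len=200, snp_position=100)


class TestGenotyping:
    def test_ref_and_alt_called_on_noiseless_reads(self, snp_locus):
        snp = snp_locus.snps[0]
        ref_t = snp_locus.left_flank + "GGGGCC" * 4 + snp_locus.right_flank
        alt_t = (
            snp_locus.left_flank[:100]
            + snp.alt_base
            + snp_locus.left_flank[101:]
            + "GGGGCC" * 4
            + snp_locus.right_flank
        )
        assert genotype_snps(ref_t, snp_locus)[snp.snp_id] == snp.ref_base
        assert genotype_snps(alt_t, snp_locus)[snp.snp_id] == snp.alt_base

    def test_excised_snp_region_missing(self, snp_locus):
        snp = snp_locus.snps[0]
        # remove the 40 nt around the SNP: neither probe aligns cleanly
        t = snp_locus.left_flank + "GGGGCC" * 4 + snp_locus.right_flank
        cut = t[:80] + t[120:]
        assert genotype_snps(cut, snp_locus)[snp.snp_id] is None

    def test_majority_genotype_correct_at_one_percent_error(self, snp_locus):
        snp = snp_locus.snps[0]
        t = snp_locus.left_flank + "GGGGCC" * 4 + snp_locus.right_flank
        reads = synthetic.simulate_ccs_reads(
            t, synthetic.ReadSimParams(n_reads=100, seed=5)
        )
        calls = call_reads(reads, snp_locus)
        bases = [
            c.snp_genotype[snp.snp_id]
            for c in calls
            if c.snp_genotype[snp.snp_id] is not None
        ]
        assert bases.count(snp.ref_base) > 0.9 * len(bases)


class TestBatchDriver:
    def test_empty_list(self, locus):
        assert call_reads([], locus) == []

    def test_off_target_flagged_not_dropped(self, locus):
        reads = [
            CcsRead("on", _template(locus, 4), 5),
            CcsRead("off", "ATATAT" * 30, 5),
            CcsRead("lowpass", _template(locus, 4), 2),
        ]
        calls = call_reads(reads, locus)
        assert [c.read_id for c in calls] == ["on", "off", "lowpass"]
        assert [c.on_target for c in calls] == [True, False, False]

    def test_deterministic_call_table(self, locus):
        t = _template(locus, 6)
        reads = synthetic.simulate_ccs_reads(
            t, synthetic.ReadSimParams(n_reads=50, seed=8)
        )
        a = call_reads(reads, locus)
        b = call_reads(reads, locus)
        assert [(c.read_id, c.repeat_count, c.on_target) for c in a] == [
            (c.read_id, c.repeat_count, c.on_target) for c in b
        ]
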