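"""Edit-outcome measurement and clonality classification against the
generating simulation specs."""

import pytest

from c9quant import synthetic
from c9quant.edits import (
    EXCISION,
    INTACT,
    RETAINED,
    EditOutcome,
    ReadEdit,
    analyze_clone,
    classify_clonality,
    group_outcomes,
    measure_excision,
)
from c9quant.synthetic import EditSimSpec, OutcomeSpec, ReadSimParams


def _outcome(allele, kind, length, fraction):
    return EditOutcome(
        allele_label=allele,
        kind=kind,
        excision_length_nt=length,
        read_count=int(round(fraction * 1000)),
        fraction=fraction,
    )


class TestMeasureExcision:
    def test_unedited_read_intact(self, wt_fixture):
        t = wt_fixture.templates["allele1"]
        exc, kind, _ = measure_excision(t, t, wt_fixture.locus)
        assert (exc, kind) == (0, INTACT)

    def test_noiseless_48nt_excision_exact(self, hom_fixture):
        base = hom_fixture.templates["mutant"]
        edited = synthetic.apply_excision(base, hom_fixture.locus, 48)
        exc, kind, _ = measure_excision(edited, base, hom_fixture.locus)
        assert (exc, kind) == (48, EXCISION)

    def test_retained_expansion_sized_by_repeat_count(self, het_fixture):
        base = het_fixture.templates["mutant"]
        exc, kind, reps = measure_excision(base, base, het_fixture.locus)
        assert kind == RETAINED
        assert reps == 1491

    def test_unalignable_flanks_rejected(self, wt_fixture):
        with pytest.raises(ValueError, match="unalignable"):
            measure_excision("ATAT" * 300, wt_fixture.templates["allele1"],
                             wt_fixture.locus)


class TestGroupOutcomes:
    def test_identical_reads_single_outcome(self):
        meas = [ReadEdit(f"r{i}", "WT", EXCISION, 20) for i in range(50)]
        (o,) = group_outcomes(meas)
        assert (o.excision_length_nt, o.fraction) == (20, 1.0)

    def test_one_nt_apart_kept_distinct_with_zero_tolerance(self):
        meas = [ReadEdit(f"a{i}", "WT", EXCISION, 30) for i in range(50)] + [
            ReadEdit(f"b{i}", "WT", EXCISION, 31) for i in range(40)
        ]
        outcomes = group_outcomes(meas, collapse_tolerance=0)
        assert sorted(o.excision_length_nt for o in outcomes) == [30, 31]

    def test_collapse_tolerance_merges_when_requested(self):
        meas = [ReadEdit(f"a{i}", "WT", EXCISION, 30) for i in range(50)] + [
            ReadEdit(f"b{i}", "WT", EXCISION, 31) for i in range(40)
        ]
        (o,) = group_outcomes(meas, collapse_tolerance=1)
        assert o.read_count == 90

    def test_satellite_lengths_absorbed_into_peak(self):
        """Sparse +-1 nt neighbours (indel-noise scatter) fold into the
        dominant length; the reported length is the true one."""
        meas = (
            [ReadEdit(f"a{i}", "WT", EXCISION, 27) for i in range(80)]
            + [ReadEdit(f"b{i}", "WT", EXCISION, 26) for i in range(12)]
            + [ReadEdit(f"c{i}", "WT", EXCISION, 28) for i in range(10)]
        )
        (o,) = group_outcomes(meas)
        assert o.excision_length_nt == 27
        assert o.read_count == 102

    def test_fractions_sum_to_one(self):
        meas = (
            [ReadEdit(f"a{i}", "WT", EXCISION, 27) for i in range(52)]
            + [ReadEdit(f"b{i}", "mutant", EXCISION, 17) for i in range(32)]
            + [ReadEdit(f"c{i}", "mutant", RETAINED, 0, 1400) for i in range(16)]
        )
        outcomes = group_outcomes(meas)
        assert sum(o.fraction for o in outcomes) == pytest.approx(1.0)


class TestClassifyClonality:
    def test_heterozygous_excision_with_retained_expansion(self):
        outcomes = [
            _outcome("WT", EXCISION, 20, 0.5),
            _outcome("mutant", RETAINED, 0, 0.5),
        ]
        rep = classify_clonality(outcomes)
        assert rep.classification == "heterozygous_excision"

    def test_homozygous_excision(self):
        outcomes = [
            _outcome("mutant", EXCISION, 48, 0.5),
            _outcome("WT", EXCISION, 32, 0.5),
        ]
        assert classify_clonality(outcomes).classification == "homozygous_excision"

    def test_unedited_clone(self):
        outcomes = [
            _outcome("WT", INTACT, 0, 0.5),
            _outcome("mutant", RETAINED, 0, 0.5),
        ]
        assert classify_clonality(outcomes).classification == "unedited"

    def test_impure_clone_and_dominants(self):
        outcomes = [
            _outcome("WT", EXCISION, 27, 0.52),
            _outcome("mutant", EXCISION, 17, 0.32),
            _outcome("mutant", EXCISION, 19, 0.16),
        ]
        rep = classify_clonality(outcomes)
        assert rep.classification == "impure"
        assert rep.dominant.excision_length_nt == 27
        assert rep.per_allele_dominant["mutant"].excision_length_nt == 17

    def test_minor_outcome_below_threshold_discarded(self):
        outcomes = [
            _outcome("WT", EXCISION, 20, 0.97),
            _outcome("WT", EXCISION, 35, 0.03),
        ]
        rep = classify_clonality(outcomes, min_outcome_fraction=0.05)
        assert rep.classification == "heterozygous_excision"
        assert rep.discarded_fraction == pytest.approx(0.03)

    def test_threshold_monotonicity(self):
        """Raising the minimum outcome fraction never converts a
        non-impure call into impure."""
        outcomes = [
            _outcome("WT", EXCISION, 27, 0.60),
            _outcome("mutant", EXCISION, 17, 0.30),
            _outcome("mutant", EXCISION, 19, 0.10),
        ]
        classes = [
            classify_clonality(outcomes, min_outcome_fraction=f).classification
            for f in (0.01, 0.05, 0.15, 0.35)
        ]
        seen_pure = False
        for c in classes:
            if c != "impure":
                seen_pure = True
            assert not (seen_pure and c == "impure")

    def test_empty_outcomes_rejected(self):
        with pytest.raises(ValueError):
            classify_clonality([])


class TestEndToEndRecovery:
    def test_noiseless_recovery_exact(self, hom_fixture, noiseless_params):
        reads = synthetic.simulate_edited_pool(
            list(hom_fixture.base_specs.values()),
            hom_fixture.edit,
            noiseless_params(200, seed=13),
            hom_fixture.locus,
        )
        rep = analyze_clone(reads, hom_fixture.templates, hom_fixture.locus)
        assert rep.classification == "homozygous_excision"
        lengths = {
            o.allele_label: o.excision_length_nt
            for o in rep.outcomes
            if o.fraction >= 0.05
        }
        assert lengths == {"mutant": 48, "WT": 32}

    def test_heterozygous_retained_recovery_at_one_percent_error(self, het_fixture):
        reads = synthetic.simulate_edited_pool(
            list(het_fixture.base_specs.values()),
            het_fixture.edit,
            ReadSimParams(n_reads=200, seed=17),
            het_fixture.locus,
        )
        rep = analyze_clone(reads, het_fixture.templates, het_fixture.locus)
        assert rep.classification == "heterozygous_excision"
        wt = rep.per_allele_dominant["WT"]
        assert abs(wt.excision_length_nt - 20) <= 1
        mut = rep.per_allele_dominant["mutant"]
        assert mut.kind == RETAINED
        assert mut.repeat_count_if_retained >= 1480

    def test_impure_fractions_within_three_se(self, impure_fixture):
        n = 1000
        reads = synthetic.simulate_edited_pool(
            list(impure_fixture.base_specs.values()),
            impure_fixture.edit,
            ReadSimParams(n_reads=n, seed=19),
            impure_fixture.locus,
        )
        rep = analyze_clone(reads, impure_fixture.templates, impure_fixture.locus)
        assert rep.classification == "impure"
        got = {
            (o.allele_label, o.excision_length_nt): o.fraction
            for o in rep.outcomes
            if o.fraction >= 0.05
        }
        for key, truth in impure_fixture.truth["fractions"].items():
            se = (truth * (1 - truth) / n) ** 0.5
            assert got[key] == pytest.approx(truth, abs=3 * se)

    def test_fraction_conservation_with_qc(self, impure_fixture):
        reads = synthetic.simulate_edited_pool(
            list(impure_fixture.base_specs.values()),
            impure_fixture.edit,
            ReadSimParams(n_reads=400, seed=23),
            impure_fixture.locus,
        )
        rep = analyze_clone(reads, impure_fixture.templates, impure_fixture.locus)
        surviving = sum(
            o.fraction for o in rep.outcomes if o.fraction >= rep.min_outcome_fraction
        )
        assert surviving + rep.discarded_fraction == pytest.approx(1.0)
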