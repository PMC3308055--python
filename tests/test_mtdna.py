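"""qPCR copy-number arithmetic: 2^dCt identities, replicate aggregation,
control normalization."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rohmap import (
    CtMeasurement,
    aggregate_sample,
    normalize_to_controls,
    relative_copy_number,
)

ct = st.floats(min_value=5.0, max_value=40.0, allow_nan=False)


class TestRelativeCopyNumber:
    @pytest.mark.parametrize(
        "ct_target, ct_ref, expected", [(30, 30, 1.0), (29, 30, 2.0), (32, 30, 0.25)]
    )
    def test_closed_form(self, ct_target, ct_ref, expected):
        assert relative_copy_number(ct_target, ct_ref) == expected

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(a=ct, b=ct, c=ct)
    def test_chain_rule(self, a, b, c):
        lhs = relative_copy_number(a, b) * relative_copy_number(b, c)
        assert lhs == pytest.approx(relative_copy_number(a, c), rel=1e-12)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(a=ct, b=ct)
    def test_log2_linearity(self, a, b):
        assert math.log2(relative_copy_number(a, b)) == pytest.approx(b - a, abs=1e-9)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            relative_copy_number(float("nan"), 30.0)


def meas(sample="P", target="ND1", reaction="r1", cts=(30.0,)):
    return CtMeasurement(sample, target, reaction, tuple(cts))


class TestAggregation:
    def test_identical_replicates_equal_single_measurement(self):
        single = aggregate_sample(
            [meas(target="RNaseP", cts=(28.0,)), meas(cts=(25.0,)), meas(target="ND4", cts=(26.0,))]
        )
        triple = aggregate_sample(
            [
                meas(target="RNaseP", cts=(28.0, 28.0, 28.0)),
                meas(cts=(25.0, 25.0, 25.0)),
                meas(target="ND4", cts=(26.0, 26.0, 26.0)),
            ]
        )
        assert (single.nd1_ratio, single.nd4_ratio) == (triple.nd1_ratio, triple.nd4_ratio)
        assert single.nd1_ratio == 8.0 and single.nd4_ratio == 4.0
        assert single.deletion_index == 0.5

    def test_mean_ct_aggregation_hand_computation(self):
        # triplicates {29,30,31} against reference {30,30,30}: ratio 2^(30-30) = 1
        report = aggregate_sample(
            [meas(target="RNaseP", cts=(30.0, 30.0, 30.0)), meas(cts=(29.0, 30.0, 31.0))]
        )
        assert report.nd1_ratio == pytest.approx(1.0)

    def test_deletion_index_below_one_when_nd4_cts_higher(self):
        report = aggregate_sample(
            [
                meas(target="RNaseP", cts=(30.0,)),
                meas(target="ND1", cts=(25.0,)),
                meas(target="ND4", cts=(26.5,)),
            ]
        )
        assert report.deletion_index < 1

    def test_two_reactions_average_ratios(self):
        report = aggregate_sample(
            [
                meas(target="RNaseP", reaction="r1", cts=(30.0,)),
                meas(target="ND1", reaction="r1", cts=(29.0,)),  # ratio 2
                meas(target="RNaseP", reaction="r2", cts=(30.0,)),
                meas(target="ND1", reaction="r2", cts=(28.0,)),  # ratio 4
            ]
        )
        assert report.nd1_ratio == pytest.approx(3.0)

    def test_permutation_invariance(self):
        ms = [
            meas(target="RNaseP", reaction="r1", cts=(30.0, 30.5, 29.5)),
            meas(target="ND1", reaction="r1", cts=(28.0, 28.2, 27.8)),
            meas(target="ND4", reaction="r1", cts=(29.0, 29.1, 28.9)),
            meas(target="RNaseP", reaction="r2", cts=(31.0,)),
            meas(target="ND1", reaction="r2", cts=(29.0,)),
        ]
        fwd = aggregate_sample(ms)
        rev = aggregate_sample(ms[::-1])
        assert (fwd.nd1_ratio, fwd.nd4_ratio) == (rev.nd1_ratio, rev.nd4_ratio)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(offset=st.floats(min_value=-3, max_value=3, allow_nan=False))
    def test_ct_offset_invariance(self, offset):
        base = [
            meas(target="RNaseP", cts=(30.0, 30.4)),
            meas(target="ND1", cts=(27.0, 27.2)),
            meas(target="ND4", cts=(28.0, 27.9)),
        ]
        shifted = [
            CtMeasurement(m.sample, m.target, m.reaction, tuple(c + offset for c in m.cts))
            for m in base
        ]
        a, b = aggregate_sample(base), aggregate_sample(shifted)
        assert a.nd1_ratio == pytest.approx(b.nd1_ratio, rel=1e-9)
        assert a.nd4_ratio == pytest.approx(b.nd4_ratio, rel=1e-9)

    def test_missing_target_reported_absent(self):
        report = aggregate_sample([meas(target="RNaseP"), meas(target="ND1", cts=(29.0,))])
        assert report.nd4_ratio is None
        assert report.deletion_index is None

    def test_reaction_without_reference_rejected(self):
        with pytest.raises(ValueError, match="RNaseP"):
            aggregate_sample([meas(target="ND1")])

    def test_invalid_ct_rejected(self):
        with pytest.raises(ValueError):
            meas(cts=(0.0,))
        with pytest.raises(ValueError):
            meas(cts=())


class TestNormalization:
    def make_reports(self, patient=1.5, controls=(1.0, 1.0, 1.0, 1.0)):
        reports = []
        for i, r in enumerate(controls):
            reports.append(
                aggregate_sample(
                    [
                        meas(sample=f"C{i}", target="RNaseP", cts=(30.0,)),
                        meas(sample=f"C{i}", target="ND1", cts=(30.0 - math.log2(r),)),
                        meas(sample=f"C{i}", target="ND4", cts=(30.0 - math.log2(r),)),
                    ]
                )
            )
        reports.append(
            aggregate_sample(
                [
                    meas(sample="P", target="RNaseP", cts=(30.0,)),
                    meas(sample="P", target="ND1", cts=(30.0 - math.log2(patient),)),
                    meas(sample="P", target="ND4", cts=(30.0 - math.log2(patient),)),
                ]
            )
        )
        return reports

    def test_unit_controls_leave_patient_ratio(self):
        reports = normalize_to_controls(self.make_reports(), [f"C{i}" for i in range(4)])
        patient = next(r for r in reports if r.sample == "P")
        assert patient.nd1_normalized == pytest.approx(1.5)

    def test_single_control_normalizes_to_one(self):
        reports = normalize_to_controls(self.make_reports(controls=(2.0,)), ["C0"])
        ctrl = next(r for r in reports if r.sample == "C0")
        assert ctrl.nd1_normalized == pytest.approx(1.0)

    def test_control_mean_is_one_for_any_control_set(self):
        controls = (0.7, 1.1, 1.9, 0.4)
        reports = normalize_to_controls(
            self.make_reports(controls=controls), [f"C{i}" for i in range(4)]
        )
        norm = [r.nd1_normalized for r in reports if r.sample.startswith("C")]
        assert sum(norm) / len(norm) == pytest.approx(1.0, rel=1e-12)

    def test_zero_controls_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_controls(self.make_reports(), [])
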