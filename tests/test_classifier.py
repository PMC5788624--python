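"""Two-step subtype classifier: 3-point calls, both steps, threshold derivation."""

import itertools
import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from renalmir import panel
from renalmir.classifier import (
    CATEGORY_ABOVE,
    CATEGORY_BELOW,
    CATEGORY_GREY,
    ClassifierThresholds,
    ThreePointZone,
    classify,
    classify_table,
    derive_grey_zone,
    derive_thresholds,
    fill_unset_cutoffs,
    step1_classify,
    step2a_classify,
    step2b_classify,
    three_point_call,
)
from renalmir.errors import (
    ConfigurationError,
    DegenerateDataError,
    MarkerMissingError,
    ThresholdDerivationError,
    UsageError,
)

DEFAULTS = ClassifierThresholds()


class TestThreePointCall:
    @pytest.mark.parametrize(
        "value, expected_label, expected_cat",
        [
            (1500.0, panel.DISTAL, CATEGORY_ABOVE),   # clearly chRCC/oncocytoma
            (400.0, panel.PROXIMAL, CATEGORY_BELOW),  # clearly ccRCC/pRCC
            (1205.0, panel.GREY, CATEGORY_GREY),      # boundary: strict comparisons
            (589.0, panel.GREY, CATEGORY_GREY),
            (800.0, panel.GREY, CATEGORY_GREY),
        ],
    )
    def test_step1_semantics_at_published_bounds(self, value, expected_label, expected_cat):
        label, cat = three_point_call(value, 1205.0, 589.0, panel.DISTAL, panel.PROXIMAL)
        assert label == expected_label
        assert cat == expected_cat

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            three_point_call(100.0, 10.0, 20.0, "a", "b")

    def test_zero_width_zone_catches_only_the_boundary(self):
        assert three_point_call(7.0, 7.0, 7.0, "hi", "lo")[0] == panel.GREY
        assert three_point_call(7.1, 7.0, 7.0, "hi", "lo")[0] == "hi"
        assert three_point_call(6.9, 7.0, 7.0, "hi", "lo")[0] == "lo"


class TestStep1:
    def test_high_mir222_calls_distal(self):
        group, cat, _ = step1_classify({panel.MIR_222: 2000.0}, DEFAULTS)
        assert group == panel.DISTAL and cat == CATEGORY_ABOVE

    def test_grey_without_fallback_stays_grey(self):
        group, cat, _ = step1_classify({panel.MIR_222: 800.0}, DEFAULTS)
        assert group == panel.GREY and cat == CATEGORY_GREY

    def test_grey_resolved_by_mir221_fallback(self):
        t = ClassifierThresholds(step1_mir221_cutoff=150.0)
        group, _, votes = step1_classify({panel.MIR_222: 800.0, panel.MIR_221: 300.0}, t)
        assert group == panel.DISTAL
        assert votes[-1].marker == panel.MIR_221
        group, _, _ = step1_classify({panel.MIR_222: 800.0, panel.MIR_221: 50.0}, t)
        assert group == panel.PROXIMAL

    def test_missing_mir222_raises_named_error(self):
        with pytest.raises(MarkerMissingError, match="miR-222"):
            step1_classify({panel.MIR_221: 100.0}, DEFAULTS)


class TestStep2a:
    T = ClassifierThresholds(step2a_mir126_cutoff=600.0)

    def test_mir126_above_cutoff_calls_ccrcc(self):
        final, _ = step2a_classify({panel.MIR_126: 3000.0, panel.MIR_222: 100.0}, self.T)
        assert final == panel.CCRCC

    def test_mir222_fallback_when_mir126_absent(self):
        final, _ = step2a_classify({panel.MIR_222: 700.0}, self.T)
        assert final == panel.CCRCC  # > 682
        final, _ = step2a_classify({panel.MIR_222: 300.0}, self.T)
        assert final == panel.PRCC  # < 358
        final, _ = step2a_classify({panel.MIR_222: 500.0}, self.T)
        assert final == panel.INDETERMINATE  # grey 358-682

    def test_unconfigured_mir126_cutoff_falls_back_to_mir222(self):
        final, _ = step2a_classify({panel.MIR_126: 3000.0, panel.MIR_222: 700.0}, DEFAULTS)
        assert final == panel.CCRCC

    def test_usage_error_on_distal_group(self):
        with pytest.raises(UsageError):
            step2a_classify({panel.MIR_126: 100.0}, self.T, step1_group=panel.DISTAL)


class TestStep2b:
    def test_single_available_marker_decides(self):
        final, _ = step2b_classify({panel.MIR_200B: 250.0}, DEFAULTS)
        assert final == panel.CHRCC

    def test_unanimous_low_calls_oncocytoma(self):
        sample = {panel.MIR_200B: 100.0, panel.MIR_200C: 100.0, panel.MIR_222: 100.0}
        final, votes = step2b_classify(sample, DEFAULTS)
        assert final == panel.ONCOCYTOMA
        assert len(votes) == 3

    def test_tie_is_indeterminate(self):
        final, _ = step2b_classify({panel.MIR_200B: 250.0, panel.MIR_200C: 100.0}, DEFAULTS)
        assert final == panel.INDETERMINATE

    def test_majority_vote_matches_enumeration_of_all_patterns(self):
        # brute-force all present/absent x above/below combinations of the
        # three markers against an independent statement of the vote rule
        cutoffs = {panel.MIR_200B: 197.0, panel.MIR_200C: 180.0, panel.MIR_222: 1399.0}
        for pattern in itertools.product([None, "above", "below"], repeat=3):
            sample = {}
            expected_ch = expected_onco = 0
            for (marker, cut), state in zip(cutoffs.items(), pattern):
                if state is None:
                    continue
                sample[marker] = cut * (2.0 if state == "above" else 0.5)
                expected_ch += state == "above"
                expected_onco += state == "below"
            if expected_ch > expected_onco:
                expected = panel.CHRCC
            elif expected_onco > expected_ch:
                expected = panel.ONCOCYTOMA
            else:
                expected = panel.INDETERMINATE
            final, _ = step2b_classify(sample, DEFAULTS)
            assert final == expected, (pattern, final)

    def test_usage_error_on_proximal_group(self):
        with pytest.raises(UsageError):
            step2b_classify({panel.MIR_200B: 100.0}, DEFAULTS, step1_group=panel.PROXIMAL)


class TestClassify:
    def test_distal_composition(self):
        call = classify({panel.MIR_222: 1500.0, panel.MIR_200B: 250.0}, DEFAULTS, "s1")
        assert call.step1_group == panel.DISTAL
        assert call.final == panel.CHRCC
        assert call.category == CATEGORY_ABOVE

    def test_proximal_composition_via_mir126(self):
        t = ClassifierThresholds(step2a_mir126_cutoff=600.0)
        call = classify({panel.MIR_222: 400.0, panel.MIR_126: 3000.0}, t)
        assert call.step1_group == panel.PROXIMAL
        assert call.final == panel.CCRCC

    def test_grey_step1_is_indeterminate(self):
        call = classify({panel.MIR_222: 800.0}, DEFAULTS)
        assert call.step1_group == panel.GREY
        assert call.final == panel.INDETERMINATE

    def test_every_leaf_reachable(self):
        t = ClassifierThresholds(step1_mir221_cutoff=150.0, step2a_mir126_cutoff=600.0)
        leaves = {
            panel.CCRCC: {panel.MIR_222: 400.0, panel.MIR_126: 3000.0},
            panel.PRCC: {panel.MIR_222: 400.0, panel.MIR_126: 100.0},
            panel.CHRCC: {panel.MIR_222: 2000.0, panel.MIR_200B: 300.0},
            panel.ONCOCYTOMA: {panel.MIR_222: 1300.0, panel.MIR_200B: 100.0, panel.MIR_200C: 50.0},
        }
        for expected, sample in leaves.items():
            assert classify(sample, t).final == expected

    def test_provenance_records_every_comparison(self):
        call = classify({panel.MIR_222: 1500.0, panel.MIR_200B: 250.0, panel.MIR_200C: 90.0}, DEFAULTS)
        markers = [v.marker for v in call.votes]
        assert markers == [panel.MIR_222, panel.MIR_200B, panel.MIR_200C, panel.MIR_222]

    def test_deterministic(self):
        sample = {panel.MIR_222: 1500.0, panel.MIR_200B: 250.0}
        a = classify(sample, DEFAULTS, "x")
        b = classify(sample, DEFAULTS, "x")
        assert a == b

    @given(st.floats(min_value=1.0, max_value=5000.0), st.floats(min_value=1.0, max_value=3000.0))
    def test_increasing_mir222_never_moves_distal_to_proximal(self, v222, delta):
        order = {panel.PROXIMAL: 0, panel.GREY: 1, panel.DISTAL: 2}
        g1, _, _ = step1_classify({panel.MIR_222: v222}, DEFAULTS)
        g2, _, _ = step1_classify({panel.MIR_222: v222 + delta}, DEFAULTS)
        assert order[g2] >= order[g1]


class TestThresholdsConfig:
    def test_json_round_trip(self, tmp_path):
        t = ClassifierThresholds(step1_mir221_cutoff=123.4, step2a_mir126_cutoff=567.8)
        path = tmp_path / "thresholds.json"
        t.to_json(path)
        assert ClassifierThresholds.from_json(path) == t

    def test_published_defaults(self):
        d = DEFAULTS.to_dict()
        assert d["step1"]["mir222_upper"] == 1205.0
        assert d["step1"]["mir222_lower"] == 589.0
        assert d["step1"]["mir221_cutoff"] is None
        assert d["step2a"]["mir222_upper"] == 682.0
        assert d["step2a"]["mir222_lower"] == 358.0
        assert d["step2b"] == {"mir200b_cutoff": 197.0, "mir200c_cutoff": 180.0, "mir222_cutoff": 1399.0}

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            ThreePointZone(upper=100.0, lower=200.0)
        with pytest.raises(ConfigurationError):
            ClassifierThresholds(step2b_mir200b_cutoff=-5.0)
        with pytest.raises(ConfigurationError):
            ClassifierThresholds.from_dict({"step1": {}, "step2a": {}, "step2b": {}})


def grey_zone_by_brute_force(values, is_above, target):
    """Independent scan over all candidate bound pairs for the tightest zone."""
    v = np.asarray(values, float)
    lab = np.asarray(is_above, bool)
    uniq = np.unique(v)
    cands = (uniq[:-1] + uniq[1:]) / 2
    uppers = [
        c for c in cands if (v > c).any() and lab[v > c].mean() >= target
    ]
    lowers = [
        c for c in cands if (v < c).any() and (~lab[v < c]).mean() >= target
    ]
    if not uppers or not lowers:
        return None
    return min(uppers), max(lowers)


class TestGreyZoneDerivation:
    def test_fully_separated_data_gives_empty_zone(self):
        zone = derive_grey_zone([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1], 0.97)
        assert zone.lower == zone.upper
        assert 3 < zone.lower < 10

    def test_single_overlapping_point_spanned_at_full_purity(self):
        # below-class 1..4, above-class 3.5, 5, 6: only 3.5 overlaps
        values = [1.0, 2.0, 3.0, 4.0, 3.5, 5.0, 6.0]
        labels = [False, False, False, False, True, True, True]
        zone = derive_grey_zone(values, labels, purity_target=1.0)
        assert zone.lower < 3.5 < zone.upper
        assert zone.lower == pytest.approx(3.25)  # midpoint below the overlap
        assert zone.upper == pytest.approx(4.5)   # first bound clearing the stray 4.0
        # outside the zone both sides are pure
        v, lab = np.array(values), np.array(labels)
        assert lab[v > zone.upper].all()
        assert (~lab[v < zone.lower]).all()

    @given(st.data())
    def test_matches_brute_force_scan(self, data):
        n = data.draw(st.integers(6, 16))
        values = data.draw(
            st.lists(st.integers(0, 30), min_size=n, max_size=n)
        )
        labels = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
        if all(labels) or not any(labels) or len(set(values)) < 2:
            return
        expected = grey_zone_by_brute_force(values, labels, 0.9)
        if expected is None:
            with pytest.raises(ThresholdDerivationError):
                derive_grey_zone(values, labels, 0.9)
            return
        upper, lower = expected
        zone = derive_grey_zone(values, labels, 0.9)
        if lower > upper:
            assert zone.lower == zone.upper == pytest.approx((lower + upper) / 2)
        else:
            assert zone.upper == pytest.approx(upper)
            assert zone.lower == pytest.approx(lower)

    def test_one_sided_class_rejected(self):
        with pytest.raises(ThresholdDerivationError):
            derive_grey_zone([1, 2, 3], [True, True, True], 0.9)


class TestDeriveThresholds:
    def test_purity_outside_grey_zone_holds_by_construction(self, large_cohort):
        target = 0.97
        t = derive_thresholds(
            large_cohort[list(panel.PANEL)], large_cohort["subtype"], purity_target=target
        )
        v = large_cohort[panel.MIR_222].to_numpy()
        distal = large_cohort["subtype"].isin([panel.CHRCC, panel.ONCOCYTOMA]).to_numpy()
        above = v > t.step1_mir222.upper
        below = v < t.step1_mir222.lower
        assert distal[above].mean() >= target
        assert (~distal[below]).mean() >= target

    def test_derived_bounds_bracket_between_group_overlap(self, large_cohort):
        t = derive_thresholds(large_cohort[list(panel.PANEL)], large_cohort["subtype"])
        # the proximal and distal miR-222 distributions overlap; the zone must
        # contain values from both classes
        v = large_cohort[panel.MIR_222].to_numpy()
        distal = large_cohort["subtype"].isin([panel.CHRCC, panel.ONCOCYTOMA]).to_numpy()
        inside = (v >= t.step1_mir222.lower) & (v <= t.step1_mir222.upper)
        assert distal[inside].any() and (~distal)[inside].any()

    def test_degenerate_training_data_rejected(self):
        expr = pd.DataFrame(
            {m: [100.0] * 8 for m in panel.PANEL},
            index=[f"s{i}" for i in range(8)],
        )
        labels = [panel.CCRCC, panel.PRCC, panel.CHRCC, panel.ONCOCYTOMA] * 2
        with pytest.raises((ThresholdDerivationError, DegenerateDataError)):
            derive_thresholds(expr, labels)

    def test_fill_unset_cutoffs_only_touches_missing(self, study_cohort):
        base = ClassifierThresholds(step1_mir221_cutoff=99.0)
        filled = fill_unset_cutoffs(base, study_cohort, study_cohort["subtype"])
        assert filled.step1_mir221_cutoff == 99.0
        assert filled.step2a_mir126_cutoff is not None
        assert filled.step1_mir222 == base.step1_mir222


def test_classify_table_matches_row_wise_calls(study_cohort):
    t = fill_unset_cutoffs(DEFAULTS, study_cohort, study_cohort["subtype"])
    table = classify_table(study_cohort, t)
    assert len(table) == len(study_cohort)
    first = study_cohort.iloc[0]
    sample = {m: first[m] for m in panel.PANEL}
    assert table.iloc[0]["final_call"] == classify(sample, t).final
    json.loads(table.iloc[0]["votes"])  # vote detail is valid JSON
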