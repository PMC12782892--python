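"""Deviation effect estimation, interaction classification, GAP prediction."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from markergap.core import EmptyJoinError, GenotypeMatrix, Marker, MISSING, PhenotypeTable
from markergap.estimation import (
    GapRegressor,
    InteractionLabel,
    classify_allelic_interaction,
    compute_gpv,
    estimate_genotype_effects,
    estimate_joint_effects,
    load_model,
    marker_effect_magnitude,
    predict_cohort,
    save_model,
    train_gap_model,
)


class TestGenotypeEffects:
    def test_toy_cohort_hand_values(self, toy_cohort):
        gm, ph = toy_cohort
        est = estimate_genotype_effects(gm, ph, min_class_n=1)
        assert est.grand_mean == pytest.approx(8.0)
        eff = est.per_marker["m1"]
        assert eff["A/A"].effect == pytest.approx(3.0)
        assert eff["A/T"].effect == pytest.approx(0.0)
        assert eff["T/T"].effect == pytest.approx(-3.0)
        assert (eff["A/A"].n, eff["A/T"].n, eff["T/T"].n) == (2, 1, 2)

    def test_min_class_n_flags_small_classes(self, toy_cohort):
        gm, ph = toy_cohort
        est = estimate_genotype_effects(gm, ph, min_class_n=2)
        eff = est.per_marker["m1"]
        assert eff["A/T"].low_support and eff["A/T"].effect == 0.0
        assert eff["A/A"].effect == pytest.approx(3.0)
        assert eff["T/T"].effect == pytest.approx(-3.0)

    def test_constant_phenotypes_give_zero_effects(self, snp):
        gm = GenotypeMatrix(
            [snp], pd.DataFrame({"m1": ["A/A", "A/T", "T/T"]}, index=list("abc"))
        )
        ph = PhenotypeTable("FF", pd.Series(5.0, index=list("abc")))
        est = estimate_genotype_effects(gm, ph, min_class_n=1)
        assert all(e.effect == 0.0 for e in est.per_marker["m1"].values())

    def test_missing_call_excluded_from_class_but_not_grand_mean(self, snp):
        gm = GenotypeMatrix(
            [snp], pd.DataFrame({"m1": ["A/A", "A/A", MISSING]}, index=list("abc"))
        )
        ph = PhenotypeTable("FF", pd.Series({"a": 10.0, "b": 12.0, "c": 2.0}))
        est = estimate_genotype_effects(gm, ph, min_class_n=1)
        assert est.grand_mean == pytest.approx(8.0)  # includes c
        assert est.per_marker["m1"]["A/A"].effect == pytest.approx(3.0)

    def test_no_overlap_is_empty_join_error(self, snp):
        gm = GenotypeMatrix([snp], pd.DataFrame({"m1": ["A/A"]}, index=["a"]))
        ph = PhenotypeTable("FF", pd.Series({"zz": 1.0}))
        with pytest.raises(EmptyJoinError):
            estimate_genotype_effects(gm, ph)


class TestJointEffects:
    def test_single_member_reduces_to_per_marker(self, toy_cohort):
        gm, ph = toy_cohort
        est = estimate_genotype_effects(gm, ph, min_class_n=1)
        joint = estimate_joint_effects(gm, ph, ["m1"], min_class_n=1)
        for g, e in est.per_marker["m1"].items():
            assert joint.per_combo[(g,)].effect == pytest.approx(e.effect)

    def test_pure_epistasis_invisible_to_per_marker_effects(self, epistasis_cohort):
        gm, ph = epistasis_cohort
        est = estimate_genotype_effects(gm, ph, min_class_n=1)
        for entries in est.per_marker.values():
            for e in entries.values():
                assert e.effect == pytest.approx(0.0)
        joint = estimate_joint_effects(gm, ph, ["m1", "m2"], min_class_n=1)
        assert joint.per_combo[("A/A", "B/B")].effect == pytest.approx(2.0)
        assert joint.per_combo[("A/A", "B/b")].effect == pytest.approx(-2.0)
        assert joint.per_combo[("A/a", "B/B")].effect == pytest.approx(-2.0)
        assert joint.per_combo[("A/a", "B/b")].effect == pytest.approx(2.0)

    def test_constant_phenotypes_zero_joint_effects(self, epistasis_cohort):
        gm, _ = epistasis_cohort
        ph = PhenotypeTable("FFR", pd.Series(4.0, index=gm.calls.index))
        joint = estimate_joint_effects(gm, ph, ["m1", "m2"], min_class_n=1)
        assert all(e.effect == 0.0 for e in joint.per_combo.values())

    def test_absent_member_is_lookup_error(self, toy_cohort):
        gm, ph = toy_cohort
        with pytest.raises(KeyError):
            estimate_joint_effects(gm, ph, ["m1", "ghost"])


class TestAllelicInteraction:
    @pytest.mark.parametrize(
        "effects,ratio,label",
        [
            ({"A/A": 3.0, "A/T": 0.0, "T/T": -3.0}, 0.0, InteractionLabel.additive),
            ({"A/A": 3.0, "A/T": 3.0, "T/T": -3.0}, 1.0, InteractionLabel.dominant),
            ({"A/A": 3.0, "A/T": 1.5, "T/T": -3.0}, 0.5, InteractionLabel.partial_dominant),
            ({"A/A": 1.0, "A/T": 2.0, "T/T": -1.0}, 2.0, InteractionLabel.overdominant),
        ],
    )
    def test_dominance_ratio_and_label(self, effects, ratio, label):
        call = classify_allelic_interaction(effects, "m1")
        assert call.dominance_ratio == pytest.approx(ratio)
        assert call.label is label

    def test_zero_a_nonzero_d_is_overdominant_with_infinite_ratio(self):
        call = classify_allelic_interaction({"A/A": 1.0, "A/T": 3.0, "T/T": 1.0})
        assert call.label is InteractionLabel.overdominant
        assert np.isinf(call.dominance_ratio)

    def test_degenerate_cases_undetermined(self):
        flat = classify_allelic_interaction({"A/A": 1.0, "A/T": 1.0, "T/T": 1.0})
        assert flat.label is InteractionLabel.undetermined
        two = classify_allelic_interaction({"A/A": 1.0, "T/T": -1.0})
        assert two.label is InteractionLabel.undetermined


class TestMarkerEffectMagnitude:
    def test_range_definition(self):
        assert marker_effect_magnitude({"A/A": 3.0, "A/T": 0.0, "T/T": -3.0}) == 6.0
        assert marker_effect_magnitude({"A/A": 1.0, "T/T": 1.0}) == 0.0

    def test_single_class_undetermined(self):
        assert marker_effect_magnitude({"A/A": 3.0}) is None


class TestGapRegressor:
    def test_additive_hand_sum(self, toy_cohort):
        gm, ph = toy_cohort
        model = train_gap_model(gm, ph, min_class_n=1)
        assert model.grand_mean_ == pytest.approx(8.0)
        assert compute_gpv(model, {"m1": "A/A"}) == pytest.approx(11.0)
        assert compute_gpv(model, {"m1": "T/T"}) == pytest.approx(5.0)

    def test_no_marker_model_predicts_grand_mean(self, snp):
        gm = GenotypeMatrix([snp], pd.DataFrame({"m1": [MISSING, MISSING, MISSING]},
                                                index=list("abc")))
        ph = PhenotypeTable("FF", pd.Series({"a": 7.0, "b": 8.0, "c": 9.0}))
        model = train_gap_model(gm, ph)
        assert compute_gpv(model, {"m1": MISSING}) == pytest.approx(8.0)

    def test_unknown_marker_in_calls_is_lookup_error(self, toy_cohort):
        gm, ph = toy_cohort
        model = train_gap_model(gm, ph, min_class_n=1)
        with pytest.raises(KeyError):
            compute_gpv(model, {"ghost": "A/A"})

    def test_nonadditive_empty_sets_equals_additive_everywhere(self, toy_cohort):
        gm, ph = toy_cohort
        add = train_gap_model(gm, ph, mode="additive", min_class_n=1)
        non = train_gap_model(gm, ph, sets=[], mode="nonadditive", min_class_n=1)
        assert np.array_equal(add.predict(gm.calls), non.predict(gm.calls))

    def test_additive_mode_stores_sets_but_ignores_them(self, epistasis_cohort):
        gm, ph = epistasis_cohort
        add = train_gap_model(gm, ph, sets=[["m1", "m2"]], mode="additive", min_class_n=1)
        assert add.joint_ == []
        # additive model sees nothing in pure epistasis
        assert add.predict(gm.calls) == pytest.approx(np.full(4, 8.0))

    def test_nonadditive_captures_pure_epistasis(self, epistasis_cohort):
        gm, ph = epistasis_cohort
        non = train_gap_model(gm, ph, sets=[["m1", "m2"]], mode="nonadditive", min_class_n=1)
        assert compute_gpv(non, {"m1": "A/A", "m2": "B/B"}) == pytest.approx(10.0)
        add = train_gap_model(gm, ph, mode="additive", min_class_n=1)
        assert compute_gpv(add, {"m1": "A/A", "m2": "B/B"}) == pytest.approx(8.0)

    def test_unseen_combo_falls_back_to_additive_sum(self, toy_cohort):
        gm, ph = toy_cohort
        m2 = Marker("m2", "Chr02", 50, ("C", "G"))
        calls = gm.calls.assign(m2=["C/C", "C/C", "C/G", "G/G", "G/G"])
        gm2 = GenotypeMatrix([gm.markers[0], m2], calls)
        non = train_gap_model(gm2, ph, sets=[["m1", "m2"]], mode="nonadditive", min_class_n=1)
        # combo (A/A, G/G) never observed -> sum of individual effects
        expected = (
            non.grand_mean_
            + non.effects_.per_marker["m1"]["A/A"].effect
            + non.effects_.per_marker["m2"]["G/G"].effect
        )
        assert compute_gpv(non, {"m1": "A/A", "m2": "G/G"}) == pytest.approx(expected)
        non_zero = train_gap_model(
            gm2, ph, sets=[["m1", "m2"]], mode="nonadditive",
            min_class_n=1, fallback_policy="zero",
        )
        assert compute_gpv(non_zero, {"m1": "A/A", "m2": "G/G"}) == pytest.approx(
            non_zero.grand_mean_
        )

    def test_all_missing_individual_counts_full_panel_fallback(self, toy_cohort):
        gm, ph = toy_cohort
        model = train_gap_model(gm, ph, min_class_n=1)
        frame = predict_cohort(
            model,
            GenotypeMatrix(gm.markers, pd.DataFrame({"m1": [MISSING]}, index=["x"])),
        )
        assert frame.at["x", "gpv"] == pytest.approx(model.grand_mean_)
        assert frame.at["x", "n_fallback"] == 1

    def test_predict_cohort_matches_per_individual_loop(self, toy_cohort):
        gm, ph = toy_cohort
        model = train_gap_model(gm, ph, min_class_n=1)
        frame = predict_cohort(model, gm)
        for ind in gm.calls.index:
            assert frame.at[ind, "gpv"] == pytest.approx(
                compute_gpv(model, {"m1": gm.calls.at[ind, "m1"]})
            )

    def test_zero_panel_overlap_is_empty_join(self, toy_cohort):
        gm, ph = toy_cohort
        model = train_gap_model(gm, ph, min_class_n=1)
        other = pd.DataFrame({"zz": ["A/A"]}, index=["x"])
        with pytest.raises(EmptyJoinError):
            model.predict_frame(other)

    def test_low_support_class_contributes_zero(self, toy_cohort):
        gm, ph = toy_cohort
        model = train_gap_model(gm, ph, min_class_n=2)  # A/T flagged (n=1)
        assert compute_gpv(model, {"m1": "A/T"}) == pytest.approx(model.grand_mean_)

    def test_self_consistency_noiseless_single_marker(self, snp):
        # training and predicting the same noiseless cohort reproduces OPV
        calls = pd.DataFrame({"m1": ["A/A", "A/A", "A/T", "A/T", "T/T", "T/T"]},
                             index=[f"i{k}" for k in range(6)])
        gm = GenotypeMatrix([snp], calls)
        y = calls["m1"].map({"A/A": 11.0, "A/T": 8.0, "T/T": 5.0})
        model = train_gap_model(gm, PhenotypeTable("FF", y), min_class_n=1)
        assert model.predict(gm.calls) == pytest.approx(y.to_numpy(), abs=1e-12)

    def test_sklearn_clone_and_params_roundtrip(self):
        model = GapRegressor(mode="nonadditive", interacting_sets=[["m1", "m2"]],
                             min_class_n=2)
        cloned = clone(model)
        assert cloned.get_params() == model.get_params()
        cloned.set_params(min_class_n=5)
        assert cloned.min_class_n == 5 and model.min_class_n == 2

    def test_model_json_roundtrip(self, tmp_path, epistasis_cohort):
        gm, ph = epistasis_cohort
        model = train_gap_model(gm, ph, sets=[["m1", "m2"]], mode="nonadditive",
                                min_class_n=1)
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        assert np.array_equal(model.predict(gm.calls), back.predict(gm.calls))
        assert back.grand_mean_ == model.grand_mean_
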