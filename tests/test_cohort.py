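"""Tests of cohort filtering, longitudinal selection and group statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mimelog import (
    CohortConfig,
    estimate_phi,
    filter_cross_sectional,
    generate_synthetic_cohort,
    group_comparison,
    phi_vs_function,
    select_longitudinal,
)
from mimelog.cohort import LongitudinalSelection, selections_to_frame
from mimelog.estimators import VisitPair


def make_records(rows):
    df = pd.DataFrame(rows)
    for col in ("ft3", "lt4_dose", "weight"):
        if col not in df.columns:
            df[col] = np.nan
    return df


class TestFilterCrossSectional:
    def test_boundary_semantics_closed_intervals(self):
        records = make_records(
            [
                {"patient_id": "a", "group": "control", "visit": 1, "tsh": 1.0, "ft4": 15.0},
                {"patient_id": "b", "group": "control", "visit": 1, "tsh": 1.0, "ft4": 9.9},
                {"patient_id": "c", "group": "control", "visit": 1, "tsh": 1.0, "ft4": 10.0},
                {"patient_id": "d", "group": "control", "visit": 1, "tsh": 4.0, "ft4": 20.0},
                {"patient_id": "e", "group": "control", "visit": 1, "tsh": 4.01, "ft4": 15.0},
            ]
        )
        result = filter_cross_sectional(records)
        assert set(result.records["patient_id"]) == {"a", "c", "d"}
        reasons = dict(zip(result.excluded["patient_id"], result.excluded["reason"]))
        assert reasons == {"b": "ft4_out_of_range", "e": "tsh_out_of_range"}

    def test_carcinoma_patients_excluded_from_comparison(self):
        records = make_records(
            [
                {"patient_id": "a", "group": "carcinoma_longitudinal", "visit": 1,
                 "tsh": 1.0, "ft4": 15.0},
                {"patient_id": "b", "group": "treated_benign", "visit": 1,
                 "tsh": 1.0, "ft4": 15.0},
            ]
        )
        result = filter_cross_sectional(records)
        assert list(result.records["patient_id"]) == ["b"]
        assert result.exclusion_counts == {"carcinoma_excluded": 1}

    def test_malformed_rows_reported_not_dropped_silently(self):
        records = make_records(
            [
                {"patient_id": "a", "group": "control", "visit": 1, "tsh": np.nan, "ft4": 15.0},
                {"patient_id": "b", "group": "control", "visit": 1, "tsh": -1.0, "ft4": 15.0},
            ]
        )
        result = filter_cross_sectional(records)
        assert len(result.records) == 0
        assert list(result.excluded["reason"]) == ["malformed", "malformed"]
        assert list(result.excluded["patient_id"]) == ["a", "b"]

    def test_idempotent(self):
        records, _ = generate_synthetic_cohort(CohortConfig(), seed=2)
        once = filter_cross_sectional(records)
        twice = filter_cross_sectional(once.records)
        pd.testing.assert_frame_equal(once.records, twice.records)
        assert len(twice.excluded) == 0

    def test_generator_bookkeeping_of_inside_outside_counts(self):
        # records constructed with known inside/outside range membership
        inside = [
            {"patient_id": f"in{i}", "group": "control", "visit": 1,
             "tsh": 0.5 + 0.1 * i, "ft4": 11.0 + i}
            for i in range(8)
        ]
        outside = [
            {"patient_id": f"out{i}", "group": "control", "visit": 1,
             "tsh": 5.0 + i, "ft4": 15.0}
            for i in range(5)
        ]
        result = filter_cross_sectional(make_records(inside + outside))
        assert len(result.records) == 8
        assert result.exclusion_counts == {"tsh_out_of_range": 5}

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            filter_cross_sectional(make_records([]), ft4_range=(20.0, 10.0))


def longitudinal_records(visits_by_patient):
    rows = []
    for pid, visits in visits_by_patient.items():
        for i, (tsh, ft4, dose) in enumerate(visits, start=1):
            rows.append(
                {"patient_id": pid, "group": "carcinoma_longitudinal", "visit": i,
                 "tsh": tsh, "ft4": ft4, "lt4_dose": dose}
            )
    return make_records(rows)


class TestSelectLongitudinal:
    def test_qualifying_patient_selected_with_dose_change(self):
        records = longitudinal_records({"p1": [(0.5, 18.0, 100.0), (2.5, 13.0, 175.0)]})
        selections, exclusions = select_longitudinal(records)
        assert len(selections) == 1 and len(exclusions) == 0
        sel = selections[0]
        assert sel.dose_difference == 75.0
        assert sel.pair.tsh_1 == 2.5 and sel.pair.tsh_2 == 0.5  # max-TSH visit first
        assert sel.phi == pytest.approx(np.log(2.5 / 0.5) / (18.0 - 13.0), rel=1e-12)

    def test_suppressed_tsh_excluded(self):
        records = longitudinal_records({"p1": [(0.05, 20.0, 100.0), (2.0, 14.0, 175.0)]})
        selections, exclusions = select_longitudinal(records)
        assert selections == []
        assert list(exclusions["reason"]) == ["tsh_out_of_range"]

    def test_small_dose_change_excluded(self):
        records = longitudinal_records({"p1": [(0.5, 18.0, 100.0), (2.5, 13.0, 130.0)]})
        _, exclusions = select_longitudinal(records)
        assert list(exclusions["reason"]) == ["dose_change_too_small"]

    def test_equal_ft4_flagged_as_undefined_gradient(self):
        records = longitudinal_records({"p1": [(0.5, 15.0, 100.0), (2.5, 15.0, 175.0)]})
        _, exclusions = select_longitudinal(records)
        assert list(exclusions["reason"]) == ["phi_undefined"]

    def test_tied_max_tsh_broken_by_earliest_visit(self):
        records = longitudinal_records(
            {"p1": [(2.5, 13.0, 100.0), (2.5, 16.0, 175.0), (0.5, 18.0, 175.0)]}
        )
        selections, _ = select_longitudinal(records)
        assert selections[0].pair.ft4_1 == 13.0  # first of the tied max-TSH visits

    def test_matches_exhaustive_scan_on_synthetic_cohort(self):
        # oracle: brute-force scan of all visit pairs for the max/min-TSH pair
        records, _ = generate_synthetic_cohort(CohortConfig(noise_scale=0.0), seed=9)
        lon = records[records["group"] == "carcinoma_longitudinal"]
        selections, _ = select_longitudinal(lon)
        by_id = {s.patient_id: s for s in selections}
        for pid, visits in lon.groupby("patient_id"):
            best = max(
                itertools.permutations(visits.to_dict("records"), 2),
                key=lambda ab: ab[0]["tsh"] - ab[1]["tsh"],
            )
            if pid in by_id:
                sel = by_id[pid]
                assert sel.pair.tsh_1 == pytest.approx(best[0]["tsh"])
                assert sel.pair.tsh_2 == pytest.approx(best[1]["tsh"])

    def test_generator_bookkeeping_recovers_qualifying_subset(self):
        config = CohortConfig(noise_scale=0.0)
        records, truth = generate_synthetic_cohort(config, seed=13)
        lon = records[records["group"] == "carcinoma_longitudinal"]
        selections, exclusions = select_longitudinal(lon)
        truth_lon = truth[truth["group"] == "carcinoma_longitudinal"]
        qualifying = set(truth_lon.loc[truth_lon["qualifies"] == True, "patient_id"])
        assert {s.patient_id for s in selections} == qualifying
        # exclusion reasons agree with the generator's ground truth
        truth_reasons = truth_lon.set_index("patient_id")["reason"]
        for _, row in exclusions.iterrows():
            assert truth_reasons[row["patient_id"]] == row["reason"]

    def test_noise_free_phi_recovery_is_exact(self):
        records, truth = generate_synthetic_cohort(CohortConfig(noise_scale=0.0), seed=4)
        lon = records[records["group"] == "carcinoma_longitudinal"]
        selections, _ = select_longitudinal(lon)
        truth_phi = truth.set_index("patient_id")["phi"]
        assert len(selections) > 0
        for sel in selections:
            assert sel.phi == pytest.approx(truth_phi[sel.patient_id], rel=1e-10)


def make_selection(pid, phi, mean_ft4, mean_tsh=1.0):
    pair = VisitPair(tsh_1=2.0, ft4_1=mean_ft4 - 1, tsh_2=1.0, ft4_2=mean_ft4 + 1)
    return LongitudinalSelection(
        patient_id=pid, pair=pair, dose_difference=60.0,
        mean_ft4=mean_ft4, mean_tsh=mean_tsh, phi=phi,
    )


class TestPhiVsFunction:
    def test_perfectly_monotone_relationship_gives_unit_tau(self):
        selections = [make_selection(f"p{i}", 0.5 - 0.02 * i, 10.0 + i) for i in range(10)]
        result = phi_vs_function(selections)
        assert result["tau_phi_ft4"]["tau"] == pytest.approx(-1.0)

    def test_constructed_decreasing_linkage_gives_negative_tau(self, rng):
        ft4 = rng.uniform(11, 27, 40)
        phi = 0.65 - 0.02 * ft4 + 0.005 * rng.standard_normal(40)
        selections = [
            make_selection(f"p{i}", p, f) for i, (p, f) in enumerate(zip(phi, ft4))
        ]
        result = phi_vs_function(selections)
        assert result["tau_phi_ft4"]["tau"] < -0.5
        assert result["tau_phi_ft4"]["p"] < 0.001

    def test_independent_phi_and_ft4_rarely_significant(self):
        # Monte-Carlo null check: independent draws, n=200 per replicate
        hits = 0
        n_reps = 40
        for seed in range(n_reps):
            r = np.random.default_rng(seed)
            selections = [
                make_selection(f"p{i}", p, f)
                for i, (p, f) in enumerate(zip(r.uniform(0.1, 0.5, 200), r.uniform(10, 25, 200)))
            ]
            if phi_vs_function(selections)["tau_phi_ft4"]["p"] < 0.05:
                hits += 1
        assert hits / n_reps <= 0.10

    def test_too_few_or_degenerate_selections_reported_undefined(self):
        few = [make_selection("a", 0.3, 15.0)]
        assert "note" in phi_vs_function(few)["tau_phi_ft4"]
        constant = [make_selection(f"p{i}", 0.3, 10.0 + i) for i in range(8)]
        assert "note" in phi_vs_function(constant)["tau_phi_ft4"]


class TestGroupComparison:
    def make_group(self, rng, phi, n=120, label="control"):
        # records on a single pituitary curve: population slope equals -phi
        ft4 = rng.uniform(10.0, 20.0, n)
        tsh = 300.0 * np.exp(-phi * ft4)
        return make_records(
            [
                {"patient_id": f"{label}{i}", "group": label, "visit": 1,
                 "tsh": t, "ft4": f, "ft3": 5.0 + 0.1 * rng.standard_normal(),
                 "lt4_dose": 100.0, "weight": 80.0}
                for i, (t, f) in enumerate(zip(tsh, ft4))
            ]
        )

    def test_identical_groups_have_zero_slope_contrast(self, rng):
        group = self.make_group(rng, phi=0.3)
        report = group_comparison(group, group.copy())
        assert report["tsh_ft4"]["slope_contrast"] == pytest.approx(0.0, abs=1e-10)

    def test_steeper_treated_gradient_recovered_in_contrast(self, rng):
        control = self.make_group(rng, phi=0.30, label="control")
        treated = self.make_group(rng, phi=0.50, label="treated")
        report = group_comparison(control, treated)
        assert report["tsh_ft4"]["slopes"]["control"] == pytest.approx(-0.30, abs=1e-9)
        assert report["tsh_ft4"]["slopes"]["treated"] == pytest.approx(-0.50, abs=1e-9)
        assert report["tsh_ft4"]["slope_contrast"] == pytest.approx(-0.20, abs=1e-9)
        assert report["tsh_ft4"]["slope_contrast_p"] < 1e-6

    def test_weight_adjusted_dose_units(self):
        assert 100.0 / 80.0 == pytest.approx(1.25)  # µg/day at 80 kg -> µg/kg/day
        # and the generator's inverse dose-G_D linkage surfaces as negative tau
        records, _ = generate_synthetic_cohort(CohortConfig(), seed=21)
        filtered = filter_cross_sectional(records).records
        report = group_comparison(
            filtered[filtered["group"] == "control"],
            filtered[filtered["group"] == "treated_benign"],
        )
        tau = report["spina_gd"]["treated"]["tau_gd_dose_per_kg"]["tau"]
        assert tau < -0.2

    def test_missing_ft3_excluded_pairwise_with_counts(self, rng):
        control = self.make_group(rng, phi=0.3)
        treated = self.make_group(rng, phi=0.5, label="treated")
        treated.loc[treated.index[:10], "ft3"] = np.nan
        report = group_comparison(control, treated)
        assert report["tsh_ft3"]["dropped"] == 10
        assert report["spina_gd"]["treated"]["dropped"] == 10


class TestSyntheticCohort:
    def test_default_group_sizes_match_study_design(self):
        records, truth = generate_synthetic_cohort(CohortConfig(), seed=1)
        sizes = records.groupby("group")["patient_id"].nunique()
        assert sizes["control"] == 268
        assert sizes["treated_benign"] == 170
        assert sizes["carcinoma_longitudinal"] == 64
        # longitudinal patients have two visits each
        lon = records[records["group"] == "carcinoma_longitudinal"]
        assert (lon.groupby("patient_id")["visit"].count() == 2).all()

    def test_zero_noise_records_lie_on_generating_set_points(self):
        records, truth = generate_synthetic_cohort(CohortConfig(noise_scale=0.0), seed=6)
        ctl = records[records["group"] == "control"].set_index("patient_id")
        t = truth[truth["group"] == "control"].set_index("patient_id")
        assert np.allclose(ctl["ft4"], t["ft4_true"], atol=1e-12)
        assert np.allclose(ctl["tsh"], t["tsh_true"], rtol=1e-12)
        # and set points satisfy the generating pituitary curve exactly
        resid = ctl["tsh"] - t["s"] * np.exp(-t["phi"] * ctl["ft4"])
        assert np.abs(resid).max() < 1e-8

    def test_deterministic_given_seed(self):
        a, _ = generate_synthetic_cohort(CohortConfig(), seed=8)
        b, _ = generate_synthetic_cohort(CohortConfig(), seed=8)
        pd.testing.assert_frame_equal(a, b)

    def test_inconsistent_config_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_longitudinal=4, n_long_small_dose=3, n_long_suppressed=3)
        with pytest.raises(ValueError):
            CohortConfig(noise_scale=-1.0)
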