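import math

import numpy as np
import pandas as pd
import pytest

from vrloc import behavior
from vrloc.synth import ResponseSimConfig, simulate_responses


def make_records(rows):
    defaults = {
        "subject": "S01",
        "condition": "I-blind-acoustic-nohmd",
        "block": "I",
        "target_azimuth_deg": 0.0,
        "target_elevation_deg": 0.0,
        "response_azimuth_deg": 0.0,
        "response_elevation_deg": 0.0,
        "repetition": 1,
        "handedness": "right",
    }
    return pd.DataFrame([{**defaults, **row} for row in rows])


@pytest.fixture(scope="module")
def cohort():
    return simulate_responses(seed=99)


class TestMirroring:
    def test_left_handed_azimuths_negated(self):
        rec = make_records(
            [
                {"handedness": "left", "target_azimuth_deg": 30.0,
                 "response_azimuth_deg": 12.0, "response_elevation_deg": 28.0},
                {"handedness": "right", "target_azimuth_deg": 30.0,
                 "response_azimuth_deg": 12.0},
            ]
        )
        out = behavior.mirror_handedness(rec)
        assert out.loc[0, "target_azimuth_deg"] == -30.0
        assert out.loc[0, "response_azimuth_deg"] == -12.0
        assert out.loc[0, "response_elevation_deg"] == 28.0  # elevation untouched
        assert out.loc[1, "target_azimuth_deg"] == 30.0

    def test_involution(self, cohort):
        twice = behavior.mirror_handedness(behavior.mirror_handedness(cohort))
        pd.testing.assert_frame_equal(twice, cohort)


class TestBiasEstimation:
    def test_constant_offset_recovered_exactly(self):
        rows = []
        for az in (-45.0, 0.0, 45.0):
            for el in (-28.0, 0.0, 28.0):
                rows.append(
                    {
                        "condition": "III-re-visual-nohmd",
                        "target_azimuth_deg": az,
                        "target_elevation_deg": el,
                        "response_azimuth_deg": az + 2.0,
                        "response_elevation_deg": el + 10.0,
                    }
                )
        bias = behavior.estimate_pointing_bias(make_records(rows))
        assert bias.azimuth == pytest.approx(2.0)
        assert bias.elevation == pytest.approx(10.0)

    def test_group_bias_is_mean_of_subject_biases(self, cohort):
        bias = behavior.estimate_pointing_bias(behavior.mirror_handedness(cohort))
        assert bias.azimuth == pytest.approx(bias.per_subject["azimuth"].mean())
        assert bias.elevation == pytest.approx(bias.per_subject["elevation"].mean())

    def test_recovers_generator_truth(self, cohort):
        bias = behavior.estimate_pointing_bias(behavior.mirror_handedness(cohort))
        assert bias.azimuth == pytest.approx(-1.6, abs=0.5)
        assert bias.elevation == pytest.approx(19.0, abs=0.5)

    def test_subject_without_visual_trials_warns(self):
        rec = make_records(
            [
                {"condition": "III-re-visual-nohmd", "subject": "S01"},
                {"condition": "I-blind-acoustic-nohmd", "subject": "S02"},
            ]
        )
        with pytest.warns(UserWarning, match="S02"):
            bias = behavior.estimate_pointing_bias(rec)
        assert list(bias.per_subject.index) == ["S01"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            behavior.estimate_pointing_bias(make_records([]).iloc[0:0])


class TestBiasCorrection:
    def test_biased_response_restored_to_target(self):
        rec = make_records(
            [
                {"condition": "III-re-visual-nohmd", "target_azimuth_deg": 30.0,
                 "response_azimuth_deg": 32.0, "target_elevation_deg": 28.0,
                 "response_elevation_deg": 38.0}
            ]
        )
        bias = behavior.BiasEstimate(
            2.0, 10.0,
            pd.DataFrame({"azimuth": [2.0], "elevation": [10.0]}, index=["S01"]),
        )
        out = behavior.apply_bias_correction(rec, bias)
        assert out.loc[0, "response_azimuth_deg"] == pytest.approx(30.0)
        assert out.loc[0, "response_elevation_deg"] == pytest.approx(28.0)

    def test_laser_condition_passes_through(self):
        rec = make_records(
            [{"condition": "IV-laser-acoustic-hmd", "response_azimuth_deg": 15.0,
              "response_elevation_deg": 5.0}]
        )
        bias = behavior.BiasEstimate(
            2.0, 10.0,
            pd.DataFrame({"azimuth": [2.0], "elevation": [10.0]}, index=["S01"]),
        )
        out = behavior.apply_bias_correction(rec, bias)
        assert out.loc[0, "response_azimuth_deg"] == 15.0
        assert out.loc[0, "response_elevation_deg"] == 5.0

    def test_missing_subject_bias_rejected(self):
        rec = make_records([{"subject": "S09"}])
        bias = behavior.BiasEstimate(
            0.0, 0.0, pd.DataFrame({"azimuth": [0.0], "elevation": [0.0]}, index=["S01"])
        )
        with pytest.raises(ValueError, match="S09"):
            behavior.apply_bias_correction(rec, bias)

    def test_correction_then_reestimation_is_zero(self, cohort):
        mirrored = behavior.mirror_handedness(cohort)
        bias = behavior.estimate_pointing_bias(mirrored)
        corrected = behavior.apply_bias_correction(mirrored, bias, exempt_conditions=[])
        again = behavior.estimate_pointing_bias(corrected)
        assert again.azimuth == pytest.approx(0.0, abs=1e-9)
        assert again.elevation == pytest.approx(0.0, abs=1e-9)


class TestOutlierFilter:
    def test_strict_threshold_boundary(self):
        rec = make_records(
            [
                {"response_azimuth_deg": 46.0},  # az error 46 -> removed
                {"response_azimuth_deg": 45.0},  # exactly 45 -> kept
                {"response_elevation_deg": 45.0},  # exactly 45 -> kept
                {"response_elevation_deg": -45.5},  # removed
            ]
        )
        res = behavior.filter_outliers(rec)
        assert len(res.kept) == 2
        assert len(res.removed) == 2
        assert res.removed_fraction == pytest.approx(0.5)

    def test_no_removal_when_all_within_threshold(self, cohort):
        res = behavior.filter_outliers(cohort, threshold=185.0)
        assert len(res.removed) == 0

    def test_removal_monotone_in_threshold(self, cohort):
        fractions = [
            behavior.filter_outliers(cohort, t).removed_fraction
            for t in (20.0, 45.0, 90.0)
        ]
        assert fractions[0] >= fractions[1] >= fractions[2]

    def test_lapse_rate_matches_binomial_expectation(self):
        # expectation oracle: closed-form per-trial removal probability.
        # Lapses are uniform in azimuth and in sin(elevation) over the frontal
        # hemisphere (and are themselves shifted by the bias correction);
        # non-lapse trials are Gaussian around target + HMD overshoot.
        from scipy.stats import norm

        from vrloc.conditions import get_condition

        def p_az_keep(center):  # P(|U(-90,90) - center| <= 45)
            return max(0.0, (min(center + 45.0, 90.0) - max(center - 45.0, -90.0))) / 180.0

        def p_el_keep(center):  # P(|asin(U(-1,1)) - center| <= 45)
            lo = math.sin(math.radians(max(center - 45.0, -90.0)))
            hi = math.sin(math.radians(min(center + 45.0, 90.0)))
            return max(0.0, hi - lo) / 2.0

        cfg = ResponseSimConfig()
        records = pd.concat(
            [simulate_responses(cfg, seed=s) for s in (101, 102, 103)],
            ignore_index=True,
        )
        mirrored = behavior.mirror_handedness(records)
        bias = behavior.estimate_pointing_bias(mirrored)
        corrected = behavior.apply_bias_correction(mirrored, bias)
        res = behavior.filter_outliers(corrected)

        p_total, var_total = 0.0, 0.0
        for (subj, slug, t_az, t_el), chunk in corrected.groupby(
            ["subject", "condition", "target_azimuth_deg", "target_elevation_deg"]
        ):
            c = get_condition(slug)
            az_sd, el_sd = cfg.noise_sd[slug]
            shift = 0.0
            if c.hmd and c.stimulus == "acoustic":
                gain = cfg.overshoot_gain_left if t_az < 0 else cfg.overshoot_gain_right
                shift = gain * t_az
            p_az_out = norm.sf((45.0 - shift) / az_sd) + norm.sf((45.0 + shift) / az_sd)
            p_el_out = 2 * norm.sf(45.0 / el_sd)
            p_noise = 1.0 - (1 - p_az_out) * (1 - p_el_out)
            # a lapse response was also bias-corrected (unless exempt)
            b_az = 0.0 if c.bias_exempt else bias.per_subject.loc[subj, "azimuth"]
            b_el = 0.0 if c.bias_exempt else bias.per_subject.loc[subj, "elevation"]
            p_lapse_removed = 1.0 - p_az_keep(t_az + b_az) * p_el_keep(t_el + b_el)
            p = (
                cfg.lapse_probability * p_lapse_removed
                + (1 - cfg.lapse_probability) * p_noise
            )
            n = len(chunk)
            p_total += n * p
            var_total += n * p * (1 - p)
        expected = p_total / len(corrected)
        se = np.sqrt(var_total) / len(corrected)
        assert abs(res.removed_fraction - expected) <= 3 * se


class TestErrorTables:
    def test_single_record_cell(self):
        rec = make_records(
            [{"response_azimuth_deg": 5.0, "response_elevation_deg": 5.0}]
        )
        table = behavior.summarize_errors(rec, keys=("condition",))
        az = table[table.dimension == "azimuth"].iloc[0]
        assert az["mean_absolute"] == 5.0
        assert az["median_signed"] == az["q1"] == az["q3"] == 5.0
        assert az["n"] == 1

    def test_symmetric_errors(self):
        rec = make_records(
            [{"response_azimuth_deg": v} for v in (-2.0, 0.0, 2.0)]
        )
        az = behavior.summarize_errors(rec, keys=("condition",))
        row = az[az.dimension == "azimuth"].iloc[0]
        assert row["mean_absolute"] == pytest.approx(4.0 / 3.0)
        assert row["median_signed"] == 0.0

    def test_cell_counts_sum_to_record_count(self, cohort):
        kept = behavior.filter_outliers(cohort).kept
        table = behavior.summarize_errors(kept)
        az_rows = table[table.dimension == "azimuth"]
        assert int(az_rows["n"].sum()) == len(kept)

    def test_agrees_with_streaming_oracle(self, cohort):
        # independent single-pass accumulation of the absolute-error means
        errs = behavior.signed_error_columns(cohort)
        acc: dict = {}
        for row in errs.itertuples(index=False):
            key = (row.condition,)
            s, n = acc.get(key, (0.0, 0))
            acc[key] = (s + abs(row.azimuth_error_deg), n + 1)
        table = behavior.summarize_errors(cohort, keys=("condition",))
        for key, (s, n) in acc.items():
            cell = table[
                (table.condition == key[0]) & (table.dimension == "azimuth")
            ].iloc[0]
            assert cell["mean_absolute"] == pytest.approx(s / n, abs=1e-12)
            assert cell["n"] == n

    def test_quartiles_bracket_median(self, cohort):
        table = behavior.summarize_errors(cohort)
        assert np.all(table["q1"] <= table["median_signed"])
        assert np.all(table["median_signed"] <= table["q3"])
        assert np.all(table["whisker_low"] <= table["q1"])
        assert np.all(table["whisker_high"] >= table["q3"])


class TestHemifieldContrast:
    def test_symmetric_errors_give_near_zero_contrast(self):
        rng = np.random.default_rng(17)
        rows = []
        for az in (-60.0, -30.0, 30.0, 60.0):
            for _ in range(400):
                rows.append(
                    {
                        "target_azimuth_deg": az,
                        "response_azimuth_deg": az + rng.normal(0, 5.0),
                    }
                )
        table = behavior.summarize_errors(
            make_records(rows), keys=("condition", "target_azimuth_deg")
        )
        contrast = behavior.hemifield_contrast(
            table[table.dimension == "azimuth"].drop(columns="dimension")
        )
        assert np.all(np.abs(contrast["left_minus_right"]) < 1.0)

    def test_left_overshoot_detected(self):
        # construction: lateral overshoot 2 deg larger on the left than the
        # right at every lateral target -> positive left-minus-right contrast
        rng = np.random.default_rng(5)
        rows = []
        for az in (-90.0, -60.0, -30.0, 30.0, 60.0, 90.0):
            overshoot = (abs(az) / 30.0 + 2.0) if az < 0 else abs(az) / 30.0
            for _ in range(200):
                rows.append(
                    {
                        "target_azimuth_deg": az,
                        "response_azimuth_deg": az
                        + np.sign(az) * overshoot
                        + rng.normal(0.0, 0.5),
                    }
                )
        table = behavior.summarize_errors(
            make_records(rows), keys=("target_azimuth_deg",)
        )
        contrast = behavior.hemifield_contrast(
            table[table.dimension == "azimuth"].drop(columns="dimension")
        )
        assert (contrast["left_minus_right"] > 0).all()

    def test_azimuth_zero_excluded(self):
        rec = make_records(
            [{"target_azimuth_deg": a, "response_azimuth_deg": a} for a in (-30.0, 0.0, 30.0)]
        )
        table = behavior.summarize_errors(rec, keys=("condition", "target_azimuth_deg"))
        contrast = behavior.hemifield_contrast(
            table[table.dimension == "azimuth"].drop(columns="dimension")
        )
        assert 0.0 not in set(contrast["abs_azimuth_deg"])

    def test_missing_mirror_cell_warns(self):
        rec = make_records(
            [{"target_azimuth_deg": a, "response_azimuth_deg": a} for a in (-30.0, 30.0, 60.0)]
        )
        table = behavior.summarize_errors(rec, keys=("condition", "target_azimuth_deg"))
        with pytest.warns(UserWarning, match="missing mirror"):
            behavior.hemifield_contrast(
                table[table.dimension == "azimuth"].drop(columns="dimension")
            )
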