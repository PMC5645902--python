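"""Parameter detection: hand-worked fixtures for the treatment-pattern
arithmetic, period summaries, and a direct-filter oracle over synthetic
episodes."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from dhsi.cohort import DepressiveEpisode, StudyWindow, select_episodes
from dhsi.parameters import (
    ParameterVector,
    detect_parameters,
    detect_parameters_frame,
    summarize_period,
)
from dhsi.scoring import ALL_PARAMETERS
from dhsi.synthetic import SimulationConfig, generate_event_stream
from conftest import events_frame, make_event

INDEX = date(2008, 3, 1)


def base_episode(death_date=None):
    return DepressiveEpisode.from_index_date("A-E1", "A", INDEX, death_date)


def base_rows():
    """Minimal criteria-mandated events: index AD + nearby diagnosis."""
    return [
        make_event("A", date(2007, 1, 1), "birth_year_record", code="1968"),
        make_event("A", INDEX, "gp_visit"),
        make_event("A", INDEX, "ad_prescription", molecule="citalopram",
                   daily_dose=20.0, coverage_days=30),
        make_event("A", date(2008, 3, 10), "gp_visit"),
        make_event("A", date(2008, 3, 10), "depression_diagnosis", code="DEP"),
        make_event("A", date(2010, 1, 1), "gp_visit"),
    ]


def day(n):
    """Date n days after the index date."""
    return INDEX + timedelta(days=n)


class TestPeriodSummary:
    def test_empty_window_gives_zero_counts(self):
        ep = base_episode()
        events = events_frame(base_rows())
        fu = summarize_period(ep, events, "followup")
        assert fu.n_hypnotic_prescriptions == 0
        assert fu.n_somatic_prescriptions == 0
        assert fu.inter_visit_mean is None and fu.inter_visit_sd is None

    def test_constant_gap_visits(self):
        rows = base_rows() + [
            make_event("A", day(92 + k), "gp_visit") for k in (0, 30, 60)
        ]
        fu = summarize_period(base_episode(), events_frame(rows), "followup")
        assert fu.inter_visit_mean == 30.0
        assert fu.inter_visit_sd == 0.0

    def test_coverage_weighted_mean_dose(self):
        # 20 mg/day x 30 d and 40 mg/day x 30 d -> 30 mg/day
        rows = base_rows() + [
            make_event("A", day(92), "ad_prescription", molecule="citalopram",
                       daily_dose=20.0, coverage_days=30),
            make_event("A", day(122), "ad_prescription", molecule="citalopram",
                       daily_dose=40.0, coverage_days=30),
        ]
        fu = summarize_period(base_episode(), events_frame(rows), "followup")
        assert fu.ad_mean_daily_dose == pytest.approx(30.0)

    def test_unequal_coverage_weights(self):
        rows = base_rows() + [
            make_event("A", day(92), "ad_prescription", molecule="citalopram",
                       daily_dose=20.0, coverage_days=10),
            make_event("A", day(122), "ad_prescription", molecule="citalopram",
                       daily_dose=40.0, coverage_days=30),
        ]
        fu = summarize_period(base_episode(), events_frame(rows), "followup")
        assert fu.ad_mean_daily_dose == pytest.approx((20 * 10 + 40 * 30) / 40)

    def test_followup_truncated_at_death(self):
        rows = base_rows() + [
            make_event("A", day(100), "hypnotic_prescription",
                       molecule="zopiclone", coverage_days=14),
            make_event("A", day(200), "hypnotic_prescription",
                       molecule="zopiclone", coverage_days=14),
        ]
        ep = base_episode(death_date=day(150))
        fu = summarize_period(ep, events_frame(rows), "followup")
        assert fu.n_hypnotic_prescriptions == 1


class TestDetectors:
    def test_output_has_exactly_29_binary_flags(self):
        vec = detect_parameters(base_episode(), events_frame(base_rows()))
        assert list(vec) == list(ALL_PARAMETERS)
        assert all(v in (0, 1) for v in vec.values())

    def test_equal_counts_leave_relative_parameters_zero(self):
        # identical baseline and follow-up counts: equality is not a change
        rows = base_rows() + [
            make_event("A", day(-60), "hypnotic_prescription",
                       molecule="zopiclone", coverage_days=14),
            make_event("A", day(100), "hypnotic_prescription",
                       molecule="zopiclone", coverage_days=14),
            make_event("A", day(-60), "somatic_prescription",
                       molecule="statin", coverage_days=30),
            make_event("A", day(100), "somatic_prescription",
                       molecule="statin", coverage_days=30),
        ]
        vec = detect_parameters(base_episode(), events_frame(rows))
        for p in ("X4", "Y9", "X6", "Y16", "X7", "Y17", "X8", "Y18"):
            assert vec[p] == 0, p

    def test_incident_flags_fire_in_followup_only(self):
        inside = {
            "psychiatric_hospitalization": "Y2",
            "suicide_attempt": "Y3",
            "ect": "Y4",
            "psychiatrist_referral": "Y5",
            "sick_leave": "Y6",
            "pregnancy_termination": "Y8",
            "other_hospitalization": "Y19",
        }
        rows = base_rows() + [make_event("A", day(120), t) for t in inside]
        vec = detect_parameters(base_episode(), events_frame(rows))
        for flag in inside.values():
            assert vec[flag] == 1, flag
        # same events before follow-up leave all flags at zero
        rows2 = base_rows() + [make_event("A", day(40), t) for t in inside]
        vec2 = detect_parameters(base_episode(), events_frame(rows2))
        for flag in inside.values():
            assert vec2[flag] == 0, flag

    def test_death_in_followup_sets_y1(self):
        rows = base_rows()
        rows = [r for r in rows if r["date"] != date(2010, 1, 1)]
        rows.append(make_event("A", day(120), "death"))
        vec = detect_parameters(base_episode(death_date=day(120)),
                                events_frame(rows))
        assert vec["Y1"] == 1

    def test_switch_vs_combination_window_arithmetic(self):
        # initial AD coverage ends day 100 post-index; a different molecule
        # first prescribed day 150 (inside follow-up):
        #   switch window = [100-31, 100+183] contains 150 -> Y7 = 1
        #   combination needs the new AD on/before day 100-31 = 69 -> Y11 = 0
        rows = base_rows() + [
            make_event("A", day(70), "ad_prescription", molecule="citalopram",
                       daily_dose=20.0, coverage_days=30),
            make_event("A", day(150), "gp_visit"),
            make_event("A", day(150), "ad_prescription", molecule="sertraline",
                       daily_dose=50.0, coverage_days=30),
        ]
        vec = detect_parameters(base_episode(), events_frame(rows))
        assert vec["Y7"] == 1
        assert vec["Y11"] == 0

    def test_combination_overlap_in_followup(self):
        # second AD starts day 95, initial AD covered through day 180:
        # 95 <= 180-31 and the overlap lies inside follow-up -> Y11
        rows = base_rows() + [
            make_event("A", day(k), "ad_prescription", molecule="citalopram",
                       daily_dose=20.0, coverage_days=30)
            for k in (30, 60, 90, 120, 150)
        ] + [
            make_event("A", day(95), "ad_prescription", molecule="sertraline",
                       daily_dose=50.0, coverage_days=60),
        ]
        vec = detect_parameters(base_episode(), events_frame(rows))
        assert vec["Y11"] == 1
        assert vec["Y7"] == 0

    def test_augmentation_y12(self):
        rows = base_rows() + [
            make_event("A", day(k), "ad_prescription", molecule="citalopram",
                       daily_dose=20.0, coverage_days=30)
            for k in (30, 60, 90, 120, 150)
        ] + [
            make_event("A", day(95), "antipsychotic_or_lithium_prescription",
                       molecule="quetiapine", coverage_days=60),
        ]
        vec = detect_parameters(base_episode(), events_frame(rows))
        assert vec["Y12"] == 1

    def test_relapse_y13_gap_arithmetic(self):
        # AD coverage ends day 60; a psychotropic prescription at day 120
        # falls 60 days after the stop, inside [45, 183] -> Y13
        rows = base_rows() + [
            make_event("A", day(30), "ad_prescription", molecule="citalopram",
                       daily_dose=20.0, coverage_days=30),
            make_event("A", day(120), "gp_visit"),
            make_event("A", day(120), "psychiatric_prescription",
                       molecule="diazepam", coverage_days=30),
        ]
        vec = detect_parameters(base_episode(), events_frame(rows))
        assert vec["Y13"] == 1
        # 30 days after the stop is below the 45-day floor
        rows2 = base_rows() + [
            make_event("A", day(30), "ad_prescription", molecule="citalopram",
                       daily_dose=20.0, coverage_days=30),
            make_event("A", day(90), "psychiatric_prescription",
                       molecule="diazepam", coverage_days=30),
        ]
        assert detect_parameters(base_episode(), events_frame(rows2))["Y13"] == 0

    def test_x1_requires_two_visits_clear_of_ad(self):
        rows = base_rows() + [
            make_event("A", day(k), "gp_visit") for k in (100, 130, 160)
        ]
        vec = detect_parameters(base_episode(), events_frame(rows))
        assert vec["X1"] == 1
        # an AD prescription on the final follow-up visit spoils it
        rows2 = rows + [
            make_event("A", day(160), "ad_prescription", molecule="citalopram",
                       daily_dose=20.0, coverage_days=30)
        ]
        vec2 = detect_parameters(base_episode(), events_frame(rows2))
        assert vec2["X1"] == 0

    def test_x5_depression_diagnosis_clears_by_last_visit(self):
        rows = base_rows() + [
            make_event("A", day(100), "gp_visit"),
            make_event("A", day(100), "depression_diagnosis", code="DEP"),
            make_event("A", day(160), "gp_visit"),
        ]
        vec = detect_parameters(base_episode(), events_frame(rows))
        assert vec["X5"] == 1
        rows2 = rows + [make_event("A", day(160), "depression_diagnosis", code="DEP")]
        assert detect_parameters(base_episode(), events_frame(rows2))["X5"] == 0

    def test_dose_change_flags(self):
        ref = [  # 20 mg/day in the last month of baseline
            make_event("A", day(10), "ad_prescription", molecule="citalopram",
                       daily_dose=20.0, coverage_days=30),
        ]
        fu_low = [
            make_event("A", day(100), "ad_prescription", molecule="citalopram",
                       daily_dose=10.0, coverage_days=30),
        ]
        vec = detect_parameters(base_episode(), events_frame(base_rows() + ref + fu_low))
        assert vec["X10"] == 1 and vec["Y15"] == 0
        fu_high = [
            make_event("A", day(100), "ad_prescription", molecule="citalopram",
                       daily_dose=40.0, coverage_days=30),
        ]
        vec2 = detect_parameters(base_episode(), events_frame(base_rows() + ref + fu_high))
        assert vec2["X10"] == 0 and vec2["Y15"] == 1
        # a switch to another molecule voids the dose comparison
        other = [
            make_event("A", day(130), "ad_prescription", molecule="sertraline",
                       daily_dose=50.0, coverage_days=30),
        ]
        vec3 = detect_parameters(
            base_episode(), events_frame(base_rows() + ref + fu_low + other)
        )
        assert vec3["X10"] == 0 and vec3["Y15"] == 0

    def test_new_psychiatric_comorbidity_y10(self):
        rows = base_rows() + [
            make_event("A", day(-30), "psychiatric_comorbidity_diagnosis", code="ANX"),
            make_event("A", day(120), "psychiatric_comorbidity_diagnosis", code="ANX"),
        ]
        assert detect_parameters(base_episode(), events_frame(rows))["Y10"] == 0
        rows.append(
            make_event("A", day(130), "psychiatric_comorbidity_diagnosis", code="OCD")
        )
        assert detect_parameters(base_episode(), events_frame(rows))["Y10"] == 1

    def test_locality_events_outside_windows_do_not_matter(self):
        rows = base_rows()
        before = detect_parameters(base_episode(), events_frame(rows))
        far = rows + [
            make_event("A", day(400), "psychiatric_hospitalization"),
            make_event("A", day(-300), "hypnotic_prescription",
                       molecule="zopiclone", coverage_days=14),
            make_event("A", day(-300), "gp_visit"),
        ]
        after = detect_parameters(base_episode(), events_frame(far))
        assert dict(before) == dict(after)

    def test_vector_validation(self):
        with pytest.raises(ValueError):
            ParameterVector({p: 0 for p in ALL_PARAMETERS[:-1]})
        with pytest.raises(ValueError):
            ParameterVector({**{p: 0 for p in ALL_PARAMETERS}, "X1": 2})


MUTEX_PAIRS = [("X4", "Y9"), ("X3", "Y14"), ("X6", "Y16"),
               ("X7", "Y17"), ("X8", "Y18"), ("X10", "Y15")]


def test_mutual_exclusion_and_oracle_on_synthetic_episodes():
    """Strict increase and strict decrease of one quantity cannot both fire,
    and incident/count flags match a direct window-filter oracle."""
    events = generate_event_stream(SimulationConfig(n_patients=100, seed=5))
    window = StudyWindow(date(2006, 1, 1), date(2012, 12, 31))
    episodes = select_episodes(events, window)
    assert episodes
    matrix = detect_parameters_frame(episodes, events)
    assert list(matrix.columns) == ["episode_id", *ALL_PARAMETERS]
    assert matrix[list(ALL_PARAMETERS)].isin([0, 1]).all().all()
    for a, b in MUTEX_PAIRS:
        assert not ((matrix[a] == 1) & (matrix[b] == 1)).any(), (a, b)

    incident = {"Y2": "psychiatric_hospitalization", "Y3": "suicide_attempt",
                "Y4": "ect", "Y5": "psychiatrist_referral", "Y6": "sick_leave",
                "Y8": "pregnancy_termination", "Y19": "other_hospitalization"}
    by_id = {e.episode_id: e for e in episodes}
    for _, row in matrix.iterrows():
        ep = by_id[row["episode_id"]]
        pdf = events[(events["patient_id"] == ep.patient_id)]
        fu = pdf[(pdf["date"] >= ep.followup_start) & (pdf["date"] <= ep.followup_end)]
        for flag, etype in incident.items():
            assert row[flag] == int((fu["event_type"] == etype).any()), flag
        # count-comparison oracle (hypnotics; follow-up truncated at death)
        fu_end = ep.followup_end
        if ep.death_date is not None and ep.followup_start <= ep.death_date < fu_end:
            fu_end = ep.death_date
        bl = pdf[(pdf["date"] >= ep.baseline_start) & (pdf["date"] <= ep.baseline_end)]
        fu_t = pdf[(pdf["date"] >= ep.followup_start) & (pdf["date"] <= fu_end)]
        nb = int((bl["event_type"] == "hypnotic_prescription").sum())
        nf = int((fu_t["event_type"] == "hypnotic_prescription").sum())
        assert row["X7"] == int(nf < nb)
        assert row["Y17"] == int(nf > nb)
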