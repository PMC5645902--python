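"""Detection of the 29 binary episode parameters.

Ten parameters (X1-X10) indicate progression toward improvement — e.g.
visits without antidepressant prescriptions, a falling number of
psychiatric co-prescriptions, disappearing depression diagnoses — and
nineteen (Y1-Y19) indicate worsening: death, psychiatric hospitalization,
suicide attempt, ECT, treatment switch/combination/augmentation, relapse,
rising co-prescription counts.  Incident parameters read event presence in
the follow-up window; relative parameters compare follow-up against the
baseline (reference) period.

Operational conventions the source definitions leave open are documented
inline and in the methods note (degenerate visit counts, strict
inequalities for "lower/higher number", the definition of an AD "stop",
death truncation of the follow-up window).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import DepressiveEpisode
from .scoring import ALL_PARAMETERS

__all__ = [
    "ParameterVector",
    "PeriodSummary",
    "summarize_period",
    "detect_parameters",
    "detect_parameters_frame",
    "PSYCHIATRIC_CO_RX_TYPES",
    "PSYCHIATRIC_TREATMENT_TYPES",
]

# "Psychiatric co-prescription" covers every psychotropic class other than
# the antidepressant itself.
PSYCHIATRIC_CO_RX_TYPES = (
    "psychiatric_prescription",
    "hypnotic_prescription",
    "antipsychotic_or_lithium_prescription",
)
# "Any psychiatric treatment" (relapse detection) additionally includes ADs.
PSYCHIATRIC_TREATMENT_TYPES = PSYCHIATRIC_CO_RX_TYPES + ("ad_prescription",)

# Minimum visits for inter-visit gap statistics (>= 2 gaps needed for an SD).
MIN_VISITS_FOR_GAP_STATS = 3
SWITCH_LOOKBACK_DAYS = 31
SWITCH_LOOKAHEAD_DAYS = 183
COMBINATION_MARGIN_DAYS = 31
RELAPSE_GAP_MIN_DAYS = 45
RELAPSE_GAP_MAX_DAYS = 183
REFERENCE_DOSE_WINDOW_DAYS = 31  # "last month of reference period"


class ParameterVector(dict):
    """Mapping of the 29 parameter ids (X1..X10, Y1..Y19) to 0/1 flags."""

    def __init__(self, flags):
        flags = dict(flags)
        if set(flags) != set(ALL_PARAMETERS):
            raise ValueError("parameter vector must carry exactly the 29 flags")
        for p, v in flags.items():
            if v not in (0, 1):
                raise ValueError(f"{p}: flag {v!r} is not binary")
        super().__init__({p: int(flags[p]) for p in ALL_PARAMETERS})

    def as_series(self) -> pd.Series:
        return pd.Series(self, index=list(ALL_PARAMETERS), dtype=int)


@dataclass(frozen=True)
class PeriodSummary:
    """Counts and visit statistics over one episode window."""

    period: str  # "baseline" or "followup"
    visit_dates: tuple
    n_distinct_psychiatric_molecules: int
    n_hypnotic_prescriptions: int
    n_somatic_prescriptions: int
    n_distinct_somatic_comorbidities: int
    ad_mean_daily_dose: Optional[float]
    inter_visit_mean: Optional[float]
    inter_visit_sd: Optional[float]


def _patient_events(events: pd.DataFrame, patient_id: str) -> pd.DataFrame:
    df = events[events["patient_id"].astype(str) == str(patient_id)].copy()
    if not df.empty:
        df["date"] = pd.to_datetime(df["date"]).dt.date
    return df


def _in_window(df: pd.DataFrame, start: date, end: date) -> pd.DataFrame:
    if df.empty:
        return df
    return df[(df["date"] >= start) & (df["date"] <= end)]


def _effective_followup_end(episode: DepressiveEpisode) -> date:
    """Follow-up truncated at death for period summaries."""
    end = episode.followup_end
    if (
        episode.death_date is not None
        and episode.followup_start <= episode.death_date < end
    ):
        end = episode.death_date
    return end


def _index_molecule(episode: DepressiveEpisode, pdf: pd.DataFrame) -> Optional[str]:
    rows = pdf[
        (pdf["event_type"] == "ad_prescription") & (pdf["date"] == episode.index_date)
    ]
    if rows.empty:
        return None
    return sorted(rows["molecule"].dropna().astype(str).unique())[0]


def _weighted_mean_dose(ad_rows: pd.DataFrame) -> Optional[float]:
    """Coverage-weighted mean daily dose over a set of AD prescriptions."""
    rows = ad_rows.dropna(subset=["daily_dose"])
    if rows.empty:
        return None
    dose = rows["daily_dose"].astype(float).to_numpy()
    cov = rows["coverage_days"].fillna(1).astype(float).to_numpy()
    cov = np.where(cov > 0, cov, 1.0)
    return float(np.sum(dose * cov) / np.sum(cov))


def _gap_stats(visit_dates) -> tuple[Optional[float], Optional[float]]:
    if len(visit_dates) < MIN_VISITS_FOR_GAP_STATS:
        return None, None
    days = np.array([(d - visit_dates[0]).days for d in visit_dates], dtype=float)
    gaps = np.diff(days)
    return float(np.mean(gaps)), float(np.std(gaps, ddof=1))


def summarize_period(
    episode: DepressiveEpisode, events: pd.DataFrame, period: str
) -> PeriodSummary:
    """Summarize one window of an episode.

    Counts are taken over events whose date falls in the closed window;
    distinct-molecule and distinct-comorbidity counts deduplicate by the
    molecule / code string; the AD mean daily dose is a coverage-weighted
    mean over prescriptions of the episode's index molecule.  The follow-up
    window is truncated at death.
    """
    if period not in ("baseline", "followup"):
        raise ValueError(f"period must be 'baseline' or 'followup', got {period!r}")
    pdf = _patient_events(events, episode.patient_id)
    if period == "baseline":
        start, end = episode.baseline_start, episode.baseline_end
    else:
        start, end = episode.followup_start, _effective_followup_end(episode)
    win = _in_window(pdf, start, end)

    visit_dates = tuple(
        sorted(win.loc[win["event_type"] == "gp_visit", "date"].unique())
    )
    psych = win[win["event_type"] == "psychiatric_prescription"]
    molecule = _index_molecule(episode, pdf)
    ad_rows = win[
        (win["event_type"] == "ad_prescription")
        & (win["molecule"].astype(str) == str(molecule))
    ]
    mean_gap, sd_gap = _gap_stats(visit_dates)
    return PeriodSummary(
        period=period,
        visit_dates=visit_dates,
        n_distinct_psychiatric_molecules=int(psych["molecule"].dropna().nunique()),
        n_hypnotic_prescriptions=int((win["event_type"] == "hypnotic_prescription").sum()),
        n_somatic_prescriptions=int((win["event_type"] == "somatic_prescription").sum()),
        n_distinct_somatic_comorbidities=int(
            win.loc[win["event_type"] == "somatic_comorbidity_diagnosis", "code"]
            .dropna()
            .nunique()
        ),
        ad_mean_daily_dose=_weighted_mean_dose(ad_rows) if molecule else None,
        inter_visit_mean=mean_gap,
        inter_visit_sd=sd_gap,
    )


def _merged_coverage_intervals(rx: pd.DataFrame) -> list[tuple[date, date]]:
    """Merge prescription coverage spans [date, date + coverage_days]."""
    spans = []
    for _, row in rx.iterrows():
        cov = row.get("coverage_days")
        cov = 0 if pd.isna(cov) else int(cov)
        spans.append((row["date"], row["date"] + timedelta(days=cov)))
    spans.sort()
    merged: list[tuple[date, date]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _consecutive_visits_clear(
    visit_dates, rx_dates, window_end: date
) -> int:
    """1 if >= 2 consecutive visits carry no listed prescription on them and
    none occurs later in follow-up; operationally, >= 2 visits strictly after
    the last disqualifying prescription date."""
    if rx_dates:
        last_rx = max(rx_dates)
        clear = [v for v in visit_dates if v > last_rx]
    else:
        clear = list(visit_dates)
    return int(len(clear) >= 2)


def detect_parameters(
    episode: DepressiveEpisode, events: pd.DataFrame
) -> ParameterVector:
    """Compute the full 29-flag vector for one episode.

    Undefined comparisons (too few visits for gap statistics, no dose data,
    a modified AD molecule) yield flag 0.  When the baseline gap SD is zero
    the gap comparisons require a strict change, which keeps the paired
    increase/decrease flags mutually exclusive.
    """
    pdf = _patient_events(events, episode.patient_id)
    fs, fe = episode.followup_start, episode.followup_end
    fe_eff = _effective_followup_end(episode)
    obs_start, obs_end = episode.baseline_start, episode.followup_end

    base = summarize_period(episode, events, "baseline")
    fu = summarize_period(episode, events, "followup")

    fu_events = _in_window(pdf, fs, fe)  # incident flags: full follow-up
    fu_eff_events = _in_window(pdf, fs, fe_eff)

    def present(event_type: str, frame: pd.DataFrame = fu_events) -> int:
        return int((frame["event_type"] == event_type).any())

    flags: dict[str, int] = {}

    # --- visits free of prescriptions (X1, X2) -------------------------
    visit_dates = fu.visit_dates
    ad_dates = sorted(
        fu_eff_events.loc[fu_eff_events["event_type"] == "ad_prescription", "date"]
    )
    psy_dates = sorted(
        fu_eff_events.loc[
            fu_eff_events["event_type"].isin(PSYCHIATRIC_CO_RX_TYPES), "date"
        ]
    )
    flags["X1"] = _consecutive_visits_clear(visit_dates, ad_dates, fe_eff)
    flags["X2"] = _consecutive_visits_clear(visit_dates, psy_dates, fe_eff)

    # --- inter-visit gap comparisons (X3, Y14) -------------------------
    flags["X3"] = flags["Y14"] = 0
    if base.inter_visit_mean is not None and fu.inter_visit_mean is not None:
        if base.inter_visit_sd and base.inter_visit_sd > 0:
            flags["X3"] = int(
                fu.inter_visit_mean >= base.inter_visit_mean + base.inter_visit_sd
            )
            flags["Y14"] = int(
                fu.inter_visit_mean <= base.inter_visit_mean - base.inter_visit_sd
            )
        else:  # zero-SD baseline: fall back to a strict change
            flags["X3"] = int(fu.inter_visit_mean > base.inter_visit_mean)
            flags["Y14"] = int(fu.inter_visit_mean < base.inter_visit_mean)

    # --- strict count comparisons --------------------------------------
    flags["X4"] = int(
        fu.n_distinct_psychiatric_molecules < base.n_distinct_psychiatric_molecules
    )
    flags["Y9"] = int(
        fu.n_distinct_psychiatric_molecules > base.n_distinct_psychiatric_molecules
    )
    flags["X6"] = int(
        fu.n_distinct_somatic_comorbidities < base.n_distinct_somatic_comorbidities
    )
    flags["Y16"] = int(
        fu.n_distinct_somatic_comorbidities > base.n_distinct_somatic_comorbidities
    )
    flags["X7"] = int(fu.n_hypnotic_prescriptions < base.n_hypnotic_prescriptions)
    flags["Y17"] = int(fu.n_hypnotic_prescriptions > base.n_hypnotic_prescriptions)
    flags["X8"] = int(fu.n_somatic_prescriptions < base.n_somatic_prescriptions)
    flags["Y18"] = int(fu.n_somatic_prescriptions > base.n_somatic_prescriptions)

    # --- disappearance of depression diagnoses (X5) --------------------
    dep_dates = set(
        fu_eff_events.loc[fu_eff_events["event_type"] == "depression_diagnosis", "date"]
    )
    if dep_dates:
        last_visit = max(visit_dates) if visit_dates else None
        flags["X5"] = int(last_visit is None or last_visit not in dep_dates)
    else:
        flags["X5"] = 0

    # --- dose comparison (X10, Y15) ------------------------------------
    molecule = _index_molecule(episode, pdf)
    flags["X10"] = flags["Y15"] = 0
    if molecule is not None:
        ads = pdf[pdf["event_type"] == "ad_prescription"]
        span_ads = _in_window(ads, obs_start, obs_end)
        unmodified = (
            span_ads["molecule"].dropna().astype(str).unique().tolist() == [molecule]
        )
        if unmodified:
            ref_rows = span_ads[
                (span_ads["molecule"].astype(str) == molecule)
                & (span_ads["date"] >= episode.baseline_end
                   - timedelta(days=REFERENCE_DOSE_WINDOW_DAYS - 1))
                & (span_ads["date"] <= episode.baseline_end)
            ]
            ref_dose = _weighted_mean_dose(ref_rows)
            fu_dose = fu.ad_mean_daily_dose
            if ref_dose is not None and fu_dose is not None:
                flags["X10"] = int(fu_dose < ref_dose)
                flags["Y15"] = int(fu_dose > ref_dose)

    # --- pregnancy (X9): full observation period -----------------------
    obs_events = _in_window(pdf, obs_start, obs_end)
    flags["X9"] = present("pregnancy_record", obs_events)

    # --- incident flags in follow-up -----------------------------------
    flags["Y1"] = int(
        episode.death_date is not None and fs <= episode.death_date <= fe
    )
    flags["Y2"] = present("psychiatric_hospitalization")
    flags["Y3"] = present("suicide_attempt")
    flags["Y4"] = present("ect")
    flags["Y5"] = present("psychiatrist_referral")
    flags["Y6"] = present("sick_leave")
    flags["Y8"] = present("pregnancy_termination")
    flags["Y19"] = present("other_hospitalization")

    # --- new psychiatric comorbidity (Y10) ------------------------------
    base_events = _in_window(pdf, episode.baseline_start, episode.baseline_end)
    base_comorb = set(
        base_events.loc[
            base_events["event_type"] == "psychiatric_comorbidity_diagnosis", "code"
        ].dropna()
    )
    fu_comorb = set(
        fu_events.loc[
            fu_events["event_type"] == "psychiatric_comorbidity_diagnosis", "code"
        ].dropna()
    )
    flags["Y10"] = int(len(fu_comorb - base_comorb) > 0)

    # --- treatment-pattern flags (Y7, Y11, Y12, Y13) --------------------
    flags["Y7"] = flags["Y11"] = flags["Y12"] = flags["Y13"] = 0
    ads = pdf[(pdf["event_type"] == "ad_prescription") & (pdf["date"] <= obs_end)]
    if molecule is not None and not ads.empty:
        initial = ads[
            (ads["molecule"].astype(str) == molecule)
            & (ads["date"] >= episode.index_date)
        ]
        others = ads[
            (ads["molecule"].astype(str) != molecule)
            & (ads["date"] > episode.index_date)
        ]
        if not initial.empty:
            stop = max(
                row["date"] + timedelta(days=0 if pd.isna(row["coverage_days"])
                                        else int(row["coverage_days"]))
                for _, row in initial.iterrows()
            )
            if not others.empty:
                first_other = min(others["date"])
                # Switch: new molecule first appears around the initial stop
                # and inside follow-up.
                in_switch_window = (
                    stop - timedelta(days=SWITCH_LOOKBACK_DAYS)
                    <= first_other
                    <= stop + timedelta(days=SWITCH_LOOKAHEAD_DAYS)
                )
                flags["Y7"] = int(in_switch_window and fs <= first_other <= fe)
                # Combination: second AD starts well before the initial stop
                # with concomitant coverage observed during follow-up.
                for _, row in others.iterrows():
                    if row["date"] > stop - timedelta(days=COMBINATION_MARGIN_DAYS):
                        continue
                    cov = 0 if pd.isna(row["coverage_days"]) else int(row["coverage_days"])
                    ov_start = max(row["date"], episode.index_date, fs)
                    ov_end = min(row["date"] + timedelta(days=cov), stop, fe)
                    if ov_start <= ov_end:
                        flags["Y11"] = 1
                        break

        # Augmentation: antipsychotic/lithium added >= 31 d before the end
        # of all AD treatment, concomitance during follow-up.
        stop_all = max(
            row["date"] + timedelta(days=0 if pd.isna(row["coverage_days"])
                                    else int(row["coverage_days"]))
            for _, row in ads[ads["date"] >= episode.index_date].iterrows()
        ) if (ads["date"] >= episode.index_date).any() else None
        if stop_all is not None:
            aps = pdf[
                (pdf["event_type"] == "antipsychotic_or_lithium_prescription")
                & (pdf["date"] > episode.index_date)
                & (pdf["date"] <= stop_all - timedelta(days=COMBINATION_MARGIN_DAYS))
            ]
            for _, row in aps.iterrows():
                cov = 0 if pd.isna(row.get("coverage_days")) else int(row["coverage_days"])
                ov_start = max(row["date"], episode.index_date, fs)
                ov_end = min(row["date"] + timedelta(days=cov), stop_all, fe)
                if ov_start <= ov_end:
                    flags["Y12"] = 1
                    break

        # Relapse/recurrence: any psychotropic prescription 45-183 d after
        # an AD stop (end of a merged coverage interval).
        stops = [e for _, e in _merged_coverage_intervals(ads)]
        psy_rx = pdf[
            pdf["event_type"].isin(PSYCHIATRIC_TREATMENT_TYPES)
            & (pdf["date"] >= obs_start)
            & (pdf["date"] <= obs_end)
        ]
        for q in psy_rx["date"]:
            if any(
                RELAPSE_GAP_MIN_DAYS <= (q - s).days <= RELAPSE_GAP_MAX_DAYS
                for s in stops
            ):
                flags["Y13"] = 1
                break

    return ParameterVector(flags)


def detect_parameters_frame(
    episodes, events: pd.DataFrame
) -> pd.DataFrame:
    """Parameter matrix (one row per episode, columns X1..X10, Y1..Y19)."""
    rows = []
    for ep in episodes:
        vec = detect_parameters(ep, events)
        rows.append({"episode_id": ep.episode_id, **vec})
    return pd.DataFrame(rows, columns=["episode_id", *ALL_PARAMETERS])
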