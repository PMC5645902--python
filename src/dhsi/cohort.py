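"""Depressive-episode selection from a longitudinal event table.

An episode is anchored at an incident antidepressant (AD) prescription in
monotherapy (the index date) with an incident depression diagnosis within
61 days either side, in an adult with sufficient data coverage and no
lifetime bipolar/schizophrenia diagnosis.  Around each index date the
module attaches a baseline window (5 months before to 1 month after) and a
follow-up window (3 to 9 months after) over which the 29 index parameters
are measured.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Optional

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EVENT_TYPES",
    "StudyWindow",
    "DepressiveEpisode",
    "select_episodes",
    "episodes_to_frame",
    "frame_to_episodes",
    "read_events",
    "write_events",
]

EVENT_TYPES = frozenset(
    {
        "gp_visit",
        "ad_prescription",
        "psychiatric_prescription",
        "hypnotic_prescription",
        "somatic_prescription",
        "antipsychotic_or_lithium_prescription",
        "depression_diagnosis",
        "psychiatric_comorbidity_diagnosis",
        "somatic_comorbidity_diagnosis",
        "bipolar_diagnosis",
        "schizophrenia_diagnosis",
        "psychiatric_hospitalization",
        "other_hospitalization",
        "suicide_attempt",
        "ect",
        "psychiatrist_referral",
        "sick_leave",
        "pregnancy_record",
        "pregnancy_termination",
        "delivery",
        "death",
        "birth_year_record",
    }
)

# Month-to-day conversions, kept consistent with the day counts the
# parameter definitions themselves use (183 d washouts and look-backs).
AD_WASHOUT_DAYS = 183          # 6 months with no prior AD prescription
DIAGNOSIS_WINDOW_DAYS = 61     # depression diagnosis within +/- 61 d of index
PRE_INDEX_COVERAGE_DAYS = 183  # 6 months of data before index
POST_INDEX_COVERAGE_DAYS = 275  # 9 months of data after index
BASELINE_BEFORE_DAYS = 152     # 5 months before index
BASELINE_AFTER_DAYS = 31       # 1 month after index
FOLLOWUP_START_DAYS = 92       # 3 months after index
FOLLOWUP_END_DAYS = 275        # 9 months after index
MIN_AGE_YEARS = 18

EVENT_COLUMNS = [
    "patient_id",
    "date",
    "event_type",
    "code",
    "drug_class",
    "molecule",
    "daily_dose",
    "coverage_days",
    "flags",
]


@dataclass(frozen=True)
class StudyWindow:
    start: date
    end: date

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("study window start must precede end")


@dataclass(frozen=True)
class DepressiveEpisode:
    """One qualifying time section of one patient."""

    episode_id: str
    patient_id: str
    index_date: date
    baseline_start: date
    baseline_end: date
    followup_start: date
    followup_end: date
    death_date: Optional[date] = None

    @classmethod
    def from_index_date(
        cls,
        episode_id: str,
        patient_id: str,
        index_date: date,
        death_date: Optional[date] = None,
    ) -> "DepressiveEpisode":
        return cls(
            episode_id=episode_id,
            patient_id=patient_id,
            index_date=index_date,
            baseline_start=index_date - timedelta(days=BASELINE_BEFORE_DAYS),
            baseline_end=index_date + timedelta(days=BASELINE_AFTER_DAYS),
            followup_start=index_date + timedelta(days=FOLLOWUP_START_DAYS),
            followup_end=index_date + timedelta(days=FOLLOWUP_END_DAYS),
            death_date=death_date,
        )


def read_events(path) -> pd.DataFrame:
    """Read an event CSV, parsing ISO-8601 dates to ``datetime.date``."""
    df = pd.read_csv(path, dtype={"patient_id": str, "code": str, "molecule": str})
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return df


def write_events(events: pd.DataFrame, path) -> None:
    out = events.copy()
    for col in EVENT_COLUMNS:
        if col not in out.columns:
            out[col] = pd.NA
    out[EVENT_COLUMNS].to_csv(path, index=False)


def _normalize_events(events: pd.DataFrame) -> pd.DataFrame:
    df = events.copy()
    if not df.empty:
        df["date"] = pd.to_datetime(df["date"]).dt.date
        unknown = set(df["event_type"].unique()) - EVENT_TYPES
        if unknown:
            raise ValueError(f"unknown event types: {sorted(unknown)}")
        df = df.sort_values(["patient_id", "date"], kind="stable").reset_index(drop=True)
    return df


def _age_at(index_date: date, birth_year: int) -> float:
    # Year-of-birth data only: mid-year (July 1) convention.
    born = date(birth_year, 7, 1)
    return (index_date - born).days / 365.25


def select_episodes(
    events: pd.DataFrame, window: StudyWindow
) -> list[DepressiveEpisode]:
    """Apply the inclusion/exclusion criteria and return qualifying episodes.

    Inclusion, all required at a candidate index date (an AD prescription
    date inside the study window):

    a. monotherapy — exactly one distinct AD molecule prescribed that day;
    b. no AD prescription in the 183 days before the index date;
    c. an incident depression diagnosis within 61 days either side of the
       index date (incident: no depression diagnosis in the 183 days before
       the qualifying diagnosis);
    d. age >= 18 at index (from the birth_year_record, mid-year convention);
    e. data coverage >= 183 days before and >= 275 days after the index
       date, the latter waived when death occurs within those 275 days;
    f. exclusion — no bipolar or schizophrenia diagnosis at any time.

    Data coverage is taken from the patient's first and last recorded event.
    A patient may contribute several episodes; criterion (b) is the sole
    overlap rule, so successive index dates are at least 184 days apart.
    Patients without a birth_year_record are skipped with a warning.
    """
    events = _normalize_events(events)
    episodes: list[DepressiveEpisode] = []
    if events.empty:
        return episodes

    for patient_id, pdf in events.groupby("patient_id", sort=True):
        birth_rows = pdf[pdf["event_type"] == "birth_year_record"]
        if birth_rows.empty:
            logger.warning("patient %s: no birth_year_record; skipped", patient_id)
            continue
        birth_year = int(birth_rows["code"].iloc[0])

        if pdf["event_type"].isin(["bipolar_diagnosis", "schizophrenia_diagnosis"]).any():
            continue

        death_rows = pdf[pdf["event_type"] == "death"]
        death_date = death_rows["date"].iloc[0] if not death_rows.empty else None

        first_seen = pdf["date"].min()
        last_seen = pdf["date"].max()

        ad = pdf[pdf["event_type"] == "ad_prescription"]
        ad_dates = sorted(ad["date"].unique())
        depression_dates = sorted(
            pdf.loc[pdf["event_type"] == "depression_diagnosis", "date"].unique()
        )

        n_episode = 0
        for idx_date in ad_dates:
            if not (window.start <= idx_date <= window.end):
                continue
            # (a) monotherapy on the index day
            day_molecules = ad.loc[ad["date"] == idx_date, "molecule"].nunique()
            if day_molecules != 1:
                continue
            # (b) AD washout
            washout_start = idx_date - timedelta(days=AD_WASHOUT_DAYS)
            if any(washout_start <= d < idx_date for d in ad_dates):
                continue
            # (c) incident depression diagnosis within +/- 61 d
            lo = idx_date - timedelta(days=DIAGNOSIS_WINDOW_DAYS)
            hi = idx_date + timedelta(days=DIAGNOSIS_WINDOW_DAYS)
            qualifying = False
            for d in depression_dates:
                if lo <= d <= hi:
                    d_washout = d - timedelta(days=AD_WASHOUT_DAYS)
                    if not any(d_washout <= e < d for e in depression_dates):
                        qualifying = True
                        break
            if not qualifying:
                continue
            # (d) adult at index
            if _age_at(idx_date, birth_year) < MIN_AGE_YEARS:
                continue
            # (e) data coverage
            if first_seen > idx_date - timedelta(days=PRE_INDEX_COVERAGE_DAYS):
                continue
            post_end = idx_date + timedelta(days=POST_INDEX_COVERAGE_DAYS)
            died_in_span = death_date is not None and idx_date <= death_date <= post_end
            if last_seen < post_end and not died_in_span:
                continue

            n_episode += 1
            episodes.append(
                DepressiveEpisode.from_index_date(
                    episode_id=f"{patient_id}-E{n_episode}",
                    patient_id=str(patient_id),
                    index_date=idx_date,
                    death_date=death_date,
                )
            )
    return episodes


def episodes_to_frame(episodes: list[DepressiveEpisode]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "episode_id": e.episode_id,
                "patient_id": e.patient_id,
                "index_date": e.index_date,
                "baseline_start": e.baseline_start,
                "baseline_end": e.baseline_end,
                "followup_start": e.followup_start,
                "followup_end": e.followup_end,
                "death_date": e.death_date,
            }
            for e in episodes
        ],
        columns=[
            "episode_id",
            "patient_id",
            "index_date",
            "baseline_start",
            "baseline_end",
            "followup_start",
            "followup_end",
            "death_date",
        ],
    )


def frame_to_episodes(df: pd.DataFrame) -> list[DepressiveEpisode]:
    eps = []
    for _, row in df.iterrows():
        death = row.get("death_date")
        if pd.isna(death):
            death = None
        else:
            death = pd.Timestamp(death).date()
        eps.append(
            DepressiveEpisode(
                episode_id=str(row["episode_id"]),
                patient_id=str(row["patient_id"]),
                index_date=pd.Timestamp(row["index_date"]).date(),
                baseline_start=pd.Timestamp(row["baseline_start"]).date(),
                baseline_end=pd.Timestamp(row["baseline_end"]).date(),
                followup_start=pd.Timestamp(row["followup_start"]).date(),
                followup_end=pd.Timestamp(row["followup_end"]).date(),
                death_date=death,
            )
        )
    return eps
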