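"""Synthetic primary-care event streams and episode parameter matrices.

No public extract of the original primary-care database exists, so this
module generates data with the statistical structure the pipeline assumes:
patients with registration spans and GP visit streams, antidepressant
initiation with refills, stops, switches and co-prescriptions, diagnosis
and hospitalization events, and — at the episode level — a single latent
severity scalar that couples the 29 binary parameters to one another and
to a remission proxy.  Higher severity raises the probability of the
worsening (Y) parameters, lowers that of the improvement (X) parameters,
and lowers the remission probability, so the expected association between
the index and remission is emergent rather than hard-coded.

Probabilities are adjusted additively and clamped to [0, 1]; a logistic
link would be smoother but the clamp is transparent and sufficient for a
generator whose role is to exercise the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .cohort import EVENT_COLUMNS
from .scoring import ALL_PARAMETERS, NEGATIVE_PARAMETERS, POSITIVE_PARAMETERS

__all__ = [
    "SimulationConfig",
    "LatentEpisodeTruth",
    "generate_event_stream",
    "generate_parameter_matrix",
    "simulate_scored_dataset",
    "DEFAULT_PREVALENCE",
    "DEFAULT_LOADING",
]

AD_MOLECULES = ("citalopram", "fluoxetine", "sertraline", "venlafaxine", "mirtazapine")
PSY_MOLECULES = ("diazepam", "lorazepam", "pregabalin", "buspirone")
HYPNOTIC_MOLECULES = ("zopiclone", "zolpidem", "temazepam")
AP_MOLECULES = ("quetiapine", "olanzapine", "lithium")

# Baseline marginal probability of each parameter in an average-severity
# episode.  Rare catastrophic events (death, suicide attempt, ECT) are kept
# rare; treatment-pattern and co-prescription parameters are common.
DEFAULT_PREVALENCE: dict[str, float] = {
    "X1": 0.35, "X2": 0.30, "X3": 0.20, "X4": 0.15, "X5": 0.25,
    "X6": 0.15, "X7": 0.15, "X8": 0.20, "X9": 0.02, "X10": 0.10,
    "Y1": 0.005, "Y2": 0.02, "Y3": 0.01, "Y4": 0.005, "Y5": 0.08,
    "Y6": 0.10, "Y7": 0.12, "Y8": 0.005, "Y9": 0.15, "Y10": 0.10,
    "Y11": 0.06, "Y12": 0.05, "Y13": 0.15, "Y14": 0.15, "Y15": 0.12,
    "Y16": 0.15, "Y17": 0.12, "Y18": 0.20, "Y19": 0.05,
}

# Additive shift per unit of latent severity: negative for improvement
# parameters, positive for worsening parameters.
DEFAULT_LOADING: dict[str, float] = {
    "X1": -0.12, "X2": -0.10, "X3": -0.08, "X4": -0.06, "X5": -0.10,
    "X6": -0.04, "X7": -0.05, "X8": -0.05, "X9": -0.003, "X10": -0.04,
    "Y1": 0.004, "Y2": 0.015, "Y3": 0.008, "Y4": 0.004, "Y5": 0.05,
    "Y6": 0.05, "Y7": 0.06, "Y8": 0.003, "Y9": 0.08, "Y10": 0.05,
    "Y11": 0.03, "Y12": 0.03, "Y13": 0.08, "Y14": 0.06, "Y15": 0.06,
    "Y16": 0.06, "Y17": 0.05, "Y18": 0.08, "Y19": 0.02,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    ``visit_rate`` is the mean number of GP visits per 30 days.  The
    latent severity is Normal(0, ``severity_sd``) per patient/episode;
    each binary parameter j is Bernoulli(clamp(prevalence_j + loading_j *
    severity)), and the remission proxy is Bernoulli(clamp(
    remission_base_prob - remission_severity_slope * severity)).
    """

    n_patients: int = 200
    study_start: date = date(2006, 1, 1)
    study_end: date = date(2012, 12, 31)
    visit_rate: float = 1.0
    ad_initiation_prob: float = 0.7
    severity_sd: float = 1.0
    parameter_prevalence: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    severity_loading: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LOADING)
    )
    remission_base_prob: float = 0.55
    remission_severity_slope: float = 0.20
    exclusion_fraction: float = 0.04
    emit_depression_diagnosis: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        if self.study_end <= self.study_start:
            raise ValueError("study_end must be after study_start")
        for name in ("visit_rate",):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("ad_initiation_prob", "remission_base_prob", "exclusion_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} is not a probability")
        if self.severity_sd < 0:
            raise ValueError("severity_sd must be >= 0")
        extra = set(self.parameter_prevalence) - set(ALL_PARAMETERS)
        missing = set(ALL_PARAMETERS) - set(self.parameter_prevalence)
        if extra or missing:
            raise ValueError(
                f"parameter_prevalence keys must be exactly the 29 parameter ids "
                f"(extra={sorted(extra)}, missing={sorted(missing)})"
            )
        extra_l = set(self.severity_loading) - set(ALL_PARAMETERS)
        if extra_l:
            raise ValueError(f"unknown parameter ids in severity_loading: {sorted(extra_l)}")
        for p, v in self.parameter_prevalence.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"prevalence of {p} is {v}, not a probability")


@dataclass(frozen=True)
class LatentEpisodeTruth:
    """Ground truth behind one generated episode row."""

    episode_id: str
    severity: float
    generated_parameters: dict
    remission_flag: bool


def _clamp(p: np.ndarray) -> np.ndarray:
    return np.clip(p, 0.0, 1.0)


def generate_parameter_matrix(
    n_episodes: int, config: SimulationConfig
) -> tuple[pd.DataFrame, list[LatentEpisodeTruth]]:
    """Draw an episode-by-parameter binary matrix from the latent model.

    Returns a frame with columns ``episode_id, X1..X10, Y1..Y19,
    remission_truth, severity`` plus the per-episode ground truth records.
    Deterministic given ``config.seed``.
    """
    if n_episodes < 1:
        raise ValueError("n_episodes must be >= 1")
    rng = np.random.default_rng(config.seed)
    severity = rng.normal(0.0, config.severity_sd, size=n_episodes)
    cols = {}
    for p in ALL_PARAMETERS:
        prob = _clamp(
            config.parameter_prevalence[p]
            + config.severity_loading.get(p, 0.0) * severity
        )
        cols[p] = (rng.random(n_episodes) < prob).astype(int)
    rem_prob = _clamp(
        config.remission_base_prob - config.remission_severity_slope * severity
    )
    remission = (rng.random(n_episodes) < rem_prob).astype(int)

    df = pd.DataFrame({"episode_id": [f"S{i + 1}" for i in range(n_episodes)], **cols})
    df["remission_truth"] = remission
    df["severity"] = severity
    truths = [
        LatentEpisodeTruth(
            episode_id=df["episode_id"].iloc[i],
            severity=float(severity[i]),
            generated_parameters={p: int(cols[p][i]) for p in ALL_PARAMETERS},
            remission_flag=bool(remission[i]),
        )
        for i in range(n_episodes)
    ]
    return df, truths


def _rand_date(rng, start: date, end: date) -> date:
    span = (end - start).days
    return start + timedelta(days=int(rng.integers(0, span + 1)))


def generate_event_stream(config: SimulationConfig) -> pd.DataFrame:
    """Simulate dated clinical events for ``config.n_patients`` patients.

    Each patient gets a registration span bracketing the study window, a
    birth-year record, a Poisson stream of GP visits, and — with
    probability ``ad_initiation_prob`` — an antidepressant episode: an
    incident AD prescription with monthly refills whose persistence,
    switching and co-medication all load on the patient's latent severity.
    A configurable fraction of patients carries a bipolar or schizophrenia
    diagnosis (exercising the exclusion criterion).  Events are internally
    consistent: nothing is recorded after death and prescriptions fall on
    visit dates (a visit is recorded for every prescription).
    """
    rng = np.random.default_rng(config.seed)
    rows: list[dict] = []

    for i in range(config.n_patients):
        pid = f"P{i + 1:05d}"
        severity = float(rng.normal(0.0, config.severity_sd))
        reg_start = config.study_start - timedelta(days=int(rng.integers(200, 700)))
        reg_end = config.study_end + timedelta(days=int(rng.integers(0, 200)))
        birth_year = int(rng.integers(1940, 2001))
        death_date: Optional[date] = None

        def emit(d: date, event_type: str, **kw) -> None:
            rows.append(
                {
                    "patient_id": pid,
                    "date": d,
                    "event_type": event_type,
                    "code": kw.get("code", ""),
                    "drug_class": kw.get("drug_class", ""),
                    "molecule": kw.get("molecule", ""),
                    "daily_dose": kw.get("daily_dose", np.nan),
                    "coverage_days": kw.get("coverage_days", np.nan),
                    "flags": kw.get("flags", ""),
                }
            )

        emit(reg_start, "birth_year_record", code=str(birth_year))

        span_days = (reg_end - reg_start).days
        n_visits = rng.poisson(config.visit_rate * span_days / 30.0)
        visit_dates = sorted(
            {reg_start + timedelta(days=int(d))
             for d in rng.integers(0, span_days + 1, size=n_visits)}
        )
        for v in visit_dates:
            emit(v, "gp_visit")

        if rng.random() < config.exclusion_fraction and visit_dates:
            d = visit_dates[int(rng.integers(0, len(visit_dates)))]
            kind = "bipolar_diagnosis" if rng.random() < 0.5 else "schizophrenia_diagnosis"
            emit(d, kind, code=kind[:3].upper())

        # background somatic burden
        for v in visit_dates:
            if rng.random() < 0.10:
                emit(v, "somatic_prescription",
                     molecule=f"somatic{int(rng.integers(1, 6))}", coverage_days=30)
            if rng.random() < 0.03:
                emit(v, "somatic_comorbidity_diagnosis",
                     code=f"SOM{int(rng.integers(1, 8))}")

        if rng.random() < config.ad_initiation_prob:
            # choose an index date with room for washout and follow-up
            lo = max(config.study_start, reg_start + timedelta(days=200))
            hi = min(config.study_end, reg_end - timedelta(days=300))
            if lo < hi:
                index_date = _rand_date(rng, lo, hi)
                molecule = AD_MOLECULES[int(rng.integers(0, len(AD_MOLECULES)))]
                dose = float(rng.choice([10.0, 20.0, 40.0]))
                if config.emit_depression_diagnosis:
                    emit(index_date, "depression_diagnosis", code="DEP")
                # persistence in months rises with severity
                months = int(np.clip(round(3 + 2.5 * severity + rng.normal(0, 1)), 1, 12))
                for m in range(months):
                    d = index_date + timedelta(days=30 * m)
                    emit(d, "gp_visit")
                    emit(d, "ad_prescription", molecule=molecule,
                         drug_class="antidepressant", daily_dose=dose,
                         coverage_days=30)
                stop = index_date + timedelta(days=30 * months)
                # severe patients may switch to a second AD after the stop
                if rng.random() < _clamp(np.array([0.15 + 0.15 * severity]))[0]:
                    gap = int(rng.integers(0, 60))
                    d = stop + timedelta(days=gap)
                    other = AD_MOLECULES[
                        (AD_MOLECULES.index(molecule) + 1) % len(AD_MOLECULES)
                    ]
                    for m in range(int(rng.integers(1, 4))):
                        dd = d + timedelta(days=30 * m)
                        emit(dd, "gp_visit")
                        emit(dd, "ad_prescription", molecule=other,
                             drug_class="antidepressant", daily_dose=dose,
                             coverage_days=30)
                # severity-linked co-medication and adverse events in the
                # nine months after index
                fu_lo, fu_hi = index_date, index_date + timedelta(days=275)
                p_sev = _clamp(np.array([
                    0.15 + 0.12 * severity,   # psychiatric co-prescription
                    0.10 + 0.08 * severity,   # hypnotic
                    0.04 + 0.04 * severity,   # psychiatrist referral
                    0.03 + 0.03 * severity,   # psychiatric hospitalization
                    0.05 + 0.04 * severity,   # sick leave
                    0.01 + 0.01 * severity,   # suicide attempt
                ]))
                if rng.random() < p_sev[0]:
                    d = _rand_date(rng, fu_lo, fu_hi)
                    emit(d, "gp_visit")
                    emit(d, "psychiatric_prescription",
                         molecule=PSY_MOLECULES[int(rng.integers(0, len(PSY_MOLECULES)))],
                         coverage_days=30)
                if rng.random() < p_sev[1]:
                    d = _rand_date(rng, fu_lo, fu_hi)
                    emit(d, "gp_visit")
                    emit(d, "hypnotic_prescription",
                         molecule=HYPNOTIC_MOLECULES[int(rng.integers(0, 3))],
                         coverage_days=14)
                if rng.random() < p_sev[2]:
                    emit(_rand_date(rng, fu_lo, fu_hi), "psychiatrist_referral")
                if rng.random() < p_sev[3]:
                    emit(_rand_date(rng, fu_lo, fu_hi), "psychiatric_hospitalization")
                if rng.random() < p_sev[4]:
                    emit(_rand_date(rng, fu_lo, fu_hi), "sick_leave")
                if rng.random() < p_sev[5]:
                    emit(_rand_date(rng, fu_lo, fu_hi), "suicide_attempt")
                if rng.random() < 0.02:
                    emit(_rand_date(rng, fu_lo, fu_hi), "other_hospitalization")
                if rng.random() < 0.01 and birth_year > 1970:
                    emit(_rand_date(rng, fu_lo, fu_hi), "pregnancy_record")
                if rng.random() < _clamp(np.array([0.005 + 0.005 * severity]))[0]:
                    death_date = _rand_date(rng, fu_lo, fu_hi)

        if death_date is None and rng.random() < 0.005:
            death_date = _rand_date(rng, reg_start, reg_end)
        if death_date is not None:
            emit(death_date, "death")

    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    if df.empty:
        return df
    # consistency: drop anything recorded after a patient's death
    deaths = df[df["event_type"] == "death"].groupby("patient_id")["date"].min()
    df = df.merge(deaths.rename("death_date"), on="patient_id", how="left")
    keep = df["death_date"].isna() | (df["date"] <= df["death_date"])
    df = df[keep].drop(columns="death_date")
    return df.sort_values(["patient_id", "date", "event_type"], kind="stable").reset_index(
        drop=True
    )


def simulate_scored_dataset(
    n_episodes: int,
    config: Optional[SimulationConfig] = None,
    interactions: tuple = (("Y2", "Y5", -15.0), ("X1", "X2", 10.0), ("Y7", "Y13", -12.0)),
    noise_sd: float = 5.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Binary parameter matrix plus a score with planted pairwise interactions.

    The score is a linear combination of the 29 parameters (positive
    coefficients for X, negative for Y), the listed interaction products,
    and Gaussian noise — a test bed for interaction discovery where the
    true interaction structure is known.
    """
    cfg = replace(config or SimulationConfig(), seed=seed)
    X, _ = generate_parameter_matrix(n_episodes, cfg)
    rng = np.random.default_rng(seed + 1)
    beta = {
        p: (rng.uniform(2.0, 6.0) if p in POSITIVE_PARAMETERS else -rng.uniform(2.0, 6.0))
        for p in ALL_PARAMETERS
    }
    y = np.full(n_episodes, 55.0)
    for p in ALL_PARAMETERS:
        y = y + beta[p] * X[p].to_numpy()
    for a, b, gamma in interactions:
        y = y + gamma * (X[a] * X[b]).to_numpy()
    y = y + rng.normal(0.0, noise_sd, size=n_episodes)
    return X, y
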