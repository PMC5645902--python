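"""Hold-out testing and descriptive comparisons of the index.

A random 90% of episodes (the learning sample) drives ranking,
normalization and model fitting; the held-out 10% is ranked and normalized
on its own, without reference to the learning sample, and the fitted
models' predictions are compared with that independent ranking score
through residual summaries.  The module also computes score quartiles and
the remission proxy (an antidepressant-free gap of 45 days or more during
follow-up), whose rate is expected to rise across index quartiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import DepressiveEpisode
from .modeling import (
    DHSIModel,
    derive_interactions,
    fit_improved_model,
    fit_initial_model,
    grow_interaction_tree,
    predict_frame,
)
from .scoring import ALL_PARAMETERS, WeightScheme, DEFAULT_WEIGHT_SCHEME, score_episodes

__all__ = [
    "SplitAssignment",
    "ResidualSummary",
    "split_learning_test",
    "evaluate_on_test",
    "remission_proxy",
    "quartile_report",
    "learning_test_evaluation",
    "REMISSION_GAP_DAYS",
]

REMISSION_GAP_DAYS = 45


@dataclass(frozen=True)
class SplitAssignment:
    learning_ids: tuple
    test_ids: tuple
    seed: int
    learning_fraction: float

    def assignment(self) -> dict:
        out = {e: "learning" for e in self.learning_ids}
        out.update({e: "test" for e in self.test_ids})
        return out


@dataclass(frozen=True)
class ResidualSummary:
    residual_se: float
    mean: float
    median: float
    iqr_low: float
    iqr_high: float
    min: float
    max: float


def split_learning_test(
    episode_ids: Sequence, fraction: float = 0.9, seed: int = 0
) -> SplitAssignment:
    """Uniform random partition into learning and test samples.

    ``|test| = round((1 - fraction) * n)``; deterministic given the seed.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    ids = list(episode_ids)
    n = len(ids)
    if n < 10:
        raise ValueError("need at least 10 episodes for a meaningful split")
    rng = np.random.default_rng(seed)
    n_test = int(round((1.0 - fraction) * n))
    test_idx = set(rng.choice(n, size=n_test, replace=False).tolist())
    test = tuple(ids[i] for i in range(n) if i in test_idx)
    learning = tuple(ids[i] for i in range(n) if i not in test_idx)
    return SplitAssignment(
        learning_ids=learning, test_ids=test, seed=seed, learning_fraction=fraction
    )


def evaluate_on_test(
    model: DHSIModel, test_matrix: pd.DataFrame, test_dhsi
) -> ResidualSummary:
    """Residuals of the model against the test sample's own ranking score.

    ``residual = ranking score - predicted score``.  The residual SE is
    sqrt(sum(r^2)/(n-1)), i.e. dispersion about zero rather than about the
    residual mean, with no model degrees of freedom subtracted out of
    sample.
    """
    if len(test_matrix) == 0:
        raise ValueError("empty test set")
    predicted = predict_frame(model, test_matrix)
    resid = np.asarray(test_dhsi, dtype=float) - predicted
    n = len(resid)
    se = float(np.sqrt(np.sum(resid**2) / (n - 1))) if n > 1 else 0.0
    return ResidualSummary(
        residual_se=se,
        mean=float(np.mean(resid)),
        median=float(np.median(resid)),
        iqr_low=float(np.percentile(resid, 25)),
        iqr_high=float(np.percentile(resid, 75)),
        min=float(np.min(resid)),
        max=float(np.max(resid)),
    )


def remission_proxy(episode: DepressiveEpisode, events: pd.DataFrame) -> bool:
    """Antidepressant-free gap of >= 45 days during follow-up.

    Prescription coverage runs from the prescription date to date +
    coverage_days; gaps abutting the follow-up window edges count, and the
    45-day bound is inclusive.
    """
    fs, fe = episode.followup_start, episode.followup_end
    pdf = events[events["patient_id"].astype(str) == str(episode.patient_id)]
    ads = pdf[pdf["event_type"] == "ad_prescription"].copy()
    spans = []
    for _, row in ads.iterrows():
        d = pd.Timestamp(row["date"]).date()
        cov = 0 if pd.isna(row.get("coverage_days")) else int(row["coverage_days"])
        start, end = d, d + timedelta(days=cov)
        if end < fs or start > fe:
            continue
        spans.append((max(start, fs), min(end, fe)))
    spans.sort()
    merged: list[tuple] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    cursor = fs
    for s, e in merged:
        if (s - cursor).days >= REMISSION_GAP_DAYS:
            return True
        cursor = max(cursor, e)
    return (fe - cursor).days >= REMISSION_GAP_DAYS


def quartile_report(scores, remission_flags) -> pd.DataFrame:
    """Episode counts, score ranges and remission rates by score quartile.

    Boundaries sit at the empirical 25/50/75 percentiles; episodes tied
    with a boundary fall in the lower quartile.  A warning is attached
    (``df.attrs['degenerate']``) when fewer than four distinct scores
    exist, in which case some quartiles may be empty.
    """
    scores = np.asarray(scores, dtype=float)
    flags = np.asarray(remission_flags, dtype=float)
    if len(scores) < 4:
        raise ValueError("quartile report needs at least 4 episodes")
    if len(scores) != len(flags):
        raise ValueError("scores and remission flags differ in length")
    q1, q2, q3 = np.percentile(scores, [25, 50, 75])
    group = np.select(
        [scores <= q1, scores <= q2, scores <= q3], [0, 1, 2], default=3
    )
    rows = []
    n = len(scores)
    for g in range(4):
        m = group == g
        count = int(m.sum())
        rows.append(
            {
                "quartile": f"Q{g + 1}",
                "n_episodes": count,
                "percent": 100.0 * count / n,
                "score_low": float(scores[m].min()) if count else float("nan"),
                "score_high": float(scores[m].max()) if count else float("nan"),
                "remission_rate": float(flags[m].mean()) if count else float("nan"),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["degenerate"] = bool(len(np.unique(scores)) < 4)
    return df


def learning_test_evaluation(
    matrix: pd.DataFrame,
    seed: int = 0,
    fraction: float = 0.9,
    min_node_size: int = 50,
    delta_r2: float = 0.01,
    weights: Optional[WeightScheme] = None,
) -> dict:
    """End-to-end hold-out evaluation on an episode-by-parameter matrix.

    Splits the episodes 90/10, scores each sample by its own ranking,
    fits the initial and improved models on the learning sample, and
    summarizes both models' residuals on the test sample.
    """
    w = weights or DEFAULT_WEIGHT_SCHEME
    df = matrix.set_index("episode_id") if "episode_id" in matrix.columns else matrix
    split = split_learning_test(list(df.index), fraction=fraction, seed=seed)

    learn = df.loc[list(split.learning_ids), list(ALL_PARAMETERS)]
    test = df.loc[list(split.test_ids), list(ALL_PARAMETERS)]

    learn_scores = score_episodes(learn, w).set_index("episode_id")
    test_scores = score_episodes(test, w).set_index("episode_id")
    y_learn = learn_scores.loc[list(split.learning_ids), "dhsi"].to_numpy()
    y_test = test_scores.loc[list(split.test_ids), "dhsi"].to_numpy()

    initial = fit_initial_model(learn, y_learn)
    tree = grow_interaction_tree(
        learn, y_learn, min_node_size=min_node_size, delta_r2=delta_r2
    )
    interactions = derive_interactions(tree)
    improved = fit_improved_model(learn, y_learn, interactions)

    return {
        "split": split,
        "initial_model": initial,
        "improved_model": improved,
        "tree": tree,
        "interactions": interactions,
        "learning_scores": learn_scores,
        "test_scores": test_scores,
        "initial_residuals": evaluate_on_test(initial, test, y_test),
        "improved_residuals": evaluate_on_test(improved, test, y_test),
    }
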