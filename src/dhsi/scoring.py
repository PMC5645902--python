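"""Lexicographic weighting, dual ranking and 0-100 normalization.

The index aggregates 29 binary parameters describing a depressive episode:
10 with a presumed positive impact on the health state (X1-X10) and 19 with
a presumed negative impact (Y1-Y19).  Each parameter carries a weight
``value_code * 6**exponent`` where the exponent encodes its ordered class
(base 6 because no class holds more than six parameters) and the value code
(1-3) orders parameters within a class.  Present positive parameters sum to
a positive pre-score, present negative parameters to a negative pre-score;
episodes are then ranked ascending on the positive pre-score and descending
on the negative one, the two ranks averaged, and the mean rank linearly
rescaled to [0, 100] (0 = worst health state, 100 = best).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "POSITIVE_PARAMETERS",
    "NEGATIVE_PARAMETERS",
    "ALL_PARAMETERS",
    "WeightScheme",
    "PreScores",
    "ScoredEpisode",
    "pre_scores",
    "rank_episodes",
    "normalize",
    "score_episodes",
    "dominance_report",
]

POSITIVE_PARAMETERS = tuple(f"X{i}" for i in range(1, 11))
NEGATIVE_PARAMETERS = tuple(f"Y{i}" for i in range(1, 20))
ALL_PARAMETERS = POSITIVE_PARAMETERS + NEGATIVE_PARAMETERS

# Default (value_code, exponent) per parameter: the published expert weights.
_DEFAULT_WEIGHTS: dict[str, tuple[int, int]] = {
    "X1": (3, 5), "X2": (3, 5), "X3": (3, 4), "X4": (2, 3), "X5": (2, 2),
    "X6": (1, 1), "X7": (1, 1), "X8": (1, 1), "X9": (1, 1), "X10": (1, 1),
    "Y1": (3, 10), "Y2": (3, 9), "Y3": (3, 9), "Y4": (2, 8), "Y5": (2, 8),
    "Y6": (1, 7), "Y7": (3, 6), "Y8": (2, 5), "Y9": (1, 4),
    "Y10": (2, 3), "Y11": (2, 3), "Y12": (2, 3), "Y13": (2, 3),
    "Y14": (1, 2), "Y15": (1, 1),
    "Y16": (1, 0), "Y17": (1, 0), "Y18": (1, 0), "Y19": (1, 0),
}


@dataclass(frozen=True)
class WeightScheme:
    """Per-parameter value codes and base-6 class exponents.

    ``weights[p] = value_code * 6**exponent``.  The default instance
    reproduces the published expert weighting; alternative schemes (for
    sensitivity analyses) can be loaded from YAML/JSON via :meth:`from_file`.
    """

    value_codes: Mapping[str, int] = field(
        default_factory=lambda: {p: vc for p, (vc, _) in _DEFAULT_WEIGHTS.items()}
    )
    exponents: Mapping[str, int] = field(
        default_factory=lambda: {p: e for p, (_, e) in _DEFAULT_WEIGHTS.items()}
    )

    def __post_init__(self) -> None:
        missing = set(ALL_PARAMETERS) - set(self.value_codes)
        if missing:
            raise ValueError(f"weight scheme missing parameters: {sorted(missing)}")
        for p in ALL_PARAMETERS:
            vc, e = self.value_codes[p], self.exponents[p]
            if vc not in (1, 2, 3):
                raise ValueError(f"{p}: value code {vc} not in {{1,2,3}}")
            if not 0 <= e <= 10:
                raise ValueError(f"{p}: exponent {e} outside [0, 10]")

    def weight(self, parameter: str) -> int:
        return self.value_codes[parameter] * 6 ** self.exponents[parameter]

    def sign(self, parameter: str) -> str:
        return "positive" if parameter.startswith("X") else "negative"

    @classmethod
    def from_file(cls, path) -> "WeightScheme":
        """Load a scheme from YAML (or JSON, a YAML subset).

        Expected layout: a list of mappings with keys
        ``parameter, sign, value_code, exponent``.
        """
        with open(path) as fh:
            rows = yaml.safe_load(fh)
        vcs, exps = {}, {}
        for row in rows:
            p = row["parameter"]
            expected = "positive" if p.startswith("X") else "negative"
            if row.get("sign", expected) != expected:
                raise ValueError(f"{p}: sign {row['sign']!r} contradicts prefix")
            vcs[p] = int(row["value_code"])
            exps[p] = int(row["exponent"])
        return cls(value_codes=vcs, exponents=exps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": ALL_PARAMETERS,
                "sign": [self.sign(p) for p in ALL_PARAMETERS],
                "value_code": [self.value_codes[p] for p in ALL_PARAMETERS],
                "exponent": [self.exponents[p] for p in ALL_PARAMETERS],
                "weight": [self.weight(p) for p in ALL_PARAMETERS],
            }
        )


DEFAULT_WEIGHT_SCHEME = WeightScheme()


@dataclass(frozen=True)
class PreScores:
    """Weighted sums of present positive and negative parameters."""

    positive: int
    negative: int

    def __post_init__(self) -> None:
        if self.positive < 0 or self.negative < 0:
            raise ValueError("pre-scores are non-negative by construction")


@dataclass(frozen=True)
class ScoredEpisode:
    episode_id: str
    pre_scores: PreScores
    positive_rank: float
    negative_rank: float
    mean_rank: float
    dhsi: float


def _as_flag_mapping(v) -> Mapping[str, int]:
    """Accept a mapping, a pandas Series or a length-29 sequence (X1..Y19)."""
    if isinstance(v, Mapping):
        return v
    if isinstance(v, pd.Series):
        return v.to_dict()
    seq = list(v)
    if len(seq) != len(ALL_PARAMETERS):
        raise ValueError(
            f"expected {len(ALL_PARAMETERS)} flags (X1..X10, Y1..Y19), got {len(seq)}"
        )
    return dict(zip(ALL_PARAMETERS, seq))


def pre_scores(v, w: WeightScheme = DEFAULT_WEIGHT_SCHEME) -> PreScores:
    """Sum the weights of the present parameters, separately by sign.

    Pure integer arithmetic: the largest possible positive pre-score is
    51,078 (all ten X parameters present) and the largest negative one is
    3*6**10 plus the remaining Y weights, well within exact int range.
    """
    flags = _as_flag_mapping(v)
    pos = neg = 0
    for p in ALL_PARAMETERS:
        f = int(flags[p])
        if f not in (0, 1):
            raise ValueError(f"{p}: flag {flags[p]!r} is not binary")
        if f:
            if p.startswith("X"):
                pos += w.weight(p)
            else:
                neg += w.weight(p)
    return PreScores(positive=pos, negative=neg)


def rank_episodes(
    scores: Sequence[PreScores],
) -> list[tuple[float, float, float]]:
    """Dual ranking: ascending on positive, descending on negative pre-score.

    The smallest positive pre-score gets positive rank 1; the largest
    negative pre-score gets negative rank 1.  Ties receive the mid (average)
    rank.  A higher mean rank indicates a better health state.
    """
    if len(scores) == 0:
        raise ValueError("cannot rank an empty episode set")
    pos = pd.Series([s.positive for s in scores], dtype=float)
    neg = pd.Series([s.negative for s in scores], dtype=float)
    pos_rank = pos.rank(method="average", ascending=True)
    neg_rank = neg.rank(method="average", ascending=False)
    mean_rank = (pos_rank + neg_rank) / 2.0
    return list(zip(pos_rank.tolist(), neg_rank.tolist(), mean_rank.tolist()))


def normalize(mean_ranks: Iterable[float]) -> list[float]:
    """Linear rescaling of mean ranks to [0, 100].

    The episode with the lowest mean rank maps to 0 (worst health state),
    the highest to 100.  Raises on degenerate input where every mean rank
    is equal, because no scale exists.
    """
    mr = np.asarray(list(mean_ranks), dtype=float)
    if mr.size < 2:
        raise ValueError("normalization needs at least two episodes")
    lo, hi = mr.min(), mr.max()
    if hi == lo:
        raise ValueError("all mean ranks equal: normalization is degenerate")
    return (100.0 * (mr - lo) / (hi - lo)).tolist()


def score_episodes(
    matrix: pd.DataFrame, w: WeightScheme = DEFAULT_WEIGHT_SCHEME
) -> pd.DataFrame:
    """Full scoring pipeline on an episode-by-parameter binary matrix.

    ``matrix`` must carry the 29 parameter columns; the index (or an
    ``episode_id`` column) identifies episodes.  Returns a frame with
    pre-scores, the two ranks, the mean rank and the normalized index.
    """
    df = matrix.set_index("episode_id") if "episode_id" in matrix.columns else matrix
    ps = [pre_scores(row, w) for _, row in df[list(ALL_PARAMETERS)].iterrows()]
    ranks = rank_episodes(ps)
    mean_ranks = [r[2] for r in ranks]
    dhsi = normalize(mean_ranks)
    return pd.DataFrame(
        {
            "episode_id": df.index,
            "pos_prescore": [s.positive for s in ps],
            "neg_prescore": [s.negative for s in ps],
            "pos_rank": [r[0] for r in ranks],
            "neg_rank": [r[1] for r in ranks],
            "mean_rank": mean_ranks,
            "dhsi": dhsi,
        }
    ).reset_index(drop=True)


def dominance_report(w: WeightScheme = DEFAULT_WEIGHT_SCHEME) -> pd.DataFrame:
    """Diagnostic: where a single parameter fails to outweigh the combined
    sum of all parameters in strictly lower classes of the same sign.

    The weighting preserves pairwise inter-class order (any single weight of
    exponent k+1 exceeds any single weight of exponent k, since 6 > 3), but
    not necessarily dominance over *sums* of lower classes.  This report
    makes the distinction explicit instead of altering the published
    weights.
    """
    rows = []
    for p in ALL_PARAMETERS:
        sign = w.sign(p)
        same_sign = [q for q in ALL_PARAMETERS if w.sign(q) == sign and q != p]
        lower_sum = sum(
            w.weight(q) for q in same_sign if w.exponents[q] < w.exponents[p]
        )
        rows.append(
            {
                "parameter": p,
                "weight": w.weight(p),
                "sum_of_lower_classes": lower_sum,
                "dominates_lower_sum": w.weight(p) > lower_sum or lower_sum == 0,
            }
        )
    return pd.DataFrame(rows)
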