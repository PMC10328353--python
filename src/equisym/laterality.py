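"""Forelimb preference-test scoring.

A preference test records, over repeated approaches to a feed bucket, which
forelimb the horse keeps protracted while feeding.  Valid observations are
labelled LEFT or RIGHT; side preference is judged per horse by an exact
binomial test against a fair-coin null of 0.5.  The module implements the
laterality index, the exact two-sided binomial p-value, the critical count
(e.g. 12 of 15 at the 5% level), and the early-stopping rule that admits a
horse with fewer than the target number of valid observations whenever no
possible completion of the run could change its classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PreferenceRecord",
    "LateralityResult",
    "laterality_index",
    "binomial_two_sided_p",
    "critical_count",
    "early_stop_decision",
    "classify_preference",
    "PreferenceTestModel",
    "PreferenceTestResults",
]

LEFT = "LEFT"
RIGHT = "RIGHT"


@dataclass
class PreferenceRecord:
    """Ordered valid observations of one horse's preference test."""

    horse_id: str
    observations: List[str] = field(default_factory=list)
    n_invalid: int = 0

    def __post_init__(self) -> None:
        bad = {o for o in self.observations} - {LEFT, RIGHT}
        if bad:
            raise ValueError(f"observations must be LEFT or RIGHT, got {sorted(bad)}")

    @property
    def n_left(self) -> int:
        return sum(1 for o in self.observations if o == LEFT)

    @property
    def n_right(self) -> int:
        return sum(1 for o in self.observations if o == RIGHT)

    @property
    def n_valid(self) -> int:
        return len(self.observations)


@dataclass
class LateralityResult:
    """Per-horse preference-test outcome.

    ``li`` is the laterality index in [-100, 100] (positive = rightward),
    ``p_value`` the exact two-sided binomial p at the actual number of valid
    observations, ``classification`` 'positive' (p < alpha, or decided by the
    early-stopping rule) or 'negative', and ``side`` the preferred side for
    positive horses.  Horses with too few valid observations and an
    undecidable outcome are flagged ``excluded`` rather than classified.
    """

    horse_id: str
    li: float
    p_value: float
    classification: Optional[str]
    side: str
    n_valid: int
    n_left: int
    n_right: int
    excluded: bool = False
    exclusion_reason: Optional[str] = None


def laterality_index(n_left: int, n_right: int) -> float:
    """100 * (nR - nL) / (nR + nL); positive indexes are rightward."""
    total = n_left + n_right
    if total < 1:
        raise ValueError("no valid observations")
    return 100.0 * (n_right - n_left) / total


def binomial_two_sided_p(k: int, n: int) -> float:
    """Exact two-sided p-value of k successes in n trials against p = 0.5.

    Defined as twice the smaller tail, capped at 1; for the symmetric null
    this coincides with the minimum-likelihood two-sided definition used by
    R's ``binom.test``.
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"require 0 <= k <= n with n >= 1, got k={k}, n={n}")
    lower = stats.binom.cdf(k, n, 0.5)
    upper = stats.binom.sf(k - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


def critical_count(n: int, alpha: float = 0.05) -> Optional[int]:
    """Smallest count k of same-side observations out of n that is significant.

    Returns None when even a unanimous run is not significant at ``alpha``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    for k in range(math.ceil(n / 2), n + 1):
        if binomial_two_sided_p(k, n) < alpha:
            return k
    return None


def early_stop_decision(
    n_left: int, n_right: int, target_n: int = 15, alpha: float = 0.05
) -> str:
    """Decide whether a partial run already determines the classification.

    Considers every completion of the run to ``target_n`` valid observations:
    'decided_positive' if each one is significant, 'decided_negative' if none
    is, 'undecided' otherwise.  Equivalently, with critical count k* at
    ``target_n``: positive when max(nL, nR) >= k*, negative when even
    awarding every remaining observation to the leading side stays below k*.
    """
    if n_left < 0 or n_right < 0:
        raise ValueError("counts must be non-negative")
    done = n_left + n_right
    if done > target_n:
        raise ValueError(f"nL + nR = {done} exceeds target_n = {target_n}")
    k_star = critical_count(target_n, alpha)
    if k_star is None:
        return "decided_negative"
    remaining = target_n - done
    if max(n_left, n_right) >= k_star:
        return "decided_positive"
    if max(n_left, n_right) + remaining < k_star:
        return "decided_negative"
    return "undecided"


def classify_preference(
    record: PreferenceRecord, alpha: float = 0.05, target_n: int = 15
) -> LateralityResult:
    """Score one preference test: LI, exact binomial p and classification.

    A horse with at least ``target_n`` valid observations is classified by
    the binomial test at its actual count.  A shorter run is included only
    when the early-stopping rule already decides the outcome; otherwise the
    horse is excluded.  The reported p-value is always computed at the
    actual number of valid observations.
    """
    n_l, n_r = record.n_left, record.n_right
    n_valid = n_l + n_r
    if n_valid == 0:
        return LateralityResult(
            horse_id=record.horse_id, li=float("nan"), p_value=float("nan"),
            classification=None, side="none", n_valid=0, n_left=0, n_right=0,
            excluded=True, exclusion_reason="no valid observations",
        )
    li = laterality_index(n_l, n_r)
    p = binomial_two_sided_p(n_r, n_valid)
    if n_valid >= target_n:
        positive = p < alpha
    else:
        decision = early_stop_decision(n_l, n_r, target_n, alpha)
        if decision == "undecided":
            return LateralityResult(
                horse_id=record.horse_id, li=li, p_value=p, classification=None,
                side="none", n_valid=n_valid, n_left=n_l, n_right=n_r,
                excluded=True,
                exclusion_reason=(
                    f"only {n_valid} valid observations and outcome undecided"
                ),
            )
        positive = decision == "decided_positive"
    if positive:
        side = "right" if n_r > n_l else "left"
    else:
        side = "none"
    return LateralityResult(
        horse_id=record.horse_id, li=li, p_value=p,
        classification="positive" if positive else "negative", side=side,
        n_valid=n_valid, n_left=n_l, n_right=n_r,
    )


class PreferenceTestModel:
    """Preference tests for a cohort, statsmodels-style.

    Parameters
    ----------
    records : sequence of PreferenceRecord
    alpha : significance level of the exact binomial test (default 0.05).
    target_n : valid observations aimed for per horse (default 15).
    """

    def __init__(
        self,
        records: Sequence[PreferenceRecord],
        alpha: float = 0.05,
        target_n: int = 15,
    ):
        self.records = list(records)
        self.alpha = alpha
        self.target_n = target_n

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "PreferenceTestModel":
        """Build from a long table with columns horse_id, obs_index, label, valid."""
        records = []
        for horse_id, grp in df.groupby("horse_id", sort=True):
            grp = grp.sort_values("obs_index")
            valid = grp["valid"].astype(int) == 1
            obs = [str(l).upper() for l in grp.loc[valid, "label"]]
            records.append(
                PreferenceRecord(
                    horse_id=str(horse_id),
                    observations=obs,
                    n_invalid=int((~valid).sum()),
                )
            )
        return cls(records, **kwargs)

    def fit(self) -> "PreferenceTestResults":
        rows = [classify_preference(r, self.alpha, self.target_n) for r in self.records]
        return PreferenceTestResults(self, rows)


class PreferenceTestResults:
    """Fitted preference-test results for a cohort."""

    def __init__(self, model: PreferenceTestModel, results: List[LateralityResult]):
        self.model = model
        self.results = results
        self.frame = pd.DataFrame(
            [
                {
                    "horse_id": r.horse_id,
                    "n_valid": r.n_valid,
                    "n_left": r.n_left,
                    "n_right": r.n_right,
                    "li": r.li,
                    "p_value": r.p_value,
                    "classification": r.classification,
                    "side": r.side,
                    "excluded": r.excluded,
                    "exclusion_reason": r.exclusion_reason,
                }
                for r in results
            ]
        )

    @property
    def included(self) -> pd.DataFrame:
        return self.frame[~self.frame["excluded"]]

    @property
    def positive_rate(self) -> float:
        inc = self.included
        if len(inc) == 0:
            return float("nan")
        return float((inc["classification"] == "positive").mean())

    def group_table(self, tas: Optional[pd.Series] = None) -> pd.DataFrame:
        """Descriptive table per classification group (and side among positives).

        ``tas`` optionally maps horse_id to the total asymmetry score of the
        gait trial run alongside the preference test; absolute LI values are
        summarized, as in the descriptive reporting convention.
        """
        inc = self.included.copy()
        inc["abs_li"] = inc["li"].abs()
        if tas is not None:
            inc = inc.merge(
                tas.rename("tas"), left_on="horse_id", right_index=True, how="left"
            )
        groups = {
            "positive": inc[inc["classification"] == "positive"],
            "right_sided": inc[inc["side"] == "right"],
            "left_sided": inc[inc["side"] == "left"],
            "negative": inc[inc["classification"] == "negative"],
        }
        rows = []
        for name, g in groups.items():
            row = {
                "group": name,
                "n": len(g),
                "mean_li": g["abs_li"].mean() if len(g) else np.nan,
                "sd_li": g["abs_li"].std(ddof=1) if len(g) > 1 else np.nan,
            }
            if tas is not None:
                row["mean_tas"] = g["tas"].mean() if len(g) else np.nan
                row["sd_tas"] = g["tas"].std(ddof=1) if len(g) > 1 else np.nan
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        inc = self.included
        n_pos = int((inc["classification"] == "positive").sum())
        lines = [
            "Preference test results",
            "=" * 47,
            f"Horses tested:        {len(self.frame)}",
            f"Included:             {len(inc)}",
            f"Excluded:             {int(self.frame['excluded'].sum())}",
            f"Positive (p < {self.model.alpha:g}):   {n_pos}"
            f" ({100.0 * self.positive_rate:.1f}% of included)"
            if len(inc) else "Positive:             0",
            f"  right-sided:        {int((inc['side'] == 'right').sum())}",
            f"  left-sided:         {int((inc['side'] == 'left').sum())}",
        ]
        return "\n".join(lines)
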