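"""Vertical movement asymmetry quantification.

At trot the head and pelvis each describe two vertical oscillations per
stride, one per diagonal stance phase.  The per-stride differences between
the two displacement minima and the two maxima — HDmin, HDmax for the head,
PDmin, PDmax for the pelvis — quantify asymmetry: negative values attribute
the asymmetry to the left limb, positive to the right.  Trial means of these
parameters are classified against clinical thresholds (|6| mm head, |3| mm
pelvis, with the stride SD required to stay within 100% of the mean), after
iterative removal of outlier strides (three-or-more SDs from the mean,
repeated to a fixpoint; head parameters only).  The Total Asymmetry Score
collapses the four means into one non-negative scalar with head terms
down-weighted to the pelvic threshold scale:

    TAS = |HDmin|/2 + |HDmax|/2 + |PDmin| + |PDmax|
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .config import ThresholdConfig
from .simulate import PARAMS, TrialSignal

__all__ = [
    "StrideWindow",
    "TrialSummary",
    "segment_strides",
    "extract_stride_parameters",
    "remove_outliers",
    "outlier_mask",
    "classify_parameter",
    "total_asymmetry_score",
    "summarize_trial",
    "summarize_trials",
    "mirror_stride_table",
    "GaitAsymmetryModel",
    "GaitAsymmetryResults",
]

logger = logging.getLogger(__name__)

HEAD_PARAMS = ("hdmin", "hdmax")
PELVIS_PARAMS = ("pdmin", "pdmax")


@dataclass
class StrideWindow:
    """One stride bounded by successive right-forelimb stance events.

    Each half-cycle slice carries (time, head_z, pelvis_z) samples; the
    right half starts at the right-forelimb stance, the left half at the
    following left-forelimb stance.
    """

    stride_index: int
    duration: float
    right: Dict[str, np.ndarray]
    left: Dict[str, np.ndarray]


def segment_strides(signal: TrialSignal) -> List[StrideWindow]:
    """Split a trial signal into stride windows with half-cycle labels.

    Strides are bounded by successive right-forelimb stance events; a
    trailing incomplete stride is discarded.  Raises on non-monotone or
    non-alternating stance annotations and when fewer than two right-fore
    events are present.
    """
    events = signal.stance_events
    times = np.array([t for t, _ in events])
    if np.any(np.diff(times) <= 0):
        raise ValueError("stance events are not strictly increasing in time")
    right_idx = [i for i, (_, limb) in enumerate(events) if limb == "right_fore"]
    if len(right_idx) < 2:
        raise ValueError("insufficient strides: need at least 2 right-forelimb events")

    t = signal.time
    windows: List[StrideWindow] = []
    for k, (i0, i1) in enumerate(zip(right_idx, right_idx[1:])):
        if i1 != i0 + 2:
            raise ValueError("stance events must alternate right_fore/left_fore")
        t_r, t_l, t_end = times[i0], times[i0 + 1], times[i1]
        sel_r = (t >= t_r) & (t < t_l)
        sel_l = (t >= t_l) & (t < t_end)
        windows.append(
            StrideWindow(
                stride_index=k,
                duration=float(t_end - t_r),
                right={
                    "time": t[sel_r], "head_z": signal.head_z[sel_r],
                    "pelvis_z": signal.pelvis_z[sel_r],
                },
                left={
                    "time": t[sel_l], "head_z": signal.head_z[sel_l],
                    "pelvis_z": signal.pelvis_z[sel_l],
                },
            )
        )
    return windows


def _interior_extrema(y: np.ndarray) -> Optional[tuple]:
    """(min, max) of a half-cycle, requiring both to be interior samples."""
    if len(y) < 3:
        return None
    i_min, i_max = int(np.argmin(y)), int(np.argmax(y))
    if i_min in (0, len(y) - 1) or i_max in (0, len(y) - 1):
        return None
    return float(y[i_min]), float(y[i_max])


def extract_stride_parameters(windows: Sequence[StrideWindow]) -> pd.DataFrame:
    """Per-stride asymmetry parameters from segmented stride windows.

    hdmin is the head minimum in the right half-cycle minus the head minimum
    in the left half-cycle; hdmax the analogous difference of the maxima
    following each stance; pdmin/pdmax the same on the pelvis signal.
    Strides whose half-cycles lack an interior extremum are skipped and
    logged.
    """
    rows = []
    for w in windows:
        ext = {}
        ok = True
        for body, key in (("hd", "head_z"), ("pd", "pelvis_z")):
            for side in ("right", "left"):
                e = _interior_extrema(getattr(w, side)[key])
                if e is None:
                    ok = False
                    break
                ext[f"{body}_{side}"] = e
            if not ok:
                break
        if not ok:
            logger.warning(
                "stride %d skipped: no interior extremum in a half-cycle",
                w.stride_index,
            )
            continue
        rows.append(
            {
                "stride_index": w.stride_index,
                "hdmin": ext["hd_right"][0] - ext["hd_left"][0],
                "hdmax": ext["hd_right"][1] - ext["hd_left"][1],
                "pdmin": ext["pd_right"][0] - ext["pd_left"][0],
                "pdmax": ext["pd_right"][1] - ext["pd_left"][1],
                "stride_duration": w.duration,
            }
        )
    return pd.DataFrame(
        rows, columns=["stride_index", *PARAMS, "stride_duration"]
    )


def outlier_mask(values: Sequence[float], factor: float = 3.0) -> np.ndarray:
    """Boolean keep-mask of the iterative SD-based outlier rule.

    Repeatedly removes every value lying ``factor`` or more sample SDs from
    the current mean, recomputing mean and SD after each pass, until a pass
    removes nothing.  An SD of zero terminates immediately (identical values
    are all retained).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values for outlier removal")
    keep = np.ones(x.size, dtype=bool)
    while True:
        cur = x[keep]
        if cur.size == 0:
            raise ValueError("degenerate trial: all values removed as outliers")
        sd = cur.std(ddof=1) if cur.size > 1 else 0.0
        if sd == 0.0:
            return keep
        bad = keep & (np.abs(x - cur.mean()) >= factor * sd)
        if not bad.any():
            return keep
        keep &= ~bad
        if not keep.any():
            raise ValueError("degenerate trial: all values removed as outliers")


def remove_outliers(values: Sequence[float], factor: float = 3.0) -> np.ndarray:
    """Retained values, in original order, after iterative outlier removal."""
    x = np.asarray(values, dtype=float)
    return x[outlier_mask(x, factor)]


def classify_parameter(
    mean: float, sd: float, threshold: float, sd_ratio_max: float = 1.0
) -> str:
    """'asymmetric' iff |mean| strictly exceeds the threshold and sd <= sd_ratio_max*|mean|."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if abs(mean) > threshold and sd <= sd_ratio_max * abs(mean):
        return "asymmetric"
    return "symmetric"


def total_asymmetry_score(
    hdmin: float, hdmax: float, pdmin: float, pdmax: float,
    head_weight: float = 0.5, pelvis_weight: float = 1.0,
) -> float:
    """Total asymmetry score of four trial means (default head weight 1/2)."""
    return (
        head_weight * (abs(hdmin) + abs(hdmax))
        + pelvis_weight * (abs(pdmin) + abs(pdmax))
    )


@dataclass
class TrialSummary:
    """Per-trial means, SDs, classifications and total asymmetry score."""

    means: Dict[str, float]
    sds: Dict[str, float]
    n_strides_used: Dict[str, int]
    n_outliers_removed: Dict[str, int]
    classifications: Dict[str, str]
    tas: float
    any_asymmetric: bool
    surface: Optional[str] = None
    mean_stride_duration: float = float("nan")
    horse_id: Optional[str] = None
    visit: Optional[int] = None

    def to_row(self) -> Dict[str, object]:
        row: Dict[str, object] = {
            "horse_id": self.horse_id, "visit": self.visit, "surface": self.surface,
            "mean_stride_duration": self.mean_stride_duration,
        }
        for p in PARAMS:
            row[p] = self.means[p]
            row[f"{p}_sd"] = self.sds[p]
            row[f"{p}_n_used"] = self.n_strides_used[p]
            row[f"{p}_n_removed"] = self.n_outliers_removed[p]
            row[f"{p}_class"] = self.classifications[p]
        row["tas"] = self.tas
        row["any_asymmetric"] = self.any_asymmetric
        return row


def summarize_trial(
    strides: pd.DataFrame,
    surface: Optional[str] = None,
    thresholds: Optional[ThresholdConfig] = None,
    horse_id: Optional[str] = None,
    visit: Optional[int] = None,
) -> TrialSummary:
    """Mean/SD, classification and TAS for one trial's stride parameters.

    Head parameters are outlier-filtered independently per parameter before
    the mean and sample SD are taken; pelvis parameters are never filtered.
    """
    if thresholds is None:
        thresholds = ThresholdConfig()
    if len(strides) < 2:
        raise ValueError("need at least 2 strides to summarize a trial")
    means, sds, n_used, n_rem, classes = {}, {}, {}, {}, {}
    for p in PARAMS:
        x = strides[p].to_numpy(dtype=float)
        if p in HEAD_PARAMS:
            keep = outlier_mask(x, thresholds.outlier_sd_factor)
            x = x[keep]
            n_rem[p] = int((~keep).sum())
        else:
            n_rem[p] = 0
        means[p] = float(x.mean())
        sds[p] = float(x.std(ddof=1)) if x.size > 1 else 0.0
        n_used[p] = int(x.size)
        classes[p] = classify_parameter(
            means[p], sds[p], thresholds.threshold_for(p), thresholds.sd_ratio_max
        )
    tas = total_asymmetry_score(
        means["hdmin"], means["hdmax"], means["pdmin"], means["pdmax"],
        head_weight=thresholds.head_tas_weight,
    )
    return TrialSummary(
        means=means, sds=sds, n_strides_used=n_used, n_outliers_removed=n_rem,
        classifications=classes, tas=tas,
        any_asymmetric=any(c == "asymmetric" for c in classes.values()),
        surface=surface,
        mean_stride_duration=float(strides["stride_duration"].mean())
        if "stride_duration" in strides else float("nan"),
        horse_id=horse_id, visit=visit,
    )


def summarize_trials(
    stride_table: pd.DataFrame, thresholds: Optional[ThresholdConfig] = None
) -> pd.DataFrame:
    """Trial summaries for a long stride table (one row per horse x visit)."""
    rows = []
    for (horse_id, visit), grp in stride_table.groupby(["horse_id", "visit"], sort=True):
        surface = grp["surface"].iloc[0] if "surface" in grp else None
        rows.append(
            summarize_trial(
                grp, surface=surface, thresholds=thresholds,
                horse_id=str(horse_id), visit=int(visit),
            ).to_row()
        )
    return pd.DataFrame(rows)


def mirror_stride_table(stride_table: pd.DataFrame) -> pd.DataFrame:
    """Left/right mirror image of a stride table (all four parameters negated)."""
    out = stride_table.copy()
    for p in PARAMS:
        out[p] = -out[p]
    return out


class GaitAsymmetryModel:
    """Trial-level asymmetry analysis of a per-stride parameter table.

    Parameters
    ----------
    stride_table : DataFrame with columns horse_id, visit, stride_index,
        hdmin, hdmax, pdmin, pdmax, stride_duration and (optionally) surface.
    thresholds : classification and outlier-removal constants.
    """

    def __init__(self, stride_table: pd.DataFrame, thresholds: Optional[ThresholdConfig] = None):
        missing = [c for c in ("horse_id", "visit", *PARAMS) if c not in stride_table]
        if missing:
            raise ValueError(f"stride table is missing columns: {missing}")
        self.stride_table = stride_table
        self.thresholds = thresholds or ThresholdConfig()

    @classmethod
    def from_signal(
        cls,
        signal: TrialSignal,
        thresholds: Optional[ThresholdConfig] = None,
        horse_id: str = "H000",
        visit: int = 0,
    ) -> "GaitAsymmetryModel":
        """Build the model for a single trial from a raw displacement signal."""
        table = extract_stride_parameters(segment_strides(signal))
        table.insert(0, "horse_id", horse_id)
        table.insert(1, "visit", visit)
        table["surface"] = signal.surface
        return cls(table, thresholds)

    def fit(self) -> "GaitAsymmetryResults":
        return GaitAsymmetryResults(self, summarize_trials(self.stride_table, self.thresholds))


class GaitAsymmetryResults:
    """Fitted trial summaries with descriptive tables."""

    def __init__(self, model: GaitAsymmetryModel, summaries: pd.DataFrame):
        self.model = model
        self.summaries = summaries

    def percent_any_asymmetric(self) -> pd.Series:
        """Per visit, percentage of horses exceeding >= 1 threshold."""
        return 100.0 * self.summaries.groupby("visit")["any_asymmetric"].mean()

    def visit_table(self) -> pd.DataFrame:
        """Descriptive per-visit table: parameter x side rows, plus TAS.

        Means, SDs and ranges of absolute values over all horses on the
        given side; n counts horses classified asymmetric on that side.
        """
        rows = []
        for visit, grp in self.summaries.groupby("visit"):
            for p in PARAMS:
                for side, sel in (("R", grp[p] > 0), ("L", grp[p] < 0)):
                    vals = grp.loc[sel, p].abs()
                    n_over = int(
                        ((grp[f"{p}_class"] == "asymmetric") & sel).sum()
                    )
                    rows.append(
                        {
                            "visit": visit, "parameter": p.upper(), "side": side,
                            "n_over_threshold": n_over,
                            "mean": vals.mean() if len(vals) else np.nan,
                            "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                            "min": vals.min() if len(vals) else np.nan,
                            "max": vals.max() if len(vals) else np.nan,
                        }
                    )
            rows.append(
                {
                    "visit": visit, "parameter": "TAS", "side": "",
                    "n_over_threshold": len(grp),
                    "mean": grp["tas"].mean(),
                    "sd": grp["tas"].std(ddof=1) if len(grp) > 1 else np.nan,
                    "min": grp["tas"].min(), "max": grp["tas"].max(),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        pct = self.percent_any_asymmetric()
        lines = [
            "Gait asymmetry summary",
            "=" * 47,
            f"Trials:  {len(self.summaries)}   "
            f"Horses: {self.summaries['horse_id'].nunique()}",
            f"Thresholds: head |{self.model.thresholds.head_threshold:g}| mm, "
            f"pelvis |{self.model.thresholds.pelvis_threshold:g}| mm",
            "Horses exceeding >= 1 threshold per visit:",
        ]
        for v, x in pct.items():
            lines.append(f"  visit {v}: {x:.0f}%")
        lines.append(f"Mean TAS: {self.summaries['tas'].mean():.2f} mm")
        return "\n".join(lines)

    def plot_tas(self, by: str = "visit", ax=None):
        """Boxplot of the total asymmetry score grouped by a summary column."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        self.summaries.boxplot(column="tas", by=by, ax=ax)
        ax.set_ylabel("TAS (mm)")
        return ax
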