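"""Correlation stage: visit agreement, questionnaire contrasts, side agreement.

Four analyses relate the objective asymmetry measurements to each other and
to the subjective data:

* ``icc_absolute_average`` — visit-to-visit agreement of a parameter as the
  intraclass correlation from a two-way random-effects ANOVA, absolute
  agreement, average of k measurements (ICC(A,k)).
* ``fit_lmm_contrast`` — random-intercept linear mixed models of absolute
  asymmetry values on binary (or ordinal) questionnaire answers, adjusting
  for surface and mean stride duration, with a Box-Cox transform applied
  when residuals are skewed.
* ``side_specific_agreement`` — contingency agreement between the answered
  side and the side of threshold-exceeding parameters: sensitivity,
  specificity, Cramér's V and Fisher's exact p.
* ``correlate_li_asymmetry`` — Pearson correlation of the laterality index
  with each asymmetry parameter and TAS, on absolute and on signed values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import ThresholdConfig
from .simulate import ANSWER_SETS, MISSING_ANSWER, PARAMS

__all__ = [
    "ICCResult",
    "ContrastResult",
    "AgreementResult",
    "icc_absolute_average",
    "binarize_response",
    "boxcox_transform",
    "fit_lmm_contrast",
    "contrast_table",
    "side_specific_agreement",
    "cramers_v",
    "correlate_li_asymmetry",
    "QUESTION_PARAM_MAP",
    "SidednessAssociationModel",
    "SidednessAssociationResults",
]

#: which asymmetry responses each questionnaire question is modelled against
QUESTION_PARAM_MAP: Dict[str, tuple] = {
    "q1": ("tas",),
    "q2a": ("pdmin", "pdmax"),
    "q2b": ("pdmin", "pdmax"),
    "q3": PARAMS,
    "q4": ("hdmin", "hdmax"),
    "q5": PARAMS,
}

ORDINAL_QUESTIONS = ("q1", "q2b")


# ---------------------------------------------------------------------------
# ICC

@dataclass
class ICCResult:
    """ICC(A,k) with its ANOVA decomposition and F-test."""

    icc: float
    f_stat: float
    p_value: float
    n_subjects: int
    k_visits: int
    ms_rows: float
    ms_cols: float
    ms_error: float


def icc_absolute_average(values) -> ICCResult:
    """Intraclass correlation, two-way random effects, absolute agreement,
    average of k measurements.

    ``values`` is a complete subjects x visits matrix.  From the two-way
    ANOVA mean squares (MSR rows/subjects, MSC columns/visits, MSE residual):

        ICC(A,k) = (MSR - MSE) / (MSR + (MSC - MSE) / n)

    with F = MSR/MSE on (n-1, (n-1)(k-1)) degrees of freedom.
    Missing cells are rejected; filter to complete cases first.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValueError("values must be a 2-D subjects x visits matrix")
    if np.isnan(x).any():
        raise ValueError(
            "matrix contains missing cells; filter to complete cases first"
        )
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 visits")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (msc - mse) / n
    icc = (msr - mse) / denom if denom != 0 else float("nan")
    f = msr / mse if mse > 0 else float("inf")
    p = float(stats.f.sf(f, n - 1, (n - 1) * (k - 1))) if np.isfinite(f) else 0.0
    return ICCResult(
        icc=float(icc), f_stat=float(f), p_value=p, n_subjects=n, k_visits=k,
        ms_rows=float(msr), ms_cols=float(msc), ms_error=float(mse),
    )


# ---------------------------------------------------------------------------
# questionnaire handling

_YES_TOKENS = {"left", "right"}
_NO_TOKENS = {"no", "none"}
_MISSING_TOKENS = {
    MISSING_ANSWER, "no perception", "did not answer", "missing", "",
}


def binarize_response(answer) -> Optional[str]:
    """LEFT/RIGHT -> 'YES'; no/none -> 'NO'; missing answers -> None.

    Unknown tokens raise, naming the token.
    """
    if answer is None or (isinstance(answer, float) and np.isnan(answer)):
        return None
    token = str(answer).strip().lower()
    if token in _YES_TOKENS:
        return "YES"
    if token in _NO_TOKENS:
        return "NO"
    if token in _MISSING_TOKENS:
        return None
    raise ValueError(f"unknown questionnaire answer token: {answer!r}")


def boxcox_transform(y, offset: float = 0.0):
    """Box-Cox transform with maximum-likelihood lambda.

    ``offset`` is added first (used to lift zero asymmetry values off zero);
    all values must then be strictly positive.  Returns (transformed, lambda).
    """
    y = np.asarray(y, dtype=float) + offset
    if np.any(y <= 0):
        raise ValueError("Box-Cox requires strictly positive values (after offset)")
    transformed, lam = stats.boxcox(y)
    return transformed, float(lam)


@dataclass
class ContrastResult:
    """YES-NO contrast (or across-group F-test) of one model.

    ``estimate``/``se``/``p_value`` are on the transformed scale when
    ``transform_lambda`` is not None.  ``kind`` is 'contrast' for binary
    questions and 'anova' for ordinal ones (joint test across answer
    levels).  ``df_method`` records how the test statistic was referenced.
    """

    estimate: float
    se: float
    p_value: float
    response_parameter: str
    question_id: str
    transform_lambda: Optional[float]
    kind: str = "contrast"
    df_method: str = "wald"
    degenerate: bool = False
    singular: bool = False
    n_obs: int = 0
    n_horses: int = 0


def _prepare_lmm_frame(
    records: pd.DataFrame, response: str, question: str
) -> pd.DataFrame:
    df = records.copy()
    df["y"] = df[response].abs()
    if question in ORDINAL_QUESTIONS:
        levels = ANSWER_SETS[question]
        ans = df[question].astype(str).str.strip().str.lower()
        ans = ans.where(ans.isin(levels))
        df["answer"] = pd.Categorical(ans, categories=levels, ordered=True)
    else:
        df["answer"] = df[question].map(binarize_response)
    keep = df["answer"].notna() & df["y"].notna()
    for cov in ("surface", "stride_duration"):
        if cov in df:
            keep &= df[cov].notna()
    return df.loc[keep]


def fit_lmm_contrast(
    records: pd.DataFrame,
    response: str,
    question: str,
    skew_threshold: float = 1.0,
    boxcox_offset: float = 0.1,
) -> ContrastResult:
    """Random-intercept mixed model of |response| on a questionnaire answer.

    Fixed effects: the (binary or ordinal) answer, surface and mean stride
    duration; random intercept per horse; REML estimation.  The response is
    Box-Cox transformed (after adding ``boxcox_offset`` when zeros are
    present) whenever the untransformed model's residual skewness exceeds
    ``skew_threshold`` in magnitude.  For binary questions the YES-NO fixed
    effect is the adjusted-means contrast; ordinal questions get a joint
    Wald test across answer levels.
    """
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    if question not in QUESTION_PARAM_MAP:
        raise ValueError(f"unknown question id {question!r}")
    if response not in QUESTION_PARAM_MAP[question]:
        raise ValueError(
            f"response {response!r} is not modelled against question {question!r}; "
            f"allowed: {QUESTION_PARAM_MAP[question]}"
        )
    df = _prepare_lmm_frame(records, response, question)
    ordinal = question in ORDINAL_QUESTIONS
    if ordinal:
        present = [l for l in ANSWER_SETS[question] if (df["answer"] == l).any()]
        df = df[df["answer"].isin(present)]
        df["answer"] = df["answer"].cat.remove_unused_categories()
        enough_levels = len(present) >= 2
    else:
        enough_levels = df["answer"].nunique() == 2
    n_horses = df["horse_id"].nunique()
    base = ContrastResult(
        estimate=float("nan"), se=float("nan"), p_value=float("nan"),
        response_parameter=response, question_id=question, transform_lambda=None,
        kind="anova" if ordinal else "contrast",
        n_obs=len(df), n_horses=n_horses,
    )
    if n_horses < 2 or not enough_levels or df["y"].nunique() < 2:
        base.degenerate = True
        base.estimate = 0.0 if df["y"].nunique() < 2 else base.estimate
        return base

    covs = [c for c in ("surface", "stride_duration") if c in df]
    terms = ["C(answer)" if ordinal else "C(answer, Treatment('NO'))"]
    terms += [f"C({c})" if df[c].dtype == object else c for c in covs]
    formula = "y ~ " + " + ".join(terms)

    def _fit(frame):
        singular = False
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            model = smf.mixedlm(formula, frame, groups=frame["horse_id"])
            fit = model.fit(reml=True)
            singular = any(issubclass(w.category, ConvergenceWarning) for w in caught)
        return fit, singular

    fit, singular = _fit(df)
    lam = None
    resid_skew = stats.skew(np.asarray(fit.resid, dtype=float))
    if abs(resid_skew) > skew_threshold:
        offset = boxcox_offset if (df["y"] <= 0).any() else 0.0
        yt, lam = boxcox_transform(df["y"], offset=offset)
        df = df.assign(y=yt)
        fit, singular = _fit(df)

    base.transform_lambda = lam
    base.singular = singular
    base.df_method = "wald"
    if ordinal:
        names = [n for n in fit.fe_params.index if n.startswith("C(answer)")]
        contrast = np.zeros((len(names), len(fit.params)))
        for i, n in enumerate(names):
            contrast[i, list(fit.params.index).index(n)] = 1.0
        wald = fit.wald_test(contrast, scalar=True)
        base.p_value = float(wald.pvalue)
        base.estimate = float("nan")
        base.se = float("nan")
    else:
        name = [n for n in fit.fe_params.index if n.startswith("C(answer")][0]
        base.estimate = float(fit.fe_params[name])
        base.se = float(fit.bse[name])
        base.p_value = float(fit.pvalues[name])
    return base


def contrast_table(records: pd.DataFrame, questions: Optional[Sequence[str]] = None,
                   **kwargs) -> pd.DataFrame:
    """Contrast/ANOVA results for every question-response pairing."""
    questions = questions or list(QUESTION_PARAM_MAP)
    rows = []
    for q in questions:
        for p in QUESTION_PARAM_MAP[q]:
            r = fit_lmm_contrast(records, p, q, **kwargs)
            rows.append(
                {
                    "question": q, "response": p.upper(), "kind": r.kind,
                    "estimate": r.estimate, "se": r.se, "p_value": r.p_value,
                    "lambda": r.transform_lambda, "n_obs": r.n_obs,
                    "degenerate": r.degenerate, "singular": r.singular,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# contingency agreement

def cramers_v(table) -> float:
    """Cramér's V of an r x c contingency table: sqrt(chi2/(N*(min(r,c)-1)))."""
    t = np.asarray(table, dtype=float)
    n = t.sum()
    if n == 0 or min(t.shape) < 2:
        return float("nan")
    chi2 = stats.chi2_contingency(t, correction=False)[0]
    return float(np.sqrt(chi2 / (n * (min(t.shape) - 1))))


@dataclass
class AgreementResult:
    """Answer-side vs parameter-side contingency agreement."""

    table: pd.DataFrame
    sensitivity: float
    specificity: float
    cramers_v: float
    fisher_p: float
    p_method: str = "fisher"


def _parameter_side(row, parameters, thresholds: ThresholdConfig) -> str:
    """Side of the largest threshold-exceeding parameter, or 'none'."""
    from .asymmetry import classify_parameter

    best, best_mag = "none", 0.0
    for p in parameters:
        mean = row[p]
        sd = row.get(f"{p}_sd", 0.0)
        if classify_parameter(mean, sd, thresholds.threshold_for(p),
                              thresholds.sd_ratio_max) == "asymmetric":
            if abs(mean) > best_mag:
                best_mag = abs(mean)
                best = "right" if mean > 0 else "left"
    return best


def side_specific_agreement(
    records: pd.DataFrame,
    question: str,
    thresholds: Optional[ThresholdConfig] = None,
    parameters: Sequence[str] = ("pdmin", "pdmax"),
) -> AgreementResult:
    """Agreement between an answered side and the side of a threshold-exceeding
    parameter.

    Sensitivity is the fraction of parameter-positive records (any of
    ``parameters`` exceeding its threshold) whose answer is YES; specificity
    the fraction of parameter-negative records answered NO.  Cramér's V and
    Fisher's exact p are computed on the side cross-tabulation (answers
    no/left/right vs parameter none/left/right); Fisher's test falls back to
    the chi-square p for tables larger than 2 x 2 (flagged in ``p_method``).
    Empty margins yield NaN metrics rather than an exception.
    """
    thresholds = thresholds or ThresholdConfig()
    df = records.copy()
    answers = df[question].map(
        lambda a: str(a).strip().lower()
        if binarize_response(a) is not None else None
    )
    df = df.assign(answer=answers).dropna(subset=["answer"])
    df["param_side"] = df.apply(
        _parameter_side, axis=1, parameters=parameters, thresholds=thresholds
    )
    answer_yes = df["answer"].isin(_YES_TOKENS)
    param_pos = df["param_side"] != "none"
    tp = int((answer_yes & param_pos).sum())
    tn = int((~answer_yes & ~param_pos).sum())
    sens = tp / param_pos.sum() if param_pos.sum() else float("nan")
    spec = tn / (~param_pos).sum() if (~param_pos).sum() else float("nan")

    table = pd.crosstab(df["answer"], df["param_side"])
    v = cramers_v(table) if table.size else float("nan")
    if table.shape == (2, 2):
        fisher_p = float(stats.fisher_exact(table.to_numpy())[1])
        p_method = "fisher"
    elif min(table.shape) >= 2:
        fisher_p = float(stats.chi2_contingency(table.to_numpy(), correction=False)[1])
        p_method = "chi2"
    else:
        fisher_p = float("nan")
        p_method = "undefined"
    return AgreementResult(
        table=table, sensitivity=float(sens), specificity=float(spec),
        cramers_v=v, fisher_p=fisher_p, p_method=p_method,
    )


# ---------------------------------------------------------------------------
# LI vs asymmetry correlation

def correlate_li_asymmetry(joined: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations of LI with each parameter and TAS.

    ``joined`` holds one row per horse with columns ``li``, the four
    parameters and ``tas``.  Each variable pair is tested twice: on absolute
    values (magnitude association) and on signed values (side-specific
    association).  Zero-variance variables yield NaN, flagged in ``defined``.
    """
    if len(joined) < 3:
        raise ValueError("need at least 3 joined records for correlation")
    rows = []
    for p in (*PARAMS, "tas"):
        row = {"parameter": p.upper()}
        for variant, (x, y) in {
            "abs": (joined["li"].abs(), joined[p].abs()),
            "signed": (joined["li"], joined[p]),
        }.items():
            if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
                row[f"r_{variant}"] = float("nan")
                row[f"p_{variant}"] = float("nan")
                row["defined"] = False
            else:
                r, pval = stats.pearsonr(x, y)
                row[f"r_{variant}"] = float(r)
                row[f"p_{variant}"] = float(pval)
                row.setdefault("defined", True)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model facade

class SidednessAssociationModel:
    """Associations between objective asymmetry and subjective sidedness.

    Parameters
    ----------
    visit_records : one row per horse x visit, joining trial summaries
        (parameter means/SDs, tas, surface, mean stride duration as
        ``stride_duration``) with questionnaire answers q1..q5.
    laterality : optional per-horse table with columns horse_id, li and the
        trial summary run alongside the preference test (parameters + tas),
        enabling the LI correlation stage.
    """

    def __init__(
        self,
        visit_records: pd.DataFrame,
        laterality: Optional[pd.DataFrame] = None,
        thresholds: Optional[ThresholdConfig] = None,
    ):
        self.visit_records = visit_records
        self.laterality = laterality
        self.thresholds = thresholds or ThresholdConfig()

    def icc_table(self) -> pd.DataFrame:
        """ICC(A,k) per parameter over complete-case horse x visit matrices."""
        rows = []
        for p in PARAMS:
            wide = self.visit_records.pivot_table(
                index="horse_id", columns="visit", values=p, aggfunc="first"
            ).dropna()
            if len(wide) >= 2 and wide.shape[1] >= 2:
                r = icc_absolute_average(wide.to_numpy())
                rows.append(
                    {
                        "parameter": p.upper(), "icc": r.icc, "f": r.f_stat,
                        "p_value": r.p_value, "n_complete": r.n_subjects,
                        "k_visits": r.k_visits,
                    }
                )
        return pd.DataFrame(rows)

    def fit(self, questions: Optional[Sequence[str]] = None) -> "SidednessAssociationResults":
        contrasts = contrast_table(self.visit_records, questions)
        agreement = side_specific_agreement(
            self.visit_records, "q2a", self.thresholds, parameters=("pdmin", "pdmax")
        )
        correlations = None
        if self.laterality is not None and len(self.laterality) >= 3:
            correlations = correlate_li_asymmetry(self.laterality)
        return SidednessAssociationResults(
            self, self.icc_table(), contrasts, agreement, correlations
        )


class SidednessAssociationResults:
    """Fitted correlation-stage results."""

    def __init__(self, model, icc, contrasts, agreement, correlations):
        self.model = model
        self.icc = icc
        self.contrasts = contrasts
        self.agreement = agreement
        self.correlations = correlations

    def summary(self) -> str:
        lines = ["Sidedness association results", "=" * 47, "ICC(A,k) per parameter:"]
        for _, r in self.icc.iterrows():
            lines.append(
                f"  {r['parameter']:<6} ICC = {r['icc']:.3f}  (p = {r['p_value']:.2g},"
                f" n = {int(r['n_complete'])})"
            )
        sig = self.contrasts[
            (self.contrasts["p_value"] < 0.05) & ~self.contrasts["degenerate"]
        ]
        lines.append(
            f"Mixed-model tests: {len(self.contrasts)} fitted, "
            f"{len(sig)} significant at p < 0.05"
        )
        lines.append(
            f"Weaker-hindlimb side agreement: sensitivity {self.agreement.sensitivity:.2f},"
            f" specificity {self.agreement.specificity:.2f},"
            f" V = {self.agreement.cramers_v:.3f} (p = {self.agreement.fisher_p:.2g},"
            f" {self.agreement.p_method})"
        )
        if self.correlations is not None:
            tas = self.correlations.set_index("parameter").loc["TAS"]
            lines.append(
                f"|LI| vs TAS: r = {tas['r_abs']:.3f} (p = {tas['p_abs']:.2g})"
            )
        return "\n".join(lines)
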