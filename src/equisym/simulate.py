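"""Synthetic study generator with known ground truth.

Emulates the data-generating process of a longitudinal field study of young
riding horses: each horse carries a latent, signed vertical-asymmetry vector
(expected per-stride differences of head and pelvis displacement extrema, in
mm; negative = attributable to the left side, positive = right), a
probability of protracting the right forelimb in a preference test, and
questionnaire answer propensities.  From that truth the module generates

* trot-trial displacement waveforms with stance annotations (`synth_trial`),
* per-stride extremum-difference tables directly, marginalizing the
  waveform (`simulate_stride_table` — same extremum-level model, much
  faster; the waveform carries no extra information for the downstream
  parameters),
* preference-test observation sequences (`synth_preference_sequence`),
* per-visit questionnaire records (`synth_questionnaire`),

all reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import ConfigurationError, SimConfig
from .laterality import LEFT, RIGHT, PreferenceRecord

__all__ = [
    "CohortTruth",
    "TrialSignal",
    "StudyData",
    "make_cohort",
    "mirror_cohort",
    "synth_trial",
    "synth_preference_sequence",
    "synth_questionnaire",
    "simulate_stride_table",
    "simulate_questionnaires",
    "simulate_preferences",
    "simulate_study",
]

PARAMS = ("hdmin", "hdmax", "pdmin", "pdmax")
LATENTS = tuple("a_" + p for p in PARAMS)
MISSING_ANSWER = "no perception/did not answer"

#: answer sets of the rider questionnaire (side questions share no/left/right
#: up to the "none" wording of questions 3-5)
ANSWER_SETS: Dict[str, Tuple[str, ...]] = {
    "q1": ("no", "mild", "moderate", "severe"),
    "q2a": ("no", "left", "right"),
    "q2b": ("equally", "inner", "outer"),
    "q3": ("none", "left", "right"),
    "q4": ("none", "left", "right"),
    "q5": ("no", "left", "right"),
}

# baseline answer frequencies when the questionnaire is not linked to the
# latent asymmetry (slope = 0); grades roughly follow field-reported rates
_Q1_BASE_CUM = (0.29, 0.83, 0.97)  # cumulative P(no), P(<=mild), P(<=moderate)
_Q2B_PROBS = (0.16, 0.36, 0.48)  # equally / inner / outer


def _rng(seed, *stream) -> np.random.Generator:
    """Deterministic child generator for a named stream."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(s) for s in stream))
    )


# ---------------------------------------------------------------------------
# cohort truth

CohortTruth = pd.DataFrame
"""Per-horse ground truth: columns horse_id, a_hdmin, a_hdmax, a_pdmin,
a_pdmax (mm, signed), p_right, sidedness_grade."""


def make_cohort(config: SimConfig) -> CohortTruth:
    """Draw a cohort's latent asymmetries and laterality probabilities.

    Latent parameters are uniform on the configured head/pelvis ranges;
    p_right is uniform on ``laterality_prob_range``.  Reproducible from
    ``config.seed``.
    """
    rng = _rng(config.seed, 0)
    n = config.n_horses
    lo_h, hi_h = config.asym_range_head
    lo_p, hi_p = config.asym_range_pelvis
    lo_l, hi_l = config.laterality_prob_range
    truth = pd.DataFrame(
        {
            "horse_id": [f"H{i:03d}" for i in range(n)],
            "a_hdmin": rng.uniform(lo_h, hi_h, n),
            "a_hdmax": rng.uniform(lo_h, hi_h, n),
            "a_pdmin": rng.uniform(lo_p, hi_p, n),
            "a_pdmax": rng.uniform(lo_p, hi_p, n),
            "p_right": rng.uniform(lo_l, hi_l, n),
        }
    )
    # severity grade from the magnitude of the latent vector, on the scale of
    # the total asymmetry score (head terms halved)
    magnitude = (
        truth["a_hdmin"].abs() / 2
        + truth["a_hdmax"].abs() / 2
        + truth["a_pdmin"].abs()
        + truth["a_pdmax"].abs()
    )
    truth["sidedness_grade"] = pd.cut(
        magnitude,
        bins=[-np.inf, 4.5, 12.0, 20.0, np.inf],
        labels=["no", "mild", "moderate", "severe"],
    ).astype(str)
    return truth


def mirror_cohort(truth: CohortTruth) -> CohortTruth:
    """Left/right mirror image of a cohort: latents negated, p_right flipped."""
    out = truth.copy()
    for col in LATENTS:
        out[col] = -out[col]
    out["p_right"] = 1.0 - out["p_right"]
    return out


# ---------------------------------------------------------------------------
# trial signals

@dataclass
class TrialSignal:
    """One straight-line trot trial: sampled displacement plus annotations.

    ``stance_events`` are (time, limb) pairs, limb in {right_fore,
    left_fore}, strictly increasing and alternating; ``true_extrema`` holds
    the generator's designed per-stride extremum values for recovery tests.
    """

    time: np.ndarray
    head_z: np.ndarray
    pelvis_z: np.ndarray
    stance_events: List[Tuple[float, str]]
    surface: str
    true_extrema: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        times = [t for t, _ in self.stance_events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("stance_events must be strictly increasing in time")
        limbs = [l for _, l in self.stance_events]
        if any(a == b for a, b in zip(limbs, limbs[1:])):
            raise ValueError("stance_events must alternate limbs")
        if not (np.all(np.isfinite(self.head_z)) and np.all(np.isfinite(self.pelvis_z))):
            raise ValueError("displacement series must be finite")


def _cosine_fill(y: np.ndarray, i0: int, i1: int, v0: float, v1: float) -> None:
    """Fill y[i0..i1] with a half-cosine arc from v0 to v1 (zero-slope ends)."""
    n = i1 - i0
    if n <= 0:
        y[i1] = v1
        return
    u = np.arange(n + 1) / n
    y[i0 : i1 + 1] = v0 + (v1 - v0) * (1.0 - np.cos(np.pi * u)) / 2.0


def synth_trial(
    horse: pd.Series, config: SimConfig, visit: int = 0, seed: Optional[int] = None
) -> TrialSignal:
    """Generate one trial's head/pelvis waveform for a horse.

    Per stride the head and pelvis each describe two vertical oscillations,
    one per forelimb stance half-cycle.  Extrema follow the additive model
    right-half extremum = baseline + latent + noise, left-half extremum =
    baseline + noise, so the per-stride right-minus-left difference has the
    latent asymmetry as its expectation.  With probability ``outlier_prob``
    one head extremum of a stride is displaced by +/- ``outlier_magnitude``.
    The waveform is a piecewise-cosine through the extrema; extremum knots
    and stance events are snapped to the sample grid, so the sampled series
    attains the designed extrema exactly.
    """
    if config.strides_per_trial < 2:
        raise ConfigurationError(
            "strides_per_trial: at least two strides needed for an SD"
        )
    for col in LATENTS:
        if not np.isfinite(horse[col]):
            raise ValueError(f"latent asymmetry {col} must be finite")
    if seed is None:
        seed = config.seed
    rng = _rng(seed, 1, int(visit))
    n = config.strides_per_trial
    dt = 1.0 / config.sample_rate

    durations = rng.normal(config.stride_duration_mean, config.stride_duration_sd, n)
    durations = np.maximum(durations, 0.3)
    half_samples = np.maximum(np.round(durations / (2.0 * dt)).astype(int), 8)

    amp = {"hd": config.head_amplitude, "pd": config.pelvis_amplitude}
    noise = config.extremum_noise_sd

    rows = []
    for i in range(n):
        row = {"stride_index": i, "stride_duration": 2 * half_samples[i] * dt}
        for body in ("hd", "pd"):
            eps = rng.normal(0.0, noise, 4)  # min R, min L, max R, max L
            row[f"{body}_min_right"] = -amp[body] + horse[f"a_{body}min"] + eps[0]
            row[f"{body}_min_left"] = -amp[body] + eps[1]
            row[f"{body}_max_right"] = amp[body] + horse[f"a_{body}max"] + eps[2]
            row[f"{body}_max_left"] = amp[body] + eps[3]
        row["outlier_param"] = ""
        if config.outlier_prob > 0 and rng.random() < config.outlier_prob:
            # outliers occur on head extrema only and exaggerate the extremum
            # (minima displaced downward, maxima upward) as in a head toss
            which = rng.choice(
                ["hd_min_right", "hd_min_left", "hd_max_right", "hd_max_left"]
            )
            row[which] += (-1.0 if "min" in which else 1.0) * config.outlier_magnitude
            row["outlier_param"] = "hdmin" if "min" in which else "hdmax"
        rows.append(row)
    extrema = pd.DataFrame(rows)

    total = int(2 * half_samples.sum()) + 1
    time = np.arange(total) * dt
    head = np.zeros(total)
    pelvis = np.zeros(total)
    stance_events: List[Tuple[float, str]] = []

    # knot layout per half-cycle: zero crossing at the stance boundary,
    # minimum at 1/4, maximum at 3/4.  Anchoring every boundary at zero
    # keeps each half-cycle's extrema interior to its own window even when
    # an outlier displaces a neighbouring extremum far from baseline.
    knots = {"hd": [], "pd": []}
    start = 0
    for i in range(n):
        h = half_samples[i]
        for side, s0 in (("right", start), ("left", start + h)):
            limb = "right_fore" if side == "right" else "left_fore"
            stance_events.append((s0 * dt, limb))
            i_min = s0 + h // 4
            i_max = s0 + (3 * h) // 4
            for body in ("hd", "pd"):
                knots[body].append((s0, 0.0))
                knots[body].append((i_min, extrema.loc[i, f"{body}_min_{side}"]))
                knots[body].append((i_max, extrema.loc[i, f"{body}_max_{side}"]))
        start += 2 * h
    stance_events.append((start * dt, "right_fore"))  # closes the final stride
    for body, y in (("hd", head), ("pd", pelvis)):
        ks = knots[body] + [(total - 1, 0.0)]
        for (i0, v0), (i1, v1) in zip(ks, ks[1:]):
            _cosine_fill(y, i0, i1, v0, v1)

    surface = "soft" if rng.random() < config.surface_probs["soft"] else "hard"
    return TrialSignal(
        time=time, head_z=head, pelvis_z=pelvis, stance_events=stance_events,
        surface=surface, true_extrema=extrema,
    )


# ---------------------------------------------------------------------------
# preference tests

def synth_preference_sequence(
    horse: pd.Series, n_attempts: int, valid_prob: float = 0.9,
    seed: Optional[int] = None,
) -> PreferenceRecord:
    """Simulate a preference-test run for one horse.

    Each attempt is valid with probability ``valid_prob``; each valid
    observation is RIGHT with the horse's latent ``p_right``, else LEFT.
    """
    if n_attempts < 1:
        raise ConfigurationError("n_attempts: must be >= 1")
    if not 0.0 <= valid_prob <= 1.0:
        raise ConfigurationError("valid_prob: probability must be in [0, 1]")
    rng = _rng(0 if seed is None else seed, 3)
    p_right = float(horse["p_right"])
    observations = []
    n_invalid = 0
    for _ in range(n_attempts):
        if rng.random() < valid_prob:
            observations.append(RIGHT if rng.random() < p_right else LEFT)
        else:
            n_invalid += 1
    return PreferenceRecord(
        horse_id=str(horse.get("horse_id", "H000")),
        observations=observations,
        n_invalid=n_invalid,
    )


# ---------------------------------------------------------------------------
# questionnaires

def _softmax_side(rng, latent: float, slope: float) -> str:
    """Draw no/left/right with utilities (0, -slope*latent, +slope*latent)."""
    z = np.array([0.0, -slope * latent, slope * latent])
    z -= z.max()
    p = np.exp(z)
    p /= p.sum()
    return ["no", "left", "right"][rng.choice(3, p=p)]


def synth_questionnaire(
    horse: pd.Series, config: SimConfig, visit: int = 0, seed: Optional[int] = None
) -> Dict[str, str]:
    """Generate one visit's rider questionnaire answers for a horse.

    Side questions follow a softmax over {no, left, right} whose logits are
    +/- ``questionnaire_link_slope`` times the linked latent asymmetry
    (question 2a: pelvic minima; question 4: head; 3 and 5: mean of all
    four).  With slope 0 the answers are independent of the latent truth.
    Each question is independently missing ("no perception/did not answer")
    with probability ``missingness_prob``.
    """
    if seed is None:
        seed = config.seed
    rng = _rng(seed, 2, int(visit))
    s = config.questionnaire_link_slope
    head_latent = (horse["a_hdmin"] + horse["a_hdmax"]) / 2.0
    all_latent = (
        horse["a_hdmin"] + horse["a_hdmax"] + horse["a_pdmin"] + horse["a_pdmax"]
    ) / 4.0
    magnitude = (
        abs(horse["a_hdmin"]) / 2 + abs(horse["a_hdmax"]) / 2
        + abs(horse["a_pdmin"]) + abs(horse["a_pdmax"])
    )

    answers: Dict[str, str] = {}
    # Q1: ordered grade; linkage shifts the cumulative logits by slope*magnitude
    u = rng.random()
    shift = s * magnitude
    cum = [1.0 / (1.0 + np.exp(-(np.log(c / (1 - c)) - shift))) for c in _Q1_BASE_CUM]
    grade = int(np.searchsorted(cum, u))
    answers["q1"] = ANSWER_SETS["q1"][grade]
    answers["q2a"] = _softmax_side(rng, float(horse["a_pdmin"]), s)
    answers["q2b"] = ANSWER_SETS["q2b"][rng.choice(3, p=_Q2B_PROBS)]
    answers["q3"] = _softmax_side(rng, float(all_latent), s).replace("no", "none")
    answers["q4"] = _softmax_side(rng, float(head_latent), s).replace("no", "none")
    answers["q5"] = _softmax_side(rng, float(all_latent), s)
    for q in answers:
        if rng.random() < config.missingness_prob:
            answers[q] = MISSING_ANSWER
    return answers


# ---------------------------------------------------------------------------
# vectorized study-level generation

def simulate_stride_table(
    truth: CohortTruth, config: SimConfig, seed: Optional[int] = None
) -> pd.DataFrame:
    """Per-stride parameter table for the whole cohort (fast path).

    Draws each stride's right-minus-left extremum difference directly from
    the extremum-level model (difference = latent + N(0, sqrt(2)*noise_sd);
    head outliers displace one extremum of hdmin or hdmax away from zero by
    ``outlier_magnitude``, shifting the difference by +/- that amount
    depending on the side hit), skipping the waveform interpolation,
    which is information-free for these parameters.

    Returns columns horse_id, visit, stride_index, hdmin, hdmax, pdmin,
    pdmax, stride_duration, surface.
    """
    if seed is None:
        seed = config.seed
    rng = _rng(seed, 4)
    n_h = len(truth)
    n_v = config.n_visits
    n_s = config.strides_per_trial
    total = n_h * n_v * n_s
    diff_sd = np.sqrt(2.0) * config.extremum_noise_sd

    base = {
        p: np.repeat(truth["a_" + p].to_numpy(), n_v * n_s) for p in PARAMS
    }
    out = pd.DataFrame(
        {
            "horse_id": np.repeat(truth["horse_id"].to_numpy(), n_v * n_s),
            "visit": np.tile(np.repeat(np.arange(n_v), n_s), n_h),
            "stride_index": np.tile(np.arange(n_s), n_h * n_v),
        }
    )
    for p in PARAMS:
        out[p] = base[p] + rng.normal(0.0, diff_sd, total)
    # head outliers: one of hdmin/hdmax displaced
    is_out = rng.random(total) < config.outlier_prob
    which_max = rng.random(total) < 0.5
    sign = rng.choice([-1.0, 1.0], total)
    out.loc[is_out & ~which_max, "hdmin"] += (sign * config.outlier_magnitude)[
        is_out & ~which_max
    ]
    out.loc[is_out & which_max, "hdmax"] += (sign * config.outlier_magnitude)[
        is_out & which_max
    ]
    out["stride_duration"] = np.maximum(
        rng.normal(config.stride_duration_mean, config.stride_duration_sd, total), 0.3
    )
    surf = rng.random(n_h * n_v) < config.surface_probs["soft"]
    out["surface"] = np.repeat(np.where(surf, "soft", "hard"), n_s)
    return out


def simulate_questionnaires(
    truth: CohortTruth, config: SimConfig, seed: Optional[int] = None
) -> pd.DataFrame:
    """Questionnaire answers for every horse x visit (long table)."""
    if seed is None:
        seed = config.seed
    rows = []
    for i, (_, horse) in enumerate(truth.iterrows()):
        for v in range(config.n_visits):
            ans = synth_questionnaire(horse, config, visit=v, seed=int(seed) + 7919 * (i + 1))
            rows.append({"horse_id": horse["horse_id"], "visit": v, **ans})
    return pd.DataFrame(rows)


def simulate_preferences(
    truth: CohortTruth, config: SimConfig, n_attempts: int = 18,
    valid_prob: float = 0.9, seed: Optional[int] = None,
) -> List[PreferenceRecord]:
    """Preference-test runs for every horse in the cohort."""
    if seed is None:
        seed = config.seed
    return [
        synth_preference_sequence(
            horse, n_attempts, valid_prob, seed=int(seed) + 104729 * (i + 1)
        )
        for i, (_, horse) in enumerate(truth.iterrows())
    ]


@dataclass
class StudyData:
    """A full synthetic study: truth plus every raw data stream."""

    truth: CohortTruth
    stride_table: pd.DataFrame
    questionnaires: pd.DataFrame
    preferences: List[PreferenceRecord] = field(default_factory=list)


def simulate_study(
    config: SimConfig, seed: Optional[int] = None,
    pt_attempts: int = 18, pt_valid_prob: float = 0.9,
) -> StudyData:
    """Generate a complete synthetic study from one configuration."""
    if seed is not None:
        config = SimConfig(**{**config.__dict__, "seed": int(seed)})
    truth = make_cohort(config)
    return StudyData(
        truth=truth,
        stride_table=simulate_stride_table(truth, config),
        questionnaires=simulate_questionnaires(truth, config),
        preferences=simulate_preferences(
            truth, config, n_attempts=pt_attempts, valid_prob=pt_valid_prob
        ),
    )
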