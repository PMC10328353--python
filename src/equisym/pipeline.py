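"""End-to-end pipeline: simulate -> extract -> laterality -> correlate -> report."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import pandas as pd

from .asymmetry import GaitAsymmetryModel
from .config import PipelineConfig
from .laterality import PreferenceTestModel
from .simulate import simulate_study
from .statcorr import SidednessAssociationModel

__all__ = ["ReportBundle", "run_pipeline", "build_visit_records"]

logger = logging.getLogger(__name__)


@dataclass
class ReportBundle:
    """Every output table of one pipeline run."""

    summaries: pd.DataFrame
    visit_table: pd.DataFrame
    pct_any_asymmetric: pd.Series
    laterality: pd.DataFrame
    laterality_groups: pd.DataFrame
    icc: pd.DataFrame
    contrasts: pd.DataFrame
    agreement_table: pd.DataFrame
    agreement_stats: pd.DataFrame
    correlations: Optional[pd.DataFrame]
    exclusions: List[dict] = field(default_factory=list)

    def tables(self) -> Dict[str, pd.DataFrame]:
        out = {
            "trial_summaries": self.summaries,
            "visit_table": self.visit_table,
            "pct_any_asymmetric": self.pct_any_asymmetric.rename("percent").reset_index(),
            "laterality": self.laterality,
            "laterality_groups": self.laterality_groups,
            "icc": self.icc,
            "contrasts": self.contrasts,
            "agreement_table": self.agreement_table.reset_index(),
            "agreement_stats": self.agreement_stats,
            "exclusions": pd.DataFrame(self.exclusions),
        }
        if self.correlations is not None:
            out["correlations"] = self.correlations
        return out


def build_visit_records(summaries: pd.DataFrame, questionnaires: pd.DataFrame
                        ) -> pd.DataFrame:
    """Join trial summaries with questionnaire answers per horse x visit."""
    records = summaries.merge(questionnaires, on=["horse_id", "visit"], how="left")
    return records.rename(columns={"mean_stride_duration": "stride_duration"})


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: started", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                logger.info("stage %s: done in %.2fs", name, dt)
            else:
                logger.error("stage %s: failed after %.2fs: %s", name, dt, exc)
            return False

    return _Timer()


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run the full synthetic study pipeline and assemble the report bundle.

    Deterministic given ``config.seed``: simulates the cohort and all data
    streams, summarizes trials, scores preference tests, and runs the
    correlation stage.  Writes CSV reports when ``config.out_dir`` is set.
    """
    stages = {}

    def run_stage(name, fn):
        try:
            with _stage(name):
                stages[name] = fn()
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        return stages[name]

    sim = config.sim
    if config.seed is not None:
        from .config import SimConfig

        sim = SimConfig(**{**sim.__dict__, "seed": int(config.seed)})

    study = run_stage(
        "simulate",
        lambda: simulate_study(
            sim, pt_attempts=config.pt_attempts, pt_valid_prob=config.pt_valid_prob
        ),
    )

    def _summarize():
        return GaitAsymmetryModel(study.stride_table, config.thresholds).fit()

    gait = run_stage("summarize", _summarize)

    def _laterality():
        return PreferenceTestModel(
            study.preferences, alpha=config.alpha, target_n=config.target_n
        ).fit()

    pt = run_stage("laterality", _laterality)

    def _correlate():
        records = build_visit_records(gait.summaries, study.questionnaires)
        # gait trial run alongside the preference test: use the first visit
        first = gait.summaries[gait.summaries["visit"] == 0].set_index("horse_id")
        joined = pt.included.merge(
            first[[*("hdmin", "hdmax", "pdmin", "pdmax"), "tas"]],
            left_on="horse_id", right_index=True, how="inner",
        )
        model = SidednessAssociationModel(
            records, laterality=joined if len(joined) >= 3 else None,
            thresholds=config.thresholds,
        )
        return model.fit()

    assoc = run_stage("correlate", _correlate)

    exclusions = [
        {"horse_id": r.horse_id, "stage": "laterality", "reason": r.exclusion_reason}
        for r in pt.results
        if r.excluded
    ]
    for e in exclusions:
        logger.info("excluded %s (%s): %s", e["horse_id"], e["stage"], e["reason"])

    tas_by_horse = (
        gait.summaries[gait.summaries["visit"] == 0].set_index("horse_id")["tas"]
    )
    agreement = assoc.agreement
    bundle = ReportBundle(
        summaries=gait.summaries,
        visit_table=gait.visit_table(),
        pct_any_asymmetric=gait.percent_any_asymmetric(),
        laterality=pt.frame,
        laterality_groups=pt.group_table(tas=tas_by_horse),
        icc=assoc.icc,
        contrasts=assoc.contrasts,
        agreement_table=agreement.table,
        agreement_stats=pd.DataFrame(
            [
                {
                    "sensitivity": agreement.sensitivity,
                    "specificity": agreement.specificity,
                    "cramers_v": agreement.cramers_v,
                    "p_value": agreement.fisher_p,
                    "p_method": agreement.p_method,
                }
            ]
        ),
        correlations=assoc.correlations,
        exclusions=exclusions,
    )

    if config.out_dir:
        from .io import write_report

        with _stage("report"):
            write_report(config.out_dir, bundle.tables())
    return bundle
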