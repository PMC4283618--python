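"""End-to-end validation pipeline.

Reproduces the structure of the published analysis on any input cohort
(typically the synthetic simulator, since the raw scorer data are not
public): per-muscle inter-observer reliability with item classification, the
intra-observer repeat (proportional agreement), informative-item selection,
per-case consensus with the modified domain totals, quadriceps-vs-biceps
group comparisons, and clinical associations.  Every stage is deterministic
under the configured seed; re-running with an identical config produces
byte-identical CSV outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import association as assoc
from .consensus import ExerciseClassification, consensus_table, select_informative_items
from .design import DesignAllocation, latin_square, partial_latin_square
from .reliability import (
    InterRaterReliability,
    proportional_agreement,
    reliability_table,
)
from .simulate import SimulationConfig, SyntheticTruth, simulate_cohort, simulate_ratings
from .tool import ScoreToolDefinition, default_tool, load_tool_definition

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StudyData", "simulate_study", "run_validation_pipeline"]

MAIN_EXERCISE_SIZE = 11
INTRARATER_SIZE = 8
PARTIAL_SCORERS_PER_CASE = 5


@dataclass
class PipelineConfig:
    tool_path: Optional[str] = None
    scores_path: Optional[str] = None
    vas_path: Optional[str] = None
    clinical_path: Optional[str] = None
    simulation: Optional[SimulationConfig] = None
    n_boot: int = 1000
    seed: int = 0
    out_dir: Optional[str] = None
    p_decimals: int = 2  # rounding of reported p-values in the summary

    def __post_init__(self):
        if self.n_boot < 100:
            raise ValueError("n_boot must be >= 100")
        for p in (self.tool_path, self.scores_path, self.vas_path, self.clinical_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


@dataclass
class StudyData:
    """A full study's worth of inputs: cases, designs, and ratings."""

    tool: ScoreToolDefinition
    cases: pd.DataFrame
    scores: pd.DataFrame  # long; sessions 1 (and 2 for the repeat subset)
    vas: pd.DataFrame
    main_cases: dict[str, list[str]]  # muscle -> case ids of the 11x11 exercise
    truth: Optional[SyntheticTruth] = None


def simulate_study(cfg: SimulationConfig, tool: ScoreToolDefinition | None = None) -> StudyData:
    """Simulate the full scoring-exercise layout.

    Per muscle group: an 11×11 full Latin square on the first 11 cases (or
    fewer if the group is smaller) and a partial design (5 scorers per case)
    on the remainder, all in session 1; plus an 8×8 intra-observer repeat on
    quadriceps cases in session 2.
    """
    tool = tool or default_tool()
    cases, truth = simulate_cohort(cfg, tool)
    scorers = list(truth.scorer_bias.index)

    all_scores, all_vas = [], []
    main_cases: dict[str, list[str]] = {}
    for gi, muscle in enumerate(("quadriceps", "biceps")):
        ids = cases.loc[cases["muscle_source"] == muscle, "case_id"].tolist()
        if not ids:
            main_cases[muscle] = []
            continue
        n_main = min(MAIN_EXERCISE_SIZE, len(ids), len(scorers))
        main_ids = ids[:n_main]
        main_cases[muscle] = main_ids
        d_main = latin_square(
            n_main, seed=cfg.seed * 7 + gi, case_ids=main_ids, scorer_ids=scorers[:n_main]
        )
        s, v = simulate_ratings(truth, d_main, cfg, tool, session=1)
        all_scores.append(s)
        all_vas.append(v)
        rest = ids[n_main:]
        if rest:
            d_rest = partial_latin_square(
                len(rest),
                min(PARTIAL_SCORERS_PER_CASE, len(scorers)),
                seed=cfg.seed * 7 + 100 + gi,
                case_ids=rest,
                scorer_ids=scorers,
            )
            s, v = simulate_ratings(truth, d_rest, cfg, tool, session=1)
            all_scores.append(s)
            all_vas.append(v)

    # intra-observer repeat: 8 quadriceps cases re-read by 8 scorers
    quad_main = main_cases.get("quadriceps", [])
    n_intra = min(INTRARATER_SIZE, len(quad_main), len(scorers))
    if n_intra >= 2:
        d_intra = latin_square(
            n_intra,
            seed=cfg.seed * 7 + 200,
            case_ids=quad_main[:n_intra],
            scorer_ids=scorers[:n_intra],
        )
        s2, v2 = simulate_ratings(truth, d_intra, cfg, tool, session=2)
        all_scores.append(s2)
        all_vas.append(v2)

    scores = pd.concat(all_scores, ignore_index=True)
    vas = pd.concat(all_vas, ignore_index=True)
    return StudyData(tool=tool, cases=cases, scores=scores, vas=vas,
                     main_cases=main_cases, truth=truth)


def exercise_reliability(
    scores: pd.DataFrame,
    vas: pd.DataFrame,
    tool: ScoreToolDefinition,
    n_boot: int | None = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Reliability table for one scoring exercise.

    Rows: every tool item, each domain's total (the sum of a scorer's item
    scores, a composite rating), and the VAS.  Columns follow the standard
    report layout (icc, CI bounds, alpha, CI bounds, class, degenerate).
    """
    out = reliability_table(scores, items=tool.item_ids, n_boot=n_boot, seed=seed)
    out["composite"] = False

    extra_rows = []
    wide = scores.pivot_table(index=["case_id", "scorer_id"], columns="item_id",
                              values="score", aggfunc="first")
    for domain in ("inflammatory", "vascular", "muscle_fibre", "connective_tissue"):
        cols = [it.item_id for it in tool.items_in_domain(domain) if it.item_id in wide.columns]
        if not cols:
            continue
        total = wide[cols].sum(axis=1).reset_index().rename(columns={0: "score"})
        est = InterRaterReliability(n_boot=n_boot, random_state=seed).fit(total)
        extra_rows.append(_est_row(f"{domain}_domain_total", est))
    if len(vas):
        v = vas.rename(columns={"vas": "score"})[["case_id", "scorer_id", "score"]]
        est = InterRaterReliability(n_boot=n_boot, random_state=seed).fit(v)
        extra_rows.append(_est_row("vas", est))
    if extra_rows:
        extra = pd.DataFrame(extra_rows)
        extra["composite"] = True
        out = pd.concat([out, extra], ignore_index=True)
    return out


def _est_row(row_id: str, est: InterRaterReliability) -> dict:
    return {
        "item_id": row_id,
        "icc": est.icc_,
        "icc_lo": est.icc_ci_[0] if est.icc_ci_ else np.nan,
        "icc_hi": est.icc_ci_[1] if est.icc_ci_ else np.nan,
        "alpha": est.alpha_,
        "alpha_lo": est.alpha_ci_[0] if est.alpha_ci_ else np.nan,
        "alpha_hi": est.alpha_ci_[1] if est.alpha_ci_ else np.nan,
        "class": est.classification_,
        "degenerate": est.degenerate_,
    }


def _group_comparisons(
    consensus: pd.DataFrame,
    cases: pd.DataFrame,
    informative: Sequence[str],
) -> pd.DataFrame:
    """Quadriceps-vs-biceps comparison of consensus scores (group-comparison
    report: categorical tests per item, Mann–Whitney for totals and VAS)."""
    merged = consensus.merge(cases[["case_id", "muscle_source"]], on="case_id")
    rows = []
    for item in informative:
        counts = (
            merged.groupby(["muscle_source", item]).size().unstack(fill_value=0)
            .reindex(["quadriceps", "biceps"])
        )
        counts = counts.loc[:, counts.sum(axis=0) > 0]
        if counts.shape[1] < 2 or counts.isna().any().any():
            rows.append({"row_id": item, "test": "none", "statistic": np.nan, "p": np.nan})
            continue
        res = assoc.compare_groups(counts.to_numpy())
        rows.append({"row_id": item, "test": res.test_name, "statistic": res.statistic, "p": res.p_value})
    for col in ("modified_inflammatory_total", "modified_muscle_total", "vas_consensus"):
        if col not in merged.columns:
            continue
        q = merged.loc[merged["muscle_source"] == "quadriceps", col].dropna()
        b = merged.loc[merged["muscle_source"] == "biceps", col].dropna()
        if len(q) and len(b):
            res = assoc.mann_whitney_u(q, b)
            rows.append({"row_id": col, "test": res.test_name, "statistic": res.statistic, "p": res.p_value})
    return pd.DataFrame(rows)


def _clinical_associations(
    consensus: pd.DataFrame,
    cases: pd.DataFrame,
    informative: Sequence[str],
) -> pd.DataFrame:
    """Association report: Spearman of each consensus row vs MMT (combined
    cohort), Kruskal–Wallis of totals vs complication flags, and Spearman of
    totals/VAS vs PGA and CMAS where available."""
    merged = consensus.merge(cases, on="case_id")
    score_rows = list(informative) + [
        c for c in ("modified_inflammatory_total", "modified_muscle_total", "vas_consensus")
        if c in merged.columns
    ]
    rows = []
    for col in score_rows:
        for clin in ("mmt_knee_extensor", "mmt_elbow_flexion", "pga", "cmas"):
            if clin not in merged.columns:
                continue
            x = merged[col].astype(float)
            y = merged[clin].astype(float)
            if (~(x.isna() | y.isna())).sum() < 3:
                continue
            res = assoc.spearman(x, y)
            rows.append({"row_id": col, "clinical": clin, "test": "spearman",
                         "r": res.effect, "statistic": res.statistic, "p": res.p_value})
        for flag in ("calcinosis", "skin_ulceration", "lung", "gi"):
            if flag not in merged.columns or col in informative:
                continue  # Kruskal-Wallis reserved for totals/VAS
            sub = merged[[col, flag]].dropna()
            groups = [g[col].to_numpy(float) for _, g in sub.groupby(flag)]
            if len(groups) < 2 or any(len(g) == 0 for g in groups):
                continue
            res = assoc.kruskal_wallis(*groups)
            rows.append({"row_id": col, "clinical": flag, "test": "kruskal_wallis",
                         "r": np.nan, "statistic": res.statistic, "p": res.p_value})
    return pd.DataFrame(rows)


def run_validation_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full validation analysis; returns a report bundle.

    The bundle maps stage names to DataFrames: ``reliability_quadriceps``,
    ``reliability_biceps``, ``intrarater``, ``informative_items``,
    ``consensus``, ``group_comparisons``, ``associations``.  With
    ``cfg.out_dir`` set, each table is written as CSV plus a Markdown
    summary (p-values rounded to ``cfg.p_decimals``; machine CSVs keep full
    precision).
    """
    tool = load_tool_definition(cfg.tool_path) if cfg.tool_path else default_tool()

    if cfg.scores_path:
        scores = pd.read_csv(cfg.scores_path)
        vas = pd.read_csv(cfg.vas_path) if cfg.vas_path else pd.DataFrame(
            columns=["scorer_id", "case_id", "session", "vas"]
        )
        cases = pd.read_csv(cfg.clinical_path) if cfg.clinical_path else None
        if cases is None:
            raise ValueError("clinical_path is required when scores_path is given")
        main_cases = {
            m: cases.loc[cases["muscle_source"] == m, "case_id"].tolist()[:MAIN_EXERCISE_SIZE]
            for m in ("quadriceps", "biceps")
        }
        data = StudyData(tool=tool, cases=cases, scores=scores, vas=vas, main_cases=main_cases)
    elif cfg.simulation is not None:
        data = simulate_study(cfg.simulation, tool)
    else:
        raise ValueError("config must provide either scores_path or a simulation")
    logger.info("inputs: %d cases, %d score rows", len(data.cases), len(data.scores))

    bundle: dict = {}
    s1 = data.scores[data.scores["session"] == 1]
    v1 = data.vas[data.vas["session"] == 1]
    classifications = []
    for muscle in ("quadriceps", "biceps"):
        ids = data.main_cases.get(muscle, [])
        sub = s1[s1["case_id"].isin(ids)]
        if sub.empty:
            continue
        rel = exercise_reliability(
            sub, v1[v1["case_id"].isin(ids)], tool, n_boot=cfg.n_boot, seed=cfg.seed
        )
        bundle[f"reliability_{muscle}"] = rel
        items_only = rel[~rel["composite"]]
        classifications.append(ExerciseClassification.from_table(items_only, exercise_id=muscle))
        logger.info("reliability[%s]: %d rows", muscle, len(rel))

    s2 = data.scores[data.scores["session"] == 2]
    if len(s2):
        pairs = s2[["scorer_id", "case_id", "item_id"]]
        s1_sub = s1.merge(pairs, on=["scorer_id", "case_id", "item_id"])
        pa = proportional_agreement(s1_sub, s2)
        bundle["intrarater"] = pd.DataFrame(
            [
                {"item_id": r.item_id, "median_pa": r.median_pa,
                 "min_pa": r.range_pa[0], "max_pa": r.range_pa[1]}
                for r in pa.values()
            ]
        )
        logger.info("intrarater: %d items", len(bundle["intrarater"]))

    informative = select_informative_items(classifications, tool)
    bundle["informative_items"] = pd.DataFrame({"item_id": informative})
    logger.info("informative items: %d", len(informative))

    consensus = consensus_table(s1, vas=v1, tool=tool, informative_items=informative)
    bundle["consensus"] = consensus
    logger.info("consensus: %d cases", len(consensus))

    if informative:
        bundle["group_comparisons"] = _group_comparisons(consensus, data.cases, informative)
        bundle["associations"] = _clinical_associations(consensus, data.cases, informative)
        logger.info("comparisons: %d rows; associations: %d rows",
                    len(bundle["group_comparisons"]), len(bundle["associations"]))

    if cfg.out_dir:
        _write_bundle(bundle, cfg)
    return bundle


def _write_bundle(bundle: dict, cfg: PipelineConfig) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in bundle.items():
        df.to_csv(out / f"{name}.csv", index=False, float_format="%.10g")
    lines = ["# Score-tool validation report", ""]
    for name, df in bundle.items():
        lines.append(f"## {name}")
        shown = df.copy()
        for col in shown.columns:
            if col in ("p",):
                shown[col] = shown[col].round(cfg.p_decimals)
            elif shown[col].dtype.kind == "f":
                shown[col] = shown[col].round(3)
        lines.append("```")
        lines.append(shown.to_string(index=False))
        lines.append("```")
        lines.append("")
    (out / "summary.md").write_text("\n".join(lines))
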