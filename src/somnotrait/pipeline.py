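"""End-to-end pipeline driver.

Stages: simulate (optional) -> summarize -> score -> factors ->
associate -> permutation_qq -> extremes -> cv_predict.  Every stage
reads its inputs from and writes its outputs to the run directory as
CSV, so stages can be toggled off and rerun against prior outputs.
A manifest records versions, seeds and output digests.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import associations as assoc
from . import io
from .actigraphy import ACTIGRAPHY_VARIABLES, summarize_cohort
from .config import CohortConfig, stage_seed
from .errors import SomnotraitError
from .factor import fit_hps_factors
from .instruments import (
    PSQI_VARIABLES,
    ScoringKey,
    score_hps_subscales_sum,
    score_hps_total,
    score_psqi,
)
from .permutation import PermutationEngine, build_envelope, qq_points
from .plotting import boxplot_extremes, qq_plot
from .prediction import cv_incremental_r2, kfold_assign
from .synthetic import generate_cohort

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "simulate",
    "summarize",
    "score",
    "factors",
    "associate",
    "permutation_qq",
    "extremes",
    "cv_predict",
)

#: the 21-variable sleep panel in report order
SLEEP_PANEL = tuple(ACTIGRAPHY_VARIABLES) + tuple(PSQI_VARIABLES)

COVARIATES = ("age", "sex")


@dataclass
class AnalysisTables:
    """In-memory analysis inputs assembled from cohort tables."""

    scores: pd.DataFrame        # hps_total, subscale sums, factor scores
    sleep: pd.DataFrame         # 21-variable panel (NaN outside subsamples)
    covariates: pd.DataFrame    # subject_id, age, sex
    subjects: pd.DataFrame


def analyze_cohort(
    tables: dict[str, pd.DataFrame],
    config: CohortConfig,
    min_nights: int = 5,
    k_factors: int | None = 3,
    pa_seed: int = 0,
) -> AnalysisTables:
    """Score a generated cohort into association-ready tables.

    Runs summarize -> score -> factors in memory and assembles the
    personality-score table, the 21-variable sleep panel and the
    covariate table, joined on subject id.
    """
    from .instruments import ScoringKey, score_hps_subscales_sum, score_hps_total, score_psqi

    summary = summarize_cohort(tables["nights"], min_nights=min_nights)
    psqi = score_psqi(tables["psqi_items"])
    key = ScoringKey.from_config(config)
    scores = score_hps_total(tables["hps_items"], key).merge(
        score_hps_subscales_sum(tables["hps_items"], key), on="subject_id"
    )
    markers = {
        sub: [i.item for i in config.items if i.factor == sub]
        for sub in ("core", "vitality", "ordinariness")
    }
    _, fscores = fit_hps_factors(
        tables["hps_items"], k=k_factors, seed=pa_seed, marker_items=markers
    )
    scores = scores.merge(fscores, on="subject_id")
    sleep = summary[["subject_id"] + list(ACTIGRAPHY_VARIABLES)].merge(
        psqi[["subject_id"] + list(PSQI_VARIABLES)], on="subject_id", how="outer", sort=False
    )
    covariates = tables["subjects"][["subject_id"] + list(COVARIATES)]
    return AnalysisTables(
        scores=scores, sleep=sleep, covariates=covariates, subjects=tables["subjects"]
    )


@dataclass
class PipelineConfig:
    out_dir: str
    cohort: CohortConfig = field(default_factory=lambda: CohortConfig.default())
    stages: tuple[str, ...] = ALL_STAGES
    min_nights: int = 5
    decile: float = 0.1
    adjust: str = "bh"
    n_replicates: int = 2000
    folds: int = 10
    k_factors: int | None = None    # None = parallel-analysis retention
    pa_sims: int = 100
    qq_log_scale: bool = True

    @property
    def seed(self) -> int:
        return self.cohort.seed


class PipelineError(SomnotraitError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _scores_table(out: Path) -> pd.DataFrame:
    return io.read_table(out / "scores.csv")


def _sleep_panel(out: Path) -> pd.DataFrame:
    summary = io.read_table(out / "sleep_summary.csv")
    psqi = io.read_table(out / "psqi_scores.csv")
    sleep = summary[["subject_id"] + list(ACTIGRAPHY_VARIABLES)].merge(
        psqi[["subject_id"] + list(PSQI_VARIABLES)], on="subject_id", how="outer", sort=False
    )
    return sleep


def _covariates(out: Path) -> pd.DataFrame:
    subjects = io.read_table(out / "subjects.csv")
    return subjects[["subject_id"] + list(COVARIATES)]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: PipelineConfig, out: Path):
    tables = generate_cohort(cfg.cohort)
    for name, df in tables.items():
        io.write_table(df, out / f"{name}.csv")
    cfg.cohort.save(out / "cohort_config.yaml")


def _stage_summarize(cfg: PipelineConfig, out: Path):
    nights = io.read_table(out / "nights.csv")
    summary = summarize_cohort(nights, min_nights=cfg.min_nights)
    io.write_table(summary, out / "sleep_summary.csv")


def _stage_score(cfg: PipelineConfig, out: Path):
    items = io.read_table(out / "hps_items.csv")
    key = ScoringKey.from_config(cfg.cohort)
    io.write_table(key.to_frame(), out / "scoring_key.csv")
    total = score_hps_total(items, key)
    subs = score_hps_subscales_sum(items, key)
    io.write_table(total.merge(subs, on="subject_id"), out / "hps_sum_scores.csv")
    psqi_items = io.read_table(out / "psqi_items.csv")
    io.write_table(score_psqi(psqi_items), out / "psqi_scores.csv")


def _stage_factors(cfg: PipelineConfig, out: Path):
    items = io.read_table(out / "hps_items.csv")
    key = ScoringKey.from_config(cfg.cohort)
    markers = {
        sub: [i for i in key.items if key.entries[i].subscale == sub]
        for sub in ("core", "vitality", "ordinariness")
    }
    solution, scores = fit_hps_factors(
        items,
        k=cfg.k_factors,
        n_sims=cfg.pa_sims,
        seed=stage_seed(cfg.seed, "parallel_analysis"),
        marker_items=markers,
    )
    load = pd.DataFrame(
        solution.loadings,
        columns=[solution.labels.get(j, f"factor_{j + 1}") for j in range(solution.k)],
    )
    load.insert(0, "item", solution.item_names)
    load["communality"] = solution.communalities
    io.write_table(load, out / "loadings.csv")
    io.write_table(
        pd.DataFrame(
            solution.factor_corr,
            columns=[solution.labels.get(j, f"factor_{j + 1}") for j in range(solution.k)],
        ),
        out / "factor_corr.csv",
    )
    io.write_table(scores, out / "factor_scores.csv")

    sums = io.read_table(out / "hps_sum_scores.csv")
    io.write_table(sums.merge(scores, on="subject_id", how="inner"), out / "scores.csv")


def _stage_associate(cfg: PipelineConfig, out: Path):
    scores = _scores_table(out)
    sleep = _sleep_panel(out)
    grid = assoc.correlate_grid(
        scores,
        sleep,
        _covariates(out),
        score_cols=list(assoc.SCORE_COLUMNS),
        sleep_cols=list(SLEEP_PANEL),
    )
    grid = assoc.adjust_pvalues(grid, method=cfg.adjust)
    io.write_table(grid, out / "associations.csv")

    wide = grid.pivot(index="sleep_variable", columns="personality_score", values=["rho", "p"])
    wide = wide.reindex(list(SLEEP_PANEL))
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    io.write_table(wide.reset_index(), out / "association_table.csv")


def _stage_permutation_qq(cfg: PipelineConfig, out: Path):
    scores = _scores_table(out)
    sleep = _sleep_panel(out)
    engine = PermutationEngine(
        scores,
        sleep,
        _covariates(out),
        score_cols=list(assoc.SCORE_COLUMNS),
        sleep_cols=list(SLEEP_PANEL),
    )
    pm = engine.permuted_pvalues(cfg.n_replicates, seed=stage_seed(cfg.seed, "permutation"))
    env = build_envelope(pm, seed=stage_seed(cfg.seed, "permutation"))
    qq = qq_points(engine.observed_pvalues(), env)
    io.write_table(env.table, out / "envelope.csv")
    io.write_table(qq, out / "qq_observed.csv")
    qq_plot(qq, env, out / "qq_plot.png", log_scale=cfg.qq_log_scale)


def _stage_extremes(cfg: PipelineConfig, out: Path):
    scores = _scores_table(out)
    sleep = _sleep_panel(out)
    merged = scores.merge(sleep, on="subject_id", how="inner", sort=False)
    results = []
    for sc in assoc.SCORE_COLUMNS:
        sub = merged.dropna(subset=[sc])
        res = assoc.extreme_group_tests(
            sub[sc].to_numpy(), sub, sleep_cols=list(SLEEP_PANEL), decile=cfg.decile
        )
        res.insert(0, "personality_score", sc)
        results.append(res)
    io.write_table(pd.concat(results, ignore_index=True), out / "extremes.csv")

    # Fig-2-style boxplots: actigraphy ISD variables by HPS total deciles
    fig_dir = out / "figures"
    fig_dir.mkdir(exist_ok=True)
    sub = merged.dropna(subset=["hps_total"])
    labels = assoc.extreme_deciles(sub["hps_total"].to_numpy(), decile=cfg.decile)
    sel = labels != "excluded"
    for var in [v for v in ACTIGRAPHY_VARIABLES if v.startswith("isd_")]:
        v = sub[var].to_numpy(dtype=float)
        ok = sel & ~np.isnan(v)
        boxplot_extremes(
            v[ok],
            np.where(labels[ok] == "top", "HPS+", "HPS-"),
            fig_dir / f"boxplot_{var}.png",
            seed=stage_seed(cfg.seed, "jitter"),
            ylabel=var,
        )


def _stage_cv_predict(cfg: PipelineConfig, out: Path):
    scores = _scores_table(out)
    sleep = _sleep_panel(out)
    subjects = io.read_table(out / "subjects.csv")
    cov_cols = [c for c in ("age", "sex", "ses", "bmi") if c in subjects.columns]
    merged = (
        scores.merge(sleep, on="subject_id", how="inner", sort=False)
        .merge(subjects[["subject_id"] + cov_cols], on="subject_id", how="inner", sort=False)
        .dropna()
    )
    rows = []
    folds = kfold_assign(len(merged), cfg.folds, seed=stage_seed(cfg.seed, "folds"))
    for target in assoc.SCORE_COLUMNS:
        res = cv_incremental_r2(
            merged[target].to_numpy(),
            merged[cov_cols].to_numpy(),
            merged[list(SLEEP_PANEL)].to_numpy(),
            folds,
            target=target,
        )
        rows.append(
            {
                "target": target,
                "n": len(merged),
                "folds": cfg.folds,
                "r2_base": res.r2_base,
                "r2_full": res.r2_full,
                "incremental": res.incremental,
            }
        )
    io.write_table(pd.DataFrame(rows), out / "cv_results.csv")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "summarize": _stage_summarize,
    "score": _stage_score,
    "factors": _stage_factors,
    "associate": _stage_associate,
    "permutation_qq": _stage_permutation_qq,
    "extremes": _stage_extremes,
    "cv_predict": _stage_cv_predict,
}


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    A stage failure aborts with a stage-tagged error; outputs of
    completed stages are retained.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("somnotrait")
    root.addHandler(fh)
    try:
        for stage in cfg.stages:
            if stage not in _STAGE_FUNCS:
                raise PipelineError(stage, ValueError("unknown stage"))
            t0 = time.perf_counter()
            logger.info("stage %s: start", stage)
            try:
                _STAGE_FUNCS[stage](cfg, out)
            except Exception as exc:
                logger.error("stage %s: failed (%s)", stage, exc)
                raise PipelineError(stage, exc) from exc
            logger.info("stage %s: done in %.2f s", stage, time.perf_counter() - t0)
        io.write_manifest(
            out,
            cfg.cohort.to_dict(),
            {"global": cfg.seed},
            [
                "subjects.csv", "truth.csv", "nights.csv", "hps_items.csv",
                "psqi_items.csv", "sleep_summary.csv", "psqi_scores.csv",
                "hps_sum_scores.csv", "scores.csv", "loadings.csv",
                "factor_corr.csv", "factor_scores.csv", "associations.csv",
                "association_table.csv", "envelope.csv", "qq_observed.csv",
                "extremes.csv", "cv_results.csv",
            ],
        )
    finally:
        root.removeHandler(fh)
        fh.close()
    return out
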