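"""End-to-end experiment orchestration.

Reproduces the study design: train the HMM and the frame-wise comparators on
the training half of the cohort, decode/predict every animal (training
animals included but flagged, mirroring how the study reports them), score
windowed concordance per animal and behavior, tabulate time budgets with
observer-vs-method t-tests, and record wall-clock timings (informational
only).  All outputs are tidy CSVs plus a run log of resolved settings.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import metrics
from .classify import ClassifierSpec, predict_frames, train_frame_classifier
from .hmm import DEFAULT_GMM_GRID, EstrusBehaviorHMM, HMMResults
from .io import (
    Trajectory,
    assemble_observations,
    read_cohort,
    stack_observations,
    write_cohort,
)
from .simulate import CohortConfig, default_config, save_manifest, simulate_cohort

ALL_METHODS = ("hmm", "rf", "svm", "nn")


@dataclass
class ExperimentConfig:
    """One full experiment: data source, split, methods, scoring window."""

    cohort: CohortConfig | str | Path = field(default_factory=default_config)
    training_ids: Sequence[str] | None = None  # None -> first half of each group
    methods: Sequence[str] = ("hmm", "rf")
    window: int = 1
    gmm_grid: Sequence[int] = DEFAULT_GMM_GRID
    classifier_overrides: dict = field(default_factory=dict)
    ttest_kind: str = "paired"
    outdir: str | Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("at least one method required")
        for m in self.methods:
            if m not in ALL_METHODS:
                raise ValueError(f"unknown method {m!r}")


@dataclass
class ExperimentResult:
    """Tidy result tables plus fitted models and provenance."""

    concordance: pd.DataFrame
    budgets: pd.DataFrame
    ttests: pd.DataFrame
    timings: pd.DataFrame
    summary: pd.DataFrame
    hmm_results: HMMResults | None
    manifest: dict | None
    config: ExperimentConfig
    errors: dict = field(default_factory=dict)


def default_training_ids(trajs: Sequence[Trajectory]) -> list[str]:
    """First half of each group, mirroring the study's 4+4 training split."""
    est = [t.animal_id for t in trajs if t.estrus]
    non = [t.animal_id for t in trajs if not t.estrus]
    return est[: (len(est) + 1) // 2] + non[: (len(non) + 1) // 2]


def _load_cohort(cfg: ExperimentConfig) -> tuple[list[Trajectory], dict | None]:
    if isinstance(cfg.cohort, CohortConfig):
        return simulate_cohort(cfg.cohort)
    return read_cohort(cfg.cohort), None


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Train every requested method, decode all animals, score everything."""
    trajs, manifest = _load_cohort(cfg)
    ids = [t.animal_id for t in trajs]
    training_ids = list(cfg.training_ids) if cfg.training_ids else default_training_ids(trajs)
    unknown = set(training_ids) - set(ids)
    if unknown:
        raise ValueError(f"unknown training animal id(s): {sorted(unknown)}")
    train = [t for t in trajs if t.animal_id in set(training_ids)]
    for t in train:
        if not t.is_labeled:
            raise ValueError(f"training animal {t.animal_id!r} has no labels")

    obs_cache = {t.animal_id: assemble_observations(t) for t in trajs}
    X_train, y_train = stack_observations(train)

    predictions: dict[str, dict[str, np.ndarray]] = {}
    timings = []
    errors: dict[str, str] = {}
    hmm_results: HMMResults | None = None

    for method in cfg.methods:
        t0 = time.perf_counter()
        try:
            if method == "hmm":
                hmm_results = EstrusBehaviorHMM(
                    train, gmm_grid=cfg.gmm_grid, seed=cfg.seed
                ).fit()
                t_train = time.perf_counter() - t0
                t0 = time.perf_counter()
                predictions[method] = {
                    t.animal_id: hmm_results.decode(obs_cache[t.animal_id]) for t in trajs
                }
            else:
                spec = ClassifierSpec(
                    method=method,
                    hyperparameters=cfg.classifier_overrides.get(method, {}),
                    seed=cfg.seed,
                )
                clf = train_frame_classifier(spec, X_train, y_train)
                t_train = time.perf_counter() - t0
                t0 = time.perf_counter()
                predictions[method] = {
                    t.animal_id: predict_frames(clf, obs_cache[t.animal_id]) for t in trajs
                }
            timings.append(
                {
                    "method": method,
                    "train_seconds": t_train,
                    "predict_seconds": time.perf_counter() - t0,
                }
            )
        except Exception as exc:  # a failing method must not sink the run
            errors[method] = f"{type(exc).__name__}: {exc}"

    conc_rows, budget_rows = [], []
    for t in trajs:
        is_train = t.animal_id in set(training_ids)
        if t.is_labeled:
            tb = metrics.behavior_time_budget(t.labels, t.animal_id)
            budget_rows.append(
                {
                    "animal_id": t.animal_id,
                    "estrus": t.estrus,
                    "is_training": is_train,
                    "method": "observation",
                    "approaching_pct": tb.approaching_pct,
                    "standing_pct": tb.standing_pct,
                }
            )
        for method, preds in predictions.items():
            pred = preds[t.animal_id]
            tb = metrics.behavior_time_budget(pred, t.animal_id)
            budget_rows.append(
                {
                    "animal_id": t.animal_id,
                    "estrus": t.estrus,
                    "is_training": is_train,
                    "method": method,
                    "approaching_pct": tb.approaching_pct,
                    "standing_pct": tb.standing_pct,
                }
            )
            if t.is_labeled:
                for r in metrics.score_animal(pred, t.labels, t.animal_id, cfg.window):
                    conc_rows.append(
                        {
                            "animal_id": t.animal_id,
                            "estrus": t.estrus,
                            "is_training": is_train,
                            "method": method,
                            "behavior": r.behavior,
                            "TP": r.TP,
                            "FN": r.FN,
                            "FP": r.FP,
                            "PC": r.PC,
                            "FP_pct": r.FP_pct,
                            "FN_pct": r.FN_pct,
                        }
                    )
    concordance = pd.DataFrame(conc_rows)
    budgets = pd.DataFrame(budget_rows)

    ttest_rows = []
    if not budgets.empty and "observation" in budgets["method"].values:
        obs_tab = budgets[budgets["method"] == "observation"].set_index("animal_id")
        for method in predictions:
            m_tab = budgets[budgets["method"] == method].set_index("animal_id")
            common = obs_tab.index.intersection(m_tab.index)
            for col, behavior in (("approaching_pct", 1), ("standing_pct", 2)):
                res = metrics.compare_budgets_ttest(
                    obs_tab.loc[common, col].to_numpy(),
                    m_tab.loc[common, col].to_numpy(),
                    kind=cfg.ttest_kind,
                )
                ttest_rows.append(
                    {
                        "method": method,
                        "behavior": behavior,
                        "statistic": res.statistic,
                        "pvalue": res.pvalue,
                        "n": res.n,
                        "kind": res.kind,
                        "degenerate": res.degenerate,
                    }
                )
    ttests = pd.DataFrame(ttest_rows)

    summary_rows = []
    if not concordance.empty:
        for (method, behavior), grp in concordance.groupby(["method", "behavior"]):
            held = grp[~grp["is_training"]]
            summary_rows.append(
                {
                    "method": method,
                    "behavior": behavior,
                    "mean_PC_pooled": grp["PC"].mean(),
                    "mean_PC_heldout": held["PC"].mean() if len(held) else np.nan,
                    "n_animals": len(grp),
                    "n_heldout": len(held),
                }
            )
    summary = pd.DataFrame(summary_rows)

    result = ExperimentResult(
        concordance=concordance,
        budgets=budgets,
        ttests=ttests,
        timings=pd.DataFrame(timings),
        summary=summary,
        hmm_results=hmm_results,
        manifest=manifest,
        config=cfg,
        errors=errors,
    )
    if cfg.outdir is not None:
        _write_outputs(result, trajs, training_ids, Path(cfg.outdir))
    return result


def _write_outputs(
    result: ExperimentResult,
    trajs: Sequence[Trajectory],
    training_ids: Sequence[str],
    outdir: Path,
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.concordance.to_csv(outdir / "concordance.csv", index=False)
    result.budgets.to_csv(outdir / "budgets.csv", index=False)
    result.ttests.to_csv(outdir / "ttests.csv", index=False)
    result.timings.to_csv(outdir / "timings.csv", index=False)
    result.summary.to_csv(outdir / "summary.csv", index=False)
    if result.hmm_results is not None:
        result.hmm_results.save(outdir / "hmm_model.json")
    if result.manifest is not None:
        save_manifest(result.manifest, outdir / "truth_manifest.json")
        write_cohort(trajs, outdir / "cohort")
    cfg = result.config
    log = {
        "seed": cfg.seed,
        "methods": list(cfg.methods),
        "window": cfg.window,
        "gmm_grid": list(cfg.gmm_grid),
        "training_ids": list(training_ids),
        "ttest_kind": cfg.ttest_kind,
        "classifier_overrides": cfg.classifier_overrides,
        "errors": result.errors,
    }
    (outdir / "run_log.yaml").write_text(yaml.safe_dump(log, sort_keys=True))
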