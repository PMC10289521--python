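"""Validation experiment drivers.

Three designs:

* **model-external** — train a single locked forest on one center, choose
  the operating point on the training OOB ROC, and transfer both model and
  operating point to the other center's cohort;
* **methodology-external** — lock the training *procedure* and rerun it on
  one cohort under patient-level bootstrap resampling (default 250
  repetitions): each repetition trains on the bootstrap-sampled patients'
  BMs and tests on the never-sampled patients' BMs, yielding averaged ROC
  curves, mean error metrics with 95% CIs, and the optimism-corrected
  AUC_0.632+;
* **pooled** — both cohorts are pooled before bootstrap resampling, with
  per-center sub-analyses of each repetition's test set.

The bootstrap is at patient level by default so that BMs of one patient
never straddle a train/test split; BM-level resampling is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortDataset
from .combat import fit_combat, harmonize_cohorts
from .forest import (
    ErrorMetrics,
    FeatureSet,
    ForestConfig,
    ProgressionForest,
    RocCurve,
    metrics_at_threshold,
    roc_from_scores,
)

logger = logging.getLogger(__name__)

N_REPS_DEFAULT = 250
FPR_GRID = np.linspace(0.0, 1.0, 101)
MAX_SPLIT_RETRIES = 20

METRIC_NAMES = ("auc", "mcr", "fnr", "fpr")


def bootstrap_split(ds: CohortDataset, rep_seed: int,
                    level: Literal["patient", "bm"] = "patient",
                    ) -> tuple[CohortDataset, CohortDataset]:
    """One bootstrap train/test split.

    Patient-level (default): patients are sampled with replacement to the
    original patient count; the training multiset is all BMs of the sampled
    patients (with multiplicity) and the test set is the BMs of
    never-sampled patients.  If the test set ends up single-class the split
    is redrawn with an incremented seed (logged), up to 20 retries.
    """
    for attempt in range(MAX_SPLIT_RETRIES):
        rng = np.random.default_rng(rep_seed + attempt)
        if level == "patient":
            patients = sorted(set(ds.patient_ids()))
            drawn = rng.choice(len(patients), size=len(patients), replace=True)
            by_patient: dict[str, list[int]] = {p: [] for p in patients}
            for i, rec in enumerate(ds.records):
                by_patient[rec.patient_id].append(i)
            train_idx = [i for k in drawn for i in by_patient[patients[k]]]
            in_bag = {patients[k] for k in drawn}
            test_idx = [i for i, rec in enumerate(ds.records)
                        if rec.patient_id not in in_bag]
        else:
            n = ds.n_records
            drawn = rng.choice(n, size=n, replace=True)
            train_idx = list(drawn)
            test_idx = sorted(set(range(n)) - set(drawn))
        train = CohortDataset([ds.records[i] for i in train_idx],
                              dict(ds.feature_schema), ds.provenance)
        test = CohortDataset([ds.records[i] for i in test_idx],
                             dict(ds.feature_schema), ds.provenance)
        labels_tr = train.labels()
        labels_te = test.labels()
        if (len(np.unique(labels_te)) == 2 and len(np.unique(labels_tr)) == 2):
            return train, test
        logger.info("bootstrap split %d produced a single-class set; "
                    "retrying (attempt %d)", rep_seed, attempt + 1)
    raise RuntimeError(f"could not draw a two-class split after "
                       f"{MAX_SPLIT_RETRIES} retries (seed {rep_seed})")


def auc_632plus(auc_apparent: float, auc_boot_mean: float) -> float:
    """The 0.632+ optimism correction blending the apparent
    (resubstitution) AUC with the mean bootstrap out-of-sample AUC.

    The relative overfitting rate R = (apparent - boot)/(apparent - 0.5) is
    clipped to [0, 1] (0 when the denominator is <= 0); the blend weight is
    w = 0.632 / (1 - 0.368 R).
    """
    for v in (auc_apparent, auc_boot_mean):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"AUC outside [0,1]: {v}")
    denom = auc_apparent - 0.5
    if denom <= 0:
        r = 0.0
    else:
        r = np.clip((auc_apparent - auc_boot_mean) / denom, 0.0, 1.0)
    w = 0.632 / (1.0 - 0.368 * r)
    return float((1.0 - w) * auc_apparent + w * auc_boot_mean)


@dataclass
class BootstrapResult:
    """Aggregated bootstrap-validation output."""

    n_reps: int
    per_rep: pd.DataFrame                  # columns auc, mcr, fnr, fpr
    fpr_grid: np.ndarray
    tpr_mean: np.ndarray
    tpr_band: tuple[np.ndarray, np.ndarray]  # 95% CI of the mean curve
    mean_metrics: ErrorMetrics
    apparent_auc: float
    auc_632plus: float
    radiomic_schema: list[str] = field(default_factory=list)
    rep_importances: list[pd.Series] | None = None  # raw, kept features only

    def summary(self) -> str:
        m, ci = self.mean_metrics, self.mean_metrics.ci or {}
        lines = [f"Bootstrap validation over {self.n_reps} repetitions",
                 "=" * 46]
        for name in METRIC_NAMES:
            lo, hi = ci.get(name, (float("nan"),) * 2)
            lines.append(f"{name.upper():>4}: {getattr(m, name):.3f} "
                         f"(95% CI {lo:.3f}-{hi:.3f})")
        lines.append(f"apparent AUC: {self.apparent_auc:.3f}")
        lines.append(f"AUC_0.632+:   {self.auc_632plus:.3f}")
        return "\n".join(lines)


def _mean_metrics(per_rep: pd.DataFrame,
                  ci_method: Literal["normal", "percentile"] = "normal",
                  ) -> ErrorMetrics:
    means = per_rep.mean()
    ci = {}
    n = len(per_rep)
    for name in METRIC_NAMES:
        if ci_method == "percentile":
            lo, hi = np.percentile(per_rep[name], [2.5, 97.5])
        else:
            half = 1.96 * per_rep[name].std(ddof=1) / np.sqrt(n)
            lo, hi = means[name] - half, means[name] + half
        ci[name] = (float(lo), float(hi))
    return ErrorMetrics(auc=float(means["auc"]), mcr=float(means["mcr"]),
                        fnr=float(means["fnr"]), fpr=float(means["fpr"]),
                        ci=ci)


def _rep_seed_ints(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32) % (2 ** 31)


def run_model_external(train_ds: CohortDataset, test_ds: CohortDataset,
                       feature_set: FeatureSet = "all",
                       harmonize: bool = False,
                       restrict_features: Sequence[str] | None = None,
                       seed: int = 0,
                       config: ForestConfig | None = None,
                       combat_fit_on: Literal["pooled", "train"] = "pooled",
                       ) -> dict:
    """Train on one cohort, lock, and test on the other.

    Optional ComBat harmonization of radiomic features is applied before
    training (fit on the pooled train+test matrices by default, or on the
    training cohort only); ``restrict_features`` limits the radiomic schema
    (e.g. to the top-n consolidated features).
    """
    if list(train_ds.feature_schema) != list(test_ds.feature_schema):
        raise ValueError("train and test cohorts must share the feature schema")
    if harmonize:
        if combat_fit_on == "train":
            model = fit_combat(train_ds.radiomic_matrix(), train_ds.centers(),
                               feature_names=train_ds.radiomic_feature_names)
            train_ds, test_ds, _ = harmonize_cohorts(train_ds, test_ds, model)
        else:
            train_ds, test_ds, _ = harmonize_cohorts(train_ds, test_ds)
    if restrict_features is not None:
        train_ds = train_ds.select_radiomic(restrict_features)
        test_ds = test_ds.select_radiomic(restrict_features)
    model = ProgressionForest.from_cohort(train_ds, feature_set,
                                          config=config)
    results = model.fit(seed=seed)
    metrics, test_roc = results.evaluate(test_ds)
    return {
        "results": results,
        "metrics": metrics,
        "test_roc": test_roc,
        "oob_roc": results.oob_roc,
        "operating_point": results.operating_point,
    }


def _bootstrap_engine(ds: CohortDataset, feature_set: FeatureSet,
                      n_reps: int, seed: int, config: ForestConfig | None,
                      bootstrap_level: Literal["patient", "bm"],
                      collect_importances: bool,
                      ci_method: Literal["normal", "percentile"],
                      per_center: bool) -> tuple[BootstrapResult, dict]:
    rep_seeds = _rep_seed_ints(seed, 2 * n_reps)
    rows, tprs, importances = [], [], []
    center_rows: dict[str, list[dict]] = {c: [] for c in ds.center_ids}
    for rep in range(n_reps):
        train, test = bootstrap_split(ds, int(rep_seeds[rep]),
                                      level=bootstrap_level)
        model = ProgressionForest.from_cohort(train, feature_set, config=config)
        results = model.fit(seed=int(rep_seeds[n_reps + rep]))
        metrics, test_roc = results.evaluate(test)
        rows.append({n: getattr(metrics, n) for n in METRIC_NAMES})
        tprs.append(np.interp(FPR_GRID, test_roc.fpr, test_roc.tpr))
        if collect_importances:
            importances.append(results.feature_importances())
        if per_center:
            scores = results.predict_scores(test)
            labels = test.labels()
            centers = test.centers()
            for c in ds.center_ids:
                sel = centers == c
                if sel.sum() == 0 or len(np.unique(labels[sel])) < 2:
                    logger.info("rep %d: center %s absent or single-class in "
                                "test set; no per-center row", rep, c)
                    continue
                m = metrics_at_threshold(scores[sel], labels[sel],
                                         results.operating_point.threshold)
                center_rows[c].append(
                    {n: getattr(m, n) for n in METRIC_NAMES})

    per_rep = pd.DataFrame(rows)
    tpr_arr = np.vstack(tprs)
    tpr_mean = tpr_arr.mean(axis=0)
    half = 1.96 * tpr_arr.std(axis=0, ddof=1) / np.sqrt(n_reps)
    # apparent (resubstitution) AUC: model trained on the full dataset,
    # scored on its own training samples
    full_model = ProgressionForest.from_cohort(ds, feature_set, config=config)
    full_results = full_model.fit(seed=int(rep_seeds[0]))
    apparent = roc_from_scores(full_results.resubstitution_scores(),
                               ds.labels()).auc
    boot = BootstrapResult(
        n_reps=n_reps,
        per_rep=per_rep,
        fpr_grid=FPR_GRID.copy(),
        tpr_mean=tpr_mean,
        tpr_band=(np.clip(tpr_mean - half, 0, 1), np.clip(tpr_mean + half, 0, 1)),
        mean_metrics=_mean_metrics(per_rep, ci_method),
        apparent_auc=apparent,
        auc_632plus=auc_632plus(apparent, float(per_rep["auc"].mean())),
        radiomic_schema=list(ds.radiomic_feature_names),
        rep_importances=importances if collect_importances else None,
    )
    per_center_out = {
        c: {"per_rep": pd.DataFrame(r),
            "mean_metrics": _mean_metrics(pd.DataFrame(r), ci_method)}
        for c, r in center_rows.items() if r
    }
    return boot, per_center_out


def run_methodology_external(ds: CohortDataset,
                             feature_set: FeatureSet = "all",
                             n_reps: int = N_REPS_DEFAULT,
                             seed: int = 0,
                             config: ForestConfig | None = None,
                             bootstrap_level: Literal["patient", "bm"] = "patient",
                             collect_importances: bool = False,
                             ci_method: Literal["normal", "percentile"] = "normal",
                             ) -> BootstrapResult:
    """Apply the locked training methodology to one cohort via bootstrap
    resampling (per-rep filter -> hyperparameter optimization -> train,
    operating point from each rep's train OOB ROC)."""
    boot, _ = _bootstrap_engine(ds, feature_set, n_reps, seed, config,
                                bootstrap_level, collect_importances,
                                ci_method, per_center=False)
    return boot


@dataclass
class PooledResult:
    overall: BootstrapResult
    per_center: dict[str, dict]

    def summary(self) -> str:
        lines = [self.overall.summary(), "", "Per-center sub-analysis:"]
        for c, sub in self.per_center.items():
            m = sub["mean_metrics"]
            lines.append(f"  center {c}: AUC={m.auc:.3f} MCR={m.mcr:.3f} "
                         f"FNR={m.fnr:.3f} FPR={m.fpr:.3f} "
                         f"({len(sub['per_rep'])} reps)")
        return "\n".join(lines)


@dataclass
class ExperimentSpec:
    """Declarative description of one validation experiment.

    ``design`` selects the driver; ``train_center``/``test_center`` assign
    cohorts for the model-external design (for the bootstrap designs the
    cohort(s) passed to :meth:`run` are used directly).
    """

    design: Literal["model_external", "methodology_external", "pooled"]
    feature_set: FeatureSet = "all"
    harmonize: bool = False
    consolidated_features: tuple[str, ...] | None = None
    n_reps: int = N_REPS_DEFAULT
    seed: int = 0
    bootstrap_level: Literal["patient", "bm"] = "patient"

    def run(self, *cohorts: CohortDataset, config: ForestConfig | None = None):
        if self.design == "model_external":
            if len(cohorts) != 2:
                raise ValueError("model_external requires two distinct datasets")
            return run_model_external(
                cohorts[0], cohorts[1], self.feature_set,
                harmonize=self.harmonize,
                restrict_features=self.consolidated_features,
                seed=self.seed, config=config)
        if self.design == "methodology_external":
            if len(cohorts) != 1:
                raise ValueError("methodology_external takes one dataset")
            return run_methodology_external(
                cohorts[0], self.feature_set, n_reps=self.n_reps,
                seed=self.seed, config=config,
                bootstrap_level=self.bootstrap_level)
        if self.design == "pooled":
            if len(cohorts) != 2:
                raise ValueError("pooled requires both datasets")
            return run_pooled(cohorts[0], cohorts[1], self.feature_set,
                              n_reps=self.n_reps, seed=self.seed,
                              config=config,
                              bootstrap_level=self.bootstrap_level)
        raise ValueError(f"unknown design {self.design!r}")


def run_pooled(ds_a: CohortDataset, ds_b: CohortDataset,
               feature_set: FeatureSet = "all",
               n_reps: int = N_REPS_DEFAULT,
               seed: int = 0,
               config: ForestConfig | None = None,
               bootstrap_level: Literal["patient", "bm"] = "patient",
               collect_importances: bool = False,
               ci_method: Literal["normal", "percentile"] = "normal",
               ) -> PooledResult:
    """Pool both cohorts, bootstrap as in methodology-external validation,
    and additionally report per-center metrics on each rep's test subset."""
    if list(ds_a.feature_schema) != list(ds_b.feature_schema):
        raise ValueError("cohorts must share the feature schema")
    pooled = CohortDataset(list(ds_a.records) + list(ds_b.records),
                           dict(ds_a.feature_schema),
                           provenance={"pooled": [ds_a.provenance,
                                                  ds_b.provenance]})
    boot, per_center = _bootstrap_engine(pooled, feature_set, n_reps, seed,
                                         config, bootstrap_level,
                                         collect_importances, ci_method,
                                         per_center=True)
    return PooledResult(overall=boot, per_center=per_center)
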