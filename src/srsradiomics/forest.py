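"""Random-decision-forest modeling of post-SRS progression.

`ProgressionForest` is the model object: it is built from a cohort (or a
raw design matrix), applies the inter-feature correlation filter to
radiomic features, and on ``fit`` runs hyperparameter optimization
maximizing out-of-bag (OOB) AUC with class-balanced sample weighting before
refitting the final forest.  `ProgressionForestResults` carries the fitted
estimator, the per-training-sample OOB scores, the OOB ROC and its
upper-left operating point (argmin of FNR^2 + FPR^2), feature importances,
and a ``summary()`` table; test-set evaluation transfers the training
operating point to the test scores.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .cohort import CohortDataset

FeatureSet = Literal["clinical", "radiomic", "all"]


# ---------------------------------------------------------------------------
# ROC primitives

@dataclass(frozen=True)
class RocCurve:
    """Threshold-parameterized ROC: classify positive iff score >= t.

    Points run from (0,0) (threshold +inf) to (1,1); tied scores share a
    point; AUC is trapezoidal.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    fnr: float
    fpr: float

    @property
    def objective(self) -> float:
        return self.fnr ** 2 + self.fpr ** 2


@dataclass
class ErrorMetrics:
    """AUC plus operating-point error rates, optionally with 95% CIs."""

    auc: float
    mcr: float
    fnr: float
    fpr: float
    ci: dict[str, tuple[float, float]] | None = None

    def as_dict(self) -> dict:
        d = {"auc": self.auc, "mcr": self.mcr, "fnr": self.fnr, "fpr": self.fpr}
        if self.ci:
            d["ci"] = {k: list(v) for k, v in self.ci.items()}
        return d


def roc_from_scores(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC from continuous scores and binary labels via a threshold sweep
    over the unique score values."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to build a ROC")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = labels[order]
    # cumulative counts at each unique score (ties collapse to one point)
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], len(s_sorted) - 1]
    tp = np.cumsum(y_sorted)[distinct]
    fp = np.cumsum(1 - y_sorted)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds, fpr, tpr, auc)


def select_operating_point(roc: RocCurve) -> OperatingPoint:
    """Upper-left operating point: argmin over curve points of
    FNR^2 + FPR^2, ties broken toward lower FPR."""
    fnr = 1.0 - roc.tpr
    objective = fnr ** 2 + roc.fpr ** 2
    # lexicographic argmin on (objective, fpr)
    best = int(np.lexsort((roc.fpr, objective))[0])
    return OperatingPoint(threshold=float(roc.thresholds[best]),
                          fnr=float(fnr[best]), fpr=float(roc.fpr[best]))


def metrics_at_threshold(scores: np.ndarray, labels: np.ndarray,
                         threshold: float) -> ErrorMetrics:
    """Confusion-count metrics classifying positive iff score >= threshold;
    AUC is threshold-independent, from the full score set."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    roc = roc_from_scores(scores, labels)
    pred = scores >= threshold
    tp = int((pred & (labels == 1)).sum())
    fp = int((pred & (labels == 0)).sum())
    fn = int((~pred & (labels == 1)).sum())
    tn = int((~pred & (labels == 0)).sum())
    return ErrorMetrics(
        auc=roc.auc,
        mcr=(fp + fn) / len(labels),
        fnr=fn / (fn + tp),
        fpr=fp / (fp + tn),
    )


# ---------------------------------------------------------------------------
# correlation filter

@dataclass
class FilterResult:
    kept: list[str]
    removed: dict[str, str]  # feature -> partner feature or "constant"
    threshold: float


def correlation_filter(matrix: np.ndarray, names: Sequence[str],
                       threshold: float = 0.8,
                       method: Literal["spearman", "pearson"] = "spearman",
                       ) -> FilterResult:
    """Greedy redundancy filter in schema order.

    A feature is removed if its absolute correlation with any already-kept
    feature exceeds the threshold; constant features are removed with
    reason "constant".  Deterministic and independent of sample order.
    """
    x = np.asarray(matrix, dtype=float)
    names = list(names)
    if x.shape[1] != len(names):
        raise ValueError("matrix/name length mismatch")
    if x.shape[1] == 0:
        raise ValueError("need at least one feature")
    if method == "spearman":
        work = np.apply_along_axis(stats.rankdata, 0, x)
    else:
        work = x
    sd = work.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(work, rowvar=False) if work.shape[1] > 1 else np.ones((1, 1))
    kept_idx: list[int] = []
    kept: list[str] = []
    removed: dict[str, str] = {}
    for j, name in enumerate(names):
        if sd[j] == 0:
            removed[name] = "constant"
            continue
        partner = None
        for i in kept_idx:
            if abs(corr[i, j]) > threshold:
                partner = names[i]
                break
        if partner is None:
            kept_idx.append(j)
            kept.append(name)
        else:
            removed[name] = partner
    return FilterResult(kept=kept, removed=removed, threshold=threshold)


# ---------------------------------------------------------------------------
# design matrix

@dataclass
class _DesignSpec:
    """Deterministic cohort -> numeric design-matrix mapping, learned on the
    training cohort and reapplied verbatim to test cohorts."""

    categorical: dict[str, list[str]]      # clinical feature -> category order
    continuous: list[str]
    radiomic: list[str]                    # post-filter radiomic features
    columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.columns:
            cols = []
            for feat, cats in self.categorical.items():
                cols.extend(f"{feat}={c}" for c in cats[1:])  # drop-first coding
            cols.extend(self.continuous)
            cols.extend(self.radiomic)
            self.columns = cols

    def matrix(self, ds: CohortDataset) -> np.ndarray:
        frame = ds.to_frame()
        blocks = []
        for feat, cats in self.categorical.items():
            col = frame[feat].astype(str)
            blocks.append(np.column_stack([(col == c).to_numpy(float)
                                           for c in cats[1:]]))
        for feat in self.continuous:
            blocks.append(frame[feat].to_numpy(float)[:, None])
        if self.radiomic:
            missing = set(self.radiomic) - set(frame.columns)
            if missing:
                raise ValueError(f"test cohort lacks features: {sorted(missing)}")
            blocks.append(frame[list(self.radiomic)].to_numpy(float))
        return np.hstack(blocks) if blocks else np.empty((len(frame), 0))


# ---------------------------------------------------------------------------
# model / results

@dataclass
class ForestConfig:
    """Hyperparameter grid and filter settings.

    The grid spans forest size, features tried per split (sqrt(p), p/3, p)
    and minimum leaf size; it is optimized on OOB AUC.  The default grid is
    intentionally small and fully configurable.
    """

    n_estimators_grid: tuple[int, ...] = (100, 300, 500)
    max_features_grid: tuple[str, ...] = ("sqrt", "third", "all")
    min_samples_leaf_grid: tuple[int, ...] = (1, 3, 5)
    correlation_threshold: float = 0.8
    correlation_method: Literal["spearman", "pearson"] = "spearman"
    importance: Literal["permutation", "impurity"] = "permutation"

    def sklearn_max_features(self, key: str):
        return {"sqrt": "sqrt", "third": 1.0 / 3.0, "all": 1.0}[key]


class ProgressionForest:
    """Random-decision-forest progression model for one training cohort."""

    def __init__(self, X: np.ndarray, y: np.ndarray, design: _DesignSpec,
                 config: ForestConfig | None = None):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=int)
        self.design = design
        self.config = config or ForestConfig()
        self.filter_result: FilterResult | None = None
        if len(np.unique(self.y)) < 2:
            raise ValueError("training labels contain a single class")

    @classmethod
    def from_cohort(cls, ds: CohortDataset, feature_set: FeatureSet = "all",
                    config: ForestConfig | None = None) -> "ProgressionForest":
        """Build the model from a cohort, one-hot-encoding categorical
        clinical features and correlation-filtering radiomic ones."""
        config = config or ForestConfig()
        frame = ds.to_frame()
        categorical: dict[str, list[str]] = {}
        continuous: list[str] = []
        radiomic: list[str] = []
        filter_result = None
        if feature_set in ("clinical", "all"):
            for name, kind in ds.feature_schema.items():
                if kind == "categorical-clinical":
                    categorical[name] = sorted(frame[name].astype(str).unique())
                elif kind == "continuous-clinical":
                    continuous.append(name)
        if feature_set in ("radiomic", "all"):
            rad_names = ds.radiomic_feature_names
            filter_result = correlation_filter(
                ds.radiomic_matrix(), rad_names,
                threshold=config.correlation_threshold,
                method=config.correlation_method)
            radiomic = filter_result.kept
        design = _DesignSpec(categorical, continuous, radiomic)
        model = cls(design.matrix(ds), ds.labels(), design, config)
        model.filter_result = filter_result
        return model

    def fit(self, seed: int = 0) -> "ProgressionForestResults":
        """Grid-search hyperparameters on OOB AUC, then refit the winner.

        Forest sizes are explored by warm-started growth so each
        (max_features, min_leaf) cell is built once.  Deterministic for a
        fixed seed and data.
        """
        cfg = self.config
        # class-balanced sample weights (explicit, so warm-started growth
        # sees identical weights at every stage)
        n, n_pos = len(self.y), int(self.y.sum())
        sw = np.where(self.y == 1, n / (2.0 * n_pos), n / (2.0 * (n - n_pos)))
        best: tuple[float, tuple] | None = None
        trace = []
        with warnings.catch_warnings():
            warnings.filterwarnings(
                "ignore", message="Some inputs do not have OOB scores")
            for mf in cfg.max_features_grid:
                for leaf in cfg.min_samples_leaf_grid:
                    clf = RandomForestClassifier(
                        n_estimators=0, warm_start=True, oob_score=True,
                        bootstrap=True,
                        max_features=cfg.sklearn_max_features(mf),
                        min_samples_leaf=leaf, random_state=seed, n_jobs=1)
                    for n_trees in sorted(cfg.n_estimators_grid):
                        clf.n_estimators = n_trees
                        clf.fit(self.X, self.y, sample_weight=sw)
                        oob = clf.oob_decision_function_[:, 1]
                        valid = ~np.isnan(oob)
                        auc = roc_from_scores(oob[valid], self.y[valid]).auc
                        params = (n_trees, mf, leaf)
                        trace.append((params, auc))
                        if best is None or auc > best[0]:
                            best = (auc, params)
            assert best is not None
            n_trees, mf, leaf = best[1]
            final = RandomForestClassifier(
                n_estimators=n_trees, oob_score=True, bootstrap=True,
                max_features=cfg.sklearn_max_features(mf),
                min_samples_leaf=leaf, random_state=seed, n_jobs=1)
            final.fit(self.X, self.y, sample_weight=sw)
            oob = final.oob_decision_function_[:, 1]
        return ProgressionForestResults(self, final,
                                        {"n_estimators": n_trees,
                                         "max_features": mf,
                                         "min_samples_leaf": leaf},
                                        oob, seed, trace, sample_weight=sw)


class ProgressionForestResults:
    """Fitted forest with OOB diagnostics and operating-point transfer."""

    def __init__(self, model: ProgressionForest,
                 estimator: RandomForestClassifier, params: dict,
                 oob_scores: np.ndarray, seed: int, search_trace: list,
                 sample_weight: np.ndarray | None = None):
        self.model = model
        self.estimator = estimator
        self.params = params
        self.oob_scores = oob_scores
        self.seed = seed
        self.search_trace = search_trace
        self.sample_weight = sample_weight
        valid = ~np.isnan(oob_scores)
        self.oob_roc = roc_from_scores(oob_scores[valid], model.y[valid])
        self.operating_point = select_operating_point(self.oob_roc)

    @property
    def oob_auc(self) -> float:
        return self.oob_roc.auc

    def predict_scores(self, ds: CohortDataset) -> np.ndarray:
        """Positive-class probability (forest vote fraction) per BM."""
        X = self.model.design.matrix(ds)
        return self.estimator.predict_proba(X)[:, 1]

    def resubstitution_scores(self) -> np.ndarray:
        return self.estimator.predict_proba(self.model.X)[:, 1]

    def evaluate(self, ds: CohortDataset,
                 threshold: float | None = None) -> tuple[ErrorMetrics, RocCurve]:
        """Score a test cohort, transferring the training OOB operating
        point (or an explicit threshold) to the test scores."""
        scores = self.predict_scores(ds)
        labels = ds.labels()
        thr = self.operating_point.threshold if threshold is None else threshold
        return metrics_at_threshold(scores, labels, thr), roc_from_scores(scores, labels)

    def feature_importances(self, rng: np.random.Generator | None = None,
                            ) -> pd.Series:
        """Raw feature importance per design column.

        Default is out-of-bag permutation importance (mean increase in a
        tree's OOB misclassification rate when the feature is permuted);
        impurity importance is available via the config.
        """
        if self.model.config.importance == "impurity":
            vals = self.estimator.feature_importances_
        else:
            rng = rng or np.random.default_rng(self.seed)
            vals = oob_permutation_importance(self.estimator, self.model.X,
                                              self.model.y, rng,
                                              self.sample_weight)
        return pd.Series(vals, index=self.model.design.columns)

    def save(self, path_prefix: str | Path) -> None:
        """Persist the fitted model: JSON metadata (hyperparameters, design,
        filter result, operating point) plus a joblib blob of the forest."""
        prefix = Path(path_prefix)
        meta = {
            "params": self.params,
            "seed": self.seed,
            "oob_auc": self.oob_auc,
            "operating_point": {"threshold": self.operating_point.threshold,
                                "fnr": self.operating_point.fnr,
                                "fpr": self.operating_point.fpr},
            "design": {"categorical": self.model.design.categorical,
                       "continuous": self.model.design.continuous,
                       "radiomic": self.model.design.radiomic},
            "filter": (None if self.model.filter_result is None else
                       {"kept": self.model.filter_result.kept,
                        "removed": self.model.filter_result.removed,
                        "threshold": self.model.filter_result.threshold}),
        }
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))
        joblib.dump({"estimator": self.estimator,
                     "oob_scores": self.oob_scores,
                     "sample_weight": self.sample_weight,
                     "X": self.model.X, "y": self.model.y},
                    prefix.with_suffix(".joblib"))

    @classmethod
    def load(cls, path_prefix: str | Path) -> "ProgressionForestResults":
        prefix = Path(path_prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        blob = joblib.load(prefix.with_suffix(".joblib"))
        design = _DesignSpec(meta["design"]["categorical"],
                             meta["design"]["continuous"],
                             meta["design"]["radiomic"])
        model = ProgressionForest(blob["X"], blob["y"], design)
        if meta["filter"] is not None:
            model.filter_result = FilterResult(**meta["filter"])
        return cls(model, blob["estimator"], meta["params"],
                   blob["oob_scores"], meta["seed"], [],
                   sample_weight=blob["sample_weight"])

    def summary(self) -> str:
        buf = io.StringIO()
        op = self.operating_point
        buf.write("Progression random-decision-forest results\n")
        buf.write("=" * 46 + "\n")
        buf.write(f"Training BMs:            {len(self.model.y)}\n")
        buf.write(f"Positives:               {int(self.model.y.sum())} "
                  f"({self.model.y.mean():.1%})\n")
        buf.write(f"Design columns:          {len(self.model.design.columns)}\n")
        if self.model.filter_result is not None:
            fr = self.model.filter_result
            buf.write(f"Radiomic kept/removed:   {len(fr.kept)}/{len(fr.removed)} "
                      f"(|rho| > {fr.threshold})\n")
        buf.write(f"Hyperparameters:         trees={self.params['n_estimators']}, "
                  f"max_features={self.params['max_features']}, "
                  f"min_leaf={self.params['min_samples_leaf']}\n")
        buf.write(f"OOB AUC:                 {self.oob_auc:.3f}\n")
        buf.write(f"Operating point:         threshold={op.threshold:.3f} "
                  f"FNR={op.fnr:.3f} FPR={op.fpr:.3f}\n")
        return buf.getvalue()


def _tree_bootstrap_indices(tree_random_state: int, n_samples: int,
                            sample_weight: np.ndarray | None = None,
                            ) -> np.ndarray:
    # mirrors sklearn's per-tree bootstrap draw (max_samples=None): uniform
    # with replacement, or weighted by sample_weight when one was passed
    rs = np.random.RandomState(tree_random_state)
    if sample_weight is None:
        return rs.randint(0, n_samples, n_samples)
    p = np.asarray(sample_weight, dtype=float)
    return rs.choice(n_samples, n_samples, replace=True, p=p / p.sum())


def oob_permutation_importance(estimator: RandomForestClassifier,
                               X: np.ndarray, y: np.ndarray,
                               rng: np.random.Generator,
                               sample_weight: np.ndarray | None = None,
                               ) -> np.ndarray:
    """Breiman-style OOB permutation importance.

    For each tree, the misclassification rate on its out-of-bag samples is
    compared before and after permuting one feature's values among those
    samples; the importance is the mean error increase across trees.
    """
    n, p = X.shape
    totals = np.zeros(p)
    n_used = np.zeros(p)
    for tree in estimator.estimators_:
        boot = _tree_bootstrap_indices(tree.random_state, n, sample_weight)
        oob_mask = np.ones(n, dtype=bool)
        oob_mask[boot] = False
        idx = np.nonzero(oob_mask)[0]
        if len(idx) == 0:
            continue
        x_oob, y_oob = X[idx], y[idx]
        n0 = len(idx)
        base_err = float((tree.predict(x_oob) != y_oob).mean())
        # one stacked predict call: block j is x_oob with column j permuted
        big = np.tile(x_oob, (p, 1))
        for j in range(p):
            perm = rng.permutation(n0)
            big[j * n0:(j + 1) * n0, j] = x_oob[perm, j]
        errs = (tree.predict(big).reshape(p, n0) != y_oob[None, :]).mean(axis=1)
        totals += errs - base_err
        n_used += 1
    return np.divide(totals, np.maximum(n_used, 1))
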