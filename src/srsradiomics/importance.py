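"""Feature-importance consolidation across centers.

Per bootstrap repetition the forest's raw importance scores are min-max
normalized to [0, 1] over the features the model actually used; features
removed by the correlation filter are assigned 0.  The per-rep scores are
averaged across repetitions and re-normalized (divided by the maximum) so
the most important feature scores 1.  Features scoring >= 0.75 are deemed
"highly important".  The cross-center consolidated ranking orders features
by the MINIMUM of their per-center scores — a feature must be important at
both centers to rank highly — and the top-n sweep reruns model-external
validation (with ComBat) restricted to the best n consolidated features,
n = 1..10 in both transfer directions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortDataset
from .forest import ForestConfig
from .validation import BootstrapResult, run_model_external

logger = logging.getLogger(__name__)

HIGHLY_IMPORTANT_CUTOFF = 0.75
TOP_K_DEFAULT = 10


@dataclass
class ImportanceProfile:
    """Mean normalized importance per feature in [0, 1] for one center."""

    center_id: str
    scores: pd.Series             # index = radiomic schema, values in [0,1]
    per_rep: pd.DataFrame         # reps x features, normalized per rep

    def __post_init__(self) -> None:
        if len(self.scores) and not self.scores.between(0.0, 1.0 + 1e-12).all():
            raise ValueError("importance scores must lie in [0, 1]")


def _normalize_rep(raw: pd.Series, schema: list[str]) -> pd.Series:
    """Min-max normalize one repetition's raw scores over the used features;
    features absent (filtered) score 0."""
    out = pd.Series(0.0, index=schema)
    used = raw.index.intersection(schema)
    vals = raw.loc[used].astype(float)
    if len(vals) == 0:
        return out
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        if hi == 0:
            logger.info("all-zero importance repetition contributes zeros")
            return out
        out.loc[used] = 1.0
        return out
    out.loc[used] = (vals - lo) / (hi - lo)
    return out


def importance_profile(boot: BootstrapResult, center_id: str,
                       ) -> ImportanceProfile:
    """Build a center's importance profile from its bootstrap run
    (requires the run to have collected per-rep importances)."""
    if boot.rep_importances is None:
        raise ValueError("bootstrap result carries no per-rep importances; "
                         "rerun with collect_importances=True")
    schema = boot.radiomic_schema
    per_rep = pd.DataFrame(
        [_normalize_rep(raw, schema) for raw in boot.rep_importances])
    mean = per_rep.mean(axis=0)
    peak = float(mean.max())
    scores = mean / peak if peak > 0 else mean
    return ImportanceProfile(center_id=center_id, scores=scores,
                             per_rep=per_rep)


def highly_important(profile: ImportanceProfile,
                     cutoff: float = HIGHLY_IMPORTANT_CUTOFF) -> list[str]:
    """Features with score >= cutoff, most important first."""
    sel = profile.scores[profile.scores >= cutoff]
    return list(sel.sort_values(ascending=False, kind="stable").index)


@dataclass
class ConsolidatedRanking:
    """Features ordered by the minimum of their per-center scores."""

    ranking: pd.Series            # ordered feature -> min-score
    cutoff: float = HIGHLY_IMPORTANT_CUTOFF
    top_k: int = TOP_K_DEFAULT

    def top(self, n: int | None = None) -> list[str]:
        n = self.top_k if n is None else n
        return list(self.ranking.index[:n])


def consolidate(profile_a: ImportanceProfile, profile_b: ImportanceProfile,
                k: int = TOP_K_DEFAULT) -> ConsolidatedRanking:
    """Cross-center consolidation: score(f) = min(score_A(f), score_B(f)),
    sorted descending with ties broken by feature name."""
    if list(profile_a.scores.index) != list(profile_b.scores.index):
        raise ValueError("profiles must share the feature schema")
    min_score = np.minimum(profile_a.scores, profile_b.scores)
    ordered = min_score.sort_index().sort_values(ascending=False, kind="stable")
    return ConsolidatedRanking(ranking=ordered.iloc[:k], top_k=k)


def consolidation_sweep(ds_a: CohortDataset, ds_b: CohortDataset,
                        ranking: ConsolidatedRanking,
                        n_max: int = TOP_K_DEFAULT,
                        seed: int = 0,
                        config: ForestConfig | None = None) -> pd.DataFrame:
    """Model-external validation with ComBat using the top-n consolidated
    radiomic features, n = 1..n_max, in both transfer directions.

    Returns one row per (n, direction) with the error metrics, plus a
    ``best_n`` attribute row selector: the n maximizing the mean
    cross-direction AUC.
    """
    if len(ranking.ranking) < n_max:
        raise ValueError(f"ranking has {len(ranking.ranking)} features; "
                         f"need >= {n_max}")
    rows = []
    for n in range(1, n_max + 1):
        feats = ranking.top(n)
        for direction, (train, test) in {
            "A->B": (ds_a, ds_b), "B->A": (ds_b, ds_a),
        }.items():
            out = run_model_external(train, test, feature_set="radiomic",
                                     harmonize=True, restrict_features=feats,
                                     seed=seed, config=config)
            m = out["metrics"]
            rows.append({"n": n, "direction": direction, "auc": m.auc,
                         "mcr": m.mcr, "fnr": m.fnr, "fpr": m.fpr})
    table = pd.DataFrame(rows)
    mean_auc = table.groupby("n")["auc"].mean()
    table.attrs["best_n"] = int(mean_auc.idxmax())
    table.attrs["mean_auc_by_n"] = mean_auc.to_dict()
    return table
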