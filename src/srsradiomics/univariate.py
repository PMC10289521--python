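"""Univariate cohort statistics.

Per-feature outcome association within a center (progressed vs not) and
center-A-vs-center-B distribution comparison: uncorrected Pearson
chi-squared for categorical clinical features, two-sided Wilcoxon rank-sum
with tie-corrected normal approximation for continuous clinical and
radiomic features.  Radiomic results are summarized per feature class as
the count and fraction of features with p < 0.05.  No multiple-testing
correction is applied anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._schema import RADIOMIC_CLASSES, radiomic_class_of
from .cohort import CohortDataset

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass(frozen=True)
class ContingencyTable:
    """Category counts in two groups (columns), e.g. progressed / not."""

    row_labels: tuple[str, ...]
    counts: np.ndarray  # shape (n_rows, 2)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[1] != 2 or counts.shape[0] < 2:
            raise ValueError("contingency table must be (>=2 rows) x 2 columns")
        if (counts < 0).any() or counts.sum() == 0:
            raise ValueError("counts must be nonnegative with positive total")

    @classmethod
    def from_groups(cls, categories: np.ndarray, groups: np.ndarray,
                    ) -> "ContingencyTable":
        """Cross-tabulate category membership against a binary grouping."""
        cats = sorted(map(str, np.unique(categories)))
        glev = sorted(map(str, np.unique(groups)))
        if len(glev) != 2:
            raise ValueError(f"need exactly 2 groups, got {glev}")
        cat_arr = categories.astype(str)
        grp_arr = groups.astype(str)
        counts = np.array([[int(((cat_arr == c) & (grp_arr == g)).sum())
                            for g in glev] for c in cats])
        return cls(tuple(cats), counts)


def chi_squared_p(table: ContingencyTable) -> float:
    """Uncorrected Pearson chi-squared upper-tail p-value.

    A zero row or column marginal raises an error naming the category.
    """
    counts = np.asarray(table.counts, dtype=float)
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    for lbl, s in zip(table.row_labels, row_sums):
        if s == 0:
            raise ValueError(f"zero marginal for category {lbl!r}")
    if (col_sums == 0).any():
        raise ValueError("zero column marginal")
    expected = np.outer(row_sums, col_sums) / counts.sum()
    if (expected < 5).any():
        logger.warning("chi-squared table has expected counts < 5: %s",
                       list(table.row_labels))
    stat = float(((counts - expected) ** 2 / expected).sum())
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    return float(stats.chi2.sf(stat, df))


def rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null distribution for small tie-free samples, tie-corrected
    normal approximation (no continuity correction) otherwise.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    return float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method="auto",
                                    use_continuity=False).pvalue)


@dataclass
class UnivariateReport:
    """Per-feature univariate p-values and the radiomic class summary."""

    feature_table: pd.DataFrame  # feature, kind, test, columns of p-values
    class_summary: pd.DataFrame  # class, n_features, per-column n/fraction p<.05

    def to_csv(self, path) -> None:
        self.feature_table.to_csv(path, index=False)


def _feature_pvalue(ds_values, labels, kind: str) -> float | None:
    try:
        if kind == "categorical-clinical":
            return chi_squared_p(ContingencyTable.from_groups(
                np.asarray(ds_values), np.asarray(labels)))
        mask0 = np.asarray(labels).astype(str) == sorted(
            map(str, np.unique(labels)))[0]
        vals = np.asarray(ds_values, dtype=float)
        return rank_sum_p(vals[mask0], vals[~mask0])
    except ValueError as exc:
        logger.warning("univariate test flagged: %s", exc)
        return None


def table1_report(ds_a: CohortDataset, ds_b: CohortDataset) -> UnivariateReport:
    """Univariate analysis of clinical and radiomic features.

    For every feature: progressed-vs-not within center A, within center B,
    and pooled; plus the A-vs-B distribution comparison.  Failures of a
    single test become flagged (missing) cells, not aborts.
    """
    if list(ds_a.feature_schema) != list(ds_b.feature_schema):
        raise ValueError("datasets must share the feature schema")
    frames = {"A": ds_a.to_frame(), "B": ds_b.to_frame()}
    # dataset membership, not the center_id column, defines the A-vs-B test
    frames["A"]["__cohort__"] = "A"
    frames["B"]["__cohort__"] = "B"
    frames["pooled"] = pd.concat([frames["A"], frames["B"]], ignore_index=True)

    rows = []
    for feat, kind in ds_a.feature_schema.items():
        test = "chi_squared" if kind == "categorical-clinical" else "rank_sum"
        row: dict = {"feature": feat, "kind": kind, "test": test}
        for col, frame in frames.items():
            row[f"p_outcome_{col}"] = _feature_pvalue(
                frame[feat].to_numpy(), frame["label"].to_numpy(), kind)
        row["p_center"] = _feature_pvalue(
            frames["pooled"][feat].to_numpy(),
            frames["pooled"]["__cohort__"].to_numpy(), kind)
        rows.append(row)
    feature_table = pd.DataFrame(rows)

    rad = feature_table[feature_table["kind"] == "radiomic"].copy()
    def _class_or_misc(f: str) -> str:
        try:
            return radiomic_class_of(f)
        except ValueError:
            return "other"

    rad["class"] = [_class_or_misc(f) for f in rad["feature"]]
    summary_rows = []
    pcols = ["p_outcome_A", "p_outcome_B", "p_outcome_pooled", "p_center"]
    classes = [c for c in RADIOMIC_CLASSES if (rad["class"] == c).any()]
    for cls in classes + ["total"]:
        sub = rad if cls == "total" else rad[rad["class"] == cls]
        row = {"class": cls, "n_features": len(sub)}
        for col in pcols:
            n_sig = int((sub[col] < ALPHA).sum())
            row[f"n_sig_{col}"] = n_sig
            row[f"frac_sig_{col}"] = n_sig / len(sub) if len(sub) else float("nan")
        summary_rows.append(row)
    return UnivariateReport(feature_table, pd.DataFrame(summary_rows))
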