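"""ComBat batch-effect harmonization of radiomic features across centers.

Parametric empirical-Bayes location/scale adjustment: each feature is
standardized against its grand mean and pooled within-batch SD, per-center
shift (gamma) and scale (delta) effects are estimated and shrunk toward
center-level normal / inverse-gamma priors by iterative conditional
estimation, and the inverse transform

    x* = sigma_g * (z - gamma*_ig) / delta*_ig + alpha_g

removes the center effects.  No biological covariates are preserved: within
this pipeline ComBat is applied only to radiomic features, and keeping the
outcome out of the model avoids leaking labels across train/test splits.
The model serializes to JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

CONVERGENCE_TOL = 1e-6
MAX_ITER = 1000


@dataclass
class CombatModel:
    """Fitted per-feature grand location/scale plus per-center shrunken
    shift/scale corrections and the center-level prior hyperparameters."""

    feature_names: list[str]
    centers: list[str]
    alpha: np.ndarray            # (p,) grand mean per feature
    sigma: np.ndarray            # (p,) pooled within-batch SD per feature
    gamma_star: dict[str, np.ndarray]   # center -> (p,) shrunken shift
    delta_star: dict[str, np.ndarray]   # center -> (p,) shrunken scale (>0)
    priors: dict[str, dict[str, float]]  # center -> gamma_bar, tau2, a_prior, b_prior
    zero_variance: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "centers": self.centers,
            "alpha": self.alpha.tolist(),
            "sigma": self.sigma.tolist(),
            "gamma_star": {c: v.tolist() for c, v in self.gamma_star.items()},
            "delta_star": {c: v.tolist() for c, v in self.delta_star.items()},
            "priors": self.priors,
            "zero_variance": self.zero_variance,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "CombatModel":
        d = json.loads(Path(path).read_text())
        return cls(
            feature_names=d["feature_names"],
            centers=d["centers"],
            alpha=np.asarray(d["alpha"]),
            sigma=np.asarray(d["sigma"]),
            gamma_star={c: np.asarray(v) for c, v in d["gamma_star"].items()},
            delta_star={c: np.asarray(v) for c, v in d["delta_star"].items()},
            priors=d["priors"],
            zero_variance=d.get("zero_variance", []),
        )


def _postmean(g_hat, g_bar, n, d_star, tau2):
    return (n * tau2 * g_hat + d_star * g_bar) / (n * tau2 + d_star)


def _postvar(ssq, n, a, b):
    return (0.5 * ssq + b) / (n / 2.0 + a - 1.0)


def _it_solve(z_batch: np.ndarray, g_hat: np.ndarray, d_hat: np.ndarray,
              g_bar: float, tau2: float, a: float, b: float,
              tol: float = CONVERGENCE_TOL) -> tuple[np.ndarray, np.ndarray]:
    """Iterative conditional estimation of the empirical-Bayes posteriors."""
    n = z_batch.shape[0]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(MAX_ITER):
        g_new = _postmean(g_hat, g_bar, n, d_old, tau2)
        ssq = ((z_batch - g_new[None, :]) ** 2).sum(axis=0)
        d_new = _postvar(ssq, n, a, b)
        change = max(
            float((np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)).max()),
            float((np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)).max()),
        )
        g_old, d_old = g_new, d_new
        if change < tol:
            break
    return g_old, d_old


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = float(delta_hat.mean()), float(delta_hat.var(ddof=1))
    return (2.0 * s2 + m ** 2) / s2

def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = float(delta_hat.mean()), float(delta_hat.var(ddof=1))
    return (m * s2 + m ** 3) / s2


def fit_combat(features: np.ndarray, center_labels: np.ndarray,
               feature_names: list[str] | None = None) -> CombatModel:
    """Fit the ComBat model on a (samples x features) matrix.

    Requires at least 2 centers with at least 2 samples each.  Zero-variance
    features are flagged and passed through unharmonized.
    """
    x = np.asarray(features, dtype=float)
    labels = np.asarray(center_labels).astype(str)
    if x.ndim != 2:
        raise ValueError("feature matrix must be 2-D (samples x features)")
    centers = sorted(np.unique(labels))
    if len(centers) < 2:
        raise ValueError("ComBat requires at least 2 centers")
    for c in centers:
        if (labels == c).sum() < 2:
            raise ValueError(f"center {c!r} has fewer than 2 samples")
    n, p = x.shape
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(p)]

    var_all = x.var(axis=0)
    zero_var = var_all == 0
    if zero_var.any():
        flagged = [feature_names[i] for i in np.nonzero(zero_var)[0]]
        logger.warning("zero-variance features passed through unharmonized: %s",
                       flagged)
    ok = ~zero_var

    batch_means = {c: x[labels == c].mean(axis=0) for c in centers}
    n_batch = {c: int((labels == c).sum()) for c in centers}
    alpha = sum(n_batch[c] * batch_means[c] for c in centers) / n
    # pooled within-batch variance (residual after batch means)
    resid = x.copy()
    for c in centers:
        resid[labels == c] -= batch_means[c][None, :]
    sigma = np.sqrt((resid ** 2).sum(axis=0) / n)
    sigma_safe = np.where(ok, np.maximum(sigma, 1e-30), 1.0)

    z = (x - alpha[None, :]) / sigma_safe[None, :]

    gamma_star: dict[str, np.ndarray] = {}
    delta_star: dict[str, np.ndarray] = {}
    priors: dict[str, dict[str, float]] = {}
    for c in centers:
        zc = z[labels == c][:, ok]
        g_hat = zc.mean(axis=0)
        d_hat = zc.var(axis=0, ddof=1)
        g_bar, tau2 = float(g_hat.mean()), float(g_hat.var(ddof=1))
        a, b = _aprior(d_hat), _bprior(d_hat)
        g_st, d_st = _it_solve(zc, g_hat, d_hat, g_bar, tau2, a, b)
        g_full = np.zeros(p)
        d_full = np.ones(p)
        g_full[ok] = g_st
        d_full[ok] = np.sqrt(np.maximum(d_st, 1e-30))
        gamma_star[c] = g_full
        delta_star[c] = d_full
        priors[c] = {"gamma_bar": g_bar, "tau2": tau2,
                     "a_prior": a, "b_prior": b}

    return CombatModel(
        feature_names=list(feature_names),
        centers=centers,
        alpha=alpha,
        sigma=np.where(ok, sigma, 0.0),
        gamma_star=gamma_star,
        delta_star=delta_star,
        priors=priors,
        zero_variance=[feature_names[i] for i in np.nonzero(zero_var)[0]],
    )


def apply_combat(model: CombatModel, features: np.ndarray,
                 center_labels: np.ndarray) -> np.ndarray:
    """Remove the fitted center effects from a feature matrix.

    Samples from centers unseen at fit time raise an error.  Zero-variance
    features pass through unchanged.
    """
    x = np.asarray(features, dtype=float)
    labels = np.asarray(center_labels).astype(str)
    if x.shape[1] != len(model.feature_names):
        raise ValueError("feature matrix does not match the model schema")
    unseen = set(np.unique(labels)) - set(model.centers)
    if unseen:
        raise ValueError(f"unseen center labels: {sorted(unseen)}")
    zero_var = np.array([f in set(model.zero_variance)
                         for f in model.feature_names])
    ok = ~zero_var
    sigma_safe = np.where(ok, np.maximum(model.sigma, 1e-30), 1.0)
    out = x.copy()
    for c in model.centers:
        sel = labels == c
        if not sel.any():
            continue
        z = (x[sel] - model.alpha[None, :]) / sigma_safe[None, :]
        adj = (z - model.gamma_star[c][None, :]) / model.delta_star[c][None, :]
        harm = adj * sigma_safe[None, :] + model.alpha[None, :]
        out[sel] = np.where(ok[None, :], harm, x[sel])
    return out


def harmonize_cohorts(ds_a, ds_b, model: CombatModel | None = None):
    """Harmonize the radiomic features of two cohorts jointly.

    Fits ComBat on the union of both centers' radiomic matrices unless a
    pre-fit model is supplied (fitting on pooled train+test features leaks
    distributional information across the split; this is logged).  Labels
    and clinical features are never altered.
    """
    if list(ds_a.radiomic_feature_names) != list(ds_b.radiomic_feature_names):
        raise ValueError("cohorts must share the radiomic schema")
    xa, xb = ds_a.radiomic_matrix(), ds_b.radiomic_matrix()
    labels = np.concatenate([ds_a.centers(), ds_b.centers()])
    if model is None:
        logger.info("fitting ComBat on the pooled feature matrices of both "
                    "cohorts (cross-center preprocessing; train/test "
                    "distributional leakage is possible)")
        model = fit_combat(np.vstack([xa, xb]), labels,
                           feature_names=ds_a.radiomic_feature_names)
    harmonized = apply_combat(model, np.vstack([xa, xb]), labels)
    return (ds_a.with_radiomic_matrix(harmonized[: len(xa)]),
            ds_b.with_radiomic_matrix(harmonized[len(xa):]),
            model)
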