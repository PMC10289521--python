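"""Two-center synthetic cohorts of brain metastases (BMs).

Each BM record carries 8 clinical features, a 107-name radiomic feature
vector and a binary post-SRS progression label.  The generator emulates the
statistical structure a dual-center radiomics analysis has to cope with:

* two centers of unequal size (defaults 123 and 117 BMs grouped within 99
  and 62 patients) with progression prevalences of 22.0% and 17.1%;
* clinical features whose categorical distributions differ strongly by
  center (site, histology, systemic therapy, fractionation) and BM volumes
  that are log-normal with very different medians (~3500 vs ~329 mm^3);
* radiomic features drawn from a latent block-correlated Gaussian, with a
  sparse true outcome signal carried by a configurable feature subset plus
  log-volume;
* per-center batch effects on radiomic features only, in the location/scale
  form that ComBat assumes: x = alpha_f + gamma_cf + delta_cf * eps.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from ._schema import (
    CATEGORICAL_CLINICAL,
    CLINICAL_FEATURES,
    CONTINUOUS_CLINICAL,
    RADIOMIC_FEATURES,
)

FeatureKind = Literal["categorical-clinical", "continuous-clinical", "radiomic"]

#: Default outcome-signal carriers: texture features found mutually
#: predictive at both centers (zone entropy / inverse difference normalized
#: being the canonical cross-center pair, plus cluster shade and the second
#: informational measure of correlation).
DEFAULT_SIGNAL_FEATURES = (
    "original_glszm_ZoneEntropy",
    "original_glcm_Idn",
    "original_glcm_ClusterShade",
    "original_glcm_Imc2",
)

# Per-center clinical sampling profiles approximating the observed cohort
# marginals: category probabilities for the categorical features, log-normal
# (mu, sigma) for volume, normal (mu, sigma, lo, hi) for age, and a discrete
# dose menu in Gy.
DEFAULT_CLINICAL_PROFILES: dict[str, dict] = {
    "A": {
        "sex": {"Female": 66 / 123, "Male": 57 / 123},
        "primary_site": {"Lung": 70 / 123, "Breast": 14 / 123,
                         "Skin": 9 / 123, "Other": 30 / 123},
        "histology": {"Adenocarcinoma": 65 / 123, "NSCLC Other": 36 / 123,
                      "Melanoma": 9 / 123, "Squamous": 8 / 123,
                      "Other": 5 / 123},
        "systemic_therapy": {"Yes": 113 / 123, "No": 10 / 123},
        "fractions": {1: 113 / 123, 3: 10 / 123},
        "log_volume": (np.log(3500.0), 1.0),
        "age": (59.0, 9.0, 38.0, 90.0),
        "dose_menu": ([15.0, 18.0, 21.0, 24.0], [0.10, 0.25, 0.45, 0.20]),
    },
    "B": {
        "sex": {"Female": 71 / 117, "Male": 46 / 117},
        "primary_site": {"Lung": 89 / 117, "Breast": 10 / 117,
                         "Skin": 8 / 117, "Other": 10 / 117},
        "histology": {"Adenocarcinoma": 82 / 117, "NSCLC Other": 9 / 117,
                      "Melanoma": 8 / 117, "Squamous": 8 / 117,
                      "Other": 10 / 117},
        "systemic_therapy": {"Yes": 57 / 117, "No": 60 / 117},
        "fractions": {1: 58 / 117, 3: 59 / 117},
        "log_volume": (np.log(329.0), 1.0),
        "age": (67.0, 8.0, 40.0, 90.0),
        "dose_menu": ([18.0, 21.0, 24.0, 27.0], [0.20, 0.45, 0.25, 0.10]),
    },
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the two-center synthetic cohort generator.

    ``signal_effect_size`` is the log-odds change in progression probability
    per 1-SD increase of each signal feature's latent (pre-batch) value;
    ``volume_effect_size`` plays the same role for standardized log-volume,
    volume being the one clinical predictor shared by both centers.
    ``batch_shift_sd`` is the SD (in units of each feature's own scale) of
    the per-feature additive center effect; ``batch_scale_range`` bounds the
    per-feature multiplicative center effect.  The defaults put roughly 80%
    of radiomic features significantly apart between centers, the regime a
    dual-center study actually observes.
    """

    seed: int = 0
    n_bms_per_center: tuple[int, int] = (123, 117)
    n_patients_per_center: tuple[int, int] = (99, 62)
    prevalence_per_center: tuple[float, float] = (0.220, 0.171)
    n_radiomic_features: int = 107
    signal_feature_names: tuple[str, ...] = DEFAULT_SIGNAL_FEATURES
    signal_effect_size: float = 1.0
    volume_effect_size: float = 0.6
    batch_shift_sd: float = 0.75
    batch_scale_range: tuple[float, float] = (0.7, 1.4)
    block_correlation: float = 0.5
    n_blocks: int = 10
    clinical_profiles: dict | None = None

    def __post_init__(self) -> None:
        for n_bm, n_pat in zip(self.n_bms_per_center, self.n_patients_per_center):
            if n_pat <= 0 or n_bm < n_pat:
                raise ValueError("need n_bms >= n_patients >= 1 per center")
        for prev in self.prevalence_per_center:
            if not 0.0 < prev < 1.0:
                raise ValueError(f"prevalence must be in (0,1), got {prev}")
        if self.n_radiomic_features <= 0:
            raise ValueError("n_radiomic_features must be positive")
        lo, hi = self.batch_scale_range
        if lo <= 0 or hi <= 0 or hi < lo:
            raise ValueError("batch_scale_range must be a positive interval")
        if not 0.0 <= self.block_correlation < 1.0:
            raise ValueError("block_correlation must be in [0, 1)")
        if self.n_blocks <= 0:
            raise ValueError("n_blocks must be positive")
        if self.batch_shift_sd < 0 or self.signal_effect_size < 0:
            raise ValueError("effect sizes must be nonnegative")
        names = set(self.feature_names())
        missing = [f for f in self.signal_feature_names if f not in names]
        if missing:
            raise ValueError(f"signal features outside schema: {missing}")

    def feature_names(self) -> list[str]:
        """Radiomic feature names for this configuration."""
        if self.n_radiomic_features == len(RADIOMIC_FEATURES):
            return list(RADIOMIC_FEATURES)
        if self.n_radiomic_features < len(RADIOMIC_FEATURES):
            return RADIOMIC_FEATURES[: self.n_radiomic_features]
        extra = self.n_radiomic_features - len(RADIOMIC_FEATURES)
        return RADIOMIC_FEATURES + [f"synthetic_radiomic_{i:03d}" for i in range(extra)]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["signal_feature_names"] = list(self.signal_feature_names)
        return d


@dataclass
class BMRecord:
    """One brain metastasis: identifiers, clinical features, radiomic
    feature vector and binary progression label (1 = progressed)."""

    bm_id: str
    patient_id: str
    center_id: str
    clinical: dict
    radiomic: np.ndarray
    label: int

    def __post_init__(self) -> None:
        if self.center_id not in ("A", "B"):
            raise ValueError(f"center_id must be 'A' or 'B', got {self.center_id!r}")
        if self.clinical.get("bm_volume_mm3", 1.0) <= 0:
            raise ValueError("BM volume must be positive")
        if self.clinical.get("fractions", 1) not in (1, 3):
            raise ValueError("fractions must be 1 or 3")


@dataclass
class CohortDataset:
    """A cohort of BM records sharing an ordered feature schema.

    ``feature_schema`` maps feature name -> kind tag in column order; the
    radiomic vector of every record follows the radiomic sub-schema order.
    """

    records: list[BMRecord]
    feature_schema: dict[str, FeatureKind]
    provenance: dict | str = "real"

    def __post_init__(self) -> None:
        n_rad = len(self.radiomic_feature_names)
        for rec in self.records:
            if len(rec.radiomic) != n_rad:
                raise ValueError(
                    f"record {rec.bm_id}: radiomic vector length "
                    f"{len(rec.radiomic)} != schema length {n_rad}"
                )

    @property
    def radiomic_feature_names(self) -> list[str]:
        return [n for n, k in self.feature_schema.items() if k == "radiomic"]

    @property
    def clinical_feature_names(self) -> list[str]:
        return [n for n, k in self.feature_schema.items() if k != "radiomic"]

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def center_ids(self) -> list[str]:
        return sorted({r.center_id for r in self.records})

    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    def patient_ids(self) -> np.ndarray:
        return np.array([r.patient_id for r in self.records])

    def centers(self) -> np.ndarray:
        return np.array([r.center_id for r in self.records])

    def radiomic_matrix(self) -> np.ndarray:
        return np.array([r.radiomic for r in self.records], dtype=float)

    def with_radiomic_matrix(self, matrix: np.ndarray) -> "CohortDataset":
        """Copy of the dataset with radiomic values replaced (labels and
        clinical features untouched)."""
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (self.n_records, len(self.radiomic_feature_names)):
            raise ValueError("replacement matrix shape mismatch")
        new_records = [
            dataclasses.replace(rec, radiomic=matrix[i].copy(),
                                clinical=dict(rec.clinical))
            for i, rec in enumerate(self.records)
        ]
        return CohortDataset(new_records, dict(self.feature_schema), self.provenance)

    def select_radiomic(self, names: Sequence[str]) -> "CohortDataset":
        """Restrict the radiomic schema to ``names`` (schema order kept)."""
        names = set(names)
        unknown = names - set(self.radiomic_feature_names)
        if unknown:
            raise ValueError(f"unknown radiomic features: {sorted(unknown)}")
        keep_idx = [i for i, n in enumerate(self.radiomic_feature_names) if n in names]
        schema = {
            n: k for n, k in self.feature_schema.items()
            if k != "radiomic" or n in names
        }
        records = [
            dataclasses.replace(rec, radiomic=rec.radiomic[keep_idx],
                                clinical=dict(rec.clinical))
            for rec in self.records
        ]
        return CohortDataset(records, schema, self.provenance)

    def to_frame(self) -> pd.DataFrame:
        """One row per BM: ids + clinical + radiomic + label."""
        rad_names = self.radiomic_feature_names
        columns = (["bm_id", "patient_id", "center_id"]
                   + self.clinical_feature_names + rad_names + ["label"])
        if not self.records:
            return pd.DataFrame(columns=columns)
        rows = []
        for rec in self.records:
            row = {"bm_id": rec.bm_id, "patient_id": rec.patient_id,
                   "center_id": rec.center_id}
            row.update({n: rec.clinical[n] for n in self.clinical_feature_names})
            row.update(dict(zip(rad_names, rec.radiomic)))
            row["label"] = rec.label
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   feature_schema: dict[str, FeatureKind],
                   provenance: dict | str = "real") -> "CohortDataset":
        rad_names = [n for n, k in feature_schema.items() if k == "radiomic"]
        clin_names = [n for n, k in feature_schema.items() if k != "radiomic"]
        records = []
        for idx, row in frame.iterrows():
            try:
                records.append(BMRecord(
                    bm_id=str(row["bm_id"]),
                    patient_id=str(row["patient_id"]),
                    center_id=str(row["center_id"]),
                    clinical={n: row[n] for n in clin_names},
                    radiomic=row[rad_names].to_numpy(dtype=float),
                    label=int(row["label"]),
                ))
            except (KeyError, ValueError, TypeError) as exc:
                raise ValueError(f"malformed cohort row {idx}: {exc}") from exc
        return cls(records, dict(feature_schema), provenance)


def _default_schema(radiomic_names: Sequence[str]) -> dict[str, FeatureKind]:
    schema: dict[str, FeatureKind] = {}
    for n in CATEGORICAL_CLINICAL:
        schema[n] = "categorical-clinical"
    for n in CONTINUOUS_CLINICAL:
        schema[n] = "continuous-clinical"
    for n in radiomic_names:
        schema[n] = "radiomic"
    return schema


def _patient_sizes(n_bms: int, n_patients: int, rng: np.random.Generator) -> np.ndarray:
    """BM counts per patient from a truncated geometric repaired to sum to
    ``n_bms`` exactly (small clusters, most patients with one BM)."""
    mean = n_bms / n_patients
    p = min(1.0, 1.0 / mean)
    sizes = rng.geometric(p, size=n_patients)
    # repair to the exact total while keeping every patient >= 1 BM
    while sizes.sum() > n_bms:
        i = int(np.argmax(sizes))
        sizes[i] -= 1
    while sizes.sum() < n_bms:
        sizes[int(rng.integers(n_patients))] += 1
    return sizes


def _sample_categorical(rng: np.random.Generator, table: dict, size: int) -> np.ndarray:
    cats = list(table.keys())
    probs = np.array([table[c] for c in cats], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(np.array(cats, dtype=object), size=size, p=probs)


def _calibrate_intercept(eta: np.ndarray, prevalence: float) -> float:
    """Intercept b0 such that mean(sigmoid(b0 + eta)) == prevalence."""
    def f(b0: float) -> float:
        return float(expit(b0 + eta).mean() - prevalence)
    return brentq(f, -30.0, 30.0)


def generate_cohorts(config: SyntheticConfig) -> tuple[CohortDataset, CohortDataset]:
    """Generate the Center A and Center B synthetic cohorts.

    Radiomic vectors come from a latent block-correlated Gaussian; the
    progression label is drawn from a logistic model on the designated
    signal features (latent scale) plus standardized log-volume; the
    per-center batch effect x = alpha + gamma_c + delta_c * eps is applied
    to radiomic features afterwards, so harmonization can in principle
    recover the latent values.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_global, rng_a, rng_b = [np.random.default_rng(s) for s in ss.spawn(3)]

    names = config.feature_names()
    p = len(names)
    profiles = config.clinical_profiles or DEFAULT_CLINICAL_PROFILES

    # shared feature geometry: base level, scale, block membership
    alpha = rng_global.normal(0.0, 2.0, size=p)
    sd = rng_global.uniform(0.5, 2.0, size=p)
    blocks = np.repeat(np.arange(config.n_blocks), int(np.ceil(p / config.n_blocks)))[:p]
    signal_idx = np.array([names.index(f) for f in config.signal_feature_names],
                          dtype=int)

    # per-center batch effects (units of each feature's own scale)
    batch: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for center, rng_c in (("A", rng_a), ("B", rng_b)):
        gamma = rng_c.normal(0.0, config.batch_shift_sd, size=p) if config.batch_shift_sd > 0 else np.zeros(p)
        delta = rng_c.uniform(*config.batch_scale_range, size=p)
        batch[center] = (gamma, delta)

    datasets = []
    for k, (center, rng_c) in enumerate((("A", rng_a), ("B", rng_b))):
        n_bms = config.n_bms_per_center[k]
        n_patients = config.n_patients_per_center[k]
        prevalence = config.prevalence_per_center[k]
        prof = profiles[center]

        sizes = _patient_sizes(n_bms, n_patients, rng_c)
        patient_of_bm = np.repeat(np.arange(n_patients), sizes)

        # latent radiomic residuals: equicorrelated within block
        rho = config.block_correlation
        block_factor = rng_c.normal(size=(n_bms, config.n_blocks))
        eps = (np.sqrt(rho) * block_factor[:, blocks]
               + np.sqrt(1.0 - rho) * rng_c.normal(size=(n_bms, p)))

        # clinical features
        clin = {
            name: _sample_categorical(rng_c, prof[name], n_bms)
            for name in CATEGORICAL_CLINICAL
        }
        mu_a, sd_a, lo_a, hi_a = prof["age"]
        age = np.clip(rng_c.normal(mu_a, sd_a, size=n_bms), lo_a, hi_a)
        mu_v, sd_v = prof["log_volume"]
        log_vol = rng_c.normal(mu_v, sd_v, size=n_bms)
        volume = np.exp(log_vol)
        dose_vals, dose_probs = prof["dose_menu"]
        dose = rng_c.choice(np.asarray(dose_vals, dtype=float), size=n_bms,
                            p=np.asarray(dose_probs) / np.sum(dose_probs))

        # outcome from latent (pre-batch) signal + standardized log-volume
        z_logvol = (log_vol - mu_v) / sd_v
        eta = (config.signal_effect_size * eps[:, signal_idx].sum(axis=1)
               + config.volume_effect_size * z_logvol)
        b0 = _calibrate_intercept(eta, prevalence)
        labels = (rng_c.random(n_bms) < expit(b0 + eta)).astype(int)

        # batch-affected observed radiomics
        gamma, delta = batch[center]
        radiomic = alpha[None, :] + sd[None, :] * (gamma[None, :] + delta[None, :] * eps)

        records = []
        for i in range(n_bms):
            records.append(BMRecord(
                bm_id=f"{center}-bm{i:04d}",
                patient_id=f"{center}-p{patient_of_bm[i]:03d}",
                center_id=center,
                clinical={
                    "sex": clin["sex"][i],
                    "primary_site": clin["primary_site"][i],
                    "histology": clin["histology"][i],
                    "systemic_therapy": clin["systemic_therapy"][i],
                    "fractions": int(clin["fractions"][i]),
                    "age_years": float(age[i]),
                    "bm_volume_mm3": float(volume[i]),
                    "dose_gy": float(dose[i]),
                },
                radiomic=radiomic[i].copy(),
                label=int(labels[i]),
            ))
        datasets.append(CohortDataset(records, _default_schema(names),
                                      provenance=config.to_dict()))
    return datasets[0], datasets[1]


def write_cohort(ds: CohortDataset, path: str | Path) -> None:
    """Write a cohort as CSV plus a ``.schema.json`` sidecar."""
    path = Path(path)
    frame = ds.to_frame()
    frame.to_csv(path, index=False)
    sidecar = {
        "feature_schema": [[n, k] for n, k in ds.feature_schema.items()],
        "provenance": ds.provenance,
    }
    path.with_suffix(path.suffix + ".schema.json").write_text(
        json.dumps(sidecar, indent=1))


def read_cohort(path: str | Path) -> CohortDataset:
    """Read a cohort written by :func:`write_cohort`.

    Unknown feature columns or malformed rows raise ``ValueError`` naming
    the offender.
    """
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".schema.json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing schema sidecar: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    schema: dict[str, FeatureKind] = {n: k for n, k in sidecar["feature_schema"]}
    frame = pd.read_csv(path)
    expected = {"bm_id", "patient_id", "center_id", "label", *schema}
    unknown = set(frame.columns) - expected
    if unknown:
        raise ValueError(f"unknown feature columns in {path}: {sorted(unknown)}")
    missing = expected - set(frame.columns)
    if missing and len(frame):
        raise ValueError(f"missing columns in {path}: {sorted(missing)}")
    if not len(frame):
        return CohortDataset([], schema, sidecar.get("provenance", "real"))
    return CohortDataset.from_frame(frame, schema, sidecar.get("provenance", "real"))
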