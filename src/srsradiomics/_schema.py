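"""Canonical feature schemas.

The radiomic schema is the standard 107-name set produced by whole-image
extraction on a single (original) image type: 18 first-order intensity
features, 14 shape descriptors, and 75 texture features from the five
matrix families (GLCM 24, GLRLM 16, GLDM 14, GLSZM 16, NGTDM 5).
Clinical records carry 8 features shared by both treatment centers.
"""

from __future__ import annotations

FIRSTORDER = [
    "10Percentile", "90Percentile", "Energy", "Entropy", "InterquartileRange",
    "Kurtosis", "Maximum", "MeanAbsoluteDeviation", "Mean", "Median",
    "Minimum", "Range", "RobustMeanAbsoluteDeviation", "RootMeanSquared",
    "Skewness", "TotalEnergy", "Uniformity", "Variance",
]

SHAPE = [
    "Elongation", "Flatness", "LeastAxisLength", "MajorAxisLength",
    "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "Maximum2DDiameterSlice",
    "Maximum3DDiameter", "MeshVolume", "MinorAxisLength", "Sphericity",
    "SurfaceArea", "SurfaceVolumeRatio", "VoxelVolume",
]

GLCM = [
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
]

GLRLM = [
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
]

GLDM = [
    "DependenceEntropy", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "DependenceVariance",
    "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
]

GLSZM = [
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy", "ZonePercentage", "ZoneVariance",
]

NGTDM = ["Busyness", "Coarseness", "Complexity", "Contrast", "Strength"]

RADIOMIC_CLASSES: dict[str, list[str]] = {
    "firstorder": FIRSTORDER,
    "shape": SHAPE,
    "glcm": GLCM,
    "glrlm": GLRLM,
    "gldm": GLDM,
    "glszm": GLSZM,
    "ngtdm": NGTDM,
}

#: The full 107-feature radiomic schema, in canonical order.
RADIOMIC_FEATURES: list[str] = [
    f"original_{cls}_{name}"
    for cls, names in RADIOMIC_CLASSES.items()
    for name in names
]

assert len(RADIOMIC_FEATURES) == 107
assert len(set(RADIOMIC_FEATURES)) == 107

#: Clinical features shared by both centers.
CATEGORICAL_CLINICAL = [
    "sex", "primary_site", "histology", "systemic_therapy", "fractions",
]
CONTINUOUS_CLINICAL = ["age_years", "bm_volume_mm3", "dose_gy"]
CLINICAL_FEATURES = CATEGORICAL_CLINICAL + CONTINUOUS_CLINICAL


def radiomic_class_of(feature: str) -> str:
    """Return the texture/intensity family of a schema feature name."""
    parts = feature.split("_")
    if len(parts) != 3 or parts[0] != "original" or parts[1] not in RADIOMIC_CLASSES:
        raise ValueError(f"not a radiomic schema feature: {feature!r}")
    return parts[1]
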