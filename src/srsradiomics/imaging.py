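"""T1w-CE MRI preprocessing and native radiomic feature extraction.

Preprocessing follows the usual multi-center recipe: Z-score intensity
normalization against healthy brain (brain mask minus the tumor), hard
clipping at +/-3 SD, trilinear resampling to 0.5 mm isotropic voxels
(nearest-neighbour for masks), then fixed-bin-count discretization of the
tumor ROI into 64 gray levels.

Feature extraction natively computes, with IBSI-style definitions, the
subset of the 107-name schema this pipeline's analyses rely on: first-order
mean, median, range, kurtosis (non-excess), skewness, energy, entropy,
minimum, maximum; mesh-free shape descriptors (voxel-count volume,
face-count surface area and derived sphericity, principal-axis lengths);
GLCM inverse difference normalized, cluster shade, informational measure of
correlation 2, contrast, and joint entropy (13 symmetric directions at
distance 1, feature values averaged across directions); GLSZM zone entropy;
and all five NGTDM features.  Remaining schema names can be supplied by an
external extractor and are otherwise flagged missing (NaN).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from ._schema import RADIOMIC_FEATURES

TARGET_SPACING_MM = (0.5, 0.5, 0.5)
DEFAULT_N_BINS = 64
CLIP_SD = 3.0

# 13 unique displacement directions at Chebyshev distance 1 in 3D
# (one representative per +/- pair), in (z, y, x) array order.
GLCM_DIRECTIONS: tuple[tuple[int, int, int], ...] = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
)
assert len(GLCM_DIRECTIONS) == 13


@dataclass
class ImageVolume:
    """A 3-D scalar image: voxel array in (z, y, x) order with physical
    spacing (x, y, z) in mm and origin/direction metadata."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, ...] = (1, 0, 0, 0, 1, 0, 0, 0, 1)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("image must be 3-D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("image intensities must be finite")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(self.voxels)
        img.SetSpacing(self.spacing)
        img.SetOrigin(self.origin)
        img.SetDirection(self.direction)
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "ImageVolume":
        return cls(sitk.GetArrayFromImage(img).astype(float),
                   tuple(img.GetSpacing()), tuple(img.GetOrigin()),
                   tuple(img.GetDirection()))

    @classmethod
    def read(cls, path: str | Path) -> "ImageVolume":
        return cls.from_sitk(sitk.ReadImage(str(path)))

    def write(self, path: str | Path) -> None:
        sitk.WriteImage(self.to_sitk(), str(path))


@dataclass
class MaskVolume:
    """Binary mask on the same grid as its image; role is 'brain' or 'gtv'."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, ...] = (1, 0, 0, 0, 1, 0, 0, 0, 1)
    role: str = "gtv"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be 3-D")
        if self.role == "gtv" and not self.voxels.any():
            raise ValueError("GTV mask must be nonempty")

    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(self.voxels.astype(np.uint8))
        img.SetSpacing(self.spacing)
        img.SetOrigin(self.origin)
        img.SetDirection(self.direction)
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image, role: str = "gtv") -> "MaskVolume":
        return cls(sitk.GetArrayFromImage(img) > 0, tuple(img.GetSpacing()),
                   tuple(img.GetOrigin()), tuple(img.GetDirection()), role)

    @classmethod
    def read(cls, path: str | Path, role: str = "gtv") -> "MaskVolume":
        return cls.from_sitk(sitk.ReadImage(str(path)), role)

    def write(self, path: str | Path) -> None:
        sitk.WriteImage(self.to_sitk(), str(path))


@dataclass
class FeatureVector:
    """Named feature values over the 107-name schema.

    ``computed_mask`` lists names produced natively; other schema names are
    NaN unless merged from an external extractor.  ``undefined`` lists
    texture names left undefined on degenerate (single-voxel) ROIs.
    """

    values: dict[str, float]
    computed_mask: set[str] = field(default_factory=set)
    undefined: set[str] = field(default_factory=set)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def merge_external(self, external: dict[str, float]) -> "FeatureVector":
        """Fill missing schema names from an external extractor's output
        (never overriding natively computed values)."""
        vals = dict(self.values)
        for name, v in external.items():
            if name not in vals:
                raise ValueError(f"unknown feature name: {name}")
            if name not in self.computed_mask:
                vals[name] = float(v)
        return FeatureVector(vals, set(self.computed_mask), set(self.undefined))


def _check_same_grid(img: ImageVolume, mask: MaskVolume) -> None:
    if img.voxels.shape != mask.voxels.shape:
        raise ValueError(f"image/mask shape mismatch: "
                         f"{img.voxels.shape} vs {mask.voxels.shape}")


def zscore_normalize(img: ImageVolume, brain: MaskVolume,
                     gtv: MaskVolume) -> ImageVolume:
    """Z-score normalize the whole scan against healthy brain.

    The mean and SD are computed over voxels inside the brain mask but
    outside the GTV; the entire scan is transformed and hard-clipped to
    [-3, +3] SD.
    """
    _check_same_grid(img, brain)
    _check_same_grid(img, gtv)
    ref = brain.voxels & ~gtv.voxels
    if not ref.any():
        raise ValueError("brain-minus-GTV reference region is empty")
    vals = img.voxels[ref]
    mu, sigma = float(vals.mean()), float(vals.std())
    if sigma == 0.0:
        raise ValueError("degenerate image: zero intensity SD in brain-minus-GTV")
    out = np.clip((img.voxels - mu) / sigma, -CLIP_SD, CLIP_SD)
    return ImageVolume(out, img.spacing, img.origin, img.direction)


def resample_isotropic(img: ImageVolume, mask: MaskVolume,
                       spacing: tuple[float, float, float] = TARGET_SPACING_MM,
                       ) -> tuple[ImageVolume, MaskVolume]:
    """Resample image (trilinear) and mask (nearest-neighbour) to isotropic
    voxels, preserving physical extent to within one voxel."""
    _check_same_grid(img, mask)
    src = img.to_sitk()
    new_size = [max(1, int(round(sz * sp / nsp)))
                for sz, sp, nsp in zip(src.GetSize(), src.GetSpacing(), spacing)]
    resampler = sitk.ResampleImageFilter()
    resampler.SetOutputSpacing(spacing)
    resampler.SetSize(new_size)
    resampler.SetOutputOrigin(src.GetOrigin())
    resampler.SetOutputDirection(src.GetDirection())
    resampler.SetInterpolator(sitk.sitkLinear)
    out_img = ImageVolume.from_sitk(resampler.Execute(src))
    resampler.SetInterpolator(sitk.sitkNearestNeighbor)
    out_mask = MaskVolume.from_sitk(resampler.Execute(mask.to_sitk()), mask.role)
    return out_img, out_mask


def discretize(img: ImageVolume, gtv: MaskVolume,
               n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """Discretize ROI intensities into a fixed COUNT of bins over the ROI's
    own [min, max] range.

    Returns an integer array shaped like the image with gray levels 1..n_bins
    inside the ROI and 0 outside.  A constant ROI maps to level 1.
    """
    _check_same_grid(img, gtv)
    roi = gtv.voxels
    if not roi.any():
        raise ValueError("empty ROI")
    vals = img.voxels[roi]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(img.voxels.shape, dtype=np.int32)
    if hi == lo:
        levels[roi] = 1
        return levels
    width = (hi - lo) / n_bins
    idx = np.floor((img.voxels[roi] - lo) / width).astype(np.int32) + 1
    levels[roi] = np.clip(idx, 1, n_bins)
    return levels


# ---------------------------------------------------------------------------
# texture matrices

def glcm_matrices(levels: np.ndarray, n_levels: int) -> list[np.ndarray]:
    """Symmetric, normalized co-occurrence matrix per direction (distance 1).

    Directions with no valid voxel pair are omitted.
    """
    out = []
    for dz, dy, dx in GLCM_DIRECTIONS:
        a = levels
        b = np.roll(levels, shift=(-dz, -dy, -dx), axis=(0, 1, 2))
        valid = np.ones(levels.shape, dtype=bool)
        for axis, d in enumerate((dz, dy, dx)):
            if d == 1:
                sl = [slice(None)] * 3
                sl[axis] = slice(-1, None)
                valid[tuple(sl)] = False
            elif d == -1:
                sl = [slice(None)] * 3
                sl[axis] = slice(0, 1)
                valid[tuple(sl)] = False
        pair = valid & (a > 0) & (b > 0)
        if not pair.any():
            continue
        mat = np.zeros((n_levels, n_levels), dtype=float)
        np.add.at(mat, (a[pair] - 1, b[pair] - 1), 1.0)
        mat = mat + mat.T  # symmetric
        out.append(mat / mat.sum())
    return out


def _glcm_features_single(p: np.ndarray) -> dict[str, float]:
    n = p.shape[0]
    i = np.arange(1, n + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu_x = float((i * px).sum())  # == mu_y by symmetry
    nz = p > 0
    joint_entropy = float(-(p[nz] * np.log2(p[nz])).sum())
    contrast = float((p * (ii - jj) ** 2).sum())
    idn = float((p / (1.0 + np.abs(ii - jj) / n)).sum())
    shade = float((p * (ii + jj - 2.0 * mu_x) ** 3).sum())
    # informational measure of correlation 2
    pxy = np.outer(px, px)
    nz2 = pxy > 0
    hxy2 = float(-(pxy[nz2] * np.log2(pxy[nz2])).sum())
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - joint_entropy))))
    return {"Contrast": contrast, "JointEntropy": joint_entropy,
            "Idn": idn, "ClusterShade": shade, "Imc2": imc2}


def glcm_features(levels: np.ndarray, n_levels: int) -> dict[str, float]:
    """Direction-averaged GLCM features (per-direction values averaged)."""
    mats = glcm_matrices(levels, n_levels)
    if not mats:
        raise ValueError("no co-occurring voxel pairs in ROI")
    per_dir = [_glcm_features_single(m) for m in mats]
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


def glszm_zones(levels: np.ndarray) -> list[tuple[int, int]]:
    """(gray level, zone size) for every 26-connected iso-intensity zone."""
    structure = np.ones((3, 3, 3), dtype=bool)
    zones = []
    for g in np.unique(levels[levels > 0]):
        labeled, n = ndimage.label(levels == g, structure=structure)
        if n:
            sizes = np.bincount(labeled.ravel())[1:]
            zones.extend((int(g), int(s)) for s in sizes)
    return zones


def glszm_features(levels: np.ndarray) -> dict[str, float]:
    """GLSZM zone entropy plus the raw zone count."""
    zones = glszm_zones(levels)
    n_zones = len(zones)
    counts: dict[tuple[int, int], int] = {}
    for z in zones:
        counts[z] = counts.get(z, 0) + 1
    p = np.array(list(counts.values()), dtype=float) / n_zones
    zone_entropy = float(-(p * np.log2(p)).sum())
    return {"ZoneEntropy": zone_entropy, "ZoneCount": float(n_zones)}


def ngtdm_features(levels: np.ndarray) -> dict[str, float]:
    """All five NGTDM features (26-neighbour average gray-tone difference).

    Single-gray-level conventions: coarseness saturates at 1e6; contrast and
    strength are 0; busyness is 0 when its denominator vanishes.
    """
    roi = levels > 0
    n_vox = int(roi.sum())
    if n_vox == 0:
        raise ValueError("empty ROI")
    kernel = np.ones((3, 3, 3), dtype=float)
    kernel[1, 1, 1] = 0.0
    neigh_sum = ndimage.convolve(levels.astype(float) * roi, kernel,
                                 mode="constant", cval=0.0)
    neigh_cnt = ndimage.convolve(roi.astype(float), kernel,
                                 mode="constant", cval=0.0)
    levels_max = int(levels.max())
    s = np.zeros(levels_max + 1)
    n_i = np.zeros(levels_max + 1)
    has_neigh = roi & (neigh_cnt > 0)
    avg = np.zeros(levels.shape)
    avg[has_neigh] = neigh_sum[has_neigh] / neigh_cnt[has_neigh]
    diffs = np.abs(levels - avg)
    for g in range(1, levels_max + 1):
        sel = has_neigh & (levels == g)
        n_i[g] = sel.sum()
        s[g] = diffs[sel].sum()
    n_total = n_i.sum()
    p_i = n_i / n_total
    present = np.nonzero(n_i)[0]
    n_gp = len(present)
    g_vals = present.astype(float)
    p_p, s_p = p_i[present], s[present]

    sum_ps = float((p_p * s_p).sum())
    coarseness = 1.0 / sum_ps if sum_ps > 0 else 1e6

    if n_gp > 1:
        gi, gj = np.meshgrid(g_vals, g_vals, indexing="ij")
        pi_, pj_ = np.meshgrid(p_p, p_p, indexing="ij")
        contrast = (float((pi_ * pj_ * (gi - gj) ** 2).sum())
                    / (n_gp * (n_gp - 1))) * (float(s_p.sum()) / n_total)
        busy_den = float(np.abs(gi * pi_ - gj * pj_).sum())
        busyness = sum_ps / busy_den if busy_den > 0 else 0.0
        si_, sj_ = np.meshgrid(s_p, s_p, indexing="ij")
        complexity = float((np.abs(gi - gj) * (pi_ * si_ + pj_ * sj_)
                            / (pi_ + pj_)).sum()) / n_total
        s_sum = float(s_p.sum())
        strength = (float(((pi_ + pj_) * (gi - gj) ** 2).sum()) / s_sum
                    if s_sum > 0 else 0.0)
    else:
        contrast = busyness = complexity = strength = 0.0

    return {"Coarseness": coarseness, "Contrast": contrast,
            "Busyness": busyness, "Complexity": complexity,
            "Strength": strength}


def _shape_features(gtv: MaskVolume) -> dict[str, float]:
    """Mesh-free shape surrogates: voxel-count volume, exposed-face surface
    area, derived sphericity/ratio, and PCA axis lengths."""
    roi = gtv.voxels
    n = int(roi.sum())
    voxel_vol = float(np.prod(gtv.spacing))
    volume = n * voxel_vol
    # exposed faces along each axis; spacing is (x, y, z), array is (z, y, x)
    sx, sy, sz = gtv.spacing
    face_areas = {0: sx * sy, 1: sx * sz, 2: sy * sz}  # normal along z, y, x
    surface = 0.0
    padded = np.pad(roi, 1)
    for axis, area in face_areas.items():
        diff = np.diff(padded.astype(np.int8), axis=axis)
        surface += float(np.abs(diff).sum()) * area
    sphericity = (math.pi ** (1 / 3) * (6.0 * volume) ** (2 / 3)) / surface if surface else 0.0
    # principal axes from voxel coordinate covariance (physical mm)
    coords = np.argwhere(roi).astype(float)
    coords *= np.array([sz, sy, sx])
    out = {
        "VoxelVolume": volume,
        "SurfaceArea": surface,
        "SurfaceVolumeRatio": surface / volume if volume else 0.0,
        "Sphericity": sphericity,
    }
    if n > 1:
        cov = np.cov(coords, rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eig = np.clip(eig, 0.0, None)
        axes = 4.0 * np.sqrt(eig)
        out.update({
            "MajorAxisLength": float(axes[0]),
            "MinorAxisLength": float(axes[1]),
            "LeastAxisLength": float(axes[2]),
            "Elongation": float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 0.0,
            "Flatness": float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 0.0,
        })
    return out


def _firstorder_features(vals: np.ndarray, levels_roi: np.ndarray,
                         n_bins: int) -> dict[str, float]:
    m2 = float(((vals - vals.mean()) ** 2).mean())
    if m2 > 0:
        m3 = float(((vals - vals.mean()) ** 3).mean())
        m4 = float(((vals - vals.mean()) ** 4).mean())
        skewness = m3 / m2 ** 1.5
        kurtosis = m4 / m2 ** 2  # non-excess (Fisher + 3)
    else:
        skewness, kurtosis = 0.0, 0.0
    p = np.bincount(levels_roi, minlength=n_bins + 1)[1:].astype(float)
    p = p[p > 0] / p.sum()
    entropy = float(-(p * np.log2(p)).sum())
    return {
        "Mean": float(vals.mean()),
        "Median": float(np.median(vals)),
        "Range": float(vals.max() - vals.min()),
        "Minimum": float(vals.min()),
        "Maximum": float(vals.max()),
        "Energy": float((vals ** 2).sum()),
        "Entropy": entropy,
        "Skewness": skewness,
        "Kurtosis": kurtosis,
    }


def extract_features(img: ImageVolume, gtv: MaskVolume,
                     n_bins: int = DEFAULT_N_BINS) -> FeatureVector:
    """Compute the native feature subset of the 107-name schema on a
    preprocessed image and its GTV mask.

    Texture features on a single-voxel ROI are flagged undefined (NaN).
    """
    _check_same_grid(img, gtv)
    roi = gtv.voxels
    if not roi.any():
        raise ValueError("empty ROI")
    vals = img.voxels[roi]
    levels = discretize(img, gtv, n_bins=n_bins)

    values: dict[str, float] = {name: float("nan") for name in RADIOMIC_FEATURES}
    computed: set[str] = set()
    undefined: set[str] = set()

    fo = _firstorder_features(vals, levels[roi], n_bins)
    for k, v in fo.items():
        name = f"original_firstorder_{k}"
        values[name] = v
        computed.add(name)

    for k, v in _shape_features(gtv).items():
        name = f"original_shape_{k}"
        values[name] = v
        computed.add(name)

    texture_names = ([f"original_glcm_{k}" for k in
                      ("Contrast", "JointEntropy", "Idn", "ClusterShade", "Imc2")]
                     + ["original_glszm_ZoneEntropy"]
                     + [f"original_ngtdm_{k}" for k in
                        ("Coarseness", "Contrast", "Busyness", "Complexity",
                         "Strength")])
    if roi.sum() == 1:
        undefined.update(texture_names)
    else:
        for k, v in glcm_features(levels, n_bins).items():
            name = f"original_glcm_{k}"
            values[name] = v
            computed.add(name)
        values["original_glszm_ZoneEntropy"] = glszm_features(levels)["ZoneEntropy"]
        computed.add("original_glszm_ZoneEntropy")
        for k, v in ngtdm_features(levels).items():
            name = f"original_ngtdm_{k}"
            values[name] = v
            computed.add(name)

    return FeatureVector(values, computed, undefined)
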