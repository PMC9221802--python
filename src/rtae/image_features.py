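"""Bounded radiomics feature extractor for 3D image+mask volumes.

Implements a documented subset of the standard (IBSI-style) feature
families: 18 first-order histogram features, a 14-feature GLCM core,
4 shape features, and single-level orthonormal 3D Haar wavelet
re-extraction (first-order + GLCM on each of the 8 sub-bands). Gray-level
dependence/run-length/zone/NGTDM families are deliberately out of scope.

GLCM conventions: 13 unique 3D directions at distance 1, symmetrized
co-occurrence counts, per-direction feature values averaged (directions
with no valid voxel pair are skipped). Discretization defaults to a fixed
bin width of 25 intensity units.

Values that are mathematically undefined for an input (skewness of a
constant region, GLCM on a single voxel) are returned as NaN and listed
in ``FeatureVector.undefined`` rather than silently propagating.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.spatial import ConvexHull, QhullError

FIRST_ORDER_NAMES = [
    "Mean", "Median", "Minimum", "Maximum", "Range", "Variance", "Skewness",
    "Kurtosis", "Energy", "TotalEnergy", "Entropy", "Uniformity",
    "Percentile10", "Percentile90", "InterquartileRange",
    "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation", "RootMeanSquared",
]

GLCM_NAMES = [
    "Autocorrelation", "ClusterProminence", "ClusterShade", "Contrast",
    "Correlation", "DifferenceAverage", "DifferenceEntropy", "Dissimilarity",
    "JointEnergy", "JointEntropy", "InverseDifference",
    "InverseDifferenceMoment", "SumAverage", "SumEntropy",
]

SHAPE_NAMES = ["VoxelVolume", "SurfaceArea", "Sphericity", "Maximum3DDiameter"]

#: 13 unique direction vectors covering all distance-1 3D offsets up to sign
DIRECTIONS_13 = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

SUBBANDS = ["LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH"]


@dataclass
class VolumeMask:
    """3D intensity volume with a binary lesion mask and voxel spacing (mm)."""

    intensities: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.intensities.shape != self.mask.shape or self.intensities.ndim != 3:
            raise ValueError("intensities and mask must be identical 3D arrays")
        if not self.mask.any():
            raise ValueError("mask must contain at least one voxel")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def mask_values(self) -> np.ndarray:
        return self.intensities[self.mask]


@dataclass
class DiscretizationSpec:
    """Gray-level discretization: fixed bin width (default 25 intensity
    units) or a fixed bin count with equal-width bins over [min, max]."""

    mode: str = "fixed-bin-width"
    width: float = 25.0
    bins: int = 32

    def __post_init__(self) -> None:
        if self.mode not in ("fixed-bin-width", "fixed-bin-count"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "fixed-bin-width" and self.width <= 0:
            raise ValueError("width must be > 0")
        if self.mode == "fixed-bin-count" and self.bins < 2:
            raise ValueError("bins must be >= 2")


@dataclass
class FeatureVector:
    """Ordered (name, value) pairs with an explicit undefined set."""

    names: list[str] = field(default_factory=list)
    values: dict[str, float] = field(default_factory=dict)
    undefined: set[str] = field(default_factory=set)

    def add(self, name: str, value: float, defined: bool = True) -> None:
        if name in self.values:
            raise ValueError(f"duplicate feature name {name!r}")
        self.names.append(name)
        self.values[name] = float(value) if defined else np.nan
        if not defined:
            self.undefined.add(name)

    def extend(self, other: "FeatureVector", prefix: str = "") -> None:
        for name in other.names:
            new = f"{prefix}{name}"
            self.add(new, other.values[name], defined=name not in other.undefined)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __len__(self) -> int:
        return len(self.names)

    def as_series(self):
        import pandas as pd

        return pd.Series({n: self.values[n] for n in self.names})


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

def discretize(volume: VolumeMask, spec: DiscretizationSpec) -> np.ndarray:
    """Integer gray levels (1-based) over mask voxels, 0 outside the mask.

    Fixed bin width: level = floor((x - min) / width) + 1. Fixed bin
    count: equal-width bins over [min, max], the maximum assigned to the
    top bin; a constant region maps to a single level 1.
    """
    vals = volume.mask_values()
    lo, hi = vals.min(), vals.max()
    levels = np.zeros(volume.mask.shape, dtype=int)
    if spec.mode == "fixed-bin-width":
        lv = np.floor((vals - lo) / spec.width).astype(int) + 1
    else:
        if hi == lo:
            lv = np.ones(len(vals), dtype=int)
        else:
            lv = np.floor((vals - lo) / (hi - lo) * spec.bins).astype(int) + 1
            lv[lv > spec.bins] = spec.bins  # top edge into top bin
    levels[volume.mask] = lv
    return levels


# ---------------------------------------------------------------------------
# first-order
# ---------------------------------------------------------------------------

def first_order_features(
    values: np.ndarray,
    spec: DiscretizationSpec | None = None,
    voxel_volume: float = 1.0,
) -> FeatureVector:
    """The 18 first-order histogram features of a voxel intensity sample.

    Entropy and uniformity are computed on the discretized histogram with
    base-2 logarithms; skewness and kurtosis (Pearson, non-excess) are
    undefined for a constant sample.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("need at least one voxel")
    spec = spec or DiscretizationSpec()
    fv = FeatureVector()
    n = x.size
    mean = x.mean()
    var = x.var()  # population variance
    fv.add("Mean", mean)
    fv.add("Median", np.median(x))
    fv.add("Minimum", x.min())
    fv.add("Maximum", x.max())
    fv.add("Range", x.max() - x.min())
    fv.add("Variance", var)
    if var > 0:
        m3 = np.mean((x - mean) ** 3)
        m4 = np.mean((x - mean) ** 4)
        fv.add("Skewness", m3 / var**1.5)
        fv.add("Kurtosis", m4 / var**2)
    else:
        fv.add("Skewness", np.nan, defined=False)
        fv.add("Kurtosis", np.nan, defined=False)
    fv.add("Energy", np.sum(x**2))
    fv.add("TotalEnergy", voxel_volume * np.sum(x**2))
    # histogram probabilities on discretized levels
    vm_like = VolumeMask(x.reshape(-1, 1, 1), np.ones((n, 1, 1), bool), (1, 1, 1))
    lv = discretize(vm_like, spec)[np.ones((n, 1, 1), bool)]
    p = np.bincount(lv)[1:].astype(float)
    p = p[p > 0] / n
    fv.add("Entropy", -np.sum(p * np.log2(p)))
    fv.add("Uniformity", np.sum(p**2))
    p10, p90 = np.percentile(x, [10, 90])
    fv.add("Percentile10", p10)
    fv.add("Percentile90", p90)
    q1, q3 = np.percentile(x, [25, 75])
    fv.add("InterquartileRange", q3 - q1)
    fv.add("MeanAbsoluteDeviation", np.mean(np.abs(x - mean)))
    sel = (x >= p10) & (x <= p90)
    fv.add(
        "RobustMeanAbsoluteDeviation",
        np.mean(np.abs(x[sel] - x[sel].mean())) if sel.any() else 0.0,
    )
    fv.add("RootMeanSquared", np.sqrt(np.mean(x**2)))
    return fv


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def _cooccurrence(levels, mask, offset) -> np.ndarray | None:
    """Symmetrized normalized co-occurrence matrix for one offset, or None
    when the offset yields no in-mask voxel pair."""
    n_levels = levels.max()
    dz, dy, dx = offset
    src = []
    dst = []
    shape = levels.shape
    z, y, x = np.nonzero(mask)
    z2, y2, x2 = z + dz, y + dy, x + dx
    ok = (
        (z2 >= 0) & (z2 < shape[0])
        & (y2 >= 0) & (y2 < shape[1])
        & (x2 >= 0) & (x2 < shape[2])
    )
    z, y, x, z2, y2, x2 = z[ok], y[ok], x[ok], z2[ok], y2[ok], x2[ok]
    inside = mask[z2, y2, x2]
    src = levels[z[inside], y[inside], x[inside]]
    dst = levels[z2[inside], y2[inside], x2[inside]]
    if len(src) == 0:
        return None
    P = np.zeros((n_levels, n_levels))
    np.add.at(P, (src - 1, dst - 1), 1.0)
    P = P + P.T  # symmetrize
    return P / P.sum()


def glcm_features_single(P: np.ndarray) -> FeatureVector:
    """The 14 GLCM features of one normalized symmetric matrix."""
    fv = FeatureVector()
    ng = P.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    mu_x = np.sum(i * px)
    sig_x = np.sqrt(np.sum((i - mu_x) ** 2 * px))
    # symmetric matrix: marginals coincide
    diff = np.abs(ii - jj)
    ssum = ii + jj
    p_diff = np.array([P[diff == k].sum() for k in range(ng)])
    p_sum = np.array([P[ssum == k].sum() for k in range(2, 2 * ng + 1)])

    def entropy(p):
        p = p[p > 0]
        return -np.sum(p * np.log2(p))

    fv.add("Autocorrelation", np.sum(P * ii * jj))
    mu_sum = ii + jj - 2 * mu_x
    fv.add("ClusterProminence", np.sum(P * mu_sum**4))
    fv.add("ClusterShade", np.sum(P * mu_sum**3))
    fv.add("Contrast", np.sum(P * (ii - jj) ** 2))
    if sig_x > 0:
        cov = np.sum(P * (ii - mu_x) * (jj - mu_x))
        fv.add("Correlation", cov / sig_x**2)
    else:
        fv.add("Correlation", 1.0)  # degenerate single-level convention
    k_diff = np.arange(ng)
    fv.add("DifferenceAverage", np.sum(k_diff * p_diff))
    fv.add("DifferenceEntropy", entropy(p_diff))
    fv.add("Dissimilarity", np.sum(P * diff))
    fv.add("JointEnergy", np.sum(P**2))
    fv.add("JointEntropy", entropy(P.ravel()))
    fv.add("InverseDifference", np.sum(P / (1.0 + diff)))
    fv.add("InverseDifferenceMoment", np.sum(P / (1.0 + diff**2)))
    k_sum = np.arange(2, 2 * ng + 1)
    fv.add("SumAverage", np.sum(k_sum * p_sum))
    fv.add("SumEntropy", entropy(p_sum))
    return fv


def glcm_features(
    levels: np.ndarray,
    mask: np.ndarray,
    offsets=None,
    distance: int = 1,
) -> FeatureVector:
    """Direction-averaged GLCM features.

    Each of the (default 13) direction vectors is scaled by ``distance``,
    a symmetrized co-occurrence matrix accumulated over in-mask voxel
    pairs, features computed per direction, then averaged. With fewer
    than two valid pairs overall every feature is flagged undefined.
    """
    mask = np.asarray(mask).astype(bool)
    offsets = offsets if offsets is not None else DIRECTIONS_13
    per_dir = []
    for off in offsets:
        P = _cooccurrence(levels, mask, tuple(int(distance) * np.array(off)))
        if P is not None:
            per_dir.append(glcm_features_single(P))
    fv = FeatureVector()
    if not per_dir:
        for name in GLCM_NAMES:
            fv.add(name, np.nan, defined=False)
        return fv
    for name in GLCM_NAMES:
        fv.add(name, float(np.mean([d[name] for d in per_dir])))
    return fv


# ---------------------------------------------------------------------------
# shape
# ---------------------------------------------------------------------------

def shape_features(mask: np.ndarray, spacing) -> FeatureVector:
    """Voxel volume, exposed-face surface area, sphericity, max 3D diameter.

    Surface area counts faces between mask voxels and non-mask/out-of-bounds
    neighbors (slight overestimate versus a mesh for smooth shapes).
    Maximum 3D diameter is the largest center-to-center distance between
    mask voxels, in mm.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    spacing = np.asarray(spacing, dtype=float)
    fv = FeatureVector()
    n_vox = int(mask.sum())
    volume = n_vox * float(np.prod(spacing))
    fv.add("VoxelVolume", volume)

    padded = np.pad(mask, 1)
    area = 0.0
    face_areas = [
        spacing[1] * spacing[2],
        spacing[0] * spacing[2],
        spacing[0] * spacing[1],
    ]
    for axis, fa in enumerate(face_areas):
        shifted_f = np.roll(padded, 1, axis=axis)
        shifted_b = np.roll(padded, -1, axis=axis)
        area += fa * np.sum(padded & ~shifted_f)
        area += fa * np.sum(padded & ~shifted_b)
    fv.add("SurfaceArea", area)
    fv.add("Sphericity", np.pi ** (1 / 3) * (6 * volume) ** (2 / 3) / area)

    coords = np.argwhere(mask) * spacing
    if len(coords) == 1:
        fv.add("Maximum3DDiameter", 0.0)
        return fv
    pts = coords
    if len(coords) > 4:
        try:
            pts = coords[ConvexHull(coords).vertices]
        except QhullError:
            pass  # degenerate (coplanar) masks: brute force below
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    fv.add("Maximum3DDiameter", float(np.sqrt(d2.max())))
    return fv


# ---------------------------------------------------------------------------
# 3D Haar wavelet
# ---------------------------------------------------------------------------

def haar3d(volume: np.ndarray) -> dict[str, np.ndarray]:
    """Single-level orthonormal 3D Haar decomposition into 8 sub-bands.

    Odd dimensions are padded by edge replication to the next even size,
    keeping the periodized transform orthonormal on the padded core.
    Returned keys are LLL..HHH with L = low-pass along that axis.
    """
    vol = np.asarray(volume, dtype=float)
    pad = [(0, s % 2) for s in vol.shape]
    if any(p[1] for p in pad):
        vol = np.pad(vol, pad, mode="edge")
    coeffs = pywt.dwtn(vol, "haar", mode="periodization")
    out = {}
    for key, arr in coeffs.items():
        band = key.replace("a", "L").replace("d", "H")
        out[band] = arr
    return out


def haar3d_inverse(bands: dict[str, np.ndarray]) -> np.ndarray:
    coeffs = {k.replace("L", "a").replace("H", "d"): v for k, v in bands.items()}
    return pywt.idwtn(coeffs, "haar", mode="periodization")


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------

def _downsample_mask(mask: np.ndarray) -> np.ndarray:
    """Half-resolution mask: a coarse voxel is inside when any voxel of its
    2x2x2 block is inside (keeps sub-band masks non-empty)."""
    pad = [(0, s % 2) for s in mask.shape]
    m = np.pad(mask, pad, mode="edge") if any(p[1] for p in pad) else mask
    s0, s1, s2 = (s // 2 for s in m.shape)
    blocks = m[: 2 * s0, : 2 * s1, : 2 * s2].reshape(s0, 2, s1, 2, s2, 2)
    return blocks.any(axis=(1, 3, 5))


def extract_all(vm: VolumeMask, spec: DiscretizationSpec | None = None) -> FeatureVector:
    """Concatenated feature vector for one lesion volume.

    Original image: first-order + GLCM + shape. Each Haar sub-band:
    first-order + GLCM on the half-resolution mask (shape is geometry-only
    and computed once). Names carry ``original_`` / ``wavelet-XXX_``
    prefixes and the family tag.
    """
    spec = spec or DiscretizationSpec()
    fv = FeatureVector()
    levels = discretize(vm, spec)
    fo = first_order_features(vm.mask_values(), spec, voxel_volume=vm.voxel_volume)
    fv.extend(fo, prefix="original_firstorder_")
    fv.extend(glcm_features(levels, vm.mask), prefix="original_glcm_")
    fv.extend(shape_features(vm.mask, vm.spacing), prefix="original_shape_")

    bands = haar3d(vm.intensities)
    sub_mask = _downsample_mask(vm.mask)
    sub_voxvol = vm.voxel_volume * 8.0
    for band in SUBBANDS:
        arr = bands[band]
        sub_vm = VolumeMask(arr, sub_mask, tuple(2 * s for s in vm.spacing))
        sub_fo = first_order_features(sub_vm.mask_values(), spec, voxel_volume=sub_voxvol)
        fv.extend(sub_fo, prefix=f"wavelet-{band}_firstorder_")
        sub_levels = discretize(sub_vm, spec)
        fv.extend(glcm_features(sub_levels, sub_mask), prefix=f"wavelet-{band}_glcm_")
    return fv
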