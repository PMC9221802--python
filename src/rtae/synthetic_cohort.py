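"""Synthetic HCC cohort generator.

The patient MRI cohort behind this analysis is not publicly deposited, so
every downstream stage is exercised on synthetic data with the same
statistical structure: per-phase tables of family-tagged radiomics
features, 12 clinical variables, 19 LI-RADS qualitative imaging columns
(lesion size plus 18 binary features), mRECIST response labels with exact
endpoint prevalences, and optional 3D lesion image/mask volumes.

Radiomics features are drawn from an equicorrelated-block Gaussian model
(blocks emulate wavelet-family redundancy); "planted" features carry a
class-conditional mean shift of delta pooled standard deviations, so that
the single-feature Bayes AUC is Phi(delta/sqrt(2)) — a closed form used
throughout the tests to calibrate recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .cohort_stats import ResponseLabel
from .image_features import VolumeMask

# mRECIST category mix of the modelled cohort: 14 CR / 15 PR / 19 SD / 3 PD of 51
CATEGORY_COUNTS = {"CR": 14, "PR": 15, "SD": 19, "PD": 3}

#: family sizes used to tag synthetic feature names (first-order, GLCM, GLDM,
#: GLRLM, GLZLM, NGTDM, shape; wavelet fills whatever remains)
FAMILY_SIZES = [
    ("original_firstorder", 18),
    ("original_glcm", 24),
    ("original_gldm", 14),
    ("original_glrlm", 16),
    ("original_glzlm", 16),
    ("original_ngtdm", 5),
    ("original_shape", 17),
]
WAVELET_BANDS = ["LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH"]

#: continuous clinical variables: name -> (median, q1, q3), log-normal
CLINICAL_CONTINUOUS = {
    "age": (73.0, 67.0, 78.0),
    "albumin": (3.6, 3.2, 3.9),
    "creatinine": (0.8, 0.7, 1.0),
    "bilirubin": (0.8, 0.6, 1.2),
    "platelet_count": (115.1, 97.0, 170.7),
    "inr": (1.0, 1.0, 1.2),
    "afp": (5.0, 2.9, 47.1),
}
#: binary/categorical clinical columns: name -> Bernoulli rate (etiology is
#: 3-level coded 0=HCV, 1=HBV, 2=NAFLD)
CLINICAL_BINARY = {
    "sex_male": 37 / 51,
    "child_pugh_b": 6 / 51,
    "ascites": 8 / 51,
    "varices": 39 / 51,
}
ETIOLOGY_PROBS = {"hcv": 43 / 51, "hbv": 6 / 51, "nafld": 2 / 51}

#: LI-RADS binary feature prevalences pooled over the cohort (size handled
#: separately, log-normal median 20 mm IQR 16-30)
LIRADS_RATES = {
    "nonrim_aphe": 49 / 51,
    "nonperipheral_washout": 43 / 51,
    "enhancing_capsule": 23 / 51,
    "threshold_growth": 4 / 51,
    "us_visibility": 9 / 51,
    "subthreshold_growth": 14 / 51,
    "corona_enhancement": 3 / 51,
    "fat_sparing": 4 / 51,
    "restricted_diffusion": 33 / 51,
    "mild_t2_hyperintensity": 27 / 51,
    "iron_sparing": 0.0,
    "transitional_hypointensity": 42 / 51,
    "hbp_hypointensity": 44 / 51,
    "nonenhancing_capsule": 1 / 51,
    "nodule_in_nodule": 4 / 51,
    "mosaic_architecture": 4 / 51,
    "fat_in_mass": 9 / 51,
    "blood_products": 1 / 51,
}
SIZE_MEDIAN_IQR = (20.0, 16.0, 30.0)


@dataclass
class SyntheticCohortConfig:
    n_patients: int = 51
    n_radiomics: int = 854
    n_clinical: int = 12
    n_lirads: int = 19
    prevalence: float = 14 / 51
    endpoint: str = "cr"  # which binary endpoint the prevalence refers to
    planted_features: list[tuple[int, float]] = field(default_factory=list)
    correlation_block_size: int = 10
    rho: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if round(self.prevalence * self.n_patients) < 1:
            raise ValueError("degenerate class: prevalence * n_patients < 1")
        idx = [j for j, _ in self.planted_features]
        if len(set(idx)) != len(idx):
            raise ValueError("duplicate planted feature indices")
        if any(j < 0 or j >= self.n_radiomics for j in idx):
            raise ValueError("planted index outside feature range")
        if any(not np.isfinite(d) for _, d in self.planted_features):
            raise ValueError("planted effect size must be finite")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if self.endpoint not in ("cr", "or"):
            raise ValueError("endpoint must be 'cr' or 'or'")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, default=list, indent=2))

    @classmethod
    def from_json(cls, path) -> "SyntheticCohortConfig":
        d = json.loads(Path(path).read_text())
        d["planted_features"] = [tuple(t) for t in d.get("planted_features", [])]
        return cls(**d)


@dataclass
class CohortDataset:
    features: pd.DataFrame
    clinical: pd.DataFrame
    lirads: pd.DataFrame
    labels: list[ResponseLabel]

    def __post_init__(self) -> None:
        n = len(self.features)
        if not (len(self.clinical) == len(self.lirads) == len(self.labels) == n):
            raise ValueError("tables must share the same patient count")
        for tab in (self.features, self.clinical, self.lirads):
            if tab.isna().any().any():
                raise ValueError("missing values not allowed")

    def endpoint(self, which: str) -> np.ndarray:
        """Binary labels for 'cr' (complete) or 'or' (objective) response."""
        if which == "cr":
            return np.array([int(lab.complete_response) for lab in self.labels])
        if which == "or":
            return np.array([int(lab.objective_response) for lab in self.labels])
        raise ValueError("endpoint must be 'cr' or 'or'")

    def design_matrix(self) -> pd.DataFrame:
        """All modelling columns: radiomics + clinical + LI-RADS, jointly."""
        return pd.concat([self.features, self.clinical, self.lirads], axis=1)


def feature_names(n_radiomics: int) -> list[str]:
    """Family-tagged synthetic feature names, wavelet filling the tail."""
    names: list[str] = []
    for family, size in FAMILY_SIZES:
        for i in range(size):
            if len(names) >= n_radiomics:
                return names
            names.append(f"{family}_f{i:02d}")
    i = 0
    while len(names) < n_radiomics:
        band = WAVELET_BANDS[i % len(WAVELET_BANDS)]
        names.append(f"wavelet-{band}_f{i // len(WAVELET_BANDS):03d}")
        i += 1
    return names


def _assign_categories(n: int, prevalence: float, endpoint: str, rng) -> list[ResponseLabel]:
    """Exact-count labels: round(prevalence*n) positives for the chosen
    endpoint; categories within positive/negative strata allocated by
    largest remainder against the cohort's published mix."""
    n_pos = int(round(prevalence * n))

    def alloc(total: int, weights: dict[str, int]) -> dict[str, int]:
        w = np.array(list(weights.values()), dtype=float)
        raw = total * w / w.sum()
        base = np.floor(raw).astype(int)
        rem = total - base.sum()
        order = np.argsort(-(raw - base))
        base[order[:rem]] += 1
        return dict(zip(weights.keys(), base))

    if endpoint == "cr":
        pos_counts = {"CR": n_pos}
        neg_counts = alloc(n - n_pos, {k: CATEGORY_COUNTS[k] for k in ("PR", "SD", "PD")})
    else:
        pos_counts = alloc(n_pos, {k: CATEGORY_COUNTS[k] for k in ("CR", "PR")})
        neg_counts = alloc(n - n_pos, {k: CATEGORY_COUNTS[k] for k in ("SD", "PD")})
    cats = [c for c, k in {**pos_counts, **neg_counts}.items() for _ in range(k)]
    rng.shuffle(cats)
    return [ResponseLabel(c) for c in cats]


def generate_clinical_lirads(
    config: SyntheticCohortConfig,
    rng: np.random.Generator | None = None,
    clinical_continuous: dict | None = None,
    lirads_rates: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Clinical (12 columns) and LI-RADS (size + 18 binary) tables.

    Continuous labs are log-normal parameterized by (median, q1, q3):
    mu = ln(median), sigma = (ln q3 - ln q1) / (2 * 0.6745). Binary
    columns are Bernoulli at the configured rates.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    cont = clinical_continuous or CLINICAL_CONTINUOUS
    rates = lirads_rates or LIRADS_RATES
    if any(not 0.0 <= r <= 1.0 for r in rates.values()):
        raise ValueError("LI-RADS rates must lie in [0, 1]")
    n = config.n_patients

    def lognormal(median, q1, q3):
        mu = np.log(median)
        sigma = (np.log(q3) - np.log(q1)) / (2 * 0.6745) if q3 > q1 else 0.0
        return np.exp(rng.normal(mu, sigma, size=n))

    clinical = {}
    for name, (m, q1, q3) in cont.items():
        clinical[name] = lognormal(m, q1, q3)
    for name, rate in CLINICAL_BINARY.items():
        clinical[name] = rng.binomial(1, rate, size=n)
    clinical["etiology"] = rng.choice(
        [0, 1, 2], size=n, p=list(ETIOLOGY_PROBS.values())
    )
    clinical_df = pd.DataFrame(clinical)
    if config.n_clinical != clinical_df.shape[1]:
        raise ValueError(
            f"clinical spec provides {clinical_df.shape[1]} columns, "
            f"config expects {config.n_clinical}"
        )

    lirads = {"size_mm": lognormal(*SIZE_MEDIAN_IQR)}
    for name, rate in rates.items():
        lirads[name] = rng.binomial(1, rate, size=n)
    lirads_df = pd.DataFrame(lirads)
    if config.n_lirads != lirads_df.shape[1]:
        raise ValueError(
            f"LI-RADS spec provides {lirads_df.shape[1]} columns, "
            f"config expects {config.n_lirads}"
        )
    return clinical_df, lirads_df


def generate_feature_table(config: SyntheticCohortConfig) -> CohortDataset:
    """Full synthetic cohort: radiomics + clinical + LI-RADS + labels.

    Radiomics columns come in equicorrelated Gaussian blocks of
    ``correlation_block_size`` (pairwise correlation ``rho`` within a
    block, independent across blocks). Each planted feature j gets a
    class-conditional mean difference of delta pooled SDs on the
    configured endpoint. Fully reproducible from ``seed``.
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n_patients, config.n_radiomics
    labels = _assign_categories(n, config.prevalence, config.endpoint, rng)
    y = np.array(
        [
            int(lab.complete_response if config.endpoint == "cr" else lab.objective_response)
            for lab in labels
        ]
    )

    b = max(1, config.correlation_block_size)
    X = np.empty((n, p))
    for start in range(0, p, b):
        width = min(b, p - start)
        shared = rng.standard_normal((n, 1))
        noise = rng.standard_normal((n, width))
        X[:, start : start + width] = (
            np.sqrt(config.rho) * shared + np.sqrt(1 - config.rho) * noise
        )
    for j, delta in config.planted_features:
        X[:, j] += delta * (y - y.mean())  # centered shift keeps unit pooled SD

    features = pd.DataFrame(X, columns=feature_names(p))
    clinical, lirads = generate_clinical_lirads(config, rng=np.random.default_rng(config.seed + 1))
    return CohortDataset(features=features, clinical=clinical, lirads=lirads, labels=labels)


def generate_lesion_volume(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    radius: float,
    texture: tuple[float, float, float] = (100.0, 20.0, 1.0),
    seed: int = 0,
) -> VolumeMask:
    """Spherical synthetic lesion: an ellipsoid-in-voxel-space mask of the
    given physical radius (mm), filled with mean + smoothed Gaussian noise
    rescaled to the requested SD. ``texture`` = (mean, sd, smoothing mm)."""
    shape = tuple(int(s) for s in shape)
    extent = [s * sp for s, sp in zip(shape, spacing)]
    if any(2 * radius > e for e in extent):
        raise ValueError(f"radius {radius} mm does not fit inside extent {extent}")
    mean, sd, smooth = texture
    if sd < 0 or smooth < 0:
        raise ValueError("texture sd and smoothing must be non-negative")
    center = [(s - 1) / 2.0 for s in shape]
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    dist2 = sum(((g - c) * sp) ** 2 for g, c, sp in zip(grids, center, spacing))
    mask = dist2 <= radius**2
    rng = np.random.default_rng(seed)
    intensities = np.zeros(shape)
    if sd > 0:
        noise = rng.standard_normal(shape)
        sigma_vox = [smooth / sp for sp in spacing]
        if smooth > 0:
            noise = ndimage.gaussian_filter(noise, sigma=sigma_vox)
            noise /= max(noise.std(), 1e-12)
        intensities[mask] = mean + sd * noise[mask]
    else:
        intensities[mask] = mean
    return VolumeMask(intensities=intensities, mask=mask, spacing=tuple(spacing))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_cohort(dataset: CohortDataset, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.features.to_csv(out / "features.csv", index=False)
    dataset.clinical.to_csv(out / "clinical.csv", index=False)
    dataset.lirads.to_csv(out / "lirads.csv", index=False)
    pd.DataFrame(
        {
            "category": [lab.category for lab in dataset.labels],
            "complete_response": [int(lab.complete_response) for lab in dataset.labels],
            "objective_response": [int(lab.objective_response) for lab in dataset.labels],
        }
    ).to_csv(out / "labels.csv", index=False)


def read_cohort(in_dir) -> CohortDataset:
    d = Path(in_dir)
    labels_df = pd.read_csv(d / "labels.csv")
    return CohortDataset(
        features=pd.read_csv(d / "features.csv"),
        clinical=pd.read_csv(d / "clinical.csv"),
        lirads=pd.read_csv(d / "lirads.csv"),
        labels=[ResponseLabel(c) for c in labels_df["category"]],
    )


def write_volume(vm: VolumeMask, image_path, mask_path) -> None:
    affine = np.diag(list(vm.spacing) + [1.0])
    nib.save(nib.Nifti1Image(vm.intensities.astype(np.float32), affine), str(image_path))
    nib.save(nib.Nifti1Image(vm.mask.astype(np.uint8), affine), str(mask_path))


def read_volume(image_path, mask_path) -> VolumeMask:
    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeMask(
        intensities=np.asarray(img.dataobj, dtype=float),
        mask=np.asarray(msk.dataobj) > 0,
        spacing=spacing,
    )
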