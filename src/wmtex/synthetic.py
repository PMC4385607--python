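"""Synthetic MRI-like cohorts with controllable class-dependent texture.

Each subject is a 3D volume with an ellipsoidal brain-like foreground, an
interior white-matter-like subregion, and stationary texture drawn from a
Gaussian random field: white noise smoothed with an isotropic Gaussian
kernel of width ``corr_length`` and rescaled so the voxel values inside the
brain have the requested marginal SD ``sigma`` around the class mean.  The
correlation length directly modulates LBP statistics (smoother fields
produce fewer non-uniform patterns), which is exactly the kind of signal
the texture pipeline must detect; no claim is made that the fields mimic
real white-matter pathology.  Optional spherical "lesions" of elevated
intensity (``contrast`` x class mean) are placed inside the WM region and
recorded in a ground-truth mask for segmentation tests.

Cohort profiles mirror a realistic dementia study: the default imbalanced
design has 57 AD, 16 LBD and 36 NC subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "TextureParams",
    "LesionParams",
    "SyntheticCohortSpec",
    "SyntheticSubject",
    "generate_volume",
    "generate_cohort",
    "paper_imbalance_spec",
    "balanced_spec",
    "null_spec",
    "signal_spec",
]


@dataclass(frozen=True)
class TextureParams:
    """Stationary texture of one class: mean intensity, marginal SD, correlation length."""

    mean: float = 100.0
    sigma: float = 10.0
    corr_length: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.corr_length <= 0:
            raise ValueError("sigma must be >= 0 and corr_length > 0")


@dataclass(frozen=True)
class LesionParams:
    """Spherical hyperintense lesions inside the WM region."""

    count: int = 3
    radius_range: Tuple[float, float] = (2.0, 4.0)
    contrast: float = 2.0

    def __post_init__(self) -> None:
        if self.contrast <= 1:
            raise ValueError("lesion contrast ratio must be > 1")
        if self.count < 0 or self.radius_range[0] <= 0:
            raise ValueError("invalid lesion parameters")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Design of one synthetic cohort: class sizes, shape, texture, lesions, seed."""

    n_per_class: Mapping[str, int]
    class_params: Mapping[str, TextureParams]
    volume_shape: Tuple[int, int, int] = (48, 48, 8)
    lesion_params: Optional[LesionParams] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_class.values()):
            raise ValueError("class counts must be >= 0")
        missing = set(self.n_per_class) - set(self.class_params)
        if missing:
            raise ValueError(f"no texture parameters for classes: {sorted(missing)}")


@dataclass
class SyntheticSubject:
    """One generated subject: intensity volume plus nested ground-truth masks."""

    subject_id: str
    label: str
    volume: np.ndarray
    brain_mask: np.ndarray
    wm_mask: np.ndarray
    wml_mask: np.ndarray  # ground-truth lesion voxels (may be empty)


def _ellipsoid_mask(shape: Tuple[int, int, int], semi_frac: float) -> np.ndarray:
    center = (np.array(shape) - 1) / 2.0
    semi = semi_frac * np.array(shape)
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return d2 <= 1.0


def generate_volume(
    shape: Tuple[int, int, int],
    params: TextureParams,
    lesions: Optional[LesionParams] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Generate one volume and its (brain, wm, wml ground truth) masks.

    The Gaussian random field is rescaled after smoothing so that its SD
    over the brain mask equals ``params.sigma`` exactly; the class mean is
    then added and lesion spheres, if requested, are set to
    ``contrast * mean`` plus the local field.  Voxels outside the brain
    are 0.  Deterministic for a given ``rng`` state.
    """
    rng = np.random.default_rng(rng)
    brain = _ellipsoid_mask(shape, 0.45)
    wm = _ellipsoid_mask(shape, 0.28)

    field_ = rng.standard_normal(shape)
    field_ = gaussian_filter(field_, sigma=params.corr_length)
    sd = field_[brain].std()
    if params.sigma > 0 and sd > 0:
        field_ *= params.sigma / sd
    else:
        field_ = np.zeros(shape)

    vol = np.zeros(shape, dtype=float)
    vol[brain] = params.mean + field_[brain]

    wml = np.zeros(shape, dtype=bool)
    if lesions is not None and lesions.count > 0:
        wm_idx = np.argwhere(wm)
        if wm_idx.size == 0:
            raise ValueError("WM region too small to place lesions")
        grids = np.ogrid[tuple(slice(0, s) for s in shape)]
        placed = 0
        for _ in range(lesions.count * 50):
            if placed == lesions.count:
                break
            center = wm_idx[rng.integers(0, len(wm_idx))]
            radius = rng.uniform(*lesions.radius_range)
            d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
            sphere = (d2 <= radius**2) & wm  # lesions are confined to WM
            if sphere.sum() >= 4:
                wml |= sphere
                placed += 1
        if placed < lesions.count:
            raise ValueError(
                "WM region too small to place the requested lesions "
                f"(placed {placed} of {lesions.count})"
            )
        vol[wml] = lesions.contrast * params.mean + field_[wml]
    return vol, brain, wm, wml


def generate_cohort(spec: SyntheticCohortSpec) -> Tuple[List[SyntheticSubject], pd.DataFrame]:
    """Generate all subjects of a cohort, deterministically per seed.

    Returns the subjects (class-sorted, ids ``<label><i>``) and the subject
    table (id, label).  Use :func:`wmtex.io.write_cohort` to persist them as
    NIfTI volumes plus a subject CSV.
    """
    ss = np.random.SeedSequence(spec.seed)
    total = sum(spec.n_per_class.values())
    children = ss.spawn(total)
    subjects: List[SyntheticSubject] = []
    i = 0
    for label in sorted(spec.n_per_class):
        params = spec.class_params[label]
        for j in range(spec.n_per_class[label]):
            rng = np.random.default_rng(children[i])
            vol, brain, wm, wml = generate_volume(
                spec.volume_shape, params, lesions=spec.lesion_params, rng=rng
            )
            subjects.append(
                SyntheticSubject(f"{label}{j:03d}", label, vol, brain, wm, wml)
            )
            i += 1
    table = pd.DataFrame(
        {"subject_id": [s.subject_id for s in subjects],
         "label": [s.label for s in subjects]}
    )
    return subjects, table


def paper_imbalance_spec(seed: int = 0, **kwargs) -> SyntheticCohortSpec:
    """The imbalanced 57 AD / 16 LBD / 36 NC design with class-graded texture."""
    return SyntheticCohortSpec(
        n_per_class={"AD": 57, "LBD": 16, "NC": 36},
        class_params={
            "NC": TextureParams(corr_length=1.0),
            "AD": TextureParams(corr_length=2.0),
            "LBD": TextureParams(corr_length=3.0),
        },
        seed=seed,
        **kwargs,
    )


def balanced_spec(n: int = 30, seed: int = 0, **kwargs) -> SyntheticCohortSpec:
    """Balanced three-class design with the same class textures."""
    return SyntheticCohortSpec(
        n_per_class={"AD": n, "LBD": n, "NC": n},
        class_params={
            "NC": TextureParams(corr_length=1.0),
            "AD": TextureParams(corr_length=2.0),
            "LBD": TextureParams(corr_length=3.0),
        },
        seed=seed,
        **kwargs,
    )


def null_spec(n: int = 12, seed: int = 0, **kwargs) -> SyntheticCohortSpec:
    """Two classes with identical texture parameters: no signal by construction."""
    p = TextureParams(corr_length=2.0)
    return SyntheticCohortSpec(
        n_per_class={"A": n, "B": n},
        class_params={"A": p, "B": p},
        seed=seed,
        **kwargs,
    )


def signal_spec(n: int = 30, ratio: float = 4.0, seed: int = 0, **kwargs) -> SyntheticCohortSpec:
    """Two classes whose correlation lengths differ by ``ratio`` (strong signal)."""
    return SyntheticCohortSpec(
        n_per_class={"A": n, "B": n},
        class_params={
            "A": TextureParams(corr_length=1.0),
            "B": TextureParams(corr_length=1.0 * ratio),
        },
        seed=seed,
        **kwargs,
    )
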