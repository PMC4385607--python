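"""ROI-wise texture features: 8 summary statistics per descriptor and scale.

For each of three circular neighborhoods — (P=8, R=1), (P=12, R=2),
(P=16, R=4) — the LBP codes and contrast values of every ROI voxel are
pooled across slices into one distribution per descriptor, and each
distribution is reduced to eight statistics: mean, standard deviation,
variance, median, interquartile range, Shannon entropy (bits), skewness and
excess kurtosis.  Two descriptors x three neighborhoods x eight statistics
gives the 48-feature vector per subject.

Notes on conventions, where more than one reading exists:

* "variation" is computed as the variance (SD squared), not the coefficient
  of variation — CV is undefined for zero-mean data such as contrast-free
  constant regions.
* LBP codes are summarized directly as numeric values even though code
  labels are nominal; histogram-of-codes features are deliberately not used.
* Entropy is base 2; for continuous (contrast) values it is taken over a
  32-bin histogram spanning [min, max]; for discrete codes over the
  empirical label distribution.
* Skewness is the adjusted Fisher-Pearson estimator, kurtosis the adjusted
  excess kurtosis (normal -> 0); a constant sample defines SD, IQR, entropy,
  skewness and kurtosis all as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .texture import NeighborhoodSpec, compute_texture_maps

__all__ = [
    "DEFAULT_SPECS",
    "STATISTICS",
    "StatisticSet",
    "FeatureVector",
    "summarize_distribution",
    "feature_names",
    "extract_features",
    "extract_cohort",
]

#: The three neighborhood scales used throughout the pipeline.
DEFAULT_SPECS: Tuple[NeighborhoodSpec, ...] = (
    NeighborhoodSpec(P=8, R=1.0),
    NeighborhoodSpec(P=12, R=2.0),
    NeighborhoodSpec(P=16, R=4.0),
)

#: Fixed statistic order within each (descriptor, neighborhood) block.
STATISTICS: Tuple[str, ...] = (
    "mean",
    "sd",
    "variance",
    "median",
    "iqr",
    "entropy",
    "skewness",
    "kurtosis",
)

MIN_VALUES = 8  # below this, skewness/kurtosis estimates are meaningless


@dataclass(frozen=True)
class StatisticSet:
    """The eight summary statistics of one value distribution."""

    mean: float
    sd: float
    variance: float
    median: float
    iqr: float
    entropy: float
    skewness: float
    kurtosis: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in STATISTICS], dtype=float)


def summarize_distribution(
    values: Sequence[float],
    kind: Literal["discrete_codes", "continuous"],
    context: str = "",
) -> StatisticSet:
    """Reduce a value collection to the eight summary statistics.

    ``kind`` only affects the entropy: ``discrete_codes`` uses the empirical
    label distribution, ``continuous`` a 32-bin histogram over [min, max].
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < MIN_VALUES:
        where = f" ({context})" if context else ""
        raise ValueError(
            f"need at least {MIN_VALUES} values to summarize, got {v.size}{where}"
        )
    if kind not in ("discrete_codes", "continuous"):
        raise ValueError(f"unknown kind {kind!r}")

    mean = float(v.mean())
    median = float(np.median(v))
    if np.ptp(v) == 0:
        # degenerate constant distribution
        return StatisticSet(mean, 0.0, 0.0, median, 0.0, 0.0, 0.0, 0.0)

    sd = float(v.std(ddof=1))
    q1, q3 = np.percentile(v, [25, 75])  # linear-interpolation quantiles
    if kind == "discrete_codes":
        _, counts = np.unique(v, return_counts=True)
    else:
        counts, _ = np.histogram(v, bins=32, range=(v.min(), v.max()))
        counts = counts[counts > 0]
    p = counts / counts.sum()
    entropy = float(-(p * np.log2(p)).sum())
    skewness = float(sps.skew(v, bias=False))
    kurtosis = float(sps.kurtosis(v, fisher=True, bias=False))
    return StatisticSet(mean, sd, sd * sd, median, float(q3 - q1), entropy, skewness, kurtosis)


@dataclass(frozen=True)
class FeatureVector:
    """The 48 named texture features of one subject/modality/ROI."""

    names: Tuple[str, ...]
    values: np.ndarray
    subject_id: str = ""
    modality: str = ""
    roi: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if len(self.names) != vals.size:
            raise ValueError("names and values must be aligned")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "names", tuple(self.names))

    def __len__(self) -> int:
        return self.values.size

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names), name=self.subject_id)


def _fmt_r(r: float) -> str:
    return f"{r:g}"


def feature_names(specs: Sequence[NeighborhoodSpec] = DEFAULT_SPECS) -> Tuple[str, ...]:
    """The fixed feature-name order: per neighborhood, LBP block then C block.

    Names follow ``{descriptor}_P{P}_R{R}_{statistic}``, e.g.
    ``LBP_P8_R1_mean`` or ``C_P16_R4_entropy``.
    """
    names = []
    for spec in specs:
        for desc in ("LBP", "C"):
            for stat in STATISTICS:
                names.append(f"{desc}_P{spec.P}_R{_fmt_r(spec.R)}_{stat}")
    return tuple(names)


def extract_features(
    volume: np.ndarray,
    mask: np.ndarray,
    specs: Sequence[NeighborhoodSpec] = DEFAULT_SPECS,
    variant: str = "ri",
    slice_axis: int = 2,
    subject_id: str = "",
    modality: str = "",
    roi: str = "",
) -> FeatureVector:
    """Compute the pooled ROI feature vector of one volume.

    For each neighborhood spec the texture maps are built once and their LBP
    code and contrast distributions (pooled over all slices) are summarized;
    blocks are concatenated in the :func:`feature_names` order.
    """
    values = []
    ctx = subject_id or "volume"
    for spec in specs:
        maps = compute_texture_maps(volume, mask, spec, variant=variant, slice_axis=slice_axis)
        if len(maps) < MIN_VALUES:
            raise ValueError(
                f"spec (P={spec.P}, R={spec.R}) yielded only {len(maps)} mapped "
                f"voxels for {ctx}; need at least {MIN_VALUES}"
            )
        lbp_stats = summarize_distribution(
            maps.lbp, "discrete_codes", context=f"{ctx}/{roi}/LBP"
        )
        c_stats = summarize_distribution(
            maps.contrast, "continuous", context=f"{ctx}/{roi}/C"
        )
        values.append(lbp_stats.as_array())
        values.append(c_stats.as_array())
    return FeatureVector(
        names=feature_names(specs),
        values=np.concatenate(values),
        subject_id=subject_id,
        modality=modality,
        roi=roi,
    )


def extract_cohort(
    subjects: Iterable[Tuple[str, str, np.ndarray, np.ndarray]],
    specs: Sequence[NeighborhoodSpec] = DEFAULT_SPECS,
    variant: str = "ri",
    slice_axis: int = 2,
    modality: str = "",
    roi: str = "",
):
    """Build a :class:`~wmtex.imbalance.CohortTable` from per-subject volumes.

    ``subjects`` yields ``(subject_id, label, volume, mask)`` tuples.
    """
    from .imbalance import CohortTable  # local import to avoid a cycle

    rows, labels, ids = [], [], []
    for subject_id, label, volume, mask in subjects:
        fv = extract_features(
            volume, mask, specs=specs, variant=variant, slice_axis=slice_axis,
            subject_id=subject_id, modality=modality, roi=roi,
        )
        rows.append(fv.values)
        labels.append(label)
        ids.append(subject_id)
    features = pd.DataFrame(np.vstack(rows), index=ids, columns=list(feature_names(specs)))
    return CohortTable(
        features=features,
        labels=pd.Series(labels, index=ids, name="label"),
        provenance=pd.Series("real", index=ids, name="provenance"),
    )
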