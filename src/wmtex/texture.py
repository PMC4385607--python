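"""Rotation-invariant local binary patterns and local contrast on 2D slices.

The local binary pattern (LBP) of a pixel is formed by thresholding the gray
values of ``P`` equally spaced samples on a circle of radius ``R`` against the
center gray value and reading the resulting signs as a ``P``-bit number, bit
``p`` carrying weight ``2**p``.  Two derived operators are provided:

``ri``
    rotation-invariant code: the minimum of the code over all ``P`` circular
    bit rotations.
``riu2``
    rotation-invariant *uniform* code: patterns with at most two circular
    0/1 transitions are labelled by their number of set bits (``0..P``),
    every other pattern collapses to the miscellaneous label ``P + 1``.

The companion contrast measure ``VAR`` is the population variance of the
``P`` neighbor gray values, a rotation-invariant local-contrast statistic
that is invariant to gray-scale shifts (but not to scaling).

All operators work slice-wise: a 3D volume is decomposed into 2D slices
perpendicular to ``slice_axis`` and each masked voxel is evaluated within
its own slice.  Neighbors at fractional pixel positions are bilinearly
interpolated from the full slice (sampling is never restricted to the mask);
masked voxels whose sampling disc leaves the slice are skipped and tallied,
never padded, since padding would fabricate texture.

A note on the binomial weights: the classical definition assigns sign ``p``
the weight ``2**p``; an occasionally reprinted variant with a constant
exponent would not yield a unique code and is not used here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence, Tuple

import numpy as np

__all__ = [
    "NeighborhoodSpec",
    "NeighborhoodSample",
    "TextureMaps",
    "neighbor_coordinates",
    "sample_neighborhood",
    "sign_threshold",
    "lbp_code",
    "bits_from_code",
    "ror",
    "rotation_invariant_code",
    "uniformity",
    "uniformity_linear",
    "riu2_code",
    "local_contrast",
    "compute_texture_maps",
]

_SNAP_TOL = 1e-9

Variant = Literal["ri", "riu2"]


@dataclass(frozen=True)
class NeighborhoodSpec:
    """Circular sampling geometry: ``P`` samples on a circle of radius ``R``.

    Parameters
    ----------
    P : int
        Number of circular samples, must exceed 1.
    R : float
        Circle radius in pixels, must be positive.
    """

    P: int
    R: float

    def __post_init__(self) -> None:
        if int(self.P) != self.P or self.P <= 1:
            raise ValueError(f"P must be an integer > 1, got {self.P!r}")
        if not self.R > 0:
            raise ValueError(f"R must be > 0, got {self.R!r}")
        object.__setattr__(self, "P", int(self.P))
        object.__setattr__(self, "R", float(self.R))

    @property
    def n_raw_codes(self) -> int:
        return 1 << self.P

    @property
    def misc_label(self) -> int:
        """The riu2 label collecting all non-uniform patterns."""
        return self.P + 1


@dataclass(frozen=True)
class NeighborhoodSample:
    """Gray values of one circular neighborhood: center ``g_c`` and ``g_0..g_{P-1}``."""

    g_c: float
    g: np.ndarray  # shape (P,)

    def __post_init__(self) -> None:
        g = np.asarray(self.g, dtype=float)
        if g.ndim != 1 or g.size < 2:
            raise ValueError("neighbor values must be a 1D array of length P > 1")
        object.__setattr__(self, "g", g)

    @property
    def P(self) -> int:
        return self.g.size


def neighbor_coordinates(spec: NeighborhoodSpec) -> np.ndarray:
    """(row, col) offsets of the ``P`` samples, anticlockwise from due east.

    Sample ``p`` sits at ``(-R sin(2*pi*p/P), R cos(2*pi*p/P))`` relative to the
    center, first coordinate along the slice's row axis, second along the
    column axis.  Offsets within 1e-9 of an integer are snapped to that
    integer so that axis-aligned samples are exact pixel reads.
    """
    p = np.arange(spec.P)
    ang = 2.0 * np.pi * p / spec.P
    offsets = np.stack([-spec.R * np.sin(ang), spec.R * np.cos(ang)], axis=1)
    nearest = np.round(offsets)
    snap = np.abs(offsets - nearest) < _SNAP_TOL
    offsets[snap] = nearest[snap]
    return offsets


def _bilinear(slice_image: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Bilinear interpolation at in-bounds fractional coordinates.

    Uses the incremental form a + fr*(c-a) + fc*(b-a) + fr*fc*(a-b-c+d),
    which is exact on constant and linear fields, so tie comparisons
    (g_p == g_c) and zero contrast behave exactly on degenerate inputs.
    """
    img = slice_image.astype(float, copy=False)
    h, w = img.shape
    r0 = np.clip(np.floor(rows).astype(int), 0, h - 1)
    c0 = np.clip(np.floor(cols).astype(int), 0, w - 1)
    r1 = np.minimum(r0 + 1, h - 1)
    c1 = np.minimum(c0 + 1, w - 1)
    fr = rows - r0
    fc = cols - c0
    a = img[r0, c0]
    b = img[r0, c1]
    c = img[r1, c0]
    d = img[r1, c1]
    return a + fr * (c - a) + fc * (b - a) + fr * fc * (a - b - c + d)


def sample_neighborhood(
    slice_image: np.ndarray, center: Tuple[int, int], spec: NeighborhoodSpec
) -> NeighborhoodSample:
    """Read the circular neighborhood of ``center`` from a 2D slice.

    Integer offsets are direct pixel reads; fractional positions are
    bilinearly interpolated from the four surrounding pixels.  The whole
    sampling disc must lie inside the slice.
    """
    slice_image = np.asarray(slice_image, dtype=float)
    if slice_image.ndim != 2:
        raise ValueError("slice_image must be 2D")
    r, c = center
    h, w = slice_image.shape
    if r - spec.R < 0 or r + spec.R > h - 1 or c - spec.R < 0 or c + spec.R > w - 1:
        raise ValueError(
            f"sampling disc of radius {spec.R} at center {center} leaves the "
            f"slice bounds {slice_image.shape}"
        )
    offsets = neighbor_coordinates(spec)
    g = _bilinear(slice_image, r + offsets[:, 0], c + offsets[:, 1])
    return NeighborhoodSample(g_c=float(slice_image[r, c]), g=g)


def sign_threshold(sample: NeighborhoodSample) -> np.ndarray:
    """Sign bits ``b_p = 1 iff g_p - g_c >= 0`` (ties count as 1)."""
    return (sample.g - sample.g_c >= 0).astype(np.uint8)


def lbp_code(bits: Sequence[int]) -> int:
    """Binomially weighted code ``sum_p b_p * 2**p`` of a bit pattern."""
    b = np.asarray(bits, dtype=np.uint64)
    return int((b << np.arange(b.size, dtype=np.uint64)).sum())


def bits_from_code(code: int, P: int) -> np.ndarray:
    """Bit pattern ``b_0..b_{P-1}`` of an integer code (b_p = bit of weight 2**p)."""
    if not 0 <= code < (1 << P):
        raise ValueError(f"code {code} out of range for P={P}")
    return ((code >> np.arange(P)) & 1).astype(np.uint8)


def ror(x: int, i: int, P: int) -> int:
    """Circular bitwise right shift of the ``P``-bit number ``x`` by ``i`` places."""
    if not 0 <= x < (1 << P):
        raise ValueError(f"code {x} out of range for P={P}")
    i %= P
    mask = (1 << P) - 1
    return ((x >> i) | (x << (P - i))) & mask


def rotation_invariant_code(x: int, P: int) -> int:
    """Minimum of ``x`` over all ``P`` circular bit rotations (the ``ri`` code)."""
    return min(ror(x, i, P) for i in range(P))


def uniformity(bits: Sequence[int]) -> int:
    """Number of circular 0/1 transitions in a bit pattern.

    The circular count includes the wrap-around pair ``(b_{P-1}, b_0)``; this
    is the quantity thresholded at 2 by the ``riu2`` operator and is always
    even.
    """
    b = np.asarray(bits, dtype=np.int64)
    return int(np.abs(b - np.roll(b, 1)).sum())


def uniformity_linear(bits: Sequence[int]) -> int:
    """Number of 0/1 transitions reading the pattern end to end (no wrap).

    This is the convention used in textbook worked illustrations where the
    pattern is read as a written bit string, e.g. ``U(00000011) = 1`` and
    ``U(10000111) = 2``; :func:`uniformity` adds the circular wrap term.
    """
    b = np.asarray(bits, dtype=np.int64)
    return int(np.abs(np.diff(b)).sum())


def riu2_code(bits: Sequence[int]) -> int:
    """Rotation-invariant uniform label: popcount if circular U <= 2, else P+1."""
    b = np.asarray(bits, dtype=np.int64)
    if uniformity(b) <= 2:
        return int(b.sum())
    return b.size + 1


def local_contrast(sample: NeighborhoodSample) -> float:
    """Rotation-invariant contrast: population variance of the P neighbor values."""
    return float(np.var(sample.g))


def _ri_codes_array(codes: np.ndarray, P: int) -> np.ndarray:
    """Vectorized ``ri`` mapping of an array of raw codes."""
    codes = codes.astype(np.uint32)
    mask = np.uint32((1 << P) - 1)
    best = codes.copy()
    for i in range(1, P):
        rot = ((codes >> np.uint32(i)) | (codes << np.uint32(P - i))) & mask
        np.minimum(best, rot, out=best)
    return best


@dataclass
class TextureMaps:
    """Per-voxel LBP codes and contrast values over a masked region.

    ``voxels`` holds the (i, j, k) index of every evaluated voxel in the
    original volume axis order; ``lbp`` and ``contrast`` are aligned with it.
    ``n_skipped`` counts masked voxels whose sampling disc left their slice.
    """

    voxels: np.ndarray  # (N, 3) int
    lbp: np.ndarray  # (N,) int
    contrast: np.ndarray  # (N,) float
    variant: Variant
    spec: NeighborhoodSpec
    slice_axis: int
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if not (len(self.voxels) == len(self.lbp) == len(self.contrast)):
            raise ValueError("voxels, lbp and contrast must be aligned")
        if np.any(self.contrast < 0):
            raise ValueError("contrast values must be non-negative")
        if self.variant == "riu2" and self.lbp.size and self.lbp.max() > self.spec.P + 1:
            raise ValueError("riu2 codes must lie in [0, P+1]")

    def __len__(self) -> int:
        return len(self.lbp)

    def to_volumes(self, shape: Tuple[int, int, int], fill: float = np.nan):
        """Materialize LBP- and contrast-valued volumes (background = ``fill``)."""
        lbp_vol = np.full(shape, fill, dtype=float)
        c_vol = np.full(shape, fill, dtype=float)
        idx = tuple(self.voxels.T)
        lbp_vol[idx] = self.lbp
        c_vol[idx] = self.contrast
        return lbp_vol, c_vol


def compute_texture_maps(
    volume: np.ndarray,
    mask: np.ndarray,
    spec: NeighborhoodSpec,
    variant: Variant = "ri",
    slice_axis: int = 2,
) -> TextureMaps:
    """Evaluate the chosen LBP variant and contrast at every masked voxel.

    The volume is processed slice-wise perpendicular to ``slice_axis``
    (default: third axis, the axial convention).  Neighbor gray values are
    read from the full slice; masked voxels whose sampling disc exits the
    slice are skipped and reported in ``n_skipped``.
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if volume.ndim != 3:
        raise ValueError("volume must be 3D")
    if volume.shape != mask.shape:
        raise ValueError(
            f"volume shape {volume.shape} and mask shape {mask.shape} differ"
        )
    if not mask.any():
        raise ValueError("mask is empty")
    if variant not in ("ri", "riu2"):
        raise ValueError(f"variant must be 'ri' or 'riu2', got {variant!r}")
    slice_axis = int(slice_axis) % 3

    vol_m = np.moveaxis(volume, slice_axis, 0)
    mask_m = np.moveaxis(mask, slice_axis, 0)
    n_slices, h, w = vol_m.shape
    offsets = neighbor_coordinates(spec)
    P, R = spec.P, spec.R
    # map moved-axis coordinates (s, r, c) back to original (i, j, k)
    axes = [slice_axis] + [ax for ax in range(3) if ax != slice_axis]
    inv = np.argsort(axes)

    all_voxels, all_codes, all_contrast = [], [], []
    n_skipped = 0
    weights = (1 << np.arange(P, dtype=np.uint64))
    for s in range(n_slices):
        rows, cols = np.nonzero(mask_m[s])
        if rows.size == 0:
            continue
        ok = (rows - R >= 0) & (rows + R <= h - 1) & (cols - R >= 0) & (cols + R <= w - 1)
        n_skipped += int((~ok).sum())
        rows, cols = rows[ok], cols[ok]
        if rows.size == 0:
            continue
        sl = vol_m[s]
        G = np.empty((P, rows.size), dtype=float)
        for p in range(P):
            dr, dc = offsets[p]
            if dr == int(dr) and dc == int(dc):
                G[p] = sl[rows + int(dr), cols + int(dc)]
            else:
                G[p] = _bilinear(sl, rows + dr, cols + dc)
        gc = sl[rows, cols]
        bits = (G - gc >= 0)
        raw = (bits.astype(np.uint64) * weights[:, None]).sum(axis=0)
        if variant == "ri":
            codes = _ri_codes_array(raw, P)
        else:
            trans = (bits != np.roll(bits, 1, axis=0)).sum(axis=0)
            codes = np.where(trans <= 2, bits.sum(axis=0), P + 1)
        contrast = G.var(axis=0)  # population variance, divisor P
        moved = np.stack([np.full(rows.size, s), rows, cols], axis=1)
        all_voxels.append(moved[:, inv])
        all_codes.append(codes.astype(np.int64))
        all_contrast.append(contrast)

    if all_voxels:
        voxels = np.concatenate(all_voxels)
        codes = np.concatenate(all_codes)
        contrast = np.concatenate(all_contrast)
    else:
        voxels = np.empty((0, 3), dtype=int)
        codes = np.empty(0, dtype=np.int64)
        contrast = np.empty(0, dtype=float)
    # numerical guard: population variance can dip infinitesimally below 0
    np.clip(contrast, 0.0, None, out=contrast)
    return TextureMaps(
        voxels=voxels,
        lbp=codes,
        contrast=contrast,
        variant=variant,
        spec=spec,
        slice_axis=slice_axis,
        n_skipped=n_skipped,
    )
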