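"""Independent brute-force reference for the texture operators.

Everything here is evaluated literally, pixel by pixel, with its own
bilinear interpolation and bit bookkeeping — deliberately sharing no code
with the package so it can serve as an oracle.
"""

import math

import numpy as np


def ref_neighbor_values(img, r, c, P, R):
    """Gray values of the P circular samples around (r, c), hand bilinear."""
    out = []
    for p in range(P):
        ang = 2.0 * math.pi * p / P
        rr = r - R * math.sin(ang)
        cc = c + R * math.cos(ang)
        # snap near-integers exactly like a careful hand computation would
        if abs(rr - round(rr)) < 1e-9:
            rr = round(rr)
        if abs(cc - round(cc)) < 1e-9:
            cc = round(cc)
        r0, c0 = int(math.floor(rr)), int(math.floor(cc))
        fr, fc = rr - r0, cc - c0
        r1 = min(r0 + 1, img.shape[0] - 1)
        c1 = min(c0 + 1, img.shape[1] - 1)
        v = (img[r0, c0] * (1 - fr) * (1 - fc)
             + img[r0, c1] * (1 - fr) * fc
             + img[r1, c0] * fr * (1 - fc)
             + img[r1, c1] * fr * fc)
        out.append(v)
    return out


def ref_bits(img, r, c, P, R):
    gc = img[r, c]
    return [1 if g - gc >= 0 else 0 for g in ref_neighbor_values(img, r, c, P, R)]


def ref_raw_code(bits):
    return sum(b * (2 ** p) for p, b in enumerate(bits))


def ref_ri_code(bits):
    """Minimum over circular rotations, done on bit lists."""
    P = len(bits)
    best = None
    for i in range(P):
        rot = bits[i:] + bits[:i]  # right rotation by i of the P-bit word
        val = ref_raw_code(rot)
        if best is None or val < best:
            best = val
    return best


def ref_uniformity(bits):
    bits = [int(b) for b in bits]
    P = len(bits)
    u = abs(bits[P - 1] - bits[0])
    for p in range(1, P):
        u += abs(bits[p] - bits[p - 1])
    return u


def ref_riu2_code(bits):
    bits = [int(b) for b in bits]
    if ref_uniformity(bits) <= 2:
        return sum(bits)
    return len(bits) + 1


def ref_contrast(values):
    mu = sum(values) / len(values)
    return sum((v - mu) ** 2 for v in values) / len(values)


def ref_texture_slice(img, mask2d, P, R, variant):
    """Per-pixel literal evaluation over one masked 2D slice.

    Returns dict (r, c) -> (code, contrast) for every masked pixel whose
    sampling disc stays inside the slice.
    """
    h, w = img.shape
    out = {}
    for r in range(h):
        for c in range(w):
            if not mask2d[r, c]:
                continue
            if r - R < 0 or r + R > h - 1 or c - R < 0 or c + R > w - 1:
                continue
            bits = ref_bits(img, r, c, P, R)
            code = ref_ri_code(bits) if variant == "ri" else ref_riu2_code(bits)
            out[(r, c)] = (code, ref_contrast(ref_neighbor_values(img, r, c, P, R)))
    return out


def dice(a, b):
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return 2.0 * (a & b).sum() / denom if denom else 1.0
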