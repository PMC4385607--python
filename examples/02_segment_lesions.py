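"""Segment synthetic white-matter hyperintensities and score them with Dice.

Generates a FLAIR-like volume with three bright lesions at twice the brain's
mean intensity, thresholds each slice at 1.4 x the slice histogram mode, and
compares the result against the generator's ground-truth lesion mask.
"""

import numpy as np

import wmtex as w

rng = np.random.default_rng(7)
vol, brain, wm, truth = w.generate_volume(
    (48, 48, 8),
    w.TextureParams(mean=100.0, sigma=5.0, corr_length=1.5),
    lesions=w.LesionParams(count=3, radius_range=(2.0, 4.0), contrast=2.0),
    rng=rng,
)

cfg = w.WMLSegmentationConfig(scale_factor=1.4)
seg = w.segment_wml(vol, brain, cfg)

inter = (seg & truth).sum()
dice = 2 * inter / (seg.sum() + truth.sum())
print(f"ground-truth lesion voxels: {truth.sum()}")
print(f"segmented lesion voxels:    {seg.sum()}")
print(f"Dice overlap:               {dice:.3f}")
print("Dice of 1.0 means the mode-scaled threshold recovered the lesions exactly;")
print("values above 0.9 indicate clinically usable agreement on this contrast.")
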