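"""Bundled reference measurements for the four wheat refraction classes.

A wheat lot is graded into quality fractions ("refractions"): sound (fully
developed, undamaged), damaged, shriveled (underdeveloped, wrinkled) and
broken kernels.  The constants below are published lot-level summary
statistics for wheat variety PBW 725 (n = 100 kernels per class): caliper
axial dimensions in millimetres, single-kernel weights in grams, and mean
scanner sRGB channel intensities on a near-black background.  They drive the
synthetic scene generator and serve as worked-example inputs for the
physical-property equations.
"""

from __future__ import annotations

REFRACTION_CLASSES = ("sound", "damaged", "shriveled", "broken")

#: Caliper means (L, W, T) in mm per refraction class.
AXIAL_MM_MEAN = {
    "sound": (6.20, 3.43, 2.87),
    "damaged": (5.82, 3.04, 2.57),
    "shriveled": (5.62, 2.47, 2.24),
    "broken": (4.91, 3.16, 2.59),
}

#: Caliper standard deviations (L, W, T) in mm per refraction class.
AXIAL_MM_SD = {
    "sound": (0.65, 0.43, 0.41),
    "damaged": (2.04, 1.58, 1.50),
    "shriveled": (1.15, 1.07, 0.80),
    "broken": (2.45, 1.21, 0.94),
}

#: Mean kernel colour (R, G, B) in 8-bit sRGB per refraction class.
MEAN_RGB = {
    "sound": (119.79, 104.98, 69.62),
    "damaged": (114.59, 91.82, 66.53),
    "shriveled": (141.15, 117.19, 90.26),
    "broken": (101.96, 83.27, 56.96),
}

#: Between-kernel standard deviation of the mean channel values (R, G, B).
RGB_SD = {
    "sound": (18.79, 16.98, 12.62),
    "damaged": (44.59, 37.82, 43.47),
    "shriveled": (22.85, 17.81, 13.74),
    "broken": (22.96, 19.73, 21.04),
}

#: Caliper aspect ratio (L/W) mean and sd per refraction class.
ASPECT_RATIO = {
    "sound": (1.81, 0.28),
    "damaged": (1.97, 1.47),
    "shriveled": (2.56, 0.74),
    "broken": (1.58, 1.41),
}

#: Single-kernel weight mean and sd in grams per refraction class.
KERNEL_WEIGHT_G = {
    "sound": (0.045, 0.010),
    "damaged": (0.036, 0.030),
    "shriveled": (0.022, 0.030),
    "broken": (0.021, 0.030),
}

#: Fixed segmentation thresholds for the non-sound classes (8-bit gray levels).
#: Sound kernels are segmented with Otsu's automatic threshold instead.
CLASS_THRESHOLDS = {"damaged": 37, "shriveled": 74, "broken": 35}
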