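"""Published reference values for one-shot depth-camera cattle
phenotyping, used to calibrate the synthetic presets and as inputs to
the validation checks.

All values are measurement-campaign summaries reported for a validated
sliding-gantry reference scanner (the "gold standard") and the
one-shot multi-camera device evaluated against it: cohort trait means
for three trials, the per-trait repeatability/reproducibility
variability table of the one-shot device, the device-comparison means
over a shared 15-cow panel, and the weigh-scale range of the heifer
cohort used for body-weight validation.

Units follow the reporting convention: linear traits in m, surfaces in
m^2, volumes in litres (convert with
:func:`ruminant3d.prediction.from_litres` before using the equations).
"""

from __future__ import annotations

#: cohort means per trial: (n, TS m^2, TV L, WH m, HW m, WB m, CD m, AC m)
COHORT_MEANS = {
    1: dict(n=16, ts=7.202, tv_l=763.9, wh=1.454, hw=0.575, wb=0.537, cd=0.811, ac=2.632),
    2: dict(n=15, ts=7.181, tv_l=739.2, wh=1.499, hw=0.565, wb=0.530, cd=0.787, ac=2.587),
    3: dict(n=13, ts=6.278, tv_l=581.2, wh=1.376, hw=0.507, wb=0.507, cd=0.755, ac=2.324),
}

#: adult reference cohort (trial 1) and heifer cohort (trial 3)
ADULT_COHORT = COHORT_MEANS[1]
HEIFER_COHORT = COHORT_MEANS[3]

#: per-trait repeatability / reproducibility of the one-shot device:
#: (CV repeatability %, CV reproducibility %, error repeatability,
#: error reproducibility) in the trait's units (volume L, surface m^2,
#: lengths m)
VARIABILITY_TABLE = {
    "complete_volume_l": (1.18, 2.71, 8.71, 21.14),
    "partial_surface_m2": (1.77, 3.26, 0.13, 0.23),
    "hip_width_m": (0.48, 1.12, 0.0028, 0.0064),
    "withers_height_m": (1.29, 1.78, 0.0186, 0.0264),
    "chest_depth_m": (0.81, 1.42, 0.0064, 0.0116),
    "heart_girth_m": (0.46, 2.16, 0.0118, 0.047),
    "buttocks_width_m": (1.34, 1.83, 0.007, 0.01),
    "diagonal_length_m": (0.76, 2.55, 0.013, 0.0447),
    "abdominal_circumference_m": (0.46, 1.8, 0.0118, 0.0475),
}

#: device-comparison means over the shared 15-cow panel:
#: reference (sliding-gantry) vs test (one-shot) device
DEVICE_COMPARISON_MEANS = {
    "wh": (1.540, 1.459),
    "hw": (0.578, 0.565),
    "wb": (0.526, 0.530),
    "cd": (0.813, 0.787),
    "ac": (2.580, 2.587),
    "tv_l": (739.8, 738.6),
    "ts": (7.481, 6.881),
}

#: weigh-scale body-weight range of the heifer validation cohort, kg
SCALE_RANGE_KG = (440.0, 550.0)

#: worked round-figure means used in the published error illustrations
ILLUSTRATION_MEANS = dict(volume_l=764.0, surface_m2=7.20, wh_m=1.45)
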