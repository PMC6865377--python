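"""Published cohort summary tables used as arithmetic inputs.

These numbers are the printed per-model results of a 3 T clinical study of
MP2RAGE-based multispectral VBM in focal epilepsy (31 healthy controls, 21
patients, of whom 5 had MRI-visible lesions and 16 were MRI-negative). The
underlying images are not available, so the package treats these summaries
as fixed inputs: the sensitivity, Euclidean-distance, ratio and
corrected-specificity arithmetic can be recomputed from them exactly, which
is how the reporting layer of this package is validated.

All values are exactly as printed: rates in percent at one decimal, ratios
at two decimals, peak t-scores at one decimal.
"""

from __future__ import annotations

MODELS = ("T1", "MP2", "T1+FLAIR", "MP2+INV1", "MP2+INV2", "MP2+FLAIR", "INV1+INV2")

#: cluster-maximum t-scores for the five MRI-visible (MCD) patients at 14 mm
#: smoothing, per model (cases 1, 4, 16, 17, 21)
LESIONAL_PEAK_T: dict[str, tuple[float, ...]] = {
    "T1": (7.9, 2.5, 4.2, 3.6, 4.6),
    "MP2": (10.1, 2.5, 3.8, 3.3, 4.8),
    "T1+FLAIR": (11.2, 5.3, 3.9, 3.2, 6.8),
    "MP2+INV1": (9.4, 2.3, 3.9, 3.8, 6.9),
    "MP2+INV2": (9.1, 4.2, 3.9, 3.1, 5.7),
    "MP2+FLAIR": (11.7, 4.7, 3.9, 3.5, 7.5),
    "INV1+INV2": (8.9, 3.1, 5.3, 2.4, 5.9),
}

#: printed sensitivity row (percent) at the T >= 3.3 rule
LESIONAL_SENSITIVITY: dict[str, float] = {
    "T1": 80.0, "MP2": 80.0, "T1+FLAIR": 80.0, "MP2+INV1": 80.0,
    "MP2+INV2": 80.0, "MP2+FLAIR": 100.0, "INV1+INV2": 60.0,
}

#: largest cutoff preserving 100% sensitivity across all models
FULL_SENSITIVITY_THRESHOLD = 2.3

#: MRI-negative cohort performance at 14 mm / T = 3.3:
#: model -> (C_R %, D_R %, S_P %, printed ED, printed C_R/D_R)
MRI_NEGATIVE_AUTOMATED: dict[str, tuple[float, float, float, float, float]] = {
    "T1": (56.3, 87.5, 19.4, 91.7, 0.64),
    "MP2": (37.5, 68.8, 32.3, 92.1, 0.55),
    "T1+FLAIR": (68.8, 81.3, 22.6, 83.5, 0.85),
    "MP2+INV1": (62.5, 93.8, 45.2, 66.4, 0.67),
    "MP2+INV2": (43.8, 62.5, 32.3, 88.0, 0.70),
    "MP2+FLAIR": (50.0, 68.8, 32.3, 84.2, 0.73),
    "INV1+INV2": (31.3, 56.3, 41.9, 90.0, 0.57),
}

MRI_NEGATIVE_VISUAL: dict[str, tuple[float, float, float, float, float]] = {
    "T1": (18.8, 68.8, 35.5, 103.7, 0.27),
    "MP2": (18.8, 43.8, 45.2, 98.0, 0.43),
    "T1+FLAIR": (25.0, 43.8, 35.5, 99.0, 0.57),
    "MP2+INV1": (37.5, 62.5, 51.6, 79.0, 0.60),
    "MP2+INV2": (31.3, 37.5, 45.2, 87.9, 0.83),
    "MP2+FLAIR": (18.8, 31.3, 35.5, 103.7, 0.60),
    "INV1+INV2": (6.3, 18.8, 54.8, 104.0, 0.34),
}

#: control visual review: model -> (unclear %, printed corrected specificity %)
CONTROL_VISUAL: dict[str, tuple[float, float]] = {
    "T1": (64.5, 35.5),
    "MP2": (54.8, 45.2),
    "T1+FLAIR": (64.5, 35.5),
    "MP2+INV1": (48.4, 51.6),
    "MP2+INV2": (54.8, 45.2),
    "MP2+FLAIR": (64.5, 35.5),
    "INV1+INV2": (45.2, 54.8),
}

#: cumulative lobe census over the 16 MRI-negative patients
LOBE_CENSUS = {"concordant": 27, "discordant": 101, "ratio": 0.27}
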