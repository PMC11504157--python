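"""Bundled example agreement cohort.

Total-kidney-volume measurements for a 10-subject ADPKD test cohort
(nine patients, one healthy control), measured twice per subject: expert
manual planimetry on T2-weighted MRI ("ground truth") and the automated
segmentation pipeline ("predicted").  Two acquisitions per subject are
available, axial and coronal, each with its own pair of measurements.

These tables exercise the agreement statistics (:mod:`tkvnet.evaluation`)
on realistic clinical numbers without requiring any image data.
Values in millilitres, one ``(ground_truth, predicted)`` pair per subject.
"""

from __future__ import annotations

AXIAL_SUBJECTS: tuple[str, ...] = tuple(
    f"participant_{i}" for i in range(1, 11))

#: axial-section TKV (ground truth mL, predicted mL); subject 6 is healthy
AXIAL_TKV_PAIRS: tuple[tuple[float, float], ...] = (
    (2992.23, 3004.72),
    (1078.51, 1117.47),
    (1121.51, 1195.16),
    (2169.31, 2162.39),
    (1740.32, 1763.23),
    (316.14, 324.86),
    (310.54, 346.36),
    (2836.07, 2794.30),
    (1770.83, 1970.30),
    (682.89, 684.51),
)

#: coronal-section TKV (ground truth mL, predicted mL); same subjects
CORONAL_TKV_PAIRS: tuple[tuple[float, float], ...] = (
    (3573.87, 2753.84),
    (1328.97, 1614.76),
    (1374.44, 1303.08),
    (2557.89, 1515.70),
    (1995.45, 2039.09),
    (248.80, 434.70),
    (312.48, 317.74),
    (3310.56, 3078.19),
    (2034.05, 2540.41),
    (666.63, 764.95),
)

#: image counts of the full axial dataset and its 80:20 train/val split
AXIAL_IMAGE_COUNT: int = 1483
AXIAL_TRAIN_COUNT: int = 1186
AXIAL_VAL_COUNT: int = 297
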