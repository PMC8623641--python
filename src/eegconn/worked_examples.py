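"""Worked-example evaluation fixtures from a 78-subject three-group cohort.

Reference summary tables for a memory-clinic cohort of 22 SCI, 28 MCI and
28 AD patients, used as worked examples for the confusion-matrix arithmetic
(total accuracy, specificity/sensitivity recombination).  Only rows whose
printed total accuracy is arithmetically consistent with the printed counts
(trace / 78, to printing precision) are included; rows failing that check
are deliberately excluded.
"""

from __future__ import annotations

import numpy as np

from .classify import ConfusionMatrix, confusion_metrics

__all__ = [
    "GROUP_SIZES",
    "THREE_CLASS_CONFUSIONS",
    "TWO_CLASS_SCI_VS_AD_EPEN",
    "recompute_total_accuracy",
    "recombine_two_class_accuracy",
]

GROUP_SIZES = {"SCI": 22, "MCI": 28, "AD": 28}

#: (graph_param, measure) -> (3x3 counts [SCI, MCI, AD rows], printed total accuracy %)
THREE_CLASS_CONFUSIONS = {
    ("CC", "EpEn"): ([[20, 2, 0], [0, 25, 3], [0, 1, 27]], 92.31),
    ("CC", "PLI"): ([[21, 1, 0], [0, 26, 2], [1, 3, 24]], 91.03),
    ("K", "EpEn"): ([[21, 0, 1], [0, 26, 2], [1, 0, 27]], 94.87),
    ("K", "PLI"): ([[17, 1, 4], [0, 25, 3], [1, 0, 27]], 88.46),
    ("L", "PLI"): ([[19, 2, 1], [0, 25, 3], [2, 3, 23]], 85.90),
    ("Eff", "EpEn"): ([[21, 1, 0], [0, 27, 1], [0, 2, 26]], 94.87),
    ("BW", "EpEn"): ([[19, 2, 1], [0, 28, 0], [1, 3, 24]], 91.02),
    ("BW", "MSC"): ([[19, 2, 1], [0, 28, 0], [3, 1, 24]], 91.03),
    ("BW", "MI"): ([[18, 1, 3], [0, 27, 1], [1, 2, 25]], 89.74),
}

#: SCI-vs-AD two-class summary with the EpEn measure:
#: graph_param -> (accuracy %, specificity % [SCI recall], sensitivity % [AD recall])
TWO_CLASS_SCI_VS_AD_EPEN = {
    "CC": (94.0, 90.91, 96.43),
    "K": (90.0, 90.91, 89.28),
    "L": (90.0, 90.91, 89.28),
    "Eff": (94.0, 95.45, 92.86),
    "BW": (92.0, 86.36, 96.43),
}


def recompute_total_accuracy(key) -> float:
    """Total accuracy (%) recomputed from the stored counts for ``key``."""
    counts, _ = THREE_CLASS_CONFUSIONS[key]
    rep = confusion_metrics(ConfusionMatrix(counts, ["SCI", "MCI", "AD"]))
    return float(rep.total_accuracy)


def recombine_two_class_accuracy(graph_param: str) -> float:
    """Accuracy (%) implied by the SCI-vs-AD specificity/sensitivity pair.

    Specificity and sensitivity are converted back to integer class-wise
    correct counts (22 SCI, 28 AD) and recombined into the overall accuracy.
    """
    _, spec, sens = TWO_CLASS_SCI_VS_AD_EPEN[graph_param]
    n_sci, n_ad = GROUP_SIZES["SCI"], GROUP_SIZES["AD"]
    correct = round(spec / 100.0 * n_sci) + round(sens / 100.0 * n_ad)
    return 100.0 * correct / (n_sci + n_ad)
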