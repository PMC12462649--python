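"""Reference cross-validation fold counts.

Per-fold validation confusion counts (TN, FP, FN, TP) reported for the
PET-, MRI- and PET/MRI-based models in the head-and-neck study whose
design this package reproduces (202 balanced cases, stratified five-fold
cross-validation). They serve as worked examples for the fold-summary
arithmetic: the unweighted per-fold means round to
0.75/0.72/0.77 (PET), 0.66/0.63/0.68 (MRI) and 0.72/0.69/0.74 (PET/MRI)
for accuracy/sensitivity/specificity.
"""

from __future__ import annotations

from petmri3d.metrics import ConfusionCounts

__all__ = ["REFERENCE_FOLD_COUNTS", "reference_fold_counts"]

# modality -> five (TN, FP, FN, TP) rows, folds 1..5
REFERENCE_FOLD_COUNTS: dict[str, list[tuple[int, int, int, int]]] = {
    "pet": [
        (14, 6, 7, 14),
        (18, 3, 4, 16),
        (14, 6, 7, 13),
        (16, 4, 5, 15),
        (16, 4, 5, 15),
    ],
    "mri": [
        (15, 5, 6, 15),
        (13, 8, 9, 11),
        (15, 5, 6, 14),
        (12, 8, 9, 11),
        (14, 6, 7, 13),
    ],
    "petmri": [
        (15, 5, 6, 15),
        (15, 6, 7, 13),
        (13, 7, 8, 12),
        (17, 3, 4, 16),
        (15, 5, 6, 14),
    ],
}


def reference_fold_counts(modality: str) -> list[ConfusionCounts]:
    """The five reference fold rows for one modality as ConfusionCounts."""
    rows = REFERENCE_FOLD_COUNTS[modality]
    return [ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn) for tn, fp, fn, tp in rows]
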