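"""Cross-validation fold-summary arithmetic on the reference counts.

Feeds the per-fold validation confusion counts of the reference
head-and-neck study (five folds for each of the PET, MRI and PET/MRI
models) through the fold-summary machinery and prints the per-fold and
summary metrics. The unweighted per-fold mean — not the pooled-count
mean — is what reproduces the published 2-decimal summaries.
"""

from petmri3d.metrics import fold_summary, round_report
from petmri3d.reference import reference_fold_counts

for modality in ("pet", "mri", "petmri"):
    fs = fold_summary(reference_fold_counts(modality), k=5)
    print(f"\n{modality.upper()} per-fold validation metrics:")
    print(fs.per_fold.round(3).to_string())
    mean = {k: round_report(v) for k, v in fs.mean.items()}
    median = {k: round_report(v) for k, v in fs.median.items()}
    print(f"mean:   acc={mean['accuracy']} sens={mean['sensitivity']} spec={mean['specificity']}")
    print(f"median: acc={median['accuracy']} sens={median['sensitivity']} spec={median['specificity']}")
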