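"""Reference score tables from the original feasibility evaluation.

These are the case-by-case examiner (true) and model-predicted rubric
scores reported by the clinician-led feasibility study this package
reimplements: 20 training preparations and 10 held-out test preparations,
with values rounded to one decimal place.  They serve as fixed inputs for
the agreement statistics — the headline statistics of that study were
computed on unrounded scores, so statistics recomputed from these rounded
tables legitimately differ in the second decimal (e.g. the test-set
Bland–Altman bias is +0.23 on the rounded totals versus +0.52 on the
unrounded data).

Known quirk, preserved verbatim rather than silently reconciled: test
case 10 records a "true occlusal preservation" of 2, above that
criterion's 1-point maximum, and its printed total (12) is consistent
only with that out-of-range value.  The strict sheet validator in
:mod:`prepscore.rubric` would reject it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "load_reference_table",
    "reference_totals",
]

_TRAIN = {
    "true_clearance_buccal": [1, 0, 0, 0, 1, 0, 1, 2, 0, 1, 2, 1, 2, 1, 0, 0, 1, 1, 0, 1],
    "predicted_clearance_buccal": [1, 0, 0.2, 0.4, 1.3, 0.5, 0.7, 1.4, 0, 0.8, 1, 1.1, 1.3, 0.2, 0.4, 0.2, 0.9, 1, 0.1, 0.7],
    "true_clearance_lingual": [2, 2, 2, 2, 0, 2, 2, 2, 1, 0, 0, 0, 2, 2, 2, 0, 1, 0, 1, 0],
    "predicted_clearance_lingual": [1.2, 1.6, 1.8, 1.7, 0.3, 1.3, 1.9, 1.9, 0.5, 0.1, 0.1, 0, 1.1, 1.9, 1.9, 0.3, 0.7, 0, 1, 0],
    "true_clearance_gingival": [2, 1, 2, 2, 2, 2, 2, 2, 0, 2, 0, 2, 2, 0, 2, 0, 1, 1, 0, 0],
    "predicted_clearance_gingival": [1.5, 0.3, 1.8, 1.2, 1.9, 1.1, 1.9, 1.9, 0.1, 1.5, 0.8, 1.9, 1.7, 0.7, 1.9, 0.5, 1.6, 0.7, 0.1, 0.2],
    "true_preservation_between": [2, 2, 2, 2, 1, 2, 2, 2, 2, 2, 2, 2, 2, 2, 2, 2, 2, 2, 2, 1],
    "predicted_preservation_between": [1.8, 1.8, 1.9, 1.9, 1.4, 1.8, 1.9, 1.9, 1.9, 1.9, 1.7, 1.7, 1.8, 1.9, 1.9, 1.8, 1.8, 1.9, 1.9, 1.7],
    "true_occlusal_preservation": [1] * 20,
    "predicted_occlusal_preservation": [0.9] * 20,
    "true_caries_removal": [8, 9, 9, 9, 9, 7, 9, 9, 9, 9, 9, 9, 7, 9, 9, 9, 9, 9, 7, 7],
    "predicted_caries_removal": [8.1, 8.6, 8.9, 8.7, 8.5, 8.3, 8.9, 8.9, 8.9, 8.9, 8, 8.8, 7.3, 8.7, 8.9, 8.7, 8.5, 8.7, 7.1, 7.2],
    "true_no_undermined_enamel": [2, 1, 2, 2, 2, 2, 2, 2, 0, 1, 0, 1, 1, 2, 2, 0, 2, 0, 0, 0],
    "predicted_no_undermined_enamel": [1.7, 0.9, 1.8, 1.8, 1.6, 1.4, 1.9, 1.9, 0, 0.4, 0.3, 0.6, 0.9, 1.8, 1.9, 0.1, 1.6, 0, 0, 0],
    "true_adjacent_damage": [0] * 20,
    "predicted_adjacent_damage": [0] * 20,
    "true_total": [18, 16, 18, 18, 16, 16, 19, 20, 13, 16, 14, 16, 17, 17, 18, 12, 17, 14, 11, 10],
    "predicted_total": [16.6, 14.6, 17.7, 17, 16.3, 15.6, 18.7, 19.4, 12.7, 14.8, 13.2, 15, 15.3, 16.3, 18.4, 12.9, 16.5, 13.5, 11.4, 11.19],
}

_TEST = {
    "true_clearance_buccal": [0.5, 0, 0, 0, 0, 0, 0, 0, 0, 0],
    "predicted_clearance_buccal": [0, 0, 0, 0, 0, 0, 0, 0.3, 0, 0],
    "true_clearance_lingual": [0, 0, 0, 1, 2, 0, 0, 1, 0, 0],
    "predicted_clearance_lingual": [0, 0, 0, 0, 0, 0, 2, 0.4, 0, 2],
    "true_clearance_gingival": [0, 0, 0, 0, 0, 0, 0, 0, 1, 1],
    "predicted_clearance_gingival": [0, 0.6, 0, 0, 0, 1, 0, 0.3, 0, 0],
    "true_preservation_between": [2, 2, 1, 2, 0, 1, 2, 1, 2, 2],
    "predicted_preservation_between": [2] * 10,
    "true_occlusal_preservation": [1, 1, 1, 1, 0.5, 0, 1, 0, 1, 2],
    "predicted_occlusal_preservation": [1] * 10,
    "true_caries_removal": [7, 8, 7, 7, 8, 8, 9, 6, 4, 8],
    "predicted_caries_removal": [8.5, 9, 4.7, 6, 7.4, 3.2, 8.8, 2.2, 5.4, 8.1],
    "true_no_undermined_enamel": [1, 0, 0, 0, 0, 0, 2, 0, 1, 0],
    "predicted_no_undermined_enamel": [0, 0, 0, 0, 0, 1.28, 1.9, 0, 0, 0],
    "true_adjacent_damage": [0, 0, 0, -2, -1, -1, 0, 0, 0, -1],
    "predicted_adjacent_damage": [0] * 10,
    "true_total": [11.5, 11, 9, 9, 9.5, 8, 12, 8, 9, 12],
    "predicted_total": [11.5, 12.6, 7.7, 9, 10.4, 8.5, 13.8, 6.3, 8.4, 13.1],
}


def load_reference_table(split: str) -> pd.DataFrame:
    """Per-case true/predicted scores for ``split`` in {"train", "test"};
    one case per row (1-based sample numbers as index)."""
    data = {"train": _TRAIN, "test": _TEST}.get(split)
    if data is None:
        raise ValueError(f"split must be 'train' or 'test', got {split!r}")
    df = pd.DataFrame(data)
    df.index = pd.RangeIndex(1, len(df) + 1, name="sample")
    return df


def reference_totals(split: str) -> tuple[np.ndarray, np.ndarray]:
    """(true_totals, predicted_totals) for the chosen split."""
    df = load_reference_table(split)
    return df["true_total"].to_numpy(float), df["predicted_total"].to_numpy(float)
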