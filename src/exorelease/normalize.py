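"""Internal-standard normalization, cube-root transform, and Z-scoring.

Every sample is spiked with internal standards (ITSDs). The ITSD with the
lowest percent CV across all retained samples serves as the reference
feature; each peak area is divided by the reference's peak area in the
same sample (removing per-sample injection/volume scaling) and cube-root
transformed to tame the right skew of peak areas. Z-scoring rows is a
separate step used for Euclidean-distance heat maps.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import InvalidReferenceError, NoValidItsdError
from .io import FeatureTable
from .release import replicate_cv_pct

logger = logging.getLogger(__name__)


def select_reference_itsd(table: FeatureTable, itsd_ids) -> str:
    """Pick the ITSD with the lowest percent CV across all samples.

    Candidates with a zero peak area in any sample are excluded (a zero
    reference would make normalization undefined); ties break to the
    lexicographically smallest feature id.
    """
    candidates = [i for i in itsd_ids if i in table.feature_ids]
    cvs: dict[str, float] = {}
    for fid in candidates:
        vals = table.data.loc[fid].to_numpy(dtype=float)
        if (vals == 0).any():
            continue
        cvs[fid] = replicate_cv_pct(vals)
    if not cvs:
        raise NoValidItsdError("no ITSD candidate is nonzero in every sample")
    best = min(sorted(cvs), key=cvs.get)
    logger.info("reference ITSD: %s (CV %.3f%%)", best, cvs[best])
    return best


def normalize_and_transform(table: FeatureTable, ref_id: str) -> FeatureTable:
    """Divide by the reference ITSD per sample and take the cube root."""
    if ref_id not in table.feature_ids:
        raise InvalidReferenceError(f"reference feature {ref_id!r} not in table")
    ref = table.data.loc[ref_id]
    zero = ref[ref == 0]
    if not zero.empty:
        raise InvalidReferenceError(
            f"reference {ref_id!r} is zero in sample(s) {zero.index.tolist()[:5]}"
        )
    norm = np.cbrt(table.data.div(ref, axis=1))
    return FeatureTable(norm, table.mz, table.rt, table.mode)


def zscore_rows(table: FeatureTable) -> FeatureTable:
    """Per-feature Z-scores (n-1 sd); constant rows map to all zeros."""
    X = table.data
    if X.shape[1] < 2:
        raise ValueError("Z-scoring needs at least two samples")
    mean = X.mean(axis=1)
    sd = X.std(axis=1, ddof=1)
    Z = X.sub(mean, axis=0).div(sd.replace(0, np.nan), axis=0).fillna(0.0)
    return FeatureTable(
        pd.DataFrame(Z, index=X.index, columns=X.columns),
        table.mz, table.rt, table.mode, signed=True,
    )
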