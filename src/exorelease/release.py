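"""Six-criterion classifier for "released" exometabolite features.

A feature counts as released by a strain when, over the sampled time
course, it (i) never peaks in a medium-only external control, (ii) clears
a 3x noise floor over the controls at the last time point, (iii) is
reproducible across replicates (CV < 20% at every time point), (iv) has
its lowest mean abundance at the first, exponential-phase time point,
(v) at least doubles on a log2 scale between the first and last time
points (LFC > 1), and (vi) accumulates roughly linearly with time
(Pearson r >= 0.7). All six criteria are evaluated for every feature —
no short-circuiting — so the per-criterion verdicts are usable as
diagnostics on their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import MissingControlsError, MissingTimepointError
from .io import CONTROL_CLASS, FeatureTable, validate_sample_meta

CRITERIA = ["c1", "c2", "c3", "c4", "c5", "c6"]


@dataclass(frozen=True)
class ReleaseThresholds:
    """Filter thresholds; defaults are the standard stationary-phase values."""

    noise_ratio: float = 3.0     # min(45 h) must reach this multiple of the control max
    cv_max_pct: float = 20.0     # per-time-point replicate CV ceiling, percent
    lfc_min: float = 1.0         # log2(mean last / mean first) must exceed this
    pearson_min: float = 0.7     # abundance-vs-time correlation floor


def c1_control_max(strain_values, control_values) -> bool:
    """Pass iff the global maximum lies strictly in a strain sample.

    A tie between a strain sample and a control sample at the global
    maximum fails (conservative: the control "holds" the max).
    """
    control_values = np.asarray(control_values, dtype=float)
    if control_values.size == 0:
        raise MissingControlsError("criterion i needs at least one control sample")
    strain_values = np.asarray(strain_values, dtype=float)
    return bool(strain_values.max() > control_values.max())


def c2_noise(last_tp_values, control_values, ratio: float = 3.0) -> bool:
    """Pass iff min over last-time-point replicates >= ratio x control max, and > 0."""
    last_tp_values = np.asarray(last_tp_values, dtype=float)
    if last_tp_values.size == 0:
        raise MissingTimepointError("criterion ii needs samples at the last time point")
    control_values = np.asarray(control_values, dtype=float)
    if control_values.size == 0:
        raise MissingControlsError("criterion ii needs at least one control sample")
    m = last_tp_values.min()
    return bool(m > 0 and m >= ratio * control_values.max())


def replicate_cv_pct(values) -> float:
    """Percent CV with the n-1 sample standard deviation; sd == 0 maps to 0."""
    values = np.asarray(values, dtype=float)
    sd = values.std(ddof=1) if values.size > 1 else 0.0
    if sd == 0:
        return 0.0
    mean = values.mean()
    return float(100.0 * sd / mean) if mean != 0 else float("inf")


def c3_cv(values_by_timepoint: dict, cv_max_pct: float = 20.0) -> bool:
    """Pass iff replicate CV < cv_max_pct at every time point with >= 2 replicates."""
    for vals in values_by_timepoint.values():
        vals = np.asarray(vals, dtype=float)
        if vals.size < 2:
            continue  # single-replicate time points carry no spread information
        if not replicate_cv_pct(vals) < cv_max_pct:
            return False
    return True


def c4_min_first(tp_means) -> bool:
    """Pass iff the first time point's mean is a (possibly tied) minimum."""
    tp_means = np.asarray(tp_means, dtype=float)
    return bool((tp_means >= tp_means[0]).all())


def c5_lfc(mean_first: float, mean_last: float, lfc_min: float = 1.0) -> tuple[bool, float]:
    """LFC = log2(mean_last/mean_first); strict > threshold.

    A feature absent at the first time point but present at the last has
    LFC = +inf and passes; absent at both fails (LFC undefined, NaN).
    """
    if mean_first == 0:
        if mean_last > 0:
            return True, float("inf")
        return False, float("nan")
    lfc = float(np.log2(mean_last / mean_first)) if mean_last > 0 else float("-inf")
    return lfc > lfc_min, lfc


def c6_pearson(times_h, values, pearson_min: float = 0.7) -> tuple[bool, float]:
    """Pearson r of abundance against time over replicate-level points.

    Zero variance in abundance (or time) leaves r undefined and fails.
    """
    t = np.asarray(times_h, dtype=float)
    x = np.asarray(values, dtype=float)
    if np.ptp(x) == 0 or np.ptp(t) == 0:
        return False, float("nan")
    r = float(np.corrcoef(t, x)[0, 1])
    return r >= pearson_min, r


@dataclass
class ReleaseReport:
    """Per-feature six-criterion verdicts and statistics for one strain/mode.

    ``frame`` is indexed by feature id with boolean columns c1..c6 and
    ``released`` (their conjunction), plus ``control_max``,
    ``last_tp_min``, ``lfc``, ``pearson_r`` and a ``reason`` column naming
    structural failures (missing controls / time points). ``tp_means`` and
    ``tp_cvs`` are features x time points.
    """

    strain: str
    mode: str
    frame: pd.DataFrame
    tp_means: pd.DataFrame
    tp_cvs: pd.DataFrame
    thresholds: ReleaseThresholds = field(default_factory=ReleaseThresholds)

    @property
    def released_ids(self) -> list[str]:
        return self.frame.index[self.frame["released"]].tolist()


def _row_cv_pct(X: np.ndarray) -> np.ndarray:
    """Row-wise percent CV (ddof=1); sd==0 -> 0; mean==0 with spread -> inf."""
    if X.shape[1] < 2:
        return np.zeros(X.shape[0])
    sd = X.std(axis=1, ddof=1)
    mean = X.mean(axis=1)
    cv = np.zeros(X.shape[0])
    nz = sd > 0
    with np.errstate(divide="ignore"):
        cv[nz] = np.where(mean[nz] != 0, 100.0 * sd[nz] / mean[nz], np.inf)
    return cv


def classify_released(
    table: FeatureTable,
    meta: pd.DataFrame,
    strain: str,
    thresholds: ReleaseThresholds | None = None,
    pearson_on: str = "replicates",
) -> ReleaseReport:
    """Evaluate all six release criteria for every feature of one strain.

    ``pearson_on`` selects the criterion-vi correlation inputs:
    ``"replicates"`` (default) correlates every replicate-level
    (time, abundance) pair; ``"means"`` correlates time-point means.
    Structural problems (no controls, no last-time-point samples) mark the
    affected criteria failed with a reason instead of raising.
    """
    thresholds = thresholds or ReleaseThresholds()
    validate_sample_meta(meta)
    meta = meta[meta["sample_id"].isin(table.sample_ids)]
    if pearson_on not in ("replicates", "means"):
        raise ValueError("pearson_on must be 'replicates' or 'means'")

    strain_meta = meta[meta["class"] == strain].sort_values(["time_h", "replicate"])
    if strain_meta.empty:
        raise ValueError(f"no samples for strain {strain!r}")
    ctrl_ids = meta.loc[meta["class"] == CONTROL_CLASS, "sample_id"].tolist()
    times = np.sort(strain_meta["time_h"].unique())
    tp_cols = {t: strain_meta.loc[strain_meta["time_h"] == t, "sample_id"].tolist() for t in times}

    feats = table.feature_ids
    Xs = table.data[strain_meta["sample_id"].tolist()].to_numpy(dtype=float)
    n = len(feats)

    reason = np.full(n, "", dtype=object)
    means = np.column_stack([table.data[tp_cols[t]].to_numpy().mean(axis=1) for t in times])
    cvs = np.column_stack([_row_cv_pct(table.data[tp_cols[t]].to_numpy(dtype=float)) for t in times])

    strain_max = Xs.max(axis=1)
    if ctrl_ids:
        Xc = table.data[ctrl_ids].to_numpy(dtype=float)
        ctrl_max = Xc.max(axis=1)
        c1 = strain_max > ctrl_max
    else:
        ctrl_max = np.full(n, np.nan)
        c1 = np.zeros(n, dtype=bool)
        reason[:] = "missing_controls"

    last_cols = tp_cols[times[-1]]
    if last_cols:
        last_min = table.data[last_cols].to_numpy(dtype=float).min(axis=1)
    else:  # pragma: no cover - tp_cols keys come from observed times
        last_min = np.full(n, np.nan)
    if ctrl_ids:
        c2 = (last_min > 0) & (last_min >= thresholds.noise_ratio * ctrl_max)
    else:
        c2 = np.zeros(n, dtype=bool)

    multi = np.array([len(tp_cols[t]) >= 2 for t in times])
    c3 = (cvs[:, multi] < thresholds.cv_max_pct).all(axis=1) if multi.any() else np.ones(n, dtype=bool)

    c4 = (means >= means[:, [0]]).all(axis=1)

    m_first, m_last = means[:, 0], means[:, -1]
    lfc = np.full(n, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        ok = (m_first > 0) & (m_last > 0)
        lfc[ok] = np.log2(m_last[ok] / m_first[ok])
        lfc[(m_first == 0) & (m_last > 0)] = np.inf
        lfc[(m_first > 0) & (m_last == 0)] = -np.inf
    c5 = np.where(np.isnan(lfc), False, lfc > thresholds.lfc_min)

    if pearson_on == "replicates":
        t_vec = strain_meta["time_h"].to_numpy(dtype=float)
        Y = Xs
    else:
        t_vec = times.astype(float)
        Y = means
    tc = t_vec - t_vec.mean()
    Yc = Y - Y.mean(axis=1, keepdims=True)
    denom = np.sqrt((Yc**2).sum(axis=1) * (tc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (Yc @ tc) / denom, np.nan)
    c6 = np.where(np.isnan(r), False, r >= thresholds.pearson_min)

    frame = pd.DataFrame(
        {
            "c1": c1, "c2": c2, "c3": c3, "c4": c4, "c5": c5, "c6": c6,
            "released": c1 & c2 & c3 & c4 & c5 & c6,
            "control_max": ctrl_max,
            "last_tp_min": last_min,
            "lfc": lfc,
            "pearson_r": r,
            "reason": reason,
        },
        index=feats,
    )
    tp_means = pd.DataFrame(means, index=feats, columns=times)
    tp_cvs = pd.DataFrame(cvs, index=feats, columns=times)
    return ReleaseReport(strain=strain, mode=table.mode, frame=frame,
                         tp_means=tp_means, tp_cvs=tp_cvs, thresholds=thresholds)
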