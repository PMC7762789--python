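"""Feature-table and metadata I/O, sample accounting, and replicate QC.

The on-disk feature table is the wide, MZmine-style aligned export: one row
per LC-MS feature with ``feature_id``, ``mz`` and ``rt`` columns followed by
one peak-area column per sample. Empty cells mean the feature was not
aligned in that sample and are read as a peak area of 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DuplicateIdError, ParseError, UnknownSampleError

logger = logging.getLogger(__name__)

#: metadata class labels for the non-strain sample types
CONTROL_CLASS = "external_control"
BLANK_CLASS = "extraction_blank"

META_COLUMNS = ["sample_id", "class", "time_h", "replicate", "mode"]


@dataclass
class FeatureTable:
    """Peak areas of LC-MS features across the samples of one mode.

    Parameters
    ----------
    data : DataFrame
        Features in rows (index = feature id), samples in columns;
        nonnegative peak areas.
    mz, rt : Series
        Informational mass-to-charge (Da) and retention time (min) per
        feature, aligned to ``data.index``.
    mode : str
        One of ``polar+``, ``polar-``, ``nonpolar+``, ``nonpolar-``.
    signed : bool
        Set for derived tables (Z-scores) whose values may be negative;
        raw and normalized peak areas must be nonnegative.
    """

    data: pd.DataFrame
    mz: pd.Series = field(default=None)  # type: ignore[assignment]
    rt: pd.Series = field(default=None)  # type: ignore[assignment]
    mode: str = "polar+"
    signed: bool = False

    def __post_init__(self) -> None:
        if self.mz is None:
            self.mz = pd.Series(np.nan, index=self.data.index, name="mz")
        if self.rt is None:
            self.rt = pd.Series(np.nan, index=self.data.index, name="rt")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise DuplicateIdError(f"duplicate feature ids: {dups[:5]}")
        if not self.signed and (self.data.to_numpy() < 0).any():
            raise ValueError("peak areas must be nonnegative")

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    def subset_samples(self, sample_ids) -> "FeatureTable":
        return FeatureTable(self.data[list(sample_ids)], self.mz, self.rt, self.mode, self.signed)

    def equals(self, other: "FeatureTable") -> bool:
        return (
            self.mode == other.mode
            and self.data.equals(other.data)
            and self.mz.equals(other.mz)
            and self.rt.equals(other.rt)
        )


def _sep_for(path: str, dialect: str | None) -> str:
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    if dialect is not None:
        raise ValueError(f"unknown dialect {dialect!r}")
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_feature_table(path, dialect: str | None = None, mode: str = "polar+") -> FeatureTable:
    """Read a wide feature table (feature_id, mz, rt, then sample columns).

    Empty peak-area cells become 0; duplicate feature ids raise
    :class:`DuplicateIdError`; non-numeric peak areas raise
    :class:`ParseError` naming the offending row and column.
    """
    sep = _sep_for(path, dialect)
    raw = pd.read_csv(path, sep=sep, dtype={0: str})
    raw = raw.set_index(raw.columns[0])
    raw.index.name = "feature_id"
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].tolist()
        raise DuplicateIdError(f"duplicate feature ids in {path}: {dups[:5]}")
    mz = pd.to_numeric(raw.pop("mz"), errors="coerce") if "mz" in raw else None
    rt = pd.to_numeric(raw.pop("rt"), errors="coerce") if "rt" in raw else None
    data = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() & raw[col].notna() & (raw[col].astype(str).str.strip() != "")
        if bad.any():
            row = raw.index[bad.argmax()]
            raise ParseError(f"non-numeric peak area at row {row!r}, column {col!r}")
        data[col] = vals.fillna(0.0).astype(float)
    if mz is not None:
        mz = mz.rename("mz")
    if rt is not None:
        rt = rt.rename("rt")
    return FeatureTable(data, mz, rt, mode)


def write_feature_table(table: FeatureTable, path, dialect: str | None = None) -> None:
    """Write a FeatureTable in the wide dialect read by :func:`read_feature_table`."""
    sep = _sep_for(path, dialect)
    out = table.data.copy()
    out.insert(0, "rt", table.rt)
    out.insert(0, "mz", table.mz)
    out.to_csv(path, sep=sep, index=True)


def validate_sample_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Check the sample-metadata contract and return the frame unchanged."""
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"sample metadata missing columns: {missing}")
    if meta["sample_id"].duplicated().any():
        raise DuplicateIdError("duplicate sample ids in metadata")
    key = meta[["class", "time_h", "replicate", "mode"]]
    if key.duplicated().any():
        raise ValueError("(class, time_h, replicate, mode) must be unique")
    return meta


def read_sample_meta(path, dialect: str | None = None) -> pd.DataFrame:
    sep = _sep_for(path, dialect)
    meta = pd.read_csv(path, sep=sep)
    return validate_sample_meta(meta)


def write_sample_meta(meta: pd.DataFrame, path, dialect: str | None = None) -> None:
    meta.to_csv(path, sep=_sep_for(path, dialect), index=False)


@dataclass
class QCReport:
    """Intragroup-reproducibility report.

    ``r`` holds, per sample, the Pearson correlation between the sample's
    feature vector and the mean vector of its co-replicates (NaN when the
    group is a singleton or the correlation is undefined); ``flagged`` marks
    samples with r at or below the threshold.
    """

    r: pd.Series
    flagged: pd.Series
    threshold: float

    @property
    def n_retained(self) -> int:
        return int((~self.flagged).sum())

    @property
    def n_removed(self) -> int:
        return int(self.flagged.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"pearson_r": self.r, "flagged": self.flagged})


def replicate_qc(table: FeatureTable, meta: pd.DataFrame, threshold: float = 0.14) -> QCReport:
    """Flag samples whose profile decorrelates from their replicate group.

    For each sample, r is the Pearson correlation between its feature vector
    and the element-wise mean of the other replicates in its
    (class, time_h, mode) group; a sample is flagged iff r <= threshold.
    Singleton groups are skipped with a warning and never flagged.
    """
    validate_sample_meta(meta)
    meta = meta[meta["sample_id"].isin(table.sample_ids)]
    r = pd.Series(np.nan, index=table.sample_ids, dtype=float)
    for (cls, t, mode), grp in meta.groupby(["class", "time_h", "mode"], dropna=False):
        ids = grp["sample_id"].tolist()
        if len(ids) < 2:
            warnings.warn(
                f"group ({cls}, {t}, {mode}) has a single sample; QC skipped",
                stacklevel=2,
            )
            continue
        sub = table.data[ids].to_numpy()
        for j, sid in enumerate(ids):
            others = np.delete(sub, j, axis=1).mean(axis=1)
            x = sub[:, j]
            if np.ptp(x) == 0 or np.ptp(others) == 0:
                continue  # undefined correlation; leave NaN, never flag
            r[sid] = sps.pearsonr(x, others)[0]
    flagged = r.notna() & (r <= threshold)
    for sid in r.index[flagged]:
        logger.info("replicate_qc: removing %s (r=%.3f <= %.3f)", sid, r[sid], threshold)
    return QCReport(r=r, flagged=flagged, threshold=threshold)


def sample_accounting(
    meta: pd.DataFrame,
    removed_ids=(),
    n_strains: int | None = None,
    n_time_points: int | None = None,
    n_replicates: int | None = None,
    n_modes: int | None = None,
) -> tuple[int, int, int]:
    """Return (designed, retained, removed) sample counts.

    ``designed`` is strains x time points x replicates x modes, inferred
    from the strain samples in the metadata unless the design dimensions
    are given explicitly; ``retained = designed - |removed|``.
    """
    removed_ids = list(removed_ids)
    known = set(meta["sample_id"])
    unknown = [s for s in removed_ids if s not in known]
    if unknown:
        raise UnknownSampleError(f"removed ids not in metadata: {unknown[:5]}")
    strain = meta[~meta["class"].isin([CONTROL_CLASS, BLANK_CLASS])]
    n_strains = n_strains or strain["class"].nunique()
    n_time_points = n_time_points or strain["time_h"].nunique()
    n_replicates = n_replicates or strain["replicate"].nunique()
    n_modes = n_modes or strain["mode"].nunique()
    designed = n_strains * n_time_points * n_replicates * n_modes
    removed = len(set(removed_ids))
    return designed, designed - removed, removed
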