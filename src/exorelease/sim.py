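"""Seeded synthetic data emulating a stationary-phase exometabolomics design.

The generator emits the study design — strains sampled at an
exponential-phase time point (12.5 h) and five stationary-phase time
points (25-45 h) with up to four destructive replicates, medium-only
external controls, extraction blanks, and spiked internal standards —
with known ground truth: planted "released" features following a monotone
doubling trajectory, and one decoy class per release criterion, each
constructed to violate exactly that criterion while satisfying the rest.

One structural caveat: a feature whose global maximum sits in a control
replicate (decoy D1, criterion i) necessarily also fails the 3x noise
floor of criterion ii, because min(45 h) <= control max < 3 x control max.
D1 therefore fails criteria i and ii and passes iii-vi; the other five
decoy classes each fail exactly their own criterion.

Replicate noise is multiplicative lognormal parameterized by its CV, so
peak areas stay nonnegative and the replicate CV target holds across
magnitudes. Transcript-side counts are negative-binomial around planted
per-gene means with a low-expression group sized to the LEM quantile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import InfeasibleConfigError
from .io import BLANK_CLASS, CONTROL_CLASS, META_COLUMNS, FeatureTable

RELEASED = "released"
DECOY_LABELS = {
    "D1": "D1_control_max",
    "D2": "D2_below_noise",
    "D3": "D3_high_cv",
    "D4": "D4_min_not_first",
    "D5": "D5_low_lfc",
    "D6": "D6_low_pearson",
}
ITSD = "itsd"

DEFAULT_STRAINS = ("Bt", "Cv", "Ps")


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic generator.

    Defaults mirror the emulated design: 3 strains x 6 time points
    (12.5, 25, 30, 35, 40, 45 h) x 4 replicates per mode, with medium-only
    controls at every time point, a 5% replicate CV, and internal
    standards at 2% CV.
    """

    n_strains: int = 3
    time_points_h: tuple = (12.5, 25.0, 30.0, 35.0, 40.0, 45.0)
    n_replicates: int = 4
    n_released: int = 50
    decoy_counts: dict = field(
        default_factory=lambda: {k: 10 for k in DECOY_LABELS}
    )
    replicate_cv: float = 0.05
    control_level: float = 1000.0
    itsd_cv: float = 0.02
    n_itsd: int = 3
    n_blanks: int = 2
    n_dropout: int = 0
    mode: str = "polar+"
    seed: int = 0
    # transcript side
    n_genes: int = 1000
    frac_low_genes: float = 0.25
    n_transporters: int = 40
    n_transporters_below_lem: int = 8
    n_de_transporters: int = 12

    def __post_init__(self) -> None:
        t = np.asarray(self.time_points_h, dtype=float)
        if len(t) < 3 or not (np.diff(t) > 0).all():
            raise InfeasibleConfigError("time_points_h must be >=3 strictly increasing hours")
        for name in ("n_strains", "n_replicates", "n_released", "n_itsd",
                     "n_blanks", "n_dropout", "n_genes", "n_transporters",
                     "n_transporters_below_lem", "n_de_transporters"):
            if getattr(self, name) < 0:
                raise InfeasibleConfigError(f"{name} must be >= 0")
        if self.replicate_cv < 0 or self.itsd_cv < 0:
            raise InfeasibleConfigError("CV targets must be >= 0")
        if self.replicate_cv >= 0.2:
            raise InfeasibleConfigError(
                "replicate_cv >= 0.2 makes the D3 decoy (CV criterion) indistinguishable"
            )
        if any(v < 0 for v in self.decoy_counts.values()):
            raise InfeasibleConfigError("decoy counts must be >= 0")
        if self.decoy_counts.get("D3", 0) > 0 and self.n_replicates < 2:
            raise InfeasibleConfigError("D3 needs >=2 replicates to carry replicate spread")
        if self.decoy_counts.get("D4", 0) > 0 and len(t) < 4:
            raise InfeasibleConfigError("D4 needs an interior time point for the dip")
        if self.n_transporters_below_lem + self.n_de_transporters > self.n_transporters:
            raise InfeasibleConfigError("transporter sub-class counts exceed n_transporters")

    @property
    def strains(self) -> list[str]:
        if self.n_strains <= len(DEFAULT_STRAINS):
            return list(DEFAULT_STRAINS[: self.n_strains])
        return [f"S{i + 1}" for i in range(self.n_strains)]


@dataclass
class GroundTruth:
    """Planted labels: feature id -> class, gene id -> class.

    ``feature_strain`` names the strain whose samples carry a feature's
    planted signal (None for internal standards).
    """

    feature_labels: dict = field(default_factory=dict)
    feature_strain: dict = field(default_factory=dict)
    gene_labels: dict = field(default_factory=dict)

    def features_with_label(self, label: str, strain: str | None = None) -> list[str]:
        return [
            f
            for f, lab in self.feature_labels.items()
            if lab == label and (strain is None or self.feature_strain.get(f) == strain)
        ]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"id": f, "label": lab, "strain": self.feature_strain.get(f)}
            for f, lab in self.feature_labels.items()
        ]
        rows += [{"id": g, "label": lab, "strain": None} for g, lab in self.gene_labels.items()]
        return pd.DataFrame(rows, columns=["id", "label", "strain"])


class FeatureSim(NamedTuple):
    table: FeatureTable
    meta: pd.DataFrame
    truth: GroundTruth


class CountSim(NamedTuple):
    counts: pd.DataFrame
    de: pd.DataFrame
    transporter_ids: list
    truth: GroundTruth


def _lognoise(rng: np.random.Generator, mean, cv: float, size=None):
    """Multiplicative lognormal draws with the given mean and CV."""
    mean = np.asarray(mean, dtype=float)
    if cv == 0:
        return np.broadcast_to(mean, size).copy() if size is not None else mean.copy()
    sigma = np.sqrt(np.log1p(cv**2))
    z = rng.normal(-0.5 * sigma**2, sigma, size=size if size is not None else mean.shape)
    return mean * np.exp(z)


def _spread_pattern(n: int) -> np.ndarray:
    """Zero-mean offsets with unit sample sd (ddof=1) for planting a target CV."""
    v = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(n)])
    v -= v.mean()
    return v / v.std(ddof=1)


def _d4_multipliers(T: int) -> np.ndarray:
    """Rising trajectory with the minimum moved to an interior time point."""
    s = np.linspace(0.0, 1.0, T)
    m = 2.0 ** (3.0 * s)  # LFC = 3
    m[min(2, T - 2)] = 0.5
    return m


def _d6_multipliers(T: int) -> np.ndarray:
    """Rise-then-fall trajectory: minimum first, LFC > 1, low time correlation."""
    m = np.empty(T)
    m[0] = 1.0
    decay = np.linspace(0.0, 1.0, T - 1)
    m[1:] = 10.0 * (2.5 / 10.0) ** decay  # ends at 2.5 -> LFC ~ 1.32
    return m


def generate_feature_table(cfg: SimConfig) -> FeatureSim:
    """Generate a feature table with planted released features and decoys.

    Returns the FeatureTable, its sample metadata, and the ground truth.
    Identical (cfg, seed) yields identical output. Released features follow
    mu(t) = a * 2^(k s(t)) with k in [1.5, 3] (so LFC = k > 1, the minimum
    sits at the first time point, and the time correlation is high);
    replicates are lognormal draws at the configured CV; each decoy class
    violates its designated criterion (D1 also fails criterion ii — see
    module docstring).
    """
    rng = np.random.default_rng(cfg.seed)
    t = np.asarray(cfg.time_points_h, dtype=float)
    T = len(t)
    s = (t - t[0]) / (t[-1] - t[0])
    strains = cfg.strains

    sample_ids, meta_rows = [], []
    strain_cols: dict[str, list[int]] = {st: [] for st in strains}
    ctrl_cols: list[int] = []
    col = 0
    for st in strains:
        for ti, tp in enumerate(t):
            for r in range(1, cfg.n_replicates + 1):
                sample_ids.append(f"{st}_t{tp:g}_r{r}")
                meta_rows.append([sample_ids[-1], st, tp, r, cfg.mode])
                strain_cols[st].append(col)
                col += 1
    for tp in t:
        for r in range(1, cfg.n_replicates + 1):
            sample_ids.append(f"CTRL_t{tp:g}_r{r}")
            meta_rows.append([sample_ids[-1], CONTROL_CLASS, tp, r, cfg.mode])
            ctrl_cols.append(col)
            col += 1
    for r in range(1, cfg.n_blanks + 1):
        sample_ids.append(f"BLANK_r{r}")
        meta_rows.append([sample_ids[-1], BLANK_CLASS, np.nan, r, cfg.mode])
        col += 1
    n_samples = col
    meta = pd.DataFrame(meta_rows, columns=META_COLUMNS)

    truth = GroundTruth()
    rows, fids = [], []
    counter = 0

    def new_id(label: str, strain: str | None) -> str:
        nonlocal counter
        counter += 1
        fid = f"F{counter:05d}"
        truth.feature_labels[fid] = label
        truth.feature_strain[fid] = strain
        return fid

    def baseline_row(ctrl_mean: float) -> np.ndarray:
        """Row with every non-target sample near the control level, blanks 0."""
        row = np.zeros(n_samples)
        if ctrl_mean > 0:
            idx = np.arange(n_samples - cfg.n_blanks)
            row[idx] = _lognoise(rng, np.full(len(idx), ctrl_mean), cfg.replicate_cv)
        return row

    def plant(row: np.ndarray, strain: str, tp_means: np.ndarray,
              fixed_tp: int | None = None, fixed_cv: float = 0.0) -> None:
        cols = np.array(strain_cols[strain]).reshape(T, cfg.n_replicates)
        for ti in range(T):
            mu = tp_means[ti]
            if fixed_tp is not None and ti == fixed_tp:
                row[cols[ti]] = mu * (1.0 + fixed_cv * _spread_pattern(cfg.n_replicates))
            else:
                row[cols[ti]] = _lognoise(rng, np.full(cfg.n_replicates, mu), cfg.replicate_cv)

    for st in strains:
        for _ in range(cfg.n_released):
            fid = new_id(RELEASED, st)
            a = float(np.exp(rng.uniform(np.log(5e4), np.log(5e5))))
            k = float(rng.uniform(1.5, 3.0))
            row = baseline_row(cfg.control_level)
            plant(row, st, a * 2.0 ** (k * s))
            rows.append(row)
            fids.append(fid)
        for decoy, label in DECOY_LABELS.items():
            for _ in range(cfg.decoy_counts.get(decoy, 0)):
                fid = new_id(label, st)
                a = float(np.exp(rng.uniform(np.log(5e4), np.log(5e5))))
                k = float(rng.uniform(1.5, 3.0))
                if decoy == "D1":
                    row = baseline_row(cfg.control_level)
                    plant(row, st, a * 2.0 ** (k * s))
                    smax = row[strain_cols[st]].max()
                    row[ctrl_cols[0]] = 1.5 * smax  # control holds the global max
                elif decoy == "D2":
                    c0 = max(cfg.control_level, 500.0)
                    row = np.zeros(n_samples)
                    non_blank = np.arange(n_samples - cfg.n_blanks)
                    row[non_blank] = _lognoise(
                        rng, np.full(len(non_blank), c0), cfg.replicate_cv
                    )
                    a2 = 2.0 * c0 / 2.0**k  # endpoint lands at 2 x control: below 3x floor
                    plant(row, st, a2 * 2.0 ** (k * s))
                elif decoy == "D3":
                    row = baseline_row(cfg.control_level)
                    plant(row, st, a * 2.0 ** (k * s),
                          fixed_tp=min(3, T - 2), fixed_cv=0.4)
                elif decoy == "D4":
                    row = baseline_row(cfg.control_level)
                    plant(row, st, a * _d4_multipliers(T))
                elif decoy == "D5":
                    row = baseline_row(cfg.control_level)
                    plant(row, st, a * 2.0 ** (0.5 * s))  # LFC = 0.5
                else:  # D6
                    row = baseline_row(cfg.control_level)
                    plant(row, st, a * _d6_multipliers(T))
                rows.append(row)
                fids.append(fid)

    for _ in range(cfg.n_itsd):
        fid = new_id(ITSD, None)
        mu = float(np.exp(rng.uniform(np.log(1e5), np.log(1e6))))
        rows.append(_lognoise(rng, np.full(n_samples, mu), cfg.itsd_cv))
        fids.append(fid)

    data = pd.DataFrame(np.array(rows), index=pd.Index(fids, name="feature_id"),
                        columns=sample_ids)
    mz = pd.Series(np.round(rng.uniform(80, 1200, len(fids)), 4), index=data.index, name="mz")
    rt = pd.Series(np.round(rng.uniform(0.5, 20, len(fids)), 3), index=data.index, name="rt")

    if cfg.n_dropout > 0:
        droppable = [
            sid
            for st in strains
            for tp in t
            for sid in meta.loc[
                (meta["class"] == st) & (meta["time_h"] == tp), "sample_id"
            ].iloc[2:]  # always keep two replicates per (strain, time)
        ]
        if cfg.n_dropout > len(droppable):
            raise InfeasibleConfigError("n_dropout would leave a time point with <2 replicates")
        drop = sorted(rng.choice(droppable, size=cfg.n_dropout, replace=False))
        data = data.drop(columns=drop)
        meta = meta[~meta["sample_id"].isin(drop)].reset_index(drop=True)

    table = FeatureTable(data, mz, rt, cfg.mode)
    return FeatureSim(table=table, meta=meta, truth=truth)


def generate_count_table(cfg: SimConfig) -> CountSim:
    """Generate one strain's gene counts, a fabricated DE table, and transporters.

    ~frac_low_genes of genes sit at low expression (below the LEM quantile
    by construction); planted DE transporters carry Q < 0.01 and a
    stationary-phase LFC > 1 in the emitted DE table. Counts are
    negative-binomial around the planted means (exact means at
    replicate_cv = 0).
    """
    rng = np.random.default_rng(cfg.seed + 1)  # independent stream from the feature table
    t = np.asarray(cfg.time_points_h, dtype=float)
    T = len(t)
    s = (t - t[0]) / (t[-1] - t[0])
    n = cfg.n_genes
    n_low = int(round(cfg.frac_low_genes * n))
    if n_low < cfg.n_transporters_below_lem or n - n_low < cfg.n_transporters - cfg.n_transporters_below_lem:
        raise InfeasibleConfigError("transporter counts incompatible with gene-class sizes")

    gene_ids = [f"G{i + 1:05d}" for i in range(n)]
    truth = GroundTruth()

    # class layout: lows first, then highs; transporters drawn from both
    low_ids = gene_ids[:n_low]
    high_ids = gene_ids[n_low:]
    tr_below = low_ids[: cfg.n_transporters_below_lem]
    n_above_tr = cfg.n_transporters - cfg.n_transporters_below_lem
    tr_above = high_ids[:n_above_tr]
    tr_de = tr_above[: cfg.n_de_transporters]
    tr_stable = tr_above[cfg.n_de_transporters:]
    transporter_ids = tr_below + tr_above

    for g in low_ids:
        truth.gene_labels[g] = "below_LEM"
    for g in high_ids:
        truth.gene_labels[g] = "expressed"
    for g in tr_de:
        truth.gene_labels[g] = "DE_transporter"
    for g in tr_stable:
        truth.gene_labels[g] = "stable_transporter"

    base = np.empty(n)
    base[:n_low] = np.exp(rng.uniform(np.log(0.5), np.log(3.0), n_low))
    base[n_low:] = np.exp(rng.uniform(np.log(50.0), np.log(5000.0), n - n_low))

    lfc_true = np.zeros(n)
    de_idx = [gene_ids.index(g) for g in tr_de]
    lfc_true[de_idx] = rng.uniform(1.5, 3.0, len(de_idx))

    sample_ids = [f"t{tp:g}_r{r}" for tp in t for r in range(1, cfg.n_replicates + 1)]
    mu = base[:, None] * 2.0 ** (lfc_true[:, None] * np.repeat(s, cfg.n_replicates)[None, :])
    if cfg.replicate_cv == 0:
        counts = np.rint(mu).astype(int)
    else:
        phi = cfg.replicate_cv**2
        r_nb = 1.0 / phi
        p_nb = r_nb / (r_nb + mu)
        counts = rng.negative_binomial(r_nb, p_nb)
    count_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                            columns=sample_ids)

    stationary = [f"LFC_{tp:g}h" for tp in t[1:]]
    de = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"),
                      columns=["Q"] + stationary, dtype=float)
    de["Q"] = rng.uniform(0.02, 1.0, n)
    for j, cname in enumerate(stationary):
        de[cname] = rng.normal(0.0, 0.3, n)
    de.loc[tr_de, "Q"] = rng.uniform(1e-5, 0.009, len(tr_de))
    de.loc[tr_de, stationary[-1]] = lfc_true[de_idx]
    return CountSim(counts=count_df, de=de, transporter_ids=transporter_ids, truth=truth)
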