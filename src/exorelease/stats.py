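"""Longitudinal multivariate statistics on normalized exometabolite profiles.

Bray-Curtis dissimilarities, principal-coordinate analysis (classical
metric scaling via Gower centering), distance-based multivariate ANOVA
(PERMANOVA) with sequential sums of squares for a strain + time +
strain x time model, a repeated-measures variant with permutations
restricted within replicate time series, pairwise tests with
Benjamini-Hochberg correction, Procrustes/Protest concordance of
ordinations, centroid dissimilarities against a baseline time point or
between successive time points, and per-feature one-way ANOVA with FDR.

PERMANOVA follows the McArdle-Anderson partitioning: with A = -D^2/2 and
G = JAJ the double-centered Gower matrix, the sum of squares captured by
a design matrix X is tr(HG) for the hat matrix H of X, and terms are
added sequentially (Type I) in the order given.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial import procrustes as _scipy_procrustes
from scipy import stats as sps
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .errors import (
    DegenerateConfigurationError,
    DegenerateFactorError,
    EmptyGroupError,
    NegativeAbundanceError,
    UnbalancedSeriesError,
)


# ---------------------------------------------------------------------------
# distances and ordination


def bray_curtis_pair(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y); two all-zero profiles -> 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if (x < 0).any() or (y < 0).any():
        raise NegativeAbundanceError("Bray-Curtis requires nonnegative profiles")
    denom = (x + y).sum()
    if denom == 0:
        return 0.0
    return float(np.abs(x - y).sum() / denom)


def bray_curtis(profiles: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis distance matrix over sample profiles (samples in rows)."""
    X = np.asarray(profiles, dtype=float)
    if (X < 0).any():
        raise NegativeAbundanceError("Bray-Curtis requires nonnegative profiles")
    num = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
    denom = X.sum(axis=1)[:, None] + X.sum(axis=1)[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(D, 0.0)
    ids = list(profiles.index) if isinstance(profiles, pd.DataFrame) else None
    return DistanceMatrix((D + D.T) / 2.0, ids=ids)


def profiles_from_table(table) -> pd.DataFrame:
    """Samples-in-rows profile matrix from a FeatureTable."""
    return table.data.T


def gower_center(D: np.ndarray) -> np.ndarray:
    """Double-centered Gower matrix G = J(-D^2/2)J."""
    A = -0.5 * np.asarray(D, dtype=float) ** 2
    n = A.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    return J @ A @ J


@dataclass
class PCoAResult:
    """Classical-scaling result: signed eigenvalues and positive-axis coordinates."""

    eigenvalues: np.ndarray          # all eigenvalues, descending, sign kept
    coordinates: pd.DataFrame        # samples x positive axes, scaled by sqrt(eigenvalue)
    proportion_explained: np.ndarray  # per positive axis, relative to positive-eigenvalue sum

    @property
    def n_negative(self) -> int:
        return int((self.eigenvalues < 0).sum())


def pcoa(dm: DistanceMatrix, eps: float = 1e-10) -> PCoAResult:
    """Principal-coordinate analysis of a distance matrix.

    Negative eigenvalues (metric distortion) are reported but excluded from
    the coordinates; no Lingoes/Cailliez correction is applied. When the
    distances are of Euclidean origin the coordinates reproduce them.
    """
    D = dm.data if isinstance(dm, DistanceMatrix) else np.asarray(dm, dtype=float)
    ids = list(dm.ids) if isinstance(dm, DistanceMatrix) else list(range(len(D)))
    G = gower_center(D)
    vals, vecs = np.linalg.eigh((G + G.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    scale = max(abs(vals[0]), 1.0) if len(vals) else 1.0
    pos = vals > eps * scale
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    cols = [f"PC{i + 1}" for i in range(pos.sum())]
    prop = vals[pos] / vals[pos].sum() if pos.any() else np.array([])
    return PCoAResult(
        eigenvalues=vals,
        coordinates=pd.DataFrame(coords, index=ids, columns=cols),
        proportion_explained=prop,
    )


# ---------------------------------------------------------------------------
# PERMANOVA


def _dummies(labels: np.ndarray) -> np.ndarray:
    """Full-rank treatment-coded dummy block (drops the first level)."""
    levels = pd.unique(labels)
    return np.column_stack([(labels == lv).astype(float) for lv in levels[1:]])


def _hat(X: np.ndarray) -> np.ndarray:
    """Projection onto the column space of X, robust to rank deficiency."""
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    r = s > s[0] * max(X.shape) * np.finfo(float).eps
    Ur = U[:, r]
    return Ur @ Ur.T


def _design_blocks(factors: pd.DataFrame, terms: list[str]) -> dict[str, np.ndarray]:
    blocks: dict[str, np.ndarray] = {}
    for term in terms:
        if ":" in term:
            a, b = term.split(":")
            la = factors[a].to_numpy().astype(str)
            lb = factors[b].to_numpy().astype(str)
            combo = np.char.add(np.char.add(la, "\x1f"), lb)
            blocks[term] = _dummies(combo)
        else:
            lab = factors[term].to_numpy().astype(str)
            if len(pd.unique(lab)) < 2:
                raise DegenerateFactorError(f"factor {term!r} has fewer than 2 levels")
            blocks[term] = _dummies(lab)
    return blocks


@dataclass
class PermanovaResult:
    """Sequential-SS PERMANOVA table with permutation p-values."""

    table: pd.DataFrame  # index: terms + Residual + Total; columns df, SS, R2, F, p
    n_perm: int
    seed: int | None

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.table.to_string()


def _permanova_fstats(G: np.ndarray, hats: list[np.ndarray], dfs: list[int]) -> tuple[np.ndarray, np.ndarray, float]:
    """Sequential term SS, F statistics and residual SS for one G."""
    total = float(np.trace(G))
    tr = [float(np.trace(H @ G)) for H in hats]
    ss = np.diff([0.0] + tr)
    ss_res = total - tr[-1]
    df_res = G.shape[0] - 1 - sum(dfs)
    with np.errstate(invalid="ignore", divide="ignore"):
        F = (ss / np.asarray(dfs)) / (ss_res / df_res)
    return ss, F, ss_res


def permanova(
    dm: DistanceMatrix,
    factors: pd.DataFrame,
    terms: list[str] | None = None,
    n_perm: int = 999,
    seed: int | None = None,
    permutations: np.ndarray | None = None,
) -> PermanovaResult:
    """Distance-based multivariate ANOVA with sequential (Type I) SS.

    ``factors`` holds one column per factor, rows aligned with ``dm.ids``.
    ``terms`` defaults to main effects in column order plus the two-way
    interaction when exactly two factors are given. p-values use the
    add-one permutation estimator over whole-sample relabelings (or the
    caller-supplied ``permutations`` index array).
    """
    D = dm.data if isinstance(dm, DistanceMatrix) else np.asarray(dm, dtype=float)
    n = D.shape[0]
    if len(factors) != n:
        raise ValueError("factors must have one row per sample")
    if terms is None:
        cols = list(factors.columns)
        terms = list(cols)
        if len(cols) == 2:
            terms.append(f"{cols[0]}:{cols[1]}")
    blocks = _design_blocks(factors, terms)

    G = gower_center(D)
    ones = np.ones((n, 1))
    X = ones
    hats, dfs = [], []
    prev_rank = 1
    for term in terms:
        X = np.hstack([X, blocks[term]])
        H = _hat(X)
        rank = int(round(np.trace(H)))
        dfs.append(rank - prev_rank)
        prev_rank = rank
        hats.append(H)

    ss, F_obs, ss_res = _permanova_fstats(G, hats, dfs)
    total = float(np.trace(G))
    df_res = n - 1 - sum(dfs)

    rng = np.random.default_rng(seed)
    if permutations is None:
        permutations = np.array([rng.permutation(n) for _ in range(n_perm)])
    else:
        permutations = np.asarray(permutations)
    n_perm_used = len(permutations)
    geq = np.zeros(len(terms))
    for p in permutations:
        Gp = G[np.ix_(p, p)]
        _, F_p, _ = _permanova_fstats(Gp, hats, dfs)
        geq += (np.nan_to_num(F_p, nan=-np.inf) >= np.nan_to_num(F_obs, nan=np.inf)) | np.isclose(F_p, F_obs)
    pvals = (geq + 1.0) / (n_perm_used + 1.0)

    rows = {
        t: [dfs[i], ss[i], ss[i] / total if total > 0 else np.nan, F_obs[i], pvals[i]]
        for i, t in enumerate(terms)
    }
    rows["Residual"] = [df_res, ss_res, ss_res / total if total > 0 else np.nan, np.nan, np.nan]
    rows["Total"] = [n - 1, total, 1.0, np.nan, np.nan]
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["df", "SS", "R2", "F", "p"]
    )
    return PermanovaResult(table=table, n_perm=n_perm_used, seed=seed)


def pairwise_permanova(
    dm: DistanceMatrix,
    groups: pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """One-way PERMANOVA for every pair of group levels, BH-adjusted.

    Returns a frame with columns pair, R2, F, p, Q (Benjamini-Hochberg over
    the family of pairs).
    """
    groups = pd.Series(np.asarray(groups), index=list(dm.ids))
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise DegenerateFactorError("pairwise tests need at least two groups")
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in combinations(levels, 2):
        ids = groups.index[groups.isin([a, b])].tolist()
        sub = dm.filter(ids)
        fac = pd.DataFrame({"group": groups.loc[ids].to_numpy()})
        res = permanova(sub, fac, terms=["group"], n_perm=n_perm,
                        seed=int(rng.integers(0, 2**31 - 1)))
        rows.append({
            "pair": f"{a} vs {b}",
            "R2": res.table.loc["group", "R2"],
            "F": res.table.loc["group", "F"],
            "p": res.table.loc["group", "p"],
        })
    out = pd.DataFrame(rows)
    out["Q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def rm_permanova(
    dm: DistanceMatrix,
    series: pd.Series,
    time: pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
    permutations: np.ndarray | None = None,
) -> PermanovaResult:
    """Repeated-measures PERMANOVA: one factor (time), permutations within series.

    Each independently replicated time series must contain every time point
    exactly once; the null distribution shuffles time labels only within
    each series, preserving the repeated-measures structure.
    """
    ids = list(dm.ids)
    series = pd.Series(np.asarray(series), index=ids)
    time = pd.Series(np.asarray(time), index=ids)
    tset = set(time.unique())
    idx_by_series = []
    for s, grp in time.groupby(series):
        if len(grp) != len(tset) or set(grp) != tset:
            raise UnbalancedSeriesError(f"series {s!r} does not cover every time point once")
        idx_by_series.append(np.array([ids.index(i) for i in grp.index]))

    n = len(ids)
    if permutations is None:
        rng = np.random.default_rng(seed)
        perms = []
        for _ in range(n_perm):
            p = np.arange(n)
            for block in idx_by_series:
                p[block] = block[rng.permutation(len(block))]
            perms.append(p)
        permutations = np.array(perms)
    fac = pd.DataFrame({"time": time.to_numpy()})
    return permanova(dm, fac, terms=["time"], seed=seed, permutations=permutations)


# ---------------------------------------------------------------------------
# centroids, Protest, per-feature ANOVA


def group_centroids(profiles: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Arithmetic mean profile per group (rows = groups)."""
    groups = pd.Series(np.asarray(groups), index=profiles.index)
    cents = {}
    for g, idx in profiles.groupby(groups).groups.items():
        if len(idx) == 0:  # pragma: no cover - groupby never yields empty
            raise EmptyGroupError(f"group {g!r} has no samples")
        cents[g] = profiles.loc[idx].mean(axis=0)
    return pd.DataFrame(cents).T


def centroid_dissimilarity(
    profiles: pd.DataFrame, groups: pd.Series, baseline
) -> pd.Series:
    """Bray-Curtis distance from each group centroid to the baseline centroid."""
    cents = group_centroids(profiles, groups)
    if baseline not in cents.index:
        raise EmptyGroupError(f"baseline group {baseline!r} has no samples")
    base = cents.loc[baseline].to_numpy()
    out = {
        g: bray_curtis_pair(cents.loc[g].to_numpy(), base)
        for g in cents.index
        if g != baseline
    }
    return pd.Series(out).sort_index()


def stepwise_centroid_dissimilarity(
    profiles: pd.DataFrame, groups: pd.Series, order=None
) -> pd.Series:
    """Bray-Curtis distance between centroids of consecutive groups.

    ``order`` defaults to the sorted group labels (time points); the result
    is indexed by "a->b" pairs.
    """
    cents = group_centroids(profiles, groups)
    order = sorted(cents.index) if order is None else list(order)
    vals = {}
    for a, b in zip(order[:-1], order[1:]):
        vals[f"{a}->{b}"] = bray_curtis_pair(cents.loc[a].to_numpy(), cents.loc[b].to_numpy())
    return pd.Series(vals)


@dataclass
class ProtestResult:
    """Procrustes concordance of two ordinations with a permutation p-value."""

    m12_squared: float
    correlation: float
    p: float
    n_perm: int
    seed: int | None


def protest(coords_x, coords_y, n_perm: int = 999, seed: int | None = None) -> ProtestResult:
    """Permutation test of Procrustes concordance (vegan-style Protest).

    m12^2 is the residual sum of squares after optimal translation,
    rotation and scaling of the standardized configurations (0 = perfect
    concordance); correlation = sqrt(1 - m12^2). The permutation null
    shuffles the rows of the second configuration.
    """
    X = np.asarray(coords_x, dtype=float)
    Y = np.asarray(coords_y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError("configurations must have matching shape")
    try:
        _, _, m2 = _scipy_procrustes(X, Y)
    except ValueError as exc:
        raise DegenerateConfigurationError(str(exc)) from exc
    rng = np.random.default_rng(seed)
    geq = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(Y))
        try:
            _, _, m2_p = _scipy_procrustes(X, Y[perm])
        except ValueError:  # permuted copy degenerate; count as extreme
            m2_p = 0.0
        if m2_p <= m2 + 1e-12:
            geq += 1
    p = (geq + 1.0) / (n_perm + 1.0)
    m2 = float(min(max(m2, 0.0), 1.0))
    return ProtestResult(
        m12_squared=m2,
        correlation=float(np.sqrt(1.0 - m2)),
        p=float(p),
        n_perm=n_perm,
        seed=seed,
    )


def feature_anova(
    table, meta: pd.DataFrame, strains=None, time_h: float | None = None
) -> pd.DataFrame:
    """One-way ANOVA per feature across strains at one time point, BH-adjusted.

    Defaults to all strain classes at the final time point. Returns a frame
    indexed by feature id with columns F, p, Q.
    """
    from .io import BLANK_CLASS, CONTROL_CLASS

    meta = meta[meta["sample_id"].isin(table.sample_ids)]
    if strains is None:
        strains = [c for c in meta["class"].unique() if c not in (CONTROL_CLASS, BLANK_CLASS)]
    if len(strains) < 2:
        raise DegenerateFactorError("ANOVA needs at least two strains")
    if time_h is None:
        time_h = meta.loc[meta["class"].isin(strains), "time_h"].max()
    groups = []
    for s in strains:
        ids = meta.loc[(meta["class"] == s) & (meta["time_h"] == time_h), "sample_id"]
        if len(ids) < 2:
            raise DegenerateFactorError(f"strain {s!r} has <2 replicates at t={time_h}")
        groups.append(table.data[list(ids)].to_numpy(dtype=float).T)
    with np.errstate(invalid="ignore", divide="ignore"):
        F, p = sps.f_oneway(*groups, axis=0)
    p = np.where(np.isnan(p), 1.0, p)
    Q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"F": np.nan_to_num(F, nan=0.0), "p": p, "Q": Q}, index=table.feature_ids
    )
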