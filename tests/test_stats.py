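import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova
from skbio.stats.ordination import pcoa as skbio_pcoa

from exorelease import (
    DegenerateFactorError,
    FeatureTable,
    NegativeAbundanceError,
    UnbalancedSeriesError,
    bray_curtis,
    bray_curtis_pair,
    centroid_dissimilarity,
    feature_anova,
    pairwise_permanova,
    pcoa,
    permanova,
    protest,
    rm_permanova,
    stepwise_centroid_dissimilarity,
)

# ---------------------------------------------------------------------------
# independent one-way pseudo-F oracle (group-sum formula, no Gower matrices)


def oneway_pseudo_f(D: np.ndarray, labels) -> float:
    labels = np.asarray(labels)
    n = len(labels)
    a = len(set(labels.tolist()))
    ss_total = (D[np.triu_indices(n, 1)] ** 2).sum() / n
    ss_within = 0.0
    for g in set(labels.tolist()):
        idx = np.where(labels == g)[0]
        sub = D[np.ix_(idx, idx)]
        ss_within += (sub[np.triu_indices(len(idx), 1)] ** 2).sum() / len(idx)
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


class TestBrayCurtis:
    def test_identical_profiles_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert bray_curtis_pair(x, x) == 0.0

    def test_disjoint_supports_one(self):
        assert bray_curtis_pair([1, 0, 2], [0, 3, 0]) == 1.0

    def test_worked_example(self):
        assert np.isclose(bray_curtis_pair([1, 2, 0], [0, 2, 2]), 3 / 7)

    def test_all_zero_pair_is_zero_by_convention(self):
        profiles = pd.DataFrame([[0.0, 0.0], [0.0, 0.0], [1.0, 2.0]],
                                index=["a", "b", "c"])
        dm = bray_curtis(profiles)
        assert dm["a", "b"] == 0.0

    def test_negative_input_rejected(self):
        with pytest.raises(NegativeAbundanceError):
            bray_curtis_pair([1, -1], [1, 1])

    def test_matches_skbio_and_bounds(self):
        rng = np.random.default_rng(0)
        profiles = pd.DataFrame(rng.lognormal(0, 1, (10, 30)),
                                index=[f"s{i}" for i in range(10)])
        dm = bray_curtis(profiles)
        oracle = DistanceMatrix.from_iterable(
            profiles.to_numpy(),
            lambda x, y: np.abs(x - y).sum() / (x + y).sum(),
            keys=profiles.index,
        )
        np.testing.assert_allclose(dm.data, oracle.data, atol=1e-12)
        assert (dm.data >= 0).all() and (dm.data <= 1).all()


class TestPCoA:
    def test_collinear_points(self):
        pts = np.array([[0.0], [3.0], [5.0]])
        D = np.abs(pts - pts.T)
        res = pcoa(DistanceMatrix(D, ids=list("abc")))
        pos = res.eigenvalues[res.eigenvalues > 1e-9]
        assert len(pos) == 1
        coords = res.coordinates.to_numpy()
        rec = np.abs(coords - coords.T)
        np.testing.assert_allclose(rec, D, atol=1e-9)

    def test_zero_matrix(self):
        res = pcoa(DistanceMatrix(np.zeros((4, 4))))
        np.testing.assert_allclose(res.eigenvalues, 0.0, atol=1e-12)
        assert res.coordinates.shape[1] == 0

    def test_euclidean_reconstruction(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(8, 3))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = pcoa(DistanceMatrix(D))
        assert res.n_negative == 0 or res.eigenvalues[res.eigenvalues < 0].max() > -1e-9
        C = res.coordinates.to_numpy()
        rec = np.sqrt(((C[:, None] - C[None]) ** 2).sum(-1))
        np.testing.assert_allclose(rec, D, atol=1e-9)

    def test_matches_skbio_eigenvalues(self):
        rng = np.random.default_rng(2)
        profiles = rng.lognormal(0, 1, (9, 20))
        dm = bray_curtis(pd.DataFrame(profiles))
        res = pcoa(dm)
        with np.errstate(all="ignore"):
            oracle = skbio_pcoa(dm, method="eigh")
        k = min(5, res.coordinates.shape[1])
        np.testing.assert_allclose(
            res.eigenvalues[:k], np.asarray(oracle.eigvals)[:k], atol=1e-8
        )
        # coordinates agree up to per-axis sign
        ours = res.coordinates.to_numpy()[:, :k]
        theirs = np.asarray(oracle.samples)[:, :k]
        for j in range(k):
            assert np.allclose(ours[:, j], theirs[:, j], atol=1e-6) or np.allclose(
                ours[:, j], -theirs[:, j], atol=1e-6
            )


def _two_group_dm(rng, sep=4.0, n_per=3):
    pts = np.vstack([rng.normal(0, 1, (n_per, 2)), rng.normal(sep, 1, (n_per, 2))])
    D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    return DistanceMatrix(D, ids=[f"s{i}" for i in range(2 * n_per)])


class TestPermanova:
    def test_exact_enumeration_two_groups_of_three(self):
        """p from all distinct relabelings equals the enumeration value."""
        rng = np.random.default_rng(3)
        dm = _two_group_dm(rng)
        labels = np.array(["A"] * 3 + ["B"] * 3)
        # all 20 distinct assignments of 3 A's among 6 positions
        perms, f_oracle = [], []
        for combo in itertools.combinations(range(6), 3):
            lab = np.array(["B"] * 6)
            lab[list(combo)] = "A"
            f_oracle.append(oneway_pseudo_f(dm.data, lab))
            # index permutation realizing this labeling
            order = [i for i in range(6) if lab[i] == "A"] + [
                i for i in range(6) if lab[i] == "B"
            ]
            perms.append(order)
        f_obs = f_oracle[0]  # identity labeling is the first combination
        p_exact = np.mean([f >= f_obs - 1e-12 for f in f_oracle])
        res = permanova(dm, pd.DataFrame({"group": labels}), terms=["group"],
                        permutations=np.array(perms[1:]))
        assert np.isclose(res.table.loc["group", "F"], f_obs)
        assert np.isclose(res.table.loc["group", "p"], p_exact)

    def test_f_matches_skbio(self):
        rng = np.random.default_rng(4)
        dm = _two_group_dm(rng, sep=2.0, n_per=5)
        labels = ["A"] * 5 + ["B"] * 5
        res = permanova(dm, pd.DataFrame({"group": labels}), terms=["group"],
                        n_perm=99, seed=0)
        oracle = skbio_permanova(dm, grouping=labels, permutations=99)
        assert np.isclose(res.table.loc["group", "F"], oracle["test statistic"])

    def test_null_calibration(self):
        rng = np.random.default_rng(5)
        pvals, r2s = [], []
        for i in range(10):
            pts = rng.normal(size=(12, 3))
            D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            labels = rng.permutation(["A"] * 6 + ["B"] * 6)
            res = permanova(DistanceMatrix(D), pd.DataFrame({"group": labels}),
                            terms=["group"], n_perm=199, seed=i)
            pvals.append(res.table.loc["group", "p"])
            r2s.append(res.table.loc["group", "R2"])
        assert 0.2 < np.mean(pvals) < 0.8
        assert np.mean(r2s) < 0.25

    def test_duplicated_identical_groups_f_near_zero(self):
        base = np.array([[0.0, 1.0], [1.0, 0.0]])
        D = np.kron(np.ones((2, 2)), base)
        np.fill_diagonal(D, 0.0)
        labels = ["A", "A", "B", "B"]
        res = permanova(DistanceMatrix(D), pd.DataFrame({"group": labels}),
                        terms=["group"], n_perm=23, seed=0)
        assert res.table.loc["group", "F"] < 1e-10

    def test_ss_decomposition_exact(self, noisy_sim):
        table, meta, _ = noisy_sim
        strain_meta = meta[~meta["class"].isin(["external_control", "extraction_blank"])]
        profiles = table.data[strain_meta["sample_id"]].T
        dm = bray_curtis(profiles)
        factors = pd.DataFrame({"strain": strain_meta["class"].to_numpy(),
                                "time": strain_meta["time_h"].astype(str).to_numpy()})
        res = permanova(dm, factors, n_perm=29, seed=1)
        tab = res.table
        terms = [t for t in tab.index if t not in ("Residual", "Total")]
        assert np.isclose(tab.loc[terms, "SS"].sum() + tab.loc["Residual", "SS"],
                          tab.loc["Total", "SS"], rtol=1e-10)
        assert set(terms) == {"strain", "time", "strain:time"}
        # 3 strains x 6 time points x 4 replicates: classical ANOVA df
        assert tab.loc["strain", "df"] == 2
        assert tab.loc["time", "df"] == 5
        assert tab.loc["strain:time", "df"] == 10
        assert tab.loc["Residual", "df"] == 72 - 18
        assert ((tab["R2"].dropna() >= -1e-12) & (tab["R2"].dropna() <= 1 + 1e-12)).all()

    def test_order_invariance_of_f(self):
        rng = np.random.default_rng(6)
        dm = _two_group_dm(rng)
        labels = np.array(["A"] * 3 + ["B"] * 3)
        res = permanova(dm, pd.DataFrame({"group": labels}), terms=["group"],
                        n_perm=9, seed=0)
        order = rng.permutation(6)
        dm2 = DistanceMatrix(dm.data[np.ix_(order, order)],
                             ids=[dm.ids[i] for i in order])
        res2 = permanova(dm2, pd.DataFrame({"group": labels[order]}), terms=["group"],
                         n_perm=9, seed=0)
        assert np.isclose(res.table.loc["group", "F"], res2.table.loc["group", "F"])

    def test_constant_factor_rejected(self):
        dm = _two_group_dm(np.random.default_rng(7))
        with pytest.raises(DegenerateFactorError):
            permanova(dm, pd.DataFrame({"group": ["A"] * 6}), terms=["group"])


class TestPairwisePermanova:
    def test_identical_groups_large_q(self):
        base = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.5], [2.0, 1.5, 0.0]])
        D = np.kron(np.ones((3, 3)), base)
        np.fill_diagonal(D, 0.0)
        dm = DistanceMatrix((D + D.T) / 2)
        groups = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        out = pairwise_permanova(dm, pd.Series(groups), n_perm=99, seed=0)
        assert len(out) == 3
        assert (out["Q"] > 0.3).all()

    def test_single_pair_q_equals_p(self):
        dm = _two_group_dm(np.random.default_rng(8))
        out = pairwise_permanova(dm, pd.Series(["A"] * 3 + ["B"] * 3), n_perm=99, seed=0)
        assert len(out) == 1
        assert out.loc[0, "Q"] == out.loc[0, "p"]

    def test_q_dominates_p(self):
        rng = np.random.default_rng(9)
        pts = np.vstack([rng.normal(i * 3, 1, (4, 2)) for i in range(3)])
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        out = pairwise_permanova(DistanceMatrix(D),
                                 pd.Series(np.repeat(list("ABC"), 4)), n_perm=99, seed=1)
        assert (out["Q"] >= out["p"] - 1e-12).all()


class TestRmPermanova:
    def _series_dm(self, trend=1.0, seed=0, n_series=3, n_time=4):
        rng = np.random.default_rng(seed)
        profiles, series, time = [], [], []
        for s in range(n_series):
            for t in range(n_time):
                profiles.append(rng.lognormal(0, 0.1, 20) * (1 + trend * t))
                series.append(f"rep{s}")
                time.append(float(t))
        dm = bray_curtis(pd.DataFrame(profiles, index=[f"s{i}" for i in range(len(profiles))]))
        return dm, pd.Series(series), pd.Series(time)

    def test_exact_enumeration_two_series_two_timepoints(self):
        dm, series, time = self._series_dm(trend=2.0, seed=1, n_series=2, n_time=2)
        # restricted permutations: swap-or-not within each series -> 4 total
        perms = []
        for swap0 in (False, True):
            for swap1 in (False, True):
                p = np.arange(4)
                if swap0:
                    p[[0, 1]] = p[[1, 0]]
                if swap1:
                    p[[2, 3]] = p[[3, 2]]
                perms.append(p)
        f_all = []
        labels = time.to_numpy()
        for p in perms:
            f_all.append(oneway_pseudo_f(dm.data[np.ix_(p, p)], labels))
        p_exact = np.mean([f >= f_all[0] - 1e-12 for f in f_all])
        res = rm_permanova(dm, series, time, permutations=np.array(perms[1:]))
        assert np.isclose(res.table.loc["time", "F"], f_all[0])
        assert np.isclose(res.table.loc["time", "p"], p_exact)

    def test_planted_trend_detected(self):
        dm, series, time = self._series_dm(trend=1.5, seed=2)
        res = rm_permanova(dm, series, time, n_perm=199, seed=0)
        assert res.table.loc["time", "p"] <= 0.05

    def test_null_when_no_trend(self):
        pvals = []
        for i in range(8):
            dm, series, time = self._series_dm(trend=0.0, seed=10 + i)
            res = rm_permanova(dm, series, time, n_perm=99, seed=i)
            pvals.append(res.table.loc["time", "p"])
        assert 0.2 < np.mean(pvals) < 0.95

    def test_unbalanced_series_rejected(self):
        dm, series, time = self._series_dm(n_series=2, n_time=3)
        time.iloc[0] = 99.0
        with pytest.raises(UnbalancedSeriesError):
            rm_permanova(dm, series, time, n_perm=9, seed=0)


class TestCentroids:
    def test_identical_samples_zero_everywhere(self):
        profiles = pd.DataFrame(np.ones((6, 4)), index=[f"s{i}" for i in range(6)])
        groups = pd.Series([1, 1, 2, 2, 3, 3])
        out = centroid_dissimilarity(profiles, groups, baseline=1)
        np.testing.assert_allclose(out, 0.0)

    def test_monotone_trajectories_diverge_from_baseline(self):
        """Exponentially accumulating features: distance to 12.5 h grows with time."""
        from exorelease.sim import SimConfig, generate_feature_table

        cfg = SimConfig(seed=8, replicate_cv=0.0, control_level=0.0, n_released=40,
                        decoy_counts={}, n_itsd=0)
        table, meta, _ = generate_feature_table(cfg)
        bt = meta[meta["class"] == "Bt"]
        profiles = table.data[bt["sample_id"]].T
        groups = pd.Series(bt["time_h"].to_numpy(), index=profiles.index)
        out = centroid_dissimilarity(profiles, groups, baseline=12.5)
        assert (np.diff(out.to_numpy()) > 0).all()

    def test_stepwise_shrinks_on_decelerating_trajectory(self):
        t = np.array([12.5, 25, 30, 35, 40, 45])
        rng = np.random.default_rng(10)
        a = rng.lognormal(0, 1, 30)
        tau = rng.uniform(5, 15, 30)
        profiles = pd.DataFrame(
            [a * (1 - np.exp(-tp / tau)) for tp in t], index=t
        )
        out = stepwise_centroid_dissimilarity(profiles, pd.Series(t, index=t))
        assert (np.diff(out.to_numpy()) < 0).all()


class TestProtest:
    def test_rotated_scaled_copy_perfect(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(8, 2))
        th = 0.9
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        Y = 2.5 * X @ R + 7.0
        res = protest(X, Y, n_perm=199, seed=0)
        assert res.m12_squared < 1e-12
        assert np.isclose(res.correlation, 1.0)
        assert res.p == pytest.approx(1 / 200)

    def test_independent_configurations(self):
        rng = np.random.default_rng(12)
        res = protest(rng.normal(size=(10, 2)), rng.normal(size=(10, 2)),
                      n_perm=199, seed=1)
        assert res.m12_squared > 0.5
        assert res.p > 0.05

    def test_small_case_matches_svd_closed_form(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(3, 2))
        Y = rng.normal(size=(3, 2))

        def standardize(M):
            M = M - M.mean(axis=0)
            return M / np.linalg.norm(M)

        Xs, Ys = standardize(X), standardize(Y)
        m2_closed = 1.0 - np.linalg.svd(Xs.T @ Ys, compute_uv=False).sum() ** 2
        res = protest(X, Y, n_perm=9, seed=0)
        assert np.isclose(res.m12_squared, m2_closed, atol=1e-10)


class TestFeatureAnova:
    def _table_meta(self, groups):
        data = pd.DataFrame({f"s{i}": [v] for i, v in enumerate(np.concatenate(groups))})
        data.index = ["F1"]
        meta = pd.DataFrame({
            "sample_id": data.columns,
            "class": np.repeat([f"S{i}" for i in range(len(groups))],
                               [len(g) for g in groups]),
            "time_h": 45.0,
            "replicate": np.concatenate([np.arange(1, len(g) + 1) for g in groups]),
            "mode": "polar+",
        })
        return FeatureTable(data), meta

    def test_hand_worked_f(self):
        table, meta = self._table_meta([[1, 2, 3], [4, 5, 6]])
        out = feature_anova(table, meta)
        assert np.isclose(out.loc["F1", "F"], 13.5)

    def test_identical_groups_f_zero(self):
        table, meta = self._table_meta([[1, 2, 3], [1, 2, 3]])
        out = feature_anova(table, meta)
        assert out.loc["F1", "F"] == 0.0

    def test_planted_strain_specific_feature_detected(self, noisy_sim):
        table, meta, truth = noisy_sim
        out = feature_anova(table, meta)
        bt_released = truth.features_with_label("released", "Bt")
        # released features are strain-specific at 45 h: strongly significant
        assert (out.loc[bt_released, "Q"] < 0.01).all()
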