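"""Scoring, clustering, apportionment and panel-builder tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from mir3d import (
    DataError,
    dbscan_cluster,
    largest_remainder,
    overlap_3d_panel,
    proportional_representatives,
    random_panel,
    spearman_scores,
    top_k_by_score,
)
from tests.conftest import make_matrix


def dbscan_oracle(coords: np.ndarray, eps: float, min_pts: int) -> list[set]:
    """Textbook DBSCAN: core points by eps-neighbourhood size (point included),
    clusters grown by BFS in index order; noise returned as singletons."""
    n = len(coords)
    d = squareform(pdist(coords))
    neigh = [set(np.flatnonzero(d[i] <= eps)) for i in range(n)]
    core = [len(neigh[i]) >= min_pts for i in range(n)]
    labels = [-1] * n
    cid = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        labels[i] = cid
        queue = [i]
        while queue:
            q = queue.pop(0)
            for nb in sorted(neigh[q]):
                if labels[nb] == -1:
                    labels[nb] = cid
                    if core[nb]:
                        queue.append(nb)
        cid += 1
    clusters = {}
    for i, lab in enumerate(labels):
        if lab == -1:
            clusters[f"noise{i}"] = {i}
        else:
            clusters.setdefault(lab, set()).add(i)
    return list(clusters.values())


def partition_of(clustering, table) -> set:
    pos = {mid: i for i, mid in enumerate(table["mirna_id"])}
    groups = {}
    for mid, cid in clustering.assignments.items():
        groups.setdefault(cid, set()).add(pos[mid])
    return {frozenset(g) for g in groups.values()}


def coords_table(coords):
    return pd.DataFrame(
        {
            "mirna_id": [f"m{i}" for i in range(len(coords))],
            "bin_id": range(len(coords)),
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
        }
    )


class TestSpearman:
    def test_perfect_monotone_attains_extremes(self):
        # with a tied binary label, mid-rank Spearman's maximum is 2/sqrt(5),
        # attained by any strictly monotone signal; reversed signal negates it
        su = spearman_scores(make_matrix([[1, 2, 3, 4]], [0, 0, 1, 1]))
        sd = spearman_scores(make_matrix([[4, 3, 2, 1]], [0, 0, 1, 1]))
        assert su.loc["m0", "rho"] == pytest.approx(2 / np.sqrt(5), abs=1e-12)
        assert sd.loc["m0", "rho"] == pytest.approx(-2 / np.sqrt(5), abs=1e-12)

    def test_tied_signal_matches_rank_pearson_oracle(self):
        m = make_matrix([[1, 1, 2, 2]], [0, 1, 0, 1])
        s = spearman_scores(m)
        assert s.loc["m0", "rho"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_scipy_spearmanr(self):
        rng = np.random.default_rng(0)
        vals = rng.integers(0, 5, size=(20, 12)).astype(float)
        labels = [0, 1] * 6
        m = make_matrix(vals, labels)
        s = spearman_scores(m)
        for i in range(20):
            ref_rho, ref_p = spearmanr(vals[i], labels)
            if np.isnan(ref_rho):
                assert s.iloc[i]["constant"]
                continue
            assert s.iloc[i]["rho"] == pytest.approx(ref_rho, abs=1e-12)
            assert s.iloc[i]["p"] == pytest.approx(ref_p, abs=1e-9)

    def test_constant_row_flagged(self):
        m = make_matrix([[3, 3, 3, 3]], [0, 0, 1, 1])
        s = spearman_scores(m)
        assert s.loc["m0", "rho"] == 0.0
        assert s.loc["m0", "p"] == 1.0
        assert bool(s.loc["m0", "constant"])

    def test_permutation_p_agrees_with_t_for_strong_signal(self):
        rng = np.random.default_rng(1)
        vals = np.vstack([np.r_[rng.lognormal(0, 1, 10), rng.lognormal(4, 1, 10)]])
        labels = [0] * 10 + [1] * 10
        m = make_matrix(vals, labels)
        pt = spearman_scores(m, method="t").loc["m0", "p"]
        pp = spearman_scores(m, method="permutation", n_perm=999, seed=0).loc["m0", "p"]
        assert pt < 0.01 and pp < 0.01


class TestTopK:
    def scores(self, rows):
        return pd.DataFrame(
            rows,
            columns=["rho", "p"],
            index=pd.Index([f"m{i}" for i in range(len(rows))], name="mirna_id"),
        ).assign(abs_rho=lambda d: d.rho.abs())

    def test_k_saturates_at_table_size(self):
        s = self.scores([(0.5, 0.01), (-0.4, 0.02)])
        panel = top_k_by_score(s, k=10)
        assert len(panel) == 2

    def test_orders_by_abs_rho(self):
        s = self.scores([(0.1, 0.01), (-0.9, 0.01)])
        panel = top_k_by_score(s, k=1)
        assert panel.mirna_ids == ["m1"]

    def test_matches_exhaustive_sort_oracle(self):
        rng = np.random.default_rng(3)
        rows = [(float(r), float(p)) for r, p in zip(rng.uniform(-1, 1, 10), rng.uniform(0, 0.1, 10))]
        s = self.scores(rows)
        panel = top_k_by_score(s, k=4, p_max=0.05)
        eligible = [(i, r) for i, (r, p) in enumerate(rows) if p < 0.05]
        expected = [f"m{i}" for i, _ in sorted(eligible, key=lambda t: (-abs(t[1]), f"m{t[0]}"))][:4]
        assert panel.mirna_ids == expected

    def test_empty_when_nothing_significant(self):
        s = self.scores([(0.9, 0.5)])
        assert len(top_k_by_score(s, k=3)) == 0


class TestDbscan:
    def test_pair_plus_singleton(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [10.0, 0, 0]])
        cl = dbscan_cluster(coords_table(coords), eps=3, min_pts=2)
        sizes = sorted(cl.sizes().values())
        assert sizes == [1, 2]
        assert cl.n_singletons == 1 and cl.n_multi == 1

    def test_identical_points_one_cluster(self):
        coords = np.zeros((4, 3))
        cl = dbscan_cluster(coords_table(coords), eps=3, min_pts=2)
        assert len(cl.sizes()) == 1

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(9)
        coords = rng.uniform(0, 10, size=(50, 3))
        table = coords_table(coords)
        cl = dbscan_cluster(table, eps=1.8, min_pts=3)
        mine = partition_of(cl, table)
        oracle = {frozenset(g) for g in dbscan_oracle(coords, 1.8, 3)}
        assert mine == oracle

    def test_partition_invariant_to_row_order_min_pts_2(self):
        rng = np.random.default_rng(10)
        coords = rng.uniform(0, 8, size=(30, 3))
        table = coords_table(coords)
        cl1 = dbscan_cluster(table, eps=2.0, min_pts=2)
        perm = rng.permutation(30)
        cl2 = dbscan_cluster(table.iloc[perm].reset_index(drop=True), eps=2.0, min_pts=2)
        g1 = {frozenset(cl1.members(c)) for c in cl1.cluster_ids}
        g2 = {frozenset(cl2.members(c)) for c in cl2.cluster_ids}
        assert g1 == g2

    def test_rigid_motion_and_scale_invariance(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(12)
        coords = rng.uniform(0, 8, size=(25, 3))
        rot = Rotation.from_rotvec([1.0, 0.2, -0.5]).as_matrix()
        moved = 2.0 * coords @ rot.T + 7.0
        t1, t2 = coords_table(coords), coords_table(moved)
        cl1 = dbscan_cluster(t1, eps=2.0, min_pts=2)
        cl2 = dbscan_cluster(t2, eps=4.0, min_pts=2)  # eps scales with coords
        g1 = {frozenset(cl1.members(c)) for c in cl1.cluster_ids}
        g2 = {frozenset(cl2.members(c)) for c in cl2.cluster_ids}
        assert g1 == g2


def allocation_oracle(sizes: dict, m: int) -> dict:
    """Independent largest-remainder implementation with the same tie rule."""
    total = sum(sizes.values())
    m_eff = min(m, total)
    if total == 0:
        return {c: 0 for c in sizes}
    quotas = {c: m_eff * s / total for c, s in sizes.items()}
    alloc = {c: int(np.floor(q)) for c, q in quotas.items()}
    order = sorted(
        sizes, key=lambda c: (-(quotas[c] - alloc[c]), -sizes[c], str(c))
    )
    left = m_eff - sum(alloc.values())
    for c in order:
        if left <= 0:
            break
        if alloc[c] < sizes[c]:
            alloc[c] += 1
            left -= 1
    return alloc


class TestApportionment:
    def test_exact_proportionality(self):
        assert largest_remainder({"a": 50, "b": 30, "c": 20}, 10) == {
            "a": 5,
            "b": 3,
            "c": 2,
        }

    def test_hand_computed_remainders(self):
        # quotas 2.333, 1.667, 1.0 -> floors (2,1,1), last seat to 0.667
        assert largest_remainder({"a": 7, "b": 5, "c": 3}, 5) == {"a": 2, "b": 2, "c": 1}

    @given(
        st.lists(st.integers(0, 40), min_size=1, max_size=8),
        st.integers(1, 60),
    )
    def test_conservation_cap_and_oracle(self, sizes_list, m):
        sizes = {f"c{i}": s for i, s in enumerate(sizes_list)}
        alloc = largest_remainder(sizes, m)
        assert sum(alloc.values()) == min(m, sum(sizes.values()))
        assert all(alloc[c] <= sizes[c] for c in sizes)
        assert alloc == allocation_oracle(sizes, m)


class TestRepresentatives:
    def clustering_and_scores(self):
        coords = np.vstack(
            [
                np.random.default_rng(0).normal(0, 0.3, size=(6, 3)),
                np.random.default_rng(1).normal(20, 0.3, size=(4, 3)),
            ]
        )
        table = coords_table(coords)
        cl = dbscan_cluster(table, eps=3, min_pts=2)
        rng = np.random.default_rng(2)
        rho = rng.uniform(-1, 1, 10)
        scores = pd.DataFrame(
            {"rho": rho, "abs_rho": np.abs(rho), "p": rng.uniform(0, 0.04, 10)},
            index=pd.Index([f"m{i}" for i in range(10)], name="mirna_id"),
        )
        return cl, scores

    def test_single_cluster_returns_top_members(self):
        coords = np.random.default_rng(5).normal(0, 0.2, size=(5, 3))
        table = coords_table(coords)
        cl = dbscan_cluster(table, eps=3, min_pts=2)
        rho = np.array([0.1, 0.9, -0.95, 0.2, 0.5])
        scores = pd.DataFrame(
            {"rho": rho, "abs_rho": np.abs(rho), "p": np.full(5, 0.001)},
            index=pd.Index([f"m{i}" for i in range(5)], name="mirna_id"),
        )
        panel = proportional_representatives(cl, scores, m=3)
        assert set(panel.mirna_ids) == {"m2", "m1", "m4"}

    def test_allocations_proportional_to_cluster_size(self):
        cl, scores = self.clustering_and_scores()
        panel = proportional_representatives(cl, scores, m=5)
        by_cluster = cl.assignments.loc[panel.mirna_ids].value_counts()
        assert sorted(by_cluster.to_list()) == [2, 3]

    def test_m_exceeding_total_returns_all(self):
        cl, scores = self.clustering_and_scores()
        panel = proportional_representatives(cl, scores, m=50)
        assert len(panel) == 10

    def test_missing_scores_rejected(self):
        cl, scores = self.clustering_and_scores()
        with pytest.raises(DataError):
            proportional_representatives(cl, scores.iloc[:5], m=3)

    def test_significance_prefilter_restricts_universe(self):
        cl, scores = self.clustering_and_scores()
        scores = scores.copy()
        scores.loc[scores.index[:6], "p"] = 0.9  # first cluster all null
        panel = proportional_representatives(cl, scores, m=4, p_max=0.05, p_adjust=None)
        assert set(panel.mirna_ids) <= {f"m{i}" for i in range(6, 10)}


class TestPanels:
    def test_overlap_is_set_intersection(self):
        rng = np.random.default_rng(7)
        mat_ids = [f"m{i}" for i in rng.choice(30, size=15, replace=False)]
        tab_ids = [f"m{i}" for i in rng.choice(30, size=15, replace=False)]
        m = make_matrix(np.ones((15, 4)), [0, 0, 1, 1], mirna_ids=mat_ids)
        table = pd.DataFrame({"mirna_id": tab_ids, "bin_id": 0, "x": 0.0, "y": 0.0, "z": 0.0})
        panel = overlap_3d_panel(m, table)
        assert set(panel.mirna_ids) == set(mat_ids) & set(tab_ids)

    def test_disjoint_sets_empty(self):
        m = make_matrix(np.ones((2, 4)), [0, 0, 1, 1], mirna_ids=["a", "b"])
        table = pd.DataFrame({"mirna_id": ["c"], "bin_id": 0, "x": 0.0, "y": 0.0, "z": 0.0})
        assert len(overlap_3d_panel(m, table)) == 0

    def test_panels_deterministic(self):
        cl_scores = TestRepresentatives().clustering_and_scores()
        p1 = proportional_representatives(*cl_scores, m=5)
        p2 = proportional_representatives(*cl_scores, m=5)
        assert p1.mirna_ids == p2.mirna_ids

    def test_random_panel_seeded(self):
        ids = [f"m{i}" for i in range(30)]
        assert random_panel(ids, 5, seed=3).mirna_ids == random_panel(ids, 5, seed=3).mirna_ids
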