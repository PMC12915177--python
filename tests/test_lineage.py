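"""Cluster MST, root-to-leaf lineages, pseudotime projection and knots."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.stats import spearmanr

from graftmac.containers import CellExperiment, KnotGrid, Lineage, LineageSet
from graftmac.lineage import (
    build_cluster_graph,
    fit_pseudotime,
    infer_lineages,
    place_knots,
)
from graftmac.synthetic import TrajectorySimConfig, simulate_trajectory_dataset


def experiment_from_points(points, clusters):
    points = np.asarray(points, dtype=float)
    n = len(points)
    genes = pd.DataFrame({"symbol": ["g0"], "is_mito": False,
                          "is_ribo": False, "is_noncoding": False},
                         index=pd.Index(["g0"], name="gene_id"))
    cells = pd.DataFrame(
        {
            "sample": "s", "tissue": "biopsy", "outcome": "rejection",
            "cluster": clusters,
            "emb_1": points[:, 0], "emb_2": points[:, 1],
            "donor_sex": "female", "recipient_sex": "male",
        },
        index=pd.Index([f"c{i}" for i in range(n)], name="cell_id"),
    )
    return CellExperiment(sp.csr_matrix(np.ones((1, n), dtype=int)),
                          genes, cells)


def brute_force_mst_weight(centroids):
    """Minimum total weight over all spanning trees (exhaustive)."""
    names = list(centroids.index)
    pts = centroids.to_numpy()
    edges = [
        (i, j, float(np.linalg.norm(pts[i] - pts[j])))
        for i, j in itertools.combinations(range(len(names)), 2)
    ]
    best = np.inf
    n = len(names)
    for combo in itertools.combinations(edges, n - 1):
        parent = list(range(n))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        ok = True
        for i, j, _ in combo:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[ri] = rj
        if ok:
            best = min(best, sum(w for _, _, w in combo))
    return best


def jittered(points, clusters, n_per=4, scale=1e-3, seed=0):
    """Replicate each point a few times so every cluster has >=3 cells."""
    rng = np.random.default_rng(seed)
    pts, labs = [], []
    for p, c in zip(points, clusters):
        for _ in range(n_per):
            pts.append(np.asarray(p) + rng.normal(0, scale, 2))
            labs.append(c)
    return experiment_from_points(pts, labs)


class TestClusterGraph:
    def test_collinear_chain(self):
        exp = jittered([(0, 0), (1, 0), (2, 0)], list("ABC"))
        tree = build_cluster_graph(exp)
        assert sorted(map(tuple, map(sorted, tree.edges))) == \
            [("A", "B"), ("B", "C")]

    def test_star_layout(self):
        pts = [(0, 0), (2, 0), (-2, 0), (0, 2), (0, -2)]
        exp = jittered(pts, ["hub", "e1", "e2", "e3", "e4"])
        tree = build_cluster_graph(exp)
        assert all("hub" in e for e in tree.edges)

    def test_two_clusters_single_edge(self):
        exp = jittered([(0, 0), (3, 1)], ["A", "B"])
        tree = build_cluster_graph(exp)
        assert len(tree.edges) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_mst(self, seed):
        rng = np.random.default_rng(seed)
        n_clusters = 6
        pts = rng.uniform(-5, 5, size=(n_clusters, 2))
        exp = jittered(pts, [f"k{i}" for i in range(n_clusters)], seed=seed)
        tree = build_cluster_graph(exp)
        got = sum(d["weight"] for _, _, d in tree.edges(data=True))
        from graftmac.lineage import cluster_centroids
        want = brute_force_mst_weight(cluster_centroids(exp))
        assert got == pytest.approx(want, rel=1e-9)

    def test_small_cluster_rejected(self):
        exp = experiment_from_points([(0, 0), (0.1, 0), (1, 1), (1, 1.1),
                                      (1.1, 1)], ["A", "A", "B", "B", "B"])
        with pytest.raises(ValueError, match="fewer than 3"):
            build_cluster_graph(exp)


class TestInferLineages:
    def test_path_graph_single_lineage(self):
        exp = jittered([(0, 0), (1, 0), (2, 0)], list("ABC"))
        lineages = infer_lineages(build_cluster_graph(exp), "A")
        assert [l.clusters for l in lineages.lineages] == [["A", "B", "C"]]

    def test_root_with_three_branches(self):
        pts = [(0, 0), (2, 0), (-2, 0), (0, 2)]
        exp = jittered(pts, ["root", "b1", "b2", "b3"])
        lineages = infer_lineages(build_cluster_graph(exp), "root")
        assert len(lineages.lineages) == 3
        assert all(l.clusters[0] == "root" for l in lineages.lineages)
        # deterministic lexicographic order by terminal cluster
        assert [l.clusters[-1] for l in lineages.lineages] == ["b1", "b2", "b3"]

    def test_synthetic_topology_recovered(self, chain_small):
        truth, lineages = chain_small["truth"], chain_small["lineages"]
        true_names = sorted(truth.lineage.unique())
        assert len(lineages.lineages) == len(true_names)
        for lin, true_name in zip(lineages.lineages, true_names):
            assert lin.clusters[-1] == f"{true_name}_bin3"
            assert all(c.startswith(("root", true_name)) for c in lin.clusters)

    def test_six_lineage_paths_are_root_to_leaf(self):
        exp, truth = simulate_trajectory_dataset(TrajectorySimConfig(
            n_lineages=6, cells_per_lineage=250, n_genes=60,
            n_planted_markers=0, seed=12))
        lineages = infer_lineages(build_cluster_graph(exp), "root_1")
        assert len(lineages.lineages) == 6
        terminals = {l.clusters[-1] for l in lineages.lineages}
        assert terminals == {f"lineage_{i}_bin3" for i in range(1, 7)}
        assert all(l.clusters[0] == "root_1" for l in lineages.lineages)


class TestPseudotime:
    def straight_two_cluster(self):
        rng = np.random.default_rng(0)
        xs = np.concatenate([rng.uniform(0, 0.5, 20), rng.uniform(4.5, 5, 20)])
        pts = np.column_stack([xs, np.zeros_like(xs)])
        labels = ["A"] * 20 + ["B"] * 20
        return experiment_from_points(pts, labels)

    def test_straight_curve_pseudotime_is_distance_from_root(self):
        exp = self.straight_two_cluster()
        lineages = infer_lineages(build_cluster_graph(exp), "A")
        fitted = fit_pseudotime(exp, lineages)
        root = exp.cells[exp.cells["cluster"] == "A"][["emb_1", "emb_2"]].mean()
        term = exp.cells[exp.cells["cluster"] == "B"][["emb_1", "emb_2"]].mean()
        name = fitted.names[0]
        # cells between the two centroids: arc length == euclidean distance
        mid = (exp.cells["emb_1"] > root["emb_1"]) & \
            (exp.cells["emb_1"] < term["emb_1"])
        expect = exp.cells.loc[mid, "emb_1"] - root["emb_1"]
        got = fitted.pseudotime.loc[mid, name]
        assert np.allclose(got, expect, atol=1e-9)

    def test_equidistant_cell_gets_half_weights(self):
        pts = [(0, 0)] * 4 + [(2, 1)] * 4 + [(2, -1)] * 4 + [(2, 0)]
        labels = ["root"] * 4 + ["up"] * 4 + ["down"] * 4 + ["root"]
        exp = experiment_from_points(pts, labels)
        lineages = infer_lineages(build_cluster_graph(exp), "root")
        fitted = fit_pseudotime(exp, lineages)
        w = fitted.weights.iloc[-1]  # the (2, 0) cell
        assert np.allclose(w, [0.5, 0.5], atol=1e-12)

    def test_weights_sum_to_one(self, chain_small):
        w = chain_small["lineages"].weights.to_numpy()
        assert np.allclose(w.sum(axis=1), 1.0, atol=1e-12)

    def test_rigid_transform_invariance(self, traj_small):
        exp, _ = traj_small
        lineages = infer_lineages(build_cluster_graph(exp), "root_1")
        base = fit_pseudotime(exp, lineages)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = exp.copy()
        xy = moved.cells[["emb_1", "emb_2"]].to_numpy() @ rot.T + [3.0, -2.0]
        moved.cells[["emb_1", "emb_2"]] = xy
        lineages2 = infer_lineages(build_cluster_graph(moved), "root_1")
        out = fit_pseudotime(moved, lineages2)
        assert np.allclose(out.pseudotime.to_numpy(),
                           base.pseudotime.to_numpy(), atol=1e-8)

    def test_recovers_true_ordering(self, chain_small):
        lineages, truth = chain_small["lineages"], chain_small["truth"]
        for name in lineages.names:
            on = (lineages.assignment == name).to_numpy()
            rho = spearmanr(lineages.pseudotime.loc[on, name],
                            truth.pseudotime[on])[0]
            assert abs(rho) >= 0.95, (name, rho)


class TestKnots:
    def make_lineage_set(self, pooled):
        n = len(pooled)
        idx = pd.Index([f"c{i}" for i in range(n)], name="cell_id")
        pt = pd.DataFrame({"lin": pooled}, index=idx)
        w = pd.DataFrame({"lin": 1.0}, index=idx)
        assign = pd.Series("lin", index=idx)
        return LineageSet(
            lineages=[Lineage("lin", ["a", "b"], np.zeros((2, 2)))],
            pseudotime=pt, weights=w, assignment=assign)

    def test_uniform_quantiles(self):
        ls = self.make_lineage_set(np.linspace(0, 1, 10001))
        grid = place_knots(ls, k=5)
        assert np.allclose(grid.positions, [0, 0.25, 0.5, 0.75, 1], atol=1e-3)
        assert grid.knot(1) == 0.0 and grid.knot(5) == pytest.approx(1.0)

    def test_two_knots_min_max(self):
        ls = self.make_lineage_set(np.array([0.2, 0.5, 0.9, 1.7]))
        grid = place_knots(ls, k=2)
        assert np.allclose(grid.positions, [0.2, 1.7])

    def test_short_lineage_rejected(self):
        pooled = np.concatenate([np.linspace(0, 1, 50), np.linspace(0, 9, 50)])
        idx = pd.Index([f"c{i}" for i in range(100)], name="cell_id")
        pt = pd.DataFrame({"short": pooled, "long": pooled}, index=idx)
        w = pd.DataFrame({"short": 0.5, "long": 0.5}, index=idx)
        assign = pd.Series(["short"] * 50 + ["long"] * 50, index=idx)
        ls = LineageSet(
            lineages=[Lineage("short", [], np.zeros((2, 2))),
                      Lineage("long", [], np.zeros((2, 2)))],
            pseudotime=pt, weights=w, assignment=assign)
        with pytest.raises(ValueError, match="too short"):
            place_knots(ls, k=5)

    def test_knot_grid_contract(self):
        with pytest.raises(ValueError):
            KnotGrid([0.0, 0.0, 1.0])
        grid = KnotGrid([0.0, 1.0, 2.0])
        with pytest.raises(IndexError):
            grid.knot(4)
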