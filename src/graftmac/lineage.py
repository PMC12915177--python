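"""Cluster-graph lineages and per-cell pseudotime (simplified slingshot).

The trajectory model follows the cluster-MST-plus-curves recipe: a minimum
spanning tree over cluster centroids in the 2-D embedding defines the
topology, each root-to-leaf path becomes a lineage, and each lineage gets a
piecewise-linear curve through its ordered centroids.  Cells are projected
onto every curve; pseudotime is the arc length from the root centroid to the
projection, and per-cell lineage weights are a softmax of negative squared
projection distances.  This substitutes simultaneous principal curves with a
piecewise-linear analogue that preserves root semantics and topology; the
curve can optionally be refined by recomputing control points as weighted
cell means along arc-length bins.

Knots for the downstream spline smoothers are placed at evenly spaced
quantiles of pooled pseudotime (pooled over each cell's argmax-weight
lineage), shared by all lineages.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd

from .containers import CellExperiment, KnotGrid, Lineage, LineageSet


def cluster_centroids(experiment: CellExperiment) -> pd.DataFrame:
    """Embedding centroid per cluster; clusters with <3 cells are rejected."""
    emb = experiment.cells[["emb_1", "emb_2"]]
    sizes = experiment.cells.groupby("cluster").size()
    small = sizes[sizes < 3]
    if len(small):
        raise ValueError(
            f"clusters with fewer than 3 cells have unstable centroids: "
            f"{sorted(small.index)}"
        )
    return emb.groupby(experiment.cells["cluster"]).mean()


def build_cluster_graph(experiment: CellExperiment) -> nx.Graph:
    """Euclidean minimum spanning tree over cluster centroids."""
    centroids = cluster_centroids(experiment)
    if len(centroids) < 2:
        raise ValueError("need at least 2 clusters to build a trajectory graph")
    g = nx.Graph()
    names = list(centroids.index)
    pts = centroids.to_numpy()
    for name, p in zip(names, pts):
        g.add_node(name, centroid=p)
    for (i, a), (j, b) in itertools.combinations(enumerate(names), 2):
        g.add_edge(a, b, weight=float(np.linalg.norm(pts[i] - pts[j])))
    return nx.minimum_spanning_tree(g, weight="weight")


def infer_lineages(tree: nx.Graph, root_cluster: str) -> LineageSet:
    """One lineage per leaf: the root-to-leaf cluster path through the tree.

    Lineages are ordered lexicographically by terminal cluster name so that
    downstream hard assignments are deterministic.
    """
    if root_cluster not in tree:
        raise ValueError(f"root cluster {root_cluster!r} is not in the tree")
    leaves = sorted(
        n for n in tree.nodes
        if n != root_cluster and tree.degree[n] == 1
    )
    if not leaves:  # a single node, or the root is the only leaf
        leaves = [n for n in tree.nodes if n != root_cluster] or [root_cluster]
    lineages = []
    for leaf in leaves:
        path = nx.shortest_path(tree, root_cluster, leaf)
        points = np.vstack([tree.nodes[c]["centroid"] for c in path])
        lineages.append(Lineage(name=f"to_{leaf}", clusters=path,
                                control_points=points))
    return LineageSet(lineages=lineages)


def _project_polyline(points: np.ndarray, curve: np.ndarray):
    """Project points onto a piecewise-linear curve.

    Returns (arc_length, squared_distance) of the closest point on the curve
    for every input point.
    """
    seg_start = curve[:-1]
    seg_vec = curve[1:] - curve[:-1]
    seg_len = np.linalg.norm(seg_vec, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])

    diff = points[:, None, :] - seg_start[None, :, :]          # n x s x 2
    denom = np.maximum(np.einsum("sd,sd->s", seg_vec, seg_vec), 1e-300)
    tproj = np.clip(np.einsum("nsd,sd->ns", diff, seg_vec) / denom, 0.0, 1.0)
    closest = seg_start[None, :, :] + tproj[:, :, None] * seg_vec[None, :, :]
    d2 = ((points[:, None, :] - closest) ** 2).sum(axis=2)
    best = np.argmin(d2, axis=1)
    idx = np.arange(points.shape[0])
    arc = cum[best] + tproj[idx, best] * seg_len[best]
    return arc, d2[idx, best]


def fit_pseudotime(
    experiment: CellExperiment,
    lineages: LineageSet,
    n_iter: int = 0,
    tol: float = 1e-3,
    refine_bins: int = 20,
) -> LineageSet:
    """Project cells onto each lineage curve; fill pseudotime and weights.

    Weights per cell are ``softmax(-d^2)`` across lineages (squared embedding
    distance to the curve), so a cell equidistant from two curves weighs them
    0.5/0.5, and weight rows always sum to 1.  With ``n_iter > 0`` the curve
    control points are refined as weight-weighted cell means within
    arc-length bins until the largest control-point shift drops below
    ``tol``; non-convergence returns the best iterate with
    ``converged=False`` rather than raising.
    """
    pts = experiment.cells[["emb_1", "emb_2"]].to_numpy()
    fitted = [Lineage(l.name, list(l.clusters), l.control_points.copy())
              for l in lineages.lineages]

    def project_all():
        arc = np.empty((pts.shape[0], len(fitted)))
        d2 = np.empty_like(arc)
        for j, lin in enumerate(fitted):
            arc[:, j], d2[:, j] = _project_polyline(pts, lin.control_points)
        logits = -d2
        logits -= logits.max(axis=1, keepdims=True)
        w = np.exp(logits)
        w /= w.sum(axis=1, keepdims=True)
        return arc, w

    converged = n_iter <= 0
    for _ in range(max(n_iter, 0)):
        arc, w = project_all()
        max_shift = 0.0
        for j, lin in enumerate(fitted):
            length = arc[:, j].max()
            edges = np.linspace(0.0, length, refine_bins + 1)
            new_pts = [lin.control_points[0]]
            for b in range(refine_bins):
                in_bin = (arc[:, j] >= edges[b]) & (arc[:, j] < edges[b + 1])
                ww = w[in_bin, j]
                if ww.sum() < 1e-9:
                    continue
                new_pts.append((pts[in_bin] * ww[:, None]).sum(0) / ww.sum())
            new_pts.append(lin.control_points[-1])
            new_curve = np.vstack(new_pts)
            if new_curve.shape == lin.control_points.shape:
                shift = float(np.abs(new_curve - lin.control_points).max())
            else:
                shift = np.inf
            max_shift = max(max_shift, shift)
            lin.control_points = new_curve
        if max_shift < tol:
            converged = True
            break
    arc, w = project_all()

    names = [l.name for l in fitted]
    pseudotime = pd.DataFrame(arc, index=experiment.cells.index, columns=names)
    weights = pd.DataFrame(w, index=experiment.cells.index, columns=names)
    # hard assignment: argmax weight, exact ties -> lexicographically first name
    order = np.argsort(names)
    sorted_names = [names[i] for i in order]
    w_sorted = weights[sorted_names].to_numpy()
    assignment = pd.Series(
        [sorted_names[i] for i in w_sorted.argmax(axis=1)],
        index=experiment.cells.index,
        name="lineage",
    )
    return LineageSet(
        lineages=fitted,
        pseudotime=pseudotime,
        weights=weights,
        assignment=assignment,
        converged=converged,
    )


def place_knots(lineages: LineageSet, k: int = 5) -> KnotGrid:
    """Knots at evenly spaced quantiles {0, 1/(K-1), ..., 1} of pooled pseudotime.

    Pseudotime is pooled over each cell's hard-assigned lineage so every
    region of the trajectory, including the shared root, contributes.  Every
    lineage must extend beyond knot K-1, otherwise the knot-(K-2)..(K-1)
    test window would be undefined for it.
    """
    if lineages.pseudotime is None or lineages.assignment is None:
        raise ValueError("fit_pseudotime must run before placing knots")
    if k < 2:
        raise ValueError("need at least 2 knots")
    pooled = np.array([
        lineages.pseudotime.at[cell, lin]
        for cell, lin in lineages.assignment.items()
    ])
    qs = np.linspace(0.0, 1.0, k)
    positions = np.quantile(pooled, qs)
    positions = np.maximum.accumulate(positions)
    if not np.all(np.diff(positions) > 0):
        raise ValueError("degenerate pseudotime distribution: tied knots")
    grid = KnotGrid(positions)
    for lin in lineages.names:
        on = lineages.assignment == lin
        lin_max = lineages.pseudotime.loc[on, lin].max()
        if lin_max < grid.knot(k - 1):
            raise ValueError(
                f"lineage {lin!r} ends at pseudotime {lin_max:.3g}, before "
                f"knot {k - 1} ({grid.knot(k - 1):.3g}); too short to test"
            )
    return grid
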