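"""Shared fixtures: synthetic datasets and fitted trajectory chains.

The heavy study-scale objects (3 lineages x 1,000 cells, 1,500 genes) are
session-scoped so the parameter-recovery tests and the acceptance tests
share one simulation and one round of NB smoother fitting.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from graftmac import lineage as lineage_mod
from graftmac import markers as markers_mod
from graftmac import preprocess, trajde
from graftmac.synthetic import (
    TrajectorySimConfig,
    simulate_celltype_experiment,
    simulate_trajectory_dataset,
)

warnings.filterwarnings("ignore", category=FutureWarning)


def run_trajectory_chain(experiment, n_knots: int = 5):
    """Gene filter -> cluster MST -> lineages -> pseudotime -> knots -> NB fits."""
    filtered, _ = preprocess.filter_genes_for_de(experiment)
    tree = lineage_mod.build_cluster_graph(filtered)
    paths = lineage_mod.infer_lineages(tree, "root_1")
    lineages = lineage_mod.fit_pseudotime(filtered, paths)
    knots = lineage_mod.place_knots(lineages, k=n_knots)
    fits = trajde.fit_nb_smoothers(filtered, lineages, knots)
    return {
        "experiment": filtered,
        "tree": tree,
        "lineages": lineages,
        "knots": knots,
        "fits": fits,
    }


def focal_lineage_name(lineages, truth) -> str:
    focal = truth.details["focal_lineage"]
    return next(n for n in lineages.names if f"{focal}_bin" in n)


@pytest.fixture(scope="session")
def traj_small():
    cfg = TrajectorySimConfig(
        cells_per_lineage=300, n_genes=200, n_planted_markers=10, seed=3
    )
    return simulate_trajectory_dataset(cfg)


@pytest.fixture(scope="session")
def chain_small(traj_small):
    experiment, truth = traj_small
    chain = run_trajectory_chain(experiment)
    chain["truth"] = truth
    chain["focal"] = focal_lineage_name(chain["lineages"], truth)
    return chain


@pytest.fixture(scope="session")
def traj_full():
    """The study-scale dataset: 3 lineages, 3,000 cells, 1,500 genes,
    25 planted knot-3..4 markers at log2FC 2."""
    return simulate_trajectory_dataset(TrajectorySimConfig(seed=101))


@pytest.fixture(scope="session")
def chain_full(traj_full):
    experiment, truth = traj_full
    chain = run_trajectory_chain(experiment)
    chain["truth"] = truth
    focal = focal_lineage_name(chain["lineages"], truth)
    chain["focal"] = focal
    chain["de"] = {
        other: trajde.early_de_test(chain["fits"], (other, focal))
        for other in chain["lineages"].names if other != focal
    }
    return chain


@pytest.fixture(scope="session")
def marker_selection_full(chain_full):
    """Rank-score -> top decile -> intersection on the study-scale chain."""
    rank_cfg = markers_mod.RankConfig(tie_seed=7)
    sets, labels = [], []
    for other, de in sorted(chain_full["de"].items()):
        scored = markers_mod.rank_score(de, rank_cfg)
        chosen, _ = markers_mod.top_quantile(scored, 0.9)
        sets.append(chosen)
        labels.append(other)
    core, venn = markers_mod.intersect_comparisons(sets, labels)
    return {"sets": sets, "labels": labels, "core": core, "venn": venn}


@pytest.fixture(scope="session")
def null_chain():
    """Study-scale dataset with no planted effect (delta = 0), 1,000 genes."""
    experiment, truth = simulate_trajectory_dataset(TrajectorySimConfig(
        n_genes=1000, n_planted_markers=0, planted_log2fc=0.0, seed=202,
    ))
    chain = run_trajectory_chain(experiment)
    chain["truth"] = truth
    focal = focal_lineage_name(chain["lineages"], truth)
    chain["focal"] = focal
    chain["p_values"] = np.concatenate([
        trajde.early_de_test(chain["fits"], (other, focal))["p"].to_numpy()
        for other in chain["lineages"].names if other != focal
    ])
    return chain


@pytest.fixture(scope="session")
def celltype_data():
    return simulate_celltype_experiment(seed=4)
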