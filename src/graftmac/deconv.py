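"""Signature-matrix construction and pseudobulk deconvolution benchmarking.

The benchmarking protocol: split cells into a small stratified training set
(default 5% per cell type, preserving composition), build a CPM-scale
signature matrix from the training cells, average the remaining validation
cells per type and combine those profiles into pseudobulk mixtures with
known random proportions, deconvolve the mixtures, and score per-type
Pearson correlations between estimated and true fractions.

The fraction solver is non-negative least squares with sum-to-one
renormalization, a standard open solver for linear deconvolution; it is
labeled as such in all outputs.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .containers import CellExperiment, MixtureSet, SignatureMatrix
from .preprocess import cpm_normalize


def split_train_validation(
    experiment: CellExperiment,
    train_frac: float = 0.05,
    seed: int = 0,
    type_column: str = "cluster",
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/validation split of cell indices per cell type.

    Each type contributes ``ceil(train_frac * n_type)`` training cells, so
    rare types are always represented; the union of the two index arrays is
    all cells and their intersection is empty.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    types = experiment.cells[type_column].to_numpy()
    train_idx: list[int] = []
    for t in sorted(pd.unique(types)):
        members = np.flatnonzero(types == t)
        n_train = min(math.ceil(train_frac * members.size), members.size)
        train_idx.extend(rng.choice(members, size=n_train, replace=False))
    train = np.sort(np.array(train_idx, dtype=int))
    validation = np.setdiff1d(np.arange(experiment.n_cells), train)
    return train, validation


def build_signature(
    experiment: CellExperiment,
    train_cells: np.ndarray,
    min_expression: float = 0.25,
    top_k_markers: int = 50,
    type_column: str = "cluster",
) -> SignatureMatrix:
    """Build a CPM-scale genes x cell-types signature from training cells.

    Candidate markers for a type are genes whose top-expressing type is that
    type with mean CPM >= ``min_expression``; per type the ``top_k_markers``
    genes with the largest fold change of the top type over the second
    highest type are kept, and the signature is the per-type mean CPM
    profile restricted to the union of markers.
    """
    sub = experiment.subset_cells(np.asarray(train_cells))
    cpm, _ = cpm_normalize(sub.counts)
    types = sorted(pd.unique(sub.cells[type_column]))
    profiles = np.column_stack([
        cpm[:, (sub.cells[type_column] == t).to_numpy()].mean(axis=1)
        for t in types
    ])
    order = np.argsort(profiles, axis=1)
    top_type = order[:, -1]
    top_val = profiles[np.arange(profiles.shape[0]), order[:, -1]]
    second_val = profiles[np.arange(profiles.shape[0]), order[:, -2]]
    fold = top_val / np.maximum(second_val, 1e-9)

    markers: dict[str, list[str]] = {}
    for j, t in enumerate(types):
        cand = np.flatnonzero((top_type == j) & (top_val >= min_expression))
        if cand.size == 0:
            raise ValueError(
                f"cell type {t!r} has no candidate marker gene at "
                f"min_expression={min_expression}"
            )
        chosen = cand[np.argsort(fold[cand])[::-1][:top_k_markers]]
        markers[t] = list(sub.gene_ids[np.sort(chosen)])
    union = sorted(set().union(*markers.values()))
    rows = sub.gene_ids.get_indexer(union)
    sig = pd.DataFrame(profiles[rows], index=pd.Index(union, name="gene_id"),
                       columns=types)
    cond = float(np.linalg.cond(sig.to_numpy()))
    return SignatureMatrix(profiles=sig, markers=markers, condition_number=cond)


def make_mixtures(
    experiment: CellExperiment,
    validation_cells: np.ndarray,
    m: int = 100,
    seed: int = 0,
    type_column: str = "cluster",
    dirichlet_alpha: float = 1.0,
    nb_dispersion: float = 0.0,
    depth: float = 1e6,
    proportions: np.ndarray | None = None,
) -> MixtureSet:
    """Pseudobulk mixtures of per-type mean validation profiles.

    Proportions are drawn from a flat simplex distribution (symmetric
    Dirichlet, configurable alpha) unless an explicit ``proportions`` array
    (M x types, rows summing to 1) is supplied.  With ``nb_dispersion=0``
    mixtures are exact weighted sums of the type profiles; a positive
    dispersion adds NB measurement noise at the stated sequencing depth.
    """
    rng = np.random.default_rng(seed)
    sub = experiment.subset_cells(np.asarray(validation_cells))
    cpm, _ = cpm_normalize(sub.counts)
    types = sorted(pd.unique(sub.cells[type_column]))
    profiles = np.column_stack([
        cpm[:, (sub.cells[type_column] == t).to_numpy()].mean(axis=1)
        for t in types
    ])
    if proportions is None:
        props = rng.dirichlet(np.full(len(types), dirichlet_alpha), size=m)
    else:
        props = np.asarray(proportions, dtype=float)
        if props.shape != (m, len(types)):
            raise ValueError("proportions must be an M x types array")
    mix = profiles @ props.T
    if nb_dispersion > 0:
        rel = mix / np.maximum(mix.sum(axis=0, keepdims=True), 1e-300)
        mu = rel * depth
        shape = 1.0 / nb_dispersion
        mix = rng.poisson(rng.gamma(shape, mu * nb_dispersion)).astype(float)
    labels = [f"mix_{i + 1:03d}" for i in range(m)]
    return MixtureSet(
        mixtures=pd.DataFrame(mix, index=sub.gene_ids, columns=labels),
        proportions=pd.DataFrame(props, index=labels, columns=types),
    )


def deconvolve_nnls(
    signature: SignatureMatrix, bulk: pd.DataFrame
) -> pd.DataFrame:
    """Estimate cell fractions per bulk sample by NNLS over signature genes.

    Solves ``min ||S x - b||_2, x >= 0`` on the signature genes present in
    the bulk profile (at least half must be present) and renormalizes each
    solution to sum to one; all-zero solutions are left at zero and flagged
    in ``result.attrs['zero_solutions']``.
    """
    genes = signature.profiles.index.intersection(bulk.index)
    if len(genes) < 0.5 * len(signature.profiles.index):
        raise ValueError(
            f"only {len(genes)}/{len(signature.profiles.index)} signature "
            "genes present in the bulk profile; estimates would be unreliable"
        )
    s = signature.profiles.loc[genes].to_numpy()
    b = bulk.loc[genes].to_numpy(dtype=float)
    # match scales: each bulk column on the same total as the signature genes
    col_tot = b.sum(axis=0, keepdims=True)
    target = s.sum(axis=0).mean()
    b = np.divide(b * target, col_tot, out=np.zeros_like(b), where=col_tot > 0)

    ests = np.zeros((bulk.shape[1], s.shape[1]))
    zero_solutions = []
    for j in range(bulk.shape[1]):
        x, _ = scipy.optimize.nnls(s, b[:, j])
        tot = x.sum()
        if tot <= 0:
            zero_solutions.append(bulk.columns[j])
            continue
        ests[j] = x / tot
    out = pd.DataFrame(ests, index=bulk.columns,
                       columns=signature.profiles.columns)
    out.attrs["solver"] = "nnls_sum_to_one"
    out.attrs["zero_solutions"] = zero_solutions
    return out


def validate_deconvolution(
    estimates: pd.DataFrame, truth: pd.DataFrame
) -> pd.DataFrame:
    """Per-type Pearson r (and two-sided p) of estimated vs true fractions.

    Types with zero variance in either vector get r = NA with the reason
    recorded, rather than a spurious correlation.
    """
    rows = []
    for t in truth.columns:
        est = estimates[t].to_numpy(dtype=float)
        tru = truth[t].to_numpy(dtype=float)
        if np.std(est) == 0 or np.std(tru) == 0:
            rows.append({"cell_type": t, "pearson_r": np.nan, "p": np.nan,
                         "mean_true_share": tru.mean(),
                         "note": "zero variance"})
            continue
        r, p = scipy.stats.pearsonr(est, tru)
        rows.append({"cell_type": t, "pearson_r": float(r), "p": float(p),
                     "mean_true_share": tru.mean(), "note": ""})
    return pd.DataFrame(rows).set_index("cell_type")
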