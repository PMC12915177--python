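"""Rank-score marker selection: the core gene-prioritization procedure.

Within each lineage-pair comparison every gene receives a rank score

    R = sqrt(rank(W)^2 + rank(FC)^2)

where ranks are ascending (the strongest statistic earns the largest rank)
and exact ties are broken by a seeded random permutation, matching the
random tie-breaking of the conventional rank definition.  Genes at or above
the chosen rank-score quantile (default the 90th percentile, linear
interpolation between order statistics) are selected per comparison, and
the marker core set is the intersection across all comparisons against the
focal lineage.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class RankConfig:
    """Quantile cut, fold-change summary choice and the tie-break seed."""

    q: float = 0.9
    fc_summary: str = "mean"     # "mean" or "median" log2 fold change
    tie_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.q < 1.0:
            raise ValueError("quantile must lie in (0, 1)")
        if self.fc_summary not in ("mean", "median"):
            raise ValueError("fc_summary must be 'mean' or 'median'")


def rank_with_random_ties(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Ascending 1..n ranks with exact ties broken uniformly at random."""
    values = np.asarray(values, dtype=float)
    jitter = rng.permutation(len(values))  # total order among tied entries
    order = np.lexsort((jitter, values))
    ranks = np.empty(len(values), dtype=float)
    ranks[order] = np.arange(1, len(values) + 1)
    return ranks


def rank_score(de: pd.DataFrame, config: RankConfig | None = None) -> pd.DataFrame:
    """Attach rank scores to one comparison's DE results.

    Genes with NaN in either statistic are excluded from ranking and
    returned with a NaN score; the exclusion list is stored in
    ``result.attrs['excluded']``.
    """
    config = config or RankConfig()
    fc_col = f"log2fc_{config.fc_summary}"
    for col in ("wald", fc_col):
        if col not in de.columns:
            raise ValueError(f"DE results lack required column {col!r}")
    out = de.copy()
    ok = out["wald"].notna() & out[fc_col].notna()
    rng = np.random.default_rng(config.tie_seed)
    rw = rank_with_random_ties(out.loc[ok, "wald"].to_numpy(), rng)
    rf = rank_with_random_ties(out.loc[ok, fc_col].to_numpy(), rng)
    out["rank_wald"] = np.nan
    out["rank_fc"] = np.nan
    out["rank_score"] = np.nan
    out.loc[ok, "rank_wald"] = rw
    out.loc[ok, "rank_fc"] = rf
    out.loc[ok, "rank_score"] = np.sqrt(rw ** 2 + rf ** 2)
    out.attrs["excluded"] = list(out.loc[~ok, "gene"]) if "gene" in out else []
    return out


def top_quantile(scored: pd.DataFrame, q: float = 0.9) -> tuple[set[str], float]:
    """Genes with rank score >= the empirical q-quantile (inclusive cut).

    The quantile uses linear interpolation between order statistics, so for
    scores 1..10 at q=0.9 the threshold is 9.1 and only the top gene passes.
    """
    ok = scored["rank_score"].notna()
    scores = scored.loc[ok, "rank_score"].to_numpy()
    if scores.size == 0:
        return set(), float("nan")
    threshold = float(np.quantile(scores, q))
    chosen = scored.loc[ok & (scored["rank_score"] >= threshold), "gene"]
    return set(chosen), threshold


def intersect_comparisons(
    sets: list[set[str]], labels: list[str] | None = None
) -> tuple[set[str], pd.DataFrame]:
    """Core set (intersection of all sets) plus all 2^k - 1 Venn region counts."""
    if not sets:
        raise ValueError("need at least one gene set")
    labels = labels or [f"set_{i + 1}" for i in range(len(sets))]
    core = set.intersection(*sets)
    rows = []
    k = len(sets)
    for membership in itertools.product([False, True], repeat=k):
        if not any(membership):
            continue
        region = None
        for inside, s in zip(membership, sets):
            if inside:
                region = s.copy() if region is None else region & s
        for inside, s in zip(membership, sets):
            if not inside:
                region -= s
        rows.append({
            "region": "&".join(l for m, l in zip(membership, labels) if m),
            "n_sets": sum(membership),
            "count": len(region),
        })
    return core, pd.DataFrame(rows)
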