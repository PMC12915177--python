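"""Config-driven end-to-end runs with reproducibility plumbing.

``run_pipeline`` executes the stages in order (simulate -> qc -> lineage ->
traj-de -> select -> origin -> deconv -> cohort-stats), writes every
intermediate as a plain-text artifact in the run directory, and records a
manifest with all seeds and parameters.  Stages can be toggled off; a
disabled stage re-uses its artifacts from a previous run in the same
directory and fails with the stage name if they are missing.  Every stage
derives its own seed from the top-level seed, so re-running a config
reproduces all outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import deconv as deconv_mod
from . import lineage as lineage_mod
from . import markers as markers_mod
from . import origin as origin_mod
from . import preprocess
from . import survival as survival_mod
from . import synthetic
from . import trajde
from .containers import CellExperiment, KnotGrid, Lineage, LineageSet, SignatureMatrix

ALL_STAGES = (
    "simulate", "qc", "lineage", "traj_de", "select",
    "origin", "deconv", "cohort_stats",
)


@dataclass
class PipelineConfig:
    """Every stage parameter in one round-trippable record.

    Defaults match the analysis constants used throughout the package: a
    5-knot grid tested between knots 3 and 4, 90th-percentile rank-score
    selection, a 5% stratified deconvolution training split with 100
    pseudobulk mixtures, ROC horizon 365 days and Kaplan-Meier censoring at
    1825 days.
    """

    outdir: str = "graftmac_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # synthetic trajectory dataset
    n_lineages: int = 3
    cells_per_lineage: int = 1000
    n_genes: int = 1500
    n_planted_markers: int = 25
    planted_log2fc: float = 2.0
    # QC / gene filter
    min_genes: int = 300
    max_genes: int = 10000
    mito_max_blood: float = 0.10
    mito_max_biopsy: float = 0.25
    min_cells_per_gene: int = 10
    # lineages + smoothers
    k_knots: int = 5
    knot_lo: int = 3
    knot_hi: int = 4
    # marker selection
    q: float = 0.9
    fc_summary: str = "mean"
    tie_seed: int = 42
    # origin
    donor_sex: str = "female"
    recipient_sex: str = "male"
    resident_donor_fraction: float = 0.18
    origin_margin: float = 0.2
    # deconvolution benchmark (distinct cell-type experiment)
    n_types: int = 8
    cells_per_type: int = 300
    celltype_genes: int = 1200
    train_frac: float = 0.05
    m_mixtures: int = 100
    mixture_dispersion: float = 0.05
    # cohort statistics
    n_cohort_samples: int = 400
    cohort_log_hr: float = float(np.log(5.0))
    tau: float = 365.0
    censor_horizon: float = 1825.0

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["stages"] = list(self.stages)
        Path(path).write_text(yaml.safe_dump(data), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        data["stages"] = tuple(data.get("stages", ALL_STAGES))
        return cls(**data)


def _stage_seed(config: PipelineConfig, stage: str) -> int:
    return (config.seed * 1000 + ALL_STAGES.index(stage)) % (2 ** 31 - 1)


def _write_lineages(lineages: LineageSet, knots: KnotGrid, outdir: Path) -> None:
    payload = {
        "knots": list(map(float, knots.positions)),
        "lineages": [
            {"name": l.name, "clusters": l.clusters,
             "control_points": l.control_points.tolist()}
            for l in lineages.lineages
        ],
    }
    (outdir / "lineages.json").write_text(json.dumps(payload, indent=1))
    long = []
    for name in lineages.names:
        long.append(pd.DataFrame({
            "cell": lineages.pseudotime.index,
            "lineage": name,
            "pseudotime": lineages.pseudotime[name].to_numpy(),
            "weight": lineages.weights[name].to_numpy(),
        }))
    pd.concat(long).to_csv(outdir / "pseudotime.tsv", sep="\t", index=False)
    lineages.assignment.rename("lineage").to_csv(
        outdir / "assignment.tsv", sep="\t", index_label="cell")


def _read_lineages(outdir: Path) -> tuple[LineageSet, KnotGrid]:
    payload = json.loads((outdir / "lineages.json").read_text())
    lins = [Lineage(d["name"], d["clusters"], np.array(d["control_points"]))
            for d in payload["lineages"]]
    long = pd.read_csv(outdir / "pseudotime.tsv", sep="\t")
    pt = long.pivot(index="cell", columns="lineage", values="pseudotime")
    w = long.pivot(index="cell", columns="lineage", values="weight")
    assignment = pd.read_csv(outdir / "assignment.tsv", sep="\t",
                             index_col="cell")["lineage"]
    order = assignment.index
    ls = LineageSet(lineages=lins, pseudotime=pt.loc[order],
                    weights=w.loc[order], assignment=assignment)
    return ls, KnotGrid(np.array(payload["knots"]))


def run_pipeline(config: PipelineConfig) -> Path:
    """Run (or resume) the pipeline; returns the run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    enabled = set(config.stages)
    unknown = enabled - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    def need(stage: str, *paths: str) -> bool:
        """True when the stage should run; otherwise its outputs must exist."""
        if stage in enabled:
            return True
        missing = [p for p in paths if not (outdir / p).exists()]
        if missing:
            raise FileNotFoundError(
                f"stage {stage!r} is disabled but its artifacts are missing: "
                f"{missing}"
            )
        return False

    manifest: dict = {"config": dataclasses.asdict(config), "stages": {}}
    manifest["config"]["stages"] = list(config.stages)

    # --- simulate ----------------------------------------------------------
    raw_dir = outdir / "raw"
    if need("simulate", "raw/counts.mtx", "raw/truth.json"):
        sim_cfg = synthetic.TrajectorySimConfig(
            n_lineages=config.n_lineages,
            cells_per_lineage=config.cells_per_lineage,
            n_genes=config.n_genes,
            n_planted_markers=config.n_planted_markers,
            planted_log2fc=config.planted_log2fc,
            seed=_stage_seed(config, "simulate"),
        )
        experiment, truth = synthetic.simulate_trajectory_dataset(sim_cfg)
        preprocess.write_mtx_experiment(experiment, raw_dir)
        (raw_dir / "truth.json").write_text(json.dumps({
            "planted_marker_ids": truth.planted_marker_ids,
            "focal_lineage": truth.details["focal_lineage"],
            "true_pseudotime": truth.pseudotime.to_dict(),
            "true_lineage": truth.lineage.to_dict(),
        }))
        manifest["stages"]["simulate"] = {"seed": sim_cfg.seed}
    experiment = preprocess.read_mtx_experiment(raw_dir)
    truth_raw = json.loads((raw_dir / "truth.json").read_text())

    # --- qc + gene filter --------------------------------------------------
    if need("qc", "qc/counts.mtx"):
        qc_cfg = preprocess.QCConfig(
            min_genes=config.min_genes, max_genes=config.max_genes,
            mito_max_blood=config.mito_max_blood,
            mito_max_biopsy=config.mito_max_biopsy,
        )
        filtered, cell_report = preprocess.qc_filter_cells(experiment, qc_cfg)
        filtered, gene_report = preprocess.filter_genes_for_de(
            filtered, min_cells=config.min_cells_per_gene)
        preprocess.write_mtx_experiment(filtered, outdir / "qc")
        manifest["stages"]["qc"] = {
            "cells_removed": cell_report.removed_by_rule,
            "genes_removed": gene_report.removed_by_rule,
        }
    filtered = preprocess.read_mtx_experiment(outdir / "qc")

    # --- lineage inference -------------------------------------------------
    root = "root_1"
    if need("lineage", "lineages.json", "pseudotime.tsv", "assignment.tsv"):
        tree = lineage_mod.build_cluster_graph(filtered)
        paths = lineage_mod.infer_lineages(tree, root)
        lineages = lineage_mod.fit_pseudotime(filtered, paths)
        knots = lineage_mod.place_knots(lineages, k=config.k_knots)
        _write_lineages(lineages, knots, outdir)
        manifest["stages"]["lineage"] = {
            "n_lineages": len(lineages.lineages),
            "knots": list(map(float, knots.positions)),
        }
    lineages, knots = _read_lineages(outdir)

    # --- trajectory differential expression --------------------------------
    focal = truth_raw["focal_lineage"]
    focal_name = next(
        (n for n in lineages.names if n.endswith(
            tuple(f"{focal}_bin{i}" for i in range(1, 10)))),
        lineages.names[0],
    )
    if need("traj_de", "de_results.tsv"):
        fits = trajde.fit_nb_smoothers(filtered, lineages, knots)
        frames = []
        for other in lineages.names:
            if other == focal_name:
                continue
            frames.append(trajde.early_de_test(
                fits, (other, focal_name),
                knot_lo=config.knot_lo, knot_hi=config.knot_hi,
            ))
        de = pd.concat(frames, ignore_index=True)
        de.to_csv(outdir / "de_results.tsv", sep="\t", index=False)
        manifest["stages"]["traj_de"] = {
            "n_comparisons": len(frames),
            "n_failed_fits": len(fits.failed),
            "focal_lineage": focal_name,
        }
    de = pd.read_csv(outdir / "de_results.tsv", sep="\t")

    # --- marker selection --------------------------------------------------
    if need("select", "core_genes.txt", "venn_counts.tsv"):
        rank_cfg = markers_mod.RankConfig(
            q=config.q, fc_summary=config.fc_summary, tie_seed=config.tie_seed)
        sets, labels = [], []
        for comp, sub in de.groupby("comparison", sort=True):
            scored = markers_mod.rank_score(sub.reset_index(drop=True), rank_cfg)
            genes, _ = markers_mod.top_quantile(scored, config.q)
            sets.append(genes)
            labels.append(comp)
        core, venn = markers_mod.intersect_comparisons(sets, labels)
        (outdir / "core_genes.txt").write_text(
            "\n".join(sorted(core)) + "\n")
        venn.to_csv(outdir / "venn_counts.tsv", sep="\t", index=False)
        manifest["stages"]["select"] = {"n_core_genes": len(core),
                                        "tie_seed": config.tie_seed}
    core = set((outdir / "core_genes.txt").read_text().split())

    # --- origin assignment -------------------------------------------------
    if need("origin", "origin_labels.tsv"):
        seed = _stage_seed(config, "origin")
        focal_clusters = [c for c in filtered.cells["cluster"].unique()
                          if c.startswith(focal)]
        fractions = {c: 0.0 for c in focal_clusters}
        for c in filtered.cells["cluster"].unique():
            if c not in fractions and not c.startswith("root"):
                fractions[c] = config.resident_donor_fraction
        with_sex, origin_truth = synthetic.simulate_origin_labels(
            filtered, fractions, config.donor_sex, config.recipient_sex,
            seed=seed,
        )
        scores = origin_mod.score_sex_signatures(with_sex)
        labels_df, frac_table = origin_mod.assign_origin(
            scores, config.donor_sex, config.recipient_sex,
            margin=config.origin_margin,
            cell_types=with_sex.cells["cluster"],
        )
        labels_df["true_origin"] = origin_truth.origin
        labels_df.to_csv(outdir / "origin_labels.tsv", sep="\t",
                         index_label="cell")
        frac_table.to_csv(outdir / "origin_fractions.tsv", sep="\t")
        manifest["stages"]["origin"] = {"seed": seed,
                                        "margin": config.origin_margin}

    # --- deconvolution benchmark -------------------------------------------
    if need("deconv", "signature_matrix.tsv", "validation_r.tsv"):
        seed = _stage_seed(config, "deconv")
        ct_exp, _ = synthetic.simulate_celltype_experiment(
            n_types=config.n_types, cells_per_type=config.cells_per_type,
            n_genes=config.celltype_genes, seed=seed,
        )
        preprocess.write_mtx_experiment(ct_exp, outdir / "celltypes")
        train, valid = deconv_mod.split_train_validation(
            ct_exp, train_frac=config.train_frac, seed=seed)
        signature = deconv_mod.build_signature(ct_exp, train)
        mixtures = deconv_mod.make_mixtures(
            ct_exp, valid, m=config.m_mixtures, seed=seed + 1,
            nb_dispersion=config.mixture_dispersion,
        )
        estimates = deconv_mod.deconvolve_nnls(signature, mixtures.mixtures)
        validation = deconv_mod.validate_deconvolution(
            estimates, mixtures.proportions)
        signature.profiles.to_csv(outdir / "signature_matrix.tsv", sep="\t")
        mixtures.mixtures.to_csv(outdir / "mixtures.tsv", sep="\t")
        mixtures.proportions.to_csv(outdir / "true_props.tsv", sep="\t")
        estimates.to_csv(outdir / "estimated_props.tsv", sep="\t")
        validation.to_csv(outdir / "validation_r.tsv", sep="\t")
        manifest["stages"]["deconv"] = {
            "seed": seed, "solver": "nnls_sum_to_one",
            "n_signature_genes": signature.profiles.shape[0],
        }

    # --- cohort statistics -------------------------------------------------
    if need("cohort_stats", "cox.tsv"):
        seed = _stage_seed(config, "cohort_stats")
        signature = SignatureMatrix(profiles=pd.read_csv(
            outdir / "signature_matrix.tsv", sep="\t", index_col=0))
        bulk, surv, truth = synthetic.simulate_bulk_cohort(
            signature, n_samples=config.n_cohort_samples,
            beta=config.cohort_log_hr, seed=seed,
        )
        focal_type = truth.details["focal_type"]
        marker = f"frac_{focal_type}"
        roc = survival_mod.td_roc(surv, marker, tau=config.tau)
        cutoff, j = survival_mod.youden_cutoff(roc)
        groups = pd.Series(
            np.where(surv[marker] > cutoff, "high", "low"), index=surv.index)
        _, chi2, logrank_p = survival_mod.km_logrank(
            surv, groups, censor_horizon=config.censor_horizon)
        surv["high_fraction"] = (surv[marker] > cutoff).astype(int)
        cox = survival_mod.cox_fit(surv, ["high_fraction"],
                                   right_censor=config.tau)
        pd.DataFrame({
            "cutoff": roc.cutoffs, "sensitivity": roc.sensitivity,
            "specificity": roc.specificity, "youden": roc.youden,
        }).to_csv(outdir / "roc.tsv", sep="\t", index=False)
        surv.to_csv(outdir / "survival.tsv", sep="\t")
        cox.summary.to_csv(outdir / "cox.tsv", sep="\t")
        corr = survival_mod.lesion_correlation(surv, marker)
        manifest["stages"]["cohort_stats"] = {
            "seed": seed, "youden_cutoff": cutoff, "youden_j": j,
            "auc": roc.auc, "logrank_chi2": chi2, "logrank_p": logrank_p,
            "lesion_correlation_r": corr["r"],
        }

    manifest_path = outdir / "manifest.json"
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        old_stages = old.get("stages", {})
        old_stages.update(manifest["stages"])
        manifest["stages"] = old_stages
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    config.to_yaml(outdir / "config.yaml")
    return outdir
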