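"""Stage orchestration: wires the modules into the end-to-end workflow.

Stages (each usable alone, chained by ``run_all``):
exclusions -> diet factors (EFA + ten Berge scores) -> PRS -> per-metabolite
mixed models -> diet+lifestyle / time signal extraction -> glasso + StARS ->
module detection -> characterization, plus the per-timepoint benchmark
(residualize on Age, Sex, Age*Sex within each timepoint, then estimate a
network per timepoint) for comparison.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import decompose as dc
from . import describe, efa, modules, network, prs, simulate
from .io_config import PipelineConfig, RepeatedMeasuresDataset, write_network

logger = logging.getLogger("metabnet")


def n_real_modules(partition: modules.ModulePartition, min_size: int = 2) -> int:
    """Number of modules with at least ``min_size`` members (singletons and
    the unassigned pool are not modules)."""
    return sum(
        1
        for mid, members in partition.module_members().items()
        if mid != 0 and len(members) >= min_size
    )


def stage_diets(ffq: efa.FFQTable, cfg: PipelineConfig):
    model = efa.fit_efa(ffq, n_factors=cfg.n_factors, rotation_seed=cfg.seed)
    scores = efa.tenberge_scores(model, ffq)
    frame = pd.DataFrame(
        scores.scores,
        index=ffq.items.index,
        columns=[f"F{j + 1}" for j in range(cfg.n_factors)],
    )
    return model, frame


def stage_prs(genotypes, effects, cfg: PipelineConfig) -> prs.PRSMatrix:
    out = prs.compute_prs(genotypes, effects, top_l=cfg.top_l)
    if cfg.standardize_prs:
        out = prs.standardize_prs(out)
    return out


def stage_decompose(
    dataset: RepeatedMeasuresDataset,
    covariates: pd.DataFrame,
    factor_scores: pd.DataFrame,
    prs_matrix,
    cfg: PipelineConfig,
):
    dataset, report = dc.apply_exclusions(dataset, covariates)
    bundle = dc.build_covariate_bundle(dataset, covariates, factor_scores, prs_matrix)
    fits = dc.fit_metabolome(
        dataset, bundle, log_transform=cfg.log_transform,
        zscore=cfg.zscore_metabolites,
    )
    y_l = dc.extract_diet_lifestyle_part(fits, bundle)
    y_t = dc.extract_time_part(fits, bundle)
    return dataset, bundle, fits, y_l, y_t, report


def stage_network(values, cfg: PipelineConfig, subject_ids=None, nodes=None):
    cfg.check_subsample_size(len(values))
    path = network.stars_select(
        values,
        n_subsamples=cfg.n_subsamples,
        subsample_size=cfg.subsample_size,
        beta_stars=cfg.beta_stars,
        seed=cfg.seed,
        standardize=cfg.standardize_yl,
        subsample_unit=cfg.subsample_unit,
        subject_ids=subject_ids,
        n_lambda=cfg.n_lambda,
        lambda_min_ratio=cfg.lambda_min_ratio,
        penalize_diagonal=cfg.penalize_diagonal,
    )
    net = network.build_network(
        path, values, standardize=cfg.standardize_yl, nodes=nodes,
        penalize_diagonal=cfg.penalize_diagonal,
    )
    return path, net


def stage_modules(net: network.Network, cfg: PipelineConfig):
    D = modules.dissimilarity_from_W(net.W)
    tree = modules.dynamic_hybrid_cut(
        D,
        linkage=cfg.linkage,
        min_module_size=cfg.min_module_size,
        deep_split=cfg.deep_split,
        cut_height=cfg.cut_height,
        nodes=net.nodes,
    )
    gn = modules.girvan_newman(net, weighted_betweenness=cfg.gn_weighted_betweenness)
    return tree, gn


def run_all(cfg: PipelineConfig, study: "simulate.SimulatedStudy | None" = None) -> dict:
    """Run every stage; writes outputs under cfg.outdir and returns a result
    dict (also serialized as report.json)."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if study is None and cfg.metabolite_table is None:
        study = simulate.simulate_study(cfg)
        simulate.write_study(study, out / "inputs")
    if study is not None:
        dataset, covariates = study.dataset, study.covariates
        ffq, genotypes, effects = study.ffq, study.genotypes, study.effects
    else:
        from .io_config import read_long_table

        dataset = read_long_table(cfg.metabolite_table)
        covariates = pd.read_csv(cfg.covariate_table)
        ffq = efa.FFQTable(pd.read_csv(cfg.ffq_table, sep="\t", index_col=0))
        genotypes = prs.GenotypeMatrix(
            pd.read_csv(cfg.genotype_table, sep="\t", index_col=0)
        )
        eff = pd.read_csv(cfg.effects_table, sep="\t")
        eta = eff.pivot(index="snp_id", columns="metabolite", values="eta")
        pv = (
            eff.pivot(index="snp_id", columns="metabolite", values="p_value")
            if "p_value" in eff.columns
            else None
        )
        effects = prs.EffectSizeTable(eta=eta, p_value=pv)

    logger.info("diet factors: EFA with %d factors", cfg.n_factors)
    model, scores = stage_diets(ffq, cfg)
    efa.loadings_frame(model).to_csv(out / "loadings.tsv", sep="\t")
    scores.rename_axis("subject_id").to_csv(out / "factor_scores.tsv", sep="\t")

    logger.info("polygenic scores over %d SNPs", len(effects.snp_ids))
    prs_matrix = stage_prs(genotypes, effects, cfg)
    prs_matrix.G.rename_axis("subject_id").to_csv(out / "prs.tsv", sep="\t")

    logger.info("mixed-model decomposition of %d metabolites", len(dataset.metabolites))
    dataset, bundle, fits, y_l, y_t, excl = stage_decompose(
        dataset, covariates, scores, prs_matrix, cfg
    )
    dc.fit_summary_frame(fits).to_csv(out / "fit_summary.tsv", sep="\t", index=False)
    y_l.frame.to_csv(out / "y_diet_lifestyle.csv", index=False)
    y_t.frame.to_csv(out / "y_time.csv", index=False)

    logger.info("network estimation (StARS + glasso)")
    if cfg.average_within_subject:
        values = y_l.averaged_within_subject()
        row_subjects = values.index.to_numpy()
    else:
        values = y_l.frame[y_l.metabolites]
        row_subjects = bundle.subject_id
    path, net = stage_network(
        values, cfg, subject_ids=row_subjects, nodes=y_l.metabolites
    )
    network.stability_path_frame(path).to_csv(
        out / "stability_path.tsv", sep="\t", index=False
    )
    write_network(net, out / "network.graphml", "graphml")
    write_network(net, out / "network_edges.tsv", "edgelist_tsv")

    logger.info("module identification")
    tree, gn = stage_modules(net, cfg)
    modules.partition_frame([tree, gn]).to_csv(
        out / "modules.tsv", sep="\t", index=False
    )

    summary = describe.summarize(net, gn, min_report_size=cfg.min_report_size)
    summary.table.to_csv(out / "summary.tsv", sep="\t", index=False)
    tree_summary = describe.summarize(net, tree, min_report_size=cfg.min_report_size)
    tree_summary.table.to_csv(out / "summary_treecut.tsv", sep="\t", index=False)
    scores_obs = scores.loc[bundle.subject_id].reset_index(drop=True)
    curves = describe.profile_curves(y_l, scores_obs, partition=tree)
    curves.to_csv(out / "profile_curves.csv", index=False)

    logger.info("per-timepoint benchmark networks")
    benchmark = {}
    residuals = dc.residualize_per_timepoint(dataset, bundle)
    for t, resid in residuals.items():
        # one row per subject within a timepoint slice
        bpath, bnet = stage_network(
            resid, cfg, subject_ids=resid.index.to_numpy(),
            nodes=list(resid.columns),
        )
        write_network(bnet, out / f"benchmark_network_t{t}.graphml", "graphml")
        bgn = modules.girvan_newman(bnet, cfg.gn_weighted_betweenness)
        bsummary = describe.summarize(bnet, bgn, min_report_size=cfg.min_report_size)
        bsummary.table.to_csv(out / f"benchmark_summary_t{t}.tsv", sep="\t",
                              index=False)
        benchmark[t] = {
            "lambda_opt": bpath.lambda_opt,
            "n_edges": bnet.n_edges,
            "n_modules_girvan_newman": n_real_modules(bgn),
            "n_modules_reported": n_real_modules(bgn, cfg.min_report_size),
        }

    report = {
        "n_observations": int(dataset.n_obs),
        "n_subjects_t0": int((dataset.data["timepoint"] == 0).sum()),
        "n_subjects_t1": int((dataset.data["timepoint"] == 1).sum()),
        "exclusions": excl,
        "lambda_opt": path.lambda_opt,
        "n_edges": net.n_edges,
        "density": describe.density(net.W),
        "centralization": describe.centralization(net.W),
        "heterogeneity": describe.heterogeneity(net.W) if net.W.sum() > 0 else None,
        "n_modules_treecut": n_real_modules(tree),
        "n_modules_girvan_newman": n_real_modules(gn),
        "n_modules_reported_treecut": n_real_modules(tree, cfg.min_report_size),
        "n_modules_reported_girvan_newman": n_real_modules(gn, cfg.min_report_size),
        "benchmark": benchmark,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    result = dict(report)
    result.update(
        {
            "network": net,
            "stability_path": path,
            "partition_treecut": tree,
            "partition_girvan_newman": gn,
            "fits": fits,
            "y_diet_lifestyle": y_l,
            "y_time": y_t,
            "efa_model": model,
            "factor_scores": scores,
            "study": study,
        }
    )
    return result
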