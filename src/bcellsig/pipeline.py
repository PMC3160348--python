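"""End-to-end orchestration of the analysis stages.

Stage order mirrors the study design: expression filtering, cohort-wide
differential expression (with immunoglobulin probes stripped before
reporting), unsupervised clustering with patient-subgroup detection,
subgroup-vs-control differential expression, directional
ligand-signature ranking, and gene-set enrichment.  Every stochastic
stage records its seed; re-running with the same configuration
reproduces every output byte for byte.
"""
from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as bio
from .cluster import agglomerate, find_patient_subgroup, sample_distances
from .containers import (
    ConfigurationError,
    ExpressionMatrix,
    SampleAnnotation,
)
from .differential import sam_test, strip_ig_genes
from .preprocess import filter_expressed, quantile_normalize
from .signature import (
    DirectionalGeneList,
    HomologMap,
    LigandCompendium,
    gene_set_enrichment,
    rank_ligands,
)
from .simulate import SimulationConfig, simulate_ligand_compendium, simulate_study

log = logging.getLogger("bcellsig.pipeline")

__all__ = ["PipelineConfig", "run_pipeline", "sle_list_from_sam"]


@dataclass
class PipelineConfig:
    """One input source (files or a simulation) plus stage settings."""

    # input: either a simulation config ...
    simulation: SimulationConfig | None = None
    # ... or file paths
    matrix_path: str | None = None
    annotation_path: str | None = None
    compendium_path: str | None = None
    homolog_path: str | None = None
    gmt_path: str | None = None

    # preprocessing
    quantile_normalize: bool = False
    threshold: float = 4.0
    filter_rule: str = "group_mean"

    # differential expression
    n_perm: int = 300
    seed: int = 0
    subgroup_fdr: float = 0.01
    subgroup_vs_all_others: bool = False  # default contrast: subgroup vs controls

    # clustering
    metric: str = "euclidean"
    linkage: str = "complete"
    min_subgroup_size: int = 3
    silhouette_floor: float = 0.05

    # ligand signature
    fc_cutoff: float = 1.5
    timepoint_h: float = 4.0
    n_resamples: int = 0
    alpha: float = 0.05

    out_dir: str | None = None

    def validate(self) -> None:
        has_sim = self.simulation is not None
        has_files = self.matrix_path is not None
        if has_sim == has_files:
            raise ConfigurationError(
                "exactly one input source required: simulation or matrix_path"
            )
        if has_files and self.annotation_path is None:
            raise ConfigurationError("file input needs annotation_path")


def sle_list_from_sam(
    sam_result, fdr: float = 0.01
) -> DirectionalGeneList:
    """Collapse a SAM table at an FDR cut to a directional gene list.

    A gene's direction comes from its most significant probe (smallest
    q, then largest |d|); genes whose significant probes disagree in
    direction are dropped with a warning.
    """
    called = sam_result.called_at(fdr)
    called = called[called["gene_symbol"] != ""]
    if called.empty:
        return DirectionalGeneList(pd.Series(dtype=int))
    called = called.assign(
        _dir=np.where(called["d"] >= 0, 1, -1),
        _sym=called["gene_symbol"].str.upper(),
        _absd=called["d"].abs(),
    ).sort_values(["q", "_absd"], ascending=[True, False], kind="mergesort")
    out: dict[str, int] = {}
    dropped = []
    for sym, sub in called.groupby("_sym", sort=True):
        dirs = set(sub["_dir"])
        if len(dirs) > 1:
            dropped.append(sym)
            continue
        out[sym] = int(sub["_dir"].iloc[0])
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} genes with conflicting probe directions"
        )
    return DirectionalGeneList.from_dict(out)


def _load_inputs(config: PipelineConfig):
    truth = None
    compendium = homolog = None
    gene_sets = None
    if config.simulation is not None:
        sim = config.simulation
        matrix, annotation, truth = simulate_study(sim)
        compendium, homolog, truth = simulate_ligand_compendium(sim, truth)
        # gene sets for the enrichment stage: the planted module plus decoys
        rng = np.random.default_rng([sim.seed, 11])
        symbols = matrix.gene_symbols[matrix.gene_symbols != ""].unique()
        gene_sets = {"planted_module": list(truth.module_gene_ids)}
        for i in range(10):
            size = int(rng.integers(50, 400))
            gene_sets[f"random_set_{i + 1:02d}"] = rng.choice(
                symbols, size=size, replace=False
            ).tolist()
    else:
        matrix = bio.read_matrix(config.matrix_path)
        annotation = bio.read_annotation(config.annotation_path)
        if config.compendium_path:
            compendium = bio.read_compendium(config.compendium_path)
            if config.homolog_path:
                homolog = bio.read_homolog_map(config.homolog_path)
            else:
                homolog = HomologMap.same_symbol(
                    compendium.table["symbol"].unique().tolist()
                )
        if config.gmt_path:
            gene_sets = bio.read_gmt(config.gmt_path)
    return matrix, annotation, truth, compendium, homolog, gene_sets


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the JSON-serializable summary.

    When ``config.out_dir`` is set, each stage's table is written
    there (tab-delimited / Newick / JSON) along with ``summary.json``.
    """
    config.validate()
    t0 = time.time()
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        log.info("stage %-12s %6.1fs", name, time.time() - t0)

    matrix, annotation, truth, compendium, homolog, gene_sets = _load_inputs(config)
    annotation.check_matches(matrix)
    stage("load")

    if config.quantile_normalize:
        matrix = quantile_normalize(matrix)
        stage("normalize")

    filt = filter_expressed(matrix, annotation, config.threshold, config.filter_rule)
    expressed = filt.matrix
    stage("filter")

    summary: dict = {
        "seed": config.seed,
        "threshold": config.threshold,
        "filter_rule": config.filter_rule,
        "n_probes_input": filt.n_input,
        "n_probes_expressed": filt.n_retained,
        "expressed_fraction": round(filt.retained_fraction, 6),
        "n_controls": len(annotation.controls),
        "n_patients": len(annotation.patients),
    }

    # cohort-wide differential expression, Ig probes stripped
    sam_all = sam_test(
        expressed, annotation, "patient", "control", config.n_perm, config.seed
    )
    kept, removed_ig = strip_ig_genes(sam_all.table)
    summary["sam_all"] = {
        **sam_all.metadata(),
        "n_ig_probes_removed": int(len(removed_ig)),
        "n_called_fdr_0.20": int((kept["q"] <= 0.20).sum()),
        "min_q": float(kept["q"].min()) if len(kept) else None,
    }
    stage("sam_all")

    # clustering + subgroup detection
    distances = sample_distances(expressed, config.metric)
    dendro = agglomerate(distances, config.linkage)
    call = find_patient_subgroup(
        dendro, annotation, config.min_subgroup_size, config.silhouette_floor
    )
    summary["subgroup"] = (
        None
        if call is None
        else {
            "members": call.member_sample_ids,
            "silhouette": round(call.silhouette, 6),
            "separation_height": round(call.separation_height, 6),
        }
    )
    stage("cluster")

    sam_sub = None
    sle_list = DirectionalGeneList(pd.Series(dtype=int))
    if call is not None:
        contrast = list(annotation.controls)
        if config.subgroup_vs_all_others:
            contrast += [
                p for p in annotation.patients if p not in call.member_sample_ids
            ]
        sub_samples = call.member_sample_ids + contrast
        sub_ann = SampleAnnotation.from_groups(
            {
                s: ("patient" if s in call.member_sample_ids else "control")
                for s in sub_samples
            }
        )
        sam_sub = sam_test(
            expressed.subset_samples(sub_samples),
            sub_ann,
            "patient",
            "control",
            config.n_perm,
            config.seed + 1,
        )
        sle_list = sle_list_from_sam(sam_sub, config.subgroup_fdr)
        summary["sam_subgroup"] = {
            **sam_sub.metadata(),
            "fdr_cut": config.subgroup_fdr,
            "n_called": int(len(sam_sub.called_at(config.subgroup_fdr))),
            "n_genes_sle_list": len(sle_list),
        }
    stage("sam_subgroup")

    ligand_table = None
    if compendium is not None and len(sle_list) > 0:
        expressed_symbols = set(
            expressed.gene_symbols[expressed.gene_symbols != ""].str.upper()
        )
        ligand_table = rank_ligands(
            sle_list,
            compendium,
            expressed_symbols,
            homolog,
            config.fc_cutoff,
            config.timepoint_h,
            config.n_resamples,
            config.seed + 2,
            config.alpha,
        )
        top = ligand_table.iloc[0]
        summary["ligands"] = {
            "n_ligands": int(len(ligand_table)),
            "top_ligand": str(top["ligand"]),
            "top_overlap": int(top["overlap"]),
            "top_same_direction": int(top["same_direction"]),
            "top_rf": round(float(top["rf"]), 4),
            "top_p_hyper": float(top["p_hyper"]),
            "top_p_sign": float(top["p_sign"]),
            "n_significant": int(ligand_table["significant"].sum()),
        }
    stage("ligands")

    enrich_table = None
    if gene_sets and len(sle_list) > 0:
        universe = set(expressed.gene_symbols[expressed.gene_symbols != ""].str.upper())
        enrich_table = gene_set_enrichment(sle_list.symbols, gene_sets, universe)
        if len(enrich_table):
            top = enrich_table.iloc[0]
            summary["enrichment"] = {
                "n_sets": int(len(enrich_table)),
                "top_set": str(top["set"]),
                "top_p_corrected": float(top["p_corrected"]),
            }
    stage("enrich")

    if truth is not None:
        summary["ground_truth"] = {
            "subgroup": truth.subgroup_sample_ids,
            "module_size": len(truth.module_directions),
            "target_ligand": truth.target_ligand,
        }
        if call is not None:
            summary["subgroup"]["recovered_exactly"] = (
                call.member_sample_ids == truth.subgroup_sample_ids
            )
        if ligand_table is not None:
            summary["ligands"]["target_ranked_first"] = (
                str(ligand_table.iloc[0]["ligand"]) == truth.target_ligand
            )

    if out_dir:
        bio.write_matrix(expressed, out_dir / "expressed_matrix.tsv")
        bio.write_annotation(annotation, out_dir / "annotation.tsv")
        kept.to_csv(out_dir / "sam_all.tsv", sep="\t")
        removed_ig.to_csv(out_dir / "sam_all_removed_ig.tsv", sep="\t")
        (out_dir / "dendrogram.nwk").write_text(dendro.to_newick() + "\n")
        if call is not None:
            call.to_json(out_dir / "subgroup.json")
        if sam_sub is not None:
            sam_sub.table.to_csv(out_dir / "sam_subgroup.tsv", sep="\t")
        if ligand_table is not None:
            ligand_table.to_csv(out_dir / "ligand_ranking.tsv", sep="\t", index=False)
        if enrich_table is not None:
            enrich_table.to_csv(out_dir / "enrichment.tsv", sep="\t", index=False)
        if truth is not None:
            truth.to_json(out_dir / "ground_truth.json")
        (out_dir / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True) + "\n"
        )
    stage("done")
    return summary
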