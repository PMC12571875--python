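"""End-to-end orchestration from a single configuration.

``run_pipeline`` executes simulate/read → QC → cell typing → niche and
compartment annotation → trajectory → pathway scores → communication
networks → protein integration (when an image or the synthetic channel is
available) → drug prioritization, writing every stage output plus a JSON
manifest (parameters, per-stage seeds and row counts).  A single global
seed fans out to per-stage seeds through a counter-based derivation, so
adding a stage never perturbs the randomness of earlier stages.
"""

from __future__ import annotations

import json
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import datasets
from .celltyping import (
    CellTypeClassifier,
    normalize_log1p,
    relabel_fibrotic_mesangial,
)
from .exceptions import GlomscapeError, ValidationError
from .interactions import (
    InteractionConfig,
    apply_slide_offsets,
    communication_probability,
    differential_network,
    incoming_signals,
    permutation_significance,
)
from .io import SpatialCellTable, qc_filter_cells, read_cells
from .niches import (
    SpatialDomainAnnotator,
    refine_glomerular_mask,
    fill_glomerulus_hulls,
    assign_compartments,
    build_roi_table,
    compartment_composition,
    glomerular_clusters,
    instance_glomeruli,
)
from .pathways import fibrosis_score, score_gene_set, trend_along_trajectory
from .trajectory import (
    CrescentTrajectory,
    cluster_rois,
    compute_pseudotime,
    correlate_with_clinical,
    median_pc1_per_patient,
    pseudobulk_rois,
    quadrant_breaks,
)

STAGES = ("simulate", "qc", "classify", "niches", "trajectory", "score",
          "interact", "protein", "drugs")


def stage_seed(global_seed: int, stage: str) -> int:
    """Counter-based per-stage seed (stable under stage insertion)."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence(entropy=int(global_seed), spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def validate_pipeline_config(config: dict) -> dict:
    """Check the one-of-{inputs, synthetic} invariant and fill defaults."""
    config = dict(config)
    has_inputs = "inputs" in config
    has_synth = "synthetic" in config
    if has_inputs == has_synth:
        raise ValidationError(
            "pipeline config must contain exactly one of 'inputs' or 'synthetic'"
        )
    config.setdefault("seed", 0)
    config.setdefault("output_dir", "glomscape_output")
    for block in ("qc", "classify", "niches", "trajectory", "score",
                  "interact", "protein", "drugs"):
        config.setdefault(block, {})
    return config


def _annotate(table, seed, params):
    """Domain clusters → glomerular mask → instancing → compartments."""
    annot = SpatialDomainAnnotator(
        k_neighbors=params.get("k_neighbors", 8),
        n_pcs=params.get("n_pcs", 20),
        resolution=params.get("resolution", 1.0),
        random_state=seed,
    )
    domains = annot.fit_predict(table)
    mask = glomerular_clusters(table, domains)
    mask = refine_glomerular_mask(
        table, mask,
        k=params.get("refine_k", 12),
        min_fraction=params.get("refine_fraction", 0.8),
    )
    glom_ids = instance_glomeruli(
        table, mask,
        link_distance_um=params.get("link_distance_um", 30.0),
        min_cells=params.get("min_cells", 15),
    )
    if params.get("fill_hulls", True):
        glom_ids = fill_glomerulus_hulls(table, glom_ids)
    labeling = assign_compartments(
        table, glom_ids,
        perimeter_um=params.get("perimeter_um", 100.0),
        domain_labels=domains,
    )
    return labeling


def run_pipeline(config: dict, clinical: pd.DataFrame | None = None) -> dict:
    """Run every stage; returns the manifest (also written to the output
    directory).  Stage failures abort with the stage name recorded."""
    config = validate_pipeline_config(config)
    seed = int(config["seed"])
    out = Path(config["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "stages": {}, "parameters": {}}
    current = None
    try:
        # -- simulate / read ------------------------------------------------
        current = "simulate"
        t0 = time.time()
        truth = None
        if "synthetic" in config:
            from .synthetic import CohortConfig, generate_cohort, generate_clinical

            overrides = {k: v for k, v in (config["synthetic"] or {}).items()}
            cohort_cfg = CohortConfig(**overrides)
            table, truth = generate_cohort(cohort_cfg, seed=stage_seed(seed, "simulate"))
            if clinical is None:
                clinical = generate_clinical(truth, seed=stage_seed(seed, "simulate"))
        else:
            paths = config["inputs"]
            table = read_cells(paths["cells"], paths["counts"],
                               paths.get("polygons"))
        manifest["stages"]["simulate"] = {"n_cells": table.n_cells,
                                          "n_genes": table.n_genes,
                                          "elapsed_s": round(time.time() - t0, 2)}

        # -- qc --------------------------------------------------------------
        current = "qc"
        qc_par = config["qc"]
        table, report = qc_filter_cells(
            table,
            min_unique_genes=qc_par.get("min_unique_genes", 5),
            max_mito_fraction=qc_par.get("max_mito_fraction"),
            exclude_cell_ids=qc_par.get("exclude_cell_ids"),
        )
        manifest["stages"]["qc"] = report

        # -- classify --------------------------------------------------------
        current = "classify"
        cls_par = config["classify"]
        if "cell_type" in table.cells.columns and not cls_par.get("retrain", False):
            labels = table.cells["cell_type"].to_numpy(dtype=object)
            conf = np.ones(table.n_cells)
        else:
            from .synthetic import generate_reference

            ref_counts, ref_labels, ref_genes = generate_reference(
                cohort_cfg if "synthetic" in config else None,
                n_per_type=cls_par.get("n_reference_per_type", 200),
                seed=stage_seed(seed, "classify"),
            )
            model = CellTypeClassifier(
                target_sum=cls_par.get("target_sum", 1000.0),
                random_state=stage_seed(seed, "classify"),
            ).fit(ref_counts, ref_labels, genes=ref_genes)
            with open(out / "cell_type_model.json", "w") as fh:
                json.dump(model.to_dict(), fh)
            labels, conf = model.predict_cells(table)
        manifest["stages"]["classify"] = {
            "n_cells": int(len(labels)),
            "median_confidence": float(np.median(conf)),
        }

        # -- niches ----------------------------------------------------------
        current = "niches"
        labeling = _annotate(table, stage_seed(seed, "niches"), config["niches"])
        # fibrotic-mesangial relabeling needs the fibrosis score
        norm_cells = normalize_log1p(table.counts, 1000.0)
        fib = fibrosis_score(norm_cells, table.gene_names)
        labels = relabel_fibrotic_mesangial(
            labels, fib.scores,
            in_glomerulus=labeling.compartment == "glomerular",
            is_control=table.cells["condition"].to_numpy() == "control",
            percentile=config["niches"].get("fibrotic_percentile", 90.0),
        )
        pd.DataFrame({"cell_type": labels, "confidence": conf},
                     index=table.cells.index).join(labeling.cells).to_csv(
            out / "cells_annotated.csv")
        roi_table = build_roi_table(labeling, table)
        roi_table.to_csv(out / "roi_summary.csv")
        per_unit, medians = compartment_composition(labeling, labels, table)
        medians.to_csv(out / "composition_medians.csv", index=False)
        manifest["stages"]["niches"] = {
            "n_rois": int(len(roi_table)),
            "n_glomerular_cells": int((labeling.compartment == "glomerular").sum()),
        }

        # -- trajectory ------------------------------------------------------
        current = "trajectory"
        raw, norm, meta = pseudobulk_rois(table, labeling)
        traj = CrescentTrajectory(
            n_pcs=config["trajectory"].get("n_pcs", 10)
        ).fit(norm, meta["condition"])
        clusters = cluster_rois(traj.pc_, meta["condition"].to_numpy(),
                                seed=stage_seed(seed, "trajectory"))
        pt = compute_pseudotime(norm, meta["condition"].to_numpy(),
                                seed=stage_seed(seed, "trajectory"))
        quadrants = quadrant_breaks(pt)
        roi_out = meta.assign(pc1=traj.pc1_, cluster=clusters,
                              pseudotime=pt, quadrant=quadrants)
        roi_out.to_csv(out / "trajectory_rois.csv")
        from .trajectory import de_between_clusters

        try:
            de = de_between_clusters(norm, clusters, meta["slide_id"].to_numpy())
            de.to_csv(out / "de_cluster1_vs_rest.csv")
        except GlomscapeError as e:
            warnings.warn(f"differential expression skipped: {e}")
        med_pc1 = median_pc1_per_patient(traj.pc1_, meta)
        med_pc1.rename("median_pc1").to_csv(out / "patient_median_pc1.csv")
        if clinical is not None:
            corr = correlate_with_clinical(med_pc1, clinical)
            corr.to_csv(out / "clinical_correlations.csv")
        manifest["stages"]["trajectory"] = {
            "n_rois": int(len(roi_out)),
            "n_clusters": int(pd.Series(clusters).nunique()),
        }

        # -- pathway scores --------------------------------------------------
        current = "score"
        pc1_per_roi = pd.Series(traj.pc1_, index=meta.index)
        sets = datasets.load_gene_sets()
        trends = {}
        score_cells = {}
        for name in ("PDGF_SIGNALING", "TGFB_SIGNALING"):
            gs = score_gene_set(norm_cells, table.gene_names, sets[name], name)
            score_cells[name] = gs.scores
            try:
                tr = trend_along_trajectory(gs.scores, labels, "PEC",
                                            labeling.roi_id, pc1_per_roi)
                trends[name] = {"coef": tr.coef.tolist(), "peak": tr.peak,
                                "curvature": tr.curvature}
            except GlomscapeError as e:
                trends[name] = {"error": str(e)}
        pd.DataFrame(score_cells, index=table.cells.index).to_csv(
            out / "pathway_scores.csv")
        with open(out / "pathway_trends.json", "w") as fh:
            json.dump(trends, fh, indent=2)
        manifest["stages"]["score"] = {"trends": trends}

        # -- interactions ----------------------------------------------------
        current = "interact"
        int_par = config["interact"]
        icfg = InteractionConfig(
            n_permutations=int_par.get("n_permutations", 100),
            seed=stage_seed(seed, "interact"),
        )
        lr_db = datasets.load_lr_database()
        typed = SpatialCellTable(table.cells.assign(cell_type=labels),
                                 table.counts, table.gene_names, table.polygons)
        typed = apply_slide_offsets(typed, icfg.interaction_range_um)
        networks = {}
        for cond in pd.unique(typed.cells["condition"]):
            sub = typed.subset((typed.cells["condition"] == cond).to_numpy())
            net = communication_probability(sub, lr_db, icfg, condition=cond)
            net = permutation_significance(sub, lr_db, net, icfg)
            net.edges.to_csv(out / f"network_{cond.replace('-', '')}.csv", index=False)
            networks[cond] = net
        if "control" in networks:
            for cond, net in networks.items():
                if cond == "control":
                    continue
                diff = differential_network(net, networks["control"], icfg.alpha)
                diff.to_csv(out / f"differential_{cond.replace('-', '')}.csv")
        incoming = incoming_signals(networks, "PEC", icfg.alpha)
        incoming.to_csv(out / "incoming_to_PEC.csv", index=False)
        manifest["stages"]["interact"] = {
            "n_conditions": len(networks),
            "n_significant_incoming_PEC": int(len(incoming)),
        }

        # -- protein ---------------------------------------------------------
        current = "protein"
        if truth is not None:
            from .protein import aggregate_protein, positivity_along_trajectory
            from .synthetic import render_protein_channel

            frames = []
            for sample in pd.unique(table.cells["sample_id"]):
                rows = (table.cells["sample_id"] == sample).to_numpy()
                sub = table.subset(rows)
                sub_truth = _subset_truth(truth, sub.cells.index)
                img, polys = render_protein_channel(
                    sub, sub_truth, cohort_cfg,
                    pixel_size_um=config["protein"].get("pixel_size_um", 2.0),
                    seed=stage_seed(seed, "protein"),
                )
                frames.append(aggregate_protein(img, polys))
            protein_table = pd.concat(frames).loc[table.cells.index]
            protein_table.to_csv(out / "protein_cells.csv")
            try:
                per_roi, trend, thr = positivity_along_trajectory(
                    protein_table, labels, labeling.roi_id, pc1_per_roi)
                per_roi.to_csv(out / "protein_rois.csv")
                manifest["stages"]["protein"] = {
                    "threshold": thr, "curvature": trend.curvature,
                    "peak": trend.peak,
                }
            except GlomscapeError as e:
                manifest["stages"]["protein"] = {"error": str(e)}
        else:
            manifest["stages"]["protein"] = {"skipped": "no protein image"}

        # -- drugs -----------------------------------------------------------
        current = "drugs"
        from .drugs import score_drugs

        drug_table = datasets.load_drug_targets()
        ranked = {}
        for name in ("PDGF_SIGNALING", "TGFB_SIGNALING"):
            r = score_drugs(drug_table, sets[name],
                            min_score=config["drugs"].get("min_score", 0.1))
            r.to_csv(out / f"drugs_{name}.csv")
            ranked[name] = r.index.tolist()[:5]
        manifest["stages"]["drugs"] = {"top": ranked}

    except Exception as e:
        manifest["failed_stage"] = current
        manifest["error"] = str(e)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise

    manifest["parameters"] = {
        k: config[k] for k in ("qc", "classify", "niches", "trajectory",
                               "score", "interact", "protein", "drugs")
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _subset_truth(truth, cell_ids):
    from .synthetic import SyntheticTruth

    cells = truth.cells.loc[cell_ids]
    return SyntheticTruth(cells=cells, rois=truth.rois, samples=truth.samples)
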