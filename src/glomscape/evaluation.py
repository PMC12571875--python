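"""End-to-end recovery evaluations on synthetic cohorts.

These helpers run the full pipeline on freshly generated synthetic cohorts
and measure how well it recovers the generator's configured ground truth:
compartment composition medians, the severity trajectory, and the
pathway/proliferation dynamics along it.  They are used by the acceptance
script and by the integration tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from . import datasets
from .celltyping import (
    CellTypeClassifier,
    normalize_log1p,
    relabel_fibrotic_mesangial,
)
from .niches import (
    SpatialDomainAnnotator,
    assign_compartments,
    compartment_composition,
    fill_glomerulus_hulls,
    glomerular_clusters,
    instance_glomeruli,
    refine_glomerular_mask,
)
from .pathways import fibrosis_score, score_gene_set, trend_along_trajectory
from .protein import aggregate_protein, positivity_along_trajectory
from .synthetic import (
    CohortConfig,
    generate_cohort,
    generate_reference,
    render_protein_channel,
    truth_labeling,
)
from .trajectory import CrescentTrajectory, compute_pseudotime, pseudobulk_rois


def _annotate_cells(table, seed: int):
    """Reference-trained typing + niche pipeline with the package defaults."""
    ref_counts, ref_labels, ref_genes = generate_reference(
        CohortConfig(), n_per_type=200, seed=seed + 1)
    model = CellTypeClassifier(random_state=seed).fit(
        ref_counts, ref_labels, genes=ref_genes)
    labels, conf = model.predict_cells(table)

    domains = SpatialDomainAnnotator(k_neighbors=8, random_state=seed).fit_predict(table)
    mask = glomerular_clusters(table, domains)
    mask = refine_glomerular_mask(table, mask)
    glom_ids = instance_glomeruli(table, mask)
    glom_ids = fill_glomerulus_hulls(table, glom_ids)
    labeling = assign_compartments(table, glom_ids)

    norm = normalize_log1p(table.counts, 1000.0)
    fib = fibrosis_score(norm, table.gene_names)
    labels = relabel_fibrotic_mesangial(
        labels, fib.scores,
        in_glomerulus=labeling.compartment == "glomerular",
        is_control=table.cells["condition"].to_numpy() == "control",
    )
    return labels, labeling


def composition_recovery(seed: int, n_samples: int = 10,
                         conditions=("control", "anti-GBM")) -> pd.DataFrame:
    """Pipeline-recovered per-condition compartment composition medians (%).

    Generates ``n_samples`` samples per condition (4 glomeruli each, i.e.
    40 ROIs per condition at the default), runs cell typing, niche
    instancing, 100-µm compartment assignment and fibrotic-mesangial
    relabeling, and returns the median cell-type fractions in percent,
    indexed by (condition, compartment, cell_type).
    """
    cfg = CohortConfig(n_samples_per_condition={c: n_samples for c in conditions})
    table, _ = generate_cohort(cfg, seed=seed)
    labels, labeling = _annotate_cells(table, seed=seed)
    _, medians = compartment_composition(labeling, labels, table)
    out = medians.set_index(["condition", "compartment", "cell_type"])["fraction"]
    return 100.0 * out


def trajectory_recovery(seed: int) -> dict:
    """Spearman correlations of PC1 with latent severity and pseudotime on
    the default four-condition cohort (ground-truth ROI membership)."""
    table, truth = generate_cohort(CohortConfig(), seed=seed)
    labeling = truth_labeling(truth)
    _, norm, meta = pseudobulk_rois(table, labeling)
    traj = CrescentTrajectory().fit(norm, meta["condition"])
    sev = truth.rois["severity"].reindex(meta.index).to_numpy()
    pt = compute_pseudotime(norm, meta["condition"].to_numpy(), seed=seed)
    return {
        "spearman_pc1_severity": float(
            scipy.stats.spearmanr(traj.pc1_, sev).statistic),
        "spearman_pc1_pseudotime": float(
            scipy.stats.spearmanr(traj.pc1_, pt).statistic),
        "pc1": traj.pc1_, "meta": meta, "severity": sev,
        "table": table, "truth": truth, "labeling": labeling,
    }


def _normalized_pc1(pc1):
    return (pc1 - pc1.min()) / (pc1.max() - pc1.min())


def dynamics_recovery(seed: int) -> dict:
    """PDGF / TGFβ / Ki-67 dynamics along the recovered trajectory.

    Returns fitted quadratic curvatures and peak locations (normalized PC1)
    together with the expected peak: the normalized-PC1 position of latent
    severity 0.5, where the generator's hump-shaped programmes peak.
    """
    rec = trajectory_recovery(seed)
    table, truth, labeling = rec["table"], rec["truth"], rec["labeling"]
    pc1n = _normalized_pc1(rec["pc1"])
    pc1_per_roi = pd.Series(pc1n, index=rec["meta"].index)
    # reference peak: the generator's noiseless hump pushed through the same
    # quadratic estimator on the same axis, so the comparison isolates what
    # the pipeline adds (scores, thresholds, typing) from the quadratic
    # approximation of the severity-to-PC1 mapping itself
    from .pathways import quadratic_trend
    from .synthetic import hump

    expected_peak = float(quadratic_trend(pc1n, hump(rec["severity"])).peak)

    types = truth.cells["true_type"].to_numpy()
    rois = labeling.roi_id
    norm = normalize_log1p(table.counts, 1000.0)
    sets = datasets.load_gene_sets()

    pdgf = score_gene_set(norm, table.gene_names, sets["PDGF_SIGNALING"], "PDGF")
    pdgf_trend = trend_along_trajectory(pdgf.scores, types, "PEC", rois, pc1_per_roi)

    tgfb = score_gene_set(norm, table.gene_names, sets["TGFB_SIGNALING"], "TGFB")
    pec = types == "PEC"
    pec_pc1 = pd.Series(rois[pec]).map(pc1_per_roi).to_numpy(dtype=float)
    tgfb_rho = float(scipy.stats.spearmanr(tgfb.scores[pec], pec_pc1).statistic)

    cfg = CohortConfig()
    frames = []
    for sample in pd.unique(table.cells["sample_id"]):
        rows = (table.cells["sample_id"] == sample).to_numpy()
        sub = table.subset(rows)
        from .synthetic import SyntheticTruth

        sub_truth = SyntheticTruth(cells=truth.cells.loc[sub.cells.index],
                                   rois=truth.rois, samples=truth.samples)
        img, polys = render_protein_channel(sub, sub_truth, cfg,
                                            pixel_size_um=2.0, seed=seed)
        frames.append(aggregate_protein(img, polys))
    protein = pd.concat(frames).loc[table.cells.index]
    _, ki67_trend, _ = positivity_along_trajectory(protein, types, rois, pc1_per_roi)

    return {
        "expected_peak": expected_peak,
        "pdgf_curvature": pdgf_trend.curvature,
        "pdgf_peak": pdgf_trend.peak,
        "tgfb_spearman_pc1": tgfb_rho,
        "ki67_curvature": ki67_trend.curvature,
        "ki67_peak": ki67_trend.peak,
    }
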