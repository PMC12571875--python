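"""Synthetic kidney-tissue cohorts with known ground truth.

The generator emulates the geometric and compositional structure that the
downstream analysis assumes: circular glomerular niches embedded in
tubulointerstitial tissue, a periglomerular annulus of exactly 100 µm, and a
latent per-glomerulus severity ``s ∈ [0, 1]`` that drives parietal epithelial
cell (PEC) expansion, podocyte loss, the mesangial-to-fibrotic-mesangial
shift, immune infiltration, fibrosis-gene expression, a hump-shaped PDGF
pathway programme and a monotone-saturating TGFβ programme in PECs, and a
Ki-67-like protein channel.

Cell-type compositions default to the published per-condition compartment
medians (see :func:`glomscape.datasets.load_compositions`); severity
perturbations are centred on each condition's median severity so that the
across-glomerulus median composition stays at the configured value.  Counts
are negative-binomial with marker genes far above background, targeting the
characteristic shallow depth of imaging-based panels (median of roughly
35–40 transcripts per cell).

Everything is driven by a single integer seed: identical configuration and
seed reproduce the cohort bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from . import datasets
from .exceptions import GeometryError, ParameterError, ValidationError
from .io import SpatialCellTable

COMPARTMENTS = ("glomerular", "periglomerular", "tubulointerstitial")

#: Labels the classifier is trained on.  Fibrotic mesangial cells are a
#: disease state of mesangial cells; references label them "mesangial" and
#: the pipeline recovers them by fibrosis-score relabeling.
CLASSIFIER_TYPES = (
    "podocyte", "PEC", "mesangial", "endothelial", "proximal_tubule", "TAL",
    "collecting_duct", "fibroblast", "macrophage", "T_cell", "B_cell",
    "plasma_cell",
)
ALL_TYPES = CLASSIFIER_TYPES + ("fibrotic_mesangial",)


def hump(s):
    """Rise-then-fall severity profile, peaking at s = 0.5 with value 1."""
    s = np.asarray(s, dtype=float)
    return 4.0 * s * (1.0 - s)


def saturating(s, k: float = 0.3):
    """Monotone-saturating severity profile, 0 at s = 0."""
    s = np.asarray(s, dtype=float)
    return (s / (s + k)) / (1.0 / (1.0 + k))


@dataclass
class SeverityEffects:
    """Slopes and amplitudes tying latent severity to composition and
    expression.

    Composition slopes are fraction change per unit severity *deviation from
    the condition's median severity*; expression amplitudes are multiplicative
    (mean × (1 + amplitude × profile(s))).
    """

    pec_slope: float = 0.10
    podocyte_slope: float = -0.08
    mesangial_to_fibrotic: float = 0.08
    macrophage_slope: float = 0.03
    t_cell_slope: float = 0.03

    pec_pdgf_amplitude: float = 6.0       # hump-shaped
    pec_tgfb_amplitude: float = 6.0       # saturating
    pec_fibrosis_slope: float = 25.0      # linear
    pec_receptor_slope: float = 4.0       # PDGF receptors on PECs, linear
    pdgf_ligand_amplitude: float = 4.0    # EC/mesangial PDGF ligands, hump
    tgfb_ligand_slope: float = 4.0        # macrophage/mesangial TGFβ ligands, linear


@dataclass
class ProteinConfig:
    """Ki-67-like channel: PEC intensity rises then falls with severity."""

    channel: str = "Ki67"
    background_mean: float = 2.0          # off-cell pixel intensity
    cell_background: float = 8.0          # in-cell intensity, non-PEC
    pec_amplitude: float = 60.0           # added to cell_background × hump(s)
    cell_cv: float = 0.4                  # lognormal per-cell intensity spread
    noise_sd: float = 0.0                 # additive Gaussian pixel noise
    polygon_radius_um: float = 4.0        # regular-hexagon circumradius


@dataclass
class CohortConfig:
    """Full description of a synthetic cohort; defaults are the study
    conditions every packaged test and acceptance run uses."""

    n_samples_per_condition: dict = field(
        default_factory=lambda: {"control": 5, "SLE": 5, "ANCA-GN": 5, "anti-GBM": 5}
    )
    glomeruli_per_sample: int = 4
    glomerulus_radius_um: tuple = (90.0, 15.0)
    field_size_um: float = 1100.0
    periglomerular_width_um: float = 100.0
    #: cells per 1000 µm², per compartment
    cell_density: dict = field(
        default_factory=lambda: {
            "glomerular": 8.0, "periglomerular": 5.0, "tubulointerstitial": 4.5,
        }
    )
    composition: dict = field(default_factory=datasets.load_compositions)
    #: per-condition Beta(a, b) parameters of latent severity
    severity_beta: dict = field(
        default_factory=lambda: {
            "control": (1.5, 12.0), "SLE": (3.0, 5.0),
            "ANCA-GN": (4.0, 3.0), "anti-GBM": (6.0, 2.0),
        }
    )
    #: Dirichlet total concentration for between-glomerulus composition jitter
    dirichlet_concentration: float = 800.0
    background_mean: float = 0.03
    marker_mean: float = 4.0
    #: negative-binomial size parameter (np.inf → Poisson)
    dispersion: float = 10.0
    severity_effects: SeverityEffects = field(default_factory=SeverityEffects)
    protein: ProteinConfig = field(default_factory=ProteinConfig)
    n_slides: int = 2
    slide_gap_um: float = 300.0

    def validate(self) -> None:
        if self.glomerulus_radius_um[0] <= 0 or self.field_size_um <= 0:
            raise ParameterError("radius and field size must be positive")
        if any(d <= 0 for d in self.cell_density.values()):
            raise ParameterError("cell densities must be positive")
        for cond, comps in self.composition.items():
            for comp, mapping in comps.items():
                total = sum(mapping.values())
                if abs(total - 1.0) > 1e-6:
                    raise ValidationError(
                        f"composition for ({cond}, {comp}) sums to {total}, not 1"
                    )
                if any(v < 0 for v in mapping.values()):
                    raise ValidationError(f"negative fraction in ({cond}, {comp})")


@dataclass
class SyntheticTruth:
    """Ground truth for every generated cell, glomerulus and sample."""

    cells: pd.DataFrame        # index cell_id: true_type, true_compartment, true_glomerulus_id
    rois: pd.DataFrame         # index roi_id: sample_id, condition, severity, cx, cy, radius
    samples: pd.DataFrame      # index sample_id: condition, slide_id, mean_severity


# ---------------------------------------------------------------------------
# expression model
# ---------------------------------------------------------------------------

def build_type_means(config: CohortConfig) -> tuple[list[str], dict[str, np.ndarray]]:
    """Per-type mean count vectors over the packaged panel (severity 0)."""
    panel = datasets.load_gene_panel()
    genes = panel["gene"].tolist()
    gidx = {g: i for i, g in enumerate(genes)}
    sets = datasets.load_gene_sets()
    markers = datasets.marker_genes()

    means: dict[str, np.ndarray] = {}
    for t in CLASSIFIER_TYPES:
        mu = np.full(len(genes), config.background_mean)
        mu[[gidx[g] for g in markers[t]]] = config.marker_mean
        means[t] = mu

    fib = [gidx[g] for g in sets["FIBROSIS"]]
    # fibrotic mesangial: mesangial programme plus a strong ECM signature
    fmc = means["mesangial"].copy()
    fmc[fib] = 3.0
    means["fibrotic_mesangial"] = fmc
    # fibroblasts constitutively make some matrix
    means["fibroblast"][fib] = 1.0

    pdgf = [gidx[g] for g in sets["PDGF_SIGNALING"]]
    tgfb = [gidx[g] for g in sets["TGFB_SIGNALING"]]
    # PEC baseline pathway tone (severity multiplies this)
    means["PEC"][pdgf] = np.maximum(means["PEC"][pdgf], 0.05)
    means["PEC"][tgfb] = np.maximum(means["PEC"][tgfb], 0.05)
    # ligand baselines for the communication analysis
    lig_pdgf = [gidx[g] for g in ("PDGFA", "PDGFB", "PDGFC", "PDGFD")]
    for t in ("endothelial", "mesangial", "fibrotic_mesangial"):
        means[t][lig_pdgf] = 0.08
    lig_tgfb = [gidx[g] for g in ("TGFB1", "TGFB2", "TGFB3")]
    for t in ("macrophage", "mesangial", "fibrotic_mesangial"):
        means[t][lig_tgfb] = 0.08
    return genes, means


def _severity_multiplier(cell_type: str, s: float, config: CohortConfig,
                         gidx: dict[str, int], n_genes: int) -> np.ndarray:
    """Gene-wise multiplicative severity effect for one cell."""
    eff = config.severity_effects
    sets = datasets.load_gene_sets()
    mult = np.ones(n_genes)
    fib = [gidx[g] for g in sets["FIBROSIS"]]
    if cell_type == "PEC":
        # receptor/effector arm only: PECs receive PDGF, they do not secrete it
        pdgf = [gidx[g] for g in sets["PDGF_SIGNALING"]
                if g not in ("PDGFA", "PDGFB", "PDGFC", "PDGFD")]
        tgfb = [gidx[g] for g in sets["TGFB_SIGNALING"]]
        mult[pdgf] *= 1.0 + eff.pec_pdgf_amplitude * float(hump(s))
        mult[tgfb] *= 1.0 + eff.pec_tgfb_amplitude * float(saturating(s))
        mult[fib] *= 1.0 + eff.pec_fibrosis_slope * s
        rec = [gidx["PDGFRA"], gidx["PDGFRB"]]
        mult[rec] *= 1.0 + eff.pec_receptor_slope * s
    elif cell_type in ("endothelial", "mesangial", "fibrotic_mesangial"):
        lig = [gidx[g] for g in ("PDGFA", "PDGFB", "PDGFC", "PDGFD")]
        mult[lig] *= 1.0 + eff.pdgf_ligand_amplitude * float(hump(s))
    if cell_type in ("macrophage", "mesangial", "fibrotic_mesangial"):
        lig = [gidx[g] for g in ("TGFB1", "TGFB2", "TGFB3")]
        mult[lig] *= 1.0 + eff.tgfb_ligand_slope * s
    if cell_type == "fibrotic_mesangial":
        mult[fib] *= 1.0 + 2.0 * s
    return mult


def expected_expression(cell_type: str, severity: float, config: CohortConfig) -> np.ndarray:
    """Analytic per-gene mean counts for a cell of ``cell_type`` at severity."""
    genes, means = build_type_means(config)
    if cell_type not in means:
        raise KeyError(f"unknown cell type {cell_type!r}")
    gidx = {g: i for i, g in enumerate(genes)}
    return means[cell_type] * _severity_multiplier(cell_type, severity, config, gidx, len(genes))


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    """Negative-binomial draws with mean mu and size theta (Poisson if inf)."""
    if not np.isfinite(theta):
        return rng.poisson(mu)
    p = theta / (theta + mu)
    return rng.negative_binomial(theta, p)


def sample_expression(cell_type: str, severity: float, config: CohortConfig,
                      rng: np.random.Generator) -> np.ndarray:
    """Draw one cell's count vector."""
    mu = expected_expression(cell_type, severity, config)
    return _nb_draw(rng, mu, config.dispersion)


def _sample_counts_batch(types, severities, genes, means, config, rng) -> sp.csr_matrix:
    """Vectorised count sampling for many cells (grouped by type)."""
    gidx = {g: i for i, g in enumerate(genes)}
    n, G = len(types), len(genes)
    out = sp.lil_matrix((n, G), dtype=np.int64)
    types = np.asarray(types)
    severities = np.asarray(severities, dtype=float)
    for t in np.unique(types):
        rows = np.flatnonzero(types == t)
        base = means[t]
        # multipliers vary with s; quantize severity to limit the loop
        for i in rows:
            mu = base * _severity_multiplier(t, severities[i], config, gidx, G)
            out[i] = _nb_draw(rng, mu, config.dispersion)
    return sp.csr_matrix(out)


def _sample_counts_fast(types, severities, genes, means, config, rng) -> sp.csr_matrix:
    """Same distribution as :func:`_sample_counts_batch` but vectorised over
    cells: multipliers are built per type from closed-form profiles."""
    gidx = {g: i for i, g in enumerate(genes)}
    sets = datasets.load_gene_sets()
    eff = config.severity_effects
    n, G = len(types), len(genes)
    types = np.asarray(types)
    s = np.asarray(severities, dtype=float)
    blocks = []
    order = []
    for t in np.unique(types):
        rows = np.flatnonzero(types == t)
        mu = np.tile(means[t], (len(rows), 1))
        st = s[rows]
        fib = [gidx[g] for g in sets["FIBROSIS"]]
        if t == "PEC":
            pdgf = [gidx[g] for g in sets["PDGF_SIGNALING"]
                    if g not in ("PDGFA", "PDGFB", "PDGFC", "PDGFD")]
            tgfb = [gidx[g] for g in sets["TGFB_SIGNALING"]]
            mu[:, pdgf] *= (1.0 + eff.pec_pdgf_amplitude * hump(st))[:, None]
            mu[:, tgfb] *= (1.0 + eff.pec_tgfb_amplitude * saturating(st))[:, None]
            mu[:, fib] *= (1.0 + eff.pec_fibrosis_slope * st)[:, None]
            mu[:, [gidx["PDGFRA"], gidx["PDGFRB"]]] *= (1.0 + eff.pec_receptor_slope * st)[:, None]
        elif t in ("endothelial", "mesangial", "fibrotic_mesangial"):
            lig = [gidx[g] for g in ("PDGFA", "PDGFB", "PDGFC", "PDGFD")]
            mu[:, lig] *= (1.0 + eff.pdgf_ligand_amplitude * hump(st))[:, None]
        if t in ("macrophage", "mesangial", "fibrotic_mesangial"):
            lig = [gidx[g] for g in ("TGFB1", "TGFB2", "TGFB3")]
            mu[:, lig] *= (1.0 + eff.tgfb_ligand_slope * st)[:, None]
        if t == "fibrotic_mesangial":
            mu[:, fib] *= (1.0 + 2.0 * st)[:, None]
        blocks.append(sp.csr_matrix(_nb_draw(rng, mu, config.dispersion)))
        order.append(rows)
    counts = sp.vstack(blocks, format="csr")
    perm = np.empty(n, dtype=int)
    perm[np.concatenate(order)] = np.arange(n)
    return counts[perm]


# ---------------------------------------------------------------------------
# geometry and composition
# ---------------------------------------------------------------------------

def _place_glomeruli(config: CohortConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    """Non-overlapping disc centres and radii; rings fit inside the field."""
    n = config.glomeruli_per_sample
    mean_r, sd_r = config.glomerulus_radius_um
    field_sz = config.field_size_um
    radii = np.clip(rng.normal(mean_r, sd_r, size=n), 0.45 * mean_r, 1.6 * mean_r)
    centers = np.zeros((n, 2))
    for i in range(n):
        margin = radii[i] + config.periglomerular_width_um + 10.0
        if 2 * margin >= field_sz:
            raise GeometryError("field too small for glomerulus plus its annulus")
        ok = False
        for _ in range(5000):
            c = rng.uniform(margin, field_sz - margin, size=2)
            d = np.hypot(*(centers[:i] - c).T) if i else np.array([])
            if np.all(d >= radii[:i] + radii[i] + 100.0):
                centers[i] = c
                ok = True
                break
        if not ok:
            raise GeometryError(
                "could not place non-overlapping glomeruli; increase field_size_um"
            )
    return centers, radii


def _adjust_composition(comp: dict, compartment: str, s: float, s_med: float,
                        eff: SeverityEffects) -> np.ndarray:
    """Severity-shifted type fractions (ordered as ALL_TYPES), centred so that
    at the condition's median severity the configured fractions are returned."""
    p = np.array([comp.get(t, 0.0) for t in ALL_TYPES], dtype=float)
    ds = s - s_med
    ti = {t: i for i, t in enumerate(ALL_TYPES)}
    if compartment == "glomerular":
        p[ti["PEC"]] = max(p[ti["PEC"]] + eff.pec_slope * ds, 1e-6)
        p[ti["podocyte"]] = max(p[ti["podocyte"]] + eff.podocyte_slope * ds, 1e-6)
        transfer = np.clip(eff.mesangial_to_fibrotic * ds,
                           -p[ti["fibrotic_mesangial"]] + 1e-6,
                           p[ti["mesangial"]] - 1e-6)
        p[ti["mesangial"]] -= transfer
        p[ti["fibrotic_mesangial"]] += transfer
        p[ti["macrophage"]] = max(p[ti["macrophage"]] + eff.macrophage_slope * ds, 1e-6)
    else:
        p[ti["T_cell"]] = max(p[ti["T_cell"]] + eff.t_cell_slope * ds, 1e-6)
    return p / p.sum()


def _draw_types(p: np.ndarray, n: int, concentration: float, rng) -> np.ndarray:
    """Draw n cell types from a Dirichlet-jittered composition."""
    alive = p > 0
    alpha = np.maximum(p[alive] * concentration, 1e-3)
    q = rng.dirichlet(alpha)
    labels = np.array(ALL_TYPES, dtype=object)[alive]
    return rng.choice(labels, size=n, p=q)


def _hexagon(cx: float, cy: float, r: float) -> np.ndarray:
    ang = np.arange(6) * (math.pi / 3.0)
    return np.column_stack([cx + r * np.cos(ang), cy + r * np.sin(ang)])


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig | None = None, seed: int = 0,
                    *, with_polygons: bool = False
                    ) -> tuple[SpatialCellTable, SyntheticTruth]:
    """Generate a full synthetic cohort.

    Returns the cell table (coordinates laid out per slide, samples tiled
    left to right with a gap) and the ground truth.  Deterministic given
    ``(config, seed)``.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    genes, means = build_type_means(config)
    eff = config.severity_effects

    s_medians = {
        cond: float(scipy.stats.beta(a, b).median())
        for cond, (a, b) in config.severity_beta.items()
    }

    cell_rows = []      # dicts of metadata
    cell_types = []
    cell_sev = []
    roi_rows = []
    sample_rows = []
    count_blocks = []

    sample_ids = []
    for cond, n_samp in config.n_samples_per_condition.items():
        for k in range(n_samp):
            sample_ids.append((f"{cond.replace(' ', '')}_{k:02d}", cond))

    slide_of = {sid: f"slide{(i % config.n_slides) + 1}" for i, (sid, _) in enumerate(sample_ids)}
    slide_cursor = {f"slide{j + 1}": 0.0 for j in range(config.n_slides)}

    roi_counter = 0
    fs = config.field_size_um
    for sample_id, cond in sample_ids:
        slide = slide_of[sample_id]
        x_off = slide_cursor[slide]
        slide_cursor[slide] += fs + config.slide_gap_um

        centers, radii = _place_glomeruli(config, rng)
        a, b = config.severity_beta[cond]
        severities = rng.beta(a, b, size=len(centers))
        s_med = s_medians[cond]
        sample_mean_s = float(np.mean(severities))

        stypes, ssev, sxy, scomp, sglom = [], [], [], [], []

        for gi, ((cx, cy), r, s) in enumerate(zip(centers, radii, severities)):
            roi_id = roi_counter
            roi_counter += 1
            roi_rows.append(dict(roi_id=roi_id, sample_id=sample_id, condition=cond,
                                 severity=float(s), cx=cx + x_off, cy=cy, radius=r))
            # glomerular core
            area = math.pi * r * r
            n_g = rng.poisson(config.cell_density["glomerular"] * area / 1000.0)
            rad = r * np.sqrt(rng.uniform(size=n_g))
            th = rng.uniform(0, 2 * math.pi, size=n_g)
            xy = np.column_stack([cx + rad * np.cos(th), cy + rad * np.sin(th)])
            p = _adjust_composition(config.composition[cond]["glomerular"],
                                    "glomerular", s, s_med, eff)
            t = _draw_types(p, n_g, config.dirichlet_concentration, rng)
            stypes.append(t); ssev.append(np.full(n_g, s)); sxy.append(xy)
            scomp.append(np.full(n_g, "glomerular", dtype=object))
            sglom.append(np.full(n_g, roi_id))
            # periglomerular annulus (exactly (r, r + width])
            w = config.periglomerular_width_um
            area_ring = math.pi * ((r + w) ** 2 - r ** 2)
            n_p = rng.poisson(config.cell_density["periglomerular"] * area_ring / 1000.0)
            rad = np.sqrt(rng.uniform(r ** 2, (r + w) ** 2, size=n_p))
            rad = np.maximum(rad, np.nextafter(r, np.inf))  # strictly outside the core
            th = rng.uniform(0, 2 * math.pi, size=n_p)
            xy = np.column_stack([cx + rad * np.cos(th), cy + rad * np.sin(th)])
            # keep ring cells inside the field and outside every other core
            keep = (xy >= 0).all(axis=1) & (xy <= fs).all(axis=1)
            for gj, ((ox, oy), orr) in enumerate(zip(centers, radii)):
                if gj != gi:
                    keep &= np.hypot(xy[:, 0] - ox, xy[:, 1] - oy) > orr
            xy = xy[keep]
            n_p = len(xy)
            p = _adjust_composition(config.composition[cond]["periglomerular"],
                                    "periglomerular", s, s_med, eff)
            t = _draw_types(p, n_p, config.dirichlet_concentration, rng)
            stypes.append(t); ssev.append(np.full(n_p, s)); sxy.append(xy)
            scomp.append(np.full(n_p, "periglomerular", dtype=object))
            sglom.append(np.full(n_p, roi_id))

        # tubulointerstitial background: uniform, outside every annulus
        n_t = rng.poisson(config.cell_density["tubulointerstitial"] * fs * fs / 1000.0)
        xy = rng.uniform(0, fs, size=(n_t, 2))
        keep = np.ones(n_t, dtype=bool)
        for (cx, cy), r in zip(centers, radii):
            keep &= np.hypot(xy[:, 0] - cx, xy[:, 1] - cy) > r + config.periglomerular_width_um
        xy = xy[keep]
        n_t = len(xy)
        p = _adjust_composition(config.composition[cond]["tubulointerstitial"],
                                "tubulointerstitial", sample_mean_s, s_med, eff)
        t = _draw_types(p, n_t, config.dirichlet_concentration, rng)
        stypes.append(t); ssev.append(np.full(n_t, sample_mean_s)); sxy.append(xy)
        scomp.append(np.full(n_t, "tubulointerstitial", dtype=object))
        sglom.append(np.full(n_t, -1))

        types = np.concatenate(stypes)
        sev = np.concatenate(ssev)
        xy = np.vstack(sxy)
        comp = np.concatenate(scomp)
        glom = np.concatenate(sglom)
        count_blocks.append(_sample_counts_fast(types, sev, genes, means, config, rng))
        for i in range(len(types)):
            cell_rows.append(dict(
                cell_id=f"{sample_id}_c{i:05d}",
                x_um=xy[i, 0] + x_off, y_um=xy[i, 1],
                slide_id=slide, sample_id=sample_id, patient_id=sample_id,
                condition=cond,
                true_type=types[i], true_compartment=comp[i],
                true_glomerulus_id=int(glom[i]),
            ))
        cell_types.append(types)
        cell_sev.append(sev)
        sample_rows.append(dict(sample_id=sample_id, condition=cond,
                                slide_id=slide, mean_severity=sample_mean_s))

    cells = pd.DataFrame(cell_rows).set_index("cell_id")
    counts = sp.vstack(count_blocks, format="csr")
    truth_cells = cells[["true_type", "true_compartment", "true_glomerulus_id"]].copy()
    truth_cells["severity"] = np.concatenate(cell_sev)
    table_cells = cells.drop(columns=["true_type", "true_compartment", "true_glomerulus_id"])

    polygons = None
    if with_polygons:
        r_hex = config.protein.polygon_radius_um
        polygons = {
            cid: _hexagon(x, y, r_hex)
            for cid, x, y in zip(cells.index, cells["x_um"], cells["y_um"])
        }

    table = SpatialCellTable(table_cells, counts, genes, polygons)
    truth = SyntheticTruth(
        cells=truth_cells,
        rois=pd.DataFrame(roi_rows).set_index("roi_id"),
        samples=pd.DataFrame(sample_rows).set_index("sample_id"),
    )
    return table, truth


def truth_labeling(truth: SyntheticTruth):
    """Ground-truth :class:`~glomscape.niches.DomainLabeling` (for tests of
    downstream stages in isolation from the niche-recovery pipeline)."""
    from .niches import DomainLabeling

    cells = pd.DataFrame(index=truth.cells.index)
    cells["domain_cluster"] = -1
    cells["compartment"] = truth.cells["true_compartment"].to_numpy()
    cells["glomerulus_id"] = truth.cells["true_glomerulus_id"].to_numpy()
    cells["roi_id"] = np.where(cells["compartment"] != "tubulointerstitial",
                               cells["glomerulus_id"], -1)
    return DomainLabeling(cells)


def generate_reference(config: CohortConfig | None = None, n_per_type: int = 200,
                       seed: int = 0) -> tuple[sp.csr_matrix, np.ndarray, list[str]]:
    """Labelled reference profiles for classifier training.

    Cells are drawn at severity 0 for each classifier label (fibrotic
    mesangial cells are labelled "mesangial", as a dissociated reference
    atlas would).
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(seed)
    genes, means = build_type_means(config)
    types = np.repeat(np.array(CLASSIFIER_TYPES, dtype=object), n_per_type)
    # a realistic atlas also contains injured mesangial cells with an ECM
    # programme; they carry the "mesangial" label
    extra = np.full(max(n_per_type // 4, 1), "fibrotic_mesangial", dtype=object)
    sev = np.concatenate([np.zeros(len(types)), rng.uniform(0.3, 0.9, len(extra))])
    counts = _sample_counts_fast(np.concatenate([types, extra]), sev, genes, means,
                                 config, rng)
    labels = np.concatenate([types, np.full(len(extra), "mesangial", dtype=object)])
    return counts, labels, genes


def generate_clinical(truth: SyntheticTruth, seed: int = 0) -> pd.DataFrame:
    """Clinical covariates driven by per-patient mean severity.

    eGFR falls with severity (inverse correlation with disease), albuminuria
    rises; age is independent.  ANCA renal risk is the severity tertile among
    ANCA-GN patients.
    """
    rng = np.random.default_rng(seed)
    samples = truth.samples
    s = samples["mean_severity"].to_numpy()
    egfr = np.clip(110.0 * (1.0 - s) + rng.normal(0, 8.0, len(s)), 5.0, 130.0)
    alb = np.clip(2500.0 * s + rng.normal(0, 150.0, len(s)), 1.0, None)
    age = np.clip(rng.normal(55.0, 12.0, len(s)), 18.0, 90.0)
    df = pd.DataFrame({
        "eGFR": egfr, "albuminuria": alb, "age": age,
    }, index=samples.index.rename("patient_id"))
    df["anca_risk"] = pd.NA
    anca = samples["condition"] == "ANCA-GN"
    if anca.sum() >= 3:
        terciles = np.quantile(s[anca], [1 / 3, 2 / 3])
        lab = np.where(s[anca] <= terciles[0], "low",
                       np.where(s[anca] <= terciles[1], "medium", "high"))
        df.loc[anca.to_numpy(), "anca_risk"] = lab
    return df


# ---------------------------------------------------------------------------
# protein channel
# ---------------------------------------------------------------------------

def protein_cell_intensity(truth: SyntheticTruth, config: CohortConfig,
                           rng: np.random.Generator | None = None) -> pd.Series:
    """Model per-cell protein intensity (before rasterisation).

    PECs follow ``cell_background + pec_amplitude × hump(s)`` with optional
    lognormal cell-to-cell spread; every other type sits at the cell
    background level (severity slope 0).
    """
    pc = config.protein
    base = np.full(len(truth.cells), pc.cell_background)
    is_pec = (truth.cells["true_type"] == "PEC").to_numpy()
    s = truth.cells["severity"].to_numpy()
    base[is_pec] += pc.pec_amplitude * hump(s[is_pec])
    if rng is not None and pc.cell_cv > 0:
        sigma = math.sqrt(math.log(1.0 + pc.cell_cv ** 2))
        base = base * rng.lognormal(-sigma ** 2 / 2.0, sigma, size=len(base))
    return pd.Series(base, index=truth.cells.index, name=pc.channel)


def render_protein_channel(table: SpatialCellTable, truth: SyntheticTruth,
                           config: CohortConfig, pixel_size_um: float = 2.0,
                           seed: int = 0, *, max_pixels: int = 4096):
    """Rasterise the Ki-67-like channel over the cohort's coordinate frame.

    Each cell's regular-hexagon polygon is filled with its model intensity
    (pixels whose centres fall inside the polygon); background pixels carry
    ``background_mean`` and optional Gaussian noise is added everywhere.
    Returns ``(ProteinImage, polygons)``.
    """
    from .protein import ProteinImage, rasterize_polygon

    if pixel_size_um <= 0:
        raise ParameterError("pixel_size_um must be positive")
    pc = config.protein
    rng = np.random.default_rng(seed)
    xy = table.xy
    x0, y0 = xy.min(axis=0) - 3 * pc.polygon_radius_um
    x1, y1 = xy.max(axis=0) + 3 * pc.polygon_radius_um
    nx = int(np.ceil((x1 - x0) / pixel_size_um))
    ny = int(np.ceil((y1 - y0) / pixel_size_um))
    if nx > max_pixels or ny > max_pixels:
        raise ParameterError(
            f"image would be {ny}×{nx} pixels (cap {max_pixels}); "
            "use a larger pixel size or a smaller cohort"
        )
    grid = np.full((ny, nx), float(pc.background_mean))
    intensities = protein_cell_intensity(truth, config, rng if pc.cell_cv > 0 else None)
    polygons = table.polygons or {
        cid: _hexagon(x, y, pc.polygon_radius_um)
        for cid, x, y in zip(table.cells.index, table.cells["x_um"], table.cells["y_um"])
    }
    for cid, poly in polygons.items():
        rr, cc = rasterize_polygon(poly, origin=(x0, y0), pixel_size=pixel_size_um,
                                   shape=grid.shape)
        grid[rr, cc] = intensities[cid]
    if pc.noise_sd > 0:
        grid = np.maximum(grid + rng.normal(0, pc.noise_sd, size=grid.shape), 0.0)
    image = ProteinImage(grid=grid, pixel_size_um=pixel_size_um,
                         channel=pc.channel, origin_um=(float(x0), float(y0)))
    return image, polygons
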