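"""Spatially constrained ligand–receptor communication.

A deliberately simple, fully specified model of cell–cell signaling: for an
ordered pair of cell types (S, T) and an interaction, the communication
probability is ``h(L̄) · h(R̄) · π`` where ``L̄`` and ``R̄`` are trimmed
(truncated) means of ligand expression over S cells and receptor expression
over T cells, ``π`` is the fraction of (S, T) cell pairs within the
interaction range (250 µm for secreted signaling, 10 µm for contact), and
``h(u) = u / (0.5 + u)`` is a half-saturating response on the
log-normalized expression scale.  Hard range truncation replaces the
diffusion-style distance weighting of full-featured interaction tools, and
the fixed half-saturation replaces their fitted mass-action response; both
constants are configurable.  Significance comes from permutations of the
cell-type labels within each slide.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .celltyping import normalize_log1p
from .exceptions import ParameterError, SchemaError, ValidationError
from .io import SpatialCellTable


@dataclass
class InteractionConfig:
    interaction_range_um: float = 250.0   # secreted signaling
    contact_range_um: float = 10.0        # contact signaling
    trim: float = 0.1
    n_permutations: int = 100
    alpha: float = 0.05
    min_cells_per_type: int = 10
    half_saturation: float = 0.5
    target_sum: float = 1000.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.trim < 0.5):
            raise ParameterError("trim must be in [0, 0.5)")
        if self.interaction_range_um <= 0 or self.contact_range_um <= 0:
            raise ParameterError("ranges must be positive")


@dataclass
class CommunicationNetwork:
    """Per (source, target, interaction) probabilities and p-values."""

    edges: pd.DataFrame          # source, target, interaction_id, pathway, category, prob[, pvalue]
    cell_types: list[str]
    condition: str | None = None

    def aggregated(self, alpha: float = 0.05) -> pd.DataFrame:
        """Source × target weight matrix: sum of significant probabilities.

        If p-values are absent, all edges count.
        """
        e = self.edges
        if "pvalue" in e.columns and e["pvalue"].notna().any():
            e = e[e["pvalue"] <= alpha]
        mat = pd.DataFrame(0.0, index=self.cell_types, columns=self.cell_types)
        if len(e):
            agg = e.groupby(["source", "target"])["prob"].sum()
            for (s, t), v in agg.items():
                mat.loc[s, t] = v
        return mat


def read_lr_database(path) -> pd.DataFrame:
    """Read the ligand–receptor CSV; multi-gene sides are ';'-joined."""
    df = pd.read_csv(path)
    required = {"interaction_id", "ligand_genes", "receptor_genes", "pathway", "category"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"LR database is missing column(s): {sorted(missing)}")
    for col in ("ligand_genes", "receptor_genes"):
        df[col] = df[col].astype(str).str.split(";")
        if df[col].map(lambda gs: any(not g for g in gs)).any():
            raise ValidationError(f"empty gene name in {col}")
    if (df["pathway"].astype(str).str.len() == 0).any():
        raise ValidationError("pathway names must be nonempty")
    bad = set(df["category"]) - {"secreted", "contact"}
    if bad:
        raise ValidationError(f"unknown interaction category: {sorted(bad)}")
    return df


def apply_slide_offsets(table: SpatialCellTable,
                        interaction_range_um: float = 250.0,
                        gap_factor: float = 10.0) -> SpatialCellTable:
    """Lay slides out left to right so cross-slide distances exceed any
    interaction range.

    Slide i+1 starts at ``max x of slide i + gap_factor × interaction_range``;
    y is unchanged, so within-slide distances are preserved exactly.
    """
    if gap_factor * interaction_range_um <= 0:
        raise ParameterError("gap_factor × interaction_range must be positive")
    cells = table.cells.copy()
    slides = sorted(cells["slide_id"].unique())
    cursor = None
    for slide in slides:
        rows = cells["slide_id"] == slide
        x = cells.loc[rows, "x_um"]
        if cursor is not None:
            cells.loc[rows, "x_um"] = x - x.min() + cursor + gap_factor * interaction_range_um
        cursor = cells.loc[rows, "x_um"].max()
    return SpatialCellTable(cells, table.counts, table.gene_names, table.polygons)


def truncated_mean(values, trim: float = 0.1) -> float:
    """Mean after dropping floor(trim·n) values from each tail."""
    values = np.sort(np.asarray(values, dtype=float))
    if values.size == 0:
        raise ParameterError("truncated_mean of an empty sequence")
    if not (0 <= trim < 0.5):
        raise ParameterError("trim must be in [0, 0.5)")
    k = math.floor(trim * values.size)
    core = values[k: values.size - k] if k else values
    return float(core.mean())


# ---------------------------------------------------------------------------
# probability model
# ---------------------------------------------------------------------------

def _gene_expression(norm, gene_names, genes) -> np.ndarray | None:
    """Per-cell geometric mean of log-normalized expression across genes."""
    lookup = {g: i for i, g in enumerate(gene_names)}
    try:
        idx = [lookup[g] for g in genes]
    except KeyError:
        return None
    X = norm[:, idx]
    X = X.toarray() if sp.issparse(X) else np.asarray(X)
    return np.exp(np.log(X + 1e-12).mean(axis=1)) if X.shape[1] > 1 else X[:, 0]


def pair_proximity(xy, labels, source: str, target: str, range_um: float,
                   slide_ids=None) -> float:
    """Fraction of ordered (source, target) cell pairs within ``range_um``.

    Computed per slide (cells on different slides never pair) and pooled by
    cell-pair count.  Pairs of a cell with itself are excluded when
    source == target.
    """
    xy = np.asarray(xy, dtype=float)
    labels = np.asarray(labels, dtype=object)
    slide_ids = (np.zeros(len(xy)) if slide_ids is None
                 else np.asarray(slide_ids, dtype=object))
    within = total = 0
    for slide in pd.unique(slide_ids):
        rows = slide_ids == slide
        s_xy = xy[rows & (labels == source)]
        t_xy = xy[rows & (labels == target)]
        if len(s_xy) == 0 or len(t_xy) == 0:
            continue
        n_pairs = len(s_xy) * len(t_xy) - (len(s_xy) if source == target else 0)
        if n_pairs <= 0:
            continue
        cnt = cKDTree(s_xy).count_neighbors(cKDTree(t_xy), range_um)
        if source == target:
            cnt -= len(s_xy)  # self-pairs at distance 0
        within += cnt
        total += n_pairs
    return within / total if total else 0.0


def _saturate(u, k: float) -> float:
    return float(u) / (k + float(u)) if u > 0 else 0.0


def communication_probability(table: SpatialCellTable, lr_db: pd.DataFrame,
                              config: InteractionConfig | None = None,
                              cell_type_col: str = "cell_type",
                              condition: str | None = None) -> CommunicationNetwork:
    """Communication probabilities for every interaction and type pair.

    The table should already have slide offsets applied when it spans
    multiple slides.  Type pairs where either side has fewer than
    ``min_cells_per_type`` cells score zero and are omitted.
    """
    config = config or InteractionConfig()
    if cell_type_col not in table.cells.columns:
        raise SchemaError(f"table has no {cell_type_col!r} column")
    labels = table.cells[cell_type_col].to_numpy(dtype=object)
    norm = normalize_log1p(table.counts, config.target_sum)
    counts = pd.Series(labels).value_counts()
    types = sorted(counts.index[counts >= config.min_cells_per_type])
    xy, slides = table.xy, table.cells["slide_id"].to_numpy(dtype=object)

    rows = []
    prox_cache: dict = {}  # (source, target, radius) -> pi
    for _, inter in lr_db.iterrows():
        lig = _gene_expression(norm, table.gene_names, inter["ligand_genes"])
        rec = _gene_expression(norm, table.gene_names, inter["receptor_genes"])
        if lig is None or rec is None:
            warnings.warn(
                f"interaction {inter['interaction_id']} skipped: gene(s) absent from panel"
            )
            continue
        rng_um = (config.interaction_range_um if inter["category"] == "secreted"
                  else config.contact_range_um)
        for s in types:
            lbar = truncated_mean(lig[labels == s], config.trim)
            if lbar == 0:
                continue
            hl = _saturate(lbar, config.half_saturation)
            for t in types:
                rbar = truncated_mean(rec[labels == t], config.trim)
                if rbar == 0:
                    continue
                key = (s, t, rng_um)
                if key not in prox_cache:
                    prox_cache[key] = pair_proximity(xy, labels, s, t, rng_um, slides)
                pi = prox_cache[key]
                prob = hl * _saturate(rbar, config.half_saturation) * pi
                rows.append(dict(source=s, target=t,
                                 interaction_id=inter["interaction_id"],
                                 pathway=inter["pathway"],
                                 category=inter["category"], prob=prob))
    edges = pd.DataFrame(rows, columns=["source", "target", "interaction_id",
                                        "pathway", "category", "prob"])
    return CommunicationNetwork(edges=edges, cell_types=types, condition=condition)


def permutation_significance(table: SpatialCellTable, lr_db: pd.DataFrame,
                             network: CommunicationNetwork,
                             config: InteractionConfig | None = None,
                             cell_type_col: str = "cell_type") -> CommunicationNetwork:
    """Permutation p-values: labels permuted within each slide, probabilities
    recomputed; p = (1 + #{perm >= observed}) / (1 + n_permutations)."""
    config = config or InteractionConfig()
    if config.n_permutations < 20:
        raise ParameterError("need at least 20 permutations")
    rng = np.random.default_rng(config.seed)
    slides = table.cells["slide_id"].to_numpy(dtype=object)
    base_labels = table.cells[cell_type_col].to_numpy(dtype=object)

    key = ["source", "target", "interaction_id"]
    observed = network.edges.set_index(key)["prob"]
    exceed = pd.Series(0, index=observed.index, dtype=int)
    shuffled = table.cells.copy()
    for _ in range(config.n_permutations):
        perm = base_labels.copy()
        for slide in pd.unique(slides):
            rows = np.flatnonzero(slides == slide)
            perm[rows] = perm[rng.permutation(rows)]
        shuffled[cell_type_col] = perm
        perm_table = SpatialCellTable(shuffled, table.counts, table.gene_names)
        net_p = communication_probability(perm_table, lr_db, config,
                                          cell_type_col=cell_type_col)
        pp = net_p.edges.set_index(key)["prob"].astype(float).reindex(observed.index).fillna(0.0)
        exceed += (pp >= observed).astype(int)
    pvals = (1 + exceed) / (1 + config.n_permutations)
    edges = network.edges.copy()
    edges["pvalue"] = pvals.to_numpy()
    return CommunicationNetwork(edges=edges, cell_types=network.cell_types,
                                condition=network.condition)


# ---------------------------------------------------------------------------
# comparisons
# ---------------------------------------------------------------------------

def differential_network(network_disease: CommunicationNetwork,
                         network_control: CommunicationNetwork,
                         alpha: float = 0.05) -> pd.DataFrame:
    """Disease-minus-control matrix of aggregated significant weights.

    Types missing from one network are padded with zeros.
    """
    types = sorted(set(network_disease.cell_types) | set(network_control.cell_types))
    a = network_disease.aggregated(alpha).reindex(index=types, columns=types, fill_value=0.0)
    b = network_control.aggregated(alpha).reindex(index=types, columns=types, fill_value=0.0)
    return a - b


def incoming_signals(networks: dict[str, CommunicationNetwork], target_type: str,
                     alpha: float = 0.05) -> pd.DataFrame:
    """All significant incoming interactions to one target type, across
    conditions, sorted by probability (descending)."""
    frames = []
    for cond, net in networks.items():
        e = net.edges
        e = e[e["target"] == target_type]
        if "pvalue" in e.columns and e["pvalue"].notna().any():
            e = e[e["pvalue"] <= alpha]
        e = e.assign(condition=cond)
        frames.append(e[["condition", "source", "interaction_id", "pathway", "prob"]])
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["condition", "source", "interaction_id", "pathway", "prob"])
    return out.sort_values("prob", ascending=False, ignore_index=True)
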