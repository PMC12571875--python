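"""The ROI-level crescent-formation trajectory.

Raw counts of each ROI (glomerulus plus periglomerular ring) are summed into
pseudo-bulk profiles, normalized to 10,000 and log1p-transformed.  The first
principal component of these profiles, oriented from control toward disease,
is the crescent trajectory; ROIs are clustered with K-means (K by the elbow
of the inertia curve, control-dominated clusters merged), ordered along a
diffusion pseudotime rooted in a random control ROI, cut into four quadrants
by Jenks natural breaks, correlated per patient with clinical covariates,
and compared between clusters by gene-wise linear models with the slide as a
covariate.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .celltyping import normalize_log1p
from .exceptions import DegenerateInputError, ParameterError, ValidationError
from .io import SpatialCellTable
from .niches import DomainLabeling


# ---------------------------------------------------------------------------
# pseudo-bulk
# ---------------------------------------------------------------------------

def pseudobulk_rois(table: SpatialCellTable, labeling: DomainLabeling,
                    target_sum: float = 10000.0
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Sum member-cell raw counts per ROI; normalize to ``target_sum`` + log1p.

    Returns ``(raw, norm, roi_meta)`` where rows are ROIs (ids with at least
    one member cell; empty ROIs are excluded with a warning) and ``roi_meta``
    carries sample, slide, condition and patient per ROI.
    """
    roi = np.asarray(labeling.roi_id)
    member = roi >= 0
    ids = np.unique(roi[member])
    if len(ids) == 0:
        raise ValidationError("no ROI has any member cell")
    groups = {g: np.flatnonzero(roi == g) for g in ids}
    raw = np.vstack([
        np.asarray(table.counts[rows].sum(axis=0)).ravel() for rows in groups.values()
    ])
    raw_df = pd.DataFrame(raw, index=pd.Index(ids, name="roi_id"),
                          columns=table.gene_names)
    norm = normalize_log1p(raw, target_sum)
    norm_df = pd.DataFrame(norm, index=raw_df.index, columns=raw_df.columns)
    meta_cols = ["sample_id", "slide_id", "condition"] + (
        ["patient_id"] if "patient_id" in table.cells.columns else []
    )
    meta = pd.DataFrame(
        {c: [table.cells[c].to_numpy()[rows[0]] for rows in groups.values()]
         for c in meta_cols},
        index=raw_df.index,
    )
    return raw_df, norm_df, meta


# ---------------------------------------------------------------------------
# PCA trajectory
# ---------------------------------------------------------------------------

class CrescentTrajectory(BaseEstimator, TransformerMixin):
    """Centered PCA of normalized pseudo-bulk profiles with PC1 oriented
    from control toward disease.

    After :meth:`fit`, ``pc_`` holds the ROI coordinates, ``pc1_`` the
    oriented first component, ``loadings_`` the gene loadings (oriented
    consistently with ``pc1_``) and ``explained_variance_ratio_`` the PCA
    spectrum.  The sign of PC1 is flipped if needed so that
    ``median(PC1 | control) <= median(PC1 | non-control)``.
    """

    def __init__(self, n_pcs: int = 10, control_label: str = "control"):
        self.n_pcs = n_pcs
        self.control_label = control_label

    def fit(self, pseudobulk_norm, conditions):
        X = np.asarray(pseudobulk_norm, dtype=float)
        if X.shape[0] < 3:
            raise ValidationError("need at least 3 ROIs for a trajectory")
        conditions = np.asarray(conditions, dtype=object)
        if len(np.unique(conditions)) < 2:
            raise ValidationError("need at least 2 conditions to orient PC1")
        if np.allclose(X.var(axis=0), 0):
            raise DegenerateInputError("pseudo-bulk matrix has no variance")
        n = min(self.n_pcs, X.shape[0] - 1, X.shape[1])
        pca = PCA(n_components=n, svd_solver="full")
        pcs = pca.fit_transform(X)
        ctrl = conditions == self.control_label
        if ctrl.any() and (~ctrl).any():
            if np.median(pcs[ctrl, 0]) > np.median(pcs[~ctrl, 0]):
                pcs[:, 0] *= -1.0
                pca.components_[0] *= -1.0
        self.pc_ = pcs
        self.pc1_ = pcs[:, 0]
        self.loadings_ = pca.components_
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self._pca = pca
        self._mean = X.mean(axis=0)
        return self

    def transform(self, X):
        return (np.asarray(X, dtype=float) - self._mean) @ self.loadings_.T

    def fit_transform(self, pseudobulk_norm, conditions):
        return self.fit(pseudobulk_norm, conditions).pc_


def fit_crescent_trajectory(pseudobulk_norm, conditions, n_pcs: int = 10):
    """Functional wrapper: returns the fitted :class:`CrescentTrajectory`."""
    return CrescentTrajectory(n_pcs=n_pcs).fit(pseudobulk_norm, conditions)


# ---------------------------------------------------------------------------
# ROI clustering
# ---------------------------------------------------------------------------

def _elbow_k(inertias: dict[int, float]) -> int:
    """Maximum discrete curvature of the inertia curve (kneedle-style)."""
    ks = sorted(inertias)
    if len(ks) <= 2:
        return ks[0]
    vals = np.array([inertias[k] for k in ks])
    curv = vals[:-2] - 2 * vals[1:-1] + vals[2:]
    return ks[1:-1][int(np.argmax(curv))]


def cluster_rois(pc_coords, conditions, k_max: int = 10,
                 merge_control_fraction: float = 0.6,
                 control_label: str = "control", seed: int = 0) -> np.ndarray:
    """K-means ROI clusters: K by the elbow, control-dominated clusters
    merged, labels C1..Cn ordered by ascending median PC1."""
    X = np.asarray(pc_coords, dtype=float)
    conditions = np.asarray(conditions, dtype=object)
    n = len(X)
    if n < k_max + 1:
        k_max = max(2, n - 1)
        warnings.warn(f"fewer ROIs than k_max; lowering k_max to {k_max}")
    inertias = {}
    fits = {}
    for k in range(2, k_max + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
        inertias[k] = km.inertia_
        fits[k] = km.labels_
    k_best = _elbow_k(inertias)
    labels = np.array([f"k{c}" for c in fits[k_best]], dtype=object)

    # merge clusters predominantly composed of control ROIs
    merged = "__control_merged__"
    for c in np.unique(labels):
        rows = labels == c
        if np.mean(conditions[rows] == control_label) > merge_control_fraction:
            labels[rows] = merged

    pc1 = X[:, 0]
    med = {c: np.median(pc1[labels == c]) for c in np.unique(labels)}
    order = sorted(med, key=lambda c: med[c])
    rename = {c: f"C{i + 1}" for i, c in enumerate(order)}
    return np.array([rename[c] for c in labels], dtype=object)


# ---------------------------------------------------------------------------
# diffusion pseudotime
# ---------------------------------------------------------------------------

def compute_pseudotime(pseudobulk_norm, conditions, seed: int = 0,
                       n_pcs: int = 10, n_neighbors: int = 10,
                       control_label: str = "control") -> np.ndarray:
    """Diffusion pseudotime of ROIs from a random control root, in [0, 1].

    Uses the diffusion-map / diffusion-pseudotime implementation of scanpy
    on a k-NN graph in PC space; the root ROI is drawn uniformly from the
    control ROIs under ``seed`` and has pseudotime 0.
    """
    import anndata as ad
    import scanpy as sc

    X = np.asarray(pseudobulk_norm, dtype=float)
    conditions = np.asarray(conditions, dtype=object)
    ctrl = np.flatnonzero(conditions == control_label)
    if len(ctrl) == 0:
        raise ValidationError("no control ROI available as pseudotime root")
    rng = np.random.default_rng(seed)
    root = int(rng.choice(ctrl))

    adata = ad.AnnData(X=X.astype(np.float32))
    n_comps = min(n_pcs, X.shape[0] - 1, X.shape[1])
    sc.pp.pca(adata, n_comps=n_comps, svd_solver="arpack", random_state=0)
    sc.pp.neighbors(adata, n_neighbors=min(n_neighbors, X.shape[0] - 1),
                    use_rep="X_pca", random_state=0)
    n_dcs = min(15, X.shape[0] - 1)
    sc.tl.diffmap(adata, n_comps=n_dcs)
    adata.uns["iroot"] = root
    sc.tl.dpt(adata, n_dcs=min(10, n_dcs))
    pt = np.asarray(adata.obs["dpt_pseudotime"], dtype=float)
    finite = np.isfinite(pt)
    if not finite.all():  # disconnected ROIs sit at the far end
        pt[~finite] = pt[finite].max()
    lo, hi = pt.min(), pt.max()
    if hi > lo:
        pt = (pt - lo) / (hi - lo)
    return pt


# ---------------------------------------------------------------------------
# Jenks natural breaks
# ---------------------------------------------------------------------------

def jenks_breaks(values, n_classes: int = 4) -> list[float]:
    """Jenks natural breaks: boundaries minimizing within-class SSD.

    Returns ``n_classes + 1`` boundaries ``[min, b1, .., b_{k-1}, max]``;
    class ``i`` is ``(b_{i-1}, b_i]`` (first class includes its lower bound).
    Exact dynamic programme, O(k·n²).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if len(np.unique(x)) < n_classes:
        raise DegenerateInputError(
            f"need at least {n_classes} distinct values for {n_classes} classes"
        )
    # prefix sums for O(1) segment SSD
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def ssd(i, j):  # segment x[i..j-1]
        s, s2, m = cs[j] - cs[i], cs2[j] - cs2[i], j - i
        return s2 - s * s / m

    INF = np.inf
    cost = np.full((n_classes + 1, n + 1), INF)
    back = np.zeros((n_classes + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for k in range(1, n_classes + 1):
        for j in range(k, n + 1):
            best, arg = INF, k - 1
            for i in range(k - 1, j):
                c = cost[k - 1, i] + ssd(i, j)
                if c < best:
                    best, arg = c, i
            cost[k, j] = best
            back[k, j] = arg
    cuts = []
    j = n
    for k in range(n_classes, 0, -1):
        cuts.append(j)
        j = back[k, j]
    cuts = cuts[::-1]  # end indices of each class
    breaks = [float(x[0])]
    for c in cuts[:-1]:
        breaks.append(float(x[c - 1]))
    breaks.append(float(x[-1]))
    return breaks


def quadrant_breaks(pseudotime, n_classes: int = 4) -> np.ndarray:
    """Cut pseudotime into quadrants Q1..Q4 by Jenks natural breaks."""
    pt = np.asarray(pseudotime, dtype=float)
    breaks = jenks_breaks(pt, n_classes)
    edges = np.asarray(breaks[1:-1])
    idx = np.searchsorted(edges, pt, side="left")
    return np.array([f"Q{i + 1}" for i in idx], dtype=object)


# ---------------------------------------------------------------------------
# clinical correlation
# ---------------------------------------------------------------------------

ANCA_RISK_CODES = {"low": 1, "medium": 2, "high": 3}


def median_pc1_per_patient(pc1, roi_meta: pd.DataFrame) -> pd.Series:
    """Median PC1 across all ROIs of each patient."""
    key = "patient_id" if "patient_id" in roi_meta.columns else "sample_id"
    return pd.Series(np.asarray(pc1), index=roi_meta[key].to_numpy()).groupby(level=0).median()


def correlate_with_clinical(median_pc1: pd.Series, clinical: pd.DataFrame,
                            covariates=("eGFR", "albuminuria", "age", "anca_risk"),
                            min_patients: int = 5) -> pd.DataFrame:
    """Spearman correlation of per-patient median PC1 with each covariate.

    Ordinal ANCA risk is encoded low=1, medium=2, high=3; two-sided p-values
    use the t approximation.  Covariates with too few patients or no
    variation are flagged (rho = NaN).
    """
    rows = []
    for cov in covariates:
        if cov not in clinical.columns:
            continue
        vals = clinical[cov]
        if cov == "anca_risk":
            vals = vals.map(lambda v: ANCA_RISK_CODES.get(v, np.nan))
        joined = pd.DataFrame({"pc1": median_pc1}).join(
            vals.rename("cov").astype(float), how="inner"
        ).dropna()
        if len(joined) < min_patients or joined["cov"].nunique() < 2:
            rows.append(dict(covariate=cov, rho=np.nan, p=np.nan,
                             n=len(joined), flag="undefined"))
            continue
        rho, p = scipy.stats.spearmanr(joined["pc1"], joined["cov"])
        rows.append(dict(covariate=cov, rho=float(rho), p=float(p),
                         n=len(joined), flag=""))
    return pd.DataFrame(rows).set_index("covariate")


# ---------------------------------------------------------------------------
# differential expression between clusters
# ---------------------------------------------------------------------------

def de_between_clusters(pseudobulk_norm, clusters, slide_ids,
                        baseline: str = "C1") -> pd.DataFrame:
    """Gene-wise linear model: expression ~ (cluster != baseline) + slide.

    The effect is the group coefficient (positive = higher outside the
    baseline cluster); two-sided p from the t distribution; Benjamini-
    Hochberg q across testable genes.  Zero-variance genes are flagged and
    excluded from the correction; if the slide factor is confounded with
    the group, the slide term is dropped with a warning.
    """
    if isinstance(pseudobulk_norm, pd.DataFrame):
        genes = list(pseudobulk_norm.columns)
        Y = pseudobulk_norm.to_numpy(dtype=float)
    else:
        Y = np.asarray(pseudobulk_norm, dtype=float)
        genes = [f"g{i}" for i in range(Y.shape[1])]
    clusters = np.asarray(clusters, dtype=object)
    slide_ids = np.asarray(slide_ids, dtype=object)
    group = (clusters != baseline).astype(float)
    if group.sum() < 3 or (1 - group).sum() < 3:
        raise ValidationError("each compared group needs at least 3 ROIs")

    slides = pd.get_dummies(pd.Series(slide_ids), drop_first=True).to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(group)), group, slides])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("slide factor is confounded with the cluster split; "
                      "dropping the slide covariate")
        X = np.column_stack([np.ones(len(group)), group])

    n, p = X.shape
    XtX_inv = np.linalg.pinv(X.T @ X)
    beta = XtX_inv @ X.T @ Y                       # p × G
    resid = Y - X @ beta
    df = n - np.linalg.matrix_rank(X)
    sigma2 = (resid ** 2).sum(axis=0) / max(df, 1)
    se = np.sqrt(np.maximum(XtX_inv[1, 1], 0) * sigma2)
    var_ok = Y.var(axis=0) > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[1] / np.where(se > 0, se, 1.0), np.nan)
    pvals = 2 * scipy.stats.t.sf(np.abs(t), df)
    pvals[~var_ok] = np.nan

    out = pd.DataFrame({"gene": genes, "effect": beta[1], "p": pvals}).set_index("gene")
    out["flag"] = np.where(var_ok, "", "zero_variance")
    testable = out["p"].notna()
    q = np.full(len(out), np.nan)
    if testable.any():
        q[testable.to_numpy()] = multipletests(out.loc[testable, "p"], method="fdr_bh")[1]
    out["q"] = q
    return out
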