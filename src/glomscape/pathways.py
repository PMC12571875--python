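"""Gene-set activity scores and their trend along the trajectory.

A cell's score for a gene set is the mean, over the set genes present in
the panel, of the gene-wise z-scored log-normalized expression (constant
genes contribute 0).  With a small targeted panel this mean-of-z-scores
rule is preferred over expression-bin-matched background scoring, whose
background pools would be too small; a binned variant is available for
comparison.  Score dynamics along the crescent trajectory are summarized
by an ordinary least squares quadratic fit with analytic pointwise 95%
confidence bands and, when the curvature is negative, the fitted peak
location.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm

from .exceptions import EmptyGeneSetError, ParameterError, ValidationError

#: Default fibrosis (extracellular matrix) gene set.
FIBROSIS_GENES = ("COL1A1", "COL4A1", "FN1", "LUM", "TIMP1")


@dataclass
class GeneSetScore:
    """Per-cell activity of one gene set."""

    name: str
    genes_used: list[str]
    fraction_present: float
    scores: np.ndarray


def _dense(x) -> np.ndarray:
    return x.toarray() if sp.issparse(x) else np.asarray(x, dtype=float)


def score_gene_set(normalized_expression, gene_names, gene_set,
                   set_name: str = "geneset", method: str = "zmean",
                   n_bins: int = 10) -> GeneSetScore:
    """Score every cell for a gene set.

    ``normalized_expression`` is the cells × genes log-normalized matrix with
    columns ``gene_names``.  ``method="zmean"`` (default) averages gene-wise
    z-scores; ``method="binned"`` subtracts, per set gene, the mean of an
    expression-matched background bin before averaging.
    """
    gene_names = list(gene_names)
    gene_set = list(gene_set)
    present = [g for g in gene_set if g in set(gene_names)]
    if not present:
        raise EmptyGeneSetError(set_name, gene_set)
    col = {g: i for i, g in enumerate(gene_names)}
    idx = [col[g] for g in present]
    X = _dense(normalized_expression[:, idx] if not isinstance(
        normalized_expression, pd.DataFrame)
        else normalized_expression.iloc[:, idx])

    if method == "zmean":
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        z = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        scores = z.mean(axis=1)
    elif method == "binned":
        full = _dense(normalized_expression)
        means = full.mean(axis=0)
        bins = pd.qcut(means, q=min(n_bins, len(means)), labels=False,
                       duplicates="drop")
        bg = np.array([full[:, bins == bins[col[g]]].mean() for g in present])
        scores = (X - bg).mean(axis=1)
    else:
        raise ParameterError(f"unknown scoring method {method!r}")
    return GeneSetScore(
        name=set_name, genes_used=present,
        fraction_present=len(present) / len(gene_set), scores=scores,
    )


def fibrosis_score(normalized_expression, gene_names,
                   gene_set=FIBROSIS_GENES, method: str = "zmean") -> GeneSetScore:
    """Fibrosis activity with the default ECM gene set (overridable)."""
    return score_gene_set(normalized_expression, gene_names, list(gene_set),
                          set_name="FIBROSIS", method=method)


# ---------------------------------------------------------------------------
# trends along the trajectory
# ---------------------------------------------------------------------------

@dataclass
class QuadraticTrend:
    """OLS quadratic fit y ~ 1 + x + x² with analytic 95% CI band."""

    coef: np.ndarray           # (intercept, linear, quadratic)
    cov: np.ndarray
    peak: float | None         # -b/(2c) when curvature c < 0
    grid: np.ndarray
    fitted: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n: int

    @property
    def curvature(self) -> float:
        return float(self.coef[2])

    def curvature_ci(self, alpha: float = 0.05) -> tuple[float, float]:
        import scipy.stats

        se = float(np.sqrt(self.cov[2, 2]))
        tcrit = scipy.stats.t.ppf(1 - alpha / 2, self.n - 3)
        return self.coef[2] - tcrit * se, self.coef[2] + tcrit * se


def quadratic_trend(x, y, n_grid: int = 100) -> QuadraticTrend:
    """Fit y on (1, x, x²) by OLS with a pointwise 95% confidence band."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 4:
        raise ValidationError("need more points than parameters for a quadratic fit")
    X = sm.add_constant(np.column_stack([x, x * x]))
    fit = sm.OLS(y, X).fit()
    grid = np.linspace(x.min(), x.max(), n_grid)
    G = sm.add_constant(np.column_stack([grid, grid * grid]))
    pred = fit.get_prediction(G)
    ci = pred.conf_int(alpha=0.05)
    b, c = fit.params[1], fit.params[2]
    peak = float(-b / (2 * c)) if c < 0 else None
    return QuadraticTrend(
        coef=np.asarray(fit.params), cov=np.asarray(fit.cov_params()),
        peak=peak, grid=grid, fitted=pred.predicted_mean,
        ci_low=ci[:, 0], ci_high=ci[:, 1], n=len(x),
    )


def trend_along_trajectory(scores, cell_types, target_type, roi_ids,
                           pc1_per_roi: pd.Series,
                           min_cells: int = 10, min_rois: int = 5) -> QuadraticTrend:
    """Quadratic trend of per-cell scores of one type along ROI PC1.

    Cells of ``target_type`` are attached their ROI's PC1 value; cells
    outside any ROI (or in ROIs without a PC1 value) are dropped.
    """
    scores = np.asarray(scores, dtype=float)
    cell_types = np.asarray(cell_types, dtype=object)
    roi_ids = np.asarray(roi_ids)
    sel = cell_types == target_type
    pc1 = pd.Series(roi_ids[sel]).map(pc1_per_roi).to_numpy(dtype=float)
    y = scores[sel]
    ok = np.isfinite(pc1)
    if ok.sum() < min_cells or len(np.unique(roi_ids[sel][ok])) < min_rois:
        raise ValidationError(
            f"need >= {min_cells} {target_type} cells over >= {min_rois} ROIs"
        )
    return quadratic_trend(pc1[ok], y[ok])
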