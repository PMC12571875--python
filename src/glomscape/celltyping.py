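"""Expression normalization and reference-based cell-type assignment.

Cell types are transferred from a labelled reference with a multinomial
logistic regression (L2 penalty, strength chosen by internal
cross-validation), applied to library-size-normalized, log1p-transformed
counts — the standard label-transfer recipe for targeted spatial panels.
The per-cell confidence is the winning class probability; clusters whose
median confidence falls below a threshold can be dropped, and mesangial
cells with a glomerular fibrotic signature can be relabelled as fibrotic
mesangial cells.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegressionCV
from sklearn.utils.validation import check_is_fitted

from .exceptions import (
    CompatibilityError,
    ParameterError,
    TrainingError,
    ValidationError,
)
from .io import SpatialCellTable


def normalize_log1p(counts, target_sum: float = 1000.0):
    """Scale each cell to ``target_sum`` total counts, then log(1 + x).

    All-zero cells pass through unchanged.  Returns a dense array for dense
    input and a CSR matrix for sparse input; satisfies
    ``sum(expm1(row)) == target_sum`` for every non-empty cell.
    """
    if target_sum <= 0:
        raise ParameterError("target_sum must be positive")
    if sp.issparse(counts):
        counts = sp.csr_matrix(counts, dtype=float)
        if counts.nnz and counts.data.min() < 0:
            raise ValidationError("counts contain negative entries")
        totals = np.asarray(counts.sum(axis=1)).ravel()
        scale = np.where(totals > 0, target_sum / np.maximum(totals, 1e-300), 0.0)
        out = sp.diags(scale) @ counts
        out.data = np.log1p(out.data)
        return out.tocsr()
    counts = np.asarray(counts, dtype=float)
    if counts.size and counts.min() < 0:
        raise ValidationError("counts contain negative entries")
    totals = counts.sum(axis=1, keepdims=True)
    scaled = np.divide(counts * target_sum, totals,
                       out=np.zeros_like(counts), where=totals > 0)
    return np.log1p(scaled)


class CellTypeClassifier(BaseEstimator, ClassifierMixin):
    """Regularized multinomial cell-type classifier over a gene panel.

    Parameters
    ----------
    target_sum
        Library-size normalization target applied before log1p (default
        1,000, the value used for panel-scale data).
    Cs
        Inverse-regularization grid searched by cross-validation.
    cv
        Number of stratified folds.
    min_gene_overlap
        Minimum fraction of the model's genes that must be present in a
        prediction target.
    random_state
        Seed for the cross-validation splits.

    Fitted attributes (trailing underscore) follow scikit-learn conventions:
    ``classes_``, ``genes_``, ``coef_``, ``intercept_``, ``C_``.
    """

    def __init__(self, target_sum: float = 1000.0, Cs=None, cv: int = 5,
                 min_gene_overlap: float = 0.5, max_iter: int = 1000,
                 random_state: int = 0):
        self.target_sum = target_sum
        self.Cs = Cs
        self.cv = cv
        self.min_gene_overlap = min_gene_overlap
        self.max_iter = max_iter
        self.random_state = random_state

    # -- training -----------------------------------------------------------
    def fit(self, counts, labels, genes=None):
        """Fit on reference raw counts (cells × genes) and type labels."""
        labels = np.asarray(labels, dtype=object)
        classes, class_counts = np.unique(labels, return_counts=True)
        if len(classes) < 2:
            raise TrainingError("need at least 2 cell-type labels")
        if class_counts.min() < 2:
            bad = classes[class_counts < 2].tolist()
            raise TrainingError(f"label(s) with fewer than 2 reference cells: {bad}")
        if genes is None:
            raise ParameterError("genes (panel order of the count columns) is required")
        X = normalize_log1p(counts, self.target_sum)
        if sp.issparse(X):
            X = X.toarray()
        Cs = self.Cs if self.Cs is not None else np.logspace(-2, 2, 5)
        cv = min(self.cv, int(class_counts.min()))
        self._lr = LogisticRegressionCV(
            Cs=Cs, cv=cv, penalty="l2", max_iter=self.max_iter,
            random_state=self.random_state, n_jobs=None,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            self._lr.fit(X, labels)
        self.classes_ = self._lr.classes_
        self.genes_ = list(genes)
        self.coef_ = self._lr.coef_
        self.intercept_ = self._lr.intercept_
        self.C_ = self._lr.C_
        return self

    # -- prediction ---------------------------------------------------------
    def _align(self, table_genes):
        present = [g for g in self.genes_ if g in set(table_genes)]
        overlap = len(present) / len(self.genes_)
        if overlap < self.min_gene_overlap:
            raise CompatibilityError(
                f"only {overlap:.0%} of the model's genes are present in the "
                f"data (minimum {self.min_gene_overlap:.0%})"
            )
        return present

    def predict_proba_matrix(self, counts, genes) -> np.ndarray:
        """Class probabilities for raw counts with the given gene order.

        Genes are intersected with the model's panel; absent model genes
        contribute zero expression.  Rows sum to 1.
        """
        check_is_fitted(self, "coef_")
        present = self._align(genes)
        col_of = {g: i for i, g in enumerate(genes)}
        model_col = {g: j for j, g in enumerate(self.genes_)}
        X = normalize_log1p(sp.csr_matrix(counts)[:, [col_of[g] for g in present]],
                            self.target_sum)
        full = np.zeros((X.shape[0], len(self.genes_)))
        full[:, [model_col[g] for g in present]] = X.toarray() if sp.issparse(X) else X
        logits = full @ self.coef_.T + self.intercept_
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        return p

    def predict_cells(self, table: SpatialCellTable) -> tuple[np.ndarray, np.ndarray]:
        """Per-cell argmax label and its probability as the confidence.

        Ties are broken by lexicographic label order (``classes_`` is
        sorted, and ``argmax`` returns the first maximum).
        """
        proba = self.predict_proba_matrix(table.counts, table.gene_names)
        idx = proba.argmax(axis=1)
        return self.classes_[idx], proba[np.arange(len(idx)), idx]

    # sklearn-compatible surface over pre-aligned matrices
    def predict(self, X):
        check_is_fitted(self, "coef_")
        return self._lr.predict(normalize_log1p(X, self.target_sum))

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y, dtype=object)))

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        check_is_fitted(self, "coef_")
        return {
            "classes": self.classes_.tolist(),
            "genes": self.genes_,
            "coef": self.coef_.tolist(),
            "intercept": self.intercept_.tolist(),
            "normalization": {"target_sum": self.target_sum, "log1p": True},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CellTypeClassifier":
        obj = cls(target_sum=d["normalization"]["target_sum"])
        obj.classes_ = np.asarray(d["classes"], dtype=object)
        obj.genes_ = list(d["genes"])
        obj.coef_ = np.asarray(d["coef"], dtype=float)
        obj.intercept_ = np.asarray(d["intercept"], dtype=float)

        class _Frozen:
            pass

        lr = _Frozen()
        obj._lr = lr
        return obj


def fit_classifier(reference_counts, reference_labels, genes,
                   target_sum: float = 1000.0, seed: int = 0) -> CellTypeClassifier:
    """Functional wrapper over :class:`CellTypeClassifier`."""
    return CellTypeClassifier(target_sum=target_sum, random_state=seed).fit(
        reference_counts, reference_labels, genes=genes
    )


def predict_cell_types(model: CellTypeClassifier, table: SpatialCellTable):
    """Functional wrapper over :meth:`CellTypeClassifier.predict_cells`."""
    return model.predict_cells(table)


def filter_low_confidence_clusters(confidences, cluster_ids,
                                   min_median_confidence: float = 0.6
                                   ) -> tuple[np.ndarray, pd.Series]:
    """Boolean retention mask removing all cells of clusters whose *median*
    annotation confidence is strictly below the threshold.

    Returns the mask and the per-cluster medians.
    """
    confidences = np.asarray(confidences, dtype=float)
    cluster_ids = np.asarray(cluster_ids)
    if len(confidences) != len(cluster_ids):
        raise ValidationError("confidences and cluster_ids must align")
    if len(confidences) == 0:
        return np.zeros(0, dtype=bool), pd.Series(dtype=float)
    medians = pd.Series(confidences).groupby(pd.Series(cluster_ids)).median()
    bad = set(medians.index[medians < min_median_confidence])
    mask = ~pd.Series(cluster_ids).isin(bad).to_numpy()
    return mask, medians


def relabel_fibrotic_mesangial(labels, fibrosis_scores, in_glomerulus, is_control,
                               percentile: float = 90.0,
                               source_label: str = "mesangial",
                               new_label: str = "fibrotic_mesangial") -> np.ndarray:
    """Relabel glomerular mesangial cells with a fibrotic signature.

    Mesangial-labelled cells inside glomerular domains whose fibrosis score
    exceeds the ``percentile``-th percentile of control mesangial cells are
    relabelled ``fibrotic_mesangial``.
    """
    labels = np.asarray(labels, dtype=object).copy()
    scores = np.asarray(fibrosis_scores, dtype=float)
    in_glom = np.asarray(in_glomerulus, dtype=bool)
    ctrl = np.asarray(is_control, dtype=bool)
    pool = scores[(labels == source_label) & ctrl]
    if pool.size == 0:
        warnings.warn("no control mesangial cells; fibrotic relabeling skipped")
        return labels
    threshold = np.percentile(pool, percentile)
    hit = (labels == source_label) & in_glom & (scores > threshold)
    labels[hit] = new_label
    return labels
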