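"""Pathway-based drug prioritization (digital pharmacology).

For a drug d with target set T_d and a pathway gene set G_p:

    S_b = |T_d ∩ G_p| / |G_p|                          (pathway coverage)
    S_a = Σ_{g ∈ T_d ∩ G_p} w(a_{d,g})                 (action relevance)
    S_f = S_b × (1 + S_a / max(1, |T_d ∩ G_p|))        (final score)

with action weights w = 1 for inhibitors/antagonists, 0.5 for binders,
activators and agonists, and 0 for anything else (unlisted actions still
count toward the overlap and S_b).  Drugs below a minimum final score are
filtered out and the rest ranked by S_f.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .exceptions import ParameterError, SchemaError

#: (substring, weight) in match order; "antagonist" must precede "agonist".
DEFAULT_ACTION_WEIGHTS = (
    ("inhibitor", 1.0),
    ("antagonist", 1.0),
    ("binder", 0.5),
    ("activator", 0.5),
    ("agonist", 0.5),
)


def read_drug_table(path) -> pd.DataFrame:
    """Read a DrugBank-style CSV (drug_id, target_gene, action); gene names
    are uppercased."""
    df = pd.read_csv(path)
    missing = {"drug_id", "target_gene", "action"} - set(df.columns)
    if missing:
        raise SchemaError(f"drug table is missing column(s): {sorted(missing)}")
    df["target_gene"] = df["target_gene"].astype(str).str.upper()
    df["action"] = df["action"].astype(str)
    return df


def action_weight(action: str, weight_map=DEFAULT_ACTION_WEIGHTS) -> float:
    """Weight of an action label by case-insensitive substring match."""
    label = str(action).lower()
    for key, w in weight_map:
        if key in label:
            return float(w)
    return 0.0


def score_drugs(drug_table: pd.DataFrame, pathway_genes,
                weight_map=DEFAULT_ACTION_WEIGHTS,
                min_score: float = 0.1) -> pd.DataFrame:
    """Score and rank all drugs against one pathway gene set.

    Returns a DataFrame (drug_id index) with ``n_overlap``, ``s_b``,
    ``s_a`` and ``s_f``, filtered to ``s_f >= min_score`` and sorted by
    ``s_f`` descending (ties by drug_id).  Duplicate (drug, gene) rows are
    deduplicated keeping the maximum action weight, with a warning.
    """
    pathway = {str(g).upper() for g in pathway_genes}
    if not pathway:
        raise ParameterError("pathway gene set is empty")
    df = drug_table.copy()
    df["weight"] = df["action"].map(lambda a: action_weight(a, weight_map))
    if df.duplicated(["drug_id", "target_gene"]).any():
        warnings.warn("duplicate (drug, gene) rows; keeping the maximum action weight")
        df = (df.sort_values("weight", ascending=False)
                .drop_duplicates(["drug_id", "target_gene"]))

    rows = []
    for drug, grp in df.groupby("drug_id"):
        hit = grp[grp["target_gene"].isin(pathway)]
        n_overlap = len(hit)
        s_b = n_overlap / len(pathway)
        s_a = float(hit["weight"].sum())
        s_f = s_b * (1.0 + s_a / max(1, n_overlap))
        rows.append(dict(drug_id=drug, n_overlap=n_overlap,
                         s_b=s_b, s_a=s_a, s_f=s_f))
    out = pd.DataFrame(rows).set_index("drug_id")
    out = out[out["s_f"] >= min_score]
    return out.reset_index().sort_values(
        ["s_f", "drug_id"], ascending=[False, True]
    ).set_index("drug_id")
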