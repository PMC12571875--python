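"""Access to packaged fixture data.

All packaged resources are synthetic stand-ins built for testing and
demonstration: a 480-gene kidney/immune panel, per-condition compartment
composition profiles whose headline medians follow the published
crescentic-glomerulonephritis cohort, small GMT pathway sets, a secreted/
contact ligand–receptor table and a DrugBank-style drug–target table.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd
import yaml


def _path(name: str):
    return resources.files("glomscape.data").joinpath(name)


def load_gene_panel() -> pd.DataFrame:
    """The packaged synthetic 480-gene panel (columns: gene, category)."""
    from .io import read_gene_panel

    with resources.as_file(_path("panel_480.synthetic.tsv")) as p:
        return read_gene_panel(p)


def load_compositions() -> dict:
    """Per-condition, per-compartment cell-type fraction profiles.

    Returns ``{condition: {compartment: {cell_type: fraction}}}`` with
    fractions normalised to sum to 1 per compartment.
    """
    raw = yaml.safe_load(_path("compositions.yaml").read_text())
    out: dict = {}
    for cond, comps in raw.items():
        out[cond] = {}
        for comp, mapping in comps.items():
            total = float(sum(mapping.values()))
            out[cond][comp] = {t: float(v) / total for t, v in mapping.items()}
    return out


def load_gene_sets() -> dict[str, list[str]]:
    """Packaged pathway gene sets (PDGF_SIGNALING, TGFB_SIGNALING, FIBROSIS)."""
    from .io import read_gmt

    with resources.as_file(_path("genesets.synthetic.gmt")) as p:
        return read_gmt(p)


def load_lr_database() -> pd.DataFrame:
    """Packaged ligand–receptor interaction table."""
    from .interactions import read_lr_database

    with resources.as_file(_path("lr_database.synthetic.csv")) as p:
        return read_lr_database(p)


def load_drug_targets() -> pd.DataFrame:
    """Packaged DrugBank-style drug–target–action table."""
    from .drugs import read_drug_table

    with resources.as_file(_path("drug_targets.synthetic.csv")) as p:
        return read_drug_table(p)


def marker_genes() -> dict[str, list[str]]:
    """Cell-type marker genes of the packaged panel, by type."""
    panel = load_gene_panel()
    out: dict[str, list[str]] = {}
    for _, row in panel.iterrows():
        if str(row["category"]).startswith("marker:"):
            out.setdefault(row["category"].split(":", 1)[1], []).append(row["gene"])
    return out
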