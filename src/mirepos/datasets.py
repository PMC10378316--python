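"""Packaged reference tables.

``load_role_reference`` returns the curated table of breast-cancer miRNA
families with concordant diagnostic and prognostic relevance: tumor/normal
fold changes from a profiled patient cohort alongside TCGA-BRCA log-rank
p-values and hazard ratios (high vs low expression) per survival isoform.
``load_breast_drug_list`` returns the 19 guideline-recommended breast
cancer drugs used to define pan-sensitivity.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .concordance import RoleCall, classify_family, family_id

__all__ = [
    "load_role_reference",
    "load_breast_drug_list",
    "role_calls_from_reference",
]


def _data_path(name: str):
    return resources.files("mirepos.data").joinpath(name)


def load_role_reference() -> pd.DataFrame:
    """Curated miRNA fold-change / hazard-ratio reference table.

    One row per (cohort miRNA, TCGA survival isoform) pair; continuation
    rows of multi-isoform families carry NA in the ``mirna`` column.
    """
    with resources.as_file(_data_path("brca_mirna_diag_prog.tsv")) as path:
        return pd.read_csv(path, sep="\t", na_values=["NA"])


def load_breast_drug_list() -> list[str]:
    """The 19 guideline breast-cancer drugs defining pan-sensitivity."""
    with resources.as_file(_data_path("nccn_breast_drugs.txt")) as path:
        return [l.strip() for l in path.read_text().splitlines() if l.strip()]


def role_calls_from_reference(reference: pd.DataFrame | None = None) -> list[RoleCall]:
    """Family-level oncomiR / tumor-suppressor calls from the reference table.

    Rows are grouped into families (via the miRBase prefix rule applied to
    the cohort id, falling back to the survival isoform id), each family
    takes the fold change of its primary row, and all significant survival
    isoforms vote on the hazard direction.
    """
    ref = reference if reference is not None else load_role_reference()
    fam_col = [
        family_id(row["mirna"] if isinstance(row["mirna"], str)
                  else row["tcga_mirna"])
        for _, row in ref.iterrows()
    ]
    ref = ref.assign(family=fam_col)
    calls = []
    for fam, grp in ref.groupby("family", sort=True):
        fcs = grp["fc_unpaired"].dropna()
        if fcs.empty:
            continue
        isoforms = [
            (float(hr), float(p))
            for hr, p in zip(grp["hr"], grp["logrank_p"])
            if pd.notna(hr) and pd.notna(p)
        ]
        calls.append(classify_family(fam, float(fcs.iloc[0]), isoforms))
    return calls
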