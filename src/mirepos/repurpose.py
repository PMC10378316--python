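"""Potency filtering of connectivity hits and responder profiling.

A connectivity hit survives the potency filter when its average in-panel
IC50 and EC50 (uM) are below 7 after removing Tukey outliers (values
outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR] with linear-interpolation quartiles,
computed on the linear uM scale so that ln-transformed inputs give the
identical verdict). When a hit has response values from several sources,
each source is judged on its own and the hit passes if any source does.

Responder profiling characterizes which multi-omic features track response
to a repositioned drug: genes must show the same significant direction at
both the mRNA and the protein level to be listed, and each classified cell
line is annotated with its top mutated and top fused genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CellLinePanel, ValidationError
from .drugsens import RESISTANT, SENSITIVE, gene_drug_call

__all__ = [
    "RepurposingHit",
    "tukey_trim",
    "potency_filter",
    "responder_genes",
    "top_alterations",
]


@dataclass
class RepurposingHit:
    perturbagen_id: str
    score: float
    p: float
    mean_ic50: float = float("nan")
    mean_ec50: float = float("nan")
    n_outliers_removed: int = 0
    passes_potency: bool | None = None  # None = undetermined (too few values)


def tukey_trim(values: np.ndarray) -> tuple[np.ndarray, int]:
    """Drop values outside the 1.5 IQR fences (linear-interpolation quartiles)."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if len(values) == 0:
        return values, 0
    q1, q3 = np.percentile(values, [25, 75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    kept = values[(values >= lo) & (values <= hi)]
    return kept, int(len(values) - len(kept))


def _to_um(values: pd.Series, measure: str) -> pd.Series:
    if measure in ("lnIC50", "lnEC50"):
        return np.exp(values)
    return values


def potency_filter(
    hits: pd.DataFrame,
    responses: pd.DataFrame,
    threshold_um: float = 7.0,
) -> list[RepurposingHit]:
    """Evaluate the <7 uM average IC50/EC50 rule for each connectivity hit.

    ``hits`` needs columns perturbagen_id, score, p; ``responses`` is long
    form with columns perturbagen_id, cell_line, measure, value (and
    optionally source). Hits with fewer than 3 response values are retained
    with ``passes_potency=None`` and a warning.
    """
    out: list[RepurposingHit] = []
    has_source = "source" in responses.columns
    for _, hrow in hits.iterrows():
        pid = hrow["perturbagen_id"]
        sel = responses[responses["perturbagen_id"] == pid]
        hit = RepurposingHit(
            perturbagen_id=str(pid), score=float(hrow["score"]), p=float(hrow["p"])
        )
        if len(sel) < 3:
            warnings.warn(f"{pid}: fewer than 3 response values; potency undetermined")
            out.append(hit)
            continue
        sources = sel["source"].unique() if has_source else [None]
        best = None  # per-source verdicts; permissive across sources
        for source in sources:
            ssel = sel if source is None else sel[sel["source"] == source]
            means: dict[str, float] = {}
            n_out = 0
            for fam, (linear, ln) in (("IC50", ("IC50", "lnIC50")),
                                      ("EC50", ("EC50", "lnEC50"))):
                lin = ssel[ssel["measure"] == linear].set_index("cell_line")["value"]
                lnv = ssel[ssel["measure"] == ln].set_index("cell_line")["value"]
                # one uM value per line: prefer the linear measure, fall back
                # to exp(ln measure) for lines reported only on the ln scale
                combined = _to_um(lnv, ln)
                combined = lin.combine_first(combined)
                pooled = combined.dropna().to_numpy(float)
                if len(pooled) == 0:
                    continue
                kept, removed = tukey_trim(pooled)
                n_out += removed
                means[fam] = float(kept.mean())
            if not means:
                continue
            passes = all(m < threshold_um for m in means.values())
            cand = (passes, means.get("IC50", float("nan")),
                    means.get("EC50", float("nan")), n_out)
            if best is None or (cand[0] and not best[0]):
                best = cand
        if best is not None:
            hit.passes_potency, hit.mean_ic50, hit.mean_ec50, \
                hit.n_outliers_removed = best
        else:
            warnings.warn(f"{pid}: no usable response measures")
        out.append(hit)
    return out


def responder_genes(
    drug: str,
    panel: CellLinePanel,
    line_labels: pd.Series,
    p_max: float = 0.05,
) -> tuple[list[str], list[str]]:
    """Genes concordantly associated with response at mRNA and protein level.

    A gene is listed sensitive iff its call is sensitive at both levels
    (both p < p_max, same direction); resistant symmetric. Genes without
    protein data are excluded from candidacy.
    """
    sens, resi = [], []
    candidates = [g for g in panel.mrna.index if g in panel.protein.index]
    for gene in candidates:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            call_m = gene_drug_call(panel.mrna.loc[gene], line_labels,
                                    feature_id=gene, drug=drug, level="mRNA",
                                    p_max=p_max)
            call_p = gene_drug_call(panel.protein.loc[gene], line_labels,
                                    feature_id=gene, drug=drug, level="protein",
                                    p_max=p_max)
        if call_m.call == SENSITIVE and call_p.call == SENSITIVE:
            sens.append(gene)
        elif call_m.call == RESISTANT and call_p.call == RESISTANT:
            resi.append(gene)
    return sorted(sens), sorted(resi)


def top_alterations(
    mutations: pd.DataFrame,
    fusions: pd.DataFrame,
    lines=None,
    k: int = 1,
) -> pd.DataFrame:
    """Top-k mutated and fused genes per line (count desc, ties alphabetical)."""
    def top_of(table: pd.DataFrame, line: str) -> list[tuple[str, int]]:
        if table.empty:
            return []
        sel = table[table["cell_line"] == line]
        if sel.empty:
            return []
        ranked = sel.sort_values(["count", "gene"], ascending=[False, True],
                                 kind="stable")
        return [(str(g), int(c)) for g, c in
                zip(ranked["gene"].head(k), ranked["count"].head(k))]

    if lines is None:
        lines = sorted(
            set(mutations.get("cell_line", pd.Series(dtype=str)))
            | set(fusions.get("cell_line", pd.Series(dtype=str)))
        )
    rows = []
    for line in lines:
        rows.append(
            {
                "cell_line": line,
                "top_mutated": top_of(mutations, line),
                "top_fused": top_of(fusions, line),
            }
        )
    return pd.DataFrame(rows).set_index("cell_line")
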