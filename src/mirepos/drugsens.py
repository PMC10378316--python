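"""Drug-sensitivity classification of cell lines and pan-status calling.

Per drug and response source, cell lines are split into sensitive /
intermediate / resistant by tertiles of the ln-scale response value (low
response = sensitive). A feature (gene or miRNA, at mRNA, protein, or
miRNA level) is called sensitive to a drug when its expression is
significantly higher (Welch two-sample t-test, p < 0.05) in the sensitive
group, resistant when higher in the resistant group, intermediates being
excluded from the test. Pan-sensitive means: at least one sensitive call
and no resistant call anywhere across the drug x source x measure grid
(pan-resistant symmetric). Essentiality comes from CRISPR/RNAi dependency
scores: a gene whose score drops below -0.5 in more than half of the
screened lines is flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CellLinePanel, ValidationError

__all__ = [
    "SensitivityCall",
    "PanStatus",
    "classify_lines",
    "gene_drug_call",
    "feature_calls",
    "pan_status",
    "pan_table",
    "essentiality",
]

SENSITIVE = "sensitive"
RESISTANT = "resistant"
INTERMEDIATE = "intermediate"
NS = "ns"

PAN_SENSITIVE = "pan_sensitive"
PAN_RESISTANT = "pan_resistant"
NEITHER = "neither"


@dataclass
class SensitivityCall:
    feature_id: str
    drug: str
    source: str
    measure: str
    level: str  # mRNA / protein / miRNA
    call: str  # sensitive / resistant / ns
    p: float


@dataclass
class PanStatus:
    feature_id: str
    level: str
    status: str
    n_sensitive: int = 0
    n_resistant: int = 0


def _ln_scale(values: pd.Series, measure: str) -> pd.Series:
    if measure in ("IC50", "EC50"):
        return np.log(values)
    return values


def classify_lines(
    responses: pd.DataFrame,
    drug: str,
    source: str,
    measure: str,
    lower_q: float = 1 / 3,
    upper_q: float = 2 / 3,
) -> pd.Series:
    """Tertile split of lines on the ln-scale response for one drug/source.

    Lines at or below the lower tertile boundary are sensitive; at or above
    the upper boundary, resistant; everything between is intermediate.
    Quantiles use linear interpolation. Ranks (hence labels) are invariant
    under monotone transforms of the response values.
    """
    sel = responses[
        (responses["drug"] == drug)
        & (responses["source"] == source)
        & (responses["measure"] == measure)
    ]
    values = sel.set_index("cell_line")["value"].dropna()
    if len(values) < 9:
        raise ValidationError(
            f"need >= 9 lines for {drug}/{source}/{measure}, have {len(values)}"
        )
    ln = _ln_scale(values, measure)
    if ln.nunique() == 1:
        warnings.warn(f"all response values equal for {drug}/{source}/{measure}")
        return pd.Series(INTERMEDIATE, index=ln.index)
    lo = ln.quantile(lower_q, interpolation="linear")
    hi = ln.quantile(upper_q, interpolation="linear")
    labels = pd.Series(INTERMEDIATE, index=ln.index)
    labels[ln <= lo] = SENSITIVE
    labels[ln >= hi] = RESISTANT
    return labels


def gene_drug_call(
    values: pd.Series,
    line_labels: pd.Series,
    feature_id: str = "",
    drug: str = "",
    source: str = "",
    measure: str = "",
    level: str = "mRNA",
    p_max: float = 0.05,
    equal_var: bool = False,
) -> SensitivityCall:
    """Two-sample t-test call for one feature against one drug's line split.

    Welch by default (``equal_var=True`` for the pooled variant).
    Degenerate groups (fewer than two non-missing values on either side, or
    zero variance in both) yield an ``ns`` call with a warning.
    """
    sens = values.reindex(line_labels.index[line_labels == SENSITIVE]).dropna()
    resi = values.reindex(line_labels.index[line_labels == RESISTANT]).dropna()
    if len(sens) < 2 or len(resi) < 2:
        warnings.warn(f"degenerate groups for {feature_id}/{drug}; ns")
        return SensitivityCall(feature_id, drug, source, measure, level, NS, 1.0)
    if sens.std(ddof=1) == 0 and resi.std(ddof=1) == 0:
        if sens.mean() == resi.mean():
            return SensitivityCall(feature_id, drug, source, measure, level, NS, 1.0)
        # complete separation with zero variance: maximally significant
        p = 0.0
    else:
        with np.errstate(invalid="ignore"):
            p = float(
                stats.ttest_ind(sens, resi, equal_var=equal_var).pvalue
            )
        if np.isnan(p):
            p = 1.0
    if p < p_max:
        call = SENSITIVE if sens.mean() > resi.mean() else RESISTANT
    else:
        call = NS
    return SensitivityCall(feature_id, drug, source, measure, level, call, p)


def feature_calls(
    expression: pd.DataFrame,
    responses: pd.DataFrame,
    drugs,
    level: str = "mRNA",
    p_max: float = 0.05,
    measures=("lnIC50", "lnEC50"),
) -> pd.DataFrame:
    """Sensitivity calls for every feature x drug x source x measure.

    ``expression`` is features x lines. Drug/source/measure combinations
    without enough lines are skipped. Returns a long-form call table.
    """
    combos = []
    present = responses[["drug", "source", "measure"]].drop_duplicates()
    for _, row in present.iterrows():
        if row["drug"] in set(drugs) and row["measure"] in set(measures):
            combos.append((row["drug"], row["source"], row["measure"]))
    rows = []
    for drug, source, measure in sorted(combos):
        try:
            labels = classify_lines(responses, drug, source, measure)
        except ValidationError:
            continue
        labels = labels.reindex([l for l in labels.index if l in expression.columns])
        sens_idx = labels.index[labels == SENSITIVE]
        resi_idx = labels.index[labels == RESISTANT]
        sens = expression[sens_idx].to_numpy(float)
        resi = expression[resi_idx].to_numpy(float)
        if sens.shape[1] < 2 or resi.shape[1] < 2:
            continue
        with np.errstate(invalid="ignore"):
            res = stats.ttest_ind(sens, resi, axis=1, equal_var=False)
        p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
        ms, mr = sens.mean(axis=1), resi.mean(axis=1)
        zero_var = (sens.std(axis=1) == 0) & (resi.std(axis=1) == 0)
        p = np.where(zero_var & (ms != mr), 0.0, p)
        call = np.where(
            p < p_max, np.where(ms > mr, SENSITIVE, RESISTANT), NS
        )
        for fid, c, pv in zip(expression.index, call, p):
            rows.append(
                {
                    "feature_id": fid,
                    "drug": drug,
                    "source": source,
                    "measure": measure,
                    "level": level,
                    "call": c,
                    "p": float(pv),
                }
            )
    return pd.DataFrame(rows)


def pan_status(calls: pd.DataFrame, drugs, feature_id: str | None = None,
               level: str | None = None) -> PanStatus:
    """Pan classification of one feature's call table across a drug list.

    Requires coverage: every drug in ``drugs`` must carry at least one call
    (any source/measure); missing drugs raise with the gap list. Status is
    pan_sensitive iff there is >= 1 sensitive call and 0 resistant calls
    (symmetric for pan_resistant); features with both, or all-ns features,
    are neither.
    """
    if feature_id is None:
        ids = calls["feature_id"].unique()
        if len(ids) != 1:
            raise ValidationError("calls must concern a single feature")
        feature_id = str(ids[0])
    if level is None:
        level = str(calls["level"].iloc[0]) if len(calls) else "mRNA"
    covered = set(calls["drug"])
    gaps = sorted(set(drugs) - covered)
    if gaps:
        raise ValidationError(f"missing drug coverage for {feature_id}: {gaps}")
    n_sens = int((calls["call"] == SENSITIVE).sum())
    n_resi = int((calls["call"] == RESISTANT).sum())
    if n_sens >= 1 and n_resi == 0:
        status = PAN_SENSITIVE
    elif n_resi >= 1 and n_sens == 0:
        status = PAN_RESISTANT
    else:
        status = NEITHER
    return PanStatus(feature_id, level, status, n_sens, n_resi)


def pan_table(calls: pd.DataFrame, drugs) -> pd.DataFrame:
    """Pan status for every (feature, level) in a long-form call table."""
    rows = []
    for (fid, level), grp in calls.groupby(["feature_id", "level"]):
        st = pan_status(grp, drugs, feature_id=str(fid), level=str(level))
        rows.append(
            {
                "feature_id": st.feature_id,
                "level": st.level,
                "status": st.status,
                "n_sensitive": st.n_sensitive,
                "n_resistant": st.n_resistant,
            }
        )
    return pd.DataFrame(rows)


def essentiality(
    crispr: pd.DataFrame | None,
    rnai: pd.DataFrame | None,
    gene: str,
    score_max: float = -0.5,
    line_fraction: float = 0.5,
    mode: str = "either",
) -> tuple[float, float, bool]:
    """Dependency-based essentiality of one gene.

    Returns (fraction of CRISPR lines with score < score_max, same for
    RNAi, essential flag). ``mode='either'`` flags the gene when either
    screen crosses ``line_fraction``; ``'both'`` requires both screens.
    Screens missing the gene contribute NaN fractions.
    """
    fracs = {}
    for name, matrix in (("crispr", crispr), ("rnai", rnai)):
        if matrix is not None and gene in matrix.index:
            scores = matrix.loc[gene].dropna()
            fracs[name] = float((scores < score_max).mean()) if len(scores) else np.nan
        else:
            fracs[name] = np.nan
    if all(np.isnan(v) for v in fracs.values()):
        raise ValidationError(f"gene {gene!r} absent from both dependency screens")
    crossing = [v > line_fraction for v in fracs.values() if not np.isnan(v)]
    if mode == "either":
        essential = any(crossing)
    elif mode == "both":
        essential = all(crossing) and len(crossing) == 2
    else:
        raise ValidationError(f"unknown essentiality mode {mode!r}")
    return fracs["crispr"], fracs["rnai"], bool(essential)
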