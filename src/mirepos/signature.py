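"""Construction of the up/down query signature for connectivity screening.

The intended drug mechanism is to maintain expression of protective,
broadly drug-sensitive target genes and suppress hazardous, broadly
drug-resistant ones. Concretely, over the universe of miRNA target genes:

* up list: hazard ratio < 1 with log-rank p < 0.05, pan-sensitive at both
  the mRNA and protein levels, and not essential in the dependency screens
  (a gene whose knockout already kills the lines is not a gene to maintain);
* down list: hazard ratio > 1 with log-rank p < 0.05 and pan-resistant at
  both levels.

The lists are deterministic (sorted by gene id); no size cap is applied,
though a top-k truncation by log-rank p is available for parity
experiments.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .containers import Signature, ValidationError
from .drugsens import PAN_RESISTANT, PAN_SENSITIVE

__all__ = ["build_signature", "signature_trace"]


def _pan_map(pan: pd.DataFrame, level: str) -> dict[str, str]:
    sel = pan[pan["level"] == level]
    return dict(zip(sel["feature_id"], sel["status"]))


def build_signature(
    targets: pd.DataFrame,
    surv: pd.DataFrame,
    pan: pd.DataFrame,
    essentials: set[str],
    p_max: float = 0.05,
    top_k: int | None = None,
) -> tuple[Signature, pd.DataFrame]:
    """Build the up/down signature and its per-gene evidence table.

    ``targets`` is a miRNA-target interaction table (defines the gene
    universe), ``surv`` a survival screen indexed by feature with ``hr``
    and ``logrank_p`` columns, ``pan`` a long-form pan-status table with
    mRNA and protein levels, ``essentials`` the set of dependency-essential
    genes.
    """
    universe = sorted(set(targets["target_gene"]))
    if not universe:
        raise ValidationError("empty target-gene universe")
    pan_mrna = _pan_map(pan, "mRNA")
    pan_protein = _pan_map(pan, "protein")
    rows = []
    up, down = [], []
    for gene in universe:
        if gene not in surv.index:
            continue
        hr = float(surv.loc[gene, "hr"])
        p = float(surv.loc[gene, "logrank_p"])
        status_m = pan_mrna.get(gene, "absent")
        status_p = pan_protein.get(gene, "absent")
        essential = gene in essentials
        side = ""
        if p < p_max and hr < 1 and status_m == PAN_SENSITIVE \
                and status_p == PAN_SENSITIVE and not essential:
            side = "up"
            up.append(gene)
        elif p < p_max and hr > 1 and status_m == PAN_RESISTANT \
                and status_p == PAN_RESISTANT:
            side = "down"
            down.append(gene)
        rows.append(
            {
                "gene": gene,
                "hr": hr,
                "logrank_p": p,
                "pan_mrna": status_m,
                "pan_protein": status_p,
                "essential": essential,
                "side": side,
            }
        )
    evidence = pd.DataFrame(rows).set_index("gene")
    if top_k is not None:
        def truncate(genes: list[str]) -> list[str]:
            ranked = sorted(genes, key=lambda g: (evidence.loc[g, "logrank_p"], g))
            return sorted(ranked[:top_k])

        up, down = truncate(up), truncate(down)
    if not up or not down:
        warnings.warn("signature has an empty side; downstream screen will refuse it")
    return Signature(up=sorted(up), down=sorted(down)), evidence


def signature_trace(signature: Signature, targets: pd.DataFrame) -> list[tuple[str, str, str]]:
    """miRNA -> signature-gene edges for the network export.

    Every signature gene traces back to at least one source miRNA in the
    interaction table; the relation encodes the side of the signature.
    """
    edges = []
    members = {g: "up" for g in signature.up} | {g: "down" for g in signature.down}
    for _, row in targets.iterrows():
        gene = row["target_gene"]
        if gene in members:
            relation = (
                "targets_up_signature" if members[gene] == "up"
                else "targets_down_signature"
            )
            edges.append((row["mirna_id"], relation, gene))
    return sorted(set(edges))
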