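"""Local connectivity engine: bidirectional weighted-KS signature matching.

A perturbation profile assigns every gene a differential-expression score.
Genes are ranked by descending score (ties broken by gene id) and a tag
set's enrichment is the signed maximum deviation of a weighted
Kolmogorov-Smirnov running sum: positions holding a tag add
``|score|^w`` (normalized over the tags), other positions subtract
``1/(N - n_tags)``. The bidirectional connectivity score of an up/down
signature is ``(ES_up - ES_down) / 2`` when the two enrichments have
opposite signs and 0 otherwise, giving the conventional [-1, 1] range
where 1 is maximal expression similarity.

Significance is assessed by tag permutation: random disjoint up/down sets
of matching sizes drawn from the profile's gene universe, enumerated
exhaustively when the number of arrangements is small enough.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .containers import PerturbationLibrary, Signature, ValidationError

__all__ = [
    "ConnectivityResult",
    "es_weighted",
    "connectivity_score",
    "permutation_p",
    "screen_library",
]


@dataclass
class ConnectivityResult:
    perturbagen_id: str
    es_up: float
    es_down: float
    score: float
    p: float = float("nan")
    n_perm: int = 0
    seed: int | None = None


def _ranked_profile(profile: pd.Series):
    """Sort a profile by descending score, ties by gene id. Returns
    (gene ids in rank order, scores in rank order)."""
    frame = profile.rename("score").rename_axis("gene").reset_index()
    frame = frame.sort_values(["score", "gene"], ascending=[False, True],
                              kind="stable")
    return frame["gene"].to_numpy(), frame["score"].to_numpy(float)


def _es_from_positions(P: np.ndarray, weights: np.ndarray, N: int) -> np.ndarray:
    """Enrichment scores for B tag sets given by sorted rank positions.

    P is (B, k) ascending positions into the ranked profile; ``weights`` is
    ``|score|^w`` in rank order. The running sum's extremes occur right
    after a tag (local max) or right before one (local min), so only those
    2k candidates are inspected.
    """
    B, k = P.shape
    if N - k <= 0:
        raise ValidationError("tag set covers the whole universe")
    wt = weights[P]
    denom = wt.sum(axis=1, keepdims=True)
    uniform = denom <= 0
    if uniform.any():
        # all-zero weights degenerate to the unweighted statistic
        wt = np.where(uniform, 1.0, wt)
        denom = wt.sum(axis=1, keepdims=True)
    hits = np.cumsum(wt, axis=1) / denom
    i = np.arange(k)
    miss_after = (P - i) / (N - k)  # misses seen once the i-th tag is passed
    dev_after = hits - miss_after
    dev_before = (hits - wt / denom) - miss_after
    cand = np.concatenate([dev_after, dev_before], axis=1)
    idx = np.argmax(np.abs(cand), axis=1)
    return cand[np.arange(B), idx]


def es_weighted(tags, profile: pd.Series, weight_exponent: float = 1.0) -> float:
    """Weighted-KS enrichment of one tag set against one profile."""
    genes, scores = _ranked_profile(profile)
    gene_pos = {g: i for i, g in enumerate(genes)}
    positions = sorted(gene_pos[t] for t in tags if t in gene_pos)
    if not positions:
        raise ValidationError("no tag overlaps the profile universe")
    weights = np.abs(scores) ** weight_exponent
    es = _es_from_positions(
        np.array([positions]), weights, len(genes)
    )
    return float(es[0])


def _signature_positions(signature: Signature, genes: np.ndarray):
    gene_pos = {g: i for i, g in enumerate(genes)}
    up = sorted(gene_pos[g] for g in signature.up if g in gene_pos)
    down = sorted(gene_pos[g] for g in signature.down if g in gene_pos)
    return up, down


def _wtcs(es_up: float, es_down: float) -> float:
    if np.sign(es_up) == np.sign(es_down):
        return 0.0
    return (es_up - es_down) / 2.0


def connectivity_score(
    signature: Signature, profile: pd.Series, perturbagen_id: str = "",
    weight_exponent: float = 1.0
) -> ConnectivityResult:
    """Bidirectional weighted-KS score of a signature against a profile."""
    if not signature.up or not signature.down:
        raise ValidationError("signature lists must be non-empty")
    genes, scores = _ranked_profile(profile)
    up, down = _signature_positions(signature, genes)
    if not up or not down:
        raise ValidationError("signature does not overlap the profile universe")
    weights = np.abs(scores) ** weight_exponent
    es_up = float(_es_from_positions(np.array([up]), weights, len(genes))[0])
    es_down = float(_es_from_positions(np.array([down]), weights, len(genes))[0])
    return ConnectivityResult(
        perturbagen_id=perturbagen_id,
        es_up=es_up,
        es_down=es_down,
        score=_wtcs(es_up, es_down),
    )


def _null_scores_sampled(
    weights: np.ndarray, N: int, n_up: int, n_down: int, n_perm: int,
    rng: np.random.Generator
) -> np.ndarray:
    # random disjoint tag sets = random disjoint rank-position sets
    draws = rng.random((n_perm, N)).argsort(axis=1)[:, : n_up + n_down]
    up_pos = np.sort(draws[:, :n_up], axis=1)
    down_pos = np.sort(draws[:, n_up:], axis=1)
    es_up = _es_from_positions(up_pos, weights, N)
    es_down = _es_from_positions(down_pos, weights, N)
    both = np.stack([es_up, es_down])
    same_sign = np.sign(both[0]) == np.sign(both[1])
    return np.where(same_sign, 0.0, (both[0] - both[1]) / 2.0)


def _null_scores_exhaustive(weights: np.ndarray, N: int, n_up: int,
                            n_down: int) -> np.ndarray:
    out = []
    positions = range(N)
    for up in combinations(positions, n_up):
        rest = [p for p in positions if p not in set(up)]
        es_up = float(_es_from_positions(np.array([up]), weights, N)[0])
        for down in combinations(rest, n_down):
            es_down = float(_es_from_positions(np.array([down]), weights, N)[0])
            out.append(_wtcs(es_up, es_down))
    return np.asarray(out)


def permutation_p(
    signature: Signature,
    profile: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> tuple[float, ConnectivityResult]:
    """Tag-permutation p-value for |score| of a signature against a profile.

    Exhaustive over all ordered disjoint (up, down) position pairs when
    their number is at most ``n_perm`` (p = k / n_total); otherwise sampled
    with the add-one convention p = (1 + k) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    obs = connectivity_score(signature, profile,
                             weight_exponent=weight_exponent)
    genes, scores = _ranked_profile(profile)
    N = len(genes)
    up, down = _signature_positions(signature, genes)
    n_up, n_down = len(up), len(down)
    if N - n_up - n_down < 1:
        raise ValidationError("universe too small for disjoint random tag sets")
    weights = np.abs(scores) ** weight_exponent
    n_total = comb(N, n_up) * comb(N - n_up, n_down)
    if n_total <= n_perm:
        null = _null_scores_exhaustive(weights, N, n_up, n_down)
        k = int((np.abs(null) >= abs(obs.score) - 1e-12).sum())
        p = k / len(null)
        obs.n_perm = len(null)
    else:
        rng = np.random.default_rng(seed)
        null = _null_scores_sampled(weights, N, n_up, n_down, n_perm, rng)
        k = int((np.abs(null) >= abs(obs.score) - 1e-12).sum())
        p = (1.0 + k) / (1.0 + n_perm)
        obs.n_perm = n_perm
    obs.p = p
    obs.seed = seed
    return p, obs


def screen_library(
    signature: Signature,
    library: PerturbationLibrary,
    score_min: float = 0.9,
    p_max: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> pd.DataFrame:
    """Score every perturbagen and flag hits (score > score_min, p < p_max).

    Each perturbagen (compound, compound-set consensus, knockdown or
    pathway entry alike) is scored as its own profile. The result frame is
    ranked by descending score with ties broken by perturbagen id.
    """
    rows = []
    for pert_id in library.perturbagen_ids:
        profile = library.profile(pert_id).dropna()
        _, res = permutation_p(
            signature, profile, n_perm=n_perm, seed=seed,
            weight_exponent=weight_exponent,
        )
        meta = library.meta.loc[pert_id]
        rows.append(
            {
                "perturbagen_id": pert_id,
                "perturbagen_class": meta.get("perturbagen_class", "compound"),
                "compound_set": meta.get("compound_set", ""),
                "es_up": res.es_up,
                "es_down": res.es_down,
                "score": res.score,
                "p": res.p,
                "n_perm": res.n_perm,
                "hit": bool(res.score > score_min and res.p < p_max),
            }
        )
    frame = pd.DataFrame(rows)
    frame = frame.sort_values(
        ["score", "perturbagen_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return frame
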