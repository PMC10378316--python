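"""Detection-threshold filtering, SAM testing, fold changes, marker selection.

The moderated statistic follows the original SAM recipe: for feature *i*,
``d_i = (mean_tumor - mean_normal) / (s_i + s0)`` where ``s_i`` is the usual
pooled standard error (unpaired) or the standard error of within-pair
differences (paired), and the exchangeability constant ``s0`` is tuned by
minimizing the coefficient of variation of ``d`` across windows of ``s``.
Significance comes from label permutations (sign flips of per-pair
differences in paired mode), enumerated exhaustively when the number of
distinct permutations is small enough; the false discovery rate is the
SAM-style pooled permutation estimate (no pi0 shrinkage, so it is
conservative).

Marker selection applies the study's three-fold rule: linear fold change
> 2 or < 0.5, p < 0.05, and permutation FDR < 0.05, all strict.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, ExpressionStudy, ValidationError

__all__ = [
    "SamConfig",
    "DetectionThreshold",
    "detection_filter",
    "sam_test",
    "fold_change",
    "marker_table",
    "select_markers",
]


@dataclass
class SamConfig:
    n_perm: int = 1000
    seed: int = 0
    s0_percentiles: tuple[float, ...] = tuple(range(0, 101, 5))
    paired: bool = False
    exhaustive_if_feasible: bool = True

    def __post_init__(self) -> None:
        if self.n_perm < 100 and not self.exhaustive_if_feasible:
            raise ValidationError("n_perm must be >= 100 unless exhaustive")


@dataclass
class DetectionThreshold:
    """Per-array signal threshold: 5 x background SD + 10% trimmed mean of
    the negative-control probes."""

    array_id: str
    background_sd: float
    negctrl_trimmed_mean: float

    @property
    def threshold(self) -> float:
        return 5.0 * self.background_sd + self.negctrl_trimmed_mean


def detection_filter(
    raw: ExpressionMatrix, low_fraction: float = 1.0
) -> tuple[ExpressionMatrix, list[DetectionThreshold]]:
    """Remove consistently-low measurement probes.

    A measurement probe is dropped iff its signal falls below the per-array
    detection threshold on at least ``low_fraction`` of the arrays
    (default: all of them). Control probes never appear in the output.
    """
    if not 0 < low_fraction <= 1:
        raise ValidationError("low_fraction must be in (0, 1]")
    if raw.probe_class is None:
        raise ValidationError("matrix carries no probe classes")
    pc = raw.probe_class
    bg = raw.values.loc[pc[pc == "background"].index]
    nc = raw.values.loc[pc[pc == "negative_control"].index]
    if bg.empty or nc.empty:
        raise ValidationError("background and negative_control probes required")
    thresholds = [
        DetectionThreshold(
            array_id=str(col),
            background_sd=float(bg[col].std(ddof=1)),
            negctrl_trimmed_mean=float(
                stats.trim_mean(nc[col].dropna(), proportiontocut=0.1)
            ),
        )
        for col in raw.values.columns
    ]
    cutoffs = np.array([t.threshold for t in thresholds])
    meas = raw.values.loc[pc[pc == "measurement"].index]
    below = meas.lt(cutoffs, axis=1)
    frac_below = below.mean(axis=1)
    # strict "at least" on a fraction: use >= with a tiny tolerance guard
    keep = meas.index[frac_below < low_fraction - 1e-12]
    return ExpressionMatrix(meas.loc[keep]), thresholds


# ---------------------------------------------------------------------------
# SAM


def _pooled_se(X: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray):
    """Tusher pooled standard error and mean difference (a minus b)."""
    na, nb = len(idx_a), len(idx_b)
    A, B = X[:, idx_a], X[:, idx_b]
    ma, mb = A.mean(axis=1), B.mean(axis=1)
    ssa = ((A - ma[:, None]) ** 2).sum(axis=1)
    ssb = ((B - mb[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / na + 1.0 / nb) * (ssa + ssb) / (na + nb - 2))
    return ma - mb, s


def _paired_se(D: np.ndarray):
    """Mean and standard error of within-pair differences (rows = features)."""
    n = D.shape[1]
    m = D.mean(axis=1)
    s = D.std(axis=1, ddof=1) / np.sqrt(n)
    return m, s


def tune_s0(r: np.ndarray, s: np.ndarray,
            percentiles=tuple(range(0, 101, 5)), n_windows: int = 100) -> float:
    """Choose s0 from candidate percentiles of s by the SAM CV criterion.

    For each candidate, the median absolute deviation of ``d = r/(s+s0)``
    is computed within ~``n_windows`` quantile windows of ``s``; the winner
    minimizes the coefficient of variation of those MADs. Falls back to the
    median of ``s`` when there are too few features to window.
    """
    if len(s) < 10:
        return float(np.median(s))
    order = np.argsort(s, kind="stable")
    s_sorted, r_sorted = s[order], r[order]
    edges = np.unique(
        np.linspace(0, len(s), min(n_windows, max(2, len(s) // 5)) + 1).astype(int)
    )
    best_s0, best_cv = float(np.median(s)), np.inf
    for pct in percentiles:
        s0 = float(np.percentile(s, pct))
        d = r_sorted / (s_sorted + s0)
        mads = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            if hi - lo >= 2:
                seg = d[lo:hi]
                mads.append(np.median(np.abs(seg - np.median(seg))))
        mads = np.asarray(mads)
        if len(mads) < 2 or mads.mean() == 0:
            continue
        cv = mads.std(ddof=1) / mads.mean()
        if cv < best_cv - 1e-15:
            best_cv, best_s0 = cv, s0
    return best_s0


def _unpaired_permutations(n_a: int, n_total: int, cfg: SamConfig):
    """Index sets for group A under permutation. Returns (list, exhaustive)."""
    from math import comb

    n_distinct = comb(n_total, n_a)
    if cfg.exhaustive_if_feasible and n_distinct <= cfg.n_perm:
        return [np.array(c) for c in combinations(range(n_total), n_a)], True
    rng = np.random.default_rng(cfg.seed)
    perms = []
    for _ in range(cfg.n_perm):
        perm = rng.permutation(n_total)
        perms.append(np.sort(perm[:n_a]))
    return perms, False


def _paired_signs(n_pairs: int, cfg: SamConfig):
    n_distinct = 2 ** n_pairs
    if cfg.exhaustive_if_feasible and n_distinct <= cfg.n_perm:
        return [np.array(sgn) for sgn in product((1.0, -1.0), repeat=n_pairs)], True
    rng = np.random.default_rng(cfg.seed)
    return [rng.choice([1.0, -1.0], size=n_pairs) for _ in range(cfg.n_perm)], False


def _perm_pvalues(d_obs: np.ndarray, d_perm: np.ndarray, exhaustive: bool):
    """Per-feature permutation p and pooled SAM FDR q.

    p_i counts permutations with |d_i^b| >= |d_i|; sampled permutations use
    the add-one convention (1+k)/(1+B), exhaustive enumerations use k/B
    (the observed labelling is one of the enumerated arrangements).
    """
    B = d_perm.shape[0]
    abs_obs = np.abs(d_obs)
    abs_perm = np.abs(d_perm)
    exceed = (abs_perm >= abs_obs[None, :] - 1e-12).sum(axis=0)
    if exhaustive:
        p = exceed / B
    else:
        p = (1.0 + exceed) / (1.0 + B)
    # pooled FDR: E[#perm |d| >= t] / #obs |d| >= t, then q = min over
    # attainable thresholds t <= |d_i|
    pool = np.sort(abs_perm.ravel())
    m = len(d_obs)
    order = np.argsort(-abs_obs, kind="stable")
    thresholds = abs_obs[order]
    n_obs_ge = np.arange(1, m + 1)
    n_perm_ge = len(pool) - np.searchsorted(pool, thresholds - 1e-12, side="left")
    fdr = np.minimum(1.0, (n_perm_ge / B) / n_obs_ge)
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty(m)
    q[order] = q_sorted
    return p, q


def sam_test(
    matrix: ExpressionMatrix, annotation: pd.DataFrame, cfg: SamConfig
) -> pd.DataFrame:
    """SAM moderated test of tumor vs normal, unpaired or paired.

    Returns a frame indexed by feature with columns ``d_stat``, ``s``,
    ``s0``, ``p_value`` (permutation), ``t_p`` (plain Welch or paired t),
    ``q_value`` (permutation FDR) and ``constant`` (flag for all-constant
    features whose d is defined through s0 alone).
    """
    ann = annotation.set_index("sample_id")
    samples = [s for s in matrix.sample_ids if s in ann.index]
    X = matrix.values[samples].to_numpy(float)
    cond = ann.loc[samples, "condition"].to_numpy()

    if cfg.paired:
        if "patient_id" not in ann.columns:
            raise ValidationError("paired mode requires patient_id annotation")
        pid = ann.loc[samples, "patient_id"]
        pairs = []
        for patient, grp in pid.groupby(pid):
            members = grp.index
            tum = [s for s in members if ann.loc[s, "condition"] == "tumor"]
            nor = [s for s in members if ann.loc[s, "condition"] == "normal"]
            if tum and nor:
                pairs.append((samples.index(tum[0]), samples.index(nor[0])))
            else:
                warnings.warn(f"incomplete pair for patient {patient!r}; skipped")
        if len(pairs) < 2:
            raise ValidationError("paired SAM needs >= 2 complete pairs")
        D = np.stack([X[:, t] - X[:, n] for t, n in pairs], axis=1)
        r, s = _paired_se(D)
        s0 = tune_s0(r, s, cfg.s0_percentiles)
        signs, exhaustive = _paired_signs(D.shape[1], cfg)
        d_perm = np.stack(
            [_paired_se(D * sgn[None, :])[0] for sgn in signs], axis=0
        ) / (
            np.stack([_paired_se(D * sgn[None, :])[1] for sgn in signs], axis=0) + s0
        )
        t_p = stats.ttest_rel(
            X[:, [t for t, _ in pairs]], X[:, [n for _, n in pairs]], axis=1
        ).pvalue
    else:
        idx_t = np.flatnonzero(cond == "tumor")
        idx_n = np.flatnonzero(cond == "normal")
        if len(idx_t) < 2 or len(idx_n) < 2:
            raise ValidationError("need >= 2 samples per condition")
        r, s = _pooled_se(X, idx_t, idx_n)
        s0 = tune_s0(r, s, cfg.s0_percentiles)
        perms, exhaustive = _unpaired_permutations(len(idx_t), len(samples), cfg)
        all_idx = np.arange(len(samples))
        d_rows = []
        for pa in perms:
            pb = np.setdiff1d(all_idx, pa, assume_unique=True)
            rp, sp = _pooled_se(X, pa, pb)
            d_rows.append(rp / (sp + s0))
        d_perm = np.stack(d_rows, axis=0)
        with np.errstate(invalid="ignore"):
            t_p = stats.ttest_ind(X[:, idx_t], X[:, idx_n], axis=1,
                                  equal_var=False).pvalue
        t_p = np.where(np.isnan(t_p), 1.0, t_p)

    if s0 <= 0 and (s == 0).any():
        s0 = max(s0, 1e-8)  # all-constant features: keep d finite through s0
    d_obs = r / (s + s0)
    p, q = _perm_pvalues(d_obs, d_perm, exhaustive)
    return pd.DataFrame(
        {
            "d_stat": d_obs,
            "s": s,
            "s0": s0,
            "p_value": p,
            "t_p": t_p,
            "q_value": q,
            "constant": s == 0,
        },
        index=matrix.feature_ids,
    )


# ---------------------------------------------------------------------------
# Fold change and marker selection


def fold_change(
    matrix: ExpressionMatrix, annotation: pd.DataFrame, paired: bool = False
) -> pd.Series:
    """Linear tumor/normal fold change from log2 data.

    Unpaired: ``2 ** (mean_tumor - mean_normal)``. Paired: ``2 ** mean`` of
    per-pair log2 differences; incomplete pairs are skipped with a warning.
    """
    ann = annotation.set_index("sample_id")
    samples = [s for s in matrix.sample_ids if s in ann.index]
    values = matrix.values[samples]
    cond = ann.loc[samples, "condition"]
    if not paired:
        mt = values.loc[:, (cond == "tumor").to_numpy()].mean(axis=1)
        mn = values.loc[:, (cond == "normal").to_numpy()].mean(axis=1)
        return np.power(2.0, mt - mn).rename("fc_unpaired")
    if "patient_id" not in ann.columns:
        raise ValidationError("paired fold change requires patient_id annotation")
    diffs = []
    for patient, grp in ann.loc[samples].groupby("patient_id"):
        tum = grp.index[grp["condition"] == "tumor"]
        nor = grp.index[grp["condition"] == "normal"]
        if len(tum) and len(nor):
            diffs.append(values[tum[0]] - values[nor[0]])
        else:
            warnings.warn(f"incomplete pair for patient {patient!r}; skipped")
    if not diffs:
        raise ValidationError("no complete pairs for paired fold change")
    return np.power(2.0, pd.concat(diffs, axis=1).mean(axis=1)).rename("fc_paired")


def marker_table(
    study: ExpressionStudy, cfg: SamConfig, with_paired_fc: bool | None = None
) -> pd.DataFrame:
    """SAM results merged with fold changes into one marker frame."""
    res = sam_test(study.matrix, study.annotation, cfg)
    res["fc_unpaired"] = fold_change(study.matrix, study.annotation, paired=False)
    has_pairs = (
        "patient_id" in study.annotation.columns
        and study.annotation["patient_id"].notna().any()
    )
    if with_paired_fc is None:
        with_paired_fc = cfg.paired
    if with_paired_fc and has_pairs:
        res["fc_paired"] = fold_change(study.matrix, study.annotation, paired=True)
    else:
        res["fc_paired"] = np.nan
    fc = res["fc_paired"] if cfg.paired else res["fc_unpaired"]
    res["fc"] = fc
    res["direction"] = np.where(fc > 1.0, "up", "down")
    res.index.name = "feature_id"
    return res


def select_markers(
    results: pd.DataFrame,
    fc_hi: float = 2.0,
    fc_lo: float = 0.5,
    p_max: float = 0.05,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Apply the three selection rules with strict inequalities.

    Keeps features with (fc > fc_hi or fc < fc_lo) and p < p_max and
    q < q_max; boundary values are excluded.
    """
    if results.empty:
        raise ValidationError("empty marker results")
    fc = results["fc"] if "fc" in results.columns else results["fc_unpaired"]
    keep = (
        ((fc > fc_hi) | (fc < fc_lo))
        & (results["p_value"] < p_max)
        & (results["q_value"] < q_max)
    )
    return results.loc[keep]
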