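"""Synthetic-data generators with planted, recoverable ground truth.

Every pipeline input can be generated here with known truth: a miRNA
microarray study with planted tumor/normal log2 shifts (plus control-probe
blocks for detection filtering, matched-pair patient effects, and a
blood-concordant marker subset), an exponential-hazard survival cohort
with planted proportional-hazard effects and uniform independent
censoring, a multi-omic cell-line panel with genes planted to separate
sensitive from resistant lines concordantly at the mRNA and protein
levels, a miRNA-target interaction table, and a perturbation-profile
library containing planted "reversal" compounds whose profiles match a
query signature (plus potency decoys with high IC50).

Determinism: all draws flow from ``numpy.random.default_rng`` seeded with
``(cfg.seed, stream)`` where ``stream`` is a fixed per-generator constant,
so an identical config reproduces identical outputs bit for bit while the
generators stay independently callable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .containers import (
    CellLinePanel,
    ExpressionMatrix,
    ExpressionStudy,
    GroundTruth,
    PerturbationLibrary,
    Signature,
    SurvivalCohort,
    ValidationError,
)

__all__ = [
    "SynthConfig",
    "gen_mirna_study",
    "gen_survival_cohort",
    "gen_cellline_panel",
    "gen_target_db",
    "gen_perturbation_library",
]

# fixed per-generator seed streams
_STREAM_STUDY = 1
_STREAM_SURVIVAL = 2
_STREAM_PANEL = 3
_STREAM_TARGETS = 4
_STREAM_LIBRARY = 5


@dataclass
class SynthConfig:
    """Study conditions for the synthetic datasets.

    The defaults mirror the profiled breast-cancer study the pipeline
    emulates: 45 tumor and 7 normal tissue arrays (52 in all, four of them
    matched pairs), 3 cancer and 6 normal blood samples, 1087 miRNA probes
    with 86 planted differentially expressed markers (log2 shift 2, i.e.
    4-fold), 12 of them prognostic with log-hazard ln(2), a TCGA-sized
    survival cohort thinned to 500 subjects for screening, ~30 profiled
    cell lines against 19 guideline drugs from three response sources, and
    a 100-perturbagen connectivity library with one planted reversal
    compound and one high-IC50 decoy.
    """

    seed: int = 0
    # miRNA study
    n_tumor: int = 45
    n_normal: int = 7
    n_matched_pairs: int = 4
    n_blood_cancer: int = 3
    n_blood_normal: int = 6
    n_features: int = 1087
    n_planted_de: int = 86
    n_blood_concordant: int = 6
    planted_log2fc: float = 2.0
    noise_sd: float = 0.5
    pair_effect_sd: float = 0.3
    n_negctrl_probes: int = 40
    n_background_probes: int = 40
    n_low_probes: int = 50
    background_mean: float = 4.0
    background_sd: float = 0.2
    # survival cohort
    n_subjects: int = 500
    n_planted_prognostic: int = 12
    planted_beta: float = float(np.log(2))
    censor_rate: float = 0.2
    baseline_hazard: float = 0.02  # events per month
    # cell-line panel
    n_lines: int = 31
    n_drugs: int = 19
    sources: tuple[str, ...] = ("PRISM", "GDSC1", "GDSC2")
    n_planted_sensitive: int = 10
    n_planted_resistant: int = 10
    n_discordant: int = 5
    n_planted_essential: int = 2
    sensitivity_effect: float = 2.0  # log2 shift per SD of line sensitivity
    panel_noise_sd: float = 0.3
    protein_noise_sd: float = 0.7  # gene-level mRNA-protein correlation ~0.4
    response_noise_sd: float = 0.05
    # target database
    targets_per_mirna: int = 5
    # perturbation library
    n_perturbagens: int = 100
    n_planted_hits: int = 1
    n_planted_decoys: int = 1
    profile_noise_sd: float = 0.0  # jitter on rank scores of planted hits
    n_response_lines: int = 10
    hit_potency_um: float = 1.5
    decoy_potency_um: float = 50.0

    def __post_init__(self) -> None:
        counts = dict(
            n_tumor=self.n_tumor,
            n_normal=self.n_normal,
            n_features=self.n_features,
            n_lines=self.n_lines,
            n_drugs=self.n_drugs,
            n_subjects=self.n_subjects,
            n_perturbagens=self.n_perturbagens,
        )
        for name, value in counts.items():
            if value <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not 0 <= self.censor_rate < 1:
            raise ValidationError("censor_rate must be in [0, 1)")
        if self.n_planted_de > self.n_features:
            raise ValidationError("n_planted_de exceeds n_features")
        if self.n_matched_pairs > min(self.n_tumor, self.n_normal):
            raise ValidationError("n_matched_pairs exceeds group sizes")


def _feature_ids(cfg: SynthConfig) -> list[str]:
    return [f"hsa-miR-s{i:04d}" for i in range(1, cfg.n_features + 1)]


def gen_mirna_study(cfg: SynthConfig) -> tuple[ExpressionStudy, GroundTruth]:
    """Raw-intensity miRNA study with planted DE markers and control probes.

    Planted features get a tumor-vs-normal mean log2 shift of exactly
    ``planted_log2fc`` (alternating up/down); the first
    ``n_blood_concordant`` planted features carry the same-direction shift
    in the blood compartment. Matched pairs share an additive patient
    effect. The matrix additionally carries negative-control and background
    probe blocks near ``background_mean`` and a block of consistently-low
    measurement probes, so detection filtering is exercisable.
    """
    rng = np.random.default_rng([cfg.seed, _STREAM_STUDY])
    features = _feature_ids(cfg)
    planted = features[: cfg.n_planted_de]
    directions = {f: ("up" if i % 2 == 0 else "down") for i, f in enumerate(planted)}
    blood_concordant = set(planted[: cfg.n_blood_concordant])

    tissue_tumor = [f"TT{i:03d}" for i in range(1, cfg.n_tumor + 1)]
    tissue_normal = [f"TN{i:03d}" for i in range(1, cfg.n_normal + 1)]
    blood_cancer = [f"BC{i:03d}" for i in range(1, cfg.n_blood_cancer + 1)]
    blood_normal = [f"BN{i:03d}" for i in range(1, cfg.n_blood_normal + 1)]
    samples = tissue_tumor + tissue_normal + blood_cancer + blood_normal

    ann_rows = []
    for i, s in enumerate(tissue_tumor):
        pid = f"P{i:03d}" if i < cfg.n_matched_pairs else None
        ann_rows.append((s, "tumor", "tissue", pid))
    for i, s in enumerate(tissue_normal):
        pid = f"P{i:03d}" if i < cfg.n_matched_pairs else None
        ann_rows.append((s, "normal", "tissue", pid))
    for s in blood_cancer:
        ann_rows.append((s, "tumor", "blood", None))
    for s in blood_normal:
        ann_rows.append((s, "normal", "blood", None))
    annotation = pd.DataFrame(
        ann_rows, columns=["sample_id", "condition", "specimen", "patient_id"]
    )

    n_meas = cfg.n_features
    baseline = rng.uniform(6.0, 12.0, size=n_meas)
    # consistently-low probes sit at background level, below every threshold
    low_idx = rng.choice(
        np.arange(cfg.n_planted_de, n_meas),
        size=min(cfg.n_low_probes, n_meas - cfg.n_planted_de),
        replace=False,
    )
    baseline[low_idx] = cfg.background_mean - 1.0

    values = np.tile(baseline[:, None], (1, len(samples)))
    values = values + rng.normal(0.0, cfg.noise_sd, size=values.shape)

    ann_idx = annotation.set_index("sample_id")
    pair_effects = rng.normal(0.0, cfg.pair_effect_sd, size=cfg.n_matched_pairs)
    for j, s in enumerate(samples):
        row = ann_idx.loc[s]
        pid = row["patient_id"]
        if isinstance(pid, str):
            values[:, j] += pair_effects[int(pid[1:])]
        if row["condition"] == "tumor":
            for i, f in enumerate(planted):
                if row["specimen"] == "tissue" or f in blood_concordant:
                    shift = cfg.planted_log2fc
                    if directions[f] == "down":
                        shift = -shift
                    values[i, j] += shift

    low_set = {features[i] for i in low_idx}
    probe_class = ["measurement"] * n_meas
    negctrl = [f"NEGCTRL{i:03d}" for i in range(1, cfg.n_negctrl_probes + 1)]
    background = [f"BKGD{i:03d}" for i in range(1, cfg.n_background_probes + 1)]
    ctrl_values = rng.normal(
        cfg.background_mean,
        cfg.background_sd,
        size=(len(negctrl) + len(background), len(samples)),
    )
    all_features = features + negctrl + background
    all_values = np.vstack([values, ctrl_values])
    probe_class = probe_class + ["negative_control"] * len(negctrl) + [
        "background"
    ] * len(background)

    matrix = ExpressionMatrix(
        pd.DataFrame(all_values, index=all_features, columns=samples),
        pd.Series(probe_class, index=all_features),
    )
    truth = GroundTruth(planted_de=directions, blood_concordant=blood_concordant)
    truth.low_probes = low_set  # extra attribute used by generator tests
    return ExpressionStudy(matrix=matrix, annotation=annotation), truth


def _uniform_censor_bound(cfg: SynthConfig) -> float:
    """Upper bound b of the Uniform(0, b) censoring time.

    Solved so the expected censored fraction under the baseline exponential
    hazard equals ``censor_rate``: P(T > C) with T ~ Exp(lam0), C ~ U(0, b)
    is (1 - exp(-lam0 b)) / (lam0 b).
    """
    r = cfg.censor_rate
    if r == 0:
        return float("inf")
    f = lambda x: (1.0 - np.exp(-x)) / x - r
    x = brentq(f, 1e-9, 1e9)
    return x / cfg.baseline_hazard


def gen_survival_cohort(
    cfg: SynthConfig, features, betas: dict[str, float] | None = None
) -> tuple[SurvivalCohort, GroundTruth]:
    """Survival cohort with exponential event times and planted PH effects.

    Per-subject hazard is ``baseline_hazard * exp(sum_f beta_f z_f)`` over
    the planted features' standardized expression. When ``betas`` is not
    given, the first ``n_planted_prognostic`` features get ``planted_beta``
    with alternating sign. Censoring times are Uniform(0, b), independent
    of everything, with b calibrated to ``censor_rate``.
    """
    features = list(features)
    if not features:
        raise ValidationError("feature list must be non-empty")
    rng = np.random.default_rng([cfg.seed, _STREAM_SURVIVAL])
    if betas is None:
        k = min(cfg.n_planted_prognostic, len(features))
        betas = {
            f: (cfg.planted_beta if i % 2 == 0 else -cfg.planted_beta)
            for i, f in enumerate(features[:k])
        }
    unknown = set(betas) - set(features)
    if unknown:
        raise ValidationError(f"betas reference unknown features: {sorted(unknown)[:5]}")
    subjects = [f"S{i:04d}" for i in range(1, cfg.n_subjects + 1)]
    Z = rng.normal(0.0, 1.0, size=(len(features), len(subjects)))
    expression = pd.DataFrame(Z + 8.0, index=features, columns=subjects)
    log_hr = np.zeros(len(subjects))
    for f, beta in betas.items():
        log_hr += beta * Z[features.index(f)]
    lam = cfg.baseline_hazard * np.exp(log_hr)
    T = rng.exponential(1.0 / lam)
    if cfg.censor_rate > 0:
        b = _uniform_censor_bound(cfg)
        C = rng.uniform(0.0, b, size=len(subjects))
        time = np.minimum(T, C)
        event = (T <= C).astype(int)
    else:
        time, event = T, np.ones(len(subjects), dtype=int)
    time = np.maximum(time, 1e-6)
    clinical = pd.DataFrame({"time": time, "event": event}, index=subjects)
    cohort = SurvivalCohort(clinical=clinical, expression=expression)
    return cohort, GroundTruth(planted_prognostic=dict(betas))


def _gene_ids(n: int) -> list[str]:
    return [f"GENE{i:04d}" for i in range(1, n + 1)]


def gen_cellline_panel(
    cfg: SynthConfig,
    genes=None,
    essential_genes=None,
    mutation_counts: dict[str, dict[str, int]] | None = None,
    fusion_counts: dict[str, dict[str, int]] | None = None,
) -> tuple[CellLinePanel, GroundTruth]:
    """Multi-omic cell-line panel with planted pan-sensitivity structure.

    A latent per-line sensitivity drives every drug's response in every
    source (low response value = sensitive line), so the tertile splits of
    different drugs largely agree. Planted sensitive genes are expressed
    higher in sensitive lines (at both mRNA and protein levels), planted
    resistant genes higher in resistant lines; discordant genes carry the
    mRNA signal but an independent protein profile. Dependency matrices
    plant essential genes below -0.5 in most lines; mutation and fusion
    counts default to sparse random records and can be overridden per line.
    """
    if cfg.n_lines < 9:
        raise ValidationError("need n_lines >= 9 for tertile splitting")
    rng = np.random.default_rng([cfg.seed, _STREAM_PANEL])
    genes = list(genes) if genes is not None else _gene_ids(200)
    lines = [f"BRCA{i:03d}" for i in range(1, cfg.n_lines + 1)]
    n_sens = min(cfg.n_planted_sensitive, len(genes))
    sens_genes = genes[:n_sens]
    resi_genes = genes[n_sens : n_sens + cfg.n_planted_resistant]
    rest = genes[n_sens + cfg.n_planted_resistant :]
    disc_genes = rest[: cfg.n_discordant]

    latent = rng.normal(0.0, 1.0, size=cfg.n_lines)  # high = resistant

    drugs = [f"drug{i:02d}" for i in range(1, cfg.n_drugs + 1)]
    resp_rows = []
    for drug in drugs:
        mu = rng.uniform(0.0, 2.0)  # ln uM
        for source in cfg.sources:
            ln_ic50 = mu + 1.5 * latent + rng.normal(
                0.0, cfg.response_noise_sd, size=cfg.n_lines
            )
            ln_ec50 = ln_ic50 - 0.2 + rng.normal(0.0, 0.02, size=cfg.n_lines)
            for line, li, le in zip(lines, ln_ic50, ln_ec50):
                resp_rows.extend(
                    [
                        (line, drug, source, "IC50", float(np.exp(li))),
                        (line, drug, source, "lnIC50", float(li)),
                        (line, drug, source, "EC50", float(np.exp(le))),
                        (line, drug, source, "lnEC50", float(le)),
                    ]
                )
    responses = pd.DataFrame(
        resp_rows, columns=["cell_line", "drug", "source", "measure", "value"]
    )

    base = rng.uniform(4.0, 10.0, size=len(genes))
    mrna = np.tile(base[:, None], (1, cfg.n_lines)) + rng.normal(
        0.0, cfg.panel_noise_sd, size=(len(genes), cfg.n_lines)
    )
    gene_index = {g: i for i, g in enumerate(genes)}
    for g in sens_genes:
        mrna[gene_index[g]] += -cfg.sensitivity_effect * latent
    for g in resi_genes:
        mrna[gene_index[g]] += cfg.sensitivity_effect * latent
    mrna_df = pd.DataFrame(mrna, index=genes, columns=lines)

    protein = mrna + rng.normal(
        0.0, cfg.protein_noise_sd, size=mrna.shape
    )
    for g in disc_genes:
        protein[gene_index[g]] = rng.normal(0.0, 1.0, size=cfg.n_lines)
    protein_df = pd.DataFrame(protein, index=genes, columns=lines)
    protein_df = protein_df.sub(protein_df.mean(axis=1), axis=0)  # mean-centered

    if essential_genes is None:
        essential_pool = [g for g in rest[cfg.n_discordant:]]
        essential_genes = essential_pool[: cfg.n_planted_essential]
    essential_genes = set(essential_genes)
    crispr = rng.normal(0.0, 0.15, size=(len(genes), cfg.n_lines))
    rnai = rng.normal(0.0, 0.15, size=(len(genes), cfg.n_lines))
    for g in essential_genes:
        if g in gene_index:
            crispr[gene_index[g]] = -0.8 + rng.normal(0.0, 0.1, size=cfg.n_lines)
            rnai[gene_index[g]] = -0.7 + rng.normal(0.0, 0.1, size=cfg.n_lines)
    crispr_df = pd.DataFrame(crispr, index=genes, columns=lines)
    rnai_df = pd.DataFrame(rnai, index=genes, columns=lines)

    def alteration_table(
        overrides: dict[str, dict[str, int]] | None, rate: float
    ) -> pd.DataFrame:
        rows = []
        for line in lines:
            if overrides and line in overrides:
                for gene, count in overrides[line].items():
                    rows.append((line, gene, int(count)))
                continue
            n_alt = rng.poisson(rate)
            alt_genes = rng.choice(genes, size=min(n_alt, len(genes)),
                                   replace=False)
            for gene in alt_genes:
                rows.append((line, str(gene), int(1 + rng.poisson(1.0))))
        return pd.DataFrame(rows, columns=["cell_line", "gene", "count"])

    mutations = alteration_table(mutation_counts, rate=5.0)
    fusions = alteration_table(fusion_counts, rate=2.0)

    panel = CellLinePanel(
        mrna=mrna_df,
        protein=protein_df,
        responses=responses,
        crispr=crispr_df,
        rnai=rnai_df,
        mutations=mutations,
        fusions=fusions,
    )
    truth = GroundTruth(
        planted_sensitive_genes=set(sens_genes),
        planted_resistant_genes=set(resi_genes),
        discordant_genes=set(disc_genes),
        essential_genes=essential_genes,
    )
    return panel, truth


def gen_target_db(cfg: SynthConfig, mirnas, genes) -> pd.DataFrame:
    """miRNA-target interaction table covering the whole gene universe.

    Every gene is assigned round-robin to a miRNA (so the union of targets
    equals the supplied universe) and each miRNA additionally receives
    random extra targets up to ``targets_per_mirna``.
    """
    mirnas, genes = list(mirnas), list(genes)
    if not mirnas or not genes:
        raise ValidationError("miRNA and gene universes must be non-empty")
    rng = np.random.default_rng([cfg.seed, _STREAM_TARGETS])
    pairs = {(mirnas[i % len(mirnas)], g) for i, g in enumerate(genes)}
    per_mirna: dict[str, set[str]] = {m: set() for m in mirnas}
    for m, g in pairs:
        per_mirna[m].add(g)
    for m in mirnas:  # top up sparse miRNAs to targets_per_mirna
        deficit = min(cfg.targets_per_mirna, len(genes)) - len(per_mirna[m])
        if deficit > 0:
            candidates = sorted(set(genes) - per_mirna[m])
            extra = rng.choice(candidates, size=min(deficit, len(candidates)),
                               replace=False)
            pairs.update((m, str(g)) for g in extra)
    rows = [(m, g, "synthetic") for m, g in sorted(pairs)]
    return pd.DataFrame(rows, columns=["mirna_id", "target_gene", "evidence_source"])


def gen_perturbation_library(
    cfg: SynthConfig, signature: Signature, genes
) -> tuple[PerturbationLibrary, GroundTruth]:
    """Perturbation library with planted reversal hits and potency decoys.

    Planted hits place the signature's up genes on the top ranks and its
    down genes on the bottom ranks (connectivity score 1.0 at zero profile
    noise); non-hits are random permutations of the same score vector.
    Every perturbagen carries an in-panel IC50/EC50 response vector: hits
    are potent (~``hit_potency_um``), decoys share the hit profile but are
    weak (~``decoy_potency_um``), so the potency filter separates them.
    """
    genes = list(genes)
    if not signature.up or not signature.down:
        raise ValidationError("signature lists must be non-empty")
    missing = (set(signature.up) | set(signature.down)) - set(genes)
    if missing:
        raise ValidationError(f"signature genes outside universe: {sorted(missing)[:5]}")
    rng = np.random.default_rng([cfg.seed, _STREAM_LIBRARY])
    N = len(genes)
    base_scores = np.linspace(3.0, -3.0, N)

    up, down = list(signature.up), list(signature.down)
    others = [g for g in genes if g not in set(up) | set(down)]

    def hit_profile() -> pd.Series:
        middle = list(others)
        rng.shuffle(middle)
        order = up + middle + down
        scores = base_scores + rng.normal(0.0, cfg.profile_noise_sd, size=N)
        return pd.Series(scores, index=order).reindex(genes)

    n_hits = cfg.n_planted_hits
    n_decoys = cfg.n_planted_decoys
    profiles = {}
    meta_rows = []
    hits, decoys = set(), set()
    for i in range(cfg.n_perturbagens):
        pid = f"pert{i:03d}"
        if i < n_hits:
            profiles[pid] = hit_profile()
            hits.add(pid)
            meta_rows.append((pid, "compound", "planted_reversal_set"))
        elif i < n_hits + n_decoys:
            profiles[pid] = hit_profile()
            decoys.add(pid)
            meta_rows.append((pid, "compound", "planted_decoy_set"))
        else:
            shuffled = rng.permutation(base_scores)
            profiles[pid] = pd.Series(shuffled, index=genes)
            klass = "compound" if i % 10 else "pathway_set"
            meta_rows.append((pid, klass, f"set{i % 5}"))
    scores = pd.DataFrame(profiles)[list(profiles)]
    meta = pd.DataFrame(
        meta_rows, columns=["perturbagen_id", "perturbagen_class", "compound_set"]
    ).set_index("perturbagen_id")

    resp_rows = []
    lines = [f"BRCA{i:03d}" for i in range(1, cfg.n_response_lines + 1)]
    for pid in scores.columns:
        if pid in hits:
            mu = cfg.hit_potency_um
        elif pid in decoys:
            mu = cfg.decoy_potency_um
        else:
            mu = float(rng.uniform(5.0, 30.0))
        ic50 = mu * np.exp(rng.normal(0.0, 0.3, size=len(lines)))
        ec50 = ic50 * np.exp(rng.normal(0.0, 0.1, size=len(lines)))
        # one extreme outlier per perturbagen exercises the Tukey fences
        ic50[-1] = mu * 40.0
        for line, i_v, e_v in zip(lines, ic50, ec50):
            resp_rows.append((pid, line, "PRISM", "IC50", float(i_v)))
            resp_rows.append((pid, line, "PRISM", "EC50", float(e_v)))
    responses = pd.DataFrame(
        resp_rows,
        columns=["perturbagen_id", "cell_line", "source", "measure", "value"],
    )
    library = PerturbationLibrary(scores=scores, meta=meta, responses=responses)
    truth = GroundTruth(planted_hits=hits, planted_decoys=decoys)
    return library, truth
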