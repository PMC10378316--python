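"""End-to-end orchestration: synthetic study -> markers -> repositioning.

A single structured config (YAML on disk, :class:`PipelineConfig` in
memory) drives every stage with the study's numeric constants as defaults:
fold-change bounds 2 / 0.5, p < 0.05, FDR < 0.05, dependency score -0.5
crossed in > 50% of lines, 19 guideline drugs, connectivity score > 0.9
with p < 0.05, and the 7 uM potency bound. Each stage writes its tables
into the run directory and a manifest records the config echo, the seeds,
and the SHA-256 of every output, so a rerun with the same config
reproduces the outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import formats
from .clusterclass import clustering_accuracy, hcluster_two_groups
from .concordance import classify_role, concordant_markers, group_by_family
from .connectivity import screen_library
from .containers import ExpressionStudy, Signature, ValidationError
from .diffexpr import SamConfig, detection_filter, marker_table, select_markers
from .drugsens import essentiality, feature_calls, pan_table
from .repurpose import potency_filter, responder_genes, top_alterations
from .drugsens import classify_lines
from .signature import build_signature, signature_trace
from .survival import survival_screen
from .synthdata import (
    SynthConfig,
    gen_cellline_panel,
    gen_mirna_study,
    gen_perturbation_library,
    gen_survival_cohort,
    gen_target_db,
)

__all__ = ["Thresholds", "PipelineConfig", "run_pipeline", "load_config"]

THRESHOLD_KEYS = (
    "fc_hi", "fc_lo", "p", "fdr", "dependency", "dependency_fraction",
    "n_drugs", "connectivity", "connectivity_p", "potency_um",
)


@dataclass
class Thresholds:
    fc_hi: float = 2.0
    fc_lo: float = 0.5
    p: float = 0.05
    fdr: float = 0.05
    dependency: float = -0.5
    dependency_fraction: float = 0.5
    n_drugs: int = 19
    connectivity: float = 0.9
    connectivity_p: float = 0.05
    potency_um: float = 7.0


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "run"
    n_perm: int = 300
    n_genes: int = 200
    thresholds: Thresholds = field(default_factory=Thresholds)
    synth: SynthConfig = field(default_factory=SynthConfig)

    def __post_init__(self) -> None:
        if self.synth.seed != self.seed:
            self.synth = dataclasses.replace(self.synth, seed=self.seed)


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline config.

    The thresholds block is mandatory and must carry every threshold key so
    a run log always echoes the full set of constants in effect.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if "thresholds" not in raw:
        raise ValidationError("config missing thresholds block")
    missing = [k for k in THRESHOLD_KEYS if k not in raw["thresholds"]]
    if missing:
        raise ValidationError(f"thresholds block missing keys: {missing}")
    thresholds = Thresholds(**raw["thresholds"])
    synth = SynthConfig(**raw.get("synth", {}))
    return PipelineConfig(
        seed=int(raw.get("seed", 0)),
        output_dir=str(raw.get("output_dir", "run")),
        n_perm=int(raw.get("n_perm", 300)),
        n_genes=int(raw.get("n_genes", 200)),
        thresholds=thresholds,
        synth=synth,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir=None) -> Path:
    """Execute every stage on the synthetic study; returns the run directory."""
    out = Path(outdir if outdir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    log: list[str] = []

    def stage(name: str):
        log.append(f"stage: {name}")

    # ---- synthesize inputs ------------------------------------------------
    stage("synth")
    study, truth = gen_mirna_study(config.synth)
    formats.write_expression_table(study.matrix, out / "raw_matrix.tsv",
                                   probe_class_column="probe_class")
    formats.write_annotation(study.annotation, out / "annotation.tsv")

    # ---- differential expression -----------------------------------------
    stage("diffexpr")
    filtered, dthresholds = detection_filter(study.matrix)
    tissue = study.samples_where(specimen="tissue")
    tissue_ann = study.annotation[study.annotation["sample_id"].isin(tissue)]
    tissue_study = ExpressionStudy(filtered.subset_samples(tissue), tissue_ann)
    cfg_sam = SamConfig(n_perm=config.n_perm, seed=config.seed)
    markers_all = marker_table(tissue_study, cfg_sam, with_paired_fc=True)
    markers = select_markers(markers_all, fc_hi=th.fc_hi, fc_lo=th.fc_lo,
                             p_max=th.p, q_max=th.fdr)
    markers.to_csv(out / "markers_tissue.tsv", sep="\t")

    blood = study.samples_where(specimen="blood")
    blood_ann = study.annotation[study.annotation["sample_id"].isin(blood)]
    blood_study = ExpressionStudy(filtered.subset_samples(blood), blood_ann)
    blood_all = marker_table(blood_study, cfg_sam)
    blood_markers = select_markers(blood_all, fc_hi=th.fc_hi, fc_lo=th.fc_lo,
                                   p_max=th.p, q_max=th.fdr)
    blood_markers.to_csv(out / "markers_blood.tsv", sep="\t")

    # ---- clustering -------------------------------------------------------
    stage("cluster")
    assignment = hcluster_two_groups(tissue_study.matrix,
                                     features=list(markers.index))
    labels = tissue_ann.set_index("sample_id")["condition"]
    accuracy = clustering_accuracy(assignment, labels)
    assignment.labels.rename("cluster").to_csv(out / "clusters.tsv", sep="\t")
    log.append(f"clustering accuracy: {accuracy:.4f}")

    # ---- concordance ------------------------------------------------------
    stage("concordance")
    tissue_dirs = dict(zip(markers.index, markers["direction"]))
    blood_dirs = dict(zip(blood_markers.index, blood_markers["direction"]))
    blood_concordant = concordant_markers(tissue_dirs, blood_dirs)
    pd.Series(blood_concordant, name="direction").rename_axis("family").to_csv(
        out / "blood_concordant.tsv", sep="\t"
    )

    # ---- survival screen on markers --------------------------------------
    stage("survival")
    marker_ids = list(markers.index)
    k = min(config.synth.n_planted_prognostic, len(marker_ids))
    betas = {
        f: (config.synth.planted_beta
            if markers.loc[f, "direction"] == "up"
            else -config.synth.planted_beta)
        for f in marker_ids[:k]
    }
    cohort, surv_truth = gen_survival_cohort(config.synth, marker_ids,
                                             betas=betas)
    surv = survival_screen(cohort.expression, cohort)
    surv.to_csv(out / "survival_screen_mirna.tsv", sep="\t")

    roles = []
    for fam, members in group_by_family(marker_ids).items():
        hits = [m for m in members if m in surv.index]
        if not hits:
            continue
        best = min(hits, key=lambda m: surv.loc[m, "logrank_p"])
        fc = float(markers.loc[best, "fc"])
        call = classify_role(fc, float(surv.loc[best, "hr"]),
                             float(surv.loc[best, "logrank_p"]), family=fam)
        roles.append({"family": fam, "fc": call.fc, "hr": call.hr,
                      "hr_p": call.hr_p, "role": call.role})
    pd.DataFrame(roles).to_csv(out / "roles.tsv", sep="\t", index=False)

    # ---- cell-line panel & drug sensitivity -------------------------------
    stage("drugsens")
    panel, panel_truth = gen_cellline_panel(
        config.synth, genes=[f"GENE{i:04d}" for i in range(1, config.n_genes + 1)]
    )
    targets = gen_target_db(config.synth, marker_ids or ["hsa-miR-s0001"],
                            list(panel.mrna.index))
    formats.write_interactions(targets, out / "targets.tsv")
    drugs = sorted(panel.responses["drug"].unique())
    calls_m = feature_calls(panel.mrna, panel.responses, drugs, level="mRNA",
                            p_max=th.p)
    calls_p = feature_calls(panel.protein, panel.responses, drugs,
                            level="protein", p_max=th.p)
    calls = pd.concat([calls_m, calls_p], ignore_index=True)
    calls.to_csv(out / "sensitivity_calls.tsv", sep="\t", index=False)
    pan = pan_table(calls, drugs)
    pan.to_csv(out / "pan_status.tsv", sep="\t", index=False)
    essentials = set()
    for gene in panel.mrna.index:
        _, _, is_ess = essentiality(panel.crispr, panel.rnai, gene,
                                    score_max=th.dependency,
                                    line_fraction=th.dependency_fraction)
        if is_ess:
            essentials.add(gene)

    # ---- gene-level survival + signature ----------------------------------
    stage("signature")
    gene_betas = {g: -config.synth.planted_beta
                  for g in sorted(panel_truth.planted_sensitive_genes)}
    gene_betas |= {g: config.synth.planted_beta
                   for g in sorted(panel_truth.planted_resistant_genes)}
    gene_cohort, _ = gen_survival_cohort(config.synth,
                                         list(panel.mrna.index),
                                         betas=gene_betas)
    gene_surv = survival_screen(gene_cohort.expression, gene_cohort)
    gene_surv.to_csv(out / "survival_screen_genes.tsv", sep="\t")
    sig, evidence = build_signature(targets, gene_surv, pan, essentials,
                                    p_max=th.p)
    evidence.to_csv(out / "signature_evidence.tsv", sep="\t")
    formats.write_gmt({"UP": sig.up, "DOWN": sig.down}, out / "signature.gmt")
    formats.export_sif(signature_trace(sig, targets), out / "signature_network.sif")
    if not sig.up or not sig.down:
        raise ValidationError("signature stage produced an empty list; "
                              "cannot screen the library")

    # ---- connectivity screen ----------------------------------------------
    stage("connectivity")
    library, lib_truth = gen_perturbation_library(config.synth, sig,
                                                  list(panel.mrna.index))
    formats.write_library(library, out / "library.gct", out / "library_meta.tsv",
                          out / "library_responses.tsv")
    screen = screen_library(sig, library, score_min=th.connectivity,
                            p_max=th.connectivity_p, n_perm=max(config.n_perm, 100),
                            seed=config.seed)
    screen.to_csv(out / "connectivity.tsv", sep="\t", index=False)
    hits = screen[screen["hit"]]

    # ---- repurposing -------------------------------------------------------
    stage("repurpose")
    rep_hits = potency_filter(hits, library.responses,
                              threshold_um=th.potency_um)
    rep = pd.DataFrame(
        [
            {
                "perturbagen_id": h.perturbagen_id,
                "score": h.score,
                "p": h.p,
                "mean_ic50": h.mean_ic50,
                "mean_ec50": h.mean_ec50,
                "n_outliers_removed": h.n_outliers_removed,
                "passes_potency": h.passes_potency,
            }
            for h in rep_hits
        ]
    )
    rep.to_csv(out / "repositioned_drugs.tsv", sep="\t", index=False)

    responder_rows = []
    for h in rep_hits:
        if not h.passes_potency:
            continue
        pseudo = library.responses[
            library.responses["perturbagen_id"] == h.perturbagen_id
        ].rename(columns={"perturbagen_id": "drug"})
        pseudo = pseudo.assign(drug=h.perturbagen_id)
        try:
            labels = classify_lines(pseudo, h.perturbagen_id, "PRISM", "IC50")
        except ValidationError:
            continue
        sens, resi = responder_genes(h.perturbagen_id, panel, labels,
                                     p_max=th.p)
        responder_rows.append(
            {"drug": h.perturbagen_id,
             "sensitive_genes": ";".join(sens),
             "resistant_genes": ";".join(resi)}
        )
    pd.DataFrame(responder_rows).to_csv(out / "responders.tsv", sep="\t",
                                        index=False)
    alt = top_alterations(panel.mutations, panel.fusions, lines=panel.lines)
    alt.to_csv(out / "top_alterations.tsv", sep="\t")

    # merged ground truth across all generators
    truth.planted_prognostic = surv_truth.planted_prognostic
    truth.planted_sensitive_genes = panel_truth.planted_sensitive_genes
    truth.planted_resistant_genes = panel_truth.planted_resistant_genes
    truth.discordant_genes = panel_truth.discordant_genes
    truth.essential_genes = panel_truth.essential_genes
    truth.planted_hits = lib_truth.planted_hits
    truth.planted_decoys = lib_truth.planted_decoys
    with open(out / "ground_truth.tsv", "w", encoding="utf-8") as fh:
        fh.write("category\tkey\tvalue\n")
        for cat, key, value in truth.to_records():
            fh.write(f"{cat}\t{key}\t{value}\n")

    # ---- manifest ----------------------------------------------------------
    outputs = sorted(p.name for p in out.iterdir()
                     if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config": {
            "seed": config.seed,
            "n_perm": config.n_perm,
            "n_genes": config.n_genes,
            "thresholds": asdict(th),
            "synth": asdict(config.synth),
        },
        "log": log,
        "clustering_accuracy": accuracy,
        "n_markers_tissue": int(len(markers)),
        "n_markers_blood": int(len(blood_markers)),
        "n_blood_concordant": int(len(blood_concordant)),
        "signature_sizes": [len(sig.up), len(sig.down)],
        "n_hits": int(len(hits)),
        "n_potent_drugs": int(sum(1 for h in rep_hits if h.passes_potency)),
        "outputs": {name: _sha256(out / name) for name in outputs},
    }
    # tuples serialize as lists for a stable JSON echo
    manifest_json = json.dumps(manifest, indent=2, default=list, sort_keys=True)
    (out / "manifest.json").write_text(manifest_json, encoding="utf-8")
    return out
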