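"""Core in-memory containers shared across the pipeline.

Tabular data lives in pandas objects with a thin validation layer on top:
an :class:`ExpressionMatrix` is a features x samples frame of log2 values
(or raw log2 intensities upstream of detection filtering), sample metadata
is a plain annotation frame, and the cell-line panel bundles the matrices
a drug-sensitivity analysis needs. Identifiers are opaque, case-sensitive
strings throughout; no identifier translation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "PROBE_CLASSES",
    "CONDITIONS",
    "SPECIMENS",
    "ExpressionMatrix",
    "ExpressionStudy",
    "SurvivalCohort",
    "CellLinePanel",
    "Signature",
    "PerturbationLibrary",
    "GroundTruth",
    "validate_annotation",
    "validate_drug_response",
    "validate_interactions",
]


class ValidationError(ValueError):
    """A container violated one of its structural invariants."""


PROBE_CLASSES = ("measurement", "negative_control", "background")
CONDITIONS = ("tumor", "normal")
SPECIMENS = ("tissue", "blood")


@dataclass
class ExpressionMatrix:
    """Features x samples matrix of expression values.

    Parameters
    ----------
    values
        Frame indexed by feature id with sample ids as columns. Values are
        floats; missing cells are NaN.
    probe_class
        Optional per-feature label in ``PROBE_CLASSES``. Absent labels mean
        every row is a measurement probe.
    """

    values: pd.DataFrame
    probe_class: pd.Series | None = None

    def __post_init__(self) -> None:
        v = self.values
        if not isinstance(v, pd.DataFrame):
            raise ValidationError("values must be a DataFrame")
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()][0]
            raise ValidationError(f"duplicate feature id: {dup!r}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        self.values = v.astype(float)
        if self.probe_class is not None:
            pc = self.probe_class.reindex(v.index)
            if pc.isna().any():
                missing = pc.index[pc.isna()][0]
                raise ValidationError(f"probe_class missing for feature {missing!r}")
            bad = set(pc.unique()) - set(PROBE_CLASSES)
            if bad:
                raise ValidationError(f"unknown probe classes: {sorted(bad)}")
            self.probe_class = pc

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_features(self, features) -> "ExpressionMatrix":
        features = [f for f in features]
        missing = set(features) - set(self.values.index)
        if missing:
            raise ValidationError(f"features not in matrix: {sorted(missing)[:5]}")
        pc = self.probe_class.loc[features] if self.probe_class is not None else None
        return ExpressionMatrix(self.values.loc[features], pc)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        samples = [s for s in samples]
        missing = set(samples) - set(self.values.columns)
        if missing:
            raise ValidationError(f"samples not in matrix: {sorted(missing)[:5]}")
        return ExpressionMatrix(self.values[samples], self.probe_class)

    def measurement_only(self) -> "ExpressionMatrix":
        if self.probe_class is None:
            return ExpressionMatrix(self.values.copy())
        keep = self.probe_class[self.probe_class == "measurement"].index
        return ExpressionMatrix(self.values.loc[keep])


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample annotation frame.

    Requires columns ``sample_id`` and ``condition``; ``specimen`` and
    ``patient_id`` are optional (matched pairs share a patient_id and carry
    opposite conditions).
    """
    for col in ("sample_id", "condition"):
        if col not in annotation.columns:
            raise ValidationError(f"annotation missing column {col!r}")
    if annotation["sample_id"].duplicated().any():
        dup = annotation["sample_id"][annotation["sample_id"].duplicated()].iloc[0]
        raise ValidationError(f"duplicate sample id in annotation: {dup!r}")
    bad = set(annotation["condition"]) - set(CONDITIONS)
    if bad:
        raise ValidationError(f"unknown conditions: {sorted(bad)}")
    if "specimen" in annotation.columns:
        bad = set(annotation["specimen"].dropna()) - set(SPECIMENS)
        if bad:
            raise ValidationError(f"unknown specimens: {sorted(bad)}")
    if "patient_id" in annotation.columns:
        paired = annotation.dropna(subset=["patient_id"])
        for pid, grp in paired.groupby("patient_id"):
            if len(grp) == 2 and set(grp["condition"]) != set(CONDITIONS):
                raise ValidationError(
                    f"matched pair {pid!r} does not have opposite conditions"
                )
    return annotation


@dataclass
class ExpressionStudy:
    """An expression matrix plus its sample annotation."""

    matrix: ExpressionMatrix
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        validate_annotation(self.annotation)
        ann_ids = set(self.annotation["sample_id"])
        mat_ids = set(self.matrix.sample_ids)
        if not mat_ids <= ann_ids:
            raise ValidationError(
                f"samples without annotation: {sorted(mat_ids - ann_ids)[:5]}"
            )

    def samples_where(self, **conditions) -> list[str]:
        mask = pd.Series(True, index=self.annotation.index)
        for col, value in conditions.items():
            mask &= self.annotation[col] == value
        ids = self.annotation.loc[mask, "sample_id"]
        return [s for s in ids if s in set(self.matrix.sample_ids)]


@dataclass
class SurvivalCohort:
    """Right-censored follow-up with per-subject expression.

    ``clinical`` is indexed by subject id with columns ``time`` (months, > 0)
    and ``event`` (1 = event observed, 0 = censored). ``expression`` is a
    features x subjects frame aligned to the same subjects.
    """

    clinical: pd.DataFrame
    expression: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("time", "event"):
            if col not in self.clinical.columns:
                raise ValidationError(f"clinical table missing column {col!r}")
        if (self.clinical["time"] <= 0).any():
            raise ValidationError("survival times must be positive")
        if not set(self.clinical["event"].unique()) <= {0, 1}:
            raise ValidationError("event must be 0/1")
        extra = set(self.expression.columns) - set(self.clinical.index)
        if extra:
            raise ValidationError(
                f"expression subjects without clinical rows: {sorted(extra)[:5]}"
            )

    @property
    def subject_ids(self) -> list[str]:
        return list(self.clinical.index)


DRUG_SOURCES = ("PRISM", "GDSC1", "GDSC2")
RESPONSE_MEASURES = ("IC50", "lnIC50", "EC50", "lnEC50")
LINEAR_MEASURES = ("IC50", "EC50")


def validate_drug_response(responses: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-form drug response table.

    Columns: cell_line, drug, source, measure, value. IC50/EC50 are in uM and
    must be positive; ln measures are unconstrained.
    """
    for col in ("cell_line", "drug", "source", "measure", "value"):
        if col not in responses.columns:
            raise ValidationError(f"response table missing column {col!r}")
    bad = set(responses["measure"]) - set(RESPONSE_MEASURES)
    if bad:
        raise ValidationError(f"unknown response measures: {sorted(bad)}")
    linear = responses["measure"].isin(LINEAR_MEASURES)
    if (responses.loc[linear, "value"] <= 0).any():
        raise ValidationError("IC50/EC50 values must be positive (uM)")
    key = responses[["cell_line", "drug", "source", "measure"]]
    if key.duplicated().any():
        row = key[key.duplicated()].iloc[0]
        raise ValidationError(
            "duplicate response entry: " + "/".join(str(x) for x in row)
        )
    return responses


def validate_interactions(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a miRNA -> target gene interaction table."""
    for col in ("mirna_id", "target_gene"):
        if col not in table.columns:
            raise ValidationError(f"interaction table missing column {col!r}")
    key = table[["mirna_id", "target_gene"]]
    if key.duplicated().any():
        row = key[key.duplicated()].iloc[0]
        raise ValidationError(
            f"duplicate interaction: {row['mirna_id']!r} -> {row['target_gene']!r}"
        )
    return table


@dataclass
class CellLinePanel:
    """Multi-omic cell-line panel used for drug-sensitivity integration.

    mRNA and protein expression are genes x lines log2 frames (protein is
    mean-centered per gene); ``responses`` is a long-form drug response
    table; CRISPR/RNAi dependency matrices are genes x lines; mutation and
    fusion records carry per-line per-gene counts.
    """

    mrna: pd.DataFrame
    protein: pd.DataFrame
    responses: pd.DataFrame
    crispr: pd.DataFrame
    rnai: pd.DataFrame
    mutations: pd.DataFrame = field(default_factory=pd.DataFrame)
    fusions: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        validate_drug_response(self.responses)
        for name in ("mutations", "fusions"):
            tab = getattr(self, name)
            if len(tab):
                for col in ("cell_line", "gene", "count"):
                    if col not in tab.columns:
                        raise ValidationError(f"{name} table missing column {col!r}")

    @property
    def lines(self) -> list[str]:
        return list(self.mrna.columns)


@dataclass
class Signature:
    """Disjoint ordered up/down gene lists for connectivity screening."""

    up: list[str]
    down: list[str]

    def __post_init__(self) -> None:
        self.up = list(self.up)
        self.down = list(self.down)
        if len(set(self.up)) != len(self.up) or len(set(self.down)) != len(self.down):
            raise ValidationError("signature lists contain duplicates")
        overlap = set(self.up) & set(self.down)
        if overlap:
            raise ValidationError(f"up/down lists overlap: {sorted(overlap)[:5]}")

    def swapped(self) -> "Signature":
        return Signature(up=list(self.down), down=list(self.up))

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


@dataclass
class PerturbationLibrary:
    """Perturbation profile library standing in for a connectivity-map build.

    ``scores`` is genes x perturbagens (per-gene differential-expression
    scores); ``meta`` is indexed by perturbagen id with columns
    ``perturbagen_class`` (compound / gene_knockdown_set / pathway_set) and
    ``compound_set``; ``responses`` holds in-panel potency values (long form:
    perturbagen, cell_line, measure, value in uM).
    """

    scores: pd.DataFrame
    meta: pd.DataFrame
    responses: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        extra = set(self.scores.columns) - set(self.meta.index)
        if extra:
            raise ValidationError(
                f"perturbagens without metadata: {sorted(extra)[:5]}"
            )

    @property
    def perturbagen_ids(self) -> list[str]:
        return list(self.scores.columns)

    def profile(self, perturbagen_id: str) -> pd.Series:
        return self.scores[perturbagen_id]


@dataclass
class GroundTruth:
    """Planted effects recorded by the synthetic-data generators."""

    planted_de: dict[str, str] = field(default_factory=dict)  # feature -> up/down
    blood_concordant: set[str] = field(default_factory=set)
    planted_prognostic: dict[str, float] = field(default_factory=dict)  # feature -> log-hazard
    planted_sensitive_genes: set[str] = field(default_factory=set)
    planted_resistant_genes: set[str] = field(default_factory=set)
    discordant_genes: set[str] = field(default_factory=set)
    essential_genes: set[str] = field(default_factory=set)
    planted_hits: set[str] = field(default_factory=set)
    planted_decoys: set[str] = field(default_factory=set)

    def to_records(self) -> list[tuple[str, str, str]]:
        """Flatten to (category, key, value) rows for plain-text serialization."""
        rows: list[tuple[str, str, str]] = []
        for f, d in sorted(self.planted_de.items()):
            rows.append(("planted_de", f, d))
        for f in sorted(self.blood_concordant):
            rows.append(("blood_concordant", f, ""))
        for f, b in sorted(self.planted_prognostic.items()):
            rows.append(("planted_prognostic", f, repr(b)))
        for name in (
            "planted_sensitive_genes",
            "planted_resistant_genes",
            "discordant_genes",
            "essential_genes",
            "planted_hits",
            "planted_decoys",
        ):
            for f in sorted(getattr(self, name)):
                rows.append((name, f, ""))
        return rows
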