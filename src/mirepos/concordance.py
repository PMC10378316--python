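"""Marker concordance across compartments/cohorts and the oncomiR rule.

miRNA identifiers follow miRBase conventions: a family stem such as
``hsa-miR-101`` may appear with a star marker (``hsa-miR-30a*``), an arm
suffix (``-3p``/``-5p``), or a single-digit genomic-copy suffix
(``hsa-miR-101-1``, ``hsa-miR-101-2``). Isoforms sharing a stem are grouped
into one family before role calling, so results are not isoform specific.

The role rule: a family over-expressed in tumors (fold change > 1) whose
high expression carries a significant survival hazard (HR > 1, p < 0.05)
is a candidate oncomiR; under-expression with significant protection
(fold change < 1, HR < 1) marks a candidate tumor suppressor. Everything
else is discordant.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import pandas as pd

from .containers import ValidationError

__all__ = [
    "RoleCall",
    "group_by_family",
    "family_id",
    "classify_role",
    "classify_family",
    "concordant_markers",
]

ONCOGENE = "oncogene"
TUMOR_SUPPRESSOR = "tumor_suppressor"
DISCORDANT = "discordant"

_STAR = re.compile(r"\*$")
_ARM = re.compile(r"-(3p|5p)$")
_COPY = re.compile(r"-\d$")
_STEM = re.compile(r"^[a-z]{3}-(mir|miR|let)-\w+", re.IGNORECASE)


@dataclass
class RoleCall:
    family_id: str
    fc: float
    hr: float
    hr_p: float
    role: str


def family_id(mirna_id: str) -> str:
    """Collapse a miRBase-style id to its family stem.

    Strips, in order: a trailing star marker, a trailing arm suffix, and a
    trailing single-digit genomic-copy suffix (only when the remainder still
    names a family, i.e. keeps an alphanumeric block after the ``miR-``
    prefix). Unparseable ids pass through unchanged with a warning.
    """
    name = mirna_id.strip()
    if not _STEM.match(name):
        warnings.warn(f"unparseable miRNA id {name!r}; kept as its own family")
        return name
    name = _STAR.sub("", name)
    name = _ARM.sub("", name)
    stripped = _COPY.sub("", name)
    if stripped != name and _STEM.match(stripped) and re.search(
        r"-(mir|miR|let)-\w*[A-Za-z0-9]$", stripped
    ):
        name = stripped
    return name


def group_by_family(feature_ids) -> dict[str, list[str]]:
    """Map family stem -> sorted member ids."""
    families: dict[str, list[str]] = {}
    for fid in feature_ids:
        families.setdefault(family_id(fid), []).append(fid)
    return {fam: sorted(members) for fam, members in sorted(families.items())}


def classify_role(fc: float, hr: float, hr_p: float,
                  p_max: float = 0.05, family: str = "") -> RoleCall:
    """Role of one family from its fold change and hazard ratio."""
    if fc <= 0 or hr <= 0:
        raise ValidationError("fold change and hazard ratio must be positive")
    if fc > 1 and hr > 1 and hr_p < p_max:
        role = ONCOGENE
    elif fc < 1 and hr < 1 and hr_p < p_max:
        role = TUMOR_SUPPRESSOR
    else:
        role = DISCORDANT
    return RoleCall(family_id=family, fc=fc, hr=hr, hr_p=hr_p, role=role)


def classify_family(family: str, fc: float, isoform_hrs) -> RoleCall:
    """Role of a family with possibly several survival isoforms.

    ``isoform_hrs`` is an iterable of (hr, p) pairs. Only significant
    isoforms vote; the role is assigned when all significant isoforms agree
    in HR direction, otherwise the family is discordant. A family with no
    significant isoform is discordant (no prognostic support).
    """
    significant = [(hr, p) for hr, p in isoform_hrs if p < 0.05]
    if not significant:
        return RoleCall(family, fc, float("nan"), float("nan"), DISCORDANT)
    directions = {hr > 1 for hr, _ in significant}
    if len(directions) > 1:
        return RoleCall(family, fc, float("nan"), min(p for _, p in significant),
                        DISCORDANT)
    # representative isoform: the most significant one
    hr, p = min(significant, key=lambda t: t[1])
    return classify_role(fc, hr, p, family=family)


def concordant_markers(set_a: dict[str, str], set_b: dict[str, str]) -> dict[str, str]:
    """Families present in both marker sets with equal direction.

    Inputs map family (or feature) id -> direction in {"up", "down"};
    feature-level keys are collapsed to families first.
    """
    def collapse(markers: dict[str, str]) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for fid, direction in markers.items():
            if direction not in ("up", "down"):
                raise ValidationError(f"bad direction {direction!r} for {fid!r}")
            out.setdefault(family_id(fid), set()).add(direction)
        return out

    fam_a, fam_b = collapse(set_a), collapse(set_b)
    result: dict[str, str] = {}
    for fam in sorted(set(fam_a) & set(fam_b)):
        da, db = fam_a[fam], fam_b[fam]
        if len(da) == 1 and da == db:
            result[fam] = next(iter(da))
    return result
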