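"""Evidence integration: merge in vitro / in vivo annotations into a report.

Produces the canonical integrated metabolite table: one row per detected
(chain, m/z, RT) entity with presence flags per matrix and in silico support,
named M1, M2, ... by ascending m/z over distinct (chain, formula) groups,
with isomer letters a, b, c by ascending retention time within a group.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .annotate import NodeAnnotation, chain_name
from .formulas import ElementalFormula, format_formula
from .rules import MetaboliteCandidate

__all__ = ["EvidenceRecord", "integrate", "assign_ids", "summarize", "report_table"]

#: Generic biotransformation labels that are phase II conjugations.
_PHASE_II = {"glucuronidation", "sulfation", "methylation"}

_MZ_MERGE_TOL = 0.0015  # Da; merges matrices at 3-dp print precision
_RT_MERGE_TOL = 0.1  # min


@dataclass(frozen=True)
class EvidenceRecord:
    """One row of the integrated metabolite evidence table."""

    metabolite_id: str  # e.g. "M5a"; "" until assigned; "parent" for the drug
    formula: Optional[ElementalFormula]
    chain: Optional[Tuple[str, ...]]
    mz: float
    mass_shift: float
    rt_min: float
    in_vivo: bool
    in_vitro: bool
    insilico_support: Tuple[str, ...] = ()
    is_parent: bool = False
    rejected: bool = False  # predictor-only entries excluded from counts

    @property
    def biotransformation(self) -> str:
        if self.is_parent:
            return "Parent molecule"
        return chain_name(self.chain) if self.chain is not None else "Unknown"

    @property
    def formula_str(self) -> str:
        return format_formula(self.formula) if self.formula is not None else ""

    @property
    def phase2_only(self) -> bool:
        return bool(self.chain) and all(l in _PHASE_II for l in self.chain)


def _matches(rec: EvidenceRecord, ann: NodeAnnotation) -> bool:
    return (
        rec.chain == ann.chain
        and abs(rec.mz - ann.mz) <= _MZ_MERGE_TOL
        and abs(rec.rt_min - ann.rt_min) <= _RT_MERGE_TOL
    )


def integrate(
    annot_invitro: Sequence[NodeAnnotation],
    annot_invivo: Sequence[NodeAnnotation],
    candidates: Sequence[MetaboliteCandidate] = (),
    parent_tol: float = 0.02,
) -> List[EvidenceRecord]:
    """Merge per-matrix annotations into evidence records.

    Assigned annotations from the two matrices merge when chain, m/z (within
    3-dp print precision) and RT (within 0.1 min) agree; unassigned nodes are
    dropped.  Both matrices must agree on the parent's precursor m/z.
    """
    parents = {
        "invitro": [a for a in annot_invitro if a.is_parent],
        "invivo": [a for a in annot_invivo if a.is_parent],
    }
    p_vitro = parents["invitro"][0] if parents["invitro"] else None
    p_vivo = parents["invivo"][0] if parents["invivo"] else None
    if p_vitro is not None and p_vivo is not None:
        if abs(p_vitro.mz - p_vivo.mz) > parent_tol:
            raise ValueError(
                f"inconsistent parent between matrices: "
                f"{p_vitro.mz:.4f} vs {p_vivo.mz:.4f}"
            )

    records: List[EvidenceRecord] = []
    parent_mz = p_vitro.mz if p_vitro is not None else (p_vivo.mz if p_vivo else 0.0)

    def add(ann: NodeAnnotation, matrix: str) -> None:
        for idx, rec in enumerate(records):
            if _matches(rec, ann):
                records[idx] = replace(
                    rec,
                    in_vitro=rec.in_vitro or matrix == "invitro",
                    in_vivo=rec.in_vivo or matrix == "invivo",
                    insilico_support=tuple(
                        sorted(set(rec.insilico_support) | set(ann.insilico_support))
                    ),
                )
                return
        records.append(
            EvidenceRecord(
                metabolite_id="",
                formula=ann.formula,
                chain=ann.chain,
                mz=ann.mz,
                mass_shift=ann.mz - parent_mz,
                rt_min=ann.rt_min,
                in_vivo=matrix == "invivo",
                in_vitro=matrix == "invitro",
                insilico_support=ann.insilico_support,
                is_parent=ann.is_parent,
            )
        )

    for ann in annot_invitro:
        if ann.assigned:
            add(ann, "invitro")
    for ann in annot_invivo:
        if ann.assigned:
            add(ann, "invivo")

    records.sort(key=lambda r: (not r.is_parent, r.mz, r.rt_min))
    return records


def assign_ids(records: Sequence[EvidenceRecord]) -> List[EvidenceRecord]:
    """Assign M-numbers by ascending m/z over (chain, formula) groups and
    isomer letters a, b, c by ascending RT; singleton groups get no letter.

    A pure function of (m/z, RT, chain): input order does not matter.
    """
    metabolites = [r for r in records if not r.is_parent and not r.rejected]
    groups: Dict[Tuple[Tuple[str, ...], str], List[EvidenceRecord]] = {}
    for rec in metabolites:
        key = (rec.chain or (), rec.formula_str)
        groups.setdefault(key, []).append(rec)
    ordered = sorted(groups.items(), key=lambda kv: min(r.mz for r in kv[1]))
    labelled: Dict[Tuple[Tuple[str, ...], str, float, float], str] = {}
    for gi, (key, members) in enumerate(ordered, start=1):
        members = sorted(members, key=lambda r: (r.rt_min, r.mz))
        for li, rec in enumerate(members):
            letter = "" if len(members) == 1 else chr(ord("a") + li)
            labelled[(key[0], key[1], rec.mz, rec.rt_min)] = f"M{gi}{letter}"

    out = []
    for rec in records:
        if rec.is_parent:
            out.append(replace(rec, metabolite_id="parent"))
        elif rec.rejected:
            out.append(replace(rec, metabolite_id="-"))
        else:
            mid = labelled[(rec.chain or (), rec.formula_str, rec.mz, rec.rt_min)]
            out.append(replace(rec, metabolite_id=mid))
    out.sort(key=lambda r: (not r.is_parent, r.mz, r.rt_min))
    return out


def summarize(records: Sequence[EvidenceRecord]) -> Dict[str, int]:
    """Summary counts over metabolite rows (parent and rejected excluded)."""
    mets = [r for r in records if not r.is_parent and not r.rejected]
    return {
        "n_total": len(mets),
        "n_in_vivo": sum(r.in_vivo for r in mets),
        "n_in_vitro": sum(r.in_vitro for r in mets),
        "n_phase2_only": sum(r.phase2_only for r in mets),
    }


def report_table(records: Sequence[EvidenceRecord]) -> pd.DataFrame:
    """Integrated evidence table mirroring the standard report layout."""
    rows = []
    for r in records:
        rows.append(
            {
                "metabolite": r.metabolite_id,
                "formula": r.formula_str,
                "biotransformation": r.biotransformation,
                "mz": round(r.mz, 3),
                "mass_shift": round(r.mass_shift, 3),
                "rt_min": round(r.rt_min, 1),
                "in_vivo": "X" if r.in_vivo else "-",
                "in_vitro": "X" if r.in_vitro else "-",
                "in_silico": ";".join(r.insilico_support) if r.insilico_support else "-",
            }
        )
    return pd.DataFrame(rows)
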