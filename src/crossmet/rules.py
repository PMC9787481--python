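"""Rule-based phase I/II metabolite candidate generation.

Candidates are enumerated at the elemental-formula level: the observable that
LC-HRMS screening can actually distinguish is the exact mass (hence formula),
not regiochemistry, so distinct hydroxylation sites collapse into a single
formula-level candidate carrying an isomer-multiplicity attribute.

Applicability is structure-aware at the functional-group-count level: a
:class:`FunctionalGroupProfile` derived from the parent SMILES gates each
rule (sulfation needs a phenolic OH, aromatic hydroxylation needs an aromatic
CH, ...) and is updated as rules fire (hydroxylation creates a new phenolic
OH; O-conjugation consumes one).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from rdkit import Chem

from .formulas import (
    DEFAULT_CONVENTIONS,
    ElementalFormula,
    InfeasibleTransformation,
    MassConventions,
    combine,
    delta_mass,
    format_formula,
    protonated_mz,
)

__all__ = [
    "FunctionalGroupProfile",
    "BiotransformationRule",
    "MetaboliteCandidate",
    "profile_from_smiles",
    "default_ruleset",
    "predict_metabolites",
]

_SMARTS = {
    "phenol_oh": "[OX2H][c]",
    "aromatic_ch": "[cH]",
    "basic_ring_n": "[n;X2;H0]",
    "secondary_nh": "[NX3;H1;!$(N=*)]",
}
_CATECHOL = "[OX2H]-c:c-[OX2H]"


@dataclass(frozen=True)
class FunctionalGroupProfile:
    """Counts of metabolism-relevant functional groups in a structure."""

    phenol_oh: int = 0
    aromatic_ch: int = 0
    basic_ring_n: int = 0
    secondary_nh: int = 0
    catechol: bool = False

    def __post_init__(self) -> None:
        for name in ("phenol_oh", "aromatic_ch", "basic_ring_n", "secondary_nh"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} count must be >= 0")

    def count(self, group: str) -> int:
        return int(getattr(self, group))

    def adjust(self, changes: Mapping[str, int]) -> "FunctionalGroupProfile":
        updates = {g: self.count(g) + d for g, d in changes.items()}
        return replace(self, **updates)


@dataclass(frozen=True)
class BiotransformationRule:
    """A named metabolic reaction acting on formulas and group counts.

    ``shift_label`` is the generic mass-shift vocabulary used when reading
    network edges (e.g. both O- and N-glucuronidation read as
    "glucuronidation", both aromatic hydroxylation and N-oxidation read as
    "hydroxylation", their elemental deltas being identical).
    """

    name: str
    phase: str  # "I" or "II"
    delta: Mapping[str, int]
    site_requirement: Optional[str]  # group name that must be available, or None
    enzyme_label: str
    consumes: Mapping[str, int] = field(default_factory=dict)
    produces: Mapping[str, int] = field(default_factory=dict)
    shift_label: str = ""
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.phase not in ("I", "II"):
            raise ValueError(f"phase must be 'I' or 'II', got {self.phase!r}")
        if self.phase == "II" and self.delta_mass <= 0:
            raise ValueError(f"phase II conjugation {self.name!r} must add mass")
        if not self.shift_label:
            object.__setattr__(self, "shift_label", self.name)

    @property
    def delta_mass(self) -> float:
        return delta_mass(self.delta)

    def applicable(self, profile: FunctionalGroupProfile) -> bool:
        if self.site_requirement is None:
            return True
        return profile.count(self.site_requirement) >= 1

    def fire(
        self, formula: ElementalFormula, profile: FunctionalGroupProfile
    ) -> Tuple[ElementalFormula, FunctionalGroupProfile]:
        if not self.applicable(profile):
            raise InfeasibleTransformation(
                f"rule {self.name!r} requires {self.site_requirement}"
            )
        new_formula = combine(formula, self.delta)
        changes: Dict[str, int] = {}
        for g, n in self.consumes.items():
            changes[g] = changes.get(g, 0) - n
        for g, n in self.produces.items():
            changes[g] = changes.get(g, 0) + n
        new_profile = profile.adjust(changes)
        return new_formula, new_profile


def profile_from_smiles(smiles: str) -> FunctionalGroupProfile:
    """Derive a functional-group profile from a SMILES string via rdkit."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    counts = {
        name: len(mol.GetSubstructMatches(Chem.MolFromSmarts(patt)))
        for name, patt in _SMARTS.items()
    }
    catechol = mol.HasSubstructMatch(Chem.MolFromSmarts(_CATECHOL))
    return FunctionalGroupProfile(catechol=catechol, **counts)


def default_ruleset(include_low_confidence: bool = False) -> List[BiotransformationRule]:
    """The core phase I/II reaction set for a phenolic azaindoline drug.

    Low-confidence oxidative-cleavage rules (quinone formation, ring
    cleavage) are available but disabled by default: their products are mass
    losses that cannot be confirmed by conjugate-style fragmentation.
    """
    rules = [
        BiotransformationRule(
            name="aromatic hydroxylation",
            phase="I",
            delta={"O": 1},
            site_requirement="aromatic_ch",
            enzyme_label="CYP1A2",
            consumes={"aromatic_ch": 1},
            produces={"phenol_oh": 1},
            shift_label="hydroxylation",
        ),
        BiotransformationRule(
            name="N-oxidation",
            phase="I",
            delta={"O": 1},
            site_requirement="basic_ring_n",
            enzyme_label="CYP2C8",
            consumes={"basic_ring_n": 1},
            shift_label="hydroxylation",
        ),
        BiotransformationRule(
            name="O-glucuronidation",
            phase="II",
            delta={"C": 6, "H": 8, "O": 6},
            site_requirement="phenol_oh",
            enzyme_label="UDP-glucuronosyltransferase",
            consumes={"phenol_oh": 1},
            shift_label="glucuronidation",
        ),
        BiotransformationRule(
            name="N-glucuronidation",
            phase="II",
            delta={"C": 6, "H": 8, "O": 6},
            site_requirement="secondary_nh",
            enzyme_label="UDP-glucuronosyltransferase",
            consumes={"secondary_nh": 1},
            shift_label="glucuronidation",
        ),
        BiotransformationRule(
            name="sulfation",
            phase="II",
            delta={"S": 1, "O": 3},
            site_requirement="phenol_oh",
            enzyme_label="Aryl sulfotransferase",
            consumes={"phenol_oh": 1},
            shift_label="sulfation",
        ),
        BiotransformationRule(
            name="O-methylation",
            phase="II",
            delta={"C": 1, "H": 2},
            site_requirement="phenol_oh",
            enzyme_label="Catechol O-methyltransferase",
            consumes={"phenol_oh": 1},
            shift_label="methylation",
        ),
    ]
    if include_low_confidence:
        rules += [
            BiotransformationRule(
                name="oxidation of 4-substituted phenol to quinone",
                phase="I",
                delta={"C": -7, "H": -6, "N": -2, "O": 1},
                site_requirement="phenol_oh",
                enzyme_label="unknown",
                consumes={"phenol_oh": 1},
                shift_label="quinone cleavage",
                low_confidence=True,
            ),
            BiotransformationRule(
                name="ring cleavage",
                phase="I",
                delta={"C": -6, "H": -4, "O": -1},
                site_requirement=None,
                enzyme_label="unknown",
                shift_label="ring cleavage",
                low_confidence=True,
            ),
        ]
    return rules


@dataclass(frozen=True)
class MetaboliteCandidate:
    """A predicted metabolite: rule chain, formula, [M+H]+ m/z, mass shift."""

    chain: Tuple[str, ...]
    formula: ElementalFormula
    mz: float
    total_shift: float
    phase_summary: str  # "I-only", "II-only", "mixed", or "parent"
    generic_chain: Tuple[str, ...] = ()
    isomer_multiplicity: int = 1

    @property
    def formula_str(self) -> str:
        return format_formula(self.formula)


def _phase_summary(phases: Sequence[str]) -> str:
    s = set(phases)
    if not s:
        return "parent"
    if s == {"I"}:
        return "I-only"
    if s == {"II"}:
        return "II-only"
    return "mixed"


def predict_metabolites(
    parent_formula: ElementalFormula,
    profile: FunctionalGroupProfile,
    rules: Sequence[BiotransformationRule],
    max_steps: int = 2,
    conv: MassConventions = DEFAULT_CONVENTIONS,
) -> List[MetaboliteCandidate]:
    """Breadth-first enumeration of rule chains up to ``max_steps`` deep.

    States are deduplicated on (formula, multiset of rule names), so rule
    orderings that commute produce a single candidate.  The isomer
    multiplicity of a candidate is the number of available reaction sites at
    the first application of each site-consuming rule, multiplied along the
    chain (e.g. 7 aromatic CH positions -> multiplicity 7 for mono-
    hydroxylation at formula level).
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    if not rules:
        raise ValueError("empty ruleset")

    parent_mz = protonated_mz(parent_formula, conv)
    rule_by_name = {r.name: r for r in rules}

    # state key: (formula, sorted chain names)
    frontier: List[Tuple[ElementalFormula, FunctionalGroupProfile, Tuple[str, ...], int]] = [
        (parent_formula, profile, (), 1)
    ]
    seen = {(parent_formula, ())}
    results: Dict[Tuple[ElementalFormula, Tuple[str, ...]], MetaboliteCandidate] = {}

    for _ in range(max_steps):
        next_frontier = []
        for formula, prof, chain, mult in frontier:
            for rule in rules:
                if not rule.applicable(prof):
                    continue
                try:
                    new_formula, new_prof = rule.fire(formula, prof)
                except InfeasibleTransformation:
                    continue
                new_chain = tuple(sorted(chain + (rule.name,)))
                key = (new_formula, new_chain)
                sites = (
                    prof.count(rule.site_requirement)
                    if rule.site_requirement is not None
                    else 1
                )
                new_mult = mult * max(sites, 1)
                if key not in seen:
                    seen.add(key)
                    next_frontier.append((new_formula, new_prof, new_chain, new_mult))
                    mz = protonated_mz(new_formula, conv)
                    phases = [rule_by_name[n].phase for n in new_chain]
                    generic = tuple(
                        sorted(rule_by_name[n].shift_label for n in new_chain)
                    )
                    results[key] = MetaboliteCandidate(
                        chain=new_chain,
                        formula=new_formula,
                        mz=mz,
                        total_shift=mz - parent_mz,
                        phase_summary=_phase_summary(phases),
                        generic_chain=generic,
                        isomer_multiplicity=new_mult,
                    )
        frontier = next_frontier
        if not frontier:
            break

    out = sorted(results.values(), key=lambda c: (c.mz, len(c.chain), c.chain))
    return out
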