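"""End-to-end orchestration of the cross-sectional workflow.

simulate (or load) -> in silico prediction -> per-matrix molecular network ->
mass-shift annotation propagated from the parent -> cross-matrix evidence
integration -> integrated metabolite report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from .annotate import (
    DeltaLibrary,
    NodeAnnotation,
    build_delta_library,
    annotate_edges,
    find_parent_node,
    match_to_insilico,
    propagate_from_parent,
)
from .formulas import parse_formula
from .network import MolecularNetwork, NetworkParams, build_network
from .report import EvidenceRecord, assign_ids, integrate, summarize
from .rules import (
    MetaboliteCandidate,
    default_ruleset,
    predict_metabolites,
    profile_from_smiles,
)
from .synth import SimulatedMatrix, StudyDesign, simulate_spectra

__all__ = ["StudyResult", "run_study"]


@dataclass
class StudyResult:
    design: StudyDesign
    matrices: Dict[str, SimulatedMatrix]
    networks: Dict[str, MolecularNetwork]
    annotations: Dict[str, List[NodeAnnotation]]
    candidates: List[MetaboliteCandidate]
    records: List[EvidenceRecord]
    summary: Dict[str, int] = field(default_factory=dict)


def run_study(
    design: StudyDesign,
    params: NetworkParams = NetworkParams(),
    delta_tol: float = 0.01,
    delta_depth: int = 4,
    predict_steps: int = 2,
) -> StudyResult:
    """Run the full pipeline on a (synthetic) study design."""
    parent_formula = parse_formula(design.parent_formula)
    rules = default_ruleset()
    lib: DeltaLibrary = build_delta_library(rules, max_depth=delta_depth)
    profile = profile_from_smiles(design.parent_smiles)
    candidates = predict_metabolites(parent_formula, profile, rules, max_steps=predict_steps)

    matrices = simulate_spectra(design)
    networks: Dict[str, MolecularNetwork] = {}
    annotations: Dict[str, List[NodeAnnotation]] = {}
    for name, sim in matrices.items():
        net = build_network(sim.spectra, params)
        annotate_edges(net, lib, delta_tol)
        parent_node = find_parent_node(net, design.parent_mz, tol=max(0.02, delta_tol))
        anns = propagate_from_parent(net, parent_node, parent_formula, lib, delta_tol)
        anns = match_to_insilico(anns, candidates)
        networks[name] = net
        annotations[name] = anns

    records = integrate(
        annotations.get("invitro", []), annotations.get("invivo", []), candidates
    )
    records = assign_ids(records)
    return StudyResult(
        design=design,
        matrices=matrices,
        networks=networks,
        annotations=annotations,
        candidates=candidates,
        records=records,
        summary=summarize(records),
    )
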