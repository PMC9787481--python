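"""Mass-shift annotation of network edges and propagation from the parent.

A :class:`DeltaLibrary` enumerates all multisets of biotransformation deltas
up to a chain depth; network edges and whole nodes are then read against it.
Propagation makes the manual "information propagation" reading of a drug
cluster algorithmic: starting from the identified parent node, every node in
the parent's connected component is assigned the chain whose cumulative delta
best matches its precursor shift from the parent (precursor shifts telescope
along any path, so the direct shift equals any path-accumulated shift).
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import networkx as nx

from .formulas import (
    DEFAULT_CONVENTIONS,
    ElementalFormula,
    combine,
    format_formula,
)
from .network import MolecularNetwork
from .rules import BiotransformationRule, MetaboliteCandidate

__all__ = [
    "DeltaEntry",
    "DeltaLibrary",
    "NodeAnnotation",
    "build_delta_library",
    "annotate_edges",
    "propagate_from_parent",
    "find_parent_node",
    "match_to_insilico",
    "chain_name",
]

#: Display order of generic labels in chain names (functionalization first).
_LABEL_ORDER = ("hydroxylation", "methylation", "sulfation", "glucuronidation")


def chain_name(chain: Sequence[str]) -> str:
    """Canonical chain name, e.g. ``"2 × methylation + sulfation"``."""
    if not chain:
        return "parent"
    counts = Counter(chain)
    parts = []
    for label in (*_LABEL_ORDER, *sorted(set(counts) - set(_LABEL_ORDER))):
        n = counts.get(label, 0)
        if n == 1:
            parts.append(label)
        elif n > 1:
            parts.append(f"{n} × {label}")
    return " + ".join(parts)


@dataclass(frozen=True)
class DeltaEntry:
    name: str
    chain: Tuple[str, ...]  # sorted generic labels
    delta_formula: Mapping[str, int]
    delta_mass: float


@dataclass(frozen=True)
class DeltaLibrary:
    entries: Tuple[DeltaEntry, ...]
    max_depth: int

    def best_match(self, shift: float, tol: float) -> Optional[DeltaEntry]:
        """Entry minimizing |shift - delta|; ties -> shortest chain; None if > tol."""
        best = None
        for e in self.entries:
            err = abs(shift - e.delta_mass)
            if err > tol:
                continue
            key = (err, len(e.chain))
            if best is None or key < best[0]:
                best = (key, e)
        return best[1] if best is not None else None


def _merge_deltas(chains: Sequence[Mapping[str, int]]) -> Dict[str, int]:
    out: Dict[str, int] = {}
    for d in chains:
        for elem, n in d.items():
            out[elem] = out.get(elem, 0) + n
    return {e: n for e, n in out.items() if n != 0}


def build_delta_library(
    rules: Sequence[BiotransformationRule], max_depth: int = 2
) -> DeltaLibrary:
    """All multisets of <= ``max_depth`` rule deltas, unique by delta formula.

    Rules sharing a delta formula (O- vs N-glucuronidation, aromatic
    hydroxylation vs N-oxidation) collapse onto their generic ``shift_label``
    because a precursor mass shift cannot distinguish them.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    base: Dict[str, Mapping[str, int]] = {}
    for r in rules:
        if r.low_confidence:
            continue
        base.setdefault(r.shift_label, r.delta)
    labels = sorted(base)
    seen: Dict[str, DeltaEntry] = {}
    for depth in range(1, max_depth + 1):
        for combo in itertools.combinations_with_replacement(labels, depth):
            delta = _merge_deltas([base[l] for l in combo])
            key = format_formula(ElementalFormula({e: abs(n) for e, n in delta.items()})) + str(
                sorted(delta.items())
            )
            if key in seen:
                continue
            mass = sum(
                n * DEFAULT_CONVENTIONS.isotope_masses[e] for e, n in delta.items()
            )
            seen[key] = DeltaEntry(
                name=chain_name(combo),
                chain=tuple(sorted(combo)),
                delta_formula=delta,
                delta_mass=mass,
            )
    entries = tuple(sorted(seen.values(), key=lambda e: (e.delta_mass, len(e.chain))))
    return DeltaLibrary(entries=entries, max_depth=max_depth)


@dataclass
class NodeAnnotation:
    """Proposed chain/formula for one network node, relative to the parent."""

    node_id: str
    mz: float
    rt_min: float
    chain: Optional[Tuple[str, ...]]  # None -> unassigned
    formula: Optional[ElementalFormula]
    mass_error_mda: Optional[float]
    evidence_path: Tuple[str, ...] = ()
    insilico_support: Tuple[str, ...] = ()
    insilico_agreement: bool = False

    @property
    def assigned(self) -> bool:
        return self.chain is not None

    @property
    def is_parent(self) -> bool:
        return self.chain == ()

    @property
    def chain_label(self) -> str:
        return chain_name(self.chain) if self.chain is not None else "unassigned"


def annotate_edges(
    net: MolecularNetwork, lib: DeltaLibrary, delta_tol: float = 0.01
) -> MolecularNetwork:
    """Label each edge with the best-matching biotransformation, in place."""
    for u, v, data in net.graph.edges(data=True):
        entry = lib.best_match(abs(float(data["shift"])), delta_tol)
        data["reaction"] = entry.name if entry is not None else "unannotated"
    return net


def find_parent_node(
    net: MolecularNetwork, expected_mz: float, tol: float = 0.02
) -> str:
    """Node whose precursor is nearest to ``expected_mz`` (within tol)."""
    best = None
    for node in net.graph.nodes:
        err = abs(net.node_mz(node) - expected_mz)
        if err <= tol and (best is None or err < best[0]):
            best = (err, node)
    if best is None:
        raise ValueError(f"no node within {tol} Da of m/z {expected_mz}")
    return best[1]


def propagate_from_parent(
    net: MolecularNetwork,
    parent_node: str,
    parent_formula: ElementalFormula,
    lib: DeltaLibrary,
    delta_tol: float = 0.01,
) -> List[NodeAnnotation]:
    """Annotate every node of the parent's component by cumulative mass shift.

    Returns annotations sorted by node m/z (parent first has chain ``()``).
    Nodes whose shift matches no library chain within ``delta_tol`` are
    flagged unassigned.  Deterministic and independent of node enumeration
    order.
    """
    if parent_node not in net.graph:
        raise ValueError(f"parent node {parent_node!r} absent from network")
    parent_mz = net.node_mz(parent_node)

    component = nx.node_connected_component(net.graph, parent_node)
    paths = nx.single_source_shortest_path(net.graph.subgraph(component), parent_node)

    annotations: List[NodeAnnotation] = []
    for node in sorted(component, key=lambda n: (net.node_mz(n), n)):
        if node == parent_node:
            annotations.append(
                NodeAnnotation(
                    node_id=node,
                    mz=parent_mz,
                    rt_min=net.node_rt(node),
                    chain=(),
                    formula=parent_formula,
                    mass_error_mda=0.0,
                    evidence_path=(node,),
                )
            )
            continue
        shift = net.node_mz(node) - parent_mz
        entry = lib.best_match(shift, delta_tol) if shift > 0 else None
        path = tuple(paths.get(node, ()))
        if entry is None:
            annotations.append(
                NodeAnnotation(
                    node_id=node,
                    mz=net.node_mz(node),
                    rt_min=net.node_rt(node),
                    chain=None,
                    formula=None,
                    mass_error_mda=None,
                    evidence_path=path,
                )
            )
        else:
            formula = combine(parent_formula, entry.delta_formula)
            annotations.append(
                NodeAnnotation(
                    node_id=node,
                    mz=net.node_mz(node),
                    rt_min=net.node_rt(node),
                    chain=entry.chain,
                    formula=formula,
                    mass_error_mda=(shift - entry.delta_mass) * 1000.0,
                    evidence_path=path,
                )
            )
    annotations.sort(key=lambda a: (a.mz, a.node_id))
    return annotations


def match_to_insilico(
    annotations: Sequence[NodeAnnotation],
    candidates: Sequence[MetaboliteCandidate],
    mz_tol: float = 0.005,
    predictor_label: str = "rule-engine",
) -> List[NodeAnnotation]:
    """Cross-reference annotations with in silico candidates by m/z.

    Each annotation gains the predictor label for every candidate whose
    protonated m/z lies within ``mz_tol`` of the observed node m/z; the
    agreement flag is set when some matching candidate's generic chain
    multiset equals the annotation's chain.
    """
    out = []
    for ann in annotations:
        hits = [c for c in candidates if abs(c.mz - ann.mz) <= mz_tol]
        support = (predictor_label,) if hits else ()
        agreement = any(
            ann.chain is not None and tuple(sorted(c.generic_chain)) == tuple(sorted(ann.chain))
            for c in hits
        )
        out.append(
            NodeAnnotation(
                node_id=ann.node_id,
                mz=ann.mz,
                rt_min=ann.rt_min,
                chain=ann.chain,
                formula=ann.formula,
                mass_error_mda=ann.mass_error_mda,
                evidence_path=ann.evidence_path,
                insilico_support=support,
                insilico_agreement=agreement,
            )
        )
    return out
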