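"""Molecular networking: modified-cosine spectral similarity and graph rules.

The network follows the GNPS-style construction used in LC-HRMS/MS metabolite
screening: nodes are MS/MS features; an edge is drawn between two spectra
when their (modified) cosine similarity exceeds a threshold with a minimum
number of matched fragment ions, and is retained only if each endpoint ranks
the other among its top-k most similar neighbours.  Defaults mirror common
high-resolution practice: 0.02 Da precursor/fragment tolerance, cosine >
0.70, >= 6 shared ions, mutual top-10, minimum cluster size 1.

The modified ("shifted") cosine additionally matches fragment pairs offset by
the precursor mass difference, which is what links a compound to its
conjugates; the plain unshifted cosine is available via ``score_mode``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from .synth import MsmsSpectrum

__all__ = [
    "NetworkParams",
    "SimilarityResult",
    "MolecularNetwork",
    "spectral_similarity",
    "build_network",
    "clusters",
    "export_graphml",
    "read_graphml",
]


@dataclass(frozen=True)
class NetworkParams:
    fragment_tol: float = 0.02  # Da
    precursor_tol: float = 0.02  # Da
    cosine_threshold: float = 0.70
    min_matched_peaks: int = 6
    top_k: int = 10
    min_cluster_size: int = 1
    score_mode: str = "shifted"  # "shifted" (modified cosine) or "unshifted"
    sqrt_intensity: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.cosine_threshold <= 1.0:
            raise ValueError("cosine_threshold must be in [0, 1]")
        if self.fragment_tol <= 0 or self.precursor_tol <= 0:
            raise ValueError("tolerances must be > 0")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.score_mode not in ("shifted", "unshifted"):
            raise ValueError("score_mode must be 'shifted' or 'unshifted'")


@dataclass(frozen=True)
class SimilarityResult:
    score: float
    matched_count: int


def _weights(spec: MsmsSpectrum, sqrt_intensity: bool) -> np.ndarray:
    inten = spec.intensity_array.astype(float)
    w = np.sqrt(inten) if sqrt_intensity else inten
    norm = np.linalg.norm(w)
    return w / norm if norm > 0 else w


def candidate_pairs(
    a: MsmsSpectrum, b: MsmsSpectrum, params: NetworkParams
) -> List[Tuple[int, int]]:
    """Index pairs (i in a, j in b) matchable directly or via precursor shift."""
    mza, mzb = a.mz_array, b.mz_array
    shift = b.precursor_mz - a.precursor_mz
    pairs: Set[Tuple[int, int]] = set()
    for i, ma in enumerate(mza):
        for j, mb in enumerate(mzb):
            if abs(ma - mb) <= params.fragment_tol:
                pairs.add((i, j))
            elif params.score_mode == "shifted" and abs(ma + shift - mb) <= params.fragment_tol:
                pairs.add((i, j))
    return sorted(pairs)


def spectral_similarity(
    a: MsmsSpectrum, b: MsmsSpectrum, params: NetworkParams = NetworkParams()
) -> SimilarityResult:
    """Modified-cosine similarity with greedy one-to-one peak assignment.

    Peak intensities are square-root transformed (configurable) and
    L2-normalized; candidate matches are accumulated greedily by descending
    intensity product under a one-to-one constraint, giving a score in
    [0, 1].  Symmetric in its arguments.
    """
    if not a.peaks or not b.peaks:
        raise ValueError("cannot score an empty peak list")
    wa = _weights(a, params.sqrt_intensity)
    wb = _weights(b, params.sqrt_intensity)
    pairs = candidate_pairs(a, b, params)
    # greedy: descending product; deterministic tie-break on (i, j)
    ranked = sorted(pairs, key=lambda ij: (-wa[ij[0]] * wb[ij[1]], ij[0], ij[1]))
    used_a: Set[int] = set()
    used_b: Set[int] = set()
    score = 0.0
    matched = 0
    for i, j in ranked:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        score += float(wa[i] * wb[j])
        matched += 1
    return SimilarityResult(score=min(score, 1.0), matched_count=matched)


@dataclass
class MolecularNetwork:
    """Feature graph with scored, mass-shift-labelled edges."""

    graph: nx.Graph
    params: NetworkParams

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_mz(self, node: str) -> float:
        return float(self.graph.nodes[node]["mz"])

    def node_rt(self, node: str) -> float:
        return float(self.graph.nodes[node]["rt"])

    def node_intensities(self, node: str) -> Dict[str, float]:
        return {
            k[len("intensity_"):]: float(v)
            for k, v in self.graph.nodes[node].items()
            if k.startswith("intensity_")
        }


def _rank_key(score: float, shift: float, neighbor: str):
    return (-score, abs(shift), neighbor)


def build_network(
    spectra: Sequence[MsmsSpectrum], params: NetworkParams = NetworkParams()
) -> MolecularNetwork:
    """All-pairs scoring, threshold + min-matched filter, then mutual top-k.

    Edge retention: an edge survives iff its score strictly exceeds the
    cosine threshold, its matched-ion count meets the minimum, and each
    endpoint ranks the other within its top-k neighbours (rank by score
    descending, |precursor shift| ascending, node id ascending).
    """
    if not spectra:
        raise ValueError("need at least one spectrum")
    g = nx.Graph()
    for s in spectra:
        attrs = {"mz": s.precursor_mz, "rt": s.rt_min}
        for sample, inten in s.sample_intensities.items():
            attrs[f"intensity_{sample}"] = inten
        g.add_node(s.feature_id, **attrs)

    candidates = []  # (u, v, score, matched, shift)
    for ia in range(len(spectra)):
        for ib in range(ia + 1, len(spectra)):
            a, b = spectra[ia], spectra[ib]
            sim = spectral_similarity(a, b, params)
            if sim.score > params.cosine_threshold and sim.matched_count >= params.min_matched_peaks:
                shift = b.precursor_mz - a.precursor_mz
                candidates.append((a.feature_id, b.feature_id, sim.score, sim.matched_count, shift))

    # mutual top-k over threshold-passing edges
    incident: Dict[str, List[Tuple[float, float, str]]] = {n: [] for n in g.nodes}
    for u, v, score, matched, shift in candidates:
        incident[u].append((score, shift, v))
        incident[v].append((score, shift, u))
    topk: Dict[str, Set[str]] = {}
    for node, edges in incident.items():
        ranked = sorted(edges, key=lambda e: _rank_key(e[0], e[1], e[2]))
        topk[node] = {nb for _, _, nb in ranked[: params.top_k]}
    for u, v, score, matched, shift in candidates:
        if v in topk[u] and u in topk[v]:
            g.add_edge(u, v, score=score, matched=matched, shift=shift)

    return MolecularNetwork(graph=g, params=params)


def clusters(net: MolecularNetwork) -> List[Set[str]]:
    """Connected components, largest first (singletons retained)."""
    comps = [set(c) for c in nx.connected_components(net.graph)]
    comps = [c for c in comps if len(c) >= net.params.min_cluster_size]
    return sorted(comps, key=lambda c: (-len(c), sorted(c)[0]))


def export_graphml(net: MolecularNetwork, path: str) -> None:
    nx.write_graphml(net.graph, path)


def read_graphml(path: str, params: NetworkParams = NetworkParams()) -> MolecularNetwork:
    return MolecularNetwork(graph=nx.read_graphml(path), params=params)


def edge_list(net: MolecularNetwork) -> List[Dict[str, object]]:
    """Edge list rows (source, target, score, matched, shift) for CSV export."""
    rows = []
    for u, v, data in sorted(net.graph.edges(data=True)):
        rows.append(
            {
                "source": u,
                "target": v,
                "score": data["score"],
                "matched": data["matched"],
                "shift": data["shift"],
            }
        )
    return rows
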