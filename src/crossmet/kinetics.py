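"""Multi-matrix semi-quantitative kinetics over network node intensities.

Turns the pie-chart reading of a multi-matrix molecular network into numbers:
per-node intensities are aggregated by sample group (e.g. H1 vs H3 plasma)
and normalized to proportions, and a simple fold comparison classifies each
node's trend between two groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping

from .network import MolecularNetwork

__all__ = ["GroupProfile", "group_profiles", "kinetic_trend"]


@dataclass(frozen=True)
class GroupProfile:
    node_id: str
    intensity: Mapping[str, float]  # group -> aggregated intensity
    proportion: Mapping[str, float]  # group -> share of total (sums to 1)
    absent: bool  # all groups zero

    def __post_init__(self) -> None:
        if not self.absent:
            total = sum(self.proportion.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"proportions sum to {total}, expected 1")


def group_profiles(
    net: MolecularNetwork,
    grouping: Mapping[str, str],
    agg: str = "mean",
) -> List[GroupProfile]:
    """Aggregate per-sample node intensities into per-group profiles.

    ``grouping`` maps every sample label to a group name; samples present on
    a node but missing from the grouping raise a ``ValueError``.
    """
    if agg not in ("mean", "sum"):
        raise ValueError("agg must be 'mean' or 'sum'")
    profiles = []
    for node in sorted(net.graph.nodes):
        samples = net.node_intensities(node)
        unknown = set(samples) - set(grouping)
        if unknown:
            raise ValueError(f"unknown sample label(s) {sorted(unknown)} on node {node}")
        by_group: Dict[str, List[float]] = {}
        for sample, value in samples.items():
            by_group.setdefault(grouping[sample], []).append(value)
        intensity = {
            g: (sum(v) / len(v) if agg == "mean" else sum(v)) for g, v in by_group.items()
        }
        total = sum(intensity.values())
        if total > 0:
            proportion = {g: v / total for g, v in intensity.items()}
            absent = False
        else:
            proportion = {g: 0.0 for g in intensity}
            absent = True
        profiles.append(
            GroupProfile(node_id=node, intensity=intensity, proportion=proportion, absent=absent)
        )
    return profiles


def kinetic_trend(
    profile: GroupProfile, g1: str, g2: str, fold_threshold: float = 1.0
) -> str:
    """Classify a node as ``higher_at_<g1>``, ``higher_at_<g2>`` or ``flat``.

    ``higher_at_g1`` iff intensity(g1) > fold_threshold * intensity(g2);
    symmetric for g2; otherwise flat.  Antisymmetric under group swap and
    invariant to uniform intensity rescaling.
    """
    for g in (g1, g2):
        if g not in profile.intensity:
            raise ValueError(f"group {g!r} not in profile for node {profile.node_id}")
    i1, i2 = profile.intensity[g1], profile.intensity[g2]
    if i1 > fold_threshold * i2:
        return f"higher_at_{g1}"
    if i2 > fold_threshold * i1:
        return f"higher_at_{g2}"
    return "flat"
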