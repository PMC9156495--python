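"""Switch Analysis: A/B/U typing per network scope plus per-scope
Jaccard-Tanimoto comparison of the two phenotypes' presence lists.

Scopes are every network node (compartment) and every axis.  At a scope a
lipid present in both phenotypes is A-type; present in exactly one, B-type
attributed to that phenotype; present in neither, omitted.  U-type is a
network-wide summary per phenotype: present at every compartment.  A U-type
lipid still participates in node/axis A/B lists, so the Jaccard inputs are
unaffected by U-labelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset_io import TrafficNetwork
from .jaccard_stats import JaccardParams, JaccardResult, jaccard_test
from .presence import PresenceMap, axis_presence

__all__ = [
    "ScopeClassification",
    "SwitchReport",
    "classify_node",
    "classify_axis",
    "find_ubiquitous",
    "run_switch",
]


@dataclass(frozen=True)
class ScopeClassification:
    """A/B lists at one scope (node or axis).

    ``a_types`` and ``b_types`` are disjoint and together cover every lipid
    present in at least one phenotype at the scope; ``b_types`` maps lipid
    to the phenotype it is attributed to.
    """

    scope: str
    scope_kind: str  # "node" | "axis"
    a_types: tuple[str, ...]
    b_types: dict[str, str]


@dataclass
class SwitchReport:
    nodes: dict[str, ScopeClassification]
    axes: dict[str, ScopeClassification]
    ubiquitous: dict[str, tuple[str, ...]]  # lipid -> phenotype(s)
    jaccard: dict[str, JaccardResult] = field(default_factory=dict)

    def scope(self, label: str) -> ScopeClassification:
        if label in self.nodes:
            return self.nodes[label]
        return self.axes[label]

    def types_frame(self) -> pd.DataFrame:
        """(scope, scope_kind, lipid, type, attributed_phenotype) table.

        U-type rows carry scope="network"; attribution joins multiple
        phenotypes with "+" when a lipid is ubiquitous in both.
        """
        rows = []
        for sc in list(self.nodes.values()) + list(self.axes.values()):
            for lipid in sc.a_types:
                rows.append((sc.scope, sc.scope_kind, lipid, "A", ""))
            for lipid, pheno in sc.b_types.items():
                rows.append((sc.scope, sc.scope_kind, lipid, "B", pheno))
        for lipid, phenos in self.ubiquitous.items():
            rows.append(("network", "network", lipid, "U", "+".join(phenos)))
        return pd.DataFrame(
            rows, columns=["scope", "scope_kind", "lipid", "type", "attributed_phenotype"]
        )

    def jaccard_frame(self) -> pd.DataFrame:
        rows = []
        for scope, res in self.jaccard.items():
            rows.append(
                {
                    "scope": scope,
                    "J": res.J,
                    "p": res.p,
                    "n_intersection": res.n_intersection,
                    "n_union": res.n_union,
                    "B_permutations": res.params.B_permutations,
                    "seed": res.params.seed,
                    "uninformative": res.uninformative,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "scope", "J", "p", "n_intersection", "n_union",
                "B_permutations", "seed", "uninformative",
            ],
        )


def _classify(pm: PresenceMap, present_of: dict[str, dict[str, bool]],
              scope: str, kind: str) -> ScopeClassification:
    ph1, ph2 = pm.phenotypes
    a_types = []
    b_types: dict[str, str] = {}
    for lipid in pm.lipids:
        in1 = present_of[ph1][lipid]
        in2 = present_of[ph2][lipid]
        if in1 and in2:
            a_types.append(lipid)
        elif in1:
            b_types[lipid] = ph1
        elif in2:
            b_types[lipid] = ph2
    return ScopeClassification(
        scope=scope, scope_kind=kind, a_types=tuple(a_types), b_types=b_types
    )


def classify_node(pm: PresenceMap, compartment: str) -> ScopeClassification:
    """A/B typing of every lipid at one compartment."""
    if compartment not in pm.compartments:
        raise ValueError(f"unknown compartment {compartment!r}")
    present_of = {
        ph: {l: pm.present(l, compartment, ph) for l in pm.lipids}
        for ph in pm.phenotypes
    }
    return _classify(pm, present_of, scope=compartment, kind="node")


def classify_axis(pm: PresenceMap, axis: tuple[str, str]) -> ScopeClassification:
    """A/B typing on an axis (present at both endpoints)."""
    present_of = {ph: axis_presence(pm, axis, ph) for ph in pm.phenotypes}
    return _classify(pm, present_of, scope=pm.network.axis_label(axis), kind="axis")


def find_ubiquitous(pm: PresenceMap, network: TrafficNetwork) -> dict[str, tuple[str, ...]]:
    """Lipids present at every compartment of the network, per phenotype.

    Returns lipid -> tuple of phenotypes (one or both) it is ubiquitous in;
    lipids ubiquitous in neither are omitted.
    """
    out: dict[str, tuple[str, ...]] = {}
    for lipid in pm.lipids:
        phenos = tuple(
            ph
            for ph in pm.phenotypes
            if all(pm.present(lipid, comp, ph) for comp in network.compartments)
        )
        if phenos:
            out[lipid] = phenos
    return out


def run_switch(pm: PresenceMap, network: TrafficNetwork, jparams: JaccardParams) -> SwitchReport:
    """Full Switch Analysis: classify every node and axis, find U-types,
    and attach one Jaccard-Tanimoto result per scope.

    Scopes are processed in network declaration order (nodes first, then
    axes); per-scope permutation seeds are spawned deterministically from
    ``jparams.seed``.
    """
    nodes = {comp: classify_node(pm, comp) for comp in network.compartments}
    axes = {
        network.axis_label(axis): classify_axis(pm, axis) for axis in network.axes
    }
    ubiquitous = find_ubiquitous(pm, network)

    ph1, ph2 = pm.phenotypes
    scope_vectors: list[tuple[str, list[int], list[int]]] = []
    for comp in network.compartments:
        scope_vectors.append(
            (comp, pm.presence_vector(comp, ph1), pm.presence_vector(comp, ph2))
        )
    for axis in network.axes:
        p1 = axis_presence(pm, axis, ph1)
        p2 = axis_presence(pm, axis, ph2)
        scope_vectors.append(
            (
                network.axis_label(axis),
                [int(p1[l]) for l in pm.lipids],
                [int(p2[l]) for l in pm.lipids],
            )
        )
    seeds = np.random.SeedSequence(jparams.seed).generate_state(len(scope_vectors))
    jaccard_results = {}
    for (scope, u, v), seed in zip(scope_vectors, seeds):
        sc_params = JaccardParams(
            B_permutations=jparams.B_permutations,
            seed=int(seed),
            alternative=jparams.alternative,
        )
        jaccard_results[scope] = jaccard_test(u, v, sc_params)
    return SwitchReport(
        nodes=nodes, axes=axes, ubiquitous=ubiquitous, jaccard=jaccard_results
    )
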