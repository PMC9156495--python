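"""Presence calling: the >=66%-of-samples detection rule.

A lipid counts as present in a (compartment, phenotype) group when its
signal is strictly positive in at least ``threshold`` percent of that
group's samples.  The comparison is done in integer arithmetic
(``100 * detected >= threshold * n``) so that e.g. 2 of 3 samples (66.7%)
passes a 66% threshold without any floating-point rounding concerns.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import pandas as pd

from .dataset_io import AbundanceTable, TrafficNetwork

__all__ = ["PresenceCall", "PresenceMap", "call_presence", "axis_presence"]


@dataclass(frozen=True)
class PresenceCall:
    detected_count: int
    n: int
    present: bool

    @property
    def fraction(self) -> Fraction:
        return Fraction(self.detected_count, self.n)


@dataclass
class PresenceMap:
    """Boolean detection calls per (lipid, compartment, phenotype).

    Unobserved combinations are absent from ``calls`` and report
    ``present=False`` when queried.
    """

    calls: dict[tuple[str, str, str], PresenceCall]
    lipids: tuple[str, ...]
    compartments: tuple[str, ...]
    phenotypes: tuple[str, str]
    threshold_percent: int
    network: TrafficNetwork

    def call(self, lipid: str, compartment: str, phenotype: str) -> PresenceCall | None:
        return self.calls.get((lipid, compartment, phenotype))

    def present(self, lipid: str, compartment: str, phenotype: str) -> bool:
        c = self.calls.get((lipid, compartment, phenotype))
        return c.present if c is not None else False

    def presence_vector(self, compartment: str, phenotype: str) -> list[int]:
        """0/1 vector over ``self.lipids`` for a node scope."""
        return [int(self.present(l, compartment, phenotype)) for l in self.lipids]

    def to_frame(self) -> pd.DataFrame:
        """Long-table export: lipid, compartment, phenotype, counts, call."""
        rows = []
        for comp in self.compartments:
            for lipid in self.lipids:
                for pheno in self.phenotypes:
                    c = self.calls.get((lipid, comp, pheno))
                    if c is None:
                        continue
                    rows.append(
                        {
                            "lipid": lipid,
                            "compartment": comp,
                            "phenotype": pheno,
                            "detected_count": c.detected_count,
                            "n": c.n,
                            "present": c.present,
                        }
                    )
        return pd.DataFrame(
            rows,
            columns=["lipid", "compartment", "phenotype", "detected_count", "n", "present"],
        )


def call_presence(tbl: AbundanceTable, threshold_percent: int = 66) -> PresenceMap:
    """Binarize detection for every lipid observed anywhere in the table.

    For each (lipid, compartment, phenotype) with at least one sample in the
    group, counts samples with signal > 0 (missing records are 0) and calls
    presence via the integer rule ``100 * count >= threshold * n``.
    """
    if not (0 < threshold_percent <= 100):
        raise ValueError(
            f"threshold_percent must be in (0, 100], got {threshold_percent}"
        )
    groups = tbl.group_samples()
    lipids = tbl.lipids()
    detected: dict[tuple[str, str, str], set[str]] = {}
    for row in tbl.data.itertuples(index=False):
        if row.signal > 0:
            detected.setdefault((row.lipid, row.compartment, row.phenotype), set()).add(
                row.sample_id
            )
    calls: dict[tuple[str, str, str], PresenceCall] = {}
    for (pheno, comp), samples in groups.items():
        n = len(samples)
        for lipid in lipids:
            count = len(detected.get((lipid, comp, pheno), ()))
            calls[(lipid, comp, pheno)] = PresenceCall(
                detected_count=count,
                n=n,
                present=100 * count >= threshold_percent * n,
            )
    return PresenceMap(
        calls=calls,
        lipids=tuple(lipids),
        compartments=tbl.network.compartments,
        phenotypes=tbl.phenotypes,
        threshold_percent=threshold_percent,
        network=tbl.network,
    )


def axis_presence(pm: PresenceMap, axis: tuple[str, str], phenotype: str) -> dict[str, bool]:
    """Presence on an axis: present at BOTH endpoint compartments.

    Raises ``ValueError`` if the axis is not part of the bound network.
    """
    a, b = axis
    if not pm.network.has_axis(a, b):
        raise ValueError(f"unknown axis ({a!r}, {b!r})")
    return {
        lipid: pm.present(lipid, a, phenotype) and pm.present(lipid, b, phenotype)
        for lipid in pm.lipids
    }
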