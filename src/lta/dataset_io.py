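"""Canonical data model and IO: traffic network, abundance table, summaries.

The abundance table is long-format delimited text with header columns
``sample_id, phenotype, compartment, lipid, signal``.  A missing
(sample, compartment, lipid) record means signal 0, never missing-at-random;
group means and standard deviations therefore always run over the full set
of samples in the (phenotype, compartment) group.

The traffic network is a small YAML file declaring ``compartments`` (list)
and ``axes`` (list of two-item lists).  The bundled default is a star with
serum as the hub joined to liver, brain, heart atria, heart ventricles,
spleen, renal medulla and renal cortex.
"""

from __future__ import annotations

import csv
import importlib.resources
import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
import yaml

from .nomenclature import LipidSpecies, parse_lipid_name

__all__ = [
    "TrafficNetwork",
    "AbundanceTable",
    "GroupSummary",
    "DataValidationError",
    "NetworkConfigError",
    "default_network",
    "read_network",
    "read_abundance_table",
    "write_abundance_table",
    "summarise_groups",
]

TABLE_COLUMNS = ["sample_id", "phenotype", "compartment", "lipid", "signal"]


class DataValidationError(ValueError):
    """Raised when an input table violates the data-model invariants."""


class NetworkConfigError(ValueError):
    """Raised when a network configuration is structurally invalid."""


@dataclass(frozen=True)
class TrafficNetwork:
    """Compartments and the axes (edges) lipids are traced over.

    Axes are unordered pairs of distinct, declared compartments; the graph
    must be connected.  Compartment order is preserved from the declaration
    and fixes output ordering downstream.
    """

    compartments: tuple[str, ...]
    axes: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(set(self.compartments)) != len(self.compartments):
            raise NetworkConfigError("compartment ids must be unique")
        comp_set = set(self.compartments)
        seen: set[frozenset[str]] = set()
        for a, b in self.axes:
            if a == b:
                raise NetworkConfigError(f"self-loop axis ({a!r}, {b!r}) not allowed")
            for end in (a, b):
                if end not in comp_set:
                    raise NetworkConfigError(
                        f"axis endpoint {end!r} is not a declared compartment"
                    )
            key = frozenset((a, b))
            if key in seen:
                raise NetworkConfigError(f"duplicate axis ({a!r}, {b!r})")
            seen.add(key)
        g = self.graph()
        if len(self.compartments) > 1 and not nx.is_connected(g):
            raise NetworkConfigError("network is not connected")

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.compartments)
        g.add_edges_from(self.axes)
        return g

    def has_axis(self, a: str, b: str) -> bool:
        key = frozenset((a, b))
        return any(frozenset(ax) == key for ax in self.axes)

    def axis_label(self, axis: tuple[str, str]) -> str:
        return f"{axis[0]}--{axis[1]}"


def default_network() -> TrafficNetwork:
    """The bundled 8-compartment serum-hub star network."""
    with importlib.resources.files("lta.data").joinpath("default_network.yaml").open(
        "r", encoding="utf-8"
    ) as fh:
        return _network_from_mapping(yaml.safe_load(fh), source="<bundled default>")


def _network_from_mapping(doc: object, source: str) -> TrafficNetwork:
    if not isinstance(doc, Mapping):
        raise NetworkConfigError(f"{source}: expected a mapping with keys compartments/axes")
    try:
        compartments = [str(c) for c in doc["compartments"]]
        axes_raw = doc["axes"]
    except (KeyError, TypeError) as exc:
        raise NetworkConfigError(f"{source}: missing key {exc}") from exc
    axes = []
    for item in axes_raw:
        if not isinstance(item, (list, tuple)) or len(item) != 2:
            raise NetworkConfigError(f"{source}: axis {item!r} is not a 2-item list")
        axes.append((str(item[0]), str(item[1])))
    return TrafficNetwork(compartments=tuple(compartments), axes=tuple(axes))


def read_network(path: str | Path) -> TrafficNetwork:
    """Read and validate a traffic network from a YAML config file."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return _network_from_mapping(doc, source=str(path))


@dataclass
class AbundanceTable:
    """Validated long-format per-sample lipid signals bound to a network.

    ``data`` has columns ``sample_id, phenotype, compartment, lipid, signal``
    with lipid names canonicalised; ``species`` maps canonical name to the
    parsed :class:`~lta.nomenclature.LipidSpecies`.
    """

    data: pd.DataFrame
    network: TrafficNetwork
    species: dict[str, LipidSpecies] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        df = self.data
        missing = [c for c in TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise DataValidationError(f"missing columns: {missing}")
        phenos = sorted(df["phenotype"].unique())
        if len(phenos) != 2:
            raise DataValidationError(
                f"expected exactly 2 phenotype labels, found {len(phenos)}: {phenos}"
            )
        unknown = sorted(set(df["compartment"]) - set(self.network.compartments))
        if unknown:
            raise DataValidationError(f"unknown compartments: {unknown}")
        if (df["signal"] < 0).any():
            bad = df.index[df["signal"] < 0][0]
            raise DataValidationError(f"negative signal at row {bad}")
        dup = df.duplicated(subset=["sample_id", "compartment", "lipid"])
        if dup.any():
            row = df.loc[dup.idxmax()]
            raise DataValidationError(
                "duplicate record for (sample_id, compartment, lipid) = "
                f"({row['sample_id']!r}, {row['compartment']!r}, {row['lipid']!r})"
            )

    @property
    def phenotypes(self) -> tuple[str, str]:
        a, b = sorted(self.data["phenotype"].unique())
        return (a, b)

    def lipids(self) -> list[str]:
        """Canonical lipid names observed anywhere, in (head, C, D) order."""
        return sorted(
            set(self.data["lipid"]),
            key=lambda name: self.species[name].sort_key(),
        )

    def group_samples(self) -> dict[tuple[str, str], tuple[str, ...]]:
        """Sample ids per (phenotype, compartment); defines group sizes n."""
        out: dict[tuple[str, str], tuple[str, ...]] = {}
        grouped = self.data.groupby(["phenotype", "compartment"], sort=True)["sample_id"]
        for (pheno, comp), ids in grouped:
            out[(pheno, comp)] = tuple(sorted(set(ids)))
        return out


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_abundance_table(path: str | Path, network: TrafficNetwork) -> AbundanceTable:
    """Read a delimited abundance table, parse lipid names and validate.

    The delimiter (comma or tab) is sniffed from the header line.  Lipid
    names are canonicalised through the nomenclature parser; all data-model
    violations are reported with offending values.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline()
        if not first.strip():
            raise DataValidationError(f"empty data file: {path}")
        sep = _sniff_delimiter(first)
        fh.seek(0)
        df = pd.read_csv(fh, sep=sep, dtype={"sample_id": str, "phenotype": str, "compartment": str})
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(f"{path}: missing columns {missing}")
    species: dict[str, LipidSpecies] = {}
    canonical = []
    for idx, raw in df["lipid"].items():
        try:
            sp = parse_lipid_name(str(raw))
        except ValueError as exc:
            raise DataValidationError(f"{path} row {idx + 2}: {exc}") from exc
        species.setdefault(sp.name, sp)
        canonical.append(sp.name)
    df = df.assign(lipid=canonical, signal=pd.to_numeric(df["signal"], errors="raise"))
    try:
        return AbundanceTable(data=df[TABLE_COLUMNS], network=network, species=species)
    except DataValidationError as exc:
        raise DataValidationError(f"{path}: {exc}") from exc


def write_abundance_table(tbl: AbundanceTable, path: str | Path, sep: str = "\t") -> None:
    """Write the table back to delimited text (lossless round-trip)."""
    tbl.data.to_csv(path, sep=sep, index=False, quoting=csv.QUOTE_MINIMAL)


@dataclass
class GroupSummary:
    """Per-(unit, compartment, phenotype) group sizes, means and sds.

    ``data`` columns: ``unit, compartment, phenotype, n, mean, sd,
    degenerate`` where ``unit`` is a lipid species name or a head-group
    class, ``sd`` uses the n-1 denominator and is reported 0 with the
    ``degenerate`` flag when n = 1.  Zero signals (absent records) are
    included in every mean and sd.
    """

    data: pd.DataFrame
    level: str

    def lookup(self, unit: str, compartment: str, phenotype: str) -> pd.Series | None:
        df = self.data
        hit = df[
            (df["unit"] == unit)
            & (df["compartment"] == compartment)
            & (df["phenotype"] == phenotype)
        ]
        if hit.empty:
            return None
        return hit.iloc[0]


def _summarise(values_by_sample: dict[str, float], samples: tuple[str, ...]) -> tuple[int, float, float, bool]:
    n = len(samples)
    vals = [values_by_sample.get(s, 0.0) for s in samples]
    mean = sum(vals) / n
    if n == 1:
        return n, mean, 0.0, True
    var = sum((v - mean) ** 2 for v in vals) / (n - 1)
    return n, mean, math.sqrt(var), False


def summarise_groups(tbl: AbundanceTable, level: str = "species") -> GroupSummary:
    """Summarise signals per (unit, compartment, phenotype).

    ``level="species"`` summarises each lipid; ``level="class"`` first sums
    signals within each sample over all species sharing a head group (absent
    species contributing 0), then summarises the per-sample class values.
    A unit appears at a compartment if any of its records do, and then gets
    one row per phenotype so both groups are summarised (possibly with mean
    0) wherever either group detected it.
    """
    if level not in {"species", "class"}:
        raise ValueError(f"level must be 'species' or 'class', got {level!r}")
    groups = tbl.group_samples()
    phenos = tbl.phenotypes
    df = tbl.data
    if level == "class":
        unit_of = {name: sp.head_group for name, sp in tbl.species.items()}
        work = df.assign(unit=df["lipid"].map(unit_of))
        work = (
            work.groupby(["unit", "compartment", "phenotype", "sample_id"], sort=False)[
                "signal"
            ]
            .sum()
            .reset_index()
        )
        unit_order = sorted(set(unit_of.values()))
    else:
        work = df.rename(columns={"lipid": "unit"})
        order_key = {name: sp.sort_key() for name, sp in tbl.species.items()}
        unit_order = sorted(set(work["unit"]), key=order_key.__getitem__)

    # units observed per compartment (either phenotype)
    observed: dict[str, set[str]] = {}
    for unit, comp in work[["unit", "compartment"]].drop_duplicates().itertuples(index=False):
        observed.setdefault(comp, set()).add(unit)

    sig: dict[tuple[str, str, str], dict[str, float]] = {}
    for row in work.itertuples(index=False):
        sig.setdefault((row.unit, row.compartment, row.phenotype), {})[row.sample_id] = (
            sig.get((row.unit, row.compartment, row.phenotype), {}).get(row.sample_id, 0.0)
            + row.signal
        )

    rows = []
    for comp in tbl.network.compartments:
        units_here = observed.get(comp, set())
        for unit in unit_order:
            if unit not in units_here:
                continue
            for pheno in phenos:
                samples = groups.get((pheno, comp))
                if not samples:
                    continue  # no samples for this group in this compartment
                n, mean, sd, degen = _summarise(sig.get((unit, comp, pheno), {}), samples)
                rows.append(
                    {
                        "unit": unit,
                        "compartment": comp,
                        "phenotype": pheno,
                        "n": n,
                        "mean": mean,
                        "sd": sd,
                        "degenerate": degen,
                    }
                )
    out = pd.DataFrame(rows, columns=["unit", "compartment", "phenotype", "n", "mean", "sd", "degenerate"])
    return GroupSummary(data=out, level=level)


def table_from_records(records: Iterable[Mapping[str, object]], network: TrafficNetwork) -> AbundanceTable:
    """Build a validated AbundanceTable from in-memory records.

    Lipid names are parsed and canonicalised as in :func:`read_abundance_table`.
    """
    df = pd.DataFrame(list(records), columns=TABLE_COLUMNS)
    species: dict[str, LipidSpecies] = {}
    canonical = []
    for raw in df["lipid"]:
        sp = parse_lipid_name(str(raw))
        species.setdefault(sp.name, sp)
        canonical.append(sp.name)
    df = df.assign(lipid=canonical)
    return AbundanceTable(data=df, network=network, species=species)
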