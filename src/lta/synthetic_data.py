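"""Synthetic two-phenotype, multi-compartment lipidomics datasets with
planted traffic patterns and a machine-readable ground truth.

The generator starts from a "background" in which every panel lipid is
present in both phenotypes in every compartment, then carves the signal in:

* ``planted_switches`` make a lipid present for one phenotype only at a
  scope (a compartment, or both endpoints of an axis);
* ``planted_ubiquitous`` make a lipid present everywhere for one phenotype
  and absent everywhere for the other;
* ``planted_absences`` remove a lipid from a compartment in both
  phenotypes (used e.g. to keep a whole class out of the U-type lists);
* ``planted_effects`` multiply the case group's abundances for a unit
  (species or head-group class) in one compartment by a fold change.

Abundances are log-normal per head-group class; a truly present signal is
zeroed with probability ``detection_dropout`` (kept below 0.34 so plants
survive the 66% presence rule in expectation).  Identical seeds give
identical datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .dataset_io import AbundanceTable, TrafficNetwork, default_network, table_from_records
from .nomenclature import parse_lipid_name, render_name

__all__ = [
    "SimulationDesign",
    "GroundTruth",
    "DesignError",
    "default_panel",
    "simulate",
    "paper_fixture",
]

Scope = str | tuple[str, str]


class DesignError(ValueError):
    """Raised for internally inconsistent simulation designs."""


DEFAULT_BASELINE_LOG_MEAN = {"TG": math.log(500.0), "PC": math.log(300.0),
                             "PE": math.log(200.0), "PI": math.log(100.0)}
DEFAULT_BASELINE_LOG_SD = 0.2
FALLBACK_LOG_MEAN = math.log(100.0)


def default_panel() -> tuple[str, ...]:
    """~130 species over TG/PC/PE/PI spanning C30-C60, DB 0-12."""
    combos: list[tuple[str, int, int]] = []
    for c in range(44, 61, 2):
        for d in (0, 1, 2, 3, 6, 7):
            combos.append(("TG", c, d))
    combos += [("TG", 58, 11), ("TG", 60, 10), ("TG", 60, 11), ("TG", 60, 12)]
    for c in range(30, 41, 2):
        for d in (0, 1, 2, 4, 6):
            combos.append(("PC", c, d))
    for c in range(34, 41, 2):
        for d in (1, 2, 4, 7):
            combos.append(("PE", c, d))
    for c in range(32, 41, 2):
        for d in (1, 2, 3, 4, 6):
            combos.append(("PI", c, d))
    names = [render_name(h, c, d) for h, c, d in sorted(set(combos))]
    return tuple(names)


@dataclass(frozen=True)
class SimulationDesign:
    """Everything needed to synthesise a dataset and its ground truth."""

    seed: int
    network: TrafficNetwork = field(default_factory=default_network)
    phenotypes: tuple[str, str] = ("control", "diabetic")  # (reference, case)
    n_per_group_per_compartment: int = 5
    lipid_panel: tuple[str, ...] = field(default_factory=default_panel)
    baseline_log_mean: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_LOG_MEAN)
    )
    baseline_log_sd: float = DEFAULT_BASELINE_LOG_SD
    detection_dropout: float = 0.0
    planted_switches: tuple[tuple[str, Scope, str], ...] = ()
    planted_ubiquitous: tuple[tuple[str, str], ...] = ()
    planted_absences: tuple[tuple[str, str], ...] = ()
    planted_effects: tuple[tuple[str, str, float], ...] = ()
    n_overrides: tuple[tuple[str, str, int], ...] = ()  # (phenotype, compartment, n)

    @property
    def reference(self) -> str:
        return self.phenotypes[0]

    @property
    def case(self) -> str:
        return self.phenotypes[1]

    def canonical_panel(self) -> tuple[str, ...]:
        return tuple(parse_lipid_name(n).name for n in self.lipid_panel)

    def scope_compartments(self, scope: Scope) -> tuple[str, ...]:
        if isinstance(scope, str):
            if scope not in self.network.compartments:
                raise DesignError(f"planted scope {scope!r} is not a compartment")
            return (scope,)
        a, b = scope
        if not self.network.has_axis(a, b):
            raise DesignError(f"planted scope ({a!r}, {b!r}) is not a network axis")
        return (a, b)

    def group_n(self, phenotype: str, compartment: str) -> int:
        for ph, comp, n in self.n_overrides:
            if ph == phenotype and comp == compartment:
                return n
        return self.n_per_group_per_compartment

    def validate(self) -> None:
        panel = set(self.canonical_panel())
        if len(self.phenotypes) != 2 or len(set(self.phenotypes)) != 2:
            raise DesignError("exactly two distinct phenotype labels required")
        if not (0.0 <= self.detection_dropout < 0.34):
            raise DesignError(
                "detection_dropout must lie in [0, 0.34) so plants survive the "
                "presence rule in expectation"
            )
        claimed: dict[tuple[str, str], str] = {}
        for lipid, scope, pheno in self.planted_switches:
            name = parse_lipid_name(lipid).name
            if name not in panel:
                raise DesignError(f"planted lipid {lipid!r} is not on the panel")
            if pheno not in self.phenotypes:
                raise DesignError(f"planted phenotype {pheno!r} unknown")
            for comp in self.scope_compartments(scope):
                prev = claimed.get((name, comp))
                if prev is not None and prev != pheno:
                    raise DesignError(
                        f"{name} planted B-type for both phenotypes at {comp!r}"
                    )
                claimed[(name, comp)] = pheno
        for lipid, pheno in self.planted_ubiquitous:
            name = parse_lipid_name(lipid).name
            if name not in panel:
                raise DesignError(f"planted lipid {lipid!r} is not on the panel")
            if pheno not in self.phenotypes:
                raise DesignError(f"planted phenotype {pheno!r} unknown")
        for lipid, comp in self.planted_absences:
            if parse_lipid_name(lipid).name not in panel:
                raise DesignError(f"absence lipid {lipid!r} is not on the panel")
            if comp not in self.network.compartments:
                raise DesignError(f"absence compartment {comp!r} unknown")
        for unit, comp, fold in self.planted_effects:
            if comp not in self.network.compartments:
                raise DesignError(f"effect compartment {comp!r} unknown")
            if not fold > 0:
                raise DesignError(f"fold change must be > 0, got {fold}")

    def presence_design(self) -> dict[tuple[str, str, str], bool]:
        """Noise-free presence pattern: (lipid, compartment, phenotype) -> bool."""
        self.validate()
        panel = self.canonical_panel()
        pattern = {
            (lipid, comp, pheno): True
            for lipid in panel
            for comp in self.network.compartments
            for pheno in self.phenotypes
        }
        for lipid, comp in self.planted_absences:
            name = parse_lipid_name(lipid).name
            for pheno in self.phenotypes:
                pattern[(name, comp, pheno)] = False
        for lipid, pheno in self.planted_ubiquitous:
            name = parse_lipid_name(lipid).name
            other = self.phenotypes[1] if pheno == self.phenotypes[0] else self.phenotypes[0]
            for comp in self.network.compartments:
                pattern[(name, comp, pheno)] = True
                pattern[(name, comp, other)] = False
        for lipid, scope, pheno in self.planted_switches:
            name = parse_lipid_name(lipid).name
            other = self.phenotypes[1] if pheno == self.phenotypes[0] else self.phenotypes[0]
            for comp in self.scope_compartments(scope):
                pattern[(name, comp, pheno)] = True
                pattern[(name, comp, other)] = False
        return pattern

    def effect_fold(self, lipid_name: str, head_group: str, compartment: str) -> float:
        fold = 1.0
        for unit, comp, f in self.planted_effects:
            if comp != compartment:
                continue
            if unit == head_group:
                fold *= f
            else:
                try:
                    unit_name = parse_lipid_name(unit).name
                except ValueError:
                    continue
                if unit_name == lipid_name:
                    fold *= f
        return fold


@dataclass
class GroundTruth:
    """Expected classification and effect directions, derived from the
    design's noise-free presence pattern without running the simulator."""

    node_a: dict[str, tuple[str, ...]]
    node_b: dict[str, dict[str, str]]
    axis_a: dict[str, tuple[str, ...]]
    axis_b: dict[str, dict[str, str]]
    ubiquitous: dict[str, tuple[str, ...]]
    effect_signs: dict[tuple[str, str], int]  # (unit, compartment) -> +1/-1
    design: SimulationDesign

    def to_dict(self) -> dict:
        return {
            "node_a": {k: list(v) for k, v in self.node_a.items()},
            "node_b": self.node_b,
            "axis_a": {k: list(v) for k, v in self.axis_a.items()},
            "axis_b": self.axis_b,
            "ubiquitous": {k: list(v) for k, v in self.ubiquitous.items()},
            "effect_signs": {
                f"{unit}@{comp}": sign for (unit, comp), sign in self.effect_signs.items()
            },
            "seed": self.design.seed,
            "phenotypes": list(self.design.phenotypes),
            "compartments": list(self.design.network.compartments),
            "n_lipids": len(self.design.lipid_panel),
        }


def _derive_truth(design: SimulationDesign) -> GroundTruth:
    pattern = design.presence_design()
    panel = sorted(design.canonical_panel(), key=lambda n: parse_lipid_name(n).sort_key())
    net = design.network
    ref, case = design.phenotypes

    def classify(present_at) -> tuple[tuple[str, ...], dict[str, str]]:
        a_list, b_map = [], {}
        for lipid in panel:
            in_ref, in_case = present_at(lipid, ref), present_at(lipid, case)
            if in_ref and in_case:
                a_list.append(lipid)
            elif in_ref:
                b_map[lipid] = ref
            elif in_case:
                b_map[lipid] = case
        return tuple(a_list), b_map

    node_a, node_b, axis_a, axis_b = {}, {}, {}, {}
    for comp in net.compartments:
        a, b = classify(lambda l, p, c=comp: pattern[(l, c, p)])
        node_a[comp], node_b[comp] = a, b
    for axis in net.axes:
        c1, c2 = axis
        a, b = classify(lambda l, p: pattern[(l, c1, p)] and pattern[(l, c2, p)])
        label = net.axis_label(axis)
        axis_a[label], axis_b[label] = a, b

    ubiquitous = {}
    for lipid in panel:
        phenos = tuple(
            ph for ph in design.phenotypes
            if all(pattern[(lipid, comp, ph)] for comp in net.compartments)
        )
        if phenos:
            ubiquitous[lipid] = phenos

    effect_signs = {}
    for unit, comp, fold in design.planted_effects:
        if fold == 1.0:
            continue
        try:
            unit_key = parse_lipid_name(unit).name
            defined = pattern[(unit_key, comp, ref)] and pattern[(unit_key, comp, case)]
        except ValueError:
            unit_key = unit  # head-group class: defined if any member present
            defined = True
        if defined:
            effect_signs[(unit_key, comp)] = 1 if fold > 1 else -1
    return GroundTruth(
        node_a=node_a, node_b=node_b, axis_a=axis_a, axis_b=axis_b,
        ubiquitous=ubiquitous, effect_signs=effect_signs, design=design,
    )


def simulate(design: SimulationDesign) -> tuple[AbundanceTable, GroundTruth]:
    """Draw a dataset from the design; return it with its ground truth.

    Records are emitted for every designed-present (lipid, compartment,
    phenotype, sample) — possibly with signal 0 after dropout — and never
    for designed-absent combinations.  Iteration order is fixed, so a given
    seed reproduces the dataset exactly.
    """
    truth = _derive_truth(design)
    pattern = design.presence_design()
    rng = np.random.default_rng(design.seed)
    panel = sorted(design.canonical_panel(), key=lambda n: parse_lipid_name(n).sort_key())
    species = {name: parse_lipid_name(name) for name in panel}
    records = []
    for comp in design.network.compartments:
        for pheno in design.phenotypes:
            n = design.group_n(pheno, comp)
            sample_ids = [f"{pheno}_{i + 1:02d}" for i in range(n)]
            for lipid in panel:
                if not pattern[(lipid, comp, pheno)]:
                    continue
                sp = species[lipid]
                mu = design.baseline_log_mean.get(sp.head_group, FALLBACK_LOG_MEAN)
                values = rng.lognormal(mean=mu, sigma=design.baseline_log_sd, size=n)
                if pheno == design.case:
                    values = values * design.effect_fold(lipid, sp.head_group, comp)
                if design.detection_dropout > 0:
                    drop = rng.random(n) < design.detection_dropout
                    values = np.where(drop, 0.0, values)
                for sid, val in zip(sample_ids, values):
                    records.append(
                        {
                            "sample_id": sid,
                            "phenotype": pheno,
                            "compartment": comp,
                            "lipid": lipid,
                            "signal": float(val),
                        }
                    )
    tbl = table_from_records(records, design.network)
    return tbl, truth


def paper_fixture(seed: int = 0, detection_dropout: float = 0.0) -> SimulationDesign:
    """Bundled design encoding the qualitative findings the pipeline should
    recover: control-only short saturated TGs and case-only PUFA-TGs on the
    liver-serum axis, a PI isoform swap on the serum-brain axis, a set of
    control-ubiquitous PCs/PEs, and signed abundance effects (DNL-TGs down
    in case liver; PUFA-TGs up in case liver/serum, down in spleen;
    PI(38:6) up in case liver, down elsewhere).  TGs are held out of the
    brain compartment so no TG is ubiquitous in either phenotype.
    """
    network = default_network()
    panel = default_panel()
    liver_serum: Scope = ("serum", "liver")
    serum_brain_node = "brain"

    switches: list[tuple[str, Scope, str]] = []
    for name in ("TG(44:0)", "TG(46:0)"):
        switches.append((name, liver_serum, "control"))
    for name in ("TG(52:7)", "TG(58:11)", "TG(60:10)", "TG(60:11)", "TG(60:12)"):
        switches.append((name, liver_serum, "diabetic"))
    for name in ("PI(36:2)", "PI(36:3)"):
        switches.append((name, serum_brain_node, "control"))
    for name in ("PI(36:1)", "PI(38:6)"):
        switches.append((name, serum_brain_node, "diabetic"))

    ubiquitous = tuple(
        (name, "control")
        for name in ("PC(32:1)", "PC(32:2)", "PC(34:4)", "PC(36:6)", "PE(40:7)")
    )
    absences = tuple(
        (name, "brain") for name in panel if name.startswith("TG(")
    )

    effects: list[tuple[str, str, float]] = []
    effects.append(("PI(38:6)", "liver", 2.0))
    for comp in network.compartments:
        if comp not in ("liver", "brain"):
            effects.append(("PI(38:6)", comp, 0.5))
    for name in ("TG(48:0)", "TG(48:1)", "TG(50:0)", "TG(50:1)"):
        effects.append((name, "liver", 0.5))
    for name in ("TG(54:7)", "TG(56:7)"):
        effects.append((name, "liver", 2.0))
        effects.append((name, "serum", 2.0))
        effects.append((name, "spleen", 0.5))

    return SimulationDesign(
        seed=seed,
        network=network,
        phenotypes=("control", "diabetic"),
        lipid_panel=panel,
        detection_dropout=detection_dropout,
        planted_switches=tuple(switches),
        planted_ubiquitous=ubiquitous,
        planted_absences=absences,
        planted_effects=tuple(effects),
    )


def with_seed(design: SimulationDesign, seed: int) -> SimulationDesign:
    """Copy of the design with a different seed."""
    return replace(design, seed=seed)
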