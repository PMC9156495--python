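"""Lipid shorthand nomenclature: parsing and subclass tagging.

Lipid variables are written in sum-composition shorthand ``HEAD(C:D)`` where
``HEAD`` is the head-group token (TG, PC, PE, PI, ...), ``C`` the total number
of acyl carbons and ``D`` the total number of double bonds.  Grouped lists
such as ``PI(36:2, 36:3)`` expand to one species per ``C:D`` pair.

Species are annotated with subclass tags used downstream:

``DNL_MARKER``
    Triglycerides characteristic of de novo lipogenesis: short, (near-)
    saturated TGs, plus an explicit, configurable marker list.
``PUFA``
    Species with enough double bonds to imply at least one polyunsaturated
    fatty acid; the threshold differs between TGs (three acyl chains) and
    phospholipids (two).
``OTHER``
    Everything else.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

__all__ = [
    "LipidSpecies",
    "LipidNameError",
    "TaggingPolicy",
    "DEFAULT_POLICY",
    "KNOWN_HEAD_GROUPS",
    "parse_lipid_name",
    "expand_name_list",
    "tag_species",
    "render_name",
]

DNL_MARKER = "DNL_MARKER"
PUFA = "PUFA"
OTHER = "OTHER"

#: Head groups we recognise; anything else parses but triggers a warning.
KNOWN_HEAD_GROUPS = frozenset(
    {"TG", "DG", "PC", "PE", "PI", "PS", "PG", "PA", "SM", "CE", "LPC", "LPE"}
)

#: Head groups treated as glycerophospholipids for the PUFA double-bond rule.
PHOSPHOLIPID_HEAD_GROUPS = frozenset({"PC", "PE", "PI", "PS", "PG", "PA", "LPC", "LPE"})


class LipidNameError(ValueError):
    """Raised when a lipid shorthand name cannot be parsed."""


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid variable identified by head group and sum composition.

    Parameters
    ----------
    raw_name:
        The name exactly as it appeared in the input.
    head_group:
        Alphabetic head-group token, e.g. ``"TG"``.
    carbons:
        Total acyl carbons (>= 2).
    double_bonds:
        Total acyl double bonds (>= 0).
    tags:
        Subclass labels; empty until :func:`tag_species` is applied.
    """

    raw_name: str
    head_group: str
    carbons: int
    double_bonds: int
    tags: frozenset[str] = field(default_factory=frozenset)

    @property
    def name(self) -> str:
        """Canonical rendering ``HEAD(C:D)``."""
        return render_name(self.head_group, self.carbons, self.double_bonds)

    def sort_key(self) -> tuple[str, int, int]:
        return (self.head_group, self.carbons, self.double_bonds)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


def render_name(head_group: str, carbons: int, double_bonds: int) -> str:
    """Render the canonical shorthand ``HEAD(C:D)``."""
    return f"{head_group}({carbons}:{double_bonds})"


_NAME_RE = re.compile(r"^([A-Za-z]+)\(\s*(.+?)\s*\)$")
_PAIR_RE = re.compile(r"^(\d+)\s*:\s*(\d+)$")


def _parse_pair(head: str, pair: str, raw: str) -> LipidSpecies:
    m = _PAIR_RE.match(pair.strip())
    if m is None:
        raise LipidNameError(
            f"malformed composition {pair.strip()!r} in lipid name {raw!r}: "
            "expected integer carbons:double_bonds"
        )
    carbons = int(m.group(1))
    double_bonds = int(m.group(2))
    if carbons < 2:
        raise LipidNameError(
            f"carbons must be >= 2, got {carbons} in lipid name {raw!r}"
        )
    return LipidSpecies(
        raw_name=raw,
        head_group=head,
        carbons=carbons,
        double_bonds=double_bonds,
    )


def _split_head(name: str) -> tuple[str, str]:
    stripped = name.strip()
    m = _NAME_RE.match(stripped)
    if m is None:
        raise LipidNameError(
            f"cannot parse lipid name {name!r}: expected HEAD(C:D) shorthand"
        )
    head, body = m.group(1), m.group(2)
    if head not in KNOWN_HEAD_GROUPS:
        warnings.warn(
            f"unrecognised head group {head!r} in lipid name {name!r}",
            stacklevel=3,
        )
    return head, body


def parse_lipid_name(name: str) -> LipidSpecies:
    """Parse a single ``HEAD(C:D)`` shorthand name.

    Ether, odd-notation or adduct forms (e.g. ``PC(O-34:1)``) are rejected
    rather than coerced.

    Raises
    ------
    LipidNameError
        If the name is not plain ``HEAD(C:D)`` shorthand with integer
        ``C >= 2`` and ``D >= 0``.
    """
    head, body = _split_head(name)
    if "," in body:
        raise LipidNameError(
            f"lipid name {name!r} contains a composition list; "
            "use expand_name_list for grouped names"
        )
    return _parse_pair(head, body, name.strip())


def expand_name_list(name: str) -> list[LipidSpecies]:
    """Expand grouped shorthand ``HEAD(C1:D1, C2:D2, ...)`` into species.

    A single-pair name yields a one-element list.  All species share the
    head group; each records the full grouped string as its ``raw_name``.
    """
    head, body = _split_head(name)
    pairs = [p for p in body.split(",")]
    if not pairs:
        raise LipidNameError(f"empty composition list in lipid name {name!r}")
    return [_parse_pair(head, pair, name.strip()) for pair in pairs]


def _parse_marker_list(names: tuple[str, ...]) -> frozenset[tuple[str, int, int]]:
    out = set()
    for n in names:
        sp = parse_lipid_name(n)
        out.add((sp.head_group, sp.carbons, sp.double_bonds))
    return frozenset(out)


@dataclass(frozen=True)
class TaggingPolicy:
    """Rules deciding the subclass tags of a species.

    The defaults mark short saturated/monounsaturated TGs as DNL markers
    (head group TG, carbons <= ``dnl_max_carbons``, double bonds <=
    ``dnl_max_double_bonds``, or membership in ``dnl_explicit``) and
    high-double-bond species as PUFA-containing (``pufa_min_db_tg`` for TGs,
    ``pufa_min_db_phospholipid`` for glycerophospholipids and any other
    head group).
    """

    dnl_max_carbons: int = 50
    dnl_max_double_bonds: int = 1
    dnl_explicit: tuple[str, ...] = (
        "TG(44:0)",
        "TG(46:0)",
        "TG(48:0)",
        "TG(48:1)",
        "TG(50:0)",
        "TG(50:1)",
    )
    pufa_min_db_tg: int = 6
    pufa_min_db_phospholipid: int = 4

    def is_dnl_marker(self, sp: LipidSpecies) -> bool:
        if sp.head_group != "TG":
            return False
        if (
            sp.carbons <= self.dnl_max_carbons
            and sp.double_bonds <= self.dnl_max_double_bonds
        ):
            return True
        key = (sp.head_group, sp.carbons, sp.double_bonds)
        return key in _parse_marker_list(self.dnl_explicit)

    def is_pufa(self, sp: LipidSpecies) -> bool:
        if sp.head_group == "TG":
            return sp.double_bonds >= self.pufa_min_db_tg
        return sp.double_bonds >= self.pufa_min_db_phospholipid


DEFAULT_POLICY = TaggingPolicy()


def tag_species(sp: LipidSpecies, policy: TaggingPolicy = DEFAULT_POLICY) -> LipidSpecies:
    """Return a copy of ``sp`` with tags populated under ``policy``.

    Tags are a pure function of ``(head_group, carbons, double_bonds)`` and
    the policy; re-tagging an already tagged species is idempotent.
    """
    tags: set[str] = set()
    if policy.is_dnl_marker(sp):
        tags.add(DNL_MARKER)
    if policy.is_pufa(sp):
        tags.add(PUFA)
    if not tags:
        tags.add(OTHER)
    return replace(sp, tags=frozenset(tags))
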