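"""Oxford-notation N-glycan labels: parsing, formatting and structural predicates.

Oxford shorthand describes an N-glycan relative to the invariant
trimannosyl-chitobiose core (two GlcNAc, three mannoses):

* a leading ``F`` marks a core fucose (alpha1-6 linked to the inner GlcNAc);
* ``Ax`` gives the number of antennae (GlcNAc branches) on the core;
* ``Fx`` *after* the antenna count gives the number of antennary fucoses;
* ``B`` marks a bisecting GlcNAc on the core beta-mannose;
* ``Gx`` gives the number of beta1-4 linked galactoses, with an optional
  arm qualifier ``(6)``/``(3)`` saying which core-mannose arm carries a
  single galactose (e.g. ``A2(6)BG1``);
* ``S(...)x`` or ``Sx`` gives the number of sialic acids, optionally with
  their linkages (alpha2-3 or alpha2-6) listed positionally, e.g.
  ``S(3,6)2``; a bare ``Sx`` leaves the linkages unspecified;
* ``Mx`` alone denotes a high-mannose glycan with *x* mannoses.

Chromatographic peaks that contain several co-eluting structures are
written as labels joined by ``" + "``; those composite labels are *not*
accepted here (see :mod:`glycoproteomap.traits` for peak annotations).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "GlycanStructure",
    "Clause",
    "StructuralPredicate",
    "GlycanParseError",
    "StructureConsistencyError",
    "PredicateSchemaError",
    "parse_structure",
    "format_structure",
    "matches",
]


class GlycanParseError(ValueError):
    """A label does not conform to the Oxford-notation grammar."""

    def __init__(self, label: str, token: str, message: str):
        self.label = label
        self.token = token
        super().__init__(f"cannot parse {label!r}: {message} (at {token!r})")


class StructureConsistencyError(ValueError):
    """A label parses syntactically but violates structural constraints."""


class PredicateSchemaError(ValueError):
    """A predicate clause references an unknown field or comparator."""


@dataclass(frozen=True)
class GlycanStructure:
    """Structural features of a single N-glycan.

    ``mannoses`` is the core value 3 for complex glycans and the total
    mannose count (>= 5) for high-mannose glycans.  ``sialic_linkages``
    holds one entry per sialic acid: 3, 6, or 0 for unspecified.
    """

    raw_label: str
    family: str  # "complex" | "high_mannose"
    antennae: int = 0
    core_fucose: bool = False
    bisecting_glcnac: bool = False
    antennary_fucoses: int = 0
    galactoses: int = 0
    galactose_arm: str | None = None  # "arm3" | "arm6" | None
    sialic_acids: int = 0
    sialic_linkages: tuple[int, ...] = field(default_factory=tuple)
    mannoses: int = 3

    def __post_init__(self) -> None:
        if self.family not in ("complex", "high_mannose"):
            raise StructureConsistencyError(f"unknown family {self.family!r}")
        if self.family == "high_mannose":
            if (self.antennae or self.galactoses or self.sialic_acids
                    or self.core_fucose or self.bisecting_glcnac
                    or self.antennary_fucoses):
                raise StructureConsistencyError(
                    f"{self.raw_label!r}: high-mannose glycans carry no antennae, "
                    "galactoses, sialic acids or fucoses")
            if self.mannoses < 5:
                raise StructureConsistencyError(
                    f"{self.raw_label!r}: high-mannose requires >= 5 mannoses")
        else:
            if self.mannoses != 3:
                raise StructureConsistencyError(
                    f"{self.raw_label!r}: complex glycans have the trimannosyl core")
            if not (self.sialic_acids <= self.galactoses <= self.antennae):
                raise StructureConsistencyError(
                    f"{self.raw_label!r}: require sialic acids ({self.sialic_acids}) "
                    f"<= galactoses ({self.galactoses}) <= antennae ({self.antennae})")
            if self.antennary_fucoses > self.antennae:
                raise StructureConsistencyError(
                    f"{self.raw_label!r}: antennary fucoses exceed antennae")
        if len(self.sialic_linkages) != self.sialic_acids:
            raise StructureConsistencyError(
                f"{self.raw_label!r}: {self.sialic_acids} sialic acids but "
                f"{len(self.sialic_linkages)} linkage entries")
        for lk in self.sialic_linkages:
            if lk not in (0, 3, 6):
                raise StructureConsistencyError(
                    f"{self.raw_label!r}: sialic linkage must be 3, 6 or 0, got {lk}")
        if self.galactose_arm not in (None, "arm3", "arm6"):
            raise StructureConsistencyError(
                f"{self.raw_label!r}: bad galactose arm {self.galactose_arm!r}")


_HIGH_MANNOSE_RE = re.compile(r"^M(\d+)$")
_COMPLEX_RE = re.compile(
    r"^(?P<core_fuc>F)?"
    r"A(?P<ant>\d)"
    r"(?:\((?P<arm_a>[36])\))?"
    r"(?:F(?P<ant_fuc>\d))?"
    r"(?P<bisect>B)?"
    r"(?:\((?P<arm_b>[36])\))?"
    r"(?:G(?P<gal>\d))?"
    r"(?:S(?:\((?P<links>[36](?:,[36])*)\))?(?P<sia>\d))?$"
)


def parse_structure(label: str) -> GlycanStructure:
    """Parse one Oxford-notation label into a :class:`GlycanStructure`.

    Composite (co-eluting) labels containing ``"+"`` are rejected; split
    them at the peak-annotation level first.

    Raises
    ------
    GlycanParseError
        If the label does not match the grammar.
    StructureConsistencyError
        If counts are syntactically valid but structurally impossible
        (e.g. more sialic acids than galactoses).
    """
    if not isinstance(label, str) or not label.strip():
        raise GlycanParseError(str(label), str(label), "empty label")
    text = label.strip()
    if "+" in text:
        raise GlycanParseError(label, "+", "composite peak label; parse each structure separately")

    m = _HIGH_MANNOSE_RE.match(text)
    if m:
        return GlycanStructure(raw_label=text, family="high_mannose",
                               mannoses=int(m.group(1)))
    if text.startswith("M") or text.startswith("FM"):
        raise GlycanParseError(label, text, "malformed high-mannose label")

    m = _COMPLEX_RE.match(text)
    if m is None:
        # pinpoint the first token that breaks the grammar
        bad = re.search(r"[^A-Z0-9(),]", text)
        token = bad.group(0) if bad else text
        raise GlycanParseError(label, token, "does not match the Oxford-notation grammar")
    if m.group("arm_a") and m.group("arm_b"):
        raise GlycanParseError(label, f"({m.group('arm_b')})", "duplicate galactose-arm qualifier")

    arm_digit = m.group("arm_a") or m.group("arm_b")
    sia = int(m.group("sia")) if m.group("sia") else 0
    if m.group("links"):
        links = tuple(int(t) for t in m.group("links").split(","))
        if len(links) != sia:
            raise StructureConsistencyError(
                f"{label!r}: {sia} sialic acids but linkage list {m.group('links')!r}")
    else:
        links = (0,) * sia  # linkage not resolved chromatographically

    return GlycanStructure(
        raw_label=text,
        family="complex",
        antennae=int(m.group("ant")),
        core_fucose=m.group("core_fuc") is not None,
        bisecting_glcnac=m.group("bisect") is not None,
        antennary_fucoses=int(m.group("ant_fuc")) if m.group("ant_fuc") else 0,
        galactoses=int(m.group("gal")) if m.group("gal") else 0,
        galactose_arm={"3": "arm3", "6": "arm6"}.get(arm_digit) if arm_digit else None,
        sialic_acids=sia,
        sialic_linkages=links,
    )


def format_structure(s: GlycanStructure) -> str:
    """Render a structure back to canonical Oxford notation.

    The arm qualifier is emitted directly after the antenna count
    (``A2(6)BG1``); unspecified sialic linkages render as a bare ``Sx``.
    ``parse_structure(format_structure(s))`` reproduces ``s`` up to the
    stored ``raw_label``.
    """
    if s.family == "high_mannose":
        return f"M{s.mannoses}"
    parts = []
    if s.core_fucose:
        parts.append("F")
    parts.append(f"A{s.antennae}")
    if s.galactose_arm:
        parts.append(f"({s.galactose_arm[-1]})")
    if s.antennary_fucoses:
        parts.append(f"F{s.antennary_fucoses}")
    if s.bisecting_glcnac:
        parts.append("B")
    if s.galactoses:
        parts.append(f"G{s.galactoses}")
    if s.sialic_acids:
        if any(lk != 0 for lk in s.sialic_linkages):
            parts.append("S(" + ",".join(str(lk) for lk in s.sialic_linkages) + ")")
        else:
            parts.append("S")
        parts.append(str(s.sialic_acids))
    return "".join(parts)


# ---------------------------------------------------------------------------
# structural predicates

_COUNT_FIELDS = {"antennae", "antennary_fucoses", "galactoses", "sialic_acids", "mannoses"}
_BOOL_FIELDS = {"core_fucose", "bisecting_glcnac"}
_ENUM_FIELDS = {"family", "galactose_arm"}
_SET_FIELDS = {"sialic_linkages"}
_ALL_FIELDS = _COUNT_FIELDS | _BOOL_FIELDS | _ENUM_FIELDS | _SET_FIELDS

_COMPARATORS = {
    "eq": lambda a, b: a == b,
    "ne": lambda a, b: a != b,
    "ge": lambda a, b: a >= b,
    "le": lambda a, b: a <= b,
    "gt": lambda a, b: a > b,
    "lt": lambda a, b: a < b,
    "contains": lambda a, b: b in a,
}


@dataclass(frozen=True)
class Clause:
    """One field-comparator-value test on a :class:`GlycanStructure`."""

    field: str
    op: str
    value: object

    def __post_init__(self) -> None:
        if self.field not in _ALL_FIELDS:
            raise PredicateSchemaError(f"unknown structure field {self.field!r}")
        if self.op not in _COMPARATORS:
            raise PredicateSchemaError(f"unknown comparator {self.op!r}")
        if self.op == "contains" and self.field not in _SET_FIELDS:
            raise PredicateSchemaError(f"'contains' only applies to {sorted(_SET_FIELDS)}")
        if self.field in _SET_FIELDS and self.op != "contains":
            raise PredicateSchemaError("sialic_linkages supports only 'contains'")

    def holds(self, s: GlycanStructure) -> bool:
        return _COMPARATORS[self.op](getattr(s, self.field), self.value)


@dataclass(frozen=True)
class StructuralPredicate:
    """A conjunction of clauses; the empty conjunction matches everything."""

    clauses: tuple[Clause, ...] = ()

    @classmethod
    def of(cls, **field_eq) -> "StructuralPredicate":
        """Shorthand for a pure-equality predicate: ``of(sialic_acids=3)``."""
        return cls(tuple(Clause(f, "eq", v) for f, v in field_eq.items()))

    def to_json(self) -> list[dict]:
        return [{"field": c.field, "op": c.op, "value": c.value} for c in self.clauses]

    @classmethod
    def from_json(cls, items: list[dict]) -> "StructuralPredicate":
        return cls(tuple(Clause(d["field"], d["op"], d["value"]) for d in items))


def matches(structure: GlycanStructure, predicate: StructuralPredicate) -> bool:
    """True iff every clause of *predicate* holds on *structure*."""
    return all(c.holds(structure) for c in predicate.clauses)
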