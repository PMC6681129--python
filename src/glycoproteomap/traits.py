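"""Glycan peak annotation, peak-area normalization and the 113-trait catalog.

A HILIC-UPLC total-plasma N-glycome run is quantified as 36 chromatographic
peaks (GP1-GP36), each expressed as percent of total integrated area.  On top
of the 36 *primary* traits (one per peak) the catalog defines 77 *derived*
traits: group percentages over structurally defined peak sets (e.g.
"trisialylated structures"), sub-fraction percentages (e.g. "fucosylation of
digalactosylated structures"), per-peak percentages within the neutral
(asialylated) sub-glycome, and ratios of previously defined traits —
113 traits in total (PGP1-PGP113).

Peaks can contain several co-eluting structures; group membership is decided
by each peak's *dominant* (first-listed) structure by default.  The
annotation table ships as editable TSV configuration so an alternative
assignment can be swapped in without touching code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .nomenclature import (
    Clause,
    GlycanStructure,
    StructuralPredicate,
    matches,
    parse_structure,
)

__all__ = [
    "PEAK_IDS",
    "PeakAnnotation",
    "TraitDefinition",
    "TraitCatalog",
    "DegenerateProfileError",
    "load_annotations",
    "normalize_peaks",
    "normalize_table",
    "neutral_subprofile",
    "resolve_peaks",
    "evaluate_trait",
    "derive_all",
    "builtin_catalog",
]

PEAK_IDS = tuple(f"GP{i}" for i in range(1, 37))

NEUTRAL = StructuralPredicate.of(sialic_acids=0)

CATALOG_SCHEMA_VERSION = 1


class DegenerateProfileError(ValueError):
    """A profile (or sub-profile denominator) sums to zero."""


@dataclass(frozen=True)
class PeakAnnotation:
    """One chromatographic peak with its co-eluting structures."""

    peak_id: str
    structures: tuple[GlycanStructure, ...]
    dominant_index: int = 0

    @property
    def dominant(self) -> GlycanStructure:
        return self.structures[self.dominant_index]


def load_annotations(path: str | Path | None = None) -> dict[str, PeakAnnotation]:
    """Load a peak-annotation table (TSV: peak_id, structure_labels, dominant_index).

    With no *path*, the shipped 36-peak plasma N-glycome assignment is used.
    """
    if path is None:
        src = resources.files("glycoproteomap") / "data" / "peak_annotation.tsv"
        df = pd.read_csv(src.open(), sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, PeakAnnotation] = {}
    for row in df.itertuples(index=False):
        if row.peak_id in out:
            raise ValueError(f"duplicate peak id {row.peak_id!r}")
        structures = tuple(parse_structure(tok) for tok in row.structure_labels.split(" + "))
        dom = int(row.dominant_index)
        if not structures or not (0 <= dom < len(structures)):
            raise ValueError(f"{row.peak_id}: bad dominant index {dom}")
        out[row.peak_id] = PeakAnnotation(row.peak_id, structures, dom)
    return out


# ---------------------------------------------------------------------------
# profile normalization

def normalize_peaks(raw_areas) -> pd.Series:
    """Express raw peak areas as percent of total integrated area.

    *raw_areas* is a mapping or Series over all 36 peak ids.  Returns a
    Series over :data:`PEAK_IDS` summing to 100.
    """
    s = pd.Series(raw_areas, dtype=float)
    missing = [p for p in PEAK_IDS if p not in s.index]
    if missing:
        raise KeyError(f"missing peak areas for {missing}")
    s = s.reindex(PEAK_IDS)
    if (s < 0).any():
        bad = s.index[s < 0].tolist()
        raise ValueError(f"negative peak areas for {bad}")
    total = s.sum()
    if not total > 0:
        raise DegenerateProfileError("all peak areas are zero")
    return 100.0 * s / total


def normalize_table(raw: pd.DataFrame) -> pd.DataFrame:
    """Row-wise :func:`normalize_peaks` for a samples x peaks table."""
    missing = [p for p in PEAK_IDS if p not in raw.columns]
    if missing:
        raise KeyError(f"missing peak columns {missing}")
    x = raw[list(PEAK_IDS)].astype(float)
    if (x < 0).any().any():
        raise ValueError("negative peak areas")
    totals = x.sum(axis=1)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise DegenerateProfileError(f"all-zero profiles for samples {bad}")
    return x.div(totals, axis=0) * 100.0


def neutral_subprofile(profile: pd.Series,
                       annotations: dict[str, PeakAnnotation],
                       policy: str = "dominant") -> pd.Series:
    """Percentages over the neutral (asialylated) peak subset, summing to 100."""
    neutral_peaks = resolve_peaks(NEUTRAL, annotations, policy)
    sub = profile.reindex(neutral_peaks).astype(float)
    total = sub.sum()
    if not total > 0:
        raise DegenerateProfileError("neutral peak subset sums to zero")
    return 100.0 * sub / total


# ---------------------------------------------------------------------------
# trait definitions

@dataclass(frozen=True)
class TraitDefinition:
    """Declarative recipe for one glycan trait.

    kind:
      * ``primary``             — one peak's percent of total area
      * ``group_percent``       — sum of matching peak percents (of total)
      * ``subfraction_percent`` — 100 x numerator-sum / denominator-sum
      * ``ratio``               — value of one trait divided by another

    ``numerator``/``denominator`` are either a :class:`StructuralPredicate`
    (peaks selected by structure) or an explicit tuple of peak ids;
    ``denominator`` may also be the sentinel string ``"total"``.  Ratio
    traits instead reference two earlier trait ids.
    """

    trait_id: str
    name: str
    kind: str
    numerator: StructuralPredicate | tuple[str, ...] | None = None
    denominator: StructuralPredicate | tuple[str, ...] | str = "total"
    numerator_trait: str | None = None
    denominator_trait: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("primary", "group_percent", "subfraction_percent", "ratio"):
            raise ValueError(f"{self.trait_id}: unknown kind {self.kind!r}")
        if self.kind == "ratio":
            if not (self.numerator_trait and self.denominator_trait):
                raise ValueError(f"{self.trait_id}: ratio needs two trait ids")
        elif self.numerator is None:
            raise ValueError(f"{self.trait_id}: numerator required")
        if self.kind == "primary" and (not isinstance(self.numerator, tuple)
                                       or len(self.numerator) != 1
                                       or self.denominator != "total"):
            raise ValueError(f"{self.trait_id}: primary traits are one peak over total")


@dataclass(frozen=True)
class TraitCatalog:
    """Ordered collection of trait definitions with uniqueness guarantees."""

    traits: tuple[TraitDefinition, ...]

    def __post_init__(self) -> None:
        ids = [t.trait_id for t in self.traits]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate trait ids in catalog")
        seen: set[str] = set()
        for t in self.traits:
            if t.kind == "ratio":
                for ref in (t.numerator_trait, t.denominator_trait):
                    if ref not in seen:
                        raise ValueError(f"{t.trait_id}: ratio references undefined trait {ref!r}")
            seen.add(t.trait_id)

    def __len__(self) -> int:
        return len(self.traits)

    def __getitem__(self, trait_id: str) -> TraitDefinition:
        for t in self.traits:
            if t.trait_id == trait_id:
                return t
        raise KeyError(trait_id)

    @property
    def trait_ids(self) -> list[str]:
        return [t.trait_id for t in self.traits]

    def counts_by_kind(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for t in self.traits:
            out[t.kind] = out.get(t.kind, 0) + 1
        return out

    @property
    def n_primary(self) -> int:
        return self.counts_by_kind().get("primary", 0)

    @property
    def n_derived(self) -> int:
        return len(self) - self.n_primary

    # -- JSON (de)serialization -------------------------------------------
    def to_json(self) -> dict:
        def enc(side):
            if side is None or isinstance(side, str):
                return side
            if isinstance(side, tuple):
                return {"peaks": list(side)}
            return {"predicate": side.to_json()}

        return {
            "schema_version": CATALOG_SCHEMA_VERSION,
            "traits": [
                {
                    "trait_id": t.trait_id, "name": t.name, "kind": t.kind,
                    "numerator": enc(t.numerator), "denominator": enc(t.denominator),
                    "numerator_trait": t.numerator_trait,
                    "denominator_trait": t.denominator_trait,
                }
                for t in self.traits
            ],
        }

    @classmethod
    def from_json(cls, obj: dict) -> "TraitCatalog":
        if obj.get("schema_version") != CATALOG_SCHEMA_VERSION:
            raise ValueError(f"unsupported catalog schema {obj.get('schema_version')!r}")

        def dec(side):
            if side is None or isinstance(side, str):
                return side
            if "peaks" in side:
                return tuple(side["peaks"])
            return StructuralPredicate.from_json(side["predicate"])

        return cls(tuple(
            TraitDefinition(
                trait_id=d["trait_id"], name=d["name"], kind=d["kind"],
                numerator=dec(d["numerator"]), denominator=dec(d["denominator"]),
                numerator_trait=d.get("numerator_trait"),
                denominator_trait=d.get("denominator_trait"),
            )
            for d in obj["traits"]
        ))

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "TraitCatalog":
        return cls.from_json(json.loads(Path(path).read_text()))


def resolve_peaks(selector, annotations: dict[str, PeakAnnotation],
                  policy: str = "dominant") -> list[str]:
    """Peak ids selected by a predicate or explicit peak tuple.

    ``policy="dominant"`` tests each peak's dominant structure only;
    ``policy="any"`` admits a peak if any co-eluting structure matches.
    """
    if isinstance(selector, tuple):
        unknown = [p for p in selector if p not in annotations]
        if unknown:
            raise KeyError(f"unknown peak ids {unknown}")
        return list(selector)
    if not isinstance(selector, StructuralPredicate):
        raise TypeError(f"bad peak selector {selector!r}")
    if policy not in ("dominant", "any"):
        raise ValueError(f"unknown policy {policy!r}")
    out = []
    for pid, ann in annotations.items():
        if policy == "dominant":
            hit = matches(ann.dominant, selector)
        else:
            hit = any(matches(s, selector) for s in ann.structures)
        if hit:
            out.append(pid)
    return out


def evaluate_trait(defn: TraitDefinition, profile: pd.Series,
                   annotations: dict[str, PeakAnnotation],
                   catalog: "TraitCatalog | None" = None,
                   policy: str = "dominant") -> float:
    """Evaluate one trait on a single normalized profile.

    Zero denominators yield ``nan`` (a missing trait value), never an
    exception; downstream association drops missing values pairwise.
    Ratio traits require *catalog* to resolve their component traits.
    """
    if defn.kind == "ratio":
        if catalog is None:
            raise ValueError(f"{defn.trait_id}: ratio evaluation needs the catalog")
        num = evaluate_trait(catalog[defn.numerator_trait], profile, annotations, catalog, policy)
        den = evaluate_trait(catalog[defn.denominator_trait], profile, annotations, catalog, policy)
        return float(num / den) if den and not np.isnan(den) and den != 0 else float("nan")

    num_peaks = resolve_peaks(defn.numerator, annotations, policy)
    num = profile.reindex(num_peaks).sum(skipna=False) if num_peaks else 0.0
    if defn.kind in ("primary", "group_percent"):
        return float(num)
    # subfraction_percent
    if defn.denominator == "total":
        den_peaks = list(annotations)
    else:
        den_peaks = resolve_peaks(defn.denominator, annotations, policy)
    den = profile.reindex(den_peaks).sum(skipna=False) if den_peaks else 0.0
    if np.isnan(den) or den == 0:
        return float("nan")
    return float(100.0 * num / den)


def derive_all(profiles: pd.DataFrame, catalog: TraitCatalog,
               annotations: dict[str, PeakAnnotation],
               policy: str = "dominant") -> pd.DataFrame:
    """Evaluate the whole catalog on a samples x peaks percent table.

    Returns a samples x traits DataFrame (one column per catalog trait, in
    catalog order).  Missing peak percentages propagate to every trait that
    reads them; zero denominators yield missing values.
    """
    if profiles.shape[0] == 0:
        raise ValueError("empty profile set")
    cols: dict[str, pd.Series] = {}
    for defn in catalog.traits:
        if defn.kind == "ratio":
            num = cols[defn.numerator_trait]
            den = cols[defn.denominator_trait]
            with np.errstate(divide="ignore", invalid="ignore"):
                val = num / den.where(den != 0)
            cols[defn.trait_id] = val
            continue
        num_peaks = resolve_peaks(defn.numerator, annotations, policy)
        num = profiles[num_peaks].sum(axis=1, skipna=False) if num_peaks \
            else pd.Series(0.0, index=profiles.index)
        if defn.kind in ("primary", "group_percent"):
            cols[defn.trait_id] = num.astype(float)
            continue
        den_peaks = list(annotations) if defn.denominator == "total" \
            else resolve_peaks(defn.denominator, annotations, policy)
        den = profiles[den_peaks].sum(axis=1, skipna=False) if den_peaks \
            else pd.Series(0.0, index=profiles.index)
        cols[defn.trait_id] = 100.0 * num / den.where(den != 0)
    return pd.DataFrame(cols, index=profiles.index)


# ---------------------------------------------------------------------------
# the shipped 113-trait catalog

def _pred(*clauses: Clause, **eq) -> StructuralPredicate:
    return StructuralPredicate(tuple(clauses) + tuple(Clause(f, "eq", v) for f, v in eq.items()))


def _ge(fieldname: str, v: int) -> Clause:
    return Clause(fieldname, "ge", v)


def builtin_catalog() -> TraitCatalog:
    """The shipped total-plasma N-glycome trait catalog.

    36 primary traits (PGP1-PGP36, one per peak GP1-GP36) plus 77 derived
    traits (PGP37-PGP113): sialylation sub-fractions of the core-fucosylated
    digalactosylated family, fucosylated mono-/disialylated groups and their
    ratios, the 12 neutral-subglycome peak percentages (GPn), neutral
    sub-fractions, total-glycome sub-fractions, group percentages by
    fucosylation, sialylation degree, galactosylation degree, antennarity,
    bisection and sialic-linkage type, and ratio traits.
    """
    F = _pred(core_fucose=True)
    defs: list[TraitDefinition] = []

    def primary(i: int) -> None:
        pid = f"GP{i}"
        defs.append(TraitDefinition(f"PGP{i}", f"{pid} (% of total glycans)",
                                    "primary", numerator=(pid,)))

    def grp(i: int, name: str, pred: StructuralPredicate) -> None:
        defs.append(TraitDefinition(f"PGP{i}", name, "group_percent", numerator=pred))

    def sub(i: int, name: str, num, den) -> None:
        defs.append(TraitDefinition(f"PGP{i}", name, "subfraction_percent",
                                    numerator=num, denominator=den))

    def rat(i: int, name: str, num_id: int, den_id: int) -> None:
        defs.append(TraitDefinition(f"PGP{i}", name, "ratio",
                                    numerator_trait=f"PGP{num_id}",
                                    denominator_trait=f"PGP{den_id}"))

    for i in range(1, 37):
        primary(i)

    # core-fucosylated digalactosylated family: sialylation sub-fractions
    fg2 = _pred(core_fucose=True, galactoses=2)
    fg2_nb = _pred(core_fucose=True, galactoses=2, bisecting_glcnac=False)
    fg2_b = _pred(core_fucose=True, galactoses=2, bisecting_glcnac=True)

    def with_s(base: StructuralPredicate, s: int) -> StructuralPredicate:
        return StructuralPredicate(base.clauses + (Clause("sialic_acids", "eq", s),))

    sub(37, "asialylated fraction of core-fucosylated digalactosylated structures "
            "without bisecting GlcNAc", with_s(fg2_nb, 0), fg2_nb)
    sub(38, "disialylation of core-fucosylated digalactosylated structures "
            "without bisecting GlcNAc", with_s(fg2_nb, 2), fg2_nb)
    sub(39, "asialylated fraction of core-fucosylated digalactosylated structures "
            "with bisecting GlcNAc", with_s(fg2_b, 0), fg2_b)
    sub(40, "disialylation of core-fucosylated digalactosylated structures "
            "with bisecting GlcNAc", with_s(fg2_b, 2), fg2_b)
    sub(41, "monosialylation of core-fucosylated digalactosylated structures",
        with_s(fg2, 1), fg2)
    sub(42, "monosialylation of core-fucosylated digalactosylated structures "
            "without bisecting GlcNAc", with_s(fg2_nb, 1), fg2_nb)
    sub(43, "disialylation of core-fucosylated digalactosylated structures",
        with_s(fg2, 2), fg2)
    sub(44, "monosialylation of core-fucosylated digalactosylated structures "
            "with bisecting GlcNAc", with_s(fg2_b, 1), fg2_b)

    # fucosylated mono-/disialylated groups, bisection splits and ratios
    grp(45, "fucosylated monosialylated structures without bisecting GlcNAc",
        _pred(core_fucose=True, sialic_acids=1, bisecting_glcnac=False))
    grp(46, "fucosylated monosialylated structures with bisecting GlcNAc",
        _pred(core_fucose=True, sialic_acids=1, bisecting_glcnac=True))
    grp(47, "fucosylated disialylated structures with bisecting GlcNAc",
        _pred(core_fucose=True, sialic_acids=2, bisecting_glcnac=True))
    rat(48, "ratio of fucosylated monosialylated and disialylated structures "
            "(with bisecting GlcNAc)", 46, 47)
    grp(49, "fucosylated disialylated structures without bisecting GlcNAc",
        _pred(core_fucose=True, sialic_acids=2, bisecting_glcnac=False))
    rat(50, "ratio of fucosylated monosialylated and disialylated structures "
            "(without bisecting GlcNAc)", 45, 49)
    grp(51, "fucosylated monosialylated structures",
        _pred(core_fucose=True, sialic_acids=1))
    grp(52, "fucosylated disialylated structures",
        _pred(core_fucose=True, sialic_acids=2))
    rat(53, "ratio of fucosylated monosialylated and disialylated structures", 51, 52)
    rat(54, "ratio of fucosylated monosialylated structures with and without "
            "bisecting GlcNAc", 46, 45)
    sub(55, "the incidence of bisecting GlcNAc in all fucosylated monosialylated "
            "structures", _pred(core_fucose=True, sialic_acids=1, bisecting_glcnac=True),
        _pred(core_fucose=True, sialic_acids=1))
    sub(56, "the incidence of bisecting GlcNAc in all fucosylated disialylated "
            "structures", _pred(core_fucose=True, sialic_acids=2, bisecting_glcnac=True),
        _pred(core_fucose=True, sialic_acids=2))
    rat(57, "ratio of fucosylated disialylated structures with and without "
            "bisecting GlcNAc", 47, 49)

    # per-peak percentages within the neutral sub-glycome (GPn)
    neutral_peaks = ("GP1", "GP2", "GP3", "GP4", "GP5", "GP6", "GP7", "GP8",
                     "GP9", "GP10", "GP11", "GP18")
    for k, pid in enumerate(neutral_peaks):
        label = {"GP5": "M5", "GP7": "M6", "GP8": "A2G2", "GP18": "M9"}.get(pid, None)
        name = f"{label or pid} in total neutral plasma glycans (GPn)"
        sub(58 + k, name, (pid,), NEUTRAL)

    # neutral sub-glycome derived traits
    sub(70, "agalactosylated structures in total neutral plasma glycans",
        _pred(family="complex", galactoses=0, sialic_acids=0), NEUTRAL)
    sub(71, "monogalactosylated structures in total neutral plasma glycans",
        _pred(galactoses=1, sialic_acids=0), NEUTRAL)
    sub(72, "digalactosylated structures in total neutral plasma glycans",
        _pred(galactoses=2, sialic_acids=0), NEUTRAL)
    sub(73, "high-mannose structures in total neutral plasma glycans",
        _pred(family="high_mannose"), NEUTRAL)
    sub(74, "fucosylation of agalactosylated structures in total neutral plasma glycans",
        _pred(family="complex", galactoses=0, sialic_acids=0, core_fucose=True),
        _pred(family="complex", galactoses=0, sialic_acids=0))
    sub(75, "fucosylation of digalactosylated structures in total neutral plasma glycans",
        _pred(galactoses=2, sialic_acids=0, core_fucose=True),
        _pred(galactoses=2, sialic_acids=0))
    sub(76, "the incidence of bisecting GlcNAc in neutral digalactosylated structures",
        _pred(galactoses=2, sialic_acids=0, bisecting_glcnac=True),
        _pred(galactoses=2, sialic_acids=0))
    sub(77, "the incidence of bisecting GlcNAc in neutral complex structures",
        _pred(family="complex", sialic_acids=0, bisecting_glcnac=True),
        _pred(family="complex", sialic_acids=0))
    sub(78, "fucosylation of neutral complex structures",
        _pred(family="complex", sialic_acids=0, core_fucose=True),
        _pred(family="complex", sialic_acids=0))
    rat(79, "ratio of digalactosylated and agalactosylated neutral structures", 72, 70)

    # total-glycome sub-fractions
    g2 = _pred(family="complex", galactoses=2)
    g3 = _pred(family="complex", galactoses=3)
    g4 = _pred(family="complex", galactoses=4)
    sub(80, "monosialylation of digalactosylated structures",
        _pred(family="complex", galactoses=2, sialic_acids=1), g2)
    sub(81, "disialylation of digalactosylated structures",
        _pred(family="complex", galactoses=2, sialic_acids=2), g2)
    sub(82, "trisialylation of trigalactosylated structures",
        _pred(family="complex", galactoses=3, sialic_acids=3), g3)
    sub(83, "trisialylation of tetragalactosylated structures",
        _pred(family="complex", galactoses=4, sialic_acids=3), g4)
    sub(84, "tetrasialylation of tetragalactosylated structures",
        _pred(family="complex", galactoses=4, sialic_acids=4), g4)
    sub(85, "sialylation of core-fucosylated structures",
        _pred(_ge("sialic_acids", 1), core_fucose=True), F)
    sub(86, "the incidence of bisecting GlcNAc in digalactosylated structures",
        _pred(family="complex", galactoses=2, bisecting_glcnac=True), g2)
    sub(87, "the incidence of bisecting GlcNAc in core-fucosylated structures",
        _pred(core_fucose=True, bisecting_glcnac=True), F)
    sub(88, "core-fucosylation of monosialylated structures",
        _pred(sialic_acids=1, core_fucose=True), _pred(sialic_acids=1))
    sub(89, "core-fucosylation of disialylated structures",
        _pred(sialic_acids=2, core_fucose=True), _pred(sialic_acids=2))

    # group percentages of the total glycome
    grp(90, "structures with at least one alpha2-6-linked sialic acid",
        _pred(Clause("sialic_linkages", "contains", 6)))
    grp(91, "structures with at least one alpha2-3-linked sialic acid",
        _pred(Clause("sialic_linkages", "contains", 3)))
    grp(92, "antennary fucosylated structures", _pred(_ge("antennary_fucoses", 1)))
    grp(93, "core fucosylated structures", F)
    grp(94, "neutral (asialylated) structures", NEUTRAL)
    grp(95, "monosialylated structures", _pred(sialic_acids=1))
    grp(96, "disialylated structures", _pred(sialic_acids=2))
    grp(97, "trisialylated structures", _pred(sialic_acids=3))
    grp(98, "tetrasialylated structures", _pred(sialic_acids=4))
    grp(99, "agalactosylated structures", _pred(family="complex", galactoses=0))
    grp(100, "monogalactosylated structures", _pred(family="complex", galactoses=1))
    grp(101, "digalactosylated structures", g2)
    grp(102, "trigalactosylated structures", g3)
    grp(103, "tetragalactosylated structures", g4)
    grp(104, "biantennary structures", _pred(family="complex", antennae=2))
    grp(105, "triantennary structures", _pred(family="complex", antennae=3))
    grp(106, "tetraantennary structures", _pred(family="complex", antennae=4))
    grp(107, "high-mannose structures", _pred(family="high_mannose"))
    grp(108, "glycan structures with bisecting GlcNAc", _pred(bisecting_glcnac=True))

    rat(109, "ratio of trisialylated and tetrasialylated structures", 97, 98)
    rat(110, "ratio of trisialylated and tetrasialylated tetragalactosylated "
             "structures", 83, 84)
    sub(111, "core-fucosylation of digalactosylated structures",
        _pred(family="complex", galactoses=2, core_fucose=True), g2)
    sub(112, "antennary-fucosylation of trigalactosylated structures",
        _pred(_ge("antennary_fucoses", 1), family="complex", galactoses=3), g3)
    sub(113, "antennary-fucosylation of tetragalactosylated structures",
        _pred(_ge("antennary_fucoses", 1), family="complex", galactoses=4), g4)

    assert len(defs) == 113, len(defs)
    return TraitCatalog(tuple(defs))
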