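"""Organism network data model (PGDB-like) and its on-disk dialects.

The in-memory container is :class:`PGDB`: a keyed collection of compounds,
reactions, pathways, proteins, RNAs and genes, mirroring the frame-oriented
organization of a Pathway/Genome Database.  Every object carries a unique
``frame_id`` (a database key, matched case-sensitively) plus a human display
name and synonyms (matched case-insensitively by the search layer).

Two input dialects are supported:

* the native ``cellmap-network/1`` YAML schema (see ``docs/formats.md``),
  which is the canonical round-trippable representation; and
* SBML Level 2/3 import (species -> compounds, reactions -> reactions),
  with pathway grouping supplied either through the SBML Groups package or
  a two-column tab-delimited sidecar file.

A PGDB carries a ``version_stamp``, a content hash over the canonicalized
entity set.  The stamp is invariant under reordering of records in the
input file and changes exactly when content changes; the tile cache keys
on it.
"""

from __future__ import annotations

import hashlib
import json
from enum import Enum
from pathlib import Path
from typing import Iterator, Optional, Union

import yaml
from pydantic import BaseModel, Field, field_validator

SCHEMA_TAG = "cellmap-network/1"


class Kind(str, Enum):
    compound = "compound"
    reaction = "reaction"
    pathway = "pathway"
    protein = "protein"
    rna = "rna"
    gene = "gene"


class Compartment(str, Enum):
    cytosol = "cytosol"
    periplasm = "periplasm"
    inner_membrane = "inner_membrane"
    outer_membrane = "outer_membrane"
    extracellular = "extracellular"


class PathwayCategory(str, Enum):
    central = "central"
    catabolic = "catabolic"
    anabolic_intermediary = "anabolic_intermediary"
    signal = "signal"
    other = "other"


class SchemaError(ValueError):
    """Input file violates the native schema; names field and record."""


class DanglingReferenceError(ValueError):
    """One or more referenced frame_ids do not resolve."""

    def __init__(self, unresolved: list[str]):
        self.unresolved = sorted(set(unresolved))
        super().__init__(
            "unresolved frame_ids: " + ", ".join(self.unresolved)
        )


class Entity(BaseModel):
    frame_id: str
    name: str
    synonyms: list[str] = Field(default_factory=list)

    @field_validator("name")
    @classmethod
    def _name_nonempty(cls, v: str) -> str:
        if not v:
            raise ValueError("name must be non-empty")
        return v

    @property
    def kind(self) -> Kind:  # pragma: no cover - overridden
        raise NotImplementedError


class Compound(Entity):
    formula: Optional[str] = None

    @property
    def kind(self) -> Kind:
        return Kind.compound


class Participant(BaseModel):
    """A (compound, stoichiometric coefficient) pair on one reaction side."""

    compound: str
    coefficient: float = 1.0

    @field_validator("coefficient")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("stoichiometric coefficient must be > 0")
        return v


class Reaction(Entity):
    substrates: list[Participant] = Field(default_factory=list)
    products: list[Participant] = Field(default_factory=list)
    ec_numbers: list[str] = Field(default_factory=list)
    enzymes: list[str] = Field(default_factory=list)
    compartment: Compartment = Compartment.cytosol
    pathways: list[str] = Field(default_factory=list)

    @property
    def kind(self) -> Kind:
        return Kind.reaction


class Protein(Entity):
    is_enzyme: bool = False
    is_transporter: bool = False
    genes: list[str] = Field(default_factory=list)

    @property
    def kind(self) -> Kind:
        return Kind.protein


class Rna(Entity):
    genes: list[str] = Field(default_factory=list)

    @property
    def kind(self) -> Kind:
        return Kind.rna


class Gene(Entity):
    products: list[str] = Field(default_factory=list)

    @property
    def kind(self) -> Kind:
        return Kind.gene


class Pathway(Entity):
    reactions: list[str] = Field(default_factory=list)
    category: PathwayCategory = PathwayCategory.other
    cluster: Optional[str] = None

    @property
    def kind(self) -> Kind:
        return Kind.pathway


AnyEntity = Union[Compound, Reaction, Protein, Rna, Gene, Pathway]


class ValidationEntry(BaseModel):
    level: str  # "error" | "warning"
    code: str
    frame_id: str
    message: str


class ValidationReport(BaseModel):
    entries: list[ValidationEntry] = Field(default_factory=list)

    @property
    def errors(self) -> list[ValidationEntry]:
        return [e for e in self.entries if e.level == "error"]

    @property
    def warnings(self) -> list[ValidationEntry]:
        return [e for e in self.entries if e.level == "warning"]

    def is_clean(self) -> bool:
        return not self.entries

    def add(self, level: str, code: str, frame_id: str, message: str) -> None:
        self.entries.append(
            ValidationEntry(level=level, code=code, frame_id=frame_id, message=message)
        )


class PGDB(BaseModel):
    """An organism's network: keyed entity collections + content stamp."""

    organism_id: str
    compounds: dict[str, Compound] = Field(default_factory=dict)
    reactions: dict[str, Reaction] = Field(default_factory=dict)
    pathways: dict[str, Pathway] = Field(default_factory=dict)
    proteins: dict[str, Protein] = Field(default_factory=dict)
    rnas: dict[str, Rna] = Field(default_factory=dict)
    genes: dict[str, Gene] = Field(default_factory=dict)

    # -- collection helpers -------------------------------------------------

    def _collections(self) -> dict[Kind, dict]:
        return {
            Kind.compound: self.compounds,
            Kind.reaction: self.reactions,
            Kind.pathway: self.pathways,
            Kind.protein: self.proteins,
            Kind.rna: self.rnas,
            Kind.gene: self.genes,
        }

    def entities(self) -> Iterator[AnyEntity]:
        for coll in self._collections().values():
            yield from coll.values()

    def get(self, frame_id: str) -> Optional[AnyEntity]:
        for coll in self._collections().values():
            if frame_id in coll:
                return coll[frame_id]
        return None

    def __contains__(self, frame_id: str) -> bool:
        return self.get(frame_id) is not None

    def add(self, entity: AnyEntity) -> None:
        coll = self._collections()[entity.kind]
        if entity.frame_id in self.frame_ids():
            raise SchemaError(f"duplicate frame_id {entity.frame_id!r}")
        coll[entity.frame_id] = entity

    def frame_ids(self) -> set[str]:
        ids: set[str] = set()
        for coll in self._collections().values():
            ids.update(coll)
        return ids

    def n_entities(self) -> int:
        return sum(len(c) for c in self._collections().values())

    # -- version stamp ------------------------------------------------------

    def canonical_dict(self) -> dict:
        """Content in canonical form: entities sorted by frame_id, sorted keys."""
        out: dict = {"schema": SCHEMA_TAG, "organism": self.organism_id}
        for kind, coll in self._collections().items():
            out[kind.value + "s"] = [
                coll[fid].model_dump(mode="json") for fid in sorted(coll)
            ]
        return out

    @property
    def version_stamp(self) -> str:
        blob = json.dumps(self.canonical_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    # -- referential integrity ----------------------------------------------

    def unresolved_references(self) -> list[str]:
        known = self.frame_ids()
        missing: list[str] = []

        def check(ids: list[str]) -> None:
            missing.extend(i for i in ids if i not in known)

        for rxn in self.reactions.values():
            check([p.compound for p in rxn.substrates])
            check([p.compound for p in rxn.products])
            check(rxn.enzymes)
            check(rxn.pathways)
        for pwy in self.pathways.values():
            check(pwy.reactions)
        for prot in self.proteins.values():
            check(prot.genes)
        for rna in self.rnas.values():
            check(rna.genes)
        for gene in self.genes.values():
            check(gene.products)
        return sorted(set(missing))


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate(pgdb: PGDB) -> ValidationReport:
    """Report every invariant violation; empty report iff internally consistent.

    Errors: dangling references, pathways with no reactions, coefficients
    are already rejected at construction.  Warnings: transporters none of
    whose reactions touch a membrane or the periplasm (a transporter should
    mediate transport), enzymes flagged as such but catalyzing nothing.
    """
    report = ValidationReport()
    for fid in pgdb.unresolved_references():
        report.add("error", "dangling-reference", fid, f"frame_id {fid!r} is referenced but not defined")
    for pwy in pgdb.pathways.values():
        if not pwy.reactions:
            report.add("error", "empty-pathway", pwy.frame_id, "pathway has zero reactions")
    # reverse map: protein -> reactions it catalyzes
    catalyzes: dict[str, list[Reaction]] = {}
    for rxn in pgdb.reactions.values():
        for enz in rxn.enzymes:
            catalyzes.setdefault(enz, []).append(rxn)
    transport_compartments = {
        Compartment.inner_membrane,
        Compartment.outer_membrane,
        Compartment.periplasm,
    }
    for prot in pgdb.proteins.values():
        rxns = catalyzes.get(prot.frame_id, [])
        if prot.is_transporter and rxns and not any(
            r.compartment in transport_compartments for r in rxns
        ):
            report.add(
                "warning",
                "cytosolic-transporter",
                prot.frame_id,
                "transporter's reactions are all cytosolic; expected a membrane or periplasmic reaction",
            )
        if prot.is_enzyme and not rxns:
            report.add("warning", "idle-enzyme", prot.frame_id, "enzyme catalyzes no reaction")
    return report


# ---------------------------------------------------------------------------
# Native dialect
# ---------------------------------------------------------------------------

_KIND_SECTIONS: list[tuple[str, type]] = [
    ("compounds", Compound),
    ("proteins", Protein),
    ("rnas", Rna),
    ("genes", Gene),
    ("reactions", Reaction),
    ("pathways", Pathway),
]


def _entity_from_record(cls: type, rec: dict, section: str) -> AnyEntity:
    if not isinstance(rec, dict):
        raise SchemaError(f"{section}: record is not a mapping: {rec!r}")
    rec = dict(rec)
    if "id" in rec:
        rec["frame_id"] = rec.pop("id")
    if "frame_id" not in rec:
        raise SchemaError(f"{section}: record missing 'id': {rec!r}")
    try:
        return cls(**rec)
    except Exception as exc:
        raise SchemaError(
            f"{section}: invalid record {rec.get('frame_id')!r}: {exc}"
        ) from exc


def load_native(path: Union[str, Path]) -> PGDB:
    """Load and validate a ``cellmap-network/1`` YAML file.

    Raises :class:`SchemaError` for structural problems (naming the field
    and record) and :class:`DanglingReferenceError` listing every
    unresolved frame_id.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise SchemaError("top level of a network file must be a mapping")
    tag = doc.get("schema", SCHEMA_TAG)
    if tag != SCHEMA_TAG:
        raise SchemaError(f"unsupported schema tag {tag!r} (expected {SCHEMA_TAG!r})")
    known_keys = {"schema", "organism"} | {s for s, _ in _KIND_SECTIONS}
    unknown = set(doc) - known_keys
    if unknown:
        raise SchemaError(f"unknown top-level keys: {sorted(unknown)}")
    pgdb = PGDB(organism_id=str(doc.get("organism", "UNKNOWN")))
    for section, cls in _KIND_SECTIONS:
        for rec in doc.get(section) or []:
            ent = _entity_from_record(cls, rec, section)
            if ent.frame_id in pgdb.frame_ids():
                raise SchemaError(f"{section}: duplicate frame_id {ent.frame_id!r}")
            pgdb._collections()[ent.kind][ent.frame_id] = ent
    missing = pgdb.unresolved_references()
    if missing:
        raise DanglingReferenceError(missing)
    return pgdb


def save_native(pgdb: PGDB, path: Union[str, Path]) -> None:
    """Write the canonical native YAML representation (stamp-stable)."""
    doc = pgdb.canonical_dict()
    for section, _ in _KIND_SECTIONS:
        recs = doc.get(section, [])
        cleaned = []
        for rec in recs:
            rec = {k: v for k, v in rec.items() if v not in (None, [], {})}
            rec["id"] = rec.pop("frame_id")
            cleaned.append(rec)
        doc[section] = cleaned
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True, default_flow_style=False)


# ---------------------------------------------------------------------------
# SBML import / export
# ---------------------------------------------------------------------------

#: default mapping from common SBML compartment ids/names to our vocabulary
DEFAULT_COMPARTMENT_MAP = {
    "c": Compartment.cytosol,
    "cytosol": Compartment.cytosol,
    "cytoplasm": Compartment.cytosol,
    "p": Compartment.periplasm,
    "periplasm": Compartment.periplasm,
    "e": Compartment.extracellular,
    "extracellular": Compartment.extracellular,
    "im": Compartment.inner_membrane,
    "inner_membrane": Compartment.inner_membrane,
    "om": Compartment.outer_membrane,
    "outer_membrane": Compartment.outer_membrane,
}


class CompartmentMappingError(ValueError):
    pass


def _read_sidecar(path: Union[str, Path]) -> dict[str, list[str]]:
    """Two-column tab-delimited: reaction_id <TAB> pathway_id."""
    groups: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise SchemaError(f"sidecar line {lineno}: expected 2 tab-separated columns")
        rxn, pwy = parts
        groups.setdefault(rxn, []).append(pwy)
    return groups


def load_sbml(
    path: Union[str, Path],
    grouping: Optional[Union[str, Path]] = None,
    compartment_map: Optional[dict[str, Compartment]] = None,
    default_compartment: Optional[Compartment] = None,
) -> PGDB:
    """Import an SBML Level 2/3 model.

    Species become compounds, reactions become reactions.  SBML compartment
    ids/names are mapped onto the five-compartment vocabulary via
    ``compartment_map`` (merged over :data:`DEFAULT_COMPARTMENT_MAP`); an
    unmappable compartment raises unless ``default_compartment`` is given.
    Pathway membership comes from the SBML Groups package if present, else
    from the ``grouping`` sidecar; reactions in no group stay unassigned.
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise SchemaError(f"SBML parse error: {err.getMessage() if err else 'unreadable document'}")
    model = doc.getModel()
    if model is None:
        raise SchemaError("SBML document contains no model")

    cmap = dict(DEFAULT_COMPARTMENT_MAP)
    if compartment_map:
        cmap.update(compartment_map)

    def map_compartment(comp_id: str) -> Compartment:
        comp = model.getCompartment(comp_id)
        for key in (comp_id, comp.getName() if comp else ""):
            if key and key.lower() in cmap:
                return cmap[key.lower()]
        if default_compartment is not None:
            return default_compartment
        raise CompartmentMappingError(
            f"SBML compartment {comp_id!r} has no mapping to "
            "{cytosol, periplasm, inner_membrane, outer_membrane, extracellular}"
        )

    pgdb = PGDB(organism_id=model.getId() or model.getName() or "SBML")
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        pgdb.compounds[sp.getId()] = Compound(
            frame_id=sp.getId(), name=sp.getName() or sp.getId()
        )

    group_of: dict[str, list[str]] = {}
    gplug = model.getPlugin("groups")
    if gplug is not None:
        for gi in range(gplug.getNumGroups()):
            grp = gplug.getGroup(gi)
            pwy_id = grp.getId() or f"GROUP-{gi}"
            for mi in range(grp.getNumMembers()):
                ref = grp.getMember(mi).getIdRef()
                group_of.setdefault(ref, []).append(pwy_id)
    if grouping is not None:
        for rxn_id, pwys in _read_sidecar(grouping).items():
            group_of.setdefault(rxn_id, []).extend(pwys)

    for i in range(model.getNumReactions()):
        rx = model.getReaction(i)
        subs = [
            Participant(
                compound=rx.getReactant(j).getSpecies(),
                coefficient=rx.getReactant(j).getStoichiometry() or 1.0,
            )
            for j in range(rx.getNumReactants())
        ]
        prods = [
            Participant(
                compound=rx.getProduct(j).getSpecies(),
                coefficient=rx.getProduct(j).getStoichiometry() or 1.0,
            )
            for j in range(rx.getNumProducts())
        ]
        comp_id = rx.getCompartment()
        if not comp_id and subs:
            sp = model.getSpecies(subs[0].compound)
            comp_id = sp.getCompartment() if sp else ""
        compartment = map_compartment(comp_id) if comp_id else Compartment.cytosol
        if compartment == Compartment.extracellular:
            compartment = Compartment.outer_membrane  # drawn at the cell boundary
        pgdb.reactions[rx.getId()] = Reaction(
            frame_id=rx.getId(),
            name=rx.getName() or rx.getId(),
            substrates=subs,
            products=prods,
            compartment=compartment,
            pathways=sorted(set(group_of.get(rx.getId(), []))),
        )

    # materialize pathway frames referenced by groups/sidecar
    for pwys in group_of.values():
        for pwy_id in pwys:
            if pwy_id not in pgdb.pathways:
                pgdb.pathways[pwy_id] = Pathway(
                    frame_id=pwy_id, name=pwy_id, reactions=[]
                )
    for rxn in pgdb.reactions.values():
        for pwy_id in rxn.pathways:
            if rxn.frame_id not in pgdb.pathways[pwy_id].reactions:
                pgdb.pathways[pwy_id].reactions.append(rxn.frame_id)
    missing = pgdb.unresolved_references()
    if missing:
        raise DanglingReferenceError(missing)
    return pgdb


def save_sbml(pgdb: PGDB, path: Union[str, Path]) -> None:
    """Export compounds/reactions (and pathway grouping) to SBML Level 3."""
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1)
    ns.addPackageNamespace("groups", 1)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("groups", False)
    model = doc.createModel()
    model.setId(_sbml_safe(pgdb.organism_id))
    seen_comps: set[str] = set()
    for rxn in pgdb.reactions.values():
        seen_comps.add(rxn.compartment.value)
    if not seen_comps:
        seen_comps.add(Compartment.cytosol.value)
    for cid in sorted(seen_comps):
        comp = model.createCompartment()
        comp.setId(cid)
        comp.setConstant(True)
    for fid in sorted(pgdb.compounds):
        cpd = pgdb.compounds[fid]
        sp = model.createSpecies()
        sp.setId(_sbml_safe(fid))
        sp.setName(cpd.name)
        sp.setCompartment(sorted(seen_comps)[0])
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
    for fid in sorted(pgdb.reactions):
        rxn = pgdb.reactions[fid]
        rx = model.createReaction()
        rx.setId(_sbml_safe(fid))
        rx.setName(rxn.name)
        rx.setReversible(False)
        rx.setFast(False)
        rx.setCompartment(rxn.compartment.value)
        for part in rxn.substrates:
            sr = rx.createReactant()
            sr.setSpecies(_sbml_safe(part.compound))
            sr.setStoichiometry(part.coefficient)
            sr.setConstant(True)
        for part in rxn.products:
            sr = rx.createProduct()
            sr.setSpecies(_sbml_safe(part.compound))
            sr.setStoichiometry(part.coefficient)
            sr.setConstant(True)
    mplug = model.getPlugin("groups")
    if mplug is not None:
        for pwy_id in sorted(pgdb.pathways):
            pwy = pgdb.pathways[pwy_id]
            grp = mplug.createGroup()
            grp.setId(_sbml_safe(pwy_id))
            grp.setKind("partonomy")
            for rxn_id in pwy.reactions:
                mem = grp.createMember()
                mem.setIdRef(_sbml_safe(rxn_id))
    libsbml.writeSBMLToFile(doc, str(path))


def _sbml_safe(fid: str) -> str:
    """SBML SIds allow only [a-zA-Z0-9_] and must not start with a digit."""
    safe = "".join(c if c.isalnum() or c == "_" else "_" for c in fid)
    if safe and safe[0].isdigit():
        safe = "_" + safe
    return safe
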