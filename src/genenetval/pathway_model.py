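"""Data model for KEGG metabolic pathways and a KGML reader/writer.

Only the parts of KGML needed to build gene association networks are
modeled: ``entry`` elements (genes, compounds, groups, map links),
``relation`` elements with their subtypes, and ``reaction`` elements with
substrates and products.  Graphics, coordinates and link attributes are
ignored.

Gene identifiers are normalised to a canonical form: the KEGG organism
prefix (``sce:``, ``hsa:`` ...) is stripped and the remainder uppercased,
so ``sce:ybr160w`` and ``YBR160W`` refer to the same gene.  Inferred
networks read from edge lists are matched on the same canonical form.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

__all__ = [
    "PathwayEntry",
    "PathwayRelation",
    "PathwayReaction",
    "Pathway",
    "KGMLParseError",
    "PathwayValidationError",
    "canonical_gene_id",
    "read_kgml",
    "write_kgml",
]

#: entry kinds recognised by the model; anything else maps to "other"
ENTRY_KINDS = ("gene", "compound", "group", "map", "other")

#: relation types recognised by the model
RELATION_TYPES = (
    "PPrel",
    "ECrel",
    "GErel",
    "PCrel",
    "compound_compound",
    "maplink",
    "other",
)

#: relation types that connect two gene entries directly
GENE_RELATION_TYPES = frozenset({"PPrel", "ECrel", "GErel"})


class KGMLParseError(ValueError):
    """Raised when a KGML file cannot be parsed as XML."""


class PathwayValidationError(ValueError):
    """Raised when pathway elements reference entries that do not exist."""


def canonical_gene_id(name: str) -> str:
    """Canonicalise a gene identifier.

    Strips a KEGG organism prefix (everything up to and including the first
    ``:``) and uppercases, so KGML names and plain ORF names compare equal.

    >>> canonical_gene_id("sce:YBR160W")
    'YBR160W'
    >>> canonical_gene_id("cdc28")
    'CDC28'
    """
    name = name.strip()
    if ":" in name:
        name = name.split(":", 1)[1]
    return name.upper()


@dataclass
class PathwayEntry:
    """One KGML ``entry``: a gene, compound, group, map link or other node.

    ``names`` may hold several identifiers — KGML allows one entry to name
    multiple genes; conversion expands every name to its own gene node.
    ``members`` is only populated for ``kind == "group"`` and lists the
    entry ids of the group's components.
    """

    entry_id: str
    kind: str
    names: list[str] = field(default_factory=list)
    members: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ENTRY_KINDS:
            self.kind = "other"
        if self.kind in ("gene", "compound") and not self.names:
            raise PathwayValidationError(
                f"entry {self.entry_id!r} of kind {self.kind!r} has no names"
            )
        if self.kind == "group" and not self.members:
            raise PathwayValidationError(
                f"group entry {self.entry_id!r} has no members"
            )


@dataclass
class PathwayRelation:
    """One KGML ``relation``: a typed edge between two entries.

    ``via_compound`` carries the entry id of a mediating compound when the
    relation's subtype references one (e.g. an ECrel through a shared
    metabolite).
    """

    source: str
    target: str
    rel_type: str
    via_compound: Optional[str] = None

    def __post_init__(self) -> None:
        if self.rel_type not in RELATION_TYPES:
            self.rel_type = "other"


@dataclass
class PathwayReaction:
    """One KGML ``reaction``: enzymes transforming substrates into products.

    ``enzymes`` lists the gene entry ids catalysing the reaction;
    ``substrates``/``products`` list compound entry ids.
    """

    reaction_id: str
    enzymes: list[str] = field(default_factory=list)
    substrates: list[str] = field(default_factory=list)
    products: list[str] = field(default_factory=list)


@dataclass
class Pathway:
    """A parsed KEGG pathway: entries keyed by id, relations and reactions."""

    pathway_id: str
    organism: str = ""
    entries: dict[str, PathwayEntry] = field(default_factory=dict)
    relations: list[PathwayRelation] = field(default_factory=list)
    reactions: list[PathwayReaction] = field(default_factory=list)

    def add_entry(self, entry: PathwayEntry) -> None:
        if entry.entry_id in self.entries:
            raise PathwayValidationError(
                f"duplicate entry id {entry.entry_id!r} in pathway {self.pathway_id!r}"
            )
        self.entries[entry.entry_id] = entry

    def validate(self) -> None:
        """Check referential integrity; raise listing every dangling id."""
        dangling: list[str] = []
        for e in self.entries.values():
            for m in e.members:
                if m not in self.entries:
                    dangling.append(f"group {e.entry_id} -> member {m}")
        for r in self.relations:
            for end in (r.source, r.target):
                if end not in self.entries:
                    dangling.append(f"relation {r.source}->{r.target} -> entry {end}")
            if r.via_compound is not None and r.via_compound not in self.entries:
                dangling.append(
                    f"relation {r.source}->{r.target} -> compound {r.via_compound}"
                )
        for rx in self.reactions:
            for eid in rx.enzymes + rx.substrates + rx.products:
                if eid not in self.entries:
                    dangling.append(f"reaction {rx.reaction_id} -> entry {eid}")
        if dangling:
            raise PathwayValidationError(
                f"pathway {self.pathway_id!r} has dangling references: "
                + "; ".join(sorted(dangling))
            )

    def gene_entries(self) -> list[PathwayEntry]:
        return [e for e in self.entries.values() if e.kind == "gene"]

    def compound_entries(self) -> list[PathwayEntry]:
        return [e for e in self.entries.values() if e.kind == "compound"]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Pathway):
            return NotImplemented
        return (
            self.pathway_id == other.pathway_id
            and self.organism == other.organism
            and self.entries == other.entries
            and self.relations == other.relations
            and self.reactions == other.reactions
        )


# --- KGML I/O ---------------------------------------------------------------

# KGML writes compound-compound links with a plain type attribute; the
# in-memory name uses an underscore to stay a valid identifier.
_REL_TYPE_TO_XML = {"compound_compound": "compound-compound"}
_REL_TYPE_FROM_XML = {"compound-compound": "compound_compound"}


def read_kgml(path: str | Path) -> Pathway:
    """Parse a KGML file into a :class:`Pathway`.

    Entries of unrecognised type are kept with ``kind="other"``.  Relation
    subtypes naming a compound populate ``via_compound``.  Raises
    :class:`KGMLParseError` on malformed XML and
    :class:`PathwayValidationError` when relations, reactions or groups
    reference entry ids that do not exist.
    """
    path = Path(path)
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise KGMLParseError(f"malformed KGML in {path}: {exc}") from exc
    root = tree.getroot()
    if root.tag != "pathway":
        raise KGMLParseError(f"{path}: root element is <{root.tag}>, expected <pathway>")

    pw = Pathway(
        pathway_id=root.get("name", root.get("title", path.stem)),
        organism=root.get("org", ""),
    )

    reaction_of_entry: dict[str, str] = {}
    for el in root.findall("entry"):
        entry_id = el.get("id")
        if entry_id is None:
            raise KGMLParseError(f"{path}: entry element without id attribute")
        kind = el.get("type", "other")
        if kind not in ENTRY_KINDS:
            kind = "other"
        names = (el.get("name") or "").split()
        members = [c.get("id") for c in el.findall("component") if c.get("id")]
        reaction = el.get("reaction")
        if kind == "group" and not members:
            raise PathwayValidationError(
                f"{path}: group entry {entry_id!r} has no component elements"
            )
        entry = PathwayEntry(
            entry_id=entry_id,
            kind=kind,
            names=names,
            members=members,
        )
        pw.add_entry(entry)
        if reaction is not None:
            # enzyme membership is written on gene entries in KGML; collect
            # it here and attach to the reactions below
            reaction_of_entry[entry_id] = reaction

    for el in root.findall("relation"):
        rel_type = el.get("type", "other")
        rel_type = _REL_TYPE_FROM_XML.get(rel_type, rel_type)
        via = None
        for sub in el.findall("subtype"):
            if sub.get("name") == "compound":
                via = sub.get("value")
        pw.relations.append(
            PathwayRelation(
                source=el.get("entry1", ""),
                target=el.get("entry2", ""),
                rel_type=rel_type,
                via_compound=via,
            )
        )

    for el in root.findall("reaction"):
        rid = el.get("id") or el.get("name", "")
        rname = el.get("name", rid)
        enzymes = [
            eid
            for eid, r in reaction_of_entry.items()
            if r is not None and (rid in r.split() or rname in r.split())
        ]
        pw.reactions.append(
            PathwayReaction(
                reaction_id=rid,
                enzymes=sorted(enzymes),
                substrates=[s.get("id") for s in el.findall("substrate") if s.get("id")],
                products=[p.get("id") for p in el.findall("product") if p.get("id")],
            )
        )

    pw.validate()
    return pw


def write_kgml(pathway: Pathway, path: str | Path) -> None:
    """Serialise a :class:`Pathway` back to a KGML-dialect XML file.

    Round-trips with :func:`read_kgml` on all modeled fields.  Enzyme
    membership of reactions is written the way KGML does it: through the
    ``reaction`` attribute on gene entries.
    """
    pathway.validate()
    root = ET.Element(
        "pathway", {"name": pathway.pathway_id, "org": pathway.organism}
    )

    # enzyme -> reaction links are carried on the entries
    enzyme_reactions: dict[str, list[str]] = {}
    for rx in pathway.reactions:
        for eid in rx.enzymes:
            enzyme_reactions.setdefault(eid, []).append(rx.reaction_id)

    for entry in pathway.entries.values():
        attrs = {"id": entry.entry_id, "type": entry.kind}
        if entry.names:
            attrs["name"] = " ".join(entry.names)
        rids = enzyme_reactions.get(entry.entry_id)
        if rids:
            attrs["reaction"] = " ".join(rids)
        el = ET.SubElement(root, "entry", attrs)
        for m in entry.members:
            ET.SubElement(el, "component", {"id": m})

    for rel in pathway.relations:
        el = ET.SubElement(
            root,
            "relation",
            {
                "entry1": rel.source,
                "entry2": rel.target,
                "type": _REL_TYPE_TO_XML.get(rel.rel_type, rel.rel_type),
            },
        )
        if rel.via_compound is not None:
            ET.SubElement(el, "subtype", {"name": "compound", "value": rel.via_compound})

    for rx in pathway.reactions:
        el = ET.SubElement(
            root, "reaction", {"id": rx.reaction_id, "name": rx.reaction_id}
        )
        for s in rx.substrates:
            ET.SubElement(el, "substrate", {"id": s})
        for p in rx.products:
            ET.SubElement(el, "product", {"id": p})

    ET.indent(root)
    tree = ET.ElementTree(root)
    tree.write(path, encoding="unicode", xml_declaration=True)
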