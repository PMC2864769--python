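"""Declarative configuration: ontology sources per role, and field filters.

Replaces an interactive ontology-configuration panel with a single YAML
file so that batch runs are reproducible and work offline against local
ontology copies.  Roles name what each ontology is used for: ``entity``
(anatomy), ``quality``, ``taxonomy``, ``unit``, and ``collection`` (the
museum-code list).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import yaml

from .ontology import Ontology, TermFilter, load_obo, merge

ROLES = ("entity", "quality", "taxonomy", "unit", "collection")

#: data-entry fields that may carry a term filter, and the ontology role
#: each draws from
FIELD_ROLES = {
    "entity": "entity",
    "related_entity": "entity",
    "quality": "quality",
    "taxon": "taxonomy",
    "unit": "unit",
    "collection": "collection",
}


@dataclass
class Config:
    #: role -> list of local OBO paths (or URLs, resolved by the caller)
    ontology_sources: dict[str, list[str]] = field(default_factory=dict)
    #: field name -> TermFilter
    field_filters: dict[str, TermFilter] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for role in self.ontology_sources:
            if role not in ROLES:
                raise ValueError(f"unknown ontology role {role!r}; expected {ROLES}")
        for fieldname in self.field_filters:
            if fieldname not in FIELD_ROLES:
                raise ValueError(
                    f"field filter {fieldname!r} does not name a known field "
                    f"({sorted(FIELD_ROLES)})"
                )

    def load_ontologies(self) -> Ontology:
        """Load and merge every configured OBO source."""
        ontologies = []
        for role in ROLES:
            for path in self.ontology_sources.get(role, []):
                ontologies.append(load_obo(path))
        return merge(ontologies)

    def to_yaml(self) -> str:
        doc: dict = {"ontologies": self.ontology_sources}
        filters: dict = {}
        for name, f in self.field_filters.items():
            entry: dict = {}
            if f.namespaces is not None:
                entry["namespaces"] = sorted(f.namespaces)
            if f.subsets is not None:
                entry["subsets"] = sorted(f.subsets)
            if f.ancestor_constraint is not None:
                root, relations = f.ancestor_constraint
                entry["ancestor"] = {"term": root, "relations": sorted(relations)}
            filters[name] = entry
        if filters:
            doc["filters"] = filters
        return yaml.safe_dump(doc, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "Config":
        doc = yaml.safe_load(text) or {}
        filters: dict[str, TermFilter] = {}
        for name, entry in (doc.get("filters") or {}).items():
            ancestor = entry.get("ancestor")
            filters[name] = TermFilter(
                namespaces=frozenset(entry["namespaces"])
                if "namespaces" in entry
                else None,
                subsets=frozenset(entry["subsets"]) if "subsets" in entry else None,
                ancestor_constraint=(
                    ancestor["term"],
                    frozenset(ancestor["relations"]),
                )
                if ancestor
                else None,
            )
        return cls(
            ontology_sources={k: list(v) for k, v in (doc.get("ontologies") or {}).items()},
            field_filters=filters,
        )


def load_config(path: str) -> Config:
    """Read a YAML config; relative ontology paths resolve against the
    config file's own directory."""
    from pathlib import Path

    p = Path(path)
    config = Config.from_yaml(p.read_text(encoding="utf-8"))
    base = p.parent
    config.ontology_sources = {
        role: [str(src) if Path(src).is_absolute() else str(base / src)
               for src in sources]
        for role, sources in config.ontology_sources.items()
    }
    return config
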