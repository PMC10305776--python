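"""The stroke/thrombolysis entity inventory and eligibility-checklist linkage.

The packaged ontology holds 86 entities in five categories (Diagnosis,
Symptom, Social history, Medication, Treatment), each with a canonical
lower-kebab-case identifier, a display name, and a seed list of surface forms
used by the corpus simulator.  Custom ontologies with the same schema can be
loaded by path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import yaml

EXPECTED_CATEGORIES = (
    "Diagnosis",
    "Symptom",
    "Social history",
    "Medication",
    "Treatment",
)


class OntologyError(ValueError):
    pass


@dataclass(frozen=True)
class Entity:
    id: str
    name: str
    category: str
    synonyms: tuple[str, ...] = ()

    def surface_forms(self) -> list[str]:
        """Canonical display name plus curated synonym seeds."""
        return [self.name, *self.synonyms]


@dataclass(frozen=True)
class ChecklistItem:
    text: str
    polarity: str  # must-be-yes | must-be-no | should-be-no
    entities: tuple[str, ...] = ()


@dataclass
class Ontology:
    entities: list[Entity]
    categories: tuple[str, ...]
    checklist: list[ChecklistItem] = field(default_factory=list)
    _by_id: dict[str, Entity] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_id = {}
        for ent in self.entities:
            if ent.id in self._by_id:
                raise OntologyError(f"duplicate entity id {ent.id!r}")
            if ent.category not in self.categories:
                raise OntologyError(
                    f"entity {ent.id!r} has unknown category {ent.category!r}"
                )
            self._by_id[ent.id] = ent
        for item in self.checklist:
            for eid in item.entities:
                if eid not in self._by_id:
                    raise OntologyError(
                        f"checklist item links unknown entity {eid!r}"
                    )

    def __len__(self) -> int:
        return len(self.entities)

    def __iter__(self):
        return iter(self.entities)

    def contains(self, entity_id: str) -> bool:
        return entity_id in self._by_id

    def lookup(self, name: str) -> Entity | None:
        """Case-insensitive exact match on canonical ids or display names.

        Synonym seeds are deliberately not lookup keys; a miss returns None.
        """
        key = name.strip().lower()
        hit = self._by_id.get(key.replace(" ", "-"))
        if hit is not None:
            return hit
        for ent in self.entities:
            if ent.name.lower() == key:
                return ent
        return None

    def synonym_seeds(self, entity_id: str) -> list[str]:
        """Packaged surface-form pool for one entity (canonical name first)."""
        ent = self._by_id.get(entity_id)
        if ent is None:
            raise OntologyError(f"unknown entity {entity_id!r}")
        return ent.surface_forms()

    def entity_ids(self) -> list[str]:
        return [e.id for e in self.entities]

    def category_of(self, entity_id: str) -> str:
        ent = self._by_id.get(entity_id)
        if ent is None:
            raise OntologyError(f"unknown entity {entity_id!r}")
        return ent.category

    def validate_default_shape(self) -> None:
        """Assert the packaged-inventory invariants: 86 entities, 5 categories."""
        if len(self.entities) != 86:
            raise OntologyError(f"expected 86 entities, found {len(self.entities)}")
        if tuple(self.categories) != EXPECTED_CATEGORIES:
            raise OntologyError(f"unexpected categories {self.categories!r}")
        used = {e.category for e in self.entities}
        if used != set(EXPECTED_CATEGORIES):
            raise OntologyError(f"categories without members: {set(EXPECTED_CATEGORIES) - used}")


def load_ontology(path: str | Path, checklist_path: str | Path | None = None) -> Ontology:
    """Load an ontology (and optional checklist) from YAML files."""
    raw = yaml.safe_load(Path(path).read_text())
    entities = [
        Entity(
            id=e["id"],
            name=e["name"],
            category=e["category"],
            synonyms=tuple(str(s) for s in e.get("synonyms", ())),
        )
        for e in raw["entities"]
    ]
    checklist: list[ChecklistItem] = []
    if checklist_path is not None:
        craw = yaml.safe_load(Path(checklist_path).read_text())
        checklist = [
            ChecklistItem(
                text=item["text"],
                polarity=item["polarity"],
                entities=tuple(item.get("entities", ())),
            )
            for item in craw["items"]
        ]
    return Ontology(
        entities=entities,
        categories=tuple(raw["categories"]),
        checklist=checklist,
    )


def load_default_ontology() -> Ontology:
    """The packaged 86-entity inventory with checklist linkage, validated."""
    data = resources.files("strokener.data")
    onto = load_ontology(
        data / "ontology.yaml", checklist_path=data / "checklist.yaml"
    )
    onto.validate_default_shape()
    return onto
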