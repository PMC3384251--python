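"""Task schemas: entity/event types and valid argument structures.

A :class:`TaskSchema` declares, for one extraction task, the entity types
(given vs predicted, with optional supertypes), the event types with their
role constraints (allowed target types and cardinalities), triggerless
relation types, zero-argument event types, the site-argument representation
mode and modality dimensions. Schemas for the standard shared-task
configurations ship as JSON files under ``eventex/schemas``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

EVENT_TARGET = "Event"   # pseudo target type matching any event type


@dataclass(frozen=True)
class RoleSpec:
    role: str
    targets: tuple[str, ...]
    min_count: int = 1
    max_count: Optional[int] = 1   # None = unbounded
    site: bool = False             # secondary (site-style) argument


@dataclass
class TaskSchema:
    name: str
    entity_types: dict[str, Optional[str]]            # type -> supertype or None
    given_types: set[str]
    event_types: dict[str, dict[str, RoleSpec]]       # type -> role -> spec
    relation_types: dict[str, list[RoleSpec]] = field(default_factory=dict)
    undirected_relation_types: set[str] = field(default_factory=set)
    zero_argument_types: set[str] = field(default_factory=set)
    site_mode: str = "protein-linked"                 # or "trigger-linked"
    resolve_equiv: bool = True
    modality_types: tuple[str, ...] = ()
    reverse_event_types: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for etype, roles in self.event_types.items():
            for spec in roles.values():
                if spec.max_count is not None and spec.min_count > spec.max_count:
                    raise ValueError(f"{self.name}/{etype}: min > max for {spec.role}")
                for t in spec.targets:
                    if not self._known_type(t):
                        raise ValueError(f"{self.name}/{etype}: unknown target type {t}")

    def _known_type(self, t: str) -> bool:
        if t in (EVENT_TARGET, "*"):
            return True
        if t in self.entity_types or t in self.event_types:
            return True
        return t in set(self.entity_types.values())

    # ------------------------------------------------------------------
    def supertype(self, type_: str) -> Optional[str]:
        return self.entity_types.get(type_)

    def trigger_classes(self) -> list[str]:
        """Classes predicted by the trigger detector: event types plus
        non-given entity types (e.g. site Entity), sorted for determinism."""
        predictable = [t for t in self.entity_types if t not in self.given_types]
        return sorted(set(self.event_types) | set(predictable))

    def is_event_type(self, t: str) -> bool:
        return t in self.event_types

    def is_relation_type(self, t: str) -> bool:
        return t in self.relation_types

    def type_matches(self, concrete: str, allowed: str) -> bool:
        if allowed == "*":
            return True
        if allowed == EVENT_TARGET:
            return concrete in self.event_types
        if concrete == allowed:
            return True
        return self.entity_types.get(concrete) == allowed

    def role_accepts(self, spec: RoleSpec, target_type: str) -> bool:
        return any(self.type_matches(target_type, a) for a in spec.targets)

    def core_roles(self, event_type: str) -> dict[str, RoleSpec]:
        return {r: s for r, s in self.event_types[event_type].items() if not s.site}

    def site_roles(self, event_type: str) -> dict[str, RoleSpec]:
        return {r: s for r, s in self.event_types[event_type].items() if s.site}

    def edge_labels_for_pair(self, source_type: str, target_type: str) -> list[str]:
        """Role/relation labels a directed edge source->target may carry.

        For event-type sources these are argument roles; for entity pairs
        they are triggerless relation types whose first role accepts the
        source and second role accepts the target.
        """
        labels: list[str] = []
        if source_type in self.event_types:
            for role, spec in self.event_types[source_type].items():
                if spec.site and self.site_mode == "protein-linked":
                    continue
                if self.role_accepts(spec, target_type):
                    labels.append(role)
        for rtype, roles in self.relation_types.items():
            if len(roles) >= 2 and self.role_accepts(roles[0], source_type) \
                    and self.role_accepts(roles[1], target_type):
                labels.append(rtype)
        if self.site_mode == "protein-linked":
            # site edges run protein -> site entity
            for roles in self.event_types.values():
                for role, spec in roles.items():
                    if spec.site and source_type in self.given_types \
                            and self.role_accepts(spec, target_type):
                        labels.append(role)
        return sorted(set(labels))

    def valid_edge_pair(self, source_type: str, target_type: str) -> bool:
        return bool(self.edge_labels_for_pair(source_type, target_type))


def _parse_roles(obj: dict, default_min=1) -> dict[str, RoleSpec]:
    roles = {}
    for role, r in obj.items():
        roles[role] = RoleSpec(
            role=role,
            targets=tuple(r["targets"]),
            min_count=r.get("min", default_min),
            max_count=r.get("max", 1),
            site=r.get("site", False),
        )
    return roles


def schema_from_dict(data: dict) -> TaskSchema:
    event_types = {t: _parse_roles(roles) for t, roles in
                   data.get("event_types", {}).items()}
    relation_types = {}
    for rtype, roles in data.get("relation_types", {}).items():
        parsed = _parse_roles(roles)
        relation_types[rtype] = [parsed[r] for r in roles]  # keep declared order
    return TaskSchema(
        name=data["name"],
        entity_types={t: (v or None) for t, v in data.get("entity_types", {}).items()},
        given_types=set(data.get("given_types", [])),
        event_types=event_types,
        relation_types=relation_types,
        undirected_relation_types=set(data.get("undirected_relation_types", [])),
        zero_argument_types=set(data.get("zero_argument_types", [])),
        site_mode=data.get("site_mode", "protein-linked"),
        resolve_equiv=data.get("resolve_equiv", True),
        modality_types=tuple(data.get("modality_types", [])),
        reverse_event_types=data.get("reverse_event_types", {}),
    )


def load_schema(name_or_path: str) -> TaskSchema:
    """Load a bundled schema by short name (``ge``, ``epi``, ``id``, ``bb``,
    ``bi``, ``rel``, ``ren``) or any JSON/YAML file path."""
    p = Path(name_or_path)
    if p.suffix in (".json", ".yaml", ".yml") or p.exists():
        text = p.read_text(encoding="utf-8")
        if p.suffix in (".yaml", ".yml"):
            import yaml
            return schema_from_dict(yaml.safe_load(text))
        return schema_from_dict(json.loads(text))
    ref = resources.files("eventex").joinpath(f"schemas/{name_or_path.lower()}.json")
    if not ref.is_file():
        raise FileNotFoundError(f"no bundled schema named {name_or_path!r}")
    return schema_from_dict(json.loads(ref.read_text(encoding="utf-8")))
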