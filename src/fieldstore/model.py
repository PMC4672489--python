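"""Hierarchical experiment metadata model: users → experiments → nodes → streams.

A *user* is a logical owner (a project or research group) holding
experiments; an experiment groups *nodes* (experimental units such as field
plots, optionally georeferenced); a node groups *streams*, each a measured
variable with a unit.  Free-form string metadata can be attached at every
layer and drives filtering — e.g. select every soil-moisture stream under
irrigated plots of one trial without knowing stream names.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

__all__ = [
    "Entity",
    "EntityTree",
    "StoreError",
    "NoSuchEntityError",
    "DuplicateNameError",
    "HierarchyError",
    "BadPredicateError",
    "KINDS",
    "SEP",
]

KINDS = ("user", "experiment", "node", "stream")

#: Separator for path-form stream ids.  "~" is not a legal name character,
#: so joined paths are unambiguous and safe in file names and URLs.
SEP = "~"

_NAME_RE = re.compile(r"^[A-Za-z0-9._-]+$")


class StoreError(Exception):
    """Base class for store errors."""


class NoSuchEntityError(StoreError, KeyError):
    def __str__(self) -> str:  # KeyError would requote the message
        return self.args[0] if self.args else ""


class DuplicateNameError(StoreError):
    pass


class HierarchyError(StoreError):
    pass


class BadPredicateError(StoreError):
    pass


@dataclass
class Entity:
    """One record in the hierarchy.

    ``attrs`` holds structural attributes (unit, timezone, location…);
    ``metadata`` holds the user-attachable key/value annotations.  Both are
    string-keyed; metadata values are strings only.
    """

    kind: str
    name: str
    parent: Optional["Entity"] = None
    attrs: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)
    children: dict = field(default_factory=dict)

    @property
    def path(self) -> str:
        parts = []
        e: Optional[Entity] = self
        while e is not None:
            parts.append(e.name)
            e = e.parent
        return SEP.join(reversed(parts))

    def ancestor(self, kind: str) -> Optional["Entity"]:
        e: Optional[Entity] = self
        while e is not None and e.kind != kind:
            e = e.parent
        return e

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"<{self.kind} {self.path}>"


class EntityTree:
    """The in-memory entity hierarchy with metadata and filtering."""

    def __init__(self) -> None:
        self._users: dict[str, Entity] = {}

    # -- creation / lookup -------------------------------------------------

    def create(
        self,
        kind: str,
        name: str,
        parent: "Entity | str | None" = None,
        attrs: dict | None = None,
    ) -> Entity:
        """Create an entity under *parent* and return it.

        The parent must exist and be the kind immediately above the child
        (user → experiment → node → stream); names are case-sensitive
        ``[A-Za-z0-9._-]+`` and unique among siblings.
        """
        if kind not in KINDS:
            raise HierarchyError(f"hierarchy violation: unknown kind {kind!r}")
        if not _NAME_RE.match(name or ""):
            raise ValueError(f"invalid name {name!r}: must match [A-Za-z0-9._-]+")
        attrs = dict(attrs or {})
        depth = KINDS.index(kind)
        if depth == 0:
            if parent is not None:
                raise HierarchyError("hierarchy violation: a user has no parent")
            if name in self._users:
                raise DuplicateNameError(f"duplicate: user {name!r} already exists")
            ent = Entity("user", name, None, attrs)
            self._users[name] = ent
            return ent
        if parent is None:
            raise HierarchyError(f"hierarchy violation: {kind} requires a parent")
        parent_ent = self.resolve(parent) if isinstance(parent, str) else parent
        if parent_ent.kind != KINDS[depth - 1]:
            raise HierarchyError(
                f"hierarchy violation: {kind} must be created under a "
                f"{KINDS[depth - 1]}, got {parent_ent.kind}"
            )
        if name in parent_ent.children:
            raise DuplicateNameError(
                f"duplicate: {kind} {name!r} already exists under {parent_ent.path}"
            )
        if kind == "experiment":
            attrs.setdefault("timezone", "UTC")  # display label; storage is UTC
        if kind == "node":
            self._check_location(attrs)
        ent = Entity(kind, name, parent_ent, attrs)
        parent_ent.children[name] = ent
        return ent

    @staticmethod
    def _check_location(attrs: dict) -> None:
        lat, lon = attrs.get("latitude"), attrs.get("longitude")
        if lat is not None and not (-90.0 <= float(lat) <= 90.0):
            raise ValueError(f"latitude {lat} out of [-90, 90]")
        if lon is not None and not (-180.0 <= float(lon) <= 180.0):
            raise ValueError(f"longitude {lon} out of [-180, 180]")

    def resolve(self, path: "str | Entity") -> Entity:
        """Resolve a ``user~experiment~node~stream`` path (any depth)."""
        if isinstance(path, Entity):
            return path
        parts = path.split(SEP) if SEP in path else path.split("/")
        ent = self._users.get(parts[0])
        if ent is None:
            raise NoSuchEntityError(f"no such parent: user {parts[0]!r}")
        for name in parts[1:]:
            ent = ent.children.get(name)
            if ent is None:
                raise NoSuchEntityError(f"no such entity: {path!r}")
        return ent

    def get(self, path: "str | Entity") -> Optional[Entity]:
        try:
            return self.resolve(path)
        except NoSuchEntityError:
            return None

    def users(self) -> list[Entity]:
        return [self._users[k] for k in sorted(self._users)]

    def children(self, parent: "str | Entity") -> list[Entity]:
        p = self.resolve(parent)
        return [p.children[k] for k in sorted(p.children)]

    def delete(self, entity: "str | Entity") -> list[Entity]:
        """Remove an entity and its whole subtree; returns deleted entities."""
        ent = self.resolve(entity)
        removed = list(self.walk(ent))
        if ent.parent is None:
            del self._users[ent.name]
        else:
            del ent.parent.children[ent.name]
        return removed

    def walk(self, root: "Entity | None" = None) -> Iterator[Entity]:
        """Depth-first traversal in sorted-name order."""
        tops = [root] if root is not None else self.users()
        stack = list(reversed(tops))
        while stack:
            e = stack.pop()
            yield e
            for name in sorted(e.children, reverse=True):
                stack.append(e.children[name])

    # -- metadata ----------------------------------------------------------

    def set_metadata(self, entity: "str | Entity", key: str, value: str) -> None:
        ent = self.get(entity) if isinstance(entity, str) else entity
        if ent is None:
            raise NoSuchEntityError(f"no such entity: {entity!r}")
        ent.metadata[str(key)] = str(value)

    def get_metadata(self, entity: "str | Entity") -> dict:
        ent = self.get(entity) if isinstance(entity, str) else entity
        if ent is None:
            raise NoSuchEntityError(f"no such entity: {entity!r}")
        return dict(ent.metadata)

    # -- filtering ---------------------------------------------------------

    def streams(self, root: "Entity | str | None" = None) -> list[Entity]:
        it = self.walk(self.resolve(root)) if root is not None else self.walk()
        return [e for e in it if e.kind == "stream"]

    def filter_streams(
        self,
        user: "str | Entity",
        experiment_pattern: str | None = None,
        node_pattern: str | None = None,
        stream_pattern: str | None = None,
        unit_pattern: str | None = None,
        metadata_predicates: Iterable[tuple[str, str, str]] = (),
    ) -> list[Entity]:
        """Streams of *user* matching every filter.

        Name/unit patterns are case-insensitive literal substrings; each
        metadata predicate ``(level, key, value)`` requires the ancestor at
        *level* to carry exactly that key/value.  Results are ordered by
        (experiment, node, stream) name.
        """
        u = self._users.get(user if isinstance(user, str) else user.name)
        if u is None:
            raise NoSuchEntityError(f"no such user: {user!r}")
        preds = list(metadata_predicates)
        for level, _, _ in preds:
            if level not in KINDS:
                raise BadPredicateError(f"bad predicate: unknown level {level!r}")

        def contains(hay: str, needle: str | None) -> bool:
            return needle is None or needle.lower() in hay.lower()

        out = []
        for s in self.streams(u):
            node = s.parent
            exp = node.parent
            if not contains(exp.name, experiment_pattern):
                continue
            if not contains(node.name, node_pattern):
                continue
            if not contains(s.name, stream_pattern):
                continue
            if not contains(str(s.attrs.get("unit", "")), unit_pattern):
                continue
            ok = True
            for level, key, value in preds:
                anc = s.ancestor(level)
                if anc is None or anc.metadata.get(key) != value:
                    ok = False
                    break
            if ok:
                out.append(s)
        out.sort(key=lambda s: (s.parent.parent.name, s.parent.name, s.name))
        return out

    # -- persistence -------------------------------------------------------

    def to_records(self) -> list[dict]:
        recs = []
        for e in self.walk():
            recs.append(
                {
                    "kind": e.kind,
                    "name": e.name,
                    "parent": e.parent.path if e.parent else None,
                    "attrs": e.attrs,
                    "metadata": e.metadata,
                }
            )
        return recs

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "EntityTree":
        tree = cls()
        for r in records:
            ent = tree.create(r["kind"], r["name"], r.get("parent"), r.get("attrs") or {})
            ent.metadata.update(r.get("metadata") or {})
        return tree

    def save(self, path: "str | Path") -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for rec in self.to_records():
                fh.write(json.dumps(rec, ensure_ascii=False) + "\n")

    @classmethod
    def load(cls, path: "str | Path") -> "EntityTree":
        with open(path, encoding="utf-8") as fh:
            return cls.from_records(json.loads(line) for line in fh if line.strip())
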