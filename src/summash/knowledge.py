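"""Self-contained knowledge source: concepts, hierarchy, lexicon, MeSH map.

Stands in for the UMLS Metathesaurus / Semantic Network and MeSH.  The
``is_a`` hierarchy is a rooted DAG; concept depth (root = 1, shortest path
under multiple inheritance) drives the edge weights of the graph summarizer,
and the hypernym closure feeds sentence-graph construction after the two
broadest levels (depths 1 and 2) are removed.

On disk the knowledge source is a single JSON document with a
``format: summash-ks-1`` header and sections ``concepts``, ``isa``,
``related``, ``lexicon``, ``generic_types``, ``mesh_map``, ``mesh_tree``.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

FORMAT_TAG = "summash-ks-1"

#: relation tags allowed on non-hierarchical edges
RELATED_TAGS = ("other_related", "associated_with")


@dataclass(frozen=True)
class Concept:
    concept_id: str
    preferred_name: str
    semantic_type: str


class KnowledgeError(ValueError):
    pass


@dataclass
class KnowledgeSource:
    """Concept inventory plus hierarchy, lexicon and MeSH mapping.

    ``isa_edges`` are (parent, child) pairs forming a single-rooted DAG.
    ``related_edges`` are (concept_a, concept_b, tag) with tag in
    :data:`RELATED_TAGS`.  ``lexicon`` maps a lowercase surface term to the
    ordered list of candidate concept ids (order encodes preference).
    ``mesh_map`` maps concept ids to MeSH heading strings; ``mesh_tree`` maps
    each heading to its tree numbers (branch letter + dotted digits).
    """

    concepts: dict[str, Concept] = field(default_factory=dict)
    isa_edges: list[tuple[str, str]] = field(default_factory=list)
    related_edges: list[tuple[str, str, str]] = field(default_factory=list)
    lexicon: dict[str, list[str]] = field(default_factory=dict)
    generic_types: set[str] = field(default_factory=set)
    mesh_map: dict[str, str] = field(default_factory=dict)
    mesh_tree: dict[str, set[str]] = field(default_factory=dict)

    _parents: dict[str, list[str]] | None = field(default=None, repr=False)
    _depths: dict[str, int] | None = field(default=None, repr=False)

    # -- hierarchy -----------------------------------------------------------

    @property
    def root(self) -> str:
        children = {c for _, c in self.isa_edges}
        in_dag = {p for p, _ in self.isa_edges} | children
        roots = sorted(in_dag - children)
        if len(roots) != 1:
            raise KnowledgeError(f"isa hierarchy must have exactly one root, found {roots}")
        return roots[0]

    def parents(self, c: str) -> list[str]:
        if self._parents is None:
            par: dict[str, list[str]] = {}
            for p, ch in self.isa_edges:
                par.setdefault(ch, []).append(p)
            self._parents = {k: sorted(v) for k, v in par.items()}
        return self._parents.get(c, [])

    def _depth_table(self) -> dict[str, int]:
        if self._depths is None:
            children: dict[str, list[str]] = {}
            for p, ch in self.isa_edges:
                children.setdefault(p, []).append(ch)
            depths = {self.root: 1}
            queue = deque([self.root])
            while queue:
                node = queue.popleft()
                for ch in children.get(node, []):
                    if ch not in depths:
                        depths[ch] = depths[node] + 1
                        queue.append(ch)
            self._depths = depths
        return self._depths

    def depth(self, c: str) -> int:
        """Depth of ``c``: root has depth 1; shortest is_a path otherwise."""
        if c not in self.concepts:
            raise KnowledgeError(f"unknown concept {c!r}")
        depths = self._depth_table()
        if c not in depths:
            raise KnowledgeError(f"concept {c!r} not reachable from the root")
        return depths[c]

    def hypernym_closure(self, c: str) -> set[str]:
        """``c`` plus all is_a ancestors, with depths 1 and 2 removed.

        Under multiple inheritance the union over all parent chains is taken.
        The two broadest levels of the hierarchy are excluded because they
        carry no discriminative meaning for summarization.
        """
        if c not in self.concepts:
            raise KnowledgeError(f"unknown concept {c!r}")
        seen = {c}
        queue = deque([c])
        while queue:
            node = queue.popleft()
            for p in self.parents(node):
                if p not in seen:
                    seen.add(p)
                    queue.append(p)
        return {x for x in seen if self.depth(x) > 2}

    # -- MeSH ----------------------------------------------------------------

    def restrict_to_mesh(self, concept_ids: set[str]) -> set[str]:
        """MeSH headings for a concept set; unmapped concepts are dropped."""
        return {self.mesh_map[c] for c in concept_ids if c in self.mesh_map}

    # -- validation / IO -----------------------------------------------------

    def validate(self) -> None:
        root = self.root  # raises unless single root
        depths = self._depth_table()
        for p, ch in self.isa_edges:
            if p not in self.concepts or ch not in self.concepts:
                raise KnowledgeError(f"isa edge ({p}, {ch}) references unknown concept")
            if p not in depths or ch not in depths:
                raise KnowledgeError(f"isa edge ({p}, {ch}) unreachable from root {root}")
        # cycle check: every node strictly deeper than some parent
        for ch in {c for _, c in self.isa_edges}:
            if all(depths[ch] <= depths[p] for p in self.parents(ch)):
                raise KnowledgeError(f"isa cycle suspected at {ch}")
        for term, targets in self.lexicon.items():
            if not targets:
                raise KnowledgeError(f"lexicon term {term!r} has no concepts")
            for c in targets:
                if c not in self.concepts:
                    raise KnowledgeError(f"lexicon term {term!r} -> unknown concept {c!r}")
        for a, b, tag in self.related_edges:
            if tag not in RELATED_TAGS:
                raise KnowledgeError(f"unknown relation tag {tag!r}")
        for c, heading in self.mesh_map.items():
            if heading not in self.mesh_tree or not self.mesh_tree[heading]:
                raise KnowledgeError(f"heading {heading!r} has no tree numbers")

    def to_dict(self) -> dict:
        return {
            "format": FORMAT_TAG,
            "concepts": [
                {"id": c.concept_id, "name": c.preferred_name, "semantic_type": c.semantic_type}
                for c in sorted(self.concepts.values(), key=lambda c: c.concept_id)
            ],
            "isa": sorted(list(e) for e in self.isa_edges),
            "related": sorted(list(e) for e in self.related_edges),
            "lexicon": {t: list(v) for t, v in sorted(self.lexicon.items())},
            "generic_types": sorted(self.generic_types),
            "mesh_map": dict(sorted(self.mesh_map.items())),
            "mesh_tree": {h: sorted(v) for h, v in sorted(self.mesh_tree.items())},
        }

    @classmethod
    def from_dict(cls, data: dict) -> "KnowledgeSource":
        if data.get("format") != FORMAT_TAG:
            raise KnowledgeError(f"unsupported knowledge format {data.get('format')!r}")
        ks = cls(
            concepts={
                c["id"]: Concept(c["id"], c["name"], c["semantic_type"])
                for c in data["concepts"]
            },
            isa_edges=[tuple(e) for e in data["isa"]],
            related_edges=[tuple(e) for e in data["related"]],
            lexicon={t: list(v) for t, v in data["lexicon"].items()},
            generic_types=set(data["generic_types"]),
            mesh_map=dict(data["mesh_map"]),
            mesh_tree={h: set(v) for h, v in data["mesh_tree"].items()},
        )
        ks.validate()
        return ks

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=1, sort_keys=False) + "\n", encoding="utf-8"
        )

    @classmethod
    def load(cls, path: str | Path) -> "KnowledgeSource":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


# module-level functional aliases matching the operation names

def depth(ks: KnowledgeSource, c: str) -> int:
    return ks.depth(c)


def hypernym_closure(ks: KnowledgeSource, c: str) -> set[str]:
    return ks.hypernym_closure(c)


def restrict_to_mesh(ks: KnowledgeSource, concept_ids: set[str]) -> set[str]:
    return ks.restrict_to_mesh(concept_ids)
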