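"""Validated tree model of a reconstruction and its section decomposition.

A :class:`Morphology` holds the sample points of one neuron as a rooted
tree.  All contiguous type-1 samples reachable from the root form the
*soma cluster*; its coordinate centroid is the soma center used as the
origin for Sholl analysis and scaling.  Edges internal to the soma
cluster are excluded from dendritic metrics.

The unit on which analyses and remodeling actions operate is the
*section* (what anatomists loosely call a "dendrite"): the maximal
unbranched path between topological landmarks — from the soma or a
branch point out to the next branch point or terminal tip.  A section's
node path *includes* its proximal landmark node (shared with the parent
section) so that geometry is continuous; the landmark's own edge to its
parent belongs to the parent section, which keeps length bookkeeping
free of double counting.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import numpy as np

from .errors import SWCStructureError
from .swc import ParseReport, SWCRecord, parse_swc, read_swc, write_swc

__all__ = [
    "Node",
    "Section",
    "Morphology",
    "build",
    "load",
    "loads",
    "region_of_type",
    "branch_order",
]

#: SWC type code -> anatomical region label.
REGION_BY_TYPE = {1: "soma", 2: "axon", 3: "basal", 4: "apical"}

REGIONS = ("all", "basal", "apical", "axon", "other")


def region_of_type(type_code: int) -> str:
    return REGION_BY_TYPE.get(type_code, "other")


@dataclass
class Node:
    """One sample point held mutably inside a :class:`Morphology`."""

    id: int
    type_code: int
    pos: np.ndarray  # shape (3,), micrometers
    radius: float  # micrometers
    parent: int  # -1 for the root


@dataclass(frozen=True)
class Section:
    """A maximal unbranched path between topological landmarks.

    ``node_path`` runs from the proximal landmark (inclusive) to the
    distal landmark (branch point or tip).  ``branch_order`` is the
    centrifugal order: the number of branch points between the soma and
    the section's proximal end (stems have order 0).
    """

    section_id: int
    node_path: tuple[int, ...]
    region: str
    is_terminal: bool
    parent_section: Optional[int]
    branch_order: int


def branch_order(section: Section) -> int:
    """Centrifugal branch order of a section (stems = 0)."""
    return section.branch_order


class Morphology:
    """Rooted, acyclic, connected tree of sample points."""

    def __init__(
        self,
        nodes: dict[int, Node],
        root_id: int,
        provenance: Optional[dict] = None,
    ):
        self.nodes = nodes
        self.root_id = root_id
        self.provenance = dict(provenance or {})
        self.children: dict[int, list[int]] = {nid: [] for nid in nodes}
        for node in nodes.values():
            if node.parent != -1:
                self.children[node.parent].append(node.id)
        for kids in self.children.values():
            kids.sort()
        self.validate()

    # ------------------------------------------------------------------
    # construction

    @classmethod
    def from_records(
        cls, records: Iterable[SWCRecord], source: Optional[str] = None
    ) -> "Morphology":
        records = list(records)
        nodes: dict[int, Node] = {}
        root_id = None
        for rec in records:
            if rec.sample_id in nodes:
                raise SWCStructureError(f"duplicate sample id {rec.sample_id}")
            nodes[rec.sample_id] = Node(
                id=rec.sample_id,
                type_code=rec.type_code,
                pos=np.array([rec.x, rec.y, rec.z], dtype=float),
                radius=float(rec.radius),
                parent=rec.parent_id,
            )
            if rec.parent_id == -1:
                if root_id is not None:
                    raise SWCStructureError("multiple roots in record set")
                root_id = rec.sample_id
        if root_id is None:
            raise SWCStructureError("no root record (parent -1) found")
        provenance = {"source": source, "edits": []} if source else None
        return cls(nodes, root_id, provenance)

    def copy(self) -> "Morphology":
        nodes = {
            nid: Node(n.id, n.type_code, n.pos.copy(), n.radius, n.parent)
            for nid, n in self.nodes.items()
        }
        m = object.__new__(Morphology)
        m.nodes = nodes
        m.root_id = self.root_id
        m.provenance = dict(self.provenance)
        m.children = {nid: list(kids) for nid, kids in self.children.items()}
        return m

    # ------------------------------------------------------------------
    # validation

    def validate(self) -> None:
        """Raise :class:`SWCStructureError` unless the node set forms a
        single connected acyclic tree with positive radii."""
        if self.root_id not in self.nodes:
            raise SWCStructureError("root id missing from node set")
        if self.nodes[self.root_id].parent != -1:
            raise SWCStructureError("root node has a parent")
        for node in self.nodes.values():
            if node.radius <= 0:
                raise SWCStructureError(
                    f"sample {node.id} has non-positive radius"
                )
            if node.parent == node.id:
                raise SWCStructureError(f"sample {node.id} is its own parent")
            if node.parent != -1 and node.parent not in self.nodes:
                raise SWCStructureError(
                    f"sample {node.id} references missing parent {node.parent}"
                )
        reached = set()
        stack = [self.root_id]
        while stack:
            nid = stack.pop()
            reached.add(nid)
            stack.extend(self.children[nid])
        if len(reached) != len(self.nodes):
            stray = set(self.nodes) - reached
            # distinguish a cycle from a plain dangling component
            probe = next(iter(stray))
            seen = set()
            cur = probe
            while cur != -1 and cur not in seen:
                seen.add(cur)
                cur = self.nodes[cur].parent if cur in self.nodes else -1
            if cur != -1:
                raise SWCStructureError(
                    f"cycle detected involving sample {cur}"
                )
            raise SWCStructureError(
                f"{len(stray)} sample(s) not connected to the root "
                f"(e.g. {probe})"
            )

    # ------------------------------------------------------------------
    # basic queries

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def root(self) -> Node:
        return self.nodes[self.root_id]

    @property
    def soma_ids(self) -> frozenset[int]:
        """Contiguous type-1 samples reachable from a type-1 root."""
        root = self.root
        if root.type_code != 1:
            return frozenset()
        out = set()
        stack = [root.id]
        while stack:
            nid = stack.pop()
            out.add(nid)
            for c in self.children[nid]:
                if self.nodes[c].type_code == 1:
                    stack.append(c)
        return frozenset(out)

    @property
    def origin_ids(self) -> frozenset[int]:
        """Nodes at which section decomposition starts: the soma cluster,
        or the bare root for somaless reconstructions."""
        soma = self.soma_ids
        return soma if soma else frozenset({self.root_id})

    @property
    def soma_center(self) -> np.ndarray:
        """Centroid of the soma cluster samples (μm)."""
        ids = sorted(self.origin_ids)
        return np.mean([self.nodes[i].pos for i in ids], axis=0)

    def is_soma_edge(self, parent_id: int, child_id: int) -> bool:
        soma = self.soma_ids
        return parent_id in soma and child_id in soma

    def edges(self) -> Iterator[tuple[Node, Node]]:
        """Yield (parent, child) node pairs for every non-root sample,
        in ascending child id order."""
        for nid in sorted(self.nodes):
            node = self.nodes[nid]
            if node.parent != -1:
                yield self.nodes[node.parent], node

    def edge_length(self, parent_id: int, child_id: int) -> float:
        return float(
            np.linalg.norm(self.nodes[child_id].pos - self.nodes[parent_id].pos)
        )

    def subtree_ids(self, node_id: int) -> list[int]:
        """All node ids in the subtree rooted at ``node_id`` (inclusive)."""
        out = []
        stack = [node_id]
        while stack:
            nid = stack.pop()
            out.append(nid)
            stack.extend(self.children[nid])
        return out

    def path_length_to_soma(self, node_id: int) -> float:
        """Sum of Euclidean edge lengths from a sample up to the soma.

        Returns 0.0 for soma samples.  The stem's attachment edge (soma
        node -> first dendritic node) is included.
        """
        origin = self.origin_ids
        total = 0.0
        cur = self.nodes[node_id]
        while cur.id not in origin and cur.parent != -1:
            par = self.nodes[cur.parent]
            total += float(np.linalg.norm(cur.pos - par.pos))
            cur = par
        return total

    # ------------------------------------------------------------------
    # section decomposition

    def sections(self) -> list[Section]:
        """Decompose the tree into sections.

        Sections partition all edges outside the soma cluster; a node
        with ``c >= 2`` children terminates its own section and starts
        ``c`` child sections (trifurcations allowed).  Section ids are
        assigned in a deterministic depth-first order and are stable for
        a given morphology, but are re-assigned after any edit.
        """
        origin = self.origin_ids
        stems = []
        for lm in sorted(origin):
            for c in self.children[lm]:
                if c not in origin:
                    stems.append((lm, c))
        out: list[Section] = []
        # stack of (landmark, first_node, parent_section_id, order)
        stack = [(lm, c, None, 0) for lm, c in reversed(stems)]
        while stack:
            lm, first, parent_sid, order = stack.pop()
            path = [lm, first]
            cur = first
            while len(self.children[cur]) == 1:
                cur = self.children[cur][0]
                path.append(cur)
            kids = self.children[cur]
            counts = Counter(self.nodes[n].type_code for n in path[1:])
            # dominant type; ties broken towards the smaller code
            dominant = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
            sid = len(out)
            out.append(
                Section(
                    section_id=sid,
                    node_path=tuple(path),
                    region=region_of_type(dominant),
                    is_terminal=len(kids) == 0,
                    parent_section=parent_sid,
                    branch_order=order,
                )
            )
            for k in reversed(kids):
                stack.append((cur, k, sid, order + 1))
        return out

    def section_length(self, section: Section) -> float:
        """Euclidean path length of a section (μm)."""
        pts = np.array([self.nodes[i].pos for i in section.node_path])
        return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))

    def branch_point_ids(self) -> list[int]:
        """Non-soma samples with two or more children."""
        soma = self.soma_ids
        return [
            nid
            for nid in sorted(self.nodes)
            if nid not in soma and len(self.children[nid]) >= 2
        ]

    # ------------------------------------------------------------------
    # serialization / re-indexing

    def _preorder_ids(self) -> list[int]:
        order = []
        stack = [self.root_id]
        while stack:
            nid = stack.pop()
            order.append(nid)
            stack.extend(reversed(self.children[nid]))
        return order

    def reindex(self) -> "Morphology":
        """Return a copy with ids renumbered 1..N in pre-order, so every
        parent precedes its children.  Derived morphometrics are
        unaffected."""
        order = self._preorder_ids()
        new_id = {old: i for i, old in enumerate(order, start=1)}
        nodes = {}
        for old in order:
            n = self.nodes[old]
            parent = -1 if n.parent == -1 else new_id[n.parent]
            nodes[new_id[old]] = Node(
                new_id[old], n.type_code, n.pos.copy(), n.radius, parent
            )
        return Morphology(nodes, new_id[self.root_id], self.provenance)

    def to_swc(self) -> str:
        return write_swc(self)

    # ------------------------------------------------------------------
    # mutators (used by the remodeling actions)

    def new_id(self) -> int:
        return max(self.nodes) + 1

    def add_node(
        self, type_code: int, pos: np.ndarray, radius: float, parent: int
    ) -> int:
        nid = self.new_id()
        self.nodes[nid] = Node(nid, type_code, np.asarray(pos, float), radius, parent)
        self.children[nid] = []
        self.children[parent].append(nid)
        return nid

    def delete_subtree(self, node_id: int) -> int:
        """Remove a node and all its descendants; returns count removed."""
        ids = self.subtree_ids(node_id)
        parent = self.nodes[node_id].parent
        if parent != -1:
            self.children[parent].remove(node_id)
        for nid in ids:
            del self.nodes[nid]
            del self.children[nid]
        return len(ids)

    def reparent(self, node_id: int, new_parent: int) -> None:
        old = self.nodes[node_id].parent
        if old != -1:
            self.children[old].remove(node_id)
        self.nodes[node_id].parent = new_parent
        self.children[new_parent].append(node_id)
        self.children[new_parent].sort()

    def translate_subtree(self, node_id: int, vec: np.ndarray) -> None:
        vec = np.asarray(vec, float)
        for nid in self.subtree_ids(node_id):
            self.nodes[nid].pos = self.nodes[nid].pos + vec


def build(records: Iterable[SWCRecord], source: Optional[str] = None) -> Morphology:
    """Build a validated :class:`Morphology` from SWC records."""
    return Morphology.from_records(records, source=source)


def loads(text: str) -> tuple[Morphology, ParseReport]:
    """Parse SWC text and build the morphology."""
    records, report = parse_swc(text)
    return Morphology.from_records(records), report


def load(path) -> Morphology:
    """Read an SWC file and build the morphology (parse warnings dropped;
    use :func:`remodkit.swc.read_swc` to inspect them)."""
    records, _ = read_swc(path)
    return Morphology.from_records(records, source=str(path))
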