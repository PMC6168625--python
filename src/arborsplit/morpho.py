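"""Neuron morphology data model.

A reconstruction is a rooted tree of nodes, each carrying a 3-D position in
physical units (micrometres), a radius and a parent pointer — the semantics of
the SWC interchange format.  This module provides the in-memory tree type,
SWC and legacy-VTK serialisation, and the tree surgery the tracing pipeline
needs: rerooting (reversing parent pointers along a path) and merging two
trees at a junction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NeuronNode",
    "NeuronTree",
    "SWCParseError",
    "TreeValidationError",
    "MergeError",
    "read_swc",
    "write_swc",
    "write_vtk",
    "reroot",
    "merge_trees",
]


class SWCParseError(ValueError):
    """Raised when an SWC file cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a node collection does not form a single rooted tree."""


class MergeError(ValueError):
    """Raised when two trees cannot be joined within the junction tolerance."""

    def __init__(self, message: str, gap: float):
        super().__init__(message)
        self.gap = gap


@dataclass(frozen=True)
class NeuronNode:
    """One SWC node: id, structure type code, position (μm), radius (μm), parent.

    ``parent_id`` is -1 for the root.  ``structure_type`` follows SWC column 2;
    0 (undefined) is the default since the tracer assigns no compartment labels.
    """

    id: int
    structure_type: int
    position: tuple[float, float, float]  # (x, y, z) in μm, SWC column order
    radius: float
    parent_id: int

    def __post_init__(self):
        if self.id <= 0:
            raise TreeValidationError(f"node id must be positive, got {self.id}")
        if self.radius < 0:
            raise TreeValidationError(f"node {self.id}: negative radius {self.radius}")
        if any(not math.isfinite(c) for c in self.position):
            raise TreeValidationError(f"node {self.id}: non-finite coordinate {self.position}")
        if not math.isfinite(self.radius):
            raise TreeValidationError(f"node {self.id}: non-finite radius")


class NeuronTree:
    """A validated rooted neuron tree.

    Nodes are kept in insertion order.  Construction validates the single-root,
    acyclic, connected invariants; every public operation returns a tree that
    satisfies them.
    """

    def __init__(self, nodes: list[NeuronNode], metadata: dict[str, str] | None = None):
        if not nodes:
            raise TreeValidationError("a neuron tree must contain at least one node")
        self.nodes: list[NeuronNode] = list(nodes)
        self.metadata: dict[str, str] = dict(metadata or {})
        self._by_id = {n.id: n for n in self.nodes}
        self._validate()

    # -- invariants ---------------------------------------------------------

    def _validate(self) -> None:
        if len(self._by_id) != len(self.nodes):
            seen: set[int] = set()
            for n in self.nodes:
                if n.id in seen:
                    raise TreeValidationError(f"duplicate node id {n.id}")
                seen.add(n.id)
        roots = [n for n in self.nodes if n.parent_id == -1]
        if len(roots) != 1:
            raise TreeValidationError(f"expected exactly one root, found {len(roots)}")
        self.root_id: int = roots[0].id
        for n in self.nodes:
            if n.parent_id != -1 and n.parent_id not in self._by_id:
                raise TreeValidationError(
                    f"node {n.id} references missing parent {n.parent_id}"
                )
        # acyclicity + connectivity: every node must reach the root
        for n in self.nodes:
            seen_path: set[int] = set()
            cur = n
            while cur.parent_id != -1:
                if cur.id in seen_path:
                    raise TreeValidationError(f"cycle detected at node {cur.id}")
                seen_path.add(cur.id)
                cur = self._by_id[cur.parent_id]
            if cur.id != self.root_id:
                raise TreeValidationError(f"node {n.id} is not connected to the root")

    # -- accessors ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, node_id: int) -> NeuronNode:
        try:
            return self._by_id[node_id]
        except KeyError:
            raise KeyError(f"no node with id {node_id}") from None

    def __contains__(self, node_id: int) -> bool:
        return node_id in self._by_id

    def children(self, node_id: int) -> list[int]:
        return [n.id for n in self.nodes if n.parent_id == node_id]

    def child_map(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {n.id: [] for n in self.nodes}
        for n in self.nodes:
            if n.parent_id != -1:
                out[n.parent_id].append(n.id)
        return out

    def positions(self) -> np.ndarray:
        """(N, 3) array of node positions in μm, in node order (x, y, z)."""
        return np.array([n.position for n in self.nodes], dtype=float)

    def edge_length(self, child_id: int) -> float:
        c = self.node(child_id)
        if c.parent_id == -1:
            return 0.0
        p = self.node(c.parent_id)
        return float(np.linalg.norm(np.subtract(c.position, p.position)))

    def cable_length(self) -> float:
        """Total length of all parent→child edges, μm."""
        return sum(self.edge_length(n.id) for n in self.nodes)

    def undirected_edges(self) -> set[frozenset[int]]:
        return {
            frozenset((n.id, n.parent_id)) for n in self.nodes if n.parent_id != -1
        }

    def terminals(self) -> list[int]:
        """Ids of childless nodes (includes the root only for a 1-node tree)."""
        cm = self.child_map()
        return [nid for nid, ch in cm.items() if not ch]

    def renumbered(self) -> "NeuronTree":
        """Consecutive ids 1..N in parent-before-child order."""
        order = self.topological_order()
        mapping = {old: i + 1 for i, old in enumerate(order)}
        nodes = [
            replace(
                self._by_id[old],
                id=mapping[old],
                parent_id=-1
                if self._by_id[old].parent_id == -1
                else mapping[self._by_id[old].parent_id],
            )
            for old in order
        ]
        return NeuronTree(nodes, metadata=self.metadata)

    def topological_order(self) -> list[int]:
        cm = self.child_map()
        order: list[int] = []
        stack = [self.root_id]
        while stack:
            nid = stack.pop()
            order.append(nid)
            stack.extend(reversed(cm[nid]))
        return order

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NeuronTree):
            return NotImplemented
        if len(self) != len(other):
            return False
        for a, b in zip(self.nodes, other.nodes):
            if (a.id, a.structure_type, a.parent_id) != (b.id, b.structure_type, b.parent_id):
                return False
            if not np.allclose(a.position, b.position, rtol=1e-6, atol=0.0):
                return False
            if not math.isclose(a.radius, b.radius, rel_tol=1e-6, abs_tol=1e-12):
                return False
        return True


# ---------------------------------------------------------------------------
# SWC I/O


def read_swc(path) -> NeuronTree:
    """Read an SWC file into a validated :class:`NeuronTree`.

    Accepts the common 7-column dialect: ``id type x y z radius parent``
    whitespace-separated, ``#`` comment lines.  Node order is preserved and
    comment lines are retained in ``metadata["comments"]``.
    """
    nodes: list[NeuronNode] = []
    comments: list[str] = []
    meta_pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ": " in body:  # metadata written as "# key: value"
                    k, v = body.split(": ", 1)
                    if " " not in k:
                        meta_pairs.append((k, v))
                        continue
                comments.append(line)
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SWCParseError(
                    f"{path}: line {lineno}: expected 7 columns, got {len(parts)}"
                )
            try:
                nid = int(parts[0])
                stype = int(parts[1])
                x, y, z, r = (float(v) for v in parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise SWCParseError(f"{path}: line {lineno}: {exc}") from None
            nodes.append(NeuronNode(nid, stype, (x, y, z), r, parent))
    if not nodes:
        raise SWCParseError(f"{path}: no data lines")
    meta = dict(meta_pairs)
    if comments:
        meta["comments"] = "\n".join(comments)
    return NeuronTree(nodes, metadata=meta)


def write_swc(tree: NeuronTree, path) -> None:
    """Write a tree as 7-column SWC, renumbered 1..N parent-before-child.

    Coordinates and radii are printed with 6 significant digits so a
    read-back reproduces the tree within 1e-6 relative tolerance.  The tree
    is validated (by construction) before anything is written.
    """
    t = tree.renumbered()
    lines = ["# SWC reconstruction written by arborsplit"]
    for key, value in sorted(t.metadata.items()):
        if key == "comments":
            continue
        lines.append(f"# {key}: {value}")
    for n in t.nodes:
        x, y, z = n.position
        lines.append(
            f"{n.id} {n.structure_type} {x:.6g} {y:.6g} {z:.6g} {n.radius:.6g} {n.parent_id}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_vtk(tree: NeuronTree, path) -> None:
    """Write a legacy-VTK (ASCII) polyline representation of the tree.

    Points are nodes, line cells are parent→child edges, and the node radius
    is attached as a point-data scalar, so the file loads directly in
    ParaView or any VTK viewer.
    """
    t = tree.renumbered()
    n = len(t)
    idx = {node.id: i for i, node in enumerate(t.nodes)}
    edges = [(idx[node.parent_id], idx[node.id]) for node in t.nodes if node.parent_id != -1]
    out = [
        "# vtk DataFile Version 3.0",
        "neuron reconstruction",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n} float",
    ]
    for node in t.nodes:
        x, y, z = node.position
        out.append(f"{x:.6g} {y:.6g} {z:.6g}")
    out.append(f"LINES {len(edges)} {3 * len(edges)}")
    for a, b in edges:
        out.append(f"2 {a} {b}")
    out.append(f"POINT_DATA {n}")
    out.append("SCALARS radius float 1")
    out.append("LOOKUP_TABLE default")
    for node in t.nodes:
        out.append(f"{node.radius:.6g}")
    with open(path, "w") as fh:
        fh.write("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Tree surgery


def reroot(tree: NeuronTree, new_root_id: int) -> NeuronTree:
    """Return a tree with the same undirected edges rooted at ``new_root_id``.

    Parent pointers are reversed along the old-root→new-root path; positions
    and radii are untouched.
    """
    if new_root_id not in tree:
        raise KeyError(f"no node with id {new_root_id}")
    if new_root_id == tree.root_id:
        return NeuronTree(tree.nodes, metadata=tree.metadata)
    # path from new root up to the old root
    path = [new_root_id]
    cur = tree.node(new_root_id)
    while cur.parent_id != -1:
        path.append(cur.parent_id)
        cur = tree.node(cur.parent_id)
    on_path = dict(zip(path, [-1] + path[:-1]))  # node -> its new parent
    nodes = [
        replace(n, parent_id=on_path[n.id]) if n.id in on_path else n
        for n in tree.nodes
    ]
    return NeuronTree(nodes, metadata=tree.metadata)


def merge_trees(a: NeuronTree, b: NeuronTree, junction_tolerance: float) -> NeuronTree:
    """Attach tree ``b`` to tree ``a`` at the a-node nearest to b's root.

    The root of ``b`` must lie within ``junction_tolerance`` μm (Euclidean) of
    some node of ``a``; ties between equidistant a-nodes are broken by smallest
    node id.  Ids of ``b`` are shifted to stay unique.  Raises
    :class:`MergeError` carrying the minimal gap if no a-node qualifies.
    """
    b_root = b.node(b.root_id)
    bpos = np.asarray(b_root.position)
    best_id, best_d = None, math.inf
    for n in a.nodes:
        d = float(np.linalg.norm(np.asarray(n.position) - bpos))
        if d < best_d - 1e-12 or (abs(d - best_d) <= 1e-12 and (best_id is None or n.id < best_id)):
            best_id, best_d = n.id, d
    if best_d > junction_tolerance:
        raise MergeError(
            f"no node of the main tree within {junction_tolerance} μm of the "
            f"attaching root (minimal gap {best_d:.6g} μm)",
            gap=best_d,
        )
    offset = max(n.id for n in a.nodes)
    shifted = [
        replace(
            n,
            id=n.id + offset,
            parent_id=best_id if n.parent_id == -1 else n.parent_id + offset,
        )
        for n in b.nodes
    ]
    meta = dict(a.metadata)
    for k, v in b.metadata.items():
        meta.setdefault(k, v)
    return NeuronTree(list(a.nodes) + shifted, metadata=meta)
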