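"""Reading, validating and writing SWC neuron reconstructions.

The SWC format stores a digitally reconstructed neuron as a whitespace
separated table with seven columns per node::

    node_id  type_code  x  y  z  radius  parent_id

Lines starting with ``#`` are comments.  ``parent_id`` is ``-1`` for a
root node; every other parent must refer to an existing node and the
parent relation must be acyclic.  Multiple roots (a forest) are accepted
with a warning because repository-downloaded reconstructions vary in
quality.
"""

from __future__ import annotations

import io
import os
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SwcNode",
    "NeuronMorphology",
    "SwcParseError",
    "SwcStructureError",
    "read_swc",
    "write_swc",
]


class SwcParseError(ValueError):
    """A line of an SWC file could not be parsed."""


class SwcStructureError(ValueError):
    """The node table violates the SWC tree invariants."""


@dataclass(frozen=True)
class SwcNode:
    """One row of an SWC node table.

    Coordinates and radius are in micrometres.  ``parent_id`` is ``-1``
    for a root.
    """

    node_id: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int

    def __post_init__(self) -> None:
        if self.node_id < 1:
            raise SwcStructureError(f"node_id must be >= 1, got {self.node_id}")
        if self.radius < 0:
            raise SwcStructureError(
                f"radius must be >= 0, got {self.radius} (node {self.node_id})"
            )
        if self.parent_id == self.node_id:
            raise SwcStructureError(f"node {self.node_id} is its own parent")


@dataclass
class NeuronMorphology:
    """An in-memory neuron reconstruction: an ordered SWC node table.

    Parameters
    ----------
    nodes:
        Nodes in file order.  Ids must be unique, parents must exist,
        and the parent relation must be acyclic.
    label:
        Optional class label (used by classification pipelines).
    source_path:
        Provenance of the node table, if read from disk.
    """

    nodes: list[SwcNode]
    label: str | None = None
    source_path: str | None = None
    _index: dict[int, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.nodes = list(self.nodes)
        if not self.nodes:
            raise SwcStructureError("a morphology must contain at least one node")
        self._index = {n.node_id: i for i, n in enumerate(self.nodes)}
        if len(self._index) != len(self.nodes):
            seen: set[int] = set()
            for n in self.nodes:
                if n.node_id in seen:
                    raise SwcStructureError(f"duplicate node_id {n.node_id}")
                seen.add(n.node_id)
        roots = [n for n in self.nodes if n.parent_id == -1]
        if not roots:
            raise SwcStructureError("no root node (parent_id == -1) present")
        if len(roots) > 1:
            warnings.warn(
                f"morphology has {len(roots)} roots; treating it as a forest",
                stacklevel=3,
            )
        for n in self.nodes:
            if n.parent_id != -1 and n.parent_id not in self._index:
                raise SwcStructureError(
                    f"node {n.node_id} refers to missing parent {n.parent_id}"
                )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # Iterative parent-chasing with memoisation: each node must reach
        # a root without revisiting itself.
        state: dict[int, int] = {}  # 0 = on current path, 1 = proven safe
        for start in self._index:
            path = []
            nid = start
            while nid != -1 and state.get(nid) != 1:
                if state.get(nid) == 0:
                    raise SwcStructureError(f"cycle detected through node {nid}")
                state[nid] = 0
                path.append(nid)
                nid = self.nodes[self._index[nid]].parent_id
            for p in path:
                state[p] = 1

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def node_by_id(self, node_id: int) -> SwcNode:
        return self.nodes[self._index[node_id]]

    def coordinates(self) -> np.ndarray:
        """Node coordinates as an ``(n, 3)`` float array, in file order."""
        return np.array([[n.x, n.y, n.z] for n in self.nodes], dtype=float)

    def with_coordinates(self, xyz: np.ndarray) -> "NeuronMorphology":
        """A copy of this morphology with replaced node coordinates."""
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.nodes), 3):
            raise ValueError(f"expected shape {(len(self.nodes), 3)}, got {xyz.shape}")
        nodes = [
            replace(n, x=float(p[0]), y=float(p[1]), z=float(p[2]))
            for n, p in zip(self.nodes, xyz)
        ]
        return NeuronMorphology(nodes, label=self.label, source_path=self.source_path)

    def segments(self) -> list[tuple[int, int]]:
        """Child–parent index pairs (positions into ``nodes``)."""
        return [
            (i, self._index[n.parent_id])
            for i, n in enumerate(self.nodes)
            if n.parent_id != -1
        ]

    def root_ids(self) -> list[int]:
        return [n.node_id for n in self.nodes if n.parent_id == -1]

    # --- simple morphometrics used by the synthetic-data checks ---

    def branch_point_count(self) -> int:
        """Number of nodes with more than one child."""
        children: dict[int, int] = {}
        for n in self.nodes:
            if n.parent_id != -1:
                children[n.parent_id] = children.get(n.parent_id, 0) + 1
        return sum(1 for c in children.values() if c > 1)

    def tip_count(self) -> int:
        """Number of terminal nodes (no children, not a root)."""
        parents = {n.parent_id for n in self.nodes if n.parent_id != -1}
        return sum(
            1 for n in self.nodes if n.node_id not in parents and n.parent_id != -1
        )

    def total_cable_length(self) -> float:
        """Sum of Euclidean child–parent segment lengths (µm)."""
        xyz = self.coordinates()
        segs = self.segments()
        if not segs:
            return 0.0
        ci, pi = zip(*segs)
        return float(np.linalg.norm(xyz[list(ci)] - xyz[list(pi)], axis=1).sum())


def _parse_lines(lines: Iterable[str]) -> list[SwcNode]:
    nodes = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise SwcParseError(
                f"line {lineno}: expected 7 columns, got {len(parts)}"
            )
        try:
            nid = int(parts[0])
            tcode = int(parts[1])
            x, y, z, radius = (float(v) for v in parts[2:6])
            pid = int(parts[6])
        except ValueError as exc:
            raise SwcParseError(f"line {lineno}: non-numeric field ({exc})") from None
        nodes.append(SwcNode(nid, tcode, x, y, z, radius, pid))
    return nodes


def read_swc(path_or_text: str | os.PathLike) -> NeuronMorphology:
    """Read an SWC file (or literal SWC text) into a :class:`NeuronMorphology`.

    ``path_or_text`` may be a filesystem path or a string containing the
    file contents (detected by the presence of a newline or by the path
    not existing).  Node order is preserved as read.
    """
    text: str
    source = None
    s = os.fspath(path_or_text)
    looks_like_path = "\n" not in s and (os.sep in s or s.endswith(".swc"))
    if "\n" not in s and os.path.exists(s):
        with open(s, "r", encoding="utf-8") as fh:
            text = fh.read()
        source = s
    elif looks_like_path:
        raise FileNotFoundError(f"SWC file not found: {s}")
    else:
        text = s
    nodes = _parse_lines(io.StringIO(text))
    if not nodes:
        raise SwcParseError("no node records found")
    return NeuronMorphology(nodes, source_path=source)


def write_swc(m: NeuronMorphology, path: str | os.PathLike) -> None:
    """Write a morphology as SWC text; round-trips through :func:`read_swc`."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# id type x y z radius parent\n")
        for n in m.nodes:
            fh.write(
                f"{n.node_id} {n.type_code} {n.x!r} {n.y!r} {n.z!r} "
                f"{n.radius!r} {n.parent_id}\n"
            )
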