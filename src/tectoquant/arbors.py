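"""Neuron arbor container and SWC-dialect input/output.

A :class:`NeuronArbor` is a rooted tree of 3-D points in micrometres.  The
root is the soma; every other node is a dendritic sample point connected to
its parent by a straight segment.  Node identities are stable integers, which
lets time-lapse analyses refer to the same terminal process across
reconstructions (see :mod:`tectoquant.dynamics`).

The on-disk format is the classic 7-column SWC text table::

    node_id  type  x  y  z  radius  parent_id

with ``parent_id = -1`` for the root and type codes 1 (soma) and 3
(dendrite).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

SOMA = 1
DENDRITE = 3

_COLUMNS = ["node_id", "type", "x", "y", "z", "radius", "parent_id"]


class ArborError(ValueError):
    """Raised for structurally invalid arbors or malformed SWC input."""


@dataclass
class NeuronArbor:
    """Rooted tree of 3-D nodes with optional persistent process identities.

    Parameters
    ----------
    nodes
        DataFrame with columns ``node_id, type, x, y, z, radius, parent_id``.
        Exactly one node must have ``parent_id == -1`` (the soma/root).
    process_ids
        Optional mapping from leaf ``node_id`` to a persistent terminal-process
        identity shared across the timepoints of a series.  When absent, the
        leaf node id itself serves as the identity.
    """

    nodes: pd.DataFrame
    process_ids: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = self.nodes[_COLUMNS].reset_index(drop=True)
        validate_arbor(self)

    # -- basic structure -------------------------------------------------
    @property
    def root_id(self) -> int:
        return int(self.nodes.loc[self.nodes["parent_id"] == -1, "node_id"].iloc[0])

    @property
    def soma_xyz(self) -> np.ndarray:
        row = self.nodes.loc[self.nodes["parent_id"] == -1].iloc[0]
        return np.array([row["x"], row["y"], row["z"]], dtype=float)

    def xyz(self) -> dict[int, np.ndarray]:
        return {
            int(r.node_id): np.array([r.x, r.y, r.z], dtype=float)
            for r in self.nodes.itertuples()
        }

    def children_map(self) -> dict[int, list[int]]:
        children: dict[int, list[int]] = {int(i): [] for i in self.nodes["node_id"]}
        for r in self.nodes.itertuples():
            if r.parent_id != -1:
                children[int(r.parent_id)].append(int(r.node_id))
        return children

    def parent_map(self) -> dict[int, int]:
        return {
            int(r.node_id): int(r.parent_id)
            for r in self.nodes.itertuples()
            if r.parent_id != -1
        }

    def edges_xyz(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (parent_coords, child_coords), each (n_edges, 3), in µm."""
        non_root = self.nodes[self.nodes["parent_id"] != -1]
        if len(non_root) == 0:
            return np.empty((0, 3)), np.empty((0, 3))
        coords = self.nodes.set_index("node_id")[["x", "y", "z"]]
        child = non_root[["x", "y", "z"]].to_numpy(dtype=float)
        parent = coords.loc[non_root["parent_id"].to_numpy()].to_numpy(dtype=float)
        return parent, child

    def leaf_ids(self) -> list[int]:
        """Non-soma nodes with no children, in ascending id order."""
        children = self.children_map()
        root = self.root_id
        return sorted(i for i, ch in children.items() if not ch and i != root)

    def copy(self) -> "NeuronArbor":
        return NeuronArbor(self.nodes.copy(), dict(self.process_ids))


def validate_arbor(arbor: NeuronArbor) -> None:
    nodes = arbor.nodes
    ids = nodes["node_id"].to_numpy()
    if len(ids) == 0:
        raise ArborError("arbor has no nodes")
    if len(np.unique(ids)) != len(ids):
        raise ArborError("duplicate node ids")
    roots = nodes.loc[nodes["parent_id"] == -1, "node_id"]
    if len(roots) != 1:
        raise ArborError(f"expected exactly one root, found {len(roots)}")
    known = set(int(i) for i in ids)
    for r in nodes.itertuples():
        if r.parent_id != -1 and int(r.parent_id) not in known:
            raise ArborError(f"node {int(r.node_id)} references undefined parent {int(r.parent_id)}")
    coords = nodes[["x", "y", "z"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ArborError("non-finite coordinates")
    if len(ids) > 1:
        g = nx.DiGraph()
        g.add_nodes_from(int(i) for i in ids)
        g.add_edges_from(
            (int(r.parent_id), int(r.node_id))
            for r in nodes.itertuples()
            if r.parent_id != -1
        )
        if not nx.is_arborescence(g):
            raise ArborError("parent references do not form a rooted tree")


def read_swc(path: str | Path) -> NeuronArbor:
    """Parse a 7-column SWC file into a :class:`NeuronArbor`.

    Malformed lines, duplicate ids, undefined parents, multiple roots and
    cycles all raise :class:`ArborError` naming the offending line.
    """
    rows = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise ArborError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
        try:
            rows.append(
                (
                    int(parts[0]),
                    int(parts[1]),
                    float(parts[2]),
                    float(parts[3]),
                    float(parts[4]),
                    float(parts[5]),
                    int(parts[6]),
                )
            )
        except ValueError as exc:
            raise ArborError(f"{path}:{lineno}: malformed value ({exc})") from None
    if not rows:
        raise ArborError(f"{path}: no nodes")
    nodes = pd.DataFrame(rows, columns=_COLUMNS)
    return NeuronArbor(nodes)


def write_swc(arbor: NeuronArbor, path: str | Path) -> None:
    """Write an arbor as SWC text, preserving coordinates to full precision."""
    lines = ["# node_id type x y z radius parent_id"]
    for r in arbor.nodes.itertuples():
        lines.append(
            f"{int(r.node_id)} {int(r.type)} {r.x!r} {r.y!r} {r.z!r} {r.radius!r} {int(r.parent_id)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def make_arbor(
    node_rows: list[tuple[int, int | None, float, float, float]],
    radius: float = 0.5,
    process_ids: dict[int, int] | None = None,
) -> NeuronArbor:
    """Build an arbor from ``(node_id, parent_id_or_None, x, y, z)`` rows.

    Convenience constructor used by the generators and tests; the first
    parentless node is typed as soma, the rest as dendrite.
    """
    rows = []
    for node_id, parent, x, y, z in node_rows:
        ntype = SOMA if parent is None else DENDRITE
        rows.append((node_id, ntype, x, y, z, radius, -1 if parent is None else parent))
    return NeuronArbor(pd.DataFrame(rows, columns=_COLUMNS), process_ids or {})
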