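"""SWC skeleton I/O and geometry: read/write, resampling, spherical cropping,
and the bidirectional structure distance used to score reconstruction agreement.

An SWC file stores a rooted tree of 3D points: one node per line with
``id type x y z radius parent``, parent ``-1`` for the root.  Coordinates are
micrometres in atlas space throughout this package.  Multi-node somas are
collapsed to a single root point on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

SOMA, AXON, BASAL_DENDRITE, APICAL_DENDRITE = 1, 2, 3, 4


class SWCError(ValueError):
    """Malformed SWC content (parse or structure problem)."""


@dataclass
class NeuronSkeleton:
    """A rooted tree of 3D nodes with radii.

    Nodes are stored positionally: ``parent[i]`` is the row index of node i's
    parent (-1 for the root).  ``ids`` keeps 1-based SWC identifiers for
    round-tripping.  The root is the soma after normalization.
    """

    neuron_id: str
    ids: np.ndarray        # (n,) int
    types: np.ndarray      # (n,) int
    xyz: np.ndarray        # (n, 3) float, µm
    radius: np.ndarray     # (n,) float, µm
    parent: np.ndarray     # (n,) int row index, -1 for root
    header: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        self.ids = np.asarray(self.ids, dtype=int)
        self.types = np.asarray(self.types, dtype=int)
        self.radius = np.asarray(self.radius, dtype=float)
        self.parent = np.asarray(self.parent, dtype=int)

    # -- basic structure -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    @property
    def root(self) -> int:
        (roots,) = np.nonzero(self.parent == -1)
        if len(roots) != 1:
            raise SWCError(f"{self.neuron_id}: expected one root, found {len(roots)}")
        return int(roots[0])

    @property
    def soma_xyz(self) -> np.ndarray:
        return self.xyz[self.root]

    def children(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                out[p].append(i)
        return out

    def segment_lengths(self) -> np.ndarray:
        """Length of each parent→node segment (0 for the root)."""
        lengths = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        lengths[has_parent] = np.linalg.norm(
            self.xyz[has_parent] - self.xyz[self.parent[has_parent]], axis=1
        )
        return lengths

    def total_length(self) -> float:
        return float(self.segment_lengths().sum())

    def validate(self) -> None:
        if self.n_nodes == 0:
            raise SWCError(f"{self.neuron_id}: empty skeleton")
        if not np.all(np.isfinite(self.xyz)):
            raise SWCError(f"{self.neuron_id}: non-finite coordinates")
        if np.any(self.radius < 0):
            raise SWCError(f"{self.neuron_id}: negative radius")
        root = self.root  # raises if not exactly one
        # every node must reach the root without revisiting (no cycles)
        depth = np.full(self.n_nodes, -1, dtype=int)
        depth[root] = 0
        for i in range(self.n_nodes):
            chain = []
            j = i
            while depth[j] < 0:
                chain.append(j)
                j = self.parent[j]
                if j < 0 or j >= self.n_nodes:
                    raise SWCError(f"{self.neuron_id}: dangling parent reference")
                if len(chain) > self.n_nodes:
                    raise SWCError(f"{self.neuron_id}: cycle in parent references")
            for k, node in enumerate(reversed(chain)):
                depth[node] = depth[j] + k + 1


# ---------------------------------------------------------------------------
# reading / writing


def read_swc(path: str | Path, neuron_id: str | None = None) -> NeuronSkeleton:
    """Read an SWC file into a normalized :class:`NeuronSkeleton`.

    Multi-node somas (several type-1 nodes) are collapsed to a single root at
    the first soma node's position; node ids are re-indexed contiguously and
    the root is placed first.
    """
    path = Path(path)
    header: list[str] = []
    rows: list[tuple[int, int, float, float, float, float, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                header.append(stripped)
                continue
            parts = stripped.split()
            if len(parts) != 7:
                raise SWCError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
            try:
                rows.append(
                    (int(parts[0]), int(parts[1]), float(parts[2]), float(parts[3]),
                     float(parts[4]), float(parts[5]), int(parts[6]))
                )
            except ValueError as exc:
                raise SWCError(f"{path}:{lineno}: {exc}") from exc
    if not rows:
        raise SWCError(f"{path}: no nodes")
    return from_rows(rows, neuron_id or path.stem, header)


def from_rows(
    rows: list[tuple[int, int, float, float, float, float, int]],
    neuron_id: str,
    header: list[str] | None = None,
) -> NeuronSkeleton:
    """Build a normalized skeleton from raw ``(id, type, x, y, z, r, parent)`` rows."""
    raw_ids = [r[0] for r in rows]
    if len(set(raw_ids)) != len(raw_ids):
        raise SWCError(f"{neuron_id}: duplicate node ids")
    index = {rid: i for i, rid in enumerate(raw_ids)}
    parent = np.empty(len(rows), dtype=int)
    for i, r in enumerate(rows):
        if r[6] == -1:
            parent[i] = -1
        elif r[6] in index:
            parent[i] = index[r[6]]
        else:
            raise SWCError(f"{neuron_id}: node {r[0]} references missing parent {r[6]}")
    skel = NeuronSkeleton(
        neuron_id=neuron_id,
        ids=np.array(raw_ids),
        types=np.array([r[1] for r in rows]),
        xyz=np.array([[r[2], r[3], r[4]] for r in rows]),
        radius=np.array([r[5] for r in rows]),
        parent=parent,
        header=list(header or []),
    )
    skel.validate()
    return _normalize(skel)


def _normalize(skel: NeuronSkeleton) -> NeuronSkeleton:
    """Collapse multi-node somas to one root and re-index depth-first, root first."""
    soma_nodes = np.nonzero(skel.types == SOMA)[0]
    if len(soma_nodes) > 1:
        keep_soma = int(soma_nodes[0])
        drop = {int(s) for s in soma_nodes if s != keep_soma}
        keep = [i for i in range(skel.n_nodes) if i not in drop]
        new_index = {old: k for k, old in enumerate(keep)}

        def resolved_parent(old: int) -> int:
            p = int(skel.parent[old])
            if p == -1:
                return -1
            while p in drop:
                p = int(skel.parent[p])
                if p == -1:
                    # ancestor chain was dropped soma nodes up to the root
                    return -1 if old == keep_soma else keep_soma
            return p

        parent = np.array(
            [
                -1 if resolved_parent(old) == -1
                else new_index[resolved_parent(old)]
                for old in keep
            ]
        )
        skel = NeuronSkeleton(
            neuron_id=skel.neuron_id,
            ids=skel.ids[keep],
            types=skel.types[keep],
            xyz=skel.xyz[keep],
            radius=skel.radius[keep],
            parent=parent,
            header=skel.header,
        )
        skel.validate()
    if len(soma_nodes) >= 1:
        soma_after = int(np.nonzero(skel.types == SOMA)[0][0])
        if skel.parent[soma_after] != -1:
            skel = _reroot(skel, soma_after)
    order = _dfs_order(skel)
    return _reindex(skel, order)


def _reroot(skel: NeuronSkeleton, new_root: int) -> NeuronSkeleton:
    """Reverse parent pointers along the path from ``new_root`` to the old root."""
    path = [new_root]
    while skel.parent[path[-1]] != -1:
        path.append(int(skel.parent[path[-1]]))
    parent = skel.parent.copy()
    parent[new_root] = -1
    for child, par in zip(path[:-1], path[1:]):
        parent[par] = child
    return replace(skel, parent=parent)


def _dfs_order(skel: NeuronSkeleton) -> list[int]:
    children = skel.children()
    order: list[int] = []
    stack = [skel.root]
    while stack:
        node = stack.pop()
        order.append(node)
        stack.extend(reversed(children[node]))
    if len(order) != skel.n_nodes:
        raise SWCError(f"{skel.neuron_id}: disconnected nodes present")
    return order


def _reindex(skel: NeuronSkeleton, order: list[int]) -> NeuronSkeleton:
    new_index = {old: k for k, old in enumerate(order)}
    parent = np.array(
        [-1 if skel.parent[old] == -1 else new_index[skel.parent[old]] for old in order]
    )
    return NeuronSkeleton(
        neuron_id=skel.neuron_id,
        ids=np.arange(1, len(order) + 1),
        types=skel.types[order],
        xyz=skel.xyz[order],
        radius=skel.radius[order],
        parent=parent,
        header=skel.header,
    )


def write_swc(skel: NeuronSkeleton, path: str | Path) -> None:
    """Write standard 7-column SWC; header comment lines are preserved."""
    with open(path, "w") as fh:
        for line in skel.header:
            fh.write(line + "\n")
        for i in range(skel.n_nodes):
            pid = -1 if skel.parent[i] == -1 else skel.ids[skel.parent[i]]
            x, y, z = skel.xyz[i]
            fh.write(
                f"{skel.ids[i]} {skel.types[i]} {x:.6f} {y:.6f} {z:.6f} "
                f"{skel.radius[i]:.6f} {pid}\n"
            )


# ---------------------------------------------------------------------------
# branch decomposition


def branch_paths(skel: NeuronSkeleton) -> list[list[int]]:
    """Maximal unbranched paths between breakpoints.

    Breakpoints are the root, bifurcations (nodes with >= 2 children) and
    tips.  Each returned path starts and ends at a breakpoint and contains the
    interior pass-through nodes in order.
    """
    children = skel.children()
    root = skel.root
    paths: list[list[int]] = []
    stack = [(root, c) for c in reversed(children[root])]
    while stack:
        start, node = stack.pop()
        path = [start, node]
        while len(children[node]) == 1:
            node = children[node][0]
            path.append(node)
        paths.append(path)
        for c in reversed(children[node]):
            stack.append((node, c))
    return paths


# ---------------------------------------------------------------------------
# resampling


def resample(skel: NeuronSkeleton, spacing: float = 2.0) -> NeuronSkeleton:
    """Resample each branch to uniform arc-length node spacing.

    Branch endpoints (soma, bifurcations, tips) are preserved exactly;
    interior nodes are placed every ``spacing`` µm along the branch polyline
    and radii are linearly interpolated.  The final gap on a branch may be
    shorter than ``spacing`` (endpoints are never moved).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if skel.n_nodes == 1:
        return skel
    root = skel.root
    new_xyz: list[np.ndarray] = [skel.xyz[root]]
    new_r: list[float] = [float(skel.radius[root])]
    new_t: list[int] = [int(skel.types[root])]
    new_parent: list[int] = [-1]
    # map old breakpoint index -> new index, so branches can attach
    bp_map = {root: 0}
    for path in branch_paths(skel):
        pts = skel.xyz[path]
        rad = skel.radius[path]
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        total = arc[-1]
        interior = np.arange(spacing, total, spacing)
        interior = interior[interior < total - 1e-9]
        samples = np.concatenate([interior, [total]])
        parent_new = bp_map[path[0]]
        btype = int(skel.types[path[-1]])
        for s in samples:
            j = int(np.searchsorted(arc, s, side="right") - 1)
            j = min(j, len(arc) - 2)
            t = 0.0 if seg[j] == 0 else (s - arc[j]) / seg[j]
            new_xyz.append(pts[j] * (1 - t) + pts[j + 1] * t)
            new_r.append(float(rad[j] * (1 - t) + rad[j + 1] * t))
            new_t.append(btype)
            new_parent.append(parent_new)
            parent_new = len(new_xyz) - 1
        bp_map[path[-1]] = parent_new
    out = NeuronSkeleton(
        neuron_id=skel.neuron_id,
        ids=np.arange(1, len(new_xyz) + 1),
        types=np.array(new_t),
        xyz=np.array(new_xyz),
        radius=np.array(new_r),
        parent=np.array(new_parent),
        header=skel.header,
    )
    return out


# ---------------------------------------------------------------------------
# spherical cropping


def crop_sphere(
    skel: NeuronSkeleton,
    radius: float = 100.0,
    discard_if_disconnected: bool = False,
) -> NeuronSkeleton | None:
    """Crop the skeleton to a sphere of ``radius`` µm around the soma.

    Only the soma-connected component inside the sphere is kept; a subtree
    whose path to the soma leaves the sphere is removed even if it re-enters.
    Segments crossing the boundary are truncated with a node inserted exactly
    on the sphere surface.

    With ``discard_if_disconnected`` the whole neuron is discarded (``None``
    returned) whenever cropping disconnects any in-sphere node from the soma.
    """
    center = skel.soma_xyz
    dist = np.linalg.norm(skel.xyz - center, axis=1)
    inside = dist <= radius + 1e-9
    children = skel.children()
    root = skel.root

    new_xyz: list[np.ndarray] = [skel.xyz[root]]
    new_r: list[float] = [float(skel.radius[root])]
    new_t: list[int] = [int(skel.types[root])]
    new_parent: list[int] = [-1]
    kept = {root: 0}
    dropped_inside = False

    stack = [(root, c) for c in reversed(children[root])]
    while stack:
        p_old, node = stack.pop()
        if p_old not in kept:
            # path already left the sphere: whole subtree goes
            if inside[node]:
                dropped_inside = True
            for c in children[node]:
                stack.append((node, c))
            continue
        if inside[node]:
            new_xyz.append(skel.xyz[node])
            new_r.append(float(skel.radius[node]))
            new_t.append(int(skel.types[node]))
            new_parent.append(kept[p_old])
            kept[node] = len(new_xyz) - 1
        else:
            # truncate the crossing segment on the sphere surface
            a, b = skel.xyz[p_old], skel.xyz[node]
            t = _sphere_exit(a - center, b - center, radius)
            if t > 1e-12:
                new_xyz.append(a * (1 - t) + b * t)
                new_r.append(float(skel.radius[p_old] * (1 - t) + skel.radius[node] * t))
                new_t.append(int(skel.types[node]))
                new_parent.append(kept[p_old])
        for c in children[node]:
            stack.append((node, c))

    if discard_if_disconnected and dropped_inside:
        return None
    return NeuronSkeleton(
        neuron_id=skel.neuron_id,
        ids=np.arange(1, len(new_xyz) + 1),
        types=np.array(new_t),
        xyz=np.array(new_xyz),
        radius=np.array(new_r),
        parent=np.array(new_parent),
        header=skel.header,
    )


def _sphere_exit(a: np.ndarray, b: np.ndarray, radius: float) -> float:
    """Parameter t in [0, 1] where segment a→b (soma-centred coords) exits |x| = radius."""
    d = b - a
    aa = float(d @ d)
    if aa == 0:
        return 0.0
    bb = 2.0 * float(a @ d)
    cc = float(a @ a) - radius * radius
    disc = bb * bb - 4 * aa * cc
    if disc < 0:
        return 0.0
    t = (-bb + np.sqrt(disc)) / (2 * aa)
    return float(np.clip(t, 0.0, 1.0))


# ---------------------------------------------------------------------------
# reconstruction agreement


def bidirectional_structure_distance(
    a: NeuronSkeleton, b: NeuronSkeleton, statistic: str = "mean"
) -> float:
    """Symmetric nearest-node distance between two skeletons (µm).

    For every node of ``a`` the distance to the nearest node of ``b`` is
    taken, and vice versa; the pooled distances are summarised by ``mean``
    or ``median``.  Skeletons should be resampled to comparable node density
    first.
    """
    if a.n_nodes == 0 or b.n_nodes == 0:
        raise SWCError("cannot compare empty skeletons")
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    d_ab, _ = cKDTree(b.xyz).query(a.xyz)
    d_ba, _ = cKDTree(a.xyz).query(b.xyz)
    pooled = np.concatenate([np.atleast_1d(d_ab), np.atleast_1d(d_ba)])
    return float(np.mean(pooled) if statistic == "mean" else np.median(pooled))
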