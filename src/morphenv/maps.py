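"""RGB feature maps and the slice-stretching coordinate transform.

Three selected features are z-scored, rank-equalized onto [0, 255] and used
as RGB channels; right-hemisphere points can be mirrored to the left for a
single-hemisphere display; points are projected onto 2D slices by per-pixel
maximum intensity.  Slice stretching unbends a curved 2D region (e.g. a
hippocampal slice) into path-distance coordinates along its medial skeleton.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import rankdata
from skimage.morphology import closing, skeletonize

from .atlas import AtlasVolume, VOXEL_SIZE_UM


# ---------------------------------------------------------------------------
# RGB channels


def equalize_channels(values: np.ndarray) -> np.ndarray:
    """z-score then rank-based histogram equalization of each column onto
    [0, 255] integers.  Rank order is preserved within each channel; a
    constant channel maps to mid-gray (128) with a warning."""
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values.reshape(-1, 1)
    if values.size == 0:
        raise ValueError("empty input")
    n = values.shape[0]
    out = np.empty_like(values)
    for c in range(values.shape[1]):
        col = values[:, c]
        if np.ptp(col) == 0:
            warnings.warn(f"channel {c} constant; set to 128")
            out[:, c] = 128
            continue
        z = (col - col.mean()) / col.std()
        ranks = rankdata(z, method="average")
        out[:, c] = np.round((ranks - 1) / (n - 1) * 255.0)
    return out.astype(np.uint8)


def mirror_hemisphere(xyz_um: np.ndarray, atlas: AtlasVolume) -> np.ndarray:
    """Reflect right-hemisphere points across the mid-z plane; involution on
    a symmetric point set, identity on the left hemisphere."""
    xyz = np.atleast_2d(np.asarray(xyz_um, dtype=float)).copy()
    mid = atlas.midline_um
    right = xyz[:, 2] > mid
    xyz[right, 2] = 2 * mid - xyz[right, 2]
    return xyz


_AXIS = {"coronal": 0, "horizontal": 1, "sagittal": 2}


def render_slice(
    xyz_um: np.ndarray,
    rgb: np.ndarray,
    axis: str,
    center_um: float,
    half_width_um: float = 500.0,
    shape: tuple[int, int] | None = None,
    pixel_um: float = VOXEL_SIZE_UM,
) -> np.ndarray:
    """Maximum-intensity projection of colored points onto one slice.

    Points within ``half_width_um`` of the slice plane are projected; each
    pixel keeps the channel-wise maximum of the points that land on it.
    """
    if axis not in _AXIS:
        raise ValueError(f"axis must be one of {sorted(_AXIS)}")
    a = _AXIS[axis]
    xyz = np.atleast_2d(np.asarray(xyz_um, dtype=float))
    rgb = np.atleast_2d(np.asarray(rgb))
    keep = np.abs(xyz[:, a] - center_um) <= half_width_um
    others = [i for i in range(3) if i != a]
    pts = xyz[keep][:, others]
    colors = rgb[keep]
    if shape is None:
        extent = xyz[:, others].max(axis=0) if len(xyz) else np.zeros(2)
        shape = tuple(int(np.floor(e / pixel_um)) + 1 for e in extent)
    img = np.zeros((*shape, 3), dtype=np.uint8)
    if len(pts) == 0:
        warnings.warn("no points within the slice slab")
        return img
    ij = np.floor(pts / pixel_um).astype(int)
    inside = np.all((ij >= 0) & (ij < np.array(shape)), axis=1)
    for (i, j), c in zip(ij[inside], colors[inside]):
        img[i, j] = np.maximum(img[i, j], c)
    return img


# ---------------------------------------------------------------------------
# slice stretching


def _skeleton_path(mask: np.ndarray) -> np.ndarray:
    """Ordered pixel coordinates of the pruned skeleton of a 2D mask.

    The mask is closed with a 5-pixel square, thinned, and terminal branches
    are removed shortest-first until a simple path remains.
    """
    closed = closing(mask.astype(bool), footprint=np.ones((5, 5)))
    from scipy import ndimage

    n_comp = ndimage.label(closed)[1]
    if n_comp != 1:
        raise ValueError(f"mask must be a single connected blob (got {n_comp})")
    skel = skeletonize(closed)
    pix = {tuple(p) for p in np.argwhere(skel)}
    if len(pix) < 2:
        raise ValueError("skeleton degenerated to a point")

    def neighbors(p):
        return [
            (p[0] + di, p[1] + dj)
            for di in (-1, 0, 1)
            for dj in (-1, 0, 1)
            if (di, dj) != (0, 0) and (p[0] + di, p[1] + dj) in pix
        ]

    # prune: iteratively remove the shortest terminal branch until only two
    # endpoints remain
    while True:
        deg = {p: len(neighbors(p)) for p in pix}
        ends = [p for p in pix if deg[p] == 1]
        if len(pix) < 2:
            raise ValueError("skeleton degenerated to a point")
        if len(ends) <= 2 and all(d <= 2 for d in deg.values()):
            break
        # walk each terminal branch to its junction; drop the shortest
        branches = []
        for e in sorted(ends):
            branch = [e]
            prev, cur = None, e
            while True:
                nxt = [q for q in neighbors(cur) if q != prev]
                if len(nxt) != 1:
                    break
                prev, cur = cur, nxt[0]
                if len(neighbors(cur)) > 2:
                    break
                branch.append(cur)
            branches.append(branch)
        branches.sort(key=lambda b: (len(b), b[0]))
        for p in branches[0]:
            pix.discard(p)
        if len(pix) < 2:
            raise ValueError("skeleton degenerated to a point")

    # order the path from one endpoint to the other
    deg = {p: len(neighbors(p)) for p in pix}
    ends = sorted(p for p in pix if deg[p] == 1)
    if not ends:  # closed loop: break it at an arbitrary pixel
        ends = [sorted(pix)[0]]
    path = [ends[0]]
    prev = None
    while True:
        nxt = [q for q in neighbors(path[-1]) if q != prev]
        if not nxt:
            break
        prev = path[-1]
        path.append(nxt[0])
        if len(path) > len(pix):
            break
    return np.array(path, dtype=float)


def _extend_to_boundary(path: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Extend both path ends along their terminal tangents to the mask edge."""
    closed = closing(mask.astype(bool), footprint=np.ones((5, 5)))

    def extend(end: np.ndarray, tangent: np.ndarray) -> list[np.ndarray]:
        t = tangent / (np.linalg.norm(tangent) + 1e-12)
        pts = []
        p = end.copy()
        for _ in range(max(mask.shape) * 2):
            p = p + t
            ij = np.round(p).astype(int)
            if (
                ij[0] < 0 or ij[1] < 0
                or ij[0] >= mask.shape[0] or ij[1] >= mask.shape[1]
                or not closed[ij[0], ij[1]]
            ):
                break
            pts.append(p.copy())
        return pts

    k = min(5, len(path) - 1)
    head = extend(path[0], path[0] - path[k])
    tail = extend(path[-1], path[-1] - path[-1 - k])
    pieces = [np.array(head[::-1]).reshape(-1, 2), path, np.array(tail).reshape(-1, 2)]
    return np.vstack([p for p in pieces if len(p)])


def stretch_slice(
    mask: np.ndarray, points: np.ndarray, pixel_um: float = VOXEL_SIZE_UM
) -> tuple[np.ndarray, np.ndarray]:
    """Map 2D points (pixel coordinates) into path-stretched coordinates.

    Returns ``(xy, path)``: for each point, x is the along-path distance (µm)
    from the leftmost path terminus to the nearest path vertex (the anchor)
    and |y| is the distance (µm) to that anchor; the side of the path nearer
    the mask bounding-box center ("dorsal") gets negative y.
    """
    path = _extend_to_boundary(_skeleton_path(mask), mask)
    # orient so the path starts at the leftmost terminus (minimal column)
    if path[-1][1] < path[0][1]:
        path = path[::-1]
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])

    fg = np.argwhere(mask.astype(bool))
    bbox_center = (fg.min(axis=0) + fg.max(axis=0)) / 2.0

    pts = np.atleast_2d(np.asarray(points, dtype=float))
    _, anchor = cKDTree(path).query(pts)
    _, center_anchor = cKDTree(path).query(bbox_center)

    out = np.empty((len(pts), 2))
    for i, (p, a) in enumerate(zip(pts, anchor)):
        a = int(a)
        tangent = path[min(a + 1, len(path) - 1)] - path[max(a - 1, 0)]
        offset = p - path[a]
        dist = np.linalg.norm(offset)
        cross_pt = tangent[0] * offset[1] - tangent[1] * offset[0]
        c_off = bbox_center - path[int(center_anchor)]
        c_tan = (
            path[min(int(center_anchor) + 1, len(path) - 1)]
            - path[max(int(center_anchor) - 1, 0)]
        )
        cross_c = c_tan[0] * c_off[1] - c_tan[1] * c_off[0]
        dorsal = np.sign(cross_pt) == np.sign(cross_c) and cross_c != 0
        out[i, 0] = arc[a] * pixel_um
        out[i, 1] = (-dist if dorsal else dist) * pixel_um
    return out, path
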