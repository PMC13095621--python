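"""Mid-plane cross-section extraction.

An endplate surface is cut by the plane through the mesh centroid
orthogonal to the lateral axis (sagittal section) or to the
anterior–posterior axis (coronal section).  Per-triangle intersection
segments are chained into polylines by matching endpoints within
``CHAIN_TOL``; the polyline of greatest horizontal extent becomes the
profile, ordered posterior->anterior (sagittal) or right->left (coronal).

Profile coordinates are ``(s, h)``: ``s`` is the in-plane horizontal
position (mm, increasing toward anterior resp. patient-left) and ``h``
is the superior coordinate (mm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateSectionError, NoSectionError, ParameterError
from .mesh_io import TriangleMesh

#: chained polyline endpoints must match within this distance (mm)
CHAIN_TOL = 1e-6

#: a vertex within this distance of the cutting plane lies on it (mm)
ON_PLANE_TOL = 1e-9

END_LABELS = {"sagittal": ("posterior", "anterior"),
              "coronal": ("right", "left")}


@dataclass
class Profile:
    """Ordered planar polyline from a mid-plane cross-section."""

    s: np.ndarray
    h: np.ndarray
    plane: str                      # 'sagittal' or 'coronal'
    end_labels: tuple[str, str] = ("posterior", "anterior")

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float).ravel()
        self.h = np.asarray(self.h, dtype=float).ravel()
        if self.s.size != self.h.size:
            raise ParameterError("s and h must have equal length")
        if self.s.size < 3:
            raise DegenerateSectionError(
                f"profile needs >= 3 points, got {self.s.size}"
            )
        if not (np.isfinite(self.s).all() and np.isfinite(self.h).all()):
            raise ParameterError("profile coordinates must be finite")
        if not (np.diff(self.s) > 0).all():
            raise ParameterError("s must be strictly increasing")

    @property
    def n_points(self) -> int:
        return self.s.size

    @property
    def span(self) -> float:
        """Horizontal extent of the profile (mm)."""
        return float(self.s[-1] - self.s[0])

    def to_csv(self, path) -> None:
        pd.DataFrame({"s_mm": self.s, "h_mm": self.h}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, plane: str = "sagittal") -> "Profile":
        df = pd.read_csv(path)
        order = np.argsort(df.iloc[:, 0].to_numpy())
        return cls(df.iloc[order, 0].to_numpy(), df.iloc[order, 1].to_numpy(),
                   plane=plane, end_labels=END_LABELS[plane])


def plane_section_segments(mesh: TriangleMesh, axis: int, level: float) -> np.ndarray:
    """Intersection segments of the mesh with the plane ``coord[axis] == level``.

    Returns an (n, 2, 3) array of 3D segments, deduplicated.  Triangles
    exactly coplanar with the plane contribute their two longest edges;
    point contacts are dropped.
    """
    v, f = mesh.vertices, mesh.faces
    d = v[:, axis] - level
    on = np.abs(d) < ON_PLANE_TOL
    sgn = np.where(on, 0, np.sign(d))

    segs: list[tuple[np.ndarray, np.ndarray]] = []
    tri_sgn = sgn[f]
    n_on = (tri_sgn == 0).sum(axis=1)
    crossing = ~((tri_sgn >= 0).all(axis=1) | (tri_sgn <= 0).all(axis=1))
    candidates = np.flatnonzero(crossing | (n_on >= 2))

    for fi in candidates:
        idx = f[fi]
        s = sgn[idx]
        pts = v[idx]
        zero = np.flatnonzero(s == 0)
        if len(zero) == 3:
            # coplanar triangle: its two longest boundary edges
            edges = [(0, 1), (1, 2), (0, 2)]
            lengths = [np.linalg.norm(pts[a] - pts[b]) for a, b in edges]
            for a, b in [edges[i] for i in np.argsort(lengths)[-2:]]:
                segs.append((pts[a], pts[b]))
        elif len(zero) == 2:
            segs.append((pts[zero[0]], pts[zero[1]]))
        elif len(zero) == 1:
            others = [i for i in range(3) if i != zero[0]]
            if s[others[0]] * s[others[1]] < 0:
                a, b = others
                t = d[idx[a]] / (d[idx[a]] - d[idx[b]])
                segs.append((pts[zero[0]], pts[a] + t * (pts[b] - pts[a])))
            # single touching vertex: no segment
        else:
            cut = []
            for a, b in [(0, 1), (1, 2), (0, 2)]:
                if s[a] * s[b] < 0:
                    t = d[idx[a]] / (d[idx[a]] - d[idx[b]])
                    cut.append(pts[a] + t * (pts[b] - pts[a]))
            if len(cut) == 2:
                segs.append((cut[0], cut[1]))

    if not segs:
        return np.empty((0, 2, 3))

    arr = np.asarray(segs)
    # canonical endpoint order + quantized dedup (grid meshes produce exact twins)
    key = np.round(arr / CHAIN_TOL).astype(np.int64)
    flip = [tuple(k[0].tolist()) > tuple(k[1].tolist()) for k in key]
    arr[flip] = arr[flip][:, ::-1]
    key = np.round(arr / CHAIN_TOL).astype(np.int64).reshape(len(arr), -1)
    _, keep = np.unique(key, axis=0, return_index=True)
    arr = arr[np.sort(keep)]
    # drop zero-length segments
    lens = np.linalg.norm(arr[:, 1] - arr[:, 0], axis=1)
    return arr[lens > ON_PLANE_TOL]


def _chain_segments(segments: np.ndarray) -> list[np.ndarray]:
    """Chain segments into polylines by endpoint matching within CHAIN_TOL."""
    n = len(segments)
    keys = np.round(segments / CHAIN_TOL).astype(np.int64)
    node_of: dict[tuple, int] = {}
    ends = np.empty((n, 2), dtype=np.int64)
    for i in range(n):
        for j in (0, 1):
            k = tuple(keys[i, j].tolist())
            ends[i, j] = node_of.setdefault(k, len(node_of))

    adj: dict[int, list[tuple[int, int]]] = {}
    for i, (a, b) in enumerate(ends):
        adj.setdefault(int(a), []).append((i, int(b)))
        adj.setdefault(int(b), []).append((i, int(a)))

    used = np.zeros(n, dtype=bool)
    chains: list[np.ndarray] = []

    def walk(start_node: int) -> list[int]:
        path_nodes = [start_node]
        node = start_node
        while True:
            nxt = [(si, other) for si, other in adj[node] if not used[si]]
            if not nxt:
                break
            si, other = nxt[0]
            used[si] = True
            path_nodes.append(other)
            node = other
        return path_nodes

    # open chains first (start from odd-degree nodes), then loops
    degree = {node: sum(1 for si, _ in lst) for node, lst in adj.items()}
    point_of = {}
    for i in range(n):
        for j in (0, 1):
            point_of[int(ends[i, j])] = segments[i, j]

    for start in [nd for nd, dg in degree.items() if dg % 2 == 1]:
        if all(used[si] for si, _ in adj[start]):
            continue
        nodes = walk(start)
        if len(nodes) > 1:
            chains.append(np.asarray([point_of[nd] for nd in nodes]))
    for start in adj:
        if all(used[si] for si, _ in adj[start]):
            continue
        nodes = walk(start)
        if len(nodes) > 1:
            chains.append(np.asarray([point_of[nd] for nd in nodes]))
    return chains


def extract_profile(mesh: TriangleMesh, plane: str,
                    level: float | None = None) -> Profile:
    """Extract the mid-sagittal or mid-coronal profile of an endplate mesh.

    The cutting plane passes through the mesh centroid (override with
    ``level``, a coordinate along the cut-normal axis) orthogonal to the
    lateral axis (sagittal) or AP axis (coronal).  Of all chained
    intersection polylines the one with greatest horizontal extent is
    returned (ties broken by arc length), ordered posterior->anterior or
    right->left.
    """
    if plane not in END_LABELS:
        raise ParameterError(f"plane must be 'sagittal' or 'coronal', got {plane!r}")
    frame = mesh.frame
    normal_axis = frame.axis_index("lateral" if plane == "sagittal" else "ap")
    # horizontal in-plane axis: AP for sagittal, lateral for coronal
    s_name = "ap" if plane == "sagittal" else "lateral"
    s_axis, s_sign = frame.axis_index(s_name), frame.axis_sign(s_name)
    h_axis, h_sign = frame.axis_index("si"), frame.axis_sign("si")

    if level is None:
        level = float(mesh.centroid()[normal_axis])

    segments = plane_section_segments(mesh, normal_axis, level)
    if len(segments) == 0:
        raise NoSectionError(
            f"plane {plane} at level {level:.3f} does not intersect the mesh"
        )

    chains = _chain_segments(segments)
    best, best_key = None, None
    for chain in chains:
        s = s_sign * chain[:, s_axis]
        extent = float(s.max() - s.min())
        arclen = float(np.linalg.norm(np.diff(chain, axis=0), axis=1).sum())
        key = (extent, arclen)
        if best_key is None or key > best_key:
            best, best_key = chain, key

    s = s_sign * best[:, s_axis]
    h = h_sign * best[:, h_axis]
    if s[0] > s[-1]:
        s, h = s[::-1], h[::-1]
    # collapse chaining duplicates; a height-field section is monotone in s
    keep = np.concatenate([[True], np.diff(s) > ON_PLANE_TOL])
    s, h = s[keep], h[keep]
    if s.size < 3:
        raise DegenerateSectionError(
            f"longest {plane} section has only {s.size} points"
        )
    if not (np.diff(s) > 0).all():
        raise DegenerateSectionError(
            f"{plane} section folds back on itself; not a height-field profile"
        )
    return Profile(s, h, plane=plane, end_labels=END_LABELS[plane])
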