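"""Triangle-mesh container and STL input/output.

Endplate surfaces arrive as STL files (ASCII or binary).  STL carries no
units and no anatomical axes, so the package fixes millimetres and attaches
an :class:`AnatomicalFrame` declaring which coordinate component points
toward patient-left, anterior and superior.  The default frame is
``+x`` left, ``+y`` anterior, ``+z`` superior.

STL stores each facet independently; shared vertices are duplicated in the
file.  :func:`read_stl` merges duplicates within ``MERGE_TOL`` (1e-6 mm) so
that cross-section segments can be chained across facet boundaries.
"""

from __future__ import annotations

import io
import struct
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .errors import EmptyMeshError, MeshFormatError, ParameterError

#: vertices closer than this (mm) are considered the same point
MERGE_TOL = 1e-6

#: triangles with area below this (mm^2) are flagged as degenerate
DEGENERATE_AREA = 1e-9

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class AnatomicalFrame:
    """Maps anatomical directions onto mesh coordinate components.

    Each field is a signed axis name such as ``"+x"`` or ``"-z"``:
    ``lateral`` points toward the patient's left, ``ap`` toward anterior,
    ``si`` toward superior.  The three fields must name three distinct
    components.
    """

    lateral: str = "+x"
    ap: str = "+y"
    si: str = "+z"

    def __post_init__(self):
        comps = []
        for name in (self.lateral, self.ap, self.si):
            if len(name) != 2 or name[0] not in "+-" or name[1] not in _AXES:
                raise ParameterError(
                    f"axis spec {name!r} must be one of +x,-x,+y,-y,+z,-z"
                )
            comps.append(name[1])
        if len(set(comps)) != 3:
            raise ParameterError(
                f"frame axes must be distinct components, got {comps}"
            )

    def axis_index(self, which: str) -> int:
        """Component index (0..2) of 'lateral', 'ap' or 'si'."""
        return _AXES[getattr(self, which)[1]]

    def axis_sign(self, which: str) -> float:
        return 1.0 if getattr(self, which)[0] == "+" else -1.0

    @classmethod
    def from_string(cls, text: str) -> "AnatomicalFrame":
        """Parse ``"lateral=+x,ap=+y,si=+z"``."""
        kwargs = {}
        for part in text.split(","):
            key, _, val = part.strip().partition("=")
            if key not in ("lateral", "ap", "si"):
                raise ParameterError(f"unknown frame key {key!r}")
            kwargs[key] = val
        return cls(**kwargs)


@dataclass
class TriangleMesh:
    """A triangulated surface: vertices in mm plus faces (vertex-index triples)."""

    vertices: np.ndarray
    faces: np.ndarray
    frame: AnatomicalFrame = field(default_factory=AnatomicalFrame)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def centroid(self) -> np.ndarray:
        """Mean vertex position (mm)."""
        return self.vertices.mean(axis=0)

    def translated(self, offset) -> "TriangleMesh":
        return TriangleMesh(self.vertices + np.asarray(offset, float),
                            self.faces.copy(), self.frame)


@dataclass
class ValidationFinding:
    kind: str          # 'index', 'degenerate', 'nonfinite'
    detail: str


@dataclass
class ValidationReport:
    ok: bool
    findings: list[ValidationFinding]


def validate_mesh(mesh: TriangleMesh) -> ValidationReport:
    """Check index bounds, triangle degeneracy and coordinate finiteness.

    Always returns a report; ``ok`` is true iff no findings.
    """
    findings: list[ValidationFinding] = []
    v, f = mesh.vertices, mesh.faces

    bad = ~np.isfinite(v).all(axis=1)
    for i in np.flatnonzero(bad):
        findings.append(ValidationFinding("nonfinite", f"vertex {i} is non-finite"))

    if len(f):
        out = (f < 0) | (f >= len(v))
        for i in np.flatnonzero(out.any(axis=1)):
            findings.append(
                ValidationFinding("index", f"face {i} references vertex out of range")
            )
        ok_idx = ~out.any(axis=1)
        rep = (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
        for i in np.flatnonzero(rep):
            findings.append(
                ValidationFinding("degenerate", f"face {i} repeats a vertex index")
            )
        # area test only where indices are valid and distinct
        cand = np.flatnonzero(ok_idx & ~rep)
        if len(cand) and not bad.any():
            tri = v[f[cand]]
            areas = 0.5 * np.linalg.norm(
                np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
            )
            for i, a in zip(cand, areas):
                if a < DEGENERATE_AREA:
                    findings.append(
                        ValidationFinding(
                            "degenerate", f"face {i} has area {a:.3e} mm^2"
                        )
                    )
    return ValidationReport(ok=not findings, findings=findings)


def _merge_vertices(vertices: np.ndarray, faces: np.ndarray):
    """Merge vertices that quantize to the same MERGE_TOL cell; drop duplicate faces."""
    key = np.round(vertices / MERGE_TOL).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    merged_v = vertices[first]
    merged_f = inverse[faces]
    # drop exact duplicate faces (same vertex set)
    sorted_f = np.sort(merged_f, axis=1)
    _, keep = np.unique(sorted_f, axis=0, return_index=True)
    merged_f = merged_f[np.sort(keep)]
    return merged_v, merged_f


def _probe_ascii(head: bytes) -> bool:
    """A file beginning with 'solid' is ASCII only if facet records follow."""
    if not head.lstrip().lower().startswith(b"solid"):
        return False
    return b"facet" in head.lower() or b"endsolid" in head.lower()


def read_stl(path, frame: AnatomicalFrame | None = None) -> TriangleMesh:
    """Read an ASCII or binary STL file into a :class:`TriangleMesh`.

    The dialect is auto-detected: a file starting with ``solid`` is probed
    for ASCII facet records before falling back to binary.  Duplicate
    vertices within 1e-6 mm are merged and exact duplicate facets dropped.

    Raises :class:`MeshFormatError` (naming the byte offset) for truncated
    or corrupt files and :class:`EmptyMeshError` for facet-free files.
    """
    frame = frame or AnatomicalFrame()
    with open(path, "rb") as fh:
        raw = fh.read()

    if len(raw) == 0:
        raise EmptyMeshError(f"{path}: empty file")

    is_ascii = _probe_ascii(raw[:4096])
    if not is_ascii:
        if len(raw) < 84:
            raise MeshFormatError(
                f"{path}: binary STL shorter than the 84-byte header",
                byte_offset=len(raw),
            )
        (n_facets,) = struct.unpack("<I", raw[80:84])
        expected = 84 + 50 * n_facets
        if len(raw) < expected:
            complete = (len(raw) - 84) // 50
            raise MeshFormatError(
                f"{path}: truncated facet block, header declares {n_facets} "
                f"facets but only {complete} are complete",
                byte_offset=84 + 50 * complete,
            )
        if n_facets == 0:
            raise EmptyMeshError(f"{path}: binary STL declares zero facets")

    try:
        loaded = trimesh.exchange.stl.load_stl(io.BytesIO(raw))
    except Exception as exc:  # malformed ASCII body etc.
        raise MeshFormatError(f"{path}: unparseable STL ({exc})") from exc

    vertices = np.asarray(loaded["vertices"], dtype=float)
    faces = np.asarray(loaded["faces"], dtype=np.int64)
    if len(faces) == 0:
        raise EmptyMeshError(f"{path}: no facets")

    vertices, faces = _merge_vertices(vertices, faces)
    return TriangleMesh(vertices, faces, frame)


def write_stl(mesh: TriangleMesh, path, dialect: str = "binary") -> None:
    """Write a mesh as STL; ``dialect`` is ``"ascii"`` or ``"binary"``.

    The mesh must pass :func:`validate_mesh`.  Binary files follow the
    84-byte-header + 50-byte-facet layout; coordinates are stored at
    float32 precision (an STL format property).
    """
    if dialect not in ("ascii", "binary"):
        raise ParameterError(f"dialect must be 'ascii' or 'binary', got {dialect!r}")
    report = validate_mesh(mesh)
    if not report.ok:
        msgs = "; ".join(f.detail for f in report.findings[:5])
        raise ParameterError(f"refusing to write invalid mesh: {msgs}")

    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    file_type = "stl" if dialect == "binary" else "stl_ascii"
    data = trimesh.exchange.stl.export_stl(tm) if dialect == "binary" \
        else trimesh.exchange.stl.export_stl_ascii(tm).encode()
    _ = file_type
    with open(path, "wb") as fh:
        fh.write(data)
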