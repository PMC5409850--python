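"""Surface geometry and ROI label containers, plus the text formats they travel in.

All vertex indices are **0-based** throughout the package, matching the native
convention of FreeSurfer ASCII ``.label`` files.  Hemispheres are fully
independent: no operation in this package ever mixes left- and
right-hemisphere vertex sets.  Coordinates carried in label files are
round-tripped but never used for set arithmetic — after alignment to a common
template mesh, overlap is purely index-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import trimesh as _trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "Hemisphere",
    "TriangleMesh",
    "RoiLabel",
    "Cohort",
    "ProbabilisticMap",
    "LabelParseError",
    "read_label",
    "write_label",
    "read_mesh",
    "write_mesh",
    "vertex_neighbors",
    "vertex_areas",
]


class Hemisphere(str, Enum):
    LEFT = "left"
    RIGHT = "right"


def _as_hemisphere(h: "Hemisphere | str") -> Hemisphere:
    return h if isinstance(h, Hemisphere) else Hemisphere(h)


class LabelParseError(ValueError):
    """Raised when a label or surface file cannot be parsed; names the line."""


@dataclass(frozen=True)
class TriangleMesh:
    """A triangulated surface: vertex coordinates (mm) and 0-based face triples.

    The mesh is validated on construction: every face index must be a valid
    vertex index and each face must have three distinct vertices.  A mesh that
    is not a single connected component is accepted with a warning — patch
    growth and adjacency still work per component.
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError(f"vertices must be (n, 3), got {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValueError(f"faces must be (m, 3) triangles, got {f.shape}")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise ValueError("face index out of range for vertex array")
        if f.size and np.any(
            (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
        ):
            raise ValueError("degenerate face with repeated vertex")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)
        if f.size and self._n_components() > 1:
            warnings.warn(
                f"mesh {self.name or '<unnamed>'} is not a single connected "
                "component",
                stacklevel=2,
            )

    def _n_components(self) -> int:
        i = np.concatenate([self.faces[:, 0], self.faces[:, 1], self.faces[:, 2]])
        j = np.concatenate([self.faces[:, 1], self.faces[:, 2], self.faces[:, 0]])
        adj = coo_matrix(
            (np.ones(len(i)), (i, j)), shape=(self.n_vertices, self.n_vertices)
        )
        n, _ = connected_components(adj, directed=False)
        return int(n)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)


@dataclass(frozen=True)
class RoiLabel:
    """One subject's one ROI as a set of 0-based vertex indices on a mesh.

    ``vertex_set`` is non-empty and duplicate-free (set semantics).  Optional
    per-vertex values (e.g. probabilities) survive the label-file round trip.
    """

    subject_id: str
    roi_id: str
    hemisphere: Hemisphere
    vertex_set: frozenset[int]
    values: Mapping[int, float] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "hemisphere", _as_hemisphere(self.hemisphere))
        vs = frozenset(int(v) for v in self.vertex_set)
        if not vs:
            raise ValueError(
                f"empty vertex_set for {self.subject_id}/{self.roi_id}"
            )
        if min(vs) < 0:
            raise ValueError("negative vertex index")
        object.__setattr__(self, "vertex_set", vs)

    def validate_against(self, mesh: TriangleMesh) -> None:
        if max(self.vertex_set) >= mesh.n_vertices:
            raise ValueError(
                f"label {self.subject_id}/{self.roi_id} references vertex "
                f"{max(self.vertex_set)} but mesh has {mesh.n_vertices} vertices"
            )

    def indices(self) -> np.ndarray:
        """Sorted index array view of the vertex set."""
        return np.fromiter(sorted(self.vertex_set), dtype=np.int64)

    def __len__(self) -> int:
        return len(self.vertex_set)


@dataclass
class Cohort:
    """A full study design: subjects x ROIs x hemispheres on one mesh.

    ``labels`` maps every (subject_id, roi_id, hemisphere) combination to a
    :class:`RoiLabel` or to ``None`` — missing combinations are first-class
    (some brains lack particular ROIs) and are excluded, not silently dropped,
    by downstream group-map and fold construction.
    """

    mesh: TriangleMesh
    subjects: list[str]
    rois: list[str]
    hemispheres: list[Hemisphere]
    condition: str
    labels: dict[tuple[str, str, Hemisphere], RoiLabel | None] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        self.hemispheres = [_as_hemisphere(h) for h in self.hemispheres]
        fixed: dict[tuple[str, str, Hemisphere], RoiLabel | None] = {}
        for (s, r, h), lab in self.labels.items():
            h = _as_hemisphere(h)
            if s not in self.subjects:
                raise ValueError(f"label subject {s!r} not in subject list")
            if r not in self.rois:
                raise ValueError(f"label roi {r!r} not in roi list")
            if h not in self.hemispheres:
                raise ValueError(f"label hemisphere {h} not in hemisphere list")
            if lab is not None:
                lab.validate_against(self.mesh)
            fixed[(s, r, h)] = lab
        self.labels = fixed

    def get(self, subject: str, roi: str, hemi: "Hemisphere | str") -> RoiLabel | None:
        return self.labels.get((subject, roi, _as_hemisphere(hemi)))

    def subjects_with(self, roi: str, hemi: "Hemisphere | str") -> list[str]:
        """Subjects possessing this ROI, in cohort subject order."""
        h = _as_hemisphere(hemi)
        return [s for s in self.subjects if self.labels.get((s, roi, h)) is not None]

    def missing(self) -> list[tuple[str, str, Hemisphere]]:
        return [k for k, v in self.labels.items() if v is None]


@dataclass(frozen=True)
class ProbabilisticMap:
    """Per-vertex subject counts and fractions for one ROI.

    ``values`` is exactly ``counts / n_subjects``; the support (counts > 0)
    must be non-empty.
    """

    roi_id: str
    hemisphere: Hemisphere
    condition: str
    n_subjects: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "hemisphere", _as_hemisphere(self.hemisphere))
        c = np.asarray(self.counts, dtype=np.int64)
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if c.min(initial=0) < 0 or c.max(initial=0) > self.n_subjects:
            raise ValueError("counts outside [0, n_subjects]")
        if not np.any(c > 0):
            raise ValueError("probabilistic map has empty support")
        object.__setattr__(self, "counts", c)

    @property
    def values(self) -> np.ndarray:
        return self.counts / self.n_subjects

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(self.counts > 0)


# ---------------------------------------------------------------------------
# FreeSurfer ASCII label I/O


def read_label(
    path: "str | Path",
    mesh: TriangleMesh | None = None,
    *,
    subject_id: str = "",
    roi_id: str = "",
    hemisphere: "Hemisphere | str" = Hemisphere.LEFT,
) -> RoiLabel:
    """Read a FreeSurfer ASCII ``.label`` file.

    The format is one comment line, one vertex-count line, then one row per
    vertex: ``index x y z value``.  The count line must agree with the number
    of data rows; any malformed row raises :class:`LabelParseError` naming the
    line.  Indices are validated against ``mesh`` when given.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 2:
        raise LabelParseError(f"{path}: fewer than 2 lines")
    try:
        n = int(lines[1].split()[0])
    except (ValueError, IndexError) as e:
        raise LabelParseError(f"{path}: line 2: bad count line {lines[1]!r}") from e
    rows = [ln for ln in lines[2:] if ln.strip()]
    if len(rows) != n:
        raise LabelParseError(
            f"{path}: count line says {n} vertices but found {len(rows)} data rows"
        )
    indices: list[int] = []
    values: dict[int, float] = {}
    for k, ln in enumerate(rows, start=3):
        parts = ln.split()
        if len(parts) != 5:
            raise LabelParseError(f"{path}: line {k}: expected 5 fields, got {len(parts)}")
        try:
            idx = int(parts[0])
            _ = [float(p) for p in parts[1:4]]
            val = float(parts[4])
        except ValueError as e:
            raise LabelParseError(f"{path}: line {k}: malformed row {ln!r}") from e
        indices.append(idx)
        values[idx] = val
    label = RoiLabel(
        subject_id=subject_id,
        roi_id=roi_id,
        hemisphere=hemisphere,
        vertex_set=frozenset(indices),
        values=values,
    )
    if len(label.vertex_set) != len(indices):
        raise LabelParseError(f"{path}: duplicate vertex indices in label")
    if mesh is not None:
        label.validate_against(mesh)
    return label


def write_label(label: RoiLabel, mesh: TriangleMesh, path: "str | Path") -> None:
    """Write a FreeSurfer ASCII ``.label`` file.

    Coordinates come from ``mesh``; the value column is the label's per-vertex
    value when present, else 0.  Index and count content round-trip bit-exactly.
    """
    label.validate_against(mesh)
    path = Path(path)
    idx = sorted(label.vertex_set)
    lines = [
        f"#!ascii label {label.subject_id} {label.roi_id} {label.hemisphere.value}",
        f"{len(idx)}",
    ]
    for i in idx:
        x, y, z = mesh.vertices[i]
        v = 0.0 if label.values is None else float(label.values.get(i, 0.0))
        lines.append(f"{i}  {x:.6f}  {y:.6f}  {z:.6f} {v:.10g}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Mesh I/O: OFF and FreeSurfer ASCII surface dialects


def read_mesh(path: "str | Path", dialect: str | None = None) -> TriangleMesh:
    """Read a mesh from OFF or FreeSurfer ASCII surface (``.asc``) format.

    The dialect is declared by extension (``.off`` / ``.asc`` / ``.srf.asc``)
    or forced with ``dialect`` in {"off", "fs_ascii"}.  Non-triangular faces
    are an error.
    """
    path = Path(path)
    dialect = dialect or ("off" if path.suffix.lower() == ".off" else "fs_ascii")
    if dialect == "off":
        m = _trimesh.load(str(path), file_type="off", process=False)
        faces = np.asarray(m.faces)
        if faces.shape[1] != 3:
            raise LabelParseError(f"{path}: non-triangular face in OFF file")
        return TriangleMesh(np.asarray(m.vertices, float), faces, name=path.stem)
    if dialect == "fs_ascii":
        return _read_fs_ascii(path)
    raise ValueError(f"unknown mesh dialect {dialect!r}")


def _read_fs_ascii(path: Path) -> TriangleMesh:
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("#!ascii"):
        raise LabelParseError(f"{path}: missing '#!ascii' header")
    try:
        nv, nf = (int(x) for x in lines[1].split()[:2])
    except (ValueError, IndexError) as e:
        raise LabelParseError(f"{path}: line 2: bad vertex/face count line") from e
    if len(lines) < 2 + nv + nf:
        raise LabelParseError(f"{path}: truncated file")
    verts = np.empty((nv, 3), float)
    for i in range(nv):
        parts = lines[2 + i].split()
        if len(parts) < 3:
            raise LabelParseError(f"{path}: line {3 + i}: malformed vertex row")
        verts[i] = [float(p) for p in parts[:3]]
    faces = np.empty((nf, 3), np.int64)
    for i in range(nf):
        parts = lines[2 + nv + i].split()
        if len(parts) < 3:
            raise LabelParseError(f"{path}: line {3 + nv + i}: malformed face row")
        if len(parts) > 4:
            raise LabelParseError(f"{path}: line {3 + nv + i}: non-triangular face")
        faces[i] = [int(p) for p in parts[:3]]
    return TriangleMesh(verts, faces, name=path.stem)


def write_mesh(mesh: TriangleMesh, path: "str | Path", dialect: str | None = None) -> None:
    """Write a mesh in OFF or FreeSurfer ASCII surface format (by extension)."""
    path = Path(path)
    dialect = dialect or ("off" if path.suffix.lower() == ".off" else "fs_ascii")
    if dialect == "off":
        lines = ["OFF", f"{mesh.n_vertices} {mesh.n_faces} 0"]
        lines += [f"{x:.9g} {y:.9g} {z:.9g}" for x, y, z in mesh.vertices]
        lines += [f"3 {a} {b} {c}" for a, b, c in mesh.faces]
        path.write_text("\n".join(lines) + "\n")
    elif dialect == "fs_ascii":
        lines = [
            f"#!ascii version of {mesh.name or 'surface'}",
            f"{mesh.n_vertices} {mesh.n_faces}",
        ]
        lines += [f"{x:.9g}  {y:.9g}  {z:.9g}  0" for x, y, z in mesh.vertices]
        lines += [f"{a} {b} {c} 0" for a, b, c in mesh.faces]
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown mesh dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Mesh-derived structures


def vertex_neighbors(mesh: TriangleMesh) -> list[set[int]]:
    """Edge-sharing neighbor sets per vertex; symmetric, no self-loops."""
    nbrs: list[set[int]] = [set() for _ in range(mesh.n_vertices)]
    for a, b, c in mesh.faces:
        nbrs[a].update((b, c))
        nbrs[b].update((a, c))
        nbrs[c].update((a, b))
    return nbrs


def vertex_areas(mesh: TriangleMesh) -> np.ndarray:
    """Barycentric vertex areas: one third of each incident face's area."""
    v = mesh.vertices
    f = mesh.faces
    cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    face_area = 0.5 * np.linalg.norm(cross, axis=1)
    out = np.zeros(mesh.n_vertices)
    for k in range(3):
        np.add.at(out, f[:, k], face_area / 3.0)
    return out
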