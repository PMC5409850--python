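"""Synthetic multi-subject ROI cohorts on an icosphere.

The generator emulates the statistical structure the downstream analysis
assumes: K group-level ROI templates are geodesic patches (spherical caps) on
a common unit-sphere mesh, and each subject's version of a ROI is that patch
with its center displaced by a tangent-plane Gaussian perturbation and its
radius perturbed by a Gaussian — standing in for the residual inter-subject
misalignment left after curvature-driven surface registration to a template.
Two named conditions share templates and subjects but differ *only* in their
center-jitter SD, encoding the hypothesis that template choice changes
alignment precision without modeling registration itself.

Random streams are split per (subject, roi, condition) from one root seed
with a counter-based scheme, so adding a subject or reordering the ROI list
never perturbs other subjects' labels.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import trimesh as _trimesh
import yaml

from .surface import Cohort, Hemisphere, RoiLabel, TriangleMesh

__all__ = [
    "RoiSpec",
    "CohortConfig",
    "default_config",
    "make_icosphere",
    "geodesic_patch",
    "sample_subject_roi",
    "generate_cohort",
    "derive_second_parcellation",
    "cap_area",
    "cap_intersection_area",
]


@dataclass(frozen=True)
class RoiSpec:
    """One ROI template: an id, a unit center direction, a geodesic radius (rad)."""

    roi_id: str
    center: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        c = np.asarray(self.center, float)
        n = np.linalg.norm(c)
        if not np.isclose(n, 1.0, atol=1e-8):
            raise ValueError(f"roi {self.roi_id}: center must be a unit vector")
        if not 0 < self.radius < np.pi:
            raise ValueError(f"roi {self.roi_id}: radius must be in (0, pi)")

    @property
    def center_vec(self) -> np.ndarray:
        return np.asarray(self.center, float)


@dataclass(frozen=True)
class CohortConfig:
    """Full description of a synthetic cohort; the seed fixes everything.

    ``center_jitter_sd`` maps condition name -> tangent-plane SD in radians.
    ``missing`` lists (subject_index, roi_id) combinations to mark absent,
    emulating brains in which a region could not be identified.
    """

    subdiv: int = 4
    n_subjects: int = 9
    rois: tuple[RoiSpec, ...] = ()
    center_jitter_sd: dict[str, float] = field(
        default_factory=lambda: {"cba_pm": 0.05, "cba_fs": 0.10}
    )
    radius_jitter_sd: float = 0.02
    seed: int = 0
    hemisphere: Hemisphere = Hemisphere.LEFT
    missing: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        if self.subdiv < 0:
            raise ValueError("subdiv must be >= 0")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.radius_jitter_sd < 0:
            raise ValueError("radius_jitter_sd must be >= 0")
        if any(sd < 0 for sd in self.center_jitter_sd.values()):
            raise ValueError("center_jitter_sd must be >= 0")
        object.__setattr__(self, "hemisphere", Hemisphere(self.hemisphere))

    @property
    def conditions(self) -> list[str]:
        return list(self.center_jitter_sd)

    @property
    def subject_ids(self) -> list[str]:
        return [f"sub{i + 1:02d}" for i in range(self.n_subjects)]

    # -- YAML round trip -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "subdiv": self.subdiv,
            "n_subjects": self.n_subjects,
            "rois": [
                {"roi_id": r.roi_id, "center": list(r.center), "radius": r.radius}
                for r in self.rois
            ],
            "center_jitter_sd": dict(self.center_jitter_sd),
            "radius_jitter_sd": self.radius_jitter_sd,
            "seed": self.seed,
            "hemisphere": self.hemisphere.value,
            "missing": [list(m) for m in self.missing],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        return cls(
            subdiv=d["subdiv"],
            n_subjects=d["n_subjects"],
            rois=tuple(
                RoiSpec(r["roi_id"], tuple(r["center"]), r["radius"])
                for r in d["rois"]
            ),
            center_jitter_sd=dict(d["center_jitter_sd"]),
            radius_jitter_sd=d["radius_jitter_sd"],
            seed=d["seed"],
            hemisphere=Hemisphere(d["hemisphere"]),
            missing=tuple((int(s), str(r)) for s, r in d.get("missing", [])),
        )

    def to_yaml(self, path: "str | Path") -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "CohortConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _fibonacci_directions(k: int) -> np.ndarray:
    """k well-spread unit vectors (golden-angle spiral), for default templates."""
    i = np.arange(k) + 0.5
    phi = np.arccos(1 - 2 * i / k)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


_DEFAULT_ROI_IDS = ("hOc1", "hOc2", "hOc3v", "hOc4v", "FG1", "FG2", "FG3", "FG4")


def default_config(
    *,
    subdiv: int = 4,
    n_subjects: int = 9,
    n_rois: int = 8,
    seed: int = 0,
    hemisphere: Hemisphere = Hemisphere.LEFT,
    missing: tuple[tuple[int, str], ...] = (),
) -> CohortConfig:
    """The package's reference study design: 9 subjects x 8 ventral-stream-like
    ROIs on a subdiv-4 icosphere, two alignment conditions differing in jitter.

    ROI radii step from 0.30 rad down to 0.15 rad so the design mixes large
    early-visual-like patches with smaller higher-order ones.
    """
    dirs = _fibonacci_directions(max(n_rois, 2))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    radii = np.linspace(0.30, 0.15, n_rois)
    ids = [
        _DEFAULT_ROI_IDS[i] if i < len(_DEFAULT_ROI_IDS) else f"roi{i + 1}"
        for i in range(n_rois)
    ]
    rois = tuple(
        RoiSpec(ids[i], tuple(float(x) for x in dirs[i]), float(radii[i]))
        for i in range(n_rois)
    )
    return CohortConfig(
        subdiv=subdiv,
        n_subjects=n_subjects,
        rois=rois,
        seed=seed,
        hemisphere=hemisphere,
        missing=missing,
    )


# ---------------------------------------------------------------------------
# Geometry


def make_icosphere(subdiv: int) -> TriangleMesh:
    """Unit icosphere by repeated icosahedron subdivision: 10*4^subdiv + 2 vertices."""
    if subdiv < 0:
        raise ValueError("subdiv must be >= 0")
    m = _trimesh.creation.icosphere(subdivisions=subdiv, radius=1.0)
    return TriangleMesh(
        np.asarray(m.vertices, float), np.asarray(m.faces, np.int64),
        name=f"icosphere{subdiv}",
    )


def geodesic_patch(mesh: TriangleMesh, center: Sequence[float], radius: float) -> frozenset[int]:
    """Vertices within great-circle angle ``radius`` of ``center`` on the unit sphere.

    Always non-empty: the vertex nearest to ``center`` is included even when
    the radius is smaller than the mesh resolution.  ``radius = pi`` covers
    the whole sphere.
    """
    if not 0 < radius <= np.pi:
        raise ValueError("radius must be in (0, pi]")
    c = np.asarray(center, float)
    c = c / np.linalg.norm(c)
    v = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1, keepdims=True)
    ang = np.arccos(np.clip(v @ c, -1.0, 1.0))
    sel = set(np.flatnonzero(ang <= radius).tolist())
    sel.add(int(np.argmin(ang)))
    return frozenset(sel)


def cap_area(radius: float) -> float:
    """Closed-form area of a spherical cap of angular radius r: 2*pi*(1 - cos r)."""
    return 2 * np.pi * (1 - np.cos(radius))


def cap_intersection_area(alpha: float, beta: float, gamma: float) -> float:
    """Closed-form area of the intersection (lens) of two spherical caps.

    Caps of angular radii ``alpha`` and ``beta`` on the unit sphere, centers
    separated by angle ``gamma``.  Derived by Gauss-Bonnet over the lens: the
    two boundary arcs are small circles with geodesic curvature cot(r), and
    the exterior-angle term reduces to the spherical-triangle angle at the
    crossing points.
    """
    if gamma >= alpha + beta:
        return 0.0
    if gamma <= abs(alpha - beta):
        return cap_area(min(alpha, beta))
    sa, sb, sg = np.sin(alpha), np.sin(beta), np.sin(gamma)
    ca, cb, cg = np.cos(alpha), np.cos(beta), np.cos(gamma)
    phi_a = np.arccos(np.clip((cb - ca * cg) / (sa * sg), -1, 1))
    phi_b = np.arccos(np.clip((ca - cb * cg) / (sb * sg), -1, 1))
    c_p = np.arccos(np.clip((cg - ca * cb) / (sa * sb), -1, 1))
    return float(2 * np.pi - 2 * phi_a * ca - 2 * phi_b * cb - 2 * c_p)


def _tangent_basis(c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal basis of the tangent plane at unit vector c."""
    ref = np.array([0.0, 0.0, 1.0]) if abs(c[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(c, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(c, e1)
    return e1, e2


def _stream(seed: int, subject_idx: int, roi_id: str, condition: str) -> np.random.Generator:
    # counter-based split: each (subject, roi, condition) cell owns a stream
    key = (subject_idx, zlib.crc32(roi_id.encode()), zlib.crc32(condition.encode()))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def sample_subject_roi(
    config: CohortConfig,
    mesh: TriangleMesh,
    roi: RoiSpec,
    subject_idx: int,
    condition: str,
    *,
    max_retries: int = 10,
) -> RoiLabel:
    """One subject's realization of a ROI template under one condition.

    The template center is displaced by a tangent-plane Gaussian (SD = the
    condition's ``center_jitter_sd``) and renormalized to the sphere — a
    small-angle approximation to a von Mises-Fisher draw — and the radius is
    perturbed by a Gaussian (SD = ``radius_jitter_sd``); a perturbed radius
    outside (0, pi) is resampled up to ``max_retries`` times, then an error.
    Deterministic given (seed, subject, roi, condition).
    """
    if condition not in config.center_jitter_sd:
        raise KeyError(f"unknown condition {condition!r}")
    rng = _stream(config.seed, subject_idx, roi.roi_id, condition)
    sd = config.center_jitter_sd[condition]
    c = roi.center_vec
    e1, e2 = _tangent_basis(c)
    u, v = rng.normal(0.0, sd, size=2) if sd > 0 else (0.0, 0.0)
    center = c + u * e1 + v * e2
    center /= np.linalg.norm(center)
    radius = roi.radius
    if config.radius_jitter_sd > 0:
        for _ in range(max_retries):
            r = roi.radius + rng.normal(0.0, config.radius_jitter_sd)
            if 0 < r < np.pi:
                radius = r
                break
        else:
            raise RuntimeError(
                f"could not draw a valid radius for {roi.roi_id} after "
                f"{max_retries} retries"
            )
    return RoiLabel(
        subject_id=config.subject_ids[subject_idx],
        roi_id=roi.roi_id,
        hemisphere=config.hemisphere,
        vertex_set=geodesic_patch(mesh, center, radius),
    )


def generate_cohort(
    config: CohortConfig, mesh: TriangleMesh | None = None
) -> dict[str, Cohort]:
    """Assemble one complete :class:`Cohort` per condition.

    Conditions share ROI templates and subjects but use condition-specific
    center jitter.  Combinations listed in ``config.missing`` are recorded as
    explicitly absent (``None``) in every condition.
    """
    if not config.rois:
        raise ValueError("config has no ROI specs")
    if mesh is None:
        mesh = make_icosphere(config.subdiv)
    missing = {(config.subject_ids[si], rid) for si, rid in config.missing}
    out: dict[str, Cohort] = {}
    for cond in config.conditions:
        labels: dict = {}
        for si, sid in enumerate(config.subject_ids):
            for roi in config.rois:
                key = (sid, roi.roi_id, config.hemisphere)
                if (sid, roi.roi_id) in missing:
                    labels[key] = None
                else:
                    labels[key] = sample_subject_roi(config, mesh, roi, si, cond)
        out[cond] = Cohort(
            mesh=mesh,
            subjects=config.subject_ids,
            rois=[r.roi_id for r in config.rois],
            hemispheres=[config.hemisphere],
            condition=cond,
            labels=labels,
        )
    return out


def derive_second_parcellation(
    config: CohortConfig,
    mesh: TriangleMesh | None = None,
    *,
    displacement: float = 0.0,
    split_fraction: float = 0.0,
    prefix: str = "m_",
) -> tuple[list[RoiLabel], dict[str, str]]:
    """Group-level regions of a second parcellation derived from the templates.

    Each template center is displaced by the fixed angle ``displacement``
    along a deterministic tangent direction and regrown as a noiseless patch,
    so the ground-truth overlap with the source template is the closed-form
    cap-intersection ratio.  The first ``round(split_fraction * K)`` regions
    are additionally split into two half-patches along the great circle
    through the displaced center perpendicular to the displacement direction
    (suffixes ``_a`` / ``_b``).

    Returns the region labels (subject_id ``"group"``) and a provenance map
    region_id -> source roi_id.
    """
    if displacement < 0 or not 0 <= split_fraction <= 1:
        raise ValueError("displacement must be >= 0 and split_fraction in [0, 1]")
    if mesh is None:
        mesh = make_icosphere(config.subdiv)
    n_split = round(split_fraction * len(config.rois))
    labels: list[RoiLabel] = []
    provenance: dict[str, str] = {}
    for k, roi in enumerate(config.rois):
        c = roi.center_vec
        e1, _ = _tangent_basis(c)
        new_c = np.cos(displacement) * c + np.sin(displacement) * e1
        patch = geodesic_patch(mesh, new_c, roi.radius)
        base_id = prefix + roi.roi_id
        if k < n_split:
            # great circle through the displaced center: plane normal is the
            # displacement direction projected orthogonal to that center
            n_vec = e1 - float(e1 @ new_c) * new_c
            n_vec /= np.linalg.norm(n_vec)
            side = mesh.vertices @ n_vec
            for suffix, keep in (("_a", side >= 0), ("_b", side < 0)):
                part = frozenset(v for v in patch if keep[v])
                if part:
                    rid = base_id + suffix
                    labels.append(
                        RoiLabel("group", rid, config.hemisphere, part)
                    )
                    provenance[rid] = roi.roi_id
        else:
            labels.append(RoiLabel("group", base_id, config.hemisphere, patch))
            provenance[base_id] = roi.roi_id
    return labels, provenance
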