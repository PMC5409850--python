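"""Synthetic cohort generator: icosphere geometry, geodesic patches, jitter
model, and the derived second parcellation."""

import itertools

import numpy as np
import pytest

from surfatlas import (
    CohortConfig,
    RoiSpec,
    cap_area,
    cap_intersection_area,
    default_config,
    derive_second_parcellation,
    dice,
    generate_cohort,
    geodesic_patch,
    make_icosphere,
    overlap_proportion,
    sample_subject_roi,
    vertex_areas,
)

Z = (0.0, 0.0, 1.0)


class TestIcosphere:
    @pytest.mark.parametrize("subdiv,nv,nf", [(0, 12, 20), (1, 42, 80), (2, 162, 320)])
    def test_vertex_and_face_counts(self, subdiv, nv, nf):
        m = make_icosphere(subdiv)
        assert (m.n_vertices, m.n_faces) == (nv, nf)

    def test_vertices_on_unit_sphere(self):
        m = make_icosphere(2)
        r = np.linalg.norm(m.vertices, axis=1)
        assert np.all(np.abs(r - 1) < 1e-12)

    def test_negative_subdiv_rejected(self):
        with pytest.raises(ValueError):
            make_icosphere(-1)


class TestGeodesicPatch:
    def test_tiny_radius_gives_single_nearest_vertex(self, sphere4):
        target = sphere4.vertices[137]
        assert geodesic_patch(sphere4, target, 1e-6) == {137}

    def test_radius_pi_covers_sphere(self, icosahedron):
        assert len(geodesic_patch(icosahedron, Z, np.pi)) == 12

    def test_radius_out_of_range(self, icosahedron):
        for r in (0.0, -0.1, 4.0):
            with pytest.raises(ValueError):
                geodesic_patch(icosahedron, Z, r)

    @pytest.mark.parametrize("radius", [0.25, 0.5, 1.0])
    def test_patch_area_matches_spherical_cap(self, radius):
        # barycentric vertex areas of the patch vs closed-form 2*pi*(1-cos r)
        mesh = make_icosphere(4)
        areas = vertex_areas(mesh)
        patch = geodesic_patch(mesh, Z, radius)
        got = areas[list(patch)].sum()
        want = cap_area(radius)
        # the error is a boundary-band effect, so the relative tolerance must
        # cover one edge-length ring around the cap at this resolution
        assert abs(got - want) / want < 0.08

    def test_cap_area_error_shrinks_with_subdivision(self):
        errs = []
        for subdiv in (3, 4, 5):
            mesh = make_icosphere(subdiv)
            got = vertex_areas(mesh)[list(geodesic_patch(mesh, Z, 0.5))].sum()
            errs.append(abs(got - cap_area(0.5)))
        assert errs[0] > errs[1] > errs[2]


class TestCapIntersection:
    def test_disjoint_and_nested_branches(self):
        assert cap_intersection_area(0.2, 0.2, 0.5) == 0.0
        assert cap_intersection_area(0.2, 0.6, 0.1) == pytest.approx(cap_area(0.2))

    def test_coincident_caps_give_cap_area(self):
        assert cap_intersection_area(0.4, 0.4, 1e-12) == pytest.approx(cap_area(0.4))

    def test_matches_numeric_quadrature(self):
        # independent check: integrate the lens on a fine lat-long grid
        alpha = beta = 0.3
        gamma = 0.25
        a = np.array([0, 0, 1.0])
        b = np.array([np.sin(gamma), 0, np.cos(gamma)])
        th = np.linspace(0, np.pi, 2001)
        ph = np.linspace(0, 2 * np.pi, 2001)
        T, P = np.meshgrid(th, ph, indexing="ij")
        pts = np.stack(
            [np.sin(T) * np.cos(P), np.sin(T) * np.sin(P), np.cos(T)], axis=-1
        )
        inside = (pts @ a >= np.cos(alpha)) & (pts @ b >= np.cos(beta))
        dA = np.sin(T) * (th[1] - th[0]) * (ph[1] - ph[0])
        numeric = float((inside * dA).sum())
        assert cap_intersection_area(alpha, beta, gamma) == pytest.approx(
            numeric, rel=5e-3
        )


def _pairwise_mean_dice(cohort, roi_id):
    labs = [cohort.get(s, roi_id, "left") for s in cohort.subjects]
    vals = [
        dice(a.vertex_set, b.vertex_set) for a, b in itertools.combinations(labs, 2)
    ]
    return float(np.mean(vals))


class TestJitterModel:
    def test_zero_jitter_reproduces_template_patch(self, sphere4):
        cfg = CohortConfig(
            subdiv=4,
            n_subjects=4,
            rois=(RoiSpec("r", Z, 0.3),),
            center_jitter_sd={"c": 0.0},
            radius_jitter_sd=0.0,
            seed=5,
        )
        want = geodesic_patch(sphere4, Z, 0.3)
        for si in range(4):
            lab = sample_subject_roi(cfg, sphere4, cfg.rois[0], si, "c")
            assert lab.vertex_set == want

    def test_deterministic_given_cell_key(self, sphere4):
        cfg = default_config(subdiv=4, n_subjects=3, n_rois=2, seed=11)
        a = sample_subject_roi(cfg, sphere4, cfg.rois[1], 2, "cba_fs")
        b = sample_subject_roi(cfg, sphere4, cfg.rois[1], 2, "cba_fs")
        assert a.vertex_set == b.vertex_set

    def test_streams_differ_across_subjects_and_conditions(self, sphere4):
        cfg = default_config(subdiv=4, n_subjects=3, n_rois=1, seed=11)
        roi = cfg.rois[0]
        a = sample_subject_roi(cfg, sphere4, roi, 0, "cba_pm")
        b = sample_subject_roi(cfg, sphere4, roi, 1, "cba_pm")
        c = sample_subject_roi(cfg, sphere4, roi, 0, "cba_fs")
        assert a.vertex_set != b.vertex_set
        assert a.vertex_set != c.vertex_set

    def test_pairwise_dice_decreases_with_center_jitter(self, sphere4):
        # monotone in expectation: average the pairwise dice over 5 seeds
        sds = [0.0, 0.05, 0.15, 0.4]
        means = []
        for sd in sds:
            per_seed = []
            for seed in range(5):
                cfg = CohortConfig(
                    subdiv=4,
                    n_subjects=10,
                    rois=(RoiSpec("r", Z, 0.3),),
                    center_jitter_sd={"c": sd},
                    radius_jitter_sd=0.0,
                    seed=seed,
                )
                cohort = generate_cohort(cfg, sphere4)["c"]
                per_seed.append(_pairwise_mean_dice(cohort, "r"))
            means.append(np.mean(per_seed))
        assert means[0] > means[1] > means[2] > means[3]


class TestGenerateCohort:
    def test_full_design_size(self, sphere4):
        cfg = default_config(subdiv=4, n_subjects=9, n_rois=8, seed=0)
        cohorts = generate_cohort(cfg, sphere4)
        assert set(cohorts) == {"cba_pm", "cba_fs"}
        for c in cohorts.values():
            present = [v for v in c.labels.values() if v is not None]
            assert len(present) == 72  # 9 subjects x 8 ROIs, one hemisphere

    def test_missing_combinations_flagged_absent(self, sphere4):
        cfg = default_config(
            subdiv=4, n_subjects=10, n_rois=8, seed=0,
            missing=((9, "FG3"), (9, "FG4")),
        )
        c = generate_cohort(cfg, sphere4)["cba_pm"]
        assert c.get("sub10", "FG3", "left") is None
        assert c.get("sub10", "FG4", "left") is None
        assert len(c.missing()) == 2
        assert len(c.subjects_with("FG3", "left")) == 9

    def test_same_seed_same_cohort(self, sphere4):
        cfg = default_config(subdiv=4, n_subjects=4, n_rois=3, seed=21)
        a = generate_cohort(cfg, sphere4)["cba_fs"]
        b = generate_cohort(cfg, sphere4)["cba_fs"]
        for k, lab in a.labels.items():
            assert lab.vertex_set == b.labels[k].vertex_set


class TestSecondParcellation:
    def test_zero_displacement_reproduces_templates(self, sphere4):
        cfg = default_config(subdiv=4, n_subjects=3, n_rois=4, seed=0)
        mrois, prov = derive_second_parcellation(cfg, sphere4, displacement=0.0)
        assert len(mrois) == 4
        for m in mrois:
            src = next(r for r in cfg.rois if r.roi_id == prov[m.roi_id])
            assert m.vertex_set == geodesic_patch(sphere4, src.center_vec, src.radius)

    def test_large_displacement_disjoint(self, sphere4):
        cfg = CohortConfig(
            subdiv=4, n_subjects=3, rois=(RoiSpec("r", Z, 0.2),),
            center_jitter_sd={"c": 0.0}, radius_jitter_sd=0.0, seed=0,
        )
        mrois, _ = derive_second_parcellation(cfg, sphere4, displacement=0.5)
        src = geodesic_patch(sphere4, Z, 0.2)
        assert not (mrois[0].vertex_set & src)

    def test_displacement_equal_radius_matches_lens_ratio(self):
        mesh = make_icosphere(5)
        r = 0.3
        cfg = CohortConfig(
            subdiv=5, n_subjects=3, rois=(RoiSpec("r", Z, r),),
            center_jitter_sd={"c": 0.0}, radius_jitter_sd=0.0, seed=0,
        )
        mrois, _ = derive_second_parcellation(cfg, mesh, displacement=r)
        croi = geodesic_patch(mesh, Z, r)
        got = len(mrois[0].vertex_set & croi) / len(mrois[0].vertex_set)
        want = cap_intersection_area(r, r, r) / cap_area(r)
        assert got == pytest.approx(want, abs=0.03)

    def test_split_partitions_patch(self, sphere4):
        cfg = default_config(subdiv=4, n_subjects=3, n_rois=2, seed=0)
        whole, _ = derive_second_parcellation(cfg, sphere4, displacement=0.05)
        halves, prov = derive_second_parcellation(
            cfg, sphere4, displacement=0.05, split_fraction=0.5
        )
        ids = [m.roi_id for m in halves]
        assert any(i.endswith("_a") for i in ids) and any(i.endswith("_b") for i in ids)
        a = next(m for m in halves if m.roi_id.endswith("_a"))
        b = next(m for m in halves if m.roi_id.endswith("_b"))
        src = next(m for m in whole if m.roi_id == "m_" + prov[a.roi_id])
        assert not (a.vertex_set & b.vertex_set)
        assert a.vertex_set | b.vertex_set == src.vertex_set


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = default_config(subdiv=3, n_subjects=5, n_rois=3, seed=9,
                             missing=((4, "hOc2"),))
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        assert CohortConfig.from_yaml(p) == cfg

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(subdiv=-1)
        with pytest.raises(ValueError):
            RoiSpec("r", (0, 0, 2.0), 0.3)
        with pytest.raises(ValueError):
            RoiSpec("r", Z, 0.0)
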