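"""Template matching, RBF correction, natural representation and resampling."""

import numpy as np
import pytest

from femurmap.correspondence import (
    build_isotopological_set,
    build_rbf,
    build_template,
    natural_representation,
    resample,
)
from femurmap.features import FeatureRegion, FeaturePoint
from femurmap.mesh import TriMesh
from femurmap.pipeline import parametrise


def _region(centre, cov):
    fp = FeaturePoint(0, 0, complex(*centre), "FH", 1.0)
    return FeatureRegion(point=fp, centre=np.asarray(centre, float),
                         cov=np.asarray(cov, float), amplitude=1.0,
                         offset=0.0, support=np.arange(1))


class TestRBF:
    def test_identical_regions_give_zero_field(self):
        r = _region([0.0, 0.0], np.eye(2) * 0.5)
        rbf = build_rbf((r, _region([3.0, 0.0], np.eye(2) * 0.3)),
                        (r, _region([3.0, 0.0], np.eye(2) * 0.3)))
        pts = np.random.default_rng(0).normal(size=(50, 2))
        assert np.abs(rbf(pts)).max() == 0.0

    def test_interpolation_exact_at_controls(self):
        src = (_region([0, 0], [[0.4, 0.1], [0.1, 0.3]]),
               _region([4, 1], [[0.2, 0], [0, 0.5]]))
        dst = (_region([0.5, -0.2], [[0.6, 0.0], [0.0, 0.2]]),
               _region([4.3, 1.4], [[0.3, 0.05], [0.05, 0.4]]))
        rbf = build_rbf(src, dst)
        err = np.abs(rbf(rbf.centres) - rbf.displacements).max()
        assert err < 1e-9

    def test_compact_support_exactly_zero(self):
        src = (_region([0, 0], np.eye(2) * 0.4), _region([4, 0], np.eye(2) * 0.4))
        dst = (_region([1, 1], np.eye(2) * 0.4), _region([5, 1], np.eye(2) * 0.4))
        rbf = build_rbf(src, dst)
        far = np.array([[100.0, 100.0], [0.0, 50.0]])
        assert np.abs(rbf(far)).max() == 0.0

    def test_translation_inside_support(self):
        shift = np.array([0.7, -0.3])
        src = (_region([0, 0], np.eye(2) * 0.4), _region([6, 0], np.eye(2) * 0.4))
        dst = (_region(shift, np.eye(2) * 0.4),
               _region([6, 0] + shift, np.eye(2) * 0.4))
        rbf = build_rbf(src, dst)
        np.testing.assert_allclose(rbf(np.array([[0.0, 0.0]])), shift[None],
                                   atol=1e-9)


class TestNaturalRepresentation:
    def test_node_on_vertex_gets_unit_weight(self, femur_param):
        strip = femur_param.strip
        k = 37
        cmap = natural_representation(
            np.array([[strip.z[k].real, strip.z[k].imag]]), strip
        )
        assert cmap.bary[0].max() == pytest.approx(1.0, abs=1e-9)
        assert not cmap.clamped[0]

    def test_outside_point_clamped(self, femur_param):
        strip = femur_param.strip
        below = strip.z.real.min() - 1.0
        cmap = natural_representation(np.array([[below, np.pi]]), strip)
        assert cmap.clamped[0]
        assert cmap.bary[0].sum() == pytest.approx(1.0)

    def test_constant_and_linear_fields_reproduced(self, femur_param):
        strip = femur_param.strip
        mesh = strip.mesh
        mesh.fields["const"] = np.full(mesh.n_vertices, 7.5)
        mesh.fields["linear"] = 2.0 * strip.z.real - 3.0 * strip.z.imag + 1.0
        rng = np.random.default_rng(3)
        # random interior probe points: barycentres of random faces
        fidx = rng.integers(0, mesh.n_faces, 50)
        w = rng.dirichlet([1, 1, 1], 50)
        pts2 = np.einsum(
            "kc,kcd->kd", w,
            np.stack([np.column_stack([strip.z[mesh.faces[f]].real,
                                       strip.z[mesh.faces[f]].imag])
                      for f in fidx]),
        )
        cmap = natural_representation(pts2, strip)
        _, fields = resample(cmap, strip, field_names=("const", "linear"))
        assert np.abs(fields["const"] - 7.5).max() < 1e-9
        expected = 2.0 * pts2[:, 0] - 3.0 * pts2[:, 1] + 1.0
        assert np.abs(fields["linear"] - expected).max() < 1e-9


class TestIsotopologicalSet:
    def test_identity_recovery(self, challenge_params):
        P, _ = challenge_params["s0"]
        tpl = build_template(P.strip, P.fh_region_strip, P.lt_region_strip)
        iso = build_isotopological_set(tpl, {"s0": P})
        keep = (P.strip.z.real[P.strip.mesh.faces] >= tpl.distal_limit).all(axis=1)
        used = np.unique(P.strip.mesh.faces[keep])
        err = np.abs(iso.coords[0] - P.strip.mesh.vertices[used]).max()
        assert err < 1e-9
        for name, arr in iso.fields.items():
            ref = P.strip.mesh.fields[name][used]
            assert np.abs(arr[0] - ref).max() < 1e-9

    def test_three_shape_challenge_registers(self, challenge_params):
        P0, _ = challenge_params["s0"]
        tpl = build_template(P0.strip, P0.fh_region_strip, P0.lt_region_strip)
        iso = build_isotopological_set(
            tpl, {k: v[0] for k, v in challenge_params.items()}
        )
        assert iso.errors == {}
        assert iso.n_subjects == 3
        assert len({tuple(iso.coords[i].shape) for i in range(3)}) == 1
        # subjects genuinely differ in geometry
        assert np.abs(iso.coords[1] - iso.coords[0]).max() > 1.0

    def test_short_shaft_clamps_only_distal_rows(self, challenge_params):
        P0, _ = challenge_params["s0"]
        P2, _ = challenge_params["s2"]  # shorter shaft
        tpl = build_template(P0.strip, P0.fh_region_strip, P0.lt_region_strip,
                             distal_limit=P0.strip.z.real.min())
        iso = build_isotopological_set(tpl, {"s2": P2})
        clamped = iso.clamped[0]
        assert clamped.any()
        re = tpl.coords[:, 0]
        # the deepest template row falls off the shorter target and is clamped
        assert clamped[np.argmin(re)]
        # every other clamp hugs the domain boundary: the slit (Re = 0) or
        # the jagged cut seam (Im near 0 / 2*pi), whose wiggles differ
        # between subjects by design; no interior node is clamped
        im = tpl.coords[:, 1]
        near_boundary = (
            (re > -0.01)
            | (np.minimum(np.abs(im), np.abs(im - 2 * np.pi)) < 0.01)
        )
        interior_clamps = clamped & ~near_boundary & (re > np.percentile(re, 10))
        assert not interior_clamps.any()

    def test_feature_alignment_after_rbf(self, challenge_params):
        P0, _ = challenge_params["s0"]
        P1, _ = challenge_params["s1"]
        tpl = build_template(P0.strip, P0.fh_region_strip, P0.lt_region_strip)
        rbf = build_rbf((tpl.fh_region, tpl.lt_region),
                        (P1.fh_region_strip, P1.lt_region_strip))
        for src_r, dst_r in ((tpl.fh_region, P1.fh_region_strip),
                             (tpl.lt_region, P1.lt_region_strip)):
            moved = src_r.centre + rbf(src_r.centre[None])[0]
            assert np.abs(moved - dst_r.centre).max() < 1e-6


class TestIsometryRobustness:
    def test_rigid_motion_of_subject_moves_resampled_coords_rigidly(
        self, small_femur
    ):
        outer, _, _ = small_femur
        P1 = parametrise(outer)
        rng = np.random.default_rng(5)
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        Q *= np.linalg.det(Q)
        tvec = np.array([4.0, -6.0, 2.0])
        moved = TriMesh(outer.vertices @ Q.T + tvec, outer.faces.copy())
        moved.fields["f"] = np.linspace(0, 1, outer.n_vertices)
        outer2 = outer.copy()
        outer2.fields["f"] = np.linspace(0, 1, outer.n_vertices)
        P1 = parametrise(outer2)
        P2 = parametrise(moved)
        tpl = build_template(P1.strip, P1.fh_region_strip, P1.lt_region_strip)
        iso1 = build_isotopological_set(tpl, {"a": P1}, field_names=("f",))
        iso2 = build_isotopological_set(tpl, {"a": P2}, field_names=("f",))
        err = np.abs(iso2.coords[0] - (iso1.coords[0] @ Q.T + tvec)).max()
        assert err < 1e-6
        assert np.abs(iso2.fields["f"][0] - iso1.fields["f"][0]).max() < 1e-6
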