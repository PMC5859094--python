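"""Ricci flow, planar layout, surgery, normalisation and exponential map."""

import numpy as np
import pytest

import femurmap as fm
from femurmap.errors import ArgumentError, GeometryError, TopologyError
from femurmap.mesh import TriMesh, corner_angles, discrete_gaussian_curvature, euler_characteristic
from femurmap.ricci import (
    cut_graph,
    embed_disk,
    embed_flat,
    exponential_map,
    normalise_strip,
    ricci_flow_metric,
    slit_mesh,
)
from test_mesh import grid_mesh


def cylinder_mesh(n_theta=24, n_rings=12, radius=10.0, height=30.0):
    theta = 2 * np.pi * np.arange(n_theta) / n_theta
    verts, faces = [], []
    for i in range(n_rings):
        z = height * i / (n_rings - 1)
        for t in theta:
            verts.append((radius * np.cos(t), radius * np.sin(t), z))
    for i in range(n_rings - 1):
        for j in range(n_theta):
            a = i * n_theta + j
            b = i * n_theta + (j + 1) % n_theta
            c = (i + 1) * n_theta + j
            d = (i + 1) * n_theta + (j + 1) % n_theta
            faces.append((a, b, c))
            faces.append((b, d, c))
    return TriMesh(np.array(verts), np.array(faces))


class TestFlow:
    def test_flat_input_converges_immediately(self):
        g = grid_mesh(6)
        met = ricci_flow_metric(g, "disk_free_boundary")
        assert len(met.history) == 1  # already at the target
        assert np.abs(met.u).max() == 0.0

    def test_femur_disk_flow_contract(self, femur_param):
        met = femur_param.disk_metric
        assert met.converged and met.residual <= 1e-8
        # free boundary: boundary u fixed at zero
        bnd = femur_param.surface.boundary_vertex_mask
        assert np.abs(met.u[bnd]).max() == 0.0
        # residual decreases monotonically across Newton steps
        assert all(b < a for a, b in zip(met.history, met.history[1:]))

    def test_gauss_bonnet_after_flow(self, femur_param):
        met = femur_param.disk_metric
        K = discrete_gaussian_curvature(femur_param.surface, met.edge_lengths)
        assert K.sum() == pytest.approx(2 * np.pi, abs=1e-8)

    def test_cylinder_annulus_mode(self):
        cyl = cylinder_mesh()
        assert tuple(euler_characteristic(cyl)) == (0, 0, 2)
        met = ricci_flow_metric(cyl, "annulus_zero")
        assert met.residual <= 1e-8
        K = discrete_gaussian_curvature(cyl, met.edge_lengths)
        assert abs(K.sum()) < 1e-8  # 2*pi*chi with chi = 0

    def test_wrong_topology_rejected(self):
        g = grid_mesh(5)
        with pytest.raises(TopologyError):
            ricci_flow_metric(g, "annulus_zero")
        with pytest.raises(TopologyError):
            ricci_flow_metric(cylinder_mesh(), "disk_free_boundary")


class TestLayout:
    def test_flat_input_reproduced_up_to_similarity(self):
        g = grid_mesh(6)
        met = ricci_flow_metric(g, "disk_free_boundary")
        emb = embed_flat(g, met)
        z = emb.z
        w = g.vertices[:, 0] + 1j * g.vertices[:, 1]
        # similarity aligning two point sets; residual should vanish
        a = np.vstack([w, np.ones_like(w)]).T
        coef, *_ = np.linalg.lstsq(a, z, rcond=None)
        assert np.abs(a @ coef - z).max() < 1e-9

    def test_layout_realises_metric_lengths(self, femur_param):
        emb = femur_param.disk
        met = femur_param.disk_metric
        e = emb.mesh.edges
        lv = np.abs(emb.z[e[:, 0]] - emb.z[e[:, 1]])
        rel = np.abs(lv - met.edge_lengths) / met.edge_lengths
        assert rel.max() < 1e-6

    def test_no_flipped_faces_anywhere(self, femur_param):
        for emb in (femur_param.disk, femur_param.strip):
            assert emb.signed_areas().min() > 0

    def test_unconverged_metric_refused(self, femur_param):
        import dataclasses

        met = dataclasses.replace(femur_param.disk_metric, converged=False)
        with pytest.raises(ArgumentError):
            embed_disk(femur_param.surface, met)


class TestCutGraph:
    def test_adjacent_vertex_single_edge(self, femur):
        outer, _, _ = femur
        loop = outer.boundary_loops()[0]
        neigh = outer.vertex_neighbors()
        bset = set(loop.tolist())
        v = next(
            int(w)
            for w in range(outer.n_vertices)
            if w not in bset and any(int(x) in bset for x in neigh[w])
        )
        path = cut_graph(outer, v, 0)
        assert len(path) == 2

    def test_path_simple_and_matches_networkx_oracle(self, small_femur):
        import networkx as nx

        outer, _, truth = small_femur
        path = cut_graph(outer, truth.apex_gt, 0)
        assert len(np.unique(path)) == len(path)
        G = nx.Graph()
        e = outer.edges
        w = outer.edge_lengths()
        G.add_weighted_edges_from(
            [(int(a), int(b), float(l)) for (a, b), l in zip(e.tolist(), w)]
        )
        loop = outer.boundary_loops()[0]
        best = min(
            nx.single_source_dijkstra_path_length(G, truth.apex_gt)[int(v)]
            for v in loop
        )
        got = sum(
            G[int(a)][int(b)]["weight"] for a, b in zip(path[:-1], path[1:])
        )
        assert got == pytest.approx(best, rel=1e-12)


class TestSlit:
    def test_interfeature_slit_topology(self, femur_param):
        assert femur_param.log["slit_topology"] == (0, 0, 2)
        assert femur_param.log["fundamental_topology"] == (1, 0, 1)

    def test_edge_path_slit_vertex_count(self, femur):
        outer, _, truth = femur
        # an interior edge path of k interior vertices adds exactly k vertices
        neigh = outer.vertex_neighbors()
        bnd = outer.boundary_vertex_mask
        v0 = truth.apex_lt
        path = [v0]
        for _ in range(4):
            nxt = next(
                int(w) for w in neigh[path[-1]] if not bnd[w] and w not in path
            )
            path.append(nxt)
        out, prov, _ = slit_mesh(outer, np.array(path), mode="edge_path")
        assert out.n_vertices == outer.n_vertices + (len(path) - 2)
        assert tuple(euler_characteristic(out)) == (0, 0, 2)

    def test_slit_touching_boundary_rejected(self, femur):
        outer, _, _ = femur
        loop = outer.boundary_loops()[0]
        neigh = outer.vertex_neighbors()
        a, b = int(loop[0]), int(loop[1])
        inner = next(int(w) for w in neigh[a] if w in set(int(x) for x in neigh[b])
                     and not outer.boundary_vertex_mask[w])
        with pytest.raises((GeometryError, ArgumentError)):
            slit_mesh(outer, np.array([a, inner, b, int(loop[2])]), mode="edge_path")


class TestNormalisation:
    def test_slit_spans_exactly_0_to_2pi(self, femur_param):
        si = femur_param.strip.z[femur_param.slit_chain].imag
        assert si.min() == pytest.approx(0.0, abs=1e-9)
        assert si.max() == pytest.approx(2 * np.pi, abs=1e-9)
        assert femur_param.strip.z.real.max() <= 1e-9

    def test_already_normalised_is_identity(self, femur_param):
        strip = femur_param.strip
        again = normalise_strip(strip, femur_param.slit_chain)
        assert np.abs(again.z - strip.z).max() < 1e-9

    def test_unit_square_scale_factor(self):
        # an axis-aligned unit-square domain: the slit side scales by 2*pi
        g = grid_mesh(5)
        g = TriMesh(g.vertices / 4.0, g.faces)  # unit square
        met = ricci_flow_metric(g, "disk_free_boundary")
        emb = embed_flat(g, met)
        loops = g.boundary_loops()[0]
        # pick the boundary corner-to-corner side x = 0 as the "slit"
        side = [int(v) for v in loops if g.vertices[v, 0] == 0.0]
        side_sorted = sorted(side, key=lambda v: g.vertices[v, 1])
        strip = normalise_strip(emb, np.array(side_sorted))
        length = np.abs(
            strip.z[side_sorted[-1]] - strip.z[side_sorted[0]]
        )
        assert length == pytest.approx(2 * np.pi, rel=1e-9)


class TestExponentialMap:
    def test_pointwise_map(self, femur_param):
        strip = femur_param.strip
        ann = exponential_map(strip)
        np.testing.assert_allclose(ann.z, np.exp(strip.z), rtol=0, atol=0)
        r = np.abs(ann.z)
        assert r.max() <= 1.0 + 1e-9
        assert r.min() > 0

    def test_slit_endpoints_identified(self, femur_param):
        chain = femur_param.slit_chain
        ann = femur_param.annulus
        z0, z1 = ann.z[chain[0]], ann.z[chain[-1]]
        assert abs(z0 - z1) < 1e-9  # 0 and 2*pi*i map to the same point
        assert abs(abs(z0) - 1.0) < 1e-9

    def test_requires_normalised_strip(self, femur_param):
        with pytest.raises(ArgumentError):
            exponential_map(femur_param.disk)


class TestConformalInvariance:
    def test_rigid_motion_and_scale_leave_strip_unchanged(self, small_femur):
        from femurmap.pipeline import parametrise

        outer, _, _ = small_femur
        P1 = parametrise(outer)
        rng = np.random.default_rng(12)
        A = rng.normal(size=(3, 3))
        Q, _ = np.linalg.qr(A)
        Q *= np.linalg.det(Q)
        moved = TriMesh(outer.vertices @ Q.T * 1.7 + np.array([5.0, -3.0, 11.0]),
                        outer.faces.copy())
        P2 = parametrise(moved)
        assert np.abs(P2.strip.z - P1.strip.z).max() < 1e-6

    def test_quasi_conformality_improves_with_refinement(self):
        # per-face angle distortion between 3D and embedded triangles
        # decreases under refinement of the same smooth shape
        distortions = []
        for n in (500, 1100, 2400):
            outer, _, _ = fm.make_femur(fm.FemurSpec(n_vertices=n))
            met = ricci_flow_metric(outer, "disk_free_boundary")
            emb = embed_disk(outer, met)
            a3 = corner_angles(outer)
            e = outer.edges
            lengths2d = np.abs(emb.z[e[:, 0]] - emb.z[e[:, 1]])
            a2 = corner_angles(outer, lengths2d)
            distortions.append(float(np.abs(a3 - a2).mean()))
        assert distortions[2] < distortions[1] < distortions[0]
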