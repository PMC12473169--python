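import math

import numpy as np
import pytest

from hemisurf import meshing
from hemisurf.errors import MeshError
from hemisurf.meshing import (DensityField, DiscDomain, RectDomain,
                              TriMeshModel, mass_and_centroid, measure,
                              mesh_from_function, resection_measure,
                              surface_area, volume_under_surface, write_obj,
                              write_ply, write_stl)

R = 1.0
HEMI_AREA = 2 * math.pi * R**2
HEMI_VOL = 2 / 3 * math.pi * R**3


def flat(value=0.0):
    return lambda x, y: np.full(np.shape(np.asarray(x)), float(value))


def hemi_fn(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.sqrt(np.maximum(R * R - x * x - y * y, 0.0))


@pytest.fixture(scope="module")
def hemi_mesh():
    # radial height field: in section-space x is the signed radius
    fn = lambda x, y: np.sqrt(np.maximum(R * R - np.asarray(x) ** 2, 0.0))
    return mesh_from_function(fn, DiscDomain(R), 0.02, frame="section-space")


UNIT_SQUARE = RectDomain(0.0, 1.0, 0.0, 1.0)


class TestMeshConstruction:
    def test_unit_square_counts(self):
        m = mesh_from_function(flat(0.5), UNIT_SQUARE, 0.5)
        assert len(m.vertices) == 9
        assert m.n_elements == 8

    def test_deterministic(self):
        a = mesh_from_function(hemi_fn, DiscDomain(R), 0.1)
        b = mesh_from_function(hemi_fn, DiscDomain(R), 0.1)
        assert np.array_equal(a.vertices, b.vertices)
        assert np.array_equal(a.faces, b.faces)

    def test_oversized_element_rejected(self):
        with pytest.raises(MeshError, match="element_size larger"):
            mesh_from_function(flat(1.0), UNIT_SQUARE, 10.0)

    def test_degenerate_faces_rejected(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
        with pytest.raises(MeshError, match="degenerate"):
            TriMeshModel(vertices=v, faces=np.array([[0, 1, 2]]), element_size=1.0)

    def test_section_space_embedding_covers_full_disc(self):
        m = mesh_from_function(lambda x, y: 1.0 + 0.0 * np.asarray(x),
                               DiscDomain(2.0), 0.2, frame="section-space")
        # projected footprint must span both half-planes
        assert m.vertices[:, 0].min() < -1.5 and m.vertices[:, 0].max() > 1.5
        assert m.vertices[:, 1].min() < -1.5 and m.vertices[:, 1].max() > 1.5


class TestSurfaceArea:
    def test_flat_unit_square(self):
        m = mesh_from_function(flat(0.0), UNIT_SQUARE, 0.25)
        geo, corr = surface_area(m, k=1.0)
        assert geo == pytest.approx(1.0, rel=1e-12)
        assert corr == pytest.approx(1.0, rel=1e-12)

    def test_elasticity_scaling(self):
        m = mesh_from_function(flat(0.0), UNIT_SQUARE, 0.25)
        geo, corr = surface_area(m, k=1.1)
        assert corr == pytest.approx(1.1 * geo, rel=1e-12)

    def test_hemisphere_closed_form(self, hemi_mesh):
        geo, _ = surface_area(hemi_mesh)
        assert abs(geo - HEMI_AREA) / HEMI_AREA < 0.01

    def test_nonpositive_k_rejected(self, hemi_mesh):
        with pytest.raises(MeshError):
            surface_area(hemi_mesh, k=0.0)


class TestVolume:
    def test_flat_slab(self):
        m = mesh_from_function(flat(1.0), UNIT_SQUARE, 0.25)
        assert volume_under_surface(m, 0.0) == pytest.approx(1.0, rel=1e-12)

    def test_zero_height(self):
        m = mesh_from_function(flat(0.0), UNIT_SQUARE, 0.25)
        v = volume_under_surface(m, 0.0, method="prism")
        assert v == pytest.approx(0.0, abs=1e-15)

    def test_hemisphere_closed_form(self, hemi_mesh):
        v = volume_under_surface(hemi_mesh, 0.0)
        assert abs(v - HEMI_VOL) / HEMI_VOL < 0.01

    def test_prism_and_divergence_agree(self, hemi_mesh):
        vp = volume_under_surface(hemi_mesh, 0.0, method="prism")
        vd = volume_under_surface(hemi_mesh, 0.0, method="divergence")
        assert abs(vp - vd) <= 1e-3 * vp

    def test_divergence_matches_trimesh_oracle(self):
        trimesh = pytest.importorskip("trimesh")
        fn = lambda x, y: np.sqrt(np.maximum(R * R - np.asarray(x) ** 2, 0.0))
        m = mesh_from_function(fn, DiscDomain(R), 0.05, frame="section-space")
        verts, faces = meshing._closed_mesh(m, 0.0)
        tm = trimesh.Trimesh(verts, faces, process=False)
        ours = volume_under_surface(m, 0.0, method="divergence")
        assert ours == pytest.approx(abs(tm.volume), rel=1e-9)

    def test_below_base_rejected(self):
        m = mesh_from_function(flat(-1.0), UNIT_SQUARE, 0.25)
        with pytest.raises(MeshError, match="below the base plane"):
            volume_under_surface(m, 0.0)

    def test_convergence_with_element_size(self):
        errs = []
        for es in (0.1, 0.05):
            fn = lambda x, y: np.sqrt(np.maximum(R * R - np.asarray(x) ** 2, 0.0))
            m = mesh_from_function(fn, DiscDomain(R), es, frame="section-space")
            errs.append(abs(volume_under_surface(m, 0.0, "prism") - HEMI_VOL))
        assert errs[1] < errs[0] * 1.05  # monotone within 5% slack

    def test_rotation_about_axis_invariance(self, hemi_mesh):
        ang = 0.7
        rot = np.array([[math.cos(ang), -math.sin(ang), 0],
                        [math.sin(ang), math.cos(ang), 0],
                        [0, 0, 1.0]])
        rotated = TriMeshModel(vertices=hemi_mesh.vertices @ rot.T,
                               faces=hemi_mesh.faces,
                               element_size=hemi_mesh.element_size)
        a0, _ = surface_area(hemi_mesh)
        a1, _ = surface_area(rotated)
        assert a1 == pytest.approx(a0, rel=1e-9)
        v0 = volume_under_surface(hemi_mesh, 0.0, "prism")
        v1 = volume_under_surface(rotated, 0.0, "prism")
        assert v1 == pytest.approx(v0, rel=1e-9)


class TestMassAndCentroid:
    def test_uniform_slab(self):
        m = mesh_from_function(flat(1.0), UNIT_SQUARE, 0.25)
        mass, c, mu = mass_and_centroid(m, density=2.0)
        assert mass == pytest.approx(2.0, rel=1e-12)
        np.testing.assert_allclose([c.x, c.y, c.z], [0.5, 0.5, 0.5], atol=1e-12)
        assert mu == pytest.approx(2.0, rel=1e-12)

    def test_hemisphere_centroid_closed_form(self, hemi_mesh):
        _, c, _ = mass_and_centroid(hemi_mesh, density=1.0)
        assert abs(c.z - 3 * R / 8) / (3 * R / 8) < 0.02

    def test_linear_density_slab_analytic(self):
        # mu = z on a unit slab: m = 1/2, centroid z = 2/3
        m = mesh_from_function(flat(1.0), UNIT_SQUARE, 0.25)
        mass, c, _ = mass_and_centroid(m, density=lambda x, y, z: z, n_z=64)
        assert mass == pytest.approx(0.5, abs=1e-3)
        assert c.z == pytest.approx(2.0 / 3.0, abs=5e-3)

    def test_mean_density_is_mass_over_volume(self, hemi_mesh):
        mass, _, mu = mass_and_centroid(hemi_mesh, density=1.23)
        vol = volume_under_surface(hemi_mesh, 0.0, "prism")
        assert mu == pytest.approx(mass / vol, rel=1e-12)

    def test_nonpositive_density_rejected(self):
        m = mesh_from_function(flat(1.0), UNIT_SQUARE, 0.25)
        with pytest.raises(MeshError):
            mass_and_centroid(m, density=DensityField.from_callable(
                lambda x, y, z: np.zeros(np.shape(z))))


@pytest.fixture(scope="module")
def flat_mesh():
    return mesh_from_function(flat(0.0), UNIT_SQUARE, 0.25)


@pytest.fixture(scope="module")
def small_mesh():
    return mesh_from_function(flat(0.3), UNIT_SQUARE, 0.5)


class TestResection:
    def test_euclidean_between_given_points(self, flat_mesh):
        e, p, d1, d2 = resection_measure(flat_mesh, (0, 0, 0), (1, 1, 0))
        assert e == pytest.approx(math.sqrt(2), rel=1e-12)

    def test_same_point(self, flat_mesh):
        e, p, d1, d2 = resection_measure(flat_mesh, (0.5, 0.5, 0.0), (0.5, 0.5, 0.0))
        assert (e, p) == (0.0, 0.0)
        assert d1 == d2

    def test_path_matches_networkx_oracle(self, flat_mesh):
        nx = pytest.importorskip("networkx")
        g = nx.Graph()
        for f in flat_mesh.faces:
            for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
                w = float(np.linalg.norm(flat_mesh.vertices[a] - flat_mesh.vertices[b]))
                g.add_edge(int(a), int(b), weight=w)
        _, p, _, _ = resection_measure(flat_mesh, (0, 0, 0), (1, 1, 0))
        oracle = nx.shortest_path_length(g, 0, len(flat_mesh.vertices) - 1,
                                         weight="weight")
        # same endpoints: corner (0,0) is vertex 0, corner (1,1) the last vertex
        assert p == pytest.approx(oracle, rel=1e-12)

    def test_surface_path_bounds_euclidean(self, flat_mesh, rng):
        idx = rng.choice(len(flat_mesh.vertices), size=(10, 2))
        for i, j in idx:
            p1, p2 = flat_mesh.vertices[i], flat_mesh.vertices[j]
            e, p, _, _ = resection_measure(flat_mesh, p1, p2)
            assert p >= e - 1e-12

    def test_far_point_rejected(self, flat_mesh):
        with pytest.raises(MeshError, match="farther than"):
            resection_measure(flat_mesh, (10, 10, 10), (0, 0, 0))


class TestMeasureReport:
    def test_report_identities(self, hemi_mesh):
        rep = measure(hemi_mesh, k=1.2, density=1.0e-3)
        assert rep.area_corrected == pytest.approx(1.2 * rep.area_geometric, rel=1e-12)
        assert rep.mean_density == pytest.approx(rep.mass / rep.volume, rel=1e-9)
        assert rep.n_elements == hemi_mesh.n_elements
        d = rep.to_dict()
        assert set(d) >= {"area_geometric_mm2", "volume_mm3", "mass_g", "centroid_mm"}


class TestExporters:
    @pytest.mark.parametrize("writer,ext", [(write_obj, "obj"), (write_ply, "ply"),
                                            (write_stl, "stl")])
    def test_ascii_and_deterministic(self, tmp_path, small_mesh, writer, ext):
        p1, p2 = tmp_path / f"a.{ext}", tmp_path / f"b.{ext}"
        writer(small_mesh, p1)
        writer(small_mesh, p2)
        assert p1.read_bytes() == p2.read_bytes()
        text = p1.read_text()
        assert text.isascii()

    def test_obj_roundtrip_through_trimesh(self, tmp_path, small_mesh):
        trimesh = pytest.importorskip("trimesh")
        p = tmp_path / "m.obj"
        write_obj(small_mesh, p)
        tm = trimesh.load(str(p), process=False)
        assert np.allclose(tm.vertices, small_mesh.vertices)
        assert np.array_equal(tm.faces, small_mesh.faces)
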