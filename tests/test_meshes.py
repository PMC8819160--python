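"""Voxel meshing, Laplace-based UVC, rule-based fibres, FEC, pacing sites."""

import numpy as np
import pytest

from scarvt.anatomy import BivGeometry, generate_biv_labels, paint_scar
from scarvt.meshes import (
    LV,
    REGIONS,
    RV,
    assign_fibres,
    compute_uvc,
    extract_lv,
    load_mesh,
    mesh_from_labels,
    p1_gradients,
    rv_apical_septal_site,
    save_mesh,
    select_pacing_sites,
    tag_fec,
)
from scarvt.volumes import DEFAULT_LABELS, LabelVolume, ScarSpec


def cylinder_vol(r_endo=7.0, r_epi=12.0, height=20, h=1.0):
    """Annular-wall cylinder phantom: blood inside, open top (base)."""
    n = int(2 * (r_epi + 3) / h)
    nz = int(height / h)
    ii = np.indices((n, n, nz), dtype=float)
    c = (n - 1) / 2.0
    r = np.hypot(ii[0] - c, ii[1] - c) * h
    data = np.zeros((n, n, nz), dtype=np.int32)
    data[r <= r_epi] = DEFAULT_LABELS["lv_wall"]
    data[r <= r_endo] = DEFAULT_LABELS["lv_blood"]
    return LabelVolume(data, spacing=(h, h, h))


@pytest.fixture(scope="module")
def small_biv_mesh(small_geom):
    vol = generate_biv_labels(small_geom)
    mesh = mesh_from_labels(vol)
    uvc = compute_uvc(mesh)
    return mesh, uvc


@pytest.fixture(scope="module")
def cyl_mesh():
    vol = cylinder_vol()
    mesh = mesh_from_labels(vol)
    uvc = compute_uvc(mesh)
    return mesh, uvc


class TestMeshFromLabels:
    def test_slab_element_counts(self):
        data = np.full((10, 10, 10), DEFAULT_LABELS["lv_wall"], dtype=np.int32)
        vol = LabelVolume(data)
        assert mesh_from_labels(vol, mode="hex").n_elements == 1000
        assert mesh_from_labels(vol, mode="tet5").n_elements == 5000
        assert mesh_from_labels(vol, mode="tet6").n_elements == 6000

    def test_volume_identity(self, small_geom):
        vol = generate_biv_labels(small_geom)
        mesh = mesh_from_labels(vol)
        expected = vol.myocardium_mask().sum() * vol.voxel_volume()
        assert abs(mesh.element_volumes().sum() - expected) < 1e-6 * expected

    def test_empty_myocardium_rejected(self):
        vol = LabelVolume(np.zeros((4, 4, 4), dtype=np.int32))
        with pytest.raises(ValueError):
            mesh_from_labels(vol)

    def test_roundtrip_io(self, tmp_path, cyl_mesh):
        mesh, _ = cyl_mesh
        path = str(tmp_path / "m.npz")
        save_mesh(mesh, path)
        back = load_mesh(path)
        assert np.array_equal(back.elements, mesh.elements)
        assert np.allclose(back.nodes, mesh.nodes)


class TestP1:
    def test_gradient_of_linear_field_is_exact(self, cyl_mesh):
        mesh, _ = cyl_mesh
        f = 2.0 * mesh.nodes[:, 0] - 0.5 * mesh.nodes[:, 2]
        g, _ = p1_gradients(mesh)
        grad = np.einsum("ekd,ek->ed", g, f[mesh.elements])
        assert np.allclose(grad, [2.0, 0.0, -0.5], atol=1e-9)


class TestUVC:
    def test_transmural_matches_annulus_harmonic(self, cyl_mesh):
        mesh, uvc = cyl_mesh
        r = np.hypot(mesh.nodes[:, 0] - mesh.nodes[:, 0].mean(),
                     mesh.nodes[:, 1] - mesh.nodes[:, 1].mean())
        # effective boundary radii from the Dirichlet node sets
        r0 = r[mesh.surfaces["endo_lv"]].mean()
        r1 = r[mesh.surfaces["epi"]].mean()
        interior = (r > r0 + 1.0) & (r < r1 - 1.0) & \
            (np.abs(mesh.nodes[:, 2] - mesh.nodes[:, 2].mean()) < 5)
        expected = np.log(r[interior] / r0) / np.log(r1 / r0)
        err = np.abs(uvc.rho[interior] - expected)
        assert np.median(err) < 0.02

    def test_apicobasal_boundary_values(self, small_biv_mesh):
        mesh, uvc = small_biv_mesh
        zmin = mesh.nodes[:, 2].min()
        apex = mesh.nodes[:, 2] <= zmin + 2.0
        assert (uvc.z[apex] <= 0.05).all()
        assert (uvc.z[mesh.surfaces["base"]] >= 0.95).all()

    def test_rotational_angle_antipodal(self, small_biv_mesh):
        mesh, uvc = small_biv_mesh
        # anterior vs posterior mid-wall nodes differ by ~pi in phi
        mid = (uvc.rho > 0.3) & (uvc.rho < 0.7) & (uvc.z > 0.4) & (uvc.z < 0.6)
        ant = mid & (uvc.phi > np.pi / 2 - 0.2) & (uvc.phi < np.pi / 2 + 0.2)
        post = mid & (uvc.phi < -np.pi / 2 + 0.2) & (uvc.phi > -np.pi / 2 - 0.2)
        assert ant.sum() > 0 and post.sum() > 0
        d = np.abs(uvc.phi[ant].mean() - uvc.phi[post].mean())
        assert abs(d - np.pi) < 0.25

    def test_refinement_stability(self):
        # same geometry meshed at h and h/2 (subdivided labels, identical
        # staircase boundary): transmural profile rho(r) must match
        v1 = cylinder_vol(h=1.0)
        v2 = LabelVolume(v1.data.repeat(2, 0).repeat(2, 1).repeat(2, 2),
                         spacing=(0.5, 0.5, 0.5))
        profiles = []
        r_eval = np.linspace(8.0, 11.0, 7)
        for vol in (v1, v2):
            mesh = mesh_from_labels(vol)
            uvc = compute_uvc(mesh)
            r = np.hypot(mesh.nodes[:, 0] - mesh.nodes[:, 0].mean(),
                         mesh.nodes[:, 1] - mesh.nodes[:, 1].mean())
            mid = (np.abs(mesh.nodes[:, 2] - mesh.nodes[:, 2].mean()) < 5) \
                & (r >= 8.0) & (r <= 11.0)
            # harmonic in an annulus is linear in ln(r): fit and evaluate
            A = np.stack([np.log(r[mid]), np.ones(mid.sum())], axis=1)
            coef, *_ = np.linalg.lstsq(A, uvc.rho[mid], rcond=None)
            profiles.append(coef[0] * np.log(r_eval) + coef[1])
        assert np.abs(profiles[0] - profiles[1]).max() < 0.02


class TestFibres:
    def test_zero_angles_give_circumferential_fibres(self, cyl_mesh):
        mesh, uvc = cyl_mesh
        m = assign_fibres(mesh, uvc, angle_endo=0.0, angle_epi=0.0)
        centers = mesh.element_centers()
        cx = centers[:, 0] - mesh.nodes[:, 0].mean()
        cy = centers[:, 1] - mesh.nodes[:, 1].mean()
        rhat = np.stack([cx, cy, np.zeros(len(cx))], axis=1)
        rhat /= np.linalg.norm(rhat, axis=1, keepdims=True)
        radial = np.abs(np.einsum("ed,ed->e", m.fibre, rhat))
        axial = np.abs(m.fibre[:, 2])
        assert np.median(radial) < 0.1
        assert np.median(axial) < 0.1

    def test_fibre_orthogonal_to_transmural_gradient(self, cyl_mesh):
        mesh, uvc = cyl_mesh
        m = assign_fibres(mesh, uvc, 60.0, -60.0)
        g, _ = p1_gradients(mesh)
        grad_rho = np.einsum("ekd,ek->ed", g, uvc.rho[mesh.elements])
        norm = np.linalg.norm(grad_rho, axis=1)
        ok = norm > 1e-6
        dots = np.abs(np.einsum("ed,ed->e", m.fibre[ok],
                                grad_rho[ok] / norm[ok, None]))
        assert np.quantile(dots, 0.9) < 0.15

    def test_unit_norm(self, small_biv_mesh):
        mesh, uvc = small_biv_mesh
        m = assign_fibres(mesh, uvc)
        assert np.abs(np.linalg.norm(m.fibre, axis=1) - 1).max() < 1e-6


class TestFec:
    def test_layer_volume_fraction(self):
        # finer mesh so the one-element-layer floor approaches the 5% depth
        mesh = mesh_from_labels(cylinder_vol(h=0.5))
        uvc = compute_uvc(mesh)
        m = tag_fec(mesh, uvc)
        vols = m.element_volumes()
        frac = vols[(m.region == REGIONS["fec_healthy"])].sum() / vols.sum()
        assert 0.03 < frac < 0.12

    def test_no_scar_no_fec_bz(self, cyl_mesh):
        mesh, uvc = cyl_mesh
        m = tag_fec(mesh, uvc)
        assert (m.region != REGIONS["fec_bz"]).all()

    def test_fec_bz_band_over_transmural_scar(self, small_geom):
        vol = generate_biv_labels(small_geom)
        sv = paint_scar(vol, ScarSpec(extent=(10.0, 11.0)))
        mesh = mesh_from_labels(sv)
        uvc = compute_uvc(mesh)
        m = tag_fec(mesh, uvc)
        assert (m.region == REGIONS["fec_bz"]).sum() > 0
        # outside the endocardial layer, scar core remains scar
        rho_e = uvc.rho[mesh.elements].min(axis=1)
        changed = (mesh.region == REGIONS["scar"]) & (m.region != REGIONS["scar"])
        assert (rho_e[changed] <= 0.05).all()


class TestExtractLv:
    def test_element_bookkeeping(self, small_biv_mesh):
        mesh, uvc = small_biv_mesh
        lv, node_map = extract_lv(mesh, uvc)
        assert lv.n_elements == int((mesh.ventricle == LV).sum())
        assert (node_map[lv.surfaces["endo_lv"]] >= -1).all()

    def test_identity_on_lv_only(self, cyl_mesh):
        mesh, uvc = cyl_mesh
        lv, node_map = extract_lv(mesh, uvc)
        assert lv.n_elements == mesh.n_elements
        assert np.array_equal(node_map, np.arange(mesh.n_nodes))

    def test_rv_septal_fec_survives(self, small_geom):
        vol = generate_biv_labels(small_geom)
        mesh = mesh_from_labels(vol)
        uvc = compute_uvc(mesh)
        m = tag_fec(mesh, uvc)
        lv, _ = extract_lv(m, uvc)
        # FEC elements derived from the RV-facing septal surface are LV
        # elements and must survive extraction
        rv_endo_set = set(mesh.surfaces["endo_rv"].tolist())
        septal_fec = [
            e for e in range(mesh.n_elements)
            if m.region[e] == REGIONS["fec_healthy"]
            and mesh.ventricle[e] == LV
            and rv_endo_set.intersection(mesh.elements[e].tolist())
        ]
        assert len(septal_fec) > 0
        assert (lv.region == REGIONS["fec_healthy"]).sum() > 0


class TestPacingSites:
    def test_biv_site_count_and_separation(self, small_biv_mesh):
        mesh, uvc = small_biv_mesh
        sites = select_pacing_sites(mesh, uvc)
        assert len(sites) == 19
        seeds = mesh.nodes[[s.seed_node for s in sites]]
        d = np.linalg.norm(seeds[:, None] - seeds[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        assert d.min() > 5.0

    def test_lv_only_site_count(self, small_biv_mesh):
        mesh, uvc = small_biv_mesh
        lv, _ = extract_lv(mesh, uvc)
        uvc_lv = compute_uvc(lv)
        sites = select_pacing_sites(lv, uvc_lv)
        assert len(sites) == 17

    def test_rv_apical_septal_site(self, small_biv_mesh):
        mesh, uvc = small_biv_mesh
        site = rv_apical_septal_site(mesh, uvc)
        assert uvc.z[site.seed_node] <= 0.2
        assert site.seed_node in set(mesh.surfaces["endo_rv"].tolist())
        assert len(site.nodes) > 3
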