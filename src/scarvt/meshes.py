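"""Simulation meshes: voxel-derived ventricular meshes, UVC, fibres, FEC.

Meshes are simplicial (line/triangle/tetrahedron) or hexahedral, with a
per-element region tag, fibre unit vector and, for voxel-derived meshes,
provenance linking each element back to its source voxel.  Universal
ventricular coordinates (UVC) are computed from Laplace solves: the
transmural coordinate rho is harmonic between the endocardial (0) and
epicardial (1) surfaces, the apicobasal coordinate z between apex (0) and
base (1), and the rotational angle phi is measured about the LV long axis
referenced to the RV-insertion direction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from .volumes import LabelVolume

logger = logging.getLogger(__name__)

#: per-element region tags
REGIONS = {"healthy": 0, "bz": 1, "scar": 2, "fec_healthy": 3, "fec_bz": 4}
REGION_NAMES = {v: k for k, v in REGIONS.items()}

#: ventricle codes
LV, RV = 0, 1


@dataclass
class VentricularMesh:
    """Unstructured mesh with region tags and fibre vectors."""

    nodes: np.ndarray              # (n, 3) mm
    elements: np.ndarray           # (m, k) node indices; k = 2/3/4/8
    region: np.ndarray             # (m,) int, REGIONS codes
    fibre: np.ndarray | None = None    # (m, 3) unit vectors
    ventricle: np.ndarray | None = None  # (m,) LV/RV
    surfaces: dict = field(default_factory=dict)  # name -> node index array
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def order(self) -> int:
        return self.elements.shape[1]

    def element_centers(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def element_volumes(self) -> np.ndarray:
        """Length / area / volume depending on element order."""
        X = self.nodes[self.elements]
        k = self.order
        if k == 2:
            return np.linalg.norm(X[:, 1] - X[:, 0], axis=1)
        if k == 3:
            return 0.5 * np.linalg.norm(
                np.cross(X[:, 1] - X[:, 0], X[:, 2] - X[:, 0]), axis=1)
        if k == 4:
            return np.abs(np.einsum(
                "ij,ij->i", np.cross(X[:, 1] - X[:, 0], X[:, 2] - X[:, 0]),
                X[:, 3] - X[:, 0])) / 6.0
        if k == 8:
            # axis-aligned voxel hexahedra
            d = X.max(axis=1) - X.min(axis=1)
            return np.prod(d, axis=1)
        raise ValueError(f"unsupported element order {k}")

    def mean_edge(self) -> float:
        X = self.nodes[self.elements]
        k = self.order
        pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
        if k == 8:  # voxel hex: axis edges only
            pairs = [(0, 1), (0, 2), (0, 4)]
        lengths = [np.linalg.norm(X[:, i] - X[:, j], axis=1) for i, j in pairs]
        return float(np.mean(lengths))

    def node_regions(self) -> np.ndarray:
        """Per-node region: the minimum (most conducting) incident tag."""
        out = np.full(self.n_nodes, REGIONS["scar"], dtype=int)
        for j in range(self.order):
            np.minimum.at(out, self.elements[:, j], self.region)
        return out


@dataclass
class UVCoordinates:
    """Universal ventricular coordinates on mesh nodes."""

    rho: np.ndarray       # transmural, 0 endo .. 1 epi
    z: np.ndarray         # apicobasal, 0 apex .. 1 base
    phi: np.ndarray       # rotational, (-pi, pi], 0 toward the RV insertion
    ventricle: np.ndarray  # LV / RV per node


# ---------------------------------------------------------------------------
# voxel meshing
# ---------------------------------------------------------------------------

_TET5_EVEN = [(0, 1, 2, 4), (1, 2, 3, 7), (1, 4, 5, 7), (2, 4, 6, 7), (1, 2, 4, 7)]
_TET5_ODD = [(0, 1, 3, 5), (0, 2, 3, 6), (0, 4, 5, 6), (3, 5, 6, 7), (0, 3, 5, 6)]
# Kuhn triangulation: 6 tets around the main diagonal 0-7, conforming on a grid
_TET6 = [(0, 1, 3, 7), (0, 1, 5, 7), (0, 2, 3, 7),
         (0, 2, 6, 7), (0, 4, 5, 7), (0, 4, 6, 7)]

_LABEL_TO_REGION = {"lv_wall": REGIONS["healthy"], "rv_wall": REGIONS["healthy"],
                    "bz": REGIONS["bz"], "scar": REGIONS["scar"]}


def mesh_from_labels(vol: LabelVolume, mode: str = "tet6") -> VentricularMesh:
    """Mesh the myocardium: one hex (or 5/6 tets) per myocardial voxel.

    Nodes sit at voxel corners; element region tags come from the voxel
    label.  Surface node sets (lv endocardium, rv endocardium, epicardium,
    base) are derived from voxel-face adjacency and stored in
    ``mesh.surfaces``.
    """
    myo = vol.myocardium_mask()
    if not myo.any():
        raise ValueError("no myocardium to mesh")
    L = vol.label_map
    vox = np.argwhere(myo)
    sp_ = np.asarray(vol.spacing)
    origin = np.asarray(vol.origin)

    # corner grid: corner (i,j,k) has world position origin + (idx - 0.5)*sp
    offs = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0],
                     [0, 0, 1], [1, 0, 1], [0, 1, 1], [1, 1, 1]])
    corners = (vox[:, None, :] + offs[None, :, :]).reshape(-1, 3)
    uniq, inv = np.unique(corners.reshape(-1, 3), axis=0, return_inverse=True)
    hex_conn = inv.reshape(-1, 8)
    nodes = origin + (uniq - 0.5) * sp_

    labels = vol.data[tuple(vox.T)]
    region_of_vox = np.zeros(len(vox), dtype=int)
    region_of_vox[labels == L["bz"]] = REGIONS["bz"]
    region_of_vox[labels == L["scar"]] = REGIONS["scar"]
    # ventricle: rv_wall voxels are RV; everything else (incl. scar/bz) LV
    vent_of_vox = np.where(labels == L["rv_wall"], RV, LV)

    if mode == "hex":
        # local corner order: offs index (x-fastest); reorder to VTK-ish hex
        elements = hex_conn[:, [0, 1, 3, 2, 4, 5, 7, 6]]
        region = region_of_vox
        vent = vent_of_vox
        src = np.arange(len(vox))
    elif mode in ("tet5", "tet6"):
        if mode == "tet6":
            patterns = [np.asarray(_TET6)] * 2
            parity = np.zeros(len(vox), dtype=int)
        else:
            patterns = [np.asarray(_TET5_EVEN), np.asarray(_TET5_ODD)]
            parity = vox.sum(axis=1) % 2
        n_t = len(patterns[0])
        elements = np.empty((len(vox) * n_t, 4), dtype=np.int64)
        for p in (0, 1):
            sel = parity == p
            if not sel.any():
                continue
            conn = hex_conn[sel][:, patterns[p]]  # (nv, n_t, 4)
            idx = np.flatnonzero(sel)
            rows = (idx[:, None] * n_t + np.arange(n_t)[None, :]).ravel()
            elements[rows] = conn.reshape(-1, 4)
        region = np.repeat(region_of_vox, n_t)
        vent = np.repeat(vent_of_vox, n_t)
        src = np.repeat(np.arange(len(vox)), n_t)
    else:
        raise ValueError(f"unknown meshing mode {mode!r}")

    surfaces = _surface_nodes(vol, vox, hex_conn)
    mesh = VentricularMesh(
        nodes=nodes, elements=elements, region=region,
        ventricle=vent, surfaces=surfaces,
        meta={"spacing": vol.spacing, "origin": vol.origin,
              "source_voxel": src, "voxel_index": vox,
              "label_grid": vol.data.copy(), "label_map": dict(vol.label_map),
              "mode": mode},
    )
    logger.info("meshed %d voxels -> %d nodes, %d elements (mean edge %.3f mm)",
                len(vox), mesh.n_nodes, mesh.n_elements, mesh.mean_edge())
    return mesh


# voxel-face -> corner indices of that face (offs ordering above)
_FACES = {
    (-1, 0, 0): (0, 2, 4, 6), (1, 0, 0): (1, 3, 5, 7),
    (0, -1, 0): (0, 1, 4, 5), (0, 1, 0): (2, 3, 6, 7),
    (0, 0, -1): (0, 1, 2, 3), (0, 0, 1): (4, 5, 6, 7),
}


def _surface_nodes(vol: LabelVolume, vox: np.ndarray, hex_conn: np.ndarray) -> dict:
    L = vol.label_map
    data = vol.data
    shape = data.shape
    myo = vol.myocardium_mask()
    surf: dict[str, set] = {"endo_lv": set(), "endo_rv": set(),
                            "epi": set(), "base": set()}
    for d, face in _FACES.items():
        nb = vox + d
        inside = ((nb >= 0) & (nb < shape)).all(axis=1)
        nb_lab = np.full(len(vox), -1, dtype=int)
        nb_lab[inside] = data[tuple(nb[inside].T)]
        nb_myo = np.zeros(len(vox), dtype=bool)
        nb_myo[inside] = myo[tuple(nb[inside].T)]
        for name, cond in (
            ("endo_lv", nb_lab == L["lv_blood"]),
            ("endo_rv", nb_lab == L["rv_blood"]),
            ("epi", nb_lab == L["background"]),
        ):
            if cond.any():
                surf[name].update(hex_conn[cond][:, face].ravel().tolist())
        if d == (0, 0, 1):
            # open base: faces at the top of the grid
            top = ~inside
            if top.any():
                surf["base"].update(hex_conn[top][:, face].ravel().tolist())
    return {k: np.array(sorted(v), dtype=np.int64) for k, v in surf.items()}


# ---------------------------------------------------------------------------
# P1 finite elements (shared with the monodomain solver)
# ---------------------------------------------------------------------------

def _clean_meta(meta: dict) -> dict:
    """Copy mesh metadata, dropping cached derived structures ("_" keys).

    Caches (eikonal graphs, KD-trees) bind to a specific mesh's nodes,
    regions and fibres and must not leak into derived meshes.
    """
    return {k: v for k, v in meta.items() if not k.startswith("_")}


def p1_gradients(mesh: VentricularMesh):
    """Shape-function gradients per element: (m, k, 3), and element volumes."""
    X = mesh.nodes[mesh.elements]
    k = mesh.order
    vols = mesh.element_volumes()
    if k == 4:
        g = np.empty((mesh.n_elements, 4, 3))
        e1 = X[:, 1] - X[:, 0]
        e2 = X[:, 2] - X[:, 0]
        e3 = X[:, 3] - X[:, 0]
        J = np.stack([e1, e2, e3], axis=2)  # columns are edges
        Jinv = np.linalg.inv(J)
        # lambda_i = Jinv (x - x0): gradient of lambda_i is row i of Jinv
        g[:, 1:, :] = Jinv
        g[:, 0, :] = -g[:, 1:, :].sum(axis=1)
        return g, vols
    if k == 3:
        # triangles possibly embedded in 3-D: build a local 2-D frame
        e1 = X[:, 1] - X[:, 0]
        e2 = X[:, 2] - X[:, 0]
        n = np.cross(e1, e2)
        nn = np.linalg.norm(n, axis=1, keepdims=True)
        u = e1 / np.linalg.norm(e1, axis=1, keepdims=True)
        w = np.cross(n / np.maximum(nn, 1e-30), u)
        # 2-D coords of the three vertices
        p = np.zeros((mesh.n_elements, 3, 2))
        p[:, 1, 0] = np.einsum("ij,ij->i", e1, u)
        p[:, 2, 0] = np.einsum("ij,ij->i", e2, u)
        p[:, 2, 1] = np.einsum("ij,ij->i", e2, w)
        g2 = np.empty((mesh.n_elements, 3, 2))
        a2 = 2.0 * vols
        for i, (j, l) in enumerate(((1, 2), (2, 0), (0, 1))):
            edge = p[:, l] - p[:, j]
            g2[:, i, 0] = -edge[:, 1] / a2
            g2[:, i, 1] = edge[:, 0] / a2
        g = g2[..., 0:1] * u[:, None, :] + g2[..., 1:2] * w[:, None, :]
        return g, vols
    if k == 2:
        L = vols
        t = (X[:, 1] - X[:, 0]) / L[:, None]
        g = np.stack([-t / L[:, None], t / L[:, None]], axis=1)
        return g, vols
    raise ValueError("P1 gradients require simplicial elements")


def stiffness_matrix(mesh: VentricularMesh, sigma: np.ndarray | float = 1.0,
                     mask: np.ndarray | None = None) -> sp.csr_matrix:
    """Assemble the P1 stiffness matrix; ``sigma`` is (m,3,3), (m,) or scalar."""
    g, vols = p1_gradients(mesh)
    k = mesh.order
    if mask is None:
        mask = np.ones(mesh.n_elements, dtype=bool)
    ge = g[mask]
    ve = vols[mask]
    if np.ndim(sigma) == 3:
        flux = np.einsum("eab,ekb->eka", np.asarray(sigma)[mask], ge)
    else:
        s = np.broadcast_to(np.asarray(sigma, dtype=float), (mesh.n_elements,))[mask]
        flux = s[:, None, None] * ge
    Ke = np.einsum("eia,eja->eij", flux, ge) * ve[:, None, None]
    conn = mesh.elements[mask]
    rows = np.repeat(conn, k, axis=1).ravel()
    cols = np.tile(conn, (1, k)).ravel()
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)),
                      shape=(mesh.n_nodes, mesh.n_nodes))
    return K.tocsr()


def lumped_mass(mesh: VentricularMesh, mask: np.ndarray | None = None) -> np.ndarray:
    vols = mesh.element_volumes()
    if mask is not None:
        vols = np.where(mask, vols, 0.0)
    m = np.zeros(mesh.n_nodes)
    share = vols / mesh.order
    for j in range(mesh.order):
        np.add.at(m, mesh.elements[:, j], share)
    return m


def solve_laplace(mesh: VentricularMesh, dirichlet: dict[int, float] | tuple,
                  mask: np.ndarray | None = None) -> np.ndarray:
    """Solve Laplace's equation with Dirichlet data ``{node: value}``."""
    if isinstance(dirichlet, tuple):
        nodes_bc, vals_bc = dirichlet
    else:
        nodes_bc = np.array(list(dirichlet.keys()), dtype=np.int64)
        vals_bc = np.array(list(dirichlet.values()), dtype=float)
    K = stiffness_matrix(mesh, 1.0, mask=mask)
    n = mesh.n_nodes
    fixed = np.zeros(n, dtype=bool)
    fixed[nodes_bc] = True
    x = np.zeros(n)
    x[nodes_bc] = vals_bc
    free = ~fixed
    # nodes not touched by any active element: pin to 0 to keep K_ff SPD
    active = np.zeros(n, dtype=bool)
    conn = mesh.elements if mask is None else mesh.elements[mask]
    active[np.unique(conn)] = True
    free &= active
    Kff = K[free][:, free]
    rhs = -K[free][:, fixed] @ x[fixed]
    x[free] = spla.spsolve(Kff.tocsc(), rhs)
    return x


# ---------------------------------------------------------------------------
# UVC
# ---------------------------------------------------------------------------

def compute_uvc(mesh: VentricularMesh, apex_band: float = 2.0,
                base_band: float = 1.0) -> UVCoordinates:
    """Universal ventricular coordinates from Laplace solves.

    rho: harmonic, endocardium (LV and RV) = 0, epicardium = 1.  z:
    harmonic, apex (nodes within ``apex_band`` mm of the lowest myocardial
    point) = 0, base = 1.  phi: geometric angle about the LV long axis with
    0 at the RV-insertion (septum-centre) direction.
    """
    surf = mesh.surfaces
    if not surf.get("endo_lv", np.array([])).size:
        raise ValueError("mesh carries no endocardial surface information")
    n = mesh.n_nodes

    endo = np.concatenate([surf["endo_lv"], surf.get("endo_rv", np.array([], dtype=int))])
    epi = surf["epi"]
    bc_nodes = np.concatenate([endo, epi])
    bc_vals = np.concatenate([np.zeros(len(endo)), np.ones(len(epi))])
    # deduplicate (corner nodes can sit on two surfaces; endo wins)
    _, first = np.unique(bc_nodes, return_index=True)
    rho = solve_laplace(mesh, (bc_nodes[np.sort(first)], bc_vals[np.sort(first)]))
    rho = np.clip(rho, 0.0, 1.0)

    zmin = mesh.nodes[:, 2].min()
    apex_nodes = np.flatnonzero(mesh.nodes[:, 2] <= zmin + apex_band)
    base_nodes = surf["base"]
    bn = np.concatenate([apex_nodes, base_nodes])
    bv = np.concatenate([np.zeros(len(apex_nodes)), np.ones(len(base_nodes))])
    z = solve_laplace(mesh, (bn, bv))
    z = np.clip(z, 0.0, 1.0)

    # rotational angle about the LV centroid axis, referenced to RV direction
    lv_nodes = mesh.nodes[np.unique(mesh.elements[(mesh.ventricle == LV)])]
    cx, cy = lv_nodes[:, 0].mean(), lv_nodes[:, 1].mean()
    if (mesh.ventricle == RV).any():
        rv_c = mesh.nodes[np.unique(mesh.elements[mesh.ventricle == RV])].mean(axis=0)
        phi0 = np.arctan2(rv_c[1] - cy, rv_c[0] - cx)
    else:
        phi0 = 0.0
    phi = np.arctan2(mesh.nodes[:, 1] - cy, mesh.nodes[:, 0] - cx) - phi0
    phi = (phi + np.pi) % (2 * np.pi) - np.pi

    vent = np.full(n, LV, dtype=int)
    rv_nodes = np.unique(mesh.elements[mesh.ventricle == RV])
    vent[rv_nodes] = RV
    # nodes shared with LV elements stay LV (septum is LV territory)
    lv_set = np.unique(mesh.elements[mesh.ventricle == LV])
    vent[lv_set] = LV
    return UVCoordinates(rho=rho, z=z, phi=phi, ventricle=vent)


def assign_fibres(mesh: VentricularMesh, uvc: UVCoordinates,
                  angle_endo: float = 60.0, angle_epi: float = -60.0,
                  tol: float = 1e-8) -> VentricularMesh:
    """Rule-based fibres: helix angle linear in transmural depth.

    Builds a local frame per element from the gradients of rho (transmural)
    and z (longitudinal); the fibre lies in the plane orthogonal to the
    transmural direction, rotated from circumferential by the helix angle
    interpolated linearly from ``angle_endo`` (rho=0) to ``angle_epi``
    (rho=1).  Degenerate frames inherit the fibre of the nearest valid
    element.
    """
    g, _ = p1_gradients(mesh)
    grad_rho = np.einsum("ekd,ek->ed", g, uvc.rho[mesh.elements])
    grad_z = np.einsum("ekd,ek->ed", g, uvc.z[mesh.elements])

    t = grad_rho / np.maximum(np.linalg.norm(grad_rho, axis=1, keepdims=True), 1e-30)
    lz = grad_z - np.einsum("ed,ed->e", grad_z, t)[:, None] * t
    nl = np.linalg.norm(lz, axis=1)
    c = np.cross(lz, t)
    nc = np.linalg.norm(c, axis=1)
    valid = (np.linalg.norm(grad_rho, axis=1) > tol) & (nl > tol) & (nc > tol)
    lz[valid] /= nl[valid, None]
    c[valid] /= nc[valid, None]

    rho_e = uvc.rho[mesh.elements].mean(axis=1)
    alpha = np.deg2rad(angle_endo + rho_e * (angle_epi - angle_endo))
    fib = np.cos(alpha)[:, None] * c + np.sin(alpha)[:, None] * lz

    if (~valid).any():
        warnings.warn(f"{(~valid).sum()} degenerate fibre frames; "
                      "inheriting from nearest valid element")
        centers = mesh.element_centers()
        tree = cKDTree(centers[valid])
        _, nn = tree.query(centers[~valid])
        fib[~valid] = fib[valid][nn]
    fib /= np.linalg.norm(fib, axis=1, keepdims=True)
    out = VentricularMesh(mesh.nodes, mesh.elements, mesh.region.copy(),
                          fibre=fib, ventricle=mesh.ventricle,
                          surfaces=mesh.surfaces, meta=_clean_meta(mesh.meta))
    return out


def tag_fec(mesh: VentricularMesh, uvc: UVCoordinates,
            thickness: float = 0.05) -> VentricularMesh:
    """Tag the fast-endocardial-conduction layer (rho <= ``thickness``).

    healthy -> fec_healthy, bz -> fec_bz; scar-core elements in the layer
    become fec_bz, representing the thin sheet of surviving endocardial
    tissue over scar.  The per-element transmural depth is the minimum over
    the element's nodes, so the layer is never thinner than one element —
    at coarse desk resolutions the element size, not ``thickness``, sets
    the effective layer thickness.
    """
    rho_e = uvc.rho[mesh.elements].min(axis=1)
    region = mesh.region.copy()
    inlayer = rho_e <= thickness
    region[inlayer & (mesh.region == REGIONS["healthy"])] = REGIONS["fec_healthy"]
    region[inlayer & (mesh.region == REGIONS["bz"])] = REGIONS["fec_bz"]
    region[inlayer & (mesh.region == REGIONS["scar"])] = REGIONS["fec_bz"]
    return VentricularMesh(mesh.nodes, mesh.elements, region,
                           fibre=mesh.fibre, ventricle=mesh.ventricle,
                           surfaces=mesh.surfaces, meta=_clean_meta(mesh.meta))


def extract_lv(mesh: VentricularMesh, uvc: UVCoordinates | None = None):
    """Remove the RV free wall, keeping the septum and its RV-facing FEC.

    Returns ``(lv_mesh, node_map)`` where ``node_map[old] = new`` (-1 for
    dropped nodes).  The septum (including scar/BZ and any FEC tagged from
    the RV side) is LV territory and survives.
    """
    keep = mesh.ventricle == LV
    if keep.all():
        return mesh, np.arange(mesh.n_nodes)
    conn = mesh.elements[keep]
    used = np.unique(conn)
    node_map = np.full(mesh.n_nodes, -1, dtype=np.int64)
    node_map[used] = np.arange(len(used))
    surfaces = {}
    for name, idx in mesh.surfaces.items():
        mapped = node_map[idx]
        surfaces[name] = np.sort(mapped[mapped >= 0])
    out = VentricularMesh(
        nodes=mesh.nodes[used], elements=node_map[conn],
        region=mesh.region[keep],
        fibre=None if mesh.fibre is None else mesh.fibre[keep],
        ventricle=mesh.ventricle[keep], surfaces=surfaces,
        meta=_clean_meta(mesh.meta))
    if "source_voxel" in out.meta and len(out.meta["source_voxel"]) == len(keep):
        out.meta["source_voxel"] = out.meta["source_voxel"][keep]
    return out, node_map


# ---------------------------------------------------------------------------
# pacing sites
# ---------------------------------------------------------------------------

@dataclass
class PacingSite:
    name: str
    seed_node: int
    nodes: np.ndarray  # all nodes within the stimulus radius


def _site_from_seed(mesh: VentricularMesh, seed: int, radius: float) -> np.ndarray:
    tree = mesh.meta.get("_node_tree")
    if tree is None:
        tree = cKDTree(mesh.nodes)
        mesh.meta["_node_tree"] = tree
    return np.array(sorted(tree.query_ball_point(mesh.nodes[seed], radius)),
                    dtype=np.int64)


def select_pacing_sites(mesh: VentricularMesh, uvc: UVCoordinates,
                        n_lv: int = 17, n_rv: int = 2,
                        radius: float = 2.5) -> list[PacingSite]:
    """Pacing sites on an AHA-17-style (z, phi) grid of the LV endocardium.

    17 LV sites (apex + apical/mid/basal rings) plus, when an RV is present,
    2 RV sites (apex and free wall).  Each site is the set of nodes within
    ``radius`` mm of its seed node; sites whose seed falls in scar core are
    dropped with a warning.
    """
    node_region = mesh.node_regions()
    sites: list[PacingSite] = []

    def nearest(cands: np.ndarray, z0: float, phi0: float) -> int:
        dz = uvc.z[cands] - z0
        dphi = (uvc.phi[cands] - phi0 + np.pi) % (2 * np.pi) - np.pi
        return int(cands[np.argmin(dz ** 2 + (0.3 * dphi) ** 2)])

    lv_endo = mesh.surfaces["endo_lv"]
    layout = [(0.08, [0.0])]  # apex cap
    specs = [(0.28, 4), (0.52, 6), (0.78, 6)]  # apical/mid/basal rings
    for z0, count in specs:
        layout.append((z0, list(np.linspace(-np.pi, np.pi, count, endpoint=False))))
    for z0, phis in layout:
        for phi0 in phis:
            seed = nearest(lv_endo, z0, phi0)
            name = f"lv_z{z0:.2f}_phi{phi0:+.2f}"
            if node_region[seed] == REGIONS["scar"]:
                warnings.warn(f"pacing site {name} falls in scar core; dropped")
                logger.warning("dropped pacing site %s (scar core)", name)
                continue
            sites.append(PacingSite(name, seed, _site_from_seed(mesh, seed, radius)))

    has_rv = mesh.ventricle is not None and (mesh.ventricle == RV).any()
    if n_rv > 0 and has_rv and mesh.surfaces.get("endo_rv", np.array([])).size:
        rv_endo = mesh.surfaces["endo_rv"]
        apex_seed = int(rv_endo[np.argmin(uvc.z[rv_endo])])
        sites.append(PacingSite("rv_apex", apex_seed,
                                _site_from_seed(mesh, apex_seed, radius)))
        # free wall: most lateral mid-height RV endo node
        free = rv_endo[np.abs(uvc.z[rv_endo] - 0.5) < 0.2]
        if free.size == 0:
            free = rv_endo
        lateral = int(free[np.argmax(mesh.nodes[free, 0])])
        sites.append(PacingSite("rv_free_wall", lateral,
                                _site_from_seed(mesh, lateral, radius)))
    return sites


def rv_apical_septal_site(mesh: VentricularMesh, uvc: UVCoordinates,
                          radius: float = 2.5) -> PacingSite:
    """Mid-septal point on the RV side closest to the RV apex.

    Septal RV-facing endocardial nodes are RV-endo nodes that belong to LV
    (septal) elements; in an LV-only mesh the retained RV-septal surface is
    used directly.
    """
    rv_endo = mesh.surfaces.get("endo_rv", np.array([], dtype=int))
    if rv_endo.size == 0:
        raise ValueError("no RV endocardial surface available")
    lv_nodes = np.zeros(mesh.n_nodes, dtype=bool)
    lv_nodes[np.unique(mesh.elements[mesh.ventricle == LV])] = True
    septal = rv_endo[lv_nodes[rv_endo]]
    if septal.size == 0:
        septal = rv_endo
    # mid-septal circumferentially, apical: lowest apicobasal coordinate
    phis = uvc.phi[septal]
    mid = septal[np.abs((phis + np.pi) % (2 * np.pi) - np.pi) < np.deg2rad(40)]
    if mid.size == 0:
        mid = septal
    seed = int(mid[np.argmin(uvc.z[mid])])
    return PacingSite("rv_apical_septal", seed, _site_from_seed(mesh, seed, radius))


# ---------------------------------------------------------------------------
# analytic phantom meshes (strand / sheet / ring) for the solvers
# ---------------------------------------------------------------------------

def strand_mesh(length: float = 20.0, h: float = 0.325) -> VentricularMesh:
    """1-D strand along x with fibre +x (for CV tuning)."""
    n = int(round(length / h)) + 1
    nodes = np.zeros((n, 3))
    nodes[:, 0] = np.arange(n) * h
    elements = np.stack([np.arange(n - 1), np.arange(1, n)], axis=1)
    region = np.zeros(n - 1, dtype=int)
    fibre = np.tile([1.0, 0.0, 0.0], (n - 1, 1))
    return VentricularMesh(nodes, elements, region, fibre=fibre,
                           ventricle=np.zeros(n - 1, dtype=int),
                           meta={"h": h, "kind": "strand"})


def sheet_mesh(lx: float, ly: float, h: float = 1.0,
               region_fn=None, fibre_angle: float = 0.0) -> VentricularMesh:
    """Triangulated 2-D sheet in the z=0 plane.

    ``region_fn(x, y)`` maps element-centre coordinates to REGIONS codes
    (vectorized); fibres lie in-plane at ``fibre_angle`` degrees from +x.
    """
    nx, ny = int(round(lx / h)), int(round(ly / h))
    xs = np.arange(nx + 1) * h
    ys = np.arange(ny + 1) * h
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel(), np.zeros(X.size)], axis=1)

    def nid(i, j):
        return i * (ny + 1) + j

    i, j = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    i, j = i.ravel(), j.ravel()
    t1 = np.stack([nid(i, j), nid(i + 1, j), nid(i + 1, j + 1)], axis=1)
    t2 = np.stack([nid(i, j), nid(i + 1, j + 1), nid(i, j + 1)], axis=1)
    elements = np.concatenate([t1, t2], axis=0)
    mesh = VentricularMesh(
        nodes, elements, np.zeros(len(elements), dtype=int),
        ventricle=np.zeros(len(elements), dtype=int),
        meta={"h": h, "kind": "sheet"})
    centers = mesh.element_centers()
    if region_fn is not None:
        mesh.region = np.asarray(region_fn(centers[:, 0], centers[:, 1]), dtype=int)
    a = np.deg2rad(fibre_angle)
    mesh.fibre = np.tile([np.cos(a), np.sin(a), 0.0], (mesh.n_elements, 1))
    return mesh


def ring_mesh(r_inner: float, r_outer: float, h: float = 1.0) -> VentricularMesh:
    """Annulus in the z=0 plane with circumferential fibres (re-entry tests)."""
    pad = h
    l = 2 * (r_outer + pad)
    mesh = sheet_mesh(l, l, h=h)
    c = l / 2.0
    centers = mesh.element_centers()
    r = np.hypot(centers[:, 0] - c, centers[:, 1] - c)
    keep = (r >= r_inner) & (r <= r_outer)
    conn = mesh.elements[keep]
    used = np.unique(conn)
    remap = np.full(mesh.n_nodes, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    nodes = mesh.nodes[used] - [c, c, 0.0]
    elements = remap[conn]
    centers = nodes[elements].mean(axis=1)
    theta = np.arctan2(centers[:, 1], centers[:, 0])
    fibre = np.stack([-np.sin(theta), np.cos(theta),
                      np.zeros(len(theta))], axis=1)
    return VentricularMesh(nodes, elements,
                           np.zeros(len(elements), dtype=int), fibre=fibre,
                           ventricle=np.zeros(len(elements), dtype=int),
                           meta={"h": h, "kind": "ring",
                                 "r_inner": r_inner, "r_outer": r_outer})


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def save_mesh(mesh: VentricularMesh, path: str) -> None:
    """Save to .npz (lossless) or legacy ASCII .vtk (for visualisation)."""
    if path.endswith(".vtk"):
        _write_vtk(mesh, path)
        return
    np.savez_compressed(
        path, nodes=mesh.nodes, elements=mesh.elements, region=mesh.region,
        fibre=mesh.fibre if mesh.fibre is not None else np.zeros((0, 3)),
        ventricle=mesh.ventricle if mesh.ventricle is not None else np.zeros(0),
        **{f"surf_{k}": v for k, v in mesh.surfaces.items()})


def load_mesh(path: str) -> VentricularMesh:
    d = np.load(path)
    surfaces = {k[5:]: d[k] for k in d.files if k.startswith("surf_")}
    fibre = d["fibre"] if d["fibre"].size else None
    vent = d["ventricle"] if d["ventricle"].size else None
    return VentricularMesh(d["nodes"], d["elements"], d["region"],
                           fibre=fibre, ventricle=vent, surfaces=surfaces)


_VTK_CELL = {2: 3, 3: 5, 4: 10, 8: 12}


def _write_vtk(mesh: VentricularMesh, path: str,
               node_data: dict[str, np.ndarray] | None = None) -> None:
    k = mesh.order
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nscarvt mesh\nASCII\n"
                "DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.n_nodes} float\n")
        np.savetxt(f, mesh.nodes, fmt="%.6g")
        f.write(f"CELLS {mesh.n_elements} {mesh.n_elements * (k + 1)}\n")
        cells = np.column_stack([np.full(mesh.n_elements, k), mesh.elements])
        np.savetxt(f, cells, fmt="%d")
        f.write(f"CELL_TYPES {mesh.n_elements}\n")
        np.savetxt(f, np.full(mesh.n_elements, _VTK_CELL[k]), fmt="%d")
        f.write(f"CELL_DATA {mesh.n_elements}\n"
                "SCALARS region int 1\nLOOKUP_TABLE default\n")
        np.savetxt(f, mesh.region, fmt="%d")
        if node_data:
            f.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in node_data.items():
                f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                np.savetxt(f, arr, fmt="%.6g")
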