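"""Registration of mapping-catheter point clouds and activation scoring.

Electroanatomical point clouds (x, y, z, LAT) are rigidly registered onto
the model endocardium with iterative-closest-point alignment (rotation +
translation, no scaling), then scored against the simulated activation map
by nearest-neighbour lookup of the point-wise absolute LAT difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .eikonal import ActivationMap
from .meshes import VentricularMesh

logger = logging.getLogger(__name__)


@dataclass
class RigidTransform:
    rotation: np.ndarray     # (3, 3) proper orthogonal
    translation: np.ndarray  # (3,)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return pts @ self.rotation.T + self.translation

    def __post_init__(self):
        R = self.rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthogonal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det +1)")


def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping src onto dst."""
    cs = src.mean(axis=0)
    cd = dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return RigidTransform(rotation=R, translation=cd - R @ cs)


def rigid_register(points: np.ndarray, surface_nodes: np.ndarray,
                   max_iter: int = 200, tol: float = 1e-7) -> dict:
    """Iterative-closest-point rigid alignment of a cloud onto a surface.

    Returns ``{"transform": RigidTransform, "rms": float, "iterations": n}``;
    raises on fewer than 3 non-collinear points or non-convergence.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or len(points) < 3:
        raise ValueError("need at least 3 points to register")
    if np.linalg.matrix_rank(points - points.mean(axis=0)) < 2:
        raise ValueError("points are collinear")
    tree = cKDTree(surface_nodes)
    current = RigidTransform(np.eye(3), np.zeros(3))
    moved = points.copy()
    last_rms = np.inf
    history = []
    for it in range(max_iter):
        d, nn = tree.query(moved)
        rms = float(np.sqrt((d ** 2).mean()))
        history.append(rms)
        if abs(last_rms - rms) < tol:
            return {"transform": current, "rms": rms, "iterations": it + 1}
        last_rms = rms
        step = _kabsch(moved, surface_nodes[nn])
        moved = step.apply(moved)
        current = RigidTransform(step.rotation @ current.rotation,
                                 step.rotation @ current.translation
                                 + step.translation)
    raise RuntimeError(f"ICP did not converge; rms trace: {history[-5:]}")


@dataclass
class MappedPointCloud:
    points: np.ndarray            # registered positions (p, 3)
    lat: np.ndarray               # measured LATs (p,)
    transform: RigidTransform
    nearest_node: np.ndarray | None = None
    distance: np.ndarray | None = None


def map_cloud(points: np.ndarray, lat: np.ndarray,
              mesh: VentricularMesh,
              surface: str = "endo_lv") -> MappedPointCloud:
    """Register a point cloud to a mesh surface and attach node matches."""
    surf_nodes = mesh.nodes[mesh.surfaces[surface]]
    reg = rigid_register(points, surf_nodes)
    moved = reg["transform"].apply(np.asarray(points, dtype=float))
    tree = cKDTree(surf_nodes)
    d, nn = tree.query(moved)
    return MappedPointCloud(points=moved, lat=np.asarray(lat, dtype=float),
                            transform=reg["transform"],
                            nearest_node=mesh.surfaces[surface][nn],
                            distance=d)


def lat_error(cloud: MappedPointCloud, atmap: ActivationMap,
              align_origin: bool = True, distance_gate: float = 5.0) -> dict:
    """Point-wise |measured - simulated| LAT statistics.

    Both LAT sets are zeroed at their stimulus time (minimum) when
    ``align_origin``; points farther than ``distance_gate`` mm from the
    surface are excluded (count reported).
    """
    if cloud.lat.size == 0:
        raise ValueError("empty point cloud")
    sim = atmap.at[cloud.nearest_node]
    ok = np.isfinite(sim)
    if cloud.distance is not None:
        ok &= cloud.distance <= distance_gate
    if not ok.any():
        raise ValueError("no usable points after gating")
    exp = cloud.lat[ok].astype(float)
    sim = sim[ok]
    if align_origin:
        exp = exp - exp.min()
        sim = sim - sim.min()
    err = np.abs(exp - sim)
    return {"mean": float(err.mean()), "sd": float(err.std(ddof=0)),
            "per_point": err, "n_used": int(ok.sum()),
            "n_excluded": int((~ok).sum())}


def study_report(lat_results: dict | None = None,
                 pes_results: dict | None = None) -> dict[str, pd.DataFrame]:
    """Aggregate per-model outputs into tidy summary tables.

    ``lat_results``: model name -> lat_error dict; ``pes_results``: model
    name -> vt_heatmap dict.  Returns DataFrames keyed 'lat_error',
    'vt_heatmap', 'cycle_lengths'.
    """
    tables: dict[str, pd.DataFrame] = {}
    if lat_results:
        tables["lat_error"] = pd.DataFrame(
            [{"model": k, "mean_ms": v["mean"], "sd_ms": v["sd"],
              "n_used": v["n_used"], "n_excluded": v["n_excluded"]}
             for k, v in lat_results.items()]).set_index("model")
    else:
        tables["lat_error"] = pd.DataFrame(
            columns=["mean_ms", "sd_ms", "n_used", "n_excluded"])
    if pes_results:
        tables["vt_heatmap"] = pd.DataFrame(
            [{"model": k, "percent_induced": v["percent_induced"],
              "vt_positive": v["vt_positive"], "n_sites": v["n_sites"]}
             for k, v in pes_results.items()]).set_index("model")
        rows = []
        for k, v in pes_results.items():
            for cl in v.get("cycle_lengths", []):
                rows.append({"model": k, "cycle_length_ms": cl})
        tables["cycle_lengths"] = pd.DataFrame(
            rows, columns=["model", "cycle_length_ms"])
    else:
        tables["vt_heatmap"] = pd.DataFrame(
            columns=["percent_induced", "vt_positive", "n_sites"])
        tables["cycle_lengths"] = pd.DataFrame(
            columns=["model", "cycle_length_ms"])
    return tables


def load_eam_csv(path: str) -> tuple[np.ndarray, np.ndarray]:
    """Read an EAM-style x,y,z,LAT CSV."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    pts = df[[cols["x"], cols["y"], cols["z"]]].to_numpy(dtype=float)
    lat = df[cols["lat"]].to_numpy(dtype=float)
    return pts, lat


def save_eam_csv(path: str, points: np.ndarray, lat: np.ndarray) -> None:
    pd.DataFrame({"x": points[:, 0], "y": points[:, 1], "z": points[:, 2],
                  "lat": lat}).to_csv(path, index=False)
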