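"""Synthetic ventricular anatomy generation.

Produces labelled voxel volumes that emulate segmented LGE-MRI of an
infarcted two-ventricle heart: an idealized truncated-ellipsoid LV with a
crescent-shaped RV, an anteroseptal scar with configurable conducting
isthmus and border-zone rim, synthetic late-enhancement intensities, and
clinical z-direction down-sampling.

Conventions: the LV long axis is z with the apex at low z and an open base
at high z; the RV lies on the +x side, so the septum faces +x and the
"anterior" wall faces +y.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from scipy.stats import mode as _mode

from .volumes import DEFAULT_LABELS, LabelVolume, ScarSpec


class DegenerateGeometryError(ValueError):
    """Requested geometry cannot be resolved on the voxel grid."""


@dataclasses.dataclass(frozen=True)
class BivGeometry:
    """Idealized two-ventricle geometry (all lengths mm).

    The LV is a truncated prolate ellipsoid; the RV blood pool is a larger
    overlapping ellipsoid clipped against the LV epicardium, whose wall is
    built by uniform dilation (mirroring how an RV wall is created from a
    segmented blood pool when the free wall is too thin to segment).
    """

    lv_epi_radii: tuple[float, float, float] = (25.0, 25.0, 45.0)
    lv_wall_thickness: float = 9.0
    rv_center: tuple[float, float, float] = (14.0, 0.0, 0.0)
    rv_radii: tuple[float, float, float] = (30.0, 21.0, 42.0)
    rv_wall_thickness: float = 4.0
    base_frac: float = 0.45  # base cut plane as a fraction of the LV z semi-axis
    margin: float = 5.0

    def scaled(self, s: float) -> "BivGeometry":
        """Uniformly scaled copy (handy for small desk-test hearts)."""
        return BivGeometry(
            lv_epi_radii=tuple(x * s for x in self.lv_epi_radii),
            lv_wall_thickness=self.lv_wall_thickness * s,
            rv_center=tuple(x * s for x in self.rv_center),
            rv_radii=tuple(x * s for x in self.rv_radii),
            rv_wall_thickness=self.rv_wall_thickness * s,
            base_frac=self.base_frac,
            margin=self.margin,
        )


def _drop_small_components(mask: np.ndarray, min_size: int = 8) -> np.ndarray:
    """Remove 6-connected components smaller than ``min_size`` voxels."""
    lab, n = ndimage.label(mask, structure=ndimage.generate_binary_structure(3, 1))
    if n <= 1:
        return mask
    sizes = np.bincount(lab.ravel())
    keep = np.flatnonzero(sizes >= min_size)
    keep = keep[keep > 0]
    return np.isin(lab, keep)


def _ellipsoid(coords, center, radii) -> np.ndarray:
    x, y, z = coords
    cx, cy, cz = center
    a, b, c = radii
    return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - cz) / c) ** 2 <= 1.0


def generate_biv_labels(
    geom: BivGeometry | None = None,
    spacing: float | tuple[float, float, float] = 1.0,
) -> LabelVolume:
    """Generate a labelled two-ventricle volume.

    Returns a :class:`LabelVolume` with closed LV and RV walls, blood pools
    and an open base.  Raises :class:`DegenerateGeometryError` when a wall
    is thinner than two voxels.
    """
    geom = geom or BivGeometry()
    if np.isscalar(spacing):
        spacing = (float(spacing),) * 3
    spacing = tuple(float(s) for s in spacing)
    if max(spacing) > 2.0:
        raise ValueError("spacing must be <= 2 mm")
    if geom.lv_wall_thickness < 2 * max(spacing) or geom.rv_wall_thickness < 2 * max(spacing):
        raise DegenerateGeometryError(
            "wall thinner than 2 voxels at this spacing")

    a, b, c = geom.lv_epi_radii
    t = geom.lv_wall_thickness
    z_base = geom.base_frac * c
    m = geom.margin
    lo = np.array([min(-a, geom.rv_center[0] - geom.rv_radii[0]) - m,
                   min(-b, geom.rv_center[1] - geom.rv_radii[1]) - m,
                   -c - m])
    hi = np.array([max(a, geom.rv_center[0] + geom.rv_radii[0]) + m,
                   max(b, geom.rv_center[1] + geom.rv_radii[1]) + m,
                   z_base])
    shape = np.floor((hi - lo) / spacing).astype(int) + 1
    idx = np.indices(shape, dtype=float)
    coords = [lo[i] + idx[i] * spacing[i] for i in range(3)]
    below_base = coords[2] <= z_base + 1e-9

    lv_epi = _ellipsoid(coords, (0, 0, 0), (a, b, c)) & below_base
    lv_endo = _ellipsoid(coords, (0, 0, 0), (a - t, b - t, c - t)) & below_base
    lv_wall = lv_epi & ~lv_endo
    lv_blood = lv_endo

    rv_cav = _ellipsoid(coords, geom.rv_center, geom.rv_radii) & below_base
    rv_blood = rv_cav & ~lv_epi
    rv_blood = _drop_small_components(rv_blood, min_size=max(8, int(rv_blood.sum() * 0.01)))
    if not rv_blood.any():
        raise DegenerateGeometryError("RV blood pool empty; check rv_center/rv_radii")

    data = np.zeros(tuple(shape), dtype=np.int32)
    L = DEFAULT_LABELS
    data[lv_wall] = L["lv_wall"]
    data[lv_blood] = L["lv_blood"]
    data[rv_blood] = L["rv_blood"]

    vol = LabelVolume(data, spacing=spacing, origin=tuple(lo),
                      meta={"geom": dataclasses.asdict(geom), "z_base": z_base})
    vol = dilate_rv_bloodpool(vol, radius=geom.rv_wall_thickness)
    # the dilation step leaves the base open by construction (grid is clipped)
    return vol


def dilate_rv_bloodpool(vol: LabelVolume, radius: float = 4.0) -> LabelVolume:
    """Create/replace the RV wall by uniform dilation of the RV blood pool.

    ``rv_wall`` becomes every voxel whose centre lies within ``radius`` mm of
    the blood pool (exclusive of the pool itself) that is not an LV label.
    """
    if radius <= 0:
        raise ValueError("dilation radius must be positive")
    L = vol.label_map
    rv_blood = vol.mask("rv_blood")
    if not rv_blood.any():
        raise ValueError("no rv_blood label present")
    dist = ndimage.distance_transform_edt(~rv_blood, sampling=vol.spacing)
    shell = (dist > 0) & (dist <= radius)
    lv_labels = vol.mask("lv_wall", "lv_blood", "scar", "bz")
    new_wall = shell & ~lv_labels
    data = vol.data.copy()
    data[data == L["rv_wall"]] = L["background"]
    data[new_wall] = L["rv_wall"]
    return vol.copy(data=data)


# ---------------------------------------------------------------------------
# scar painting
# ---------------------------------------------------------------------------

def _lv_cylindrical(vol: LabelVolume):
    """Cylindrical coordinates of every voxel about the LV long axis.

    Returns (apicobasal fraction, angle rad relative to the septum
    direction, in-plane radius mm) arrays over the full grid.
    """
    wall = vol.mask("lv_wall", "scar", "bz")
    if not wall.any():
        raise ValueError("no LV wall present")
    ii = np.argwhere(wall | vol.mask("lv_blood"))
    world = vol.world(ii)
    cx, cy = world[:, 0].mean(), world[:, 1].mean()
    zw = vol.world(np.argwhere(wall))[:, 2]
    z_apex, z_base = zw.min(), zw.max()

    idx = np.indices(vol.data.shape, dtype=float)
    x = vol.origin[0] + idx[0] * vol.spacing[0] - cx
    y = vol.origin[1] + idx[1] * vol.spacing[1] - cy
    z = vol.origin[2] + idx[2] * vol.spacing[2]
    ab = (z - z_apex) / max(z_base - z_apex, 1e-9)

    rv = vol.mask("rv_blood")
    if rv.any():
        rw = vol.world(np.argwhere(rv))
        phi0 = np.arctan2(rw[:, 1].mean() - cy, rw[:, 0].mean() - cx)
    else:
        phi0 = 0.0
    phi = np.arctan2(y, x) - phi0
    phi = (phi + np.pi) % (2 * np.pi) - np.pi
    r = np.hypot(x, y)
    return ab, phi, r


def paint_scar(vol: LabelVolume, spec: ScarSpec) -> LabelVolume:
    """Paint an anteroseptal scar core with BZ rim onto the LV wall.

    The core is transmural and elliptical in (apicobasal, circumferential)
    extent.  ``spec.isthmus_width`` > 0 carves a through-going border-zone
    channel that runs circumferentially within a narrow apicobasal band,
    splitting the core into an apical and a basal lobe — the configuration
    in which thick clinical z-slices can miss the channel entirely.  Only
    wall voxels are relabelled; the myocardial voxel count is conserved.
    """
    if spec.isthmus_width > 0 and spec.isthmus_width / 2 >= spec.extent[0]:
        raise ValueError("isthmus wider than the scar extent")
    ab, phi, r = _lv_cylindrical(vol)
    zc, phic = spec.center_uvc
    wall = vol.mask("lv_wall")
    zw = vol.world(np.argwhere(wall | vol.mask("scar", "bz")))[:, 2]
    height = zw.max() - zw.min()
    dz_mm = (ab - zc) * height
    dphi = (phi - phic + np.pi) % (2 * np.pi) - np.pi
    darc = dphi * r
    ez, ephi = spec.extent
    core = wall & ((dz_mm / ez) ** 2 + (darc / ephi) ** 2 <= 1.0)
    core = _drop_small_components(core)
    if not core.any():
        raise ValueError("scar extent does not intersect the LV wall")

    L = vol.label_map
    data = vol.data.copy()
    channel = np.zeros_like(core)
    if spec.isthmus_width > 0:
        channel = core & (np.abs(dz_mm) <= spec.isthmus_width / 2.0)
        core = _drop_small_components(core & ~channel)
    data[core] = L["scar"]

    if spec.bz_rim > 0:
        dist = ndimage.distance_transform_edt(data != L["scar"], sampling=vol.spacing)
        myo = vol.myocardium_mask()  # rim may spill onto the RV septal side
        rim = myo & (data != L["scar"]) & (dist <= spec.bz_rim)
        data[rim] = L["bz"]
    data[channel & (data != L["scar"])] = L["bz"]

    out = vol.copy(data=data)
    out.meta["scar_spec"] = dataclasses.asdict(spec)
    return out


# ---------------------------------------------------------------------------
# synthetic LGE intensities and threshold segmentation
# ---------------------------------------------------------------------------

#: per-class mean signal intensity (fraction of scar-core intensity)
LGE_MEANS = {"healthy": 0.2, "bz": 0.5, "scar": 1.0}


def emulate_lge_intensities(
    vol: LabelVolume, noise_sd: float = 0.05, seed: int = 0,
    means: dict[str, float] | None = None,
) -> np.ndarray:
    """Synthetic late-enhancement intensity volume.

    Each tissue class gets its mean intensity (scar brightest) plus i.i.d.
    Gaussian noise within the myocardium; non-myocardium is zero.
    """
    means = means or LGE_MEANS
    myo = vol.myocardium_mask()
    out = np.zeros(vol.data.shape, dtype=float)
    out[vol.mask("lv_wall", "rv_wall")] = means["healthy"]
    out[vol.mask("bz")] = means["bz"]
    out[vol.mask("scar")] = means["scar"]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out[myo] += rng.normal(0.0, noise_sd, size=int(myo.sum()))
    return out


def threshold_segment(
    intensity: np.ndarray, vol: LabelVolume,
    scar_frac: float = 0.6, bz_frac: float = 0.4,
) -> LabelVolume:
    """Segment scar/BZ by fractional-of-maximum intensity thresholds.

    Scar is assigned to myocardial voxels with intensity >= ``scar_frac`` of
    the maximum within the myocardium, BZ to [``bz_frac``, ``scar_frac``),
    the remainder keeps its wall label (the standard hyperenhancement
    convention; both fractions configurable).
    """
    if not (0.0 < bz_frac < scar_frac < 1.0):
        raise ValueError("need 0 < bz_frac < scar_frac < 1")
    myo = vol.myocardium_mask()
    if not myo.any():
        raise ValueError("empty myocardium mask")
    vmax = float(intensity[myo].max())
    if vmax <= 0:
        raise ValueError("all-zero intensity volume")
    L = vol.label_map
    data = vol.data.copy()
    # restore wall identity before relabelling
    lv_side = vol.mask("lv_wall", "scar", "bz")
    data[lv_side] = L["lv_wall"]
    scar = myo & (intensity >= scar_frac * vmax)
    bz = myo & ~scar & (intensity >= bz_frac * vmax)
    data[bz] = L["bz"]
    data[scar] = L["scar"]
    return vol.copy(data=data)


# ---------------------------------------------------------------------------
# clinical z down-sampling
# ---------------------------------------------------------------------------

def downsample_z(vol: LabelVolume, dz_out: float, method: str = "center") -> LabelVolume:
    """Down-sample the slice direction to thickness ``dz_out`` mm.

    One slice is retained per ``dz_out`` window — the window-centre slice by
    default, or the per-voxel majority label over the window with
    ``method='majority'``.  In-plane resolution is unchanged.
    """
    dz_in = vol.spacing[2]
    if dz_out < dz_in:
        raise ValueError("dz_out must be >= the input slice spacing")
    f = dz_out / dz_in
    if abs(f - round(f)) > 1e-9:
        raise ValueError("dz_out must be an integer multiple of the input spacing")
    f = int(round(f))
    nz = vol.data.shape[2]
    n_out = nz // f
    if n_out < 1:
        raise ValueError("volume thinner than one output slice")
    centers = np.arange(n_out) * f + f // 2
    if method == "center":
        data = vol.data[:, :, centers].copy()
    elif method == "majority":
        trimmed = vol.data[:, :, : n_out * f]
        windows = trimmed.reshape(vol.data.shape[0], vol.data.shape[1], n_out, f)
        data = _mode(windows, axis=3, keepdims=False).mode.astype(vol.data.dtype)
    else:
        raise ValueError(f"unknown method {method!r}")
    origin = (vol.origin[0], vol.origin[1], vol.origin[2] + centers[0] * dz_in)
    spacing = (vol.spacing[0], vol.spacing[1], float(dz_out))
    out = vol.copy(data=data)
    out.spacing = spacing
    out.origin = origin
    return out
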