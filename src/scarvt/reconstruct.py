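"""logOdds shape interpolation for inter-slice scar reconstruction.

Thick-slice clinical images sample scar morphology sparsely along z.  The
reconstruction maps each binary label to a log-odds volume (Gaussian-blurred
occupancy, probabilities clamped away from 0/1, then the logit transform),
interpolates the log-odds cubically along z back onto a fine grid, and
re-segments with a logistic threshold.  Thin conducting channels narrower
than the slice spacing are typically lost in this process — the behaviour
quantified by :func:`isthmus_patency`.
"""

from __future__ import annotations

import heapq
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline, interp1d

from .volumes import LabelVolume

logger = logging.getLogger(__name__)

#: probability clamp for the logit transform
EPSILON = 1e-6


@dataclass
class LogOddsVolume:
    """Real-valued log-odds occupancy volume (>0 inside the shape)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.data)):
            raise ValueError("log-odds values must be finite")


def labels_to_logodds(
    vol: LabelVolume, target_label: str, blur_sd: float = 1.0,
) -> LogOddsVolume:
    """Binary occupancy of ``target_label`` -> in-plane Gaussian blur -> logit.

    ``blur_sd`` is in mm and is applied in-plane (x, y) only; the z direction
    is handled by the cubic slice interpolation.
    """
    if blur_sd < 0:
        raise ValueError("blur_sd must be >= 0")
    occ = vol.mask(target_label).astype(float)
    if blur_sd > 0:
        sigma_vox = (blur_sd / vol.spacing[0], blur_sd / vol.spacing[1], 0.0)
        occ = ndimage.gaussian_filter(occ, sigma=sigma_vox)
    p = np.clip(occ, EPSILON, 1.0 - EPSILON)
    return LogOddsVolume(np.log(p / (1.0 - p)), spacing=vol.spacing, origin=vol.origin)


def interpolate_slices(lo: LogOddsVolume, dz_out: float = 1.0) -> LogOddsVolume:
    """Cubic interpolation of the log-odds along z onto a ``dz_out`` grid.

    Natural cubic splines are used through the slice samples; with fewer
    than 4 slices the method falls back to linear interpolation (warned).
    """
    dz_in = lo.spacing[2]
    if dz_in <= dz_out:
        raise ValueError("interpolation requires dz_in > dz_out")
    nz = lo.data.shape[2]
    z_in = np.arange(nz) * dz_in
    z_out = np.arange(0.0, z_in[-1] + 1e-9, dz_out)
    if nz >= 4:
        spline = CubicSpline(z_in, lo.data, axis=2, bc_type="natural")
        data = spline(z_out)
    else:
        warnings.warn("fewer than 4 slices; falling back to linear interpolation")
        logger.warning("interpolate_slices: linear fallback with %d slices", nz)
        data = interp1d(z_in, lo.data, axis=2)(z_out)
    spacing = (lo.spacing[0], lo.spacing[1], float(dz_out))
    return LogOddsVolume(data, spacing=spacing, origin=lo.origin)


def logistic_threshold(
    lo: LogOddsVolume, label: str = "scar",
    label_map: dict[str, int] | None = None,
) -> LabelVolume:
    """Segment the log-odds volume: sigmoid(lo) >= 0.5, i.e. lo >= 0.

    The tie (p = 0.5 exactly) counts as foreground.
    """
    from .volumes import DEFAULT_LABELS

    lm = dict(label_map or DEFAULT_LABELS)
    fg = lo.data >= 0.0
    data = np.where(fg, lm[label], lm["background"]).astype(np.int32)
    return LabelVolume(data, spacing=lo.spacing, origin=lo.origin, label_map=lm)


def reconstruct_scar(
    lowres: LabelVolume, dz_out: float = 1.0, blur_sd: float = 1.0,
    labels: tuple[str, ...] = ("lv_wall", "rv_wall", "lv_blood", "rv_blood", "bz", "scar"),
) -> LabelVolume:
    """Reconstruct a fine-z volume from a thick-slice label volume.

    Each label class is reconstructed independently (blur -> cubic z
    interpolation -> logistic threshold) and the results are composed with
    precedence increasing left-to-right in ``labels`` (scar wins over BZ,
    BZ over wall).
    """
    if not any(lowres.count(lbl) for lbl in ("scar", "bz")):
        raise ValueError("low-resolution volume carries no scar/bz labels")
    present = [lbl for lbl in labels if lowres.count(lbl) > 0]
    out_data = None
    lm = lowres.label_map
    for lbl in present:
        lo = labels_to_logodds(lowres, lbl, blur_sd=blur_sd)
        if lowres.spacing[2] > dz_out:
            lo = interpolate_slices(lo, dz_out=dz_out)
        seg = lo.data >= 0.0
        if out_data is None:
            out_data = np.zeros(seg.shape, dtype=np.int32)
            spacing = (lowres.spacing[0], lowres.spacing[1],
                       min(dz_out, lowres.spacing[2]))
        out_data[seg] = lm[lbl]
    return LabelVolume(out_data, spacing=spacing, origin=lowres.origin,
                       label_map=dict(lm), meta=dict(lowres.meta))


# ---------------------------------------------------------------------------
# isthmus patency
# ---------------------------------------------------------------------------

def isthmus_patency(
    vol: LabelVolume,
    anchor_a: tuple[float, float, float],
    anchor_b: tuple[float, float, float],
    restrict_to_scar_span: bool = True,
    z_shrink: float = 2.5,
    arc_pad: float = 5.0,
) -> dict:
    """Is there a conducting channel between two anchors flanking the scar?

    Conducting tissue is any myocardial voxel that is not scar core.  The
    search is 6-connected and, by default, restricted to the scar's own
    apicobasal span *shrunk* by ``z_shrink`` mm (so detours over the apical
    or basal edge of the scar do not count as an isthmus) and to its angular
    span padded by ``arc_pad`` mm of arc (so the anchors at the channel
    mouths are reachable).  ``min_width`` is twice the smallest clearance
    (distance-transform maximal inscribed ball) along the widest available
    path.
    """
    from .anatomy import _lv_cylindrical

    scar = vol.mask("scar")
    if not scar.any():
        raise ValueError("no scar label present")
    conducting = vol.myocardium_mask() & ~scar

    if restrict_to_scar_span:
        _, phi, r = _lv_cylindrical(vol)
        idx = np.indices(vol.data.shape)[2]
        zmm = vol.origin[2] + idx * vol.spacing[2]
        z_scar = zmm[scar]
        arc = phi * np.maximum(r, 1e-9)
        arc_scar = arc[scar]
        span = ((zmm >= z_scar.min() + z_shrink)
                & (zmm <= z_scar.max() - z_shrink)
                & (arc >= arc_scar.min() - arc_pad)
                & (arc <= arc_scar.max() + arc_pad))
        conducting &= span

    def to_idx(p):
        return tuple(
            int(np.clip(round((p[i] - vol.origin[i]) / vol.spacing[i]),
                        0, vol.data.shape[i] - 1))
            for i in range(3))

    ia, ib = to_idx(anchor_a), to_idx(anchor_b)
    for name, idx in (("a", ia), ("b", ib)):
        if scar[idx]:
            raise ValueError(f"anchor {name} lies inside the scar core")

    # snap anchors to the nearest conducting voxel
    cond_idx = np.argwhere(conducting)
    if cond_idx.size == 0:
        return {"patent": False, "min_width": 0.0}
    sp = np.asarray(vol.spacing)

    def snap(idx):
        d = np.linalg.norm((cond_idx - idx) * sp, axis=1)
        return tuple(cond_idx[np.argmin(d)])

    ia, ib = snap(ia), snap(ib)

    # widest-path (maximin clearance) Dijkstra over the conducting voxels
    clearance = ndimage.distance_transform_edt(conducting, sampling=vol.spacing)
    best = np.full(vol.data.shape, -1.0)
    best[ia] = clearance[ia]
    heap = [(-clearance[ia], ia)]
    shape = vol.data.shape
    while heap:
        negc, cur = heapq.heappop(heap)
        c = -negc
        if c < best[cur]:
            continue
        if cur == ib:
            break
        x, y, z = cur
        for nb in ((x - 1, y, z), (x + 1, y, z), (x, y - 1, z),
                   (x, y + 1, z), (x, y, z - 1), (x, y, z + 1)):
            if not (0 <= nb[0] < shape[0] and 0 <= nb[1] < shape[1]
                    and 0 <= nb[2] < shape[2]):
                continue
            if not conducting[nb]:
                continue
            cand = min(c, clearance[nb])
            if cand > best[nb]:
                best[nb] = cand
                heapq.heappush(heap, (-cand, nb))
    if best[ib] < 0:
        return {"patent": False, "min_width": 0.0}
    return {"patent": True, "min_width": float(2.0 * best[ib])}


def channel_anchors(vol: LabelVolume) -> tuple[tuple, tuple]:
    """Ground-truth anchor points flanking the painted isthmus channel.

    Requires the ``scar_spec`` provenance stored by
    :func:`scarvt.anatomy.paint_scar`; the channel runs circumferentially at
    the scar-centre height, so the anchors sit mid-wall at that height just
    beyond the two circumferential ends of the scar core.
    """
    from .anatomy import _lv_cylindrical
    from .volumes import ScarSpec

    if "scar_spec" not in vol.meta:
        raise ValueError("volume carries no scar_spec provenance")
    spec = ScarSpec(**{k: tuple(v) if isinstance(v, list) else v
                       for k, v in vol.meta["scar_spec"].items()})
    ab, phi, r = _lv_cylindrical(vol)
    wall = vol.mask("lv_wall", "scar", "bz")
    zc, phic = spec.center_uvc
    ephi = spec.extent[1]

    anchors = []
    for side in (-1.0, 1.0):
        # angular offset of the anchor: just beyond the core's arc extent
        cand_r = np.median(r[wall & (np.abs(ab - zc) < 0.05)])
        dphi = side * (ephi + 3.0) / max(cand_r, 1e-9)
        cand = (wall & (np.abs(ab - zc) < 0.05)
                & (np.abs(((phi - phic - dphi) + np.pi) % (2 * np.pi) - np.pi) < 0.1))
        if not cand.any():
            cand = (wall & (np.abs(ab - zc) < 0.1)
                    & (np.abs(((phi - phic - dphi) + np.pi) % (2 * np.pi) - np.pi) < 0.2))
        pts = vol.world(np.argwhere(cand))
        anchors.append(tuple(pts.mean(axis=0)))
    return anchors[0], anchors[1]
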