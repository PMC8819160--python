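"""Forward 12-lead ECG, intracardiac electrograms, and feature extraction.

The extracellular potential at field points is recovered from the
transmembrane voltage with the infinite-volume-conductor dipole-source
integral: each element contributes a current dipole p = -sigma grad(Vm) V_e,
and phi_e(x) = sum p . r_hat / (4 pi sigma_b r^2).  Because the map from
nodal Vm to phi_e is linear, a lead-field matrix is assembled once per
(mesh, electrode, conductivity) combination and ECG sweeps reduce to a
matrix product.

Feature extraction follows standard clinical conventions: QRS bounds from
the spatial velocity of the vectorcardiogram, T-wave end by tangent
extrapolation to the isoelectric baseline with iterative outlier-lead
exclusion, and unipolar electrogram activation/repolarization times by the
maximum-negative-dV/dt and Wyatt methods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .eikonal import ActivationMap
from .meshes import UVCoordinates, VentricularMesh, p1_gradients
from .monodomain import ConductivitySet, VmField

logger = logging.getLogger(__name__)

LIMB_NAMES = ("RA", "LA", "LL")
PRECORDIAL_NAMES = ("V1", "V2", "V3", "V4", "V5", "V6")
LEAD_NAMES = ("I", "II", "III", "aVR", "aVL", "aVF") + PRECORDIAL_NAMES


@dataclass
class ECG12:
    """12-lead ECG: lead name -> trace (mV), uniform sampling."""

    leads: dict[str, np.ndarray]
    times: np.ndarray
    dt: float

    def __post_init__(self):
        for name in LEAD_NAMES:
            if name not in self.leads:
                raise ValueError(f"missing lead {name}")
        if not np.allclose(self.leads["III"],
                           self.leads["II"] - self.leads["I"], atol=1e-9):
            raise ValueError("lead III inconsistent with II - I")

    def stack(self, names=LEAD_NAMES) -> np.ndarray:
        return np.stack([self.leads[n] for n in names], axis=1)


@dataclass
class ECGFeatures:
    qrs_onset: float
    qrs_offset: float
    qrsd: float
    qtint: float | None = None
    apd_estimate: float | None = None


# ---------------------------------------------------------------------------
# electrodes and extracellular potentials
# ---------------------------------------------------------------------------

#: electrode directions on the torso ellipsoid (right = +x toward the RV,
#: anterior = +y, superior = +z); limb electrodes sit further out
_ELECTRODE_DIRS = {
    "RA": (0.85, -0.25, 1.0),
    "LA": (-0.85, -0.25, 1.0),
    "LL": (-0.55, -0.25, -1.3),
    "V1": (0.35, 0.95, 0.1),
    "V2": (0.12, 1.0, 0.05),
    "V3": (-0.18, 0.98, -0.05),
    "V4": (-0.45, 0.88, -0.15),
    "V5": (-0.7, 0.65, -0.15),
    "V6": (-0.92, 0.3, -0.15),
}
_LIMB_EXTRA = 1.8


def place_electrodes(mesh: VentricularMesh, torso_scale: float = 2.5) -> dict:
    """Nine electrode positions on a scaled bounding ellipsoid.

    A parametric stand-in for torso-model registration: the ellipsoid is
    ``torso_scale`` times the heart's bounding half-extents, with limb
    electrodes pushed further out.
    """
    lo = mesh.nodes.min(axis=0)
    hi = mesh.nodes.max(axis=0)
    c = 0.5 * (lo + hi)
    a = torso_scale * np.maximum(0.5 * (hi - lo), 1.0)
    out = {}
    for name, d in _ELECTRODE_DIRS.items():
        d = np.asarray(d, dtype=float)
        r = 1.0 / np.sqrt(((d / a) ** 2).sum())
        scale = _LIMB_EXTRA if name in LIMB_NAMES else 1.0
        out[name] = c + scale * r * d
    return out


def leadfield_matrix(mesh: VentricularMesh, points: np.ndarray,
                     cond: ConductivitySet, sigma_b: float = 1.0) -> np.ndarray:
    """(n_points, n_nodes) matrix mapping nodal Vm to phi_e at the points."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    g, vols = p1_gradients(mesh)
    sig = cond.region_sigmas()
    f = mesh.fibre if mesh.fibre is not None else np.tile([1., 0., 0.],
                                                          (mesh.n_elements, 1))
    sl = sig[mesh.region, 0]
    st = sig[mesh.region, 1]
    ff = f[:, :, None] * f[:, None, :]
    sigma_el = st[:, None, None] * np.eye(3)[None] + (sl - st)[:, None, None] * ff

    centers = mesh.element_centers()
    A = np.zeros((len(points), mesh.n_nodes))
    for p_idx, x in enumerate(points):
        rvec = x[None, :] - centers
        r = np.linalg.norm(rvec, axis=1)
        if r.min() < 1e-6:
            raise ValueError("field point coincides with an element centre")
        w = rvec / (4.0 * np.pi * sigma_b * r[:, None] ** 3)
        # contribution of node k of element e: -vol_e * (sigma_e^T w_e) . g_ek
        sw = np.einsum("eba,eb->ea", sigma_el, w)
        coef = -vols[:, None] * np.einsum("eka,ea->ek", g, sw)
        np.add.at(A, (np.full(mesh.n_elements * mesh.order, p_idx),
                      mesh.elements.ravel()), coef.ravel())
    return A


def compute_phie(field: VmField, mesh: VentricularMesh, cond: ConductivitySet,
                 points: np.ndarray, sigma_b: float = 1.0,
                 leadfield: np.ndarray | None = None) -> np.ndarray:
    """Extracellular potentials (n_times, n_points) at field points.

    Points must lie outside the myocardium.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    from scipy.spatial import cKDTree

    h = float(mesh.meta.get("h") or mesh.meta.get("spacing", (1.0,))[0])
    tree = mesh.meta.get("_center_tree")
    if tree is None:
        tree = cKDTree(mesh.element_centers())
        mesh.meta["_center_tree"] = tree
    d, _ = tree.query(points)
    if (d < 0.5 * h).any():
        raise ValueError("field point inside the myocardium")
    if leadfield is None:
        leadfield = leadfield_matrix(mesh, points, cond, sigma_b=sigma_b)
    return field.vm @ leadfield.T


def ecg_12lead(electrode_potentials: dict[str, np.ndarray],
               dt: float) -> ECG12:
    """Standard 12-lead combinations from 9 electrode potentials."""
    for name in LIMB_NAMES + PRECORDIAL_NAMES:
        if name not in electrode_potentials:
            raise ValueError(f"missing electrode {name}")
    ra = electrode_potentials["RA"]
    la = electrode_potentials["LA"]
    ll = electrode_potentials["LL"]
    wct = (ra + la + ll) / 3.0
    leads = {
        "I": la - ra,
        "II": ll - ra,
        "III": ll - la,
        "aVR": ra - (la + ll) / 2.0,
        "aVL": la - (ra + ll) / 2.0,
        "aVF": ll - (ra + la) / 2.0,
    }
    for v in PRECORDIAL_NAMES:
        leads[v] = electrode_potentials[v] - wct
    times = np.arange(len(ra)) * dt
    return ECG12(leads=leads, times=times, dt=dt)


def ecg_from_vm(field: VmField, mesh: VentricularMesh, cond: ConductivitySet,
                torso_scale: float = 2.5, sigma_b: float = 1.0,
                leadfields: dict | None = None) -> ECG12:
    """Convenience pipeline: electrodes -> phi_e -> 12-lead ECG."""
    electrodes = place_electrodes(mesh, torso_scale=torso_scale)
    names = list(electrodes.keys())
    pts = np.array([electrodes[n] for n in names])
    key = ("_leadfield", torso_scale, sigma_b,
           tuple(np.round(cond.region_sigmas().ravel(), 9)))
    A = None
    if leadfields is not None:
        A = leadfields.get(key)
    if A is None:
        A = leadfield_matrix(mesh, pts, cond, sigma_b=sigma_b)
        if leadfields is not None:
            leadfields[key] = A
    phie = field.vm @ A.T
    pots = {n: phie[:, i] for i, n in enumerate(names)}
    return ecg_12lead(pots, dt=field.dt_out)


# ---------------------------------------------------------------------------
# beat averaging, VCG, QRS and QT detection
# ---------------------------------------------------------------------------

def average_paced_beats(ecg: ECG12, pace_times: np.ndarray) -> ECG12:
    """Average beats 2-4 of a paced train (first beat excluded)."""
    pace_times = np.asarray(pace_times, dtype=float)
    if len(pace_times) < 4:
        raise ValueError("need at least 4 paced beats")
    starts = [int(round(t / ecg.dt)) for t in pace_times[1:4]]
    n = min(int(round((pace_times[1] - pace_times[0]) / ecg.dt)),
            len(ecg.times) - starts[-1])
    leads = {}
    for name, tr in ecg.leads.items():
        beats = np.stack([tr[s: s + n] for s in starts])
        leads[name] = beats.mean(axis=0)
    times = np.arange(n) * ecg.dt
    return ECG12(leads=leads, times=times, dt=ecg.dt)


#: quasi-orthogonal VCG transform: X lateral, Y limb/vertical, Z precordial
VCG_TRANSFORMS = {
    "quasi_orthogonal": {"x": [("V6", 1.0)],
                         "y": [("aVF", 1.0)],
                         "z": [("V1", -0.5), ("V2", -0.5)]},
}


def ecg_to_vcg(ecg: ECG12, transform: str = "quasi_orthogonal") -> np.ndarray:
    """(n_times, 3) vectorcardiogram via a fixed lead combination."""
    spec = VCG_TRANSFORMS[transform]
    out = np.zeros((len(ecg.times), 3))
    for axis, combo in enumerate((spec["x"], spec["y"], spec["z"])):
        for name, wgt in combo:
            out[:, axis] += wgt * ecg.leads[name]
    return out


def spatial_velocity(vcg: np.ndarray, dt: float,
                     smooth_ms: float = 5.0) -> np.ndarray:
    sv = np.linalg.norm(np.gradient(vcg, dt, axis=0), axis=1)
    w = max(1, int(round(smooth_ms / dt)))
    kernel = np.ones(w) / w
    return np.convolve(sv, kernel, mode="same")


def detect_qrs_onset_offset(vcg: np.ndarray, dt: float,
                            threshold_frac: float = 0.1,
                            smooth_ms: float = 5.0,
                            window_ms: float = 150.0) -> ECGFeatures:
    """QRS bounds from the spatial velocity of the VCG.

    Onset: first sample exceeding ``threshold_frac`` x peak velocity;
    offset: last such sample within ``window_ms`` after onset (a second,
    later pulse outside the window is ignored and logged).
    """
    sv = spatial_velocity(vcg, dt, smooth_ms=smooth_ms)
    peak = sv.max()
    if peak <= 0 or not np.isfinite(peak):
        raise ValueError("flat signal; no QRS detected")
    above = sv > threshold_frac * peak
    if not above.any():
        raise ValueError("no samples above the spatial-velocity threshold")
    i_on = int(np.argmax(above))
    i_max = min(len(sv), i_on + int(round(window_ms / dt)))
    win = above[i_on:i_max]
    i_off = i_on + int(np.flatnonzero(win)[-1])
    if above[i_max:].any():
        logger.info("activity beyond the QRS search window ignored")
    onset = i_on * dt
    offset = i_off * dt
    return ECGFeatures(qrs_onset=onset, qrs_offset=offset,
                       qrsd=offset - onset)


def detect_qt(ecg: ECG12, qrs_onset: float, qrs_offset: float | None = None,
              baseline_ms: float = 30.0, t_search_gap: float = 40.0) -> float:
    """Global QT interval by tangent extrapolation with outlier rejection.

    Per lead: baseline = median of the ``baseline_ms`` before QRS onset;
    T-end = intersection of the tangent at the steepest post-peak slope of
    the T wave with the baseline.  Leads with QT > median + 1 SD are
    iteratively excluded; the median of the survivors is returned
    (measured from ``qrs_onset``).
    """
    dt = ecg.dt
    i_on = int(round(qrs_onset / dt))
    i_t0 = int(round(((qrs_offset or qrs_onset + 80.0) + t_search_gap) / dt))
    qts = {}
    for name, v in ecg.leads.items():
        b0 = max(0, i_on - int(round(baseline_ms / dt)))
        baseline = np.median(v[b0: i_on + 1]) if i_on > b0 else 0.0
        seg = v[i_t0:]
        if len(seg) < 5:
            continue
        amp = np.abs(seg - baseline)
        ipk = int(np.argmax(amp))
        if amp[ipk] < 1e-12:
            continue
        tail = seg[ipk:]
        dvdt = np.gradient(tail, dt)
        # steepest return toward baseline after the T peak
        sign = -np.sign(seg[ipk] - baseline)
        cand = dvdt * sign
        img = int(np.argmax(cand))
        if cand[img] <= 0:
            continue
        slope = dvdt[img]
        t_g = (i_t0 + ipk + img) * dt
        v_g = tail[img]
        t_end = t_g + (baseline - v_g) / slope
        qt = t_end - qrs_onset
        if qt > 0:
            qts[name] = qt
    if len(qts) < 3:
        raise ValueError("T-wave end detected in fewer than 3 leads")
    vals = dict(qts)
    while True:
        arr = np.array(list(vals.values()))
        med, sd = np.median(arr), arr.std(ddof=0)
        keep = {k: q for k, q in vals.items() if q <= med + sd or sd < 1e-9}
        if len(keep) == len(vals) or len(keep) < 3:
            vals = keep if len(keep) >= 3 else vals
            break
        vals = keep
    return float(np.median(list(vals.values())))


def estimate_mean_apd(qtint: float, qrsd: float) -> float:
    """Mean ventricular APD estimate: QT interval minus QRS duration."""
    if qtint <= qrsd:
        raise ValueError("QT interval must exceed the QRS duration")
    return qtint - qrsd


def compute_tact(atmap: ActivationMap, uvc: UVCoordinates,
                 z_threshold: float = 0.9) -> float:
    """Total activation time: latest activation at the ventricular base."""
    basal = uvc.z >= z_threshold
    at = atmap.at[basal]
    at = at[np.isfinite(at)]
    if at.size == 0:
        raise ValueError("no activated basal nodes")
    return float(at.max())


# ---------------------------------------------------------------------------
# electrograms
# ---------------------------------------------------------------------------

@dataclass
class EGMSet:
    positions: np.ndarray           # (p, 3) mm
    traces: np.ndarray              # (n_times, p) mV
    times: np.ndarray
    features: list = field(default_factory=list)  # per-trace dicts


def synthesize_egm(field: VmField, mesh: VentricularMesh,
                   cond: ConductivitySet, catheter_points: np.ndarray,
                   sigma_b: float = 1.0) -> EGMSet:
    """Unipolar electrograms at catheter points (outside the tissue)."""
    traces = compute_phie(field, mesh, cond, catheter_points, sigma_b=sigma_b)
    return EGMSet(positions=np.atleast_2d(catheter_points), traces=traces,
                  times=field.times)


def detect_at(trace: np.ndarray, times: np.ndarray,
              window: tuple[float, float] | None = None) -> float:
    """Activation time: maximum negative dV/dt of the unipolar EGM."""
    dv = np.gradient(trace, times)
    sel = np.ones(len(times), dtype=bool)
    if window is not None:
        sel = (times >= window[0]) & (times <= window[1])
    if not sel.any() or np.abs(dv[sel]).max() < 1e-12:
        raise ValueError("no deflection inside the AT search window")
    idx = np.flatnonzero(sel)
    return float(times[idx[np.argmin(dv[idx])]])


def detect_rt(trace: np.ndarray, times: np.ndarray, at: float,
              pacing_interval: float = 500.0,
              window_frac: tuple[float, float] = (0.15, 0.9)) -> float:
    """Repolarization time by the Wyatt method.

    Searches [at + 0.15 CL, at + 0.9 CL].  With a positive T wave, RT is
    the maximum dV/dt before the T-wave peak; if no positive peak is found
    a negative T wave is assumed and the minimum dV/dt before the (negative)
    peak is used.
    """
    lo = at + window_frac[0] * pacing_interval
    hi = at + window_frac[1] * pacing_interval
    sel = (times >= lo) & (times <= hi)
    if sel.sum() < 5:
        raise ValueError("RT search window outside the trace")
    idx = np.flatnonzero(sel)
    seg = trace[idx]
    dv = np.gradient(trace, times)[idx]
    peaks, props = find_peaks(seg, prominence=0.05 * (seg.max() - seg.min() + 1e-12))
    if peaks.size:
        ipk = int(peaks[np.argmax(seg[peaks])])
        upto = slice(0, max(ipk, 1))
        irt = int(np.argmax(dv[upto]))
    else:
        ipk = int(np.argmin(seg))
        upto = slice(0, max(ipk, 1))
        irt = int(np.argmin(dv[upto]))
    return float(times[idx[irt]])


def ari_filter(first_ari: float, second_ari: float,
               max_rel_diff: float = 0.10) -> bool:
    """Keep a point only when consecutive ARIs agree within 10%."""
    mean = 0.5 * (first_ari + second_ari)
    if mean <= 0:
        return False
    return abs(first_ari - second_ari) / mean <= max_rel_diff
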