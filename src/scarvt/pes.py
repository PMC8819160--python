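"""Programmed electrical stimulation (S1-S2) and VT classification.

An S1 drive train followed by a single premature S2 is delivered at each
pacing site; propagation continues unstimulated for a 2 s observation
window after S2.  The 12-lead ECG of the follow-up window is analysed for
self-sustained activity: re-entry shows as a train of QRS complexes that
outlives the stimulated beats.  A run is *induced* when at least two
non-stimulated complexes follow the S2 capture and *sustained* when
complexes persist through the final 500 ms of the window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .ecg import ECG12, ecg_from_vm
from .meshes import VentricularMesh
from .monodomain import (
    ConductivitySet,
    MonodomainInstabilityError,
    Stimulus,
    monodomain_solve,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StimulusSpec:
    """PES stimulus geometry/strength.

    ``strength`` is the transmembrane current density delivered to the node
    ball (pA/pF after nodal lumping; the default is roughly twice the
    diastolic threshold for a 1 ms pulse).
    """

    radius: float = 2.5      # mm
    duration: float = 1.0    # ms
    strength: float = 100.0  # pA/pF

    def __post_init__(self):
        if min(self.radius, self.duration, self.strength) <= 0:
            raise ValueError("stimulus parameters must be positive")


@dataclass
class PESResult:
    site: str
    induced: bool
    sustained: bool
    cycle_length: float | None = None
    failed: bool = False
    ecg: ECG12 | None = None

    def __post_init__(self):
        if self.sustained and not self.induced:
            raise ValueError("sustained implies induced")
        if self.cycle_length is not None and not self.sustained:
            raise ValueError("cycle length only reported for sustained VT")


def classify_vt(ecg: ECG12, s2_time: float, horizon: float = 2000.0,
                capture_margin: float = 120.0,
                min_prominence_frac: float = 0.15):
    """(induced, sustained, cycle_length) from the post-S2 ECG morphology.

    QRS complexes are peaks of the RMS 12-lead envelope.  The S2-evoked
    complex (within ``capture_margin`` of S2) does not count as induced
    activity.
    """
    if ecg.times[-1] < s2_time + horizon - 1e-6:
        raise ValueError("ECG does not cover the full observation window")
    rms = np.sqrt(np.mean(ecg.stack() ** 2, axis=1))
    sel = ecg.times >= s2_time
    sig = rms[sel]
    t = ecg.times[sel]
    peak_amp = sig.max()
    if peak_amp < 1e-9:
        return False, False, None
    min_dist = max(1, int(round(60.0 / ecg.dt)))
    peaks, _ = find_peaks(sig, prominence=min_prominence_frac * peak_amp,
                          distance=min_dist)
    t_peaks = t[peaks]
    non_stim = t_peaks[t_peaks > s2_time + capture_margin]
    induced = len(non_stim) >= 2
    sustained = induced and bool(
        (t_peaks >= s2_time + horizon - 500.0).any())
    cl = None
    if sustained and len(t_peaks) >= 3:
        cl = float(np.median(np.diff(t_peaks[-min(6, len(t_peaks)):])))
    return induced, sustained, cl


def run_pes(mesh: VentricularMesh, cond: ConductivitySet, ionic,
            sites, s1_bcl: float = 600.0, n_s1: int = 8,
            s2_coupling: float = 250.0, follow: float = 2000.0,
            spec: StimulusSpec = StimulusSpec(), dt: float = 0.05,
            dt_out: float = 2.0, ecg_cond: ConductivitySet | None = None,
            leadfields: dict | None = None) -> list[PESResult]:
    """S1-S2 programmed stimulation over a list of pacing sites.

    ``sites`` are :class:`scarvt.meshes.PacingSite` objects (or (name,
    node-array) pairs).  A solver abort marks the site as failed, never as
    non-inducible.  Desk-scale runs may reduce ``n_s1`` from the clinical 8.
    """
    if leadfields is None:
        leadfields = {}
    results = []
    s2_time = (n_s1 - 1) * s1_bcl + s2_coupling
    t_end = s2_time + follow
    ecg_cond = ecg_cond or cond
    for site in sites:
        name, nodes = (site.name, site.nodes) if hasattr(site, "nodes") else site
        stimuli = [Stimulus(nodes, start=k * s1_bcl + 1.0,
                            duration=spec.duration, strength=spec.strength)
                   for k in range(n_s1)]
        stimuli.append(Stimulus(nodes, start=s2_time + 1.0,
                                duration=spec.duration, strength=spec.strength))
        try:
            field = monodomain_solve(mesh, cond, ionic, stimuli, t_end=t_end,
                                     dt=dt, dt_out=dt_out)
        except MonodomainInstabilityError as exc:
            logger.warning("site %s failed: %s", name, exc)
            results.append(PESResult(site=name, induced=False, sustained=False,
                                     failed=True))
            continue
        ecg = ecg_from_vm(field, mesh, ecg_cond, leadfields=leadfields)
        induced, sustained, cl = classify_vt(ecg, s2_time=s2_time,
                                             horizon=follow)
        results.append(PESResult(site=name, induced=induced,
                                 sustained=sustained, cycle_length=cl,
                                 ecg=ecg))
    return results


def vt_heatmap(results: list[PESResult]) -> dict:
    """Fraction of sites with sustained VT (failed sites excluded)."""
    valid = [r for r in results if not r.failed]
    n_failed = len(results) - len(valid)
    if n_failed:
        import warnings
        warnings.warn(f"{n_failed} failed site(s) excluded from the denominator")
    if not valid:
        return {"percent_induced": 0.0, "vt_positive": False, "n_sites": 0}
    n_sust = sum(r.sustained for r in valid)
    return {"percent_induced": 100.0 * n_sust / len(valid),
            "vt_positive": n_sust > 0,
            "n_sites": len(valid),
            "cycle_lengths": [r.cycle_length for r in valid if r.sustained]}


# ---------------------------------------------------------------------------
# canonical 2-D isthmus phantom
# ---------------------------------------------------------------------------

def isthmus_sheet_phantom(channel_open: bool = True, h: float = 0.5,
                          slow: bool = True):
    """Canonical 2-D infarct sheet with a 3 mm conducting isthmus.

    A 60 x 44 mm sheet carries two non-conducting scar lobes separated by a
    3 mm through-going channel of surviving tissue (slow-conducting,
    near-normal action potential, as in clinical zig-zag isthmus
    conduction); a border-zone rim with remodelled (long-APD,
    low-excitability) electrophysiology guards the proximal mouth.  With
    ``channel_open=False`` the channel is filled with scar, emulating the
    thick-slice reconstruction that closes the isthmus.

    ``slow=True`` uses QRSd-fit-like slow healthy conductivity (~0.4 m/s at
    0.5 mm resolution); ``slow=False`` the literature (VARP-like) value.
    Returns ``(mesh, cond, ionic, site)`` where ``site`` is the pacing node
    set at the proximal channel mouth.
    """
    from scipy.spatial import cKDTree

    from .ionic import make_bz_variant, make_porcine_baseline
    from .meshes import REGIONS as R
    from .meshes import sheet_mesh

    def region(x, y):
        r = np.full(x.shape, R["healthy"])
        lobe1 = (x > 18) & (x < 44) & (y > 14) & (y < 20.5)
        lobe2 = (x > 18) & (x < 44) & (y > 23.5) & (y < 30)
        chan = (x > 18) & (x < 44) & (y >= 20.5) & (y <= 23.5)
        rim = ((x > 16) & (x < 40) & (y > 12) & (y < 32)) \
            & ~(lobe1 | lobe2 | chan)
        r[rim] = R["bz"]
        if channel_open:
            r[chan] = R["fec_bz"]
            r[lobe1 | lobe2] = R["scar"]
        else:
            r[chan | lobe1 | lobe2] = R["scar"]
        return r

    mesh = sheet_mesh(60, 44, h=h, region_fn=region)
    sigma_h = 0.12 if slow else 0.2262
    cond = ConductivitySet(healthy=(sigma_h, sigma_h),
                           bz=(0.0642, 0.0642),
                           fec_bz=(0.027, 0.027))
    base = make_porcine_baseline()
    ionic = {R["healthy"]: base, R["bz"]: make_bz_variant(base),
             R["fec_bz"]: base}
    tree = cKDTree(mesh.nodes)
    site = np.array(sorted(tree.query_ball_point([12.0, 22.0, 0.0], 2.5)))
    return mesh, cond, ionic, site


# ---------------------------------------------------------------------------
# 2-D ring re-entry (wavelength law)
# ---------------------------------------------------------------------------

def ring_reentry(r_mean: float, width: float = 3.0, h: float = 0.5,
                 cond: ConductivitySet | None = None, ionic=None,
                 t_end: float = 1200.0, dt: float = 0.05):
    """Unidirectional wave on an annulus: does circulation self-sustain?

    Initiation uses a transient one-way block: a thin barrier strip
    clockwise of the stimulus is non-conducting while the counter-clockwise
    wave launches, then the barrier is removed (state handoff between two
    monodomain runs) so the returning wavefront may re-enter.  Circulation
    survives only when the path length exceeds the wavelength
    CV x refractory period.  Returns sustained flag, cycle length, path
    length and the number of passes recorded opposite the stimulus.
    """
    from .ionic import make_porcine_baseline
    from .meshes import REGIONS, ring_mesh
    from .monodomain import strand_cv

    cond = cond or ConductivitySet(healthy=(0.0642, 0.0642))
    ionic = ionic or make_porcine_baseline()
    mesh = ring_mesh(r_mean - width / 2, r_mean + width / 2, h=h)
    theta = np.arctan2(mesh.nodes[:, 1], mesh.nodes[:, 0])
    stim_nodes = np.flatnonzero(np.abs(theta) < (2.0 / r_mean))

    # phase 1: barrier strip just clockwise of the stimulus blocks the CW wave
    centers = mesh.element_centers()
    th_el = np.arctan2(centers[:, 1], centers[:, 0])
    barrier = (th_el < -2.5 / r_mean) & (th_el > -2.5 / r_mean - 3.0 / r_mean)
    blocked_mesh = VentricularMesh(
        mesh.nodes, mesh.elements,
        np.where(barrier, REGIONS["scar"], mesh.region),
        fibre=mesh.fibre, ventricle=mesh.ventricle, meta=dict(mesh.meta))

    path = 2 * np.pi * r_mean
    cv_est = strand_cv(cond.healthy[0], ionic, h=h)
    t1 = min(0.6 * path / cv_est, t_end - 1.0)
    field1, states = monodomain_solve(
        blocked_mesh, cond, ionic, [Stimulus(stim_nodes, start=1.0)],
        t_end=t1, dt=dt, dt_out=2.0, return_states=True)

    # phase 2: barrier removed; the returning front may re-enter
    field2 = monodomain_solve(mesh, cond, ionic, [], t_end=t_end - t1,
                              dt=dt, dt_out=2.0, states=states)
    vm = np.concatenate([field1.vm, field2.vm[1:]], axis=0)
    times = np.concatenate([field1.times, field1.times[-1] + field2.times[1:]])

    # passes: upward -20 mV crossings opposite the stimulus
    opposite = np.abs(np.abs(theta) - np.pi) < 0.2
    v_opp = vm[:, opposite].mean(axis=1)
    above = v_opp >= -20.0
    cross = np.flatnonzero(~above[:-1] & above[1:])
    t_cross = times[cross]
    sustained = len(t_cross) >= 2 and bool((t_cross > t_end - 300.0).any())
    cl = float(np.median(np.diff(t_cross))) if len(t_cross) >= 3 else None
    return {"sustained": sustained,
            "cycle_length": cl if sustained else None,
            "path_length": path,
            "n_passes": int(len(t_cross))}
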