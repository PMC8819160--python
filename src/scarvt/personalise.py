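"""ECG-based electrophysiological personalisation.

Two strategies fit the single free conduction-velocity parameter (healthy
longitudinal CV; all other regional CVs follow fixed ratios x0.45 BZ-free
transverse, x0.225 BZ, x6 FEC) to the measured QRS duration:

* TACT-fit — sweep CV over 0.36..0.96 m/s in 0.01 steps; for each CV solve
  the eikonal activation from the RV septal pacing site and use the total
  activation time at the base (TACT) as a surrogate for QRSd; keep the CV
  whose TACT best matches the measured QRSd.
* QRSd-fit — refine around the TACT-fit CV (+-0.2 m/s): for each CV compute
  the full 12-lead ECG via reaction-eikonal Vm and the dipole forward model
  and match the simulated QRSd itself.

Monodomain conductivities are then derived per region with the automated
strand-tuning loop, or taken from the literature set used by the
virtual-heart arrhythmia risk (VARP) studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .ecg import compute_tact, detect_qrs_onset_offset, ecg_from_vm, ecg_to_vcg
from .eikonal import (
    ActivationMap,
    ConductionVelocitySet,
    EikonalGraph,
    ap_template,
    reaction_eikonal_vm,
    solve_eikonal,
)
from .meshes import UVCoordinates, VentricularMesh
from .monodomain import ConductivitySet, tune_conductivity

logger = logging.getLogger(__name__)


@dataclass
class FitResult:
    cv_l: float
    objective: float            # |metric - target| at the optimum, ms
    sweep: list = field(default_factory=list)  # (cv, metric) pairs
    method: str = "tact_fit"
    boundary: bool = False      # optimum at the sweep edge


def tact_fit_cv(mesh: VentricularMesh, uvc: UVCoordinates, target_qrsd: float,
                site_nodes: np.ndarray,
                cv_range: tuple[float, float] = (0.36, 0.96),
                cv_step: float = 0.01,
                graph: EikonalGraph | None = None) -> FitResult:
    """Fit healthy longitudinal CV so the eikonal TACT matches the QRSd."""
    if target_qrsd < 0:
        raise ValueError("target QRSd must be >= 0")
    cvs = np.round(np.arange(cv_range[0], cv_range[1] + 1e-9, cv_step), 6)
    sweep = []
    for cv in cvs:
        cvset = ConductionVelocitySet.from_ratios(cv)
        am = solve_eikonal(mesh, cvset, site_nodes, graph=graph)
        tact = compute_tact(am, uvc)
        sweep.append((float(cv), float(tact)))
    errs = np.array([abs(t - target_qrsd) for _, t in sweep])
    best = int(np.argmin(errs))  # argmin keeps the slower CV on ties
    boundary = best in (0, len(cvs) - 1)
    if boundary:
        logger.warning("TACT fit hit the sweep boundary (cv=%.2f)", cvs[best])
    return FitResult(cv_l=float(cvs[best]), objective=float(errs[best]),
                     sweep=sweep, method="tact_fit", boundary=boundary)


def simulated_qrsd(mesh: VentricularMesh, am: ActivationMap,
                   template, cond_ecg: ConductivitySet,
                   leadfields: dict | None = None) -> float:
    """QRS duration of the 12-lead ECG built from an activation map."""
    finite = am.at[np.isfinite(am.at)]
    t_end = float(finite.max()) + 60.0
    vm = reaction_eikonal_vm(am, template, dt_out=1.0, t_end=t_end)
    ecg = ecg_from_vm(vm, mesh, cond_ecg, leadfields=leadfields)
    feats = detect_qrs_onset_offset(ecg_to_vcg(ecg), ecg.dt)
    return feats.qrsd


def qrsd_fit_cv(mesh: VentricularMesh, uvc: UVCoordinates,
                tact_result: FitResult, target_qrsd: float,
                site_nodes: np.ndarray, template=None,
                cond_ecg: ConductivitySet | None = None,
                window: float = 0.2, cv_step: float = 0.01,
                graph: EikonalGraph | None = None) -> FitResult:
    """Refine the CV fit by matching the simulated ECG QRS duration."""
    template = template if template is not None else ap_template()
    cond_ecg = cond_ecg or ConductivitySet()
    lo = max(tact_result.cv_l - window, 0.05)
    hi = tact_result.cv_l + window
    cvs = np.round(np.arange(lo, hi + 1e-9, cv_step), 6)
    leadfields: dict = {}
    sweep = []
    for cv in cvs:
        try:
            cvset = ConductionVelocitySet.from_ratios(cv)
            am = solve_eikonal(mesh, cvset, site_nodes, graph=graph)
            qrsd = simulated_qrsd(mesh, am, template, cond_ecg, leadfields)
        except Exception as exc:  # noqa: BLE001 - a sweep point may fail
            logger.warning("QRSd sweep point cv=%.2f failed: %s", cv, exc)
            continue
        sweep.append((float(cv), float(qrsd)))
    if not sweep:
        raise RuntimeError("every QRSd sweep point failed")
    errs = np.array([abs(q - target_qrsd) for _, q in sweep])
    best = int(np.argmin(errs))
    return FitResult(cv_l=sweep[best][0], objective=float(errs[best]),
                     sweep=sweep, method="qrsd_fit",
                     boundary=best in (0, len(sweep) - 1))


def derive_conductivities(fit: FitResult, ionic, resolution: float = 0.325,
                          dt: float = 0.05) -> ConductivitySet:
    """Strand-tune per-region conductivities matching the fitted CV set.

    Healthy longitudinal/transverse at cv_l and 0.45 cv_l; BZ slow and
    isotropic at 0.225 cv_l.  FEC conductivities follow from the healthy
    values by the square of the velocity ratio.
    """
    cv = fit.cv_l
    s_l = tune_conductivity(cv, ionic, resolution=resolution, dt=dt)
    s_t = tune_conductivity(0.45 * cv, ionic, resolution=resolution, dt=dt,
                            direction="transverse")
    s_bz = tune_conductivity(0.225 * cv, ionic, resolution=resolution, dt=dt,
                             direction="bz")
    return ConductivitySet(healthy=(s_l["sigma"], s_t["sigma"]),
                           bz=(s_bz["sigma"], s_bz["sigma"]))


def varp_conductivities() -> ConductivitySet:
    """Literature (VARP) conductivities: healthy 0.2262/0.0642 S/m;
    BZ longitudinal = healthy transverse, BZ transverse = 10% of that."""
    return ConductivitySet(healthy=(0.2262, 0.0642), bz=(0.0642, 0.00642))
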