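"""Monodomain reaction-diffusion solver and CV <-> conductivity tuning.

The monodomain equation

    dVm/dt = div( sigma grad Vm ) / (beta * Cm) + (I_stim - I_ion) / Cm

is discretized with mass-lumped P1 finite elements (line/triangle/tet) and
advanced with operator splitting: Rush-Larsen/forward-Euler membrane update
followed by an explicit diffusion step.  Conductivities are in S/m, lengths
in mm, time in ms, membrane currents in pA/pF; with the default membrane
capacitance Cm = 1 uF/cm^2 and surface-to-volume ratio beta = 0.14 um^-1,
the diffusivity in mm^2/ms is sigma / (10 * beta * Cm).

Scar is non-conducting and carries no membrane model: scar-only nodes stay
at rest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .ionic import (
    APModel,
    INITIAL_STATE,
    build_gate_tables,
    tt06_step_tab,
)
from .meshes import REGIONS, VentricularMesh, lumped_mass, stiffness_matrix

logger = logging.getLogger(__name__)

#: default membrane constants
CM_DEFAULT = 1.0      # uF/cm^2
BETA_DEFAULT = 0.14   # um^-1


@dataclass(frozen=True)
class ConductivitySet:
    """Per-region monodomain conductivities in S/m (longitudinal, transverse).

    Scar is always 0.  ``fec`` entries default to the healthy values scaled
    by the square of the FEC velocity ratio (CV scales with sqrt(sigma)).
    """

    healthy: tuple[float, float] = (0.2262, 0.0642)
    bz: tuple[float, float] = (0.0642, 0.00642)
    fec_healthy: tuple[float, float] | None = None
    fec_bz: tuple[float, float] | None = None

    def region_sigmas(self) -> np.ndarray:
        out = np.zeros((5, 2))
        out[REGIONS["healthy"]] = self.healthy
        out[REGIONS["bz"]] = self.bz
        out[REGIONS["scar"]] = (0.0, 0.0)
        out[REGIONS["fec_healthy"]] = self.fec_healthy if self.fec_healthy \
            else (36.0 * self.healthy[0], self.healthy[1])
        out[REGIONS["fec_bz"]] = self.fec_bz if self.fec_bz \
            else (36.0 * self.bz[0], self.bz[1])
        return out


@dataclass
class Stimulus:
    """Transmembrane current stimulus over a node set."""

    nodes: np.ndarray
    start: float          # ms
    duration: float = 1.0  # ms
    strength: float = 100.0  # pA/pF (inward magnitude)

    def __post_init__(self):
        if self.duration <= 0 or self.strength <= 0:
            raise ValueError("stimulus duration and strength must be positive")


@dataclass
class VmField:
    """Per-node transmembrane voltage time series."""

    vm: np.ndarray       # (n_times, n_nodes) mV
    times: np.ndarray    # (n_times,) ms
    dt_out: float

    def at_times(self) -> np.ndarray:
        """Activation time per node: upward crossing of -20 mV (last ups
        win; NaN where never activated)."""
        return activation_times(self)


def activation_times(field: VmField, threshold: float = -20.0,
                     first: bool = True) -> np.ndarray:
    v = field.vm
    above = v >= threshold
    crossed = (~above[:-1]) & above[1:]
    any_cross = crossed.any(axis=0)
    idx = np.argmax(crossed, axis=0)
    v0 = v[idx, np.arange(v.shape[1])]
    v1 = v[idx + 1, np.arange(v.shape[1])]
    frac = np.where(v1 > v0, (threshold - v0) / np.maximum(v1 - v0, 1e-12), 0.0)
    at = field.times[idx] + frac * field.dt_out
    at[~any_cross] = np.nan
    return at


class MonodomainInstabilityError(RuntimeError):
    pass


@njit(cache=True)
def _mono_loop(states, dt, n_steps, indptr, indices, data, inv_mass, active,
               scalers, stim_node_mask, stim_start, stim_dur, stim_amp,
               sample_every, vm_out, gate_tab):
    n = states.shape[0]
    n_stim = len(stim_start)
    k_out = 1
    for step in range(n_steps):
        t = step * dt
        # membrane + stimulus (tabulated-gate fast path)
        for i in range(n):
            if not active[i]:
                continue
            istim = 0.0
            for s in range(n_stim):
                if stim_node_mask[s, i] and stim_start[s] <= t < stim_start[s] + stim_dur[s]:
                    istim -= stim_amp[s]
            tt06_step_tab(states[i], dt, istim,
                          scalers[i, 0], scalers[i, 1], scalers[i, 2],
                          scalers[i, 3], gate_tab)
            if not (-200.0 < states[i, 0] < 200.0):  # catches NaN too
                return -1
        # explicit diffusion: V -= dt * Minv * K V
        v = states[:, 0].copy()
        bad = False
        for i in range(n):
            if not active[i]:
                continue
            acc = 0.0
            for p in range(indptr[i], indptr[i + 1]):
                acc += data[p] * v[indices[p]]
            vi = v[i] - dt * inv_mass[i] * acc
            states[i, 0] = vi
            if not (-200.0 < vi < 200.0):
                bad = True
        if bad:
            return -1
        if (step + 1) % sample_every == 0:
            for i in range(n):
                vm_out[k_out, i] = states[i, 0]
            k_out += 1
    return k_out


def monodomain_solve(
    mesh: VentricularMesh,
    cond: ConductivitySet,
    ionic: APModel | dict[int, APModel],
    stimuli: list[Stimulus],
    t_end: float,
    dt: float = 0.05,
    dt_out: float = 1.0,
    cm: float = CM_DEFAULT,
    beta: float = BETA_DEFAULT,
    states: np.ndarray | None = None,
    return_states: bool = False,
):
    """Simulate the monodomain equation on a mesh.

    ``ionic`` is a single cell model or a mapping from region code to
    model (regions absent from the mapping reuse the healthy entry).
    Initial states may be passed to chain runs (e.g. S1 train then S2).
    """
    if mesh.fibre is None:
        raise ValueError("mesh carries no fibre field")
    sigmas = cond.region_sigmas()          # (5, 2) S/m
    diff_scale = 1.0 / (10.0 * beta * cm)  # S/m -> mm^2/ms
    f = mesh.fibre
    ff = f[:, :, None] * f[:, None, :]
    eye = np.eye(3)[None, :, :]
    sl = sigmas[mesh.region, 0] * diff_scale
    st = sigmas[mesh.region, 1] * diff_scale
    D = st[:, None, None] * eye + (sl - st)[:, None, None] * ff
    nonscar = mesh.region != REGIONS["scar"]
    K = stiffness_matrix(mesh, D, mask=nonscar).tocsr()
    mass = lumped_mass(mesh, mask=nonscar)
    active = mass > 0
    inv_mass = np.where(active, 1.0 / np.maximum(mass, 1e-30), 0.0)

    # per-node ionic scalers from the most conducting incident region
    node_region = mesh.node_regions()
    if isinstance(ionic, APModel):
        ionic = {REGIONS["healthy"]: ionic}
    default = ionic.get(REGIONS["healthy"], APModel())
    scalers = np.empty((mesh.n_nodes, 4))
    for code in range(5):
        model = ionic.get(code, default)
        scalers[node_region == code] = model.scalers()

    if states is None:
        states = np.tile(INITIAL_STATE, (mesh.n_nodes, 1))
    n_steps = int(round(t_end / dt))
    sample_every = max(1, int(round(dt_out / dt)))
    n_out = n_steps // sample_every + 1
    vm_out = np.empty((n_out, mesh.n_nodes), dtype=np.float64)
    vm_out[0] = states[:, 0]

    stim_mask = np.zeros((len(stimuli), mesh.n_nodes), dtype=np.bool_)
    for s, stim in enumerate(stimuli):
        stim_mask[s, np.asarray(stim.nodes, dtype=np.int64)] = True
    stim_start = np.array([s.start for s in stimuli], dtype=np.float64)
    stim_dur = np.array([s.duration for s in stimuli], dtype=np.float64)
    stim_amp = np.array([s.strength for s in stimuli], dtype=np.float64)

    gate_tab = build_gate_tables(dt)
    k = _mono_loop(states, dt, n_steps, K.indptr, K.indices, K.data, inv_mass,
                   active, scalers, stim_mask, stim_start, stim_dur, stim_amp,
                   sample_every, vm_out, gate_tab)
    if k < 0:
        raise MonodomainInstabilityError(
            f"|Vm| exceeded 200 mV (dt={dt} ms); reduce dt or check sigma")
    times = np.arange(k) * dt * sample_every
    out = VmField(vm=vm_out[:k], times=times, dt_out=dt * sample_every)
    if return_states:
        return out, states
    return out


# ---------------------------------------------------------------------------
# planar CV measurement and conductivity tuning
# ---------------------------------------------------------------------------

def measure_planar_cv(at: np.ndarray, positions: np.ndarray,
                      axis: int = 0, central_frac: float = 0.5) -> float:
    """CV (m/s) from the slope of distance vs activation time.

    Uses the central ``central_frac`` of the extent along ``axis``; raises
    on non-monotone activation (blocked propagation).
    """
    x = positions[:, axis]
    lo = x.min() + (1 - central_frac) / 2 * (x.max() - x.min())
    hi = x.max() - (1 - central_frac) / 2 * (x.max() - x.min())
    sel = (x >= lo) & (x <= hi) & np.isfinite(at)
    if sel.sum() < 3:
        raise ValueError("not enough activated nodes in the central window")
    xs = x[sel]
    ts = at[sel]
    order = np.argsort(xs)
    ts_sorted = ts[order]
    # monotonicity up to measurement jitter
    if np.any(np.diff(ts_sorted) < -1.0) or np.unique(ts_sorted).size < 3:
        raise ValueError("activation not monotone along the strand (block?)")
    slope, _ = np.polyfit(ts, xs, 1)  # mm/ms = m/s
    if slope <= 0:
        raise ValueError("non-positive propagation slope")
    return float(slope)


def strand_cv(sigma: float, ionic: APModel, h: float = 0.325,
              length: float = 20.0, dt: float = 0.05,
              cm: float = CM_DEFAULT, beta: float = BETA_DEFAULT) -> float:
    """Planar CV (m/s) on a 1-D strand at the given conductivity."""
    from .meshes import strand_mesh

    mesh = strand_mesh(length=length, h=h)
    cond = ConductivitySet(healthy=(sigma, sigma))
    stim_nodes = np.flatnonzero(mesh.nodes[:, 0] <= 1.0)
    t_run = length / 0.2 + 10.0  # generous window even for slow CV
    field = monodomain_solve(mesh, cond, ionic,
                             [Stimulus(stim_nodes, start=1.0)],
                             t_end=t_run, dt=dt, dt_out=0.1,
                             cm=cm, beta=beta)
    at = activation_times(field)
    return measure_planar_cv(at, mesh.nodes, axis=0)


def tune_conductivity(target_cv: float, ionic: APModel,
                      resolution: float = 0.325, direction: str = "longitudinal",
                      sigma0: float | None = None, tol: float = 0.005,
                      max_iter: int = 20, dt: float = 0.05,
                      cm: float = CM_DEFAULT, beta: float = BETA_DEFAULT) -> dict:
    """Tune sigma so a strand at ``resolution`` mm conducts at ``target_cv``.

    Fixed-point iteration sigma <- sigma * (target/measured)^2, converging
    because CV scales with sqrt(sigma).  Returns the converged sigma, the
    achieved CV and the iteration trace.
    """
    if target_cv <= 0:
        raise ValueError("target CV must be positive")
    sigma = sigma0 if sigma0 is not None else 0.2262 * (target_cv / 0.67) ** 2
    trace = []
    for it in range(max_iter):
        cv = strand_cv(sigma, ionic, h=resolution, dt=dt, cm=cm, beta=beta)
        trace.append((sigma, cv))
        logger.info("tune_conductivity it=%d sigma=%.5f cv=%.4f", it, sigma, cv)
        if abs(cv - target_cv) < tol:
            return {"sigma": float(sigma), "cv": float(cv),
                    "iterations": it + 1, "trace": trace,
                    "direction": direction}
        sigma *= (target_cv / cv) ** 2
    raise RuntimeError(
        f"conductivity tuning did not converge in {max_iter} iterations: "
        f"{trace}")
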