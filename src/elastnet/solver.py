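"""Reduced-order pulse-wave solver.

Each tapered segment is discretized into lumped pi-elements: a series
resistance-inertance branch (Poiseuille friction, blood inertia) between
pressure nodes that carry the wall compliance,

    R = 128 mu l / (pi d^4),   L = 4 rho l / (pi d^2),   C = D A l,

with d the local tapered diameter and A its cross-section. The chain of
elements forms a transmission line that propagates and reflects pressure
waves; terminal nodes drain through three-element Windkessels. At the
root the network is coupled to the time-varying elastance ventricle
through an ideal-diode aortic valve with a small series resistance, and
the ventricle fills from a constant-pressure source through the venous
resistance.

The coupled ODE system is integrated with fixed-step explicit RK4 until
the node pressures are cycle-to-cycle periodic (max change below
``convergence_tol``) or ``n_cycles_max`` is reached. All state is SI
internally; interfaces are clinical (mmHg, ml, s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .tree import ArterialTree
from .units import (
    C_CLIN_TO_SI,
    CM_TO_M,
    MMHG_TO_PA,
    ML_TO_M3,
    R_CLIN_TO_SI,
    distensibility_to_si,
)
from .ventricle import RELAXATION_RATIO, BloodProperties, VentricleParams

__all__ = [
    "SolverSettings",
    "PressureWave",
    "BPSummary",
    "SimulationResult",
    "simulate",
    "bp_summary",
]


@dataclass(frozen=True)
class SolverSettings:
    """Numerical settings of the RK4 integrator.

    dt in s; convergence_tol is the maximum cycle-to-cycle node-pressure
    change (mmHg) accepted as periodic steady state; output_rate is the
    number of samples per cycle in the returned waveforms.
    """

    dt: float = 4e-4
    n_cycles_max: int = 20
    convergence_tol: float = 0.5
    output_rate: int = 200

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")
        if self.n_cycles_max < 1:
            raise ValueError("n_cycles_max must be >= 1")
        if self.output_rate < 16:
            raise ValueError("output_rate must be >= 16")


@dataclass(frozen=True)
class PressureWave:
    """One cardiac cycle of pressure samples (mmHg) with its period (s)."""

    samples: np.ndarray
    period: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.samples.size < 16:
            raise ValueError("need at least 16 samples per cycle")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("pressure samples must be finite")


@dataclass(frozen=True)
class BPSummary:
    """Systolic/diastolic/mean/pulse pressure (mmHg) at a named site."""

    site: str
    SBP: float
    DBP: float
    MAP: float
    PP: float

    def __post_init__(self) -> None:
        if not self.SBP >= self.DBP:
            raise ValueError("SBP must be >= DBP")
        if not np.isclose(self.PP, self.SBP - self.DBP):
            raise ValueError("PP must equal SBP - DBP")
        if not (self.DBP <= self.MAP <= self.SBP):
            raise ValueError("MAP must lie between DBP and SBP")

    def as_dict(self) -> dict[str, float]:
        return {"SBP": self.SBP, "DBP": self.DBP, "MAP": self.MAP, "PP": self.PP}


@dataclass
class SimulationResult:
    """Final-cycle waveforms of one simulation.

    pressure/flow are per-segment waves at the distal end of each segment;
    ``pressure['aortic_root']`` is the pressure at the aortic root node
    (proximal ascending aorta). Flows in ml/s, volumes in ml.
    """

    pressure: dict[str, PressureWave]
    flow: dict[str, np.ndarray]
    lv_pressure: PressureWave
    lv_volume: np.ndarray
    valve_flow: np.ndarray
    terminal_outflow: dict[str, np.ndarray]
    converged: bool
    cycles_run: int
    cycle_differences: np.ndarray = field(repr=False)
    period: float = 0.0

    @property
    def stroke_volume(self) -> float:
        """EDV - ESV over the final cycle, ml."""
        return float(self.lv_volume.max() - self.lv_volume.min())

    @property
    def ejection_fraction(self) -> float:
        """Stroke volume as a fraction of end-diastolic volume, percent."""
        return 100.0 * self.stroke_volume / float(self.lv_volume.max())


def bp_summary(wave: PressureWave, site: str = "unspecified") -> BPSummary:
    """SBP/DBP/MAP/PP of one pressure cycle.

    MAP is the time average over the cycle (samples are uniform in time).
    """
    s = wave.samples
    if not np.all(np.isfinite(s)):
        raise ValueError("non-finite pressure samples")
    sbp = float(np.max(s))
    dbp = float(np.min(s))
    return BPSummary(site=site, SBP=sbp, DBP=dbp, MAP=float(np.mean(s)), PP=sbp - dbp)


# ----------------------------------------------------------------------
# network discretization


def _discretize(tree: ArterialTree, blood: BloodProperties):
    """Flatten the tree into element/node arrays for the kernel (SI units)."""
    order = tree.topological_order()
    up_node: list[int] = []
    R_el: list[float] = []
    L_el: list[float] = []
    C_el: list[float] = []
    seg_last_node: dict[str, int] = {}
    seg_elem_range: dict[str, tuple[int, int]] = {}

    n_el = 0
    for seg_id in order:
        seg = tree.segment(seg_id)
        parent_node = 0 if seg.parent is None else seg_last_node[seg.parent]
        n = seg.n_elements
        l_el = (seg.length / n) * CM_TO_M
        D_si = distensibility_to_si(seg.distensibility)
        start = n_el
        for j in range(n):
            # local diameter at the element midpoint of the linear taper
            frac = (j + 0.5) / n
            d = (seg.d_in + frac * (seg.d_out - seg.d_in)) * CM_TO_M
            A = np.pi * d * d / 4.0
            R_el.append(128.0 * blood.mu * l_el / (np.pi * d**4))
            L_el.append(4.0 * blood.rho * l_el / (np.pi * d * d))
            C_el.append(D_si * A * l_el)
            up_node.append(parent_node if j == 0 else n_el)  # node index of element n_el-1 is n_el
            n_el += 1
            parent_node = n_el  # distal node of the element just added
        seg_last_node[seg_id] = n_el
        seg_elem_range[seg_id] = (start, n_el)

    n_nodes = n_el + 1
    # pi-element compliance: half to the proximal node, half to the distal node
    C_node = np.zeros(n_nodes)
    for e in range(n_el):
        C_node[up_node[e]] += 0.5 * C_el[e]
        C_node[e + 1] += 0.5 * C_el[e]

    term_ids = sorted(tree.terminals)
    term_node = np.array([seg_last_node[t] for t in term_ids], dtype=np.int64)
    Rc = np.array([tree.terminals[t].R_c * R_CLIN_TO_SI for t in term_ids])
    Rp = np.array([tree.terminals[t].R_p * R_CLIN_TO_SI for t in term_ids])
    Ct = np.array([tree.terminals[t].C_t * C_CLIN_TO_SI for t in term_ids])
    Pout = np.array([tree.terminals[t].P_out * MMHG_TO_PA for t in term_ids])

    return {
        "up": np.asarray(up_node, dtype=np.int64),
        "R": np.asarray(R_el),
        "L": np.asarray(L_el),
        "C_node": C_node,
        "term_ids": term_ids,
        "term_node": term_node,
        "Rc": Rc,
        "Rp": Rp,
        "Ct": Ct,
        "Pout": Pout,
        "seg_last_node": seg_last_node,
        "seg_elem_range": seg_elem_range,
        "order": order,
        "n_el": n_el,
        "n_nodes": n_nodes,
    }


# ----------------------------------------------------------------------
# numba kernel


@njit(cache=True, fastmath=True, inline="always")
def _rhs(y, dy, inflow, t, T, up, R, L, Cn, tnode, Rc, Rp, Ct, Pout,
         Ees, Eed, Vd, Pfill, tes, tr, Rven, Rvalve):  # pragma: no cover - jit
    n_el = up.shape[0]
    n_nodes = n_el + 1
    n_term = tnode.shape[0]

    # normalized elastance (raised cosine up, half-cosine relaxation)
    if t <= tes:
        en = 0.5 * (1.0 - np.cos(np.pi * t / tes))
    elif t <= tes + tr:
        en = 0.5 * (1.0 + np.cos(np.pi * (t - tes) / tr))
    else:
        en = 0.0
    E = Eed + (Ees - Eed) * en
    V = y[0]
    Plv = E * (V - Vd)

    qin = (Pfill - Plv) / Rven
    if qin < 0.0:
        qin = 0.0
    qv = (Plv - y[1]) / Rvalve
    if qv < 0.0:
        qv = 0.0
    dy[0] = qin - qv

    for j in range(n_nodes):
        inflow[j] = 0.0
    inflow[0] = qv

    iq = 1 + n_nodes
    for e in range(n_el):
        q = y[iq + e]
        pu = y[1 + up[e]]
        pd = y[2 + e]
        dy[iq + e] = (pu - pd - R[e] * q) / L[e]
        inflow[up[e]] -= q
        inflow[e + 1] += q

    ipt = iq + n_el
    for k in range(n_term):
        pn = y[1 + tnode[k]]
        pt = y[ipt + k]
        qwk = (pn - pt) / Rc[k]
        inflow[tnode[k]] -= qwk
        dy[ipt + k] = (qwk - (pt - Pout[k]) / Rp[k]) / Ct[k]

    for j in range(n_nodes):
        dy[1 + j] = inflow[j] / Cn[j]


@njit(cache=True, fastmath=True)
def _run(y, T, dt, n_cycles_max, tol_pa, n_out,
         up, R, L, Cn, tnode, Rc, Rp, Ct, Pout,
         Ees, Eed, Vd, Pfill, tes, tr, Rven, Rvalve):  # pragma: no cover - jit
    n_el = up.shape[0]
    n_nodes = n_el + 1
    n_term = tnode.shape[0]
    n_state = y.shape[0]

    n_steps = int(round(T / dt))
    if n_steps < 4 * n_out:
        n_steps = 4 * n_out
    h = T / n_steps

    k1 = np.empty(n_state)
    k2 = np.empty(n_state)
    k3 = np.empty(n_state)
    k4 = np.empty(n_state)
    yt = np.empty(n_state)
    inflow = np.empty(n_nodes)

    p_prev = np.zeros((n_nodes, n_out))
    p_cur = np.zeros((n_nodes, n_out))
    q_cur = np.zeros((n_el, n_out))
    pt_cur = np.zeros((n_term, n_out))
    v_cur = np.zeros(n_out)
    plv_cur = np.zeros(n_out)
    qv_cur = np.zeros(n_out)
    diffs = np.full(n_cycles_max, np.nan)

    # map output sample j -> step index
    samp = np.empty(n_out, dtype=np.int64)
    for j in range(n_out):
        samp[j] = (j * n_steps) // n_out

    converged = False
    diverged = False
    cycles = 0
    for cyc in range(n_cycles_max):
        jnext = 0
        for i in range(n_steps):
            t = i * h
            if jnext < n_out and i == samp[jnext]:
                for j in range(n_nodes):
                    p_cur[j, jnext] = y[1 + j]
                for e in range(n_el):
                    q_cur[e, jnext] = y[1 + n_nodes + e]
                for k in range(n_term):
                    pt_cur[k, jnext] = y[1 + n_nodes + n_el + k]
                v_cur[jnext] = y[0]
                if t <= tes:
                    en = 0.5 * (1.0 - np.cos(np.pi * t / tes))
                elif t <= tes + tr:
                    en = 0.5 * (1.0 + np.cos(np.pi * (t - tes) / tr))
                else:
                    en = 0.0
                E = Eed + (Ees - Eed) * en
                plv = E * (y[0] - Vd)
                plv_cur[jnext] = plv
                qv = (plv - y[1]) / Rvalve
                qv_cur[jnext] = qv if qv > 0.0 else 0.0
                jnext += 1

            _rhs(y, k1, inflow, t, T, up, R, L, Cn, tnode, Rc, Rp, Ct, Pout,
                 Ees, Eed, Vd, Pfill, tes, tr, Rven, Rvalve)
            for s in range(n_state):
                yt[s] = y[s] + 0.5 * h * k1[s]
            _rhs(yt, k2, inflow, t + 0.5 * h, T, up, R, L, Cn, tnode, Rc, Rp, Ct, Pout,
                 Ees, Eed, Vd, Pfill, tes, tr, Rven, Rvalve)
            for s in range(n_state):
                yt[s] = y[s] + 0.5 * h * k2[s]
            _rhs(yt, k3, inflow, t + 0.5 * h, T, up, R, L, Cn, tnode, Rc, Rp, Ct, Pout,
                 Ees, Eed, Vd, Pfill, tes, tr, Rven, Rvalve)
            for s in range(n_state):
                yt[s] = y[s] + h * k3[s]
            t4 = t + h
            if t4 >= T:
                t4 = t4 - T
            _rhs(yt, k4, inflow, t4, T, up, R, L, Cn, tnode, Rc, Rp, Ct, Pout,
                 Ees, Eed, Vd, Pfill, tes, tr, Rven, Rvalve)
            for s in range(n_state):
                y[s] = y[s] + (h / 6.0) * (k1[s] + 2.0 * k2[s] + 2.0 * k3[s] + k4[s])

        cycles = cyc + 1
        ok = True
        for s in range(n_state):
            if not np.isfinite(y[s]):
                ok = False
        if not ok:
            diverged = True
            break

        if cyc > 0:
            d = 0.0
            for j in range(n_nodes):
                for m in range(n_out):
                    a = abs(p_cur[j, m] - p_prev[j, m])
                    if a > d:
                        d = a
            diffs[cyc] = d
            if d < tol_pa:
                converged = True
                break
        for j in range(n_nodes):
            for m in range(n_out):
                p_prev[j, m] = p_cur[j, m]

    return (p_cur, q_cur, pt_cur, v_cur, plv_cur, qv_cur,
            converged, diverged, cycles, diffs)


class SimulationDivergedError(RuntimeError):
    """Raised when the integrator produces non-finite state."""


def simulate(
    v: VentricleParams,
    tree: ArterialTree,
    blood: Optional[BloodProperties] = None,
    s: Optional[SolverSettings] = None,
) -> SimulationResult:
    """Run the coupled ventricle-network simulation to periodic steady state.

    Returns the final-cycle waveforms at ``output_rate`` samples per cycle.
    Raises :class:`SimulationDivergedError` on non-finite state; a
    non-converged (but finite) run is returned with ``converged=False``.
    """
    blood = blood or BloodProperties()
    s = s or SolverSettings()
    T = v.period
    tes = v.t_es_s
    tr = RELAXATION_RATIO * tes
    if tes + tr >= T:
        raise ValueError(
            f"systole longer than cycle: t_es + t_r = {tes + tr:.3f} s >= T = {T:.3f} s"
        )

    net = _discretize(tree, blood)
    n_state = 1 + net["n_nodes"] + net["n_el"] + len(net["term_ids"])
    y0 = np.empty(n_state)
    # warm start: Ohmic mean-pressure estimate from a crude stroke-volume
    # fixed point (end-systolic pressure ~ 1.1 x MAP), clipped to sanity
    tpr = tree.total_peripheral_resistance()
    edv = v.V_d + v.P_fill / v.E_ed
    sv_est = (edv - v.V_d) / (1.0 + 1.1 * (v.HR / 60.0) * tpr / v.E_es)
    p_est = sv_est * (v.HR / 60.0) * tpr + 3.0
    p_init = float(np.clip(p_est, 40.0, 130.0)) * MMHG_TO_PA
    y0[0] = (v.V_d + v.P_fill / v.E_ed) * ML_TO_M3  # relaxed ventricle filled to P_fill
    y0[1 : 1 + net["n_nodes"]] = p_init
    y0[1 + net["n_nodes"] : 1 + net["n_nodes"] + net["n_el"]] = 0.0
    y0[1 + net["n_nodes"] + net["n_el"] :] = p_init

    # stability guard: the fastest modes are the resistively coupled nodes
    # (aortic root through R_valve while the valve is open; terminal nodes
    # through R_c). Shrink dt so RK4 stays inside its stability region for
    # the stiffest such mode.
    lam_root = 1.0 / (v.R_valve * R_CLIN_TO_SI * net["C_node"][0])
    lam_term = float(np.max(1.0 / (net["Rc"] * net["C_node"][net["term_node"]])))
    dt_eff = min(s.dt, 2.5 / max(lam_root, lam_term))

    (p_cur, q_cur, pt_cur, v_cur, plv_cur, qv_cur,
     converged, diverged, cycles, diffs) = _run(
        y0, T, dt_eff, s.n_cycles_max, s.convergence_tol * MMHG_TO_PA, s.output_rate,
        net["up"], net["R"], net["L"], net["C_node"],
        net["term_node"], net["Rc"], net["Rp"], net["Ct"], net["Pout"],
        v.E_es * MMHG_TO_PA / ML_TO_M3, v.E_ed * MMHG_TO_PA / ML_TO_M3,
        v.V_d * ML_TO_M3, v.P_fill * MMHG_TO_PA, tes, tr,
        v.R_ven * R_CLIN_TO_SI, v.R_valve * R_CLIN_TO_SI,
    )
    if diverged:
        raise SimulationDivergedError(f"simulation diverged for parameters {v}")

    pressure: dict[str, PressureWave] = {
        "aortic_root": PressureWave(p_cur[0] / MMHG_TO_PA, T)
    }
    flow: dict[str, np.ndarray] = {}
    for seg_id in net["order"]:
        node = net["seg_last_node"][seg_id]
        pressure[seg_id] = PressureWave(p_cur[node] / MMHG_TO_PA, T)
        last_el = net["seg_elem_range"][seg_id][1] - 1
        flow[seg_id] = q_cur[last_el] / ML_TO_M3

    terminal_outflow = {}
    for k, tid in enumerate(net["term_ids"]):
        po = net["Pout"][k]
        terminal_outflow[tid] = (pt_cur[k] - po) / net["Rp"][k] / ML_TO_M3

    return SimulationResult(
        pressure=pressure,
        flow=flow,
        lv_pressure=PressureWave(plv_cur / MMHG_TO_PA, T),
        lv_volume=v_cur / ML_TO_M3,
        valve_flow=qv_cur / ML_TO_M3,
        terminal_outflow=terminal_outflow,
        converged=bool(converged),
        cycles_run=int(cycles),
        cycle_differences=diffs / MMHG_TO_PA,
        period=T,
    )
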