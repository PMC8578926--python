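"""Time-varying elastance model of the left ventricle.

The ventricle is described by a normalized elastance waveform e_n(t) that
cycles between 0 (end diastole) and 1 (end systole at t = t_es). The
instantaneous elastance interpolates between the end-diastolic and
end-systolic elastances,

    E(t) = E_ed + (E_es - E_ed) * e_n(t),

and ventricular pressure follows the elastance relation

    P_LV(t) = E(t) * (V_LV(t) - V_d),

with V_d the dead volume (the volume-axis intercept of the ESPVR).

e_n(t) is a piecewise raised cosine: a half-cosine upstroke over [0, t_es],
a half-cosine relaxation over (t_es, t_es + t_r] with t_r = t_es/2, and zero
for the rest of the cycle. It is continuous and peaks at exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "VentricleParams",
    "BloodProperties",
    "normalized_elastance",
    "instantaneous_elastance",
    "lv_pressure",
    "RELAXATION_RATIO",
]

#: duration of relaxation relative to the contraction time t_es
RELAXATION_RATIO = 0.5


@dataclass(frozen=True)
class VentricleParams:
    """Parameters of the time-varying elastance left ventricle.

    Attributes
    ----------
    E_es : float
        End-systolic elastance, mmHg/ml (slope of the ESPVR).
    E_ed : float
        End-diastolic elastance, mmHg/ml.
    V_d : float
        Dead volume, ml (ESPVR volume intercept).
    P_fill : float
        Venous filling pressure, mmHg.
    t_es : float
        Time of maximal elastance, ms.
    HR : float
        Heart rate, bpm.
    R_ven : float
        Venous (filling) resistance, mmHg·s/ml.
    R_valve : float
        Aortic valve resistance, mmHg·s/ml.
    """

    E_es: float = 2.6
    E_ed: float = 0.08
    V_d: float = 15.0
    P_fill: float = 14.0
    t_es: float = 340.0
    HR: float = 75.0
    R_ven: float = 0.003
    R_valve: float = 0.006

    def __post_init__(self) -> None:
        if not (self.E_es > self.E_ed > 0):
            raise ValueError(f"need E_es > E_ed > 0, got E_es={self.E_es}, E_ed={self.E_ed}")
        if self.V_d < 0:
            raise ValueError("V_d must be >= 0")
        if self.HR <= 0:
            raise ValueError("HR must be positive")
        if not (0 < self.t_es < 60000.0 / self.HR):
            raise ValueError(
                f"t_es must lie inside the cycle: 0 < {self.t_es} < {60000.0 / self.HR:.1f} ms"
            )
        if self.R_ven <= 0 or self.R_valve <= 0:
            raise ValueError("R_ven and R_valve must be positive")

    @property
    def period(self) -> float:
        """Cardiac cycle length, s."""
        return 60.0 / self.HR

    @property
    def t_es_s(self) -> float:
        """Time of maximal elastance, s."""
        return self.t_es / 1000.0


@dataclass(frozen=True)
class BloodProperties:
    """Blood density (kg/m3) and dynamic viscosity (Pa·s)."""

    rho: float = 1050.0
    mu: float = 0.004

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("rho and mu must be positive")


def normalized_elastance(t, t_es: float, T: float):
    """Normalized elastance e_n(t) in [0, 1].

    Parameters
    ----------
    t : float or ndarray
        Time since the onset of contraction, s; must satisfy 0 <= t < T.
    t_es : float
        Time of maximal elastance, s.
    T : float
        Cycle length, s.

    Raises
    ------
    ValueError
        If systole (t_es plus the relaxation time t_es/2) does not fit
        inside the cycle.
    """
    t = np.asarray(t, dtype=float)
    t_r = RELAXATION_RATIO * t_es
    if t_es + t_r >= T:
        raise ValueError(
            f"systole longer than cycle: t_es + t_r = {t_es + t_r:.3f} s >= T = {T:.3f} s"
        )
    if np.any(t < 0) or np.any(t >= T):
        raise ValueError("t must satisfy 0 <= t < T")
    up = 0.5 * (1.0 - np.cos(np.pi * np.minimum(t, t_es) / t_es))
    down = 0.5 * (1.0 + np.cos(np.pi * (t - t_es) / t_r))
    out = np.where(t <= t_es, up, np.where(t <= t_es + t_r, down, 0.0))
    return out if out.ndim else float(out)


def instantaneous_elastance(t, p: VentricleParams, T: float):
    """Instantaneous elastance E(t) = E_ed + (E_es - E_ed) e_n(t), mmHg/ml."""
    return p.E_ed + (p.E_es - p.E_ed) * normalized_elastance(t, p.t_es_s, T)


def lv_pressure(V, E_t, V_d: float):
    """Ventricular pressure from the elastance relation, mmHg.

    P_LV = E(t) * (V - V_d). Negative values are permitted transiently;
    the solver clamps flows (valves), never pressure.
    """
    return E_t * (np.asarray(V, dtype=float) - V_d)
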