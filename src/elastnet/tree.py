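"""Arterial tree description and construction.

Each artery is a long tapered tube characterized by its length, inlet and
outlet diameters and a (constant) distensibility; terminal arteries drain
into three-element Windkessel loads. The packaged default tree is a
reduced systemic network: ascending aorta -> aortic arch (two parts) ->
thoracic -> abdominal aorta -> lumped iliac terminal, with the
brachiocephalic / right subclavian, left carotid, and left subclavian ->
axillary -> brachial -> forearm branches. The brachial pressure waveform
is recorded at the distal left brachial node, interior to the network
(the lumped radial+ulnar run-off lies beyond it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import yaml
from scipy.optimize import brentq

from .units import distensibility_to_si

__all__ = [
    "ArterialSegment",
    "WindkesselTerminal",
    "ArterialTree",
    "load_tree_config",
    "build_default_tree",
    "wave_speed",
]


@dataclass(frozen=True)
class ArterialSegment:
    """One tapered arterial segment.

    length/diameters in cm, distensibility in 1e-3/mmHg. ``n_elements``
    is the number of lumped elements used by the solver.
    """

    id: str
    parent: Optional[str]
    length: float
    d_in: float
    d_out: float
    distensibility: float
    is_terminal: bool = False
    n_elements: int = 2

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.id}: length must be positive")
        if not (self.d_in >= self.d_out > 0):
            raise ValueError(f"{self.id}: need d_in >= d_out > 0")
        if self.distensibility <= 0:
            raise ValueError(f"{self.id}: distensibility must be positive")
        if self.n_elements < 2:
            raise ValueError(f"{self.id}: n_elements must be >= 2")


@dataclass(frozen=True)
class WindkesselTerminal:
    """Three-element Windkessel: R_c in series with parallel (C_t, R_p).

    Resistances in mmHg·s/ml, compliance in ml/mmHg, P_out in mmHg.
    """

    R_c: float
    R_p: float
    C_t: float
    P_out: float = 3.0

    def __post_init__(self) -> None:
        if self.R_c < 0:
            raise ValueError("R_c must be >= 0")
        if self.R_p <= 0 or self.C_t <= 0:
            raise ValueError("R_p and C_t must be positive")


@dataclass
class ArterialTree:
    """Connected, acyclic collection of segments with terminal loads."""

    segments: list[ArterialSegment]
    terminals: dict[str, WindkesselTerminal]
    root: str = field(init=False)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.segments]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate segment ids")
        by_id = {s.id: s for s in self.segments}
        roots = [s.id for s in self.segments if s.parent is None]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {roots}")
        self.root = roots[0]
        children: dict[str, list[str]] = {i: [] for i in ids}
        for s in self.segments:
            if s.parent is not None:
                if s.parent not in by_id:
                    raise ValueError(f"{s.id}: unknown parent {s.parent}")
                children[s.parent].append(s.id)
        # connectivity + acyclicity via traversal from the root
        seen: set[str] = set()
        stack = [self.root]
        while stack:
            u = stack.pop()
            if u in seen:
                raise ValueError("cycle detected in tree")
            seen.add(u)
            stack.extend(children[u])
        if seen != set(ids):
            raise ValueError("tree is not connected")
        for s in self.segments:
            leaf = not children[s.id]
            if leaf and s.id not in self.terminals:
                raise ValueError(f"leaf segment {s.id} has no Windkessel terminal")
            if s.is_terminal != leaf:
                raise ValueError(f"{s.id}: is_terminal flag inconsistent with topology")
        self._children = children
        self._by_id = by_id

    def children_of(self, seg_id: str) -> list[str]:
        return list(self._children[seg_id])

    def segment(self, seg_id: str) -> ArterialSegment:
        return self._by_id[seg_id]

    def topological_order(self) -> list[str]:
        order: list[str] = []
        stack = [self.root]
        while stack:
            u = stack.pop(0)
            order.append(u)
            stack.extend(self._children[u])
        return order

    def total_peripheral_resistance(self) -> float:
        """Parallel combination of the terminal (R_c + R_p), mmHg·s/ml."""
        g = sum(1.0 / (t.R_c + t.R_p) for t in self.terminals.values())
        return 1.0 / g


def wave_speed(distensibility: float, rho: float) -> float:
    """Pulse wave speed c = sqrt(1 / (rho * D)), m/s.

    ``distensibility`` in 1e-3/mmHg; equivalent to the Moens-Korteweg
    speed expressed through the area distensibility.
    """
    if distensibility <= 0:
        raise ValueError("distensibility must be positive")
    if rho <= 0:
        raise ValueError("rho must be positive")
    return math.sqrt(1.0 / (rho * distensibility_to_si(distensibility)))


def _default_n_elements(length_cm: float) -> int:
    # ~one element per 2 cm: resolves waveform features to ~80-100 Hz, which
    # fine-feature extraction needs, while keeping the solver desk-scale
    return max(2, int(round(length_cm / 2.0)))


def load_tree_config(path: Optional[str] = None) -> dict:
    """Load the tree geometry config (packaged default if ``path`` is None)."""
    if path is None:
        cfg_text = (
            resources.files("elastnet.data").joinpath("default_tree.yaml").read_text()
        )
    else:
        with open(path) as fh:
            cfg_text = fh.read()
    return yaml.safe_load(cfg_text)


def build_default_tree(
    height: float = 180.0,
    aortic_diameter_scale: float = 1.0,
    distensibility: float = 5.86,
    TPR: float = 1.28,
    Ct_scale: float = 1.0,
    config: Optional[dict] = None,
) -> ArterialTree:
    """Build the packaged tree, scaled to one virtual subject.

    Parameters
    ----------
    height : float
        Subject height, cm; all lengths scale by height/180.
    aortic_diameter_scale : float
        Uniform diameter scale applied to every segment.
    distensibility : float
        Aortic distensibility, 1e-3/mmHg; per-segment values follow the
        packaged stiffness-ratio map.
    TPR : float
        Target total peripheral resistance, mmHg·s/ml; terminal R_p values
        keep their packaged ratios and are uniformly rescaled so the
        parallel total of (R_c + R_p) equals TPR.
    Ct_scale : float
        Multiplier on every terminal compliance.
    """
    for name, v in [
        ("height", height),
        ("aortic_diameter_scale", aortic_diameter_scale),
        ("distensibility", distensibility),
        ("TPR", TPR),
        ("Ct_scale", Ct_scale),
    ]:
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")

    cfg = config if config is not None else load_tree_config()
    ref_height = float(cfg["reference"]["height_cm"])
    length_scale = height / ref_height

    segments = []
    term_records = []
    for rec in cfg["segments"]:
        is_term = "terminal" in rec
        segments.append(
            ArterialSegment(
                id=rec["id"],
                parent=rec["parent"],
                length=rec["length_cm"] * length_scale,
                d_in=rec["d_in_cm"] * aortic_diameter_scale,
                d_out=rec["d_out_cm"] * aortic_diameter_scale,
                distensibility=distensibility * rec["stiffness_ratio"],
                is_terminal=is_term,
                n_elements=rec.get(
                    "n_elements", _default_n_elements(rec["length_cm"] * length_scale)
                ),
            )
        )
        if is_term:
            term_records.append((rec["id"], rec["terminal"]))

    # uniform scale s on the R_p ratios so that parallel{R_c + s*ratio} = TPR
    def residual(s: float) -> float:
        g = sum(1.0 / (t["R_c"] + s * t["R_p_ratio"]) for _, t in term_records)
        return g - 1.0 / TPR

    g_at_zero = sum(1.0 / t["R_c"] for _, t in term_records if t["R_c"] > 0)
    if g_at_zero <= 1.0 / TPR:
        raise ValueError(f"TPR={TPR} unreachable: characteristic resistances alone exceed it")
    s = brentq(residual, 1e-12, 1e6, xtol=1e-12, rtol=1e-14)

    terminals = {
        seg_id: WindkesselTerminal(
            R_c=t["R_c"],
            R_p=s * t["R_p_ratio"],
            C_t=t["C_t"] * Ct_scale,
            P_out=t.get("P_out", 3.0),
        )
        for seg_id, t in term_records
    }
    return ArterialTree(segments=segments, terminals=terminals)
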