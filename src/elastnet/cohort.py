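"""Virtual-population generation.

Cardiac and vascular parameters are drawn independently from truncated
Gaussians (redraw-until-inside, so marginals stay near-Gaussian), each
parameter set is turned into a scaled arterial tree plus ventricle,
simulated to periodic steady state, and kept only if all eight brachial
and aortic pressure summaries (SBP, DBP, MAP, PP at both sites) lie
within mean +/- 2.807 SD of the normative reference table — a 99.5%
band that discards hemodynamically implausible subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Callable, Optional

import numpy as np
import pandas as pd
import yaml

from .solver import (
    BPSummary,
    PressureWave,
    SimulationDivergedError,
    SolverSettings,
    bp_summary,
    simulate,
)
from .tree import build_default_tree
from .ventricle import RELAXATION_RATIO, BloodProperties, VentricleParams

__all__ = [
    "ParameterDistributions",
    "ReferenceBPTable",
    "VirtualSubject",
    "Cohort",
    "sample_parameters",
    "derive_scales",
    "plausibility_filter",
    "generate_cohort",
    "PLAUSIBILITY_Z",
]

#: half-width of the plausibility band in reference SDs (99.5% band)
PLAUSIBILITY_Z = 2.807

#: sampled parameters: name -> (mean, SD, lower, upper)
_DEFAULT_DISTRIBUTIONS: dict[str, tuple[float, float, float, float]] = {
    "E_es": (2.3, 1.0, 0.3, 6.0),            # mmHg/ml
    "E_ed": (0.2, 0.11, 0.02, 0.6),          # mmHg/ml
    "P_fill": (15.0, 5.4, 3.0, 30.0),        # mmHg
    "t_es": (327.0, 39.0, 200.0, 500.0),     # ms
    "HR": (63.7, 9.5, 40.0, 110.0),          # bpm
    "distensibility": (5.86, 3.23, 0.5, 16.0),  # 1e-3/mmHg, aortic
    "TPR": (1.28, 0.31, 0.5, 2.5),           # mmHg·s/ml
    "diameter": (33.2, 4.1, 20.0, 48.0),     # mm, aortic root
    "height": (169.2, 8.9, 140.0, 200.0),    # cm
}

PARAM_NAMES = tuple(_DEFAULT_DISTRIBUTIONS)


@dataclass(frozen=True)
class ParameterDistributions:
    """Truncated-Gaussian marginals of the sampled parameters.

    ``params`` maps name -> (mean, SD, lower, upper). Reference values
    used for geometry scaling (180 cm height, 33.2 mm aortic diameter,
    5.86e-3/mmHg distensibility) live on the tree config, except the two
    quoted here for the scale derivation.
    """

    params: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_DISTRIBUTIONS)
    )
    ref_height: float = 180.0
    ref_diameter: float = 33.2
    ref_distensibility: float = 5.86

    def __post_init__(self) -> None:
        for name, (mean, sd, lo, hi) in self.params.items():
            if sd <= 0:
                raise ValueError(f"{name}: SD must be positive")
            if not lo < hi:
                raise ValueError(f"{name}: lower bound must be below upper bound")

    def with_overrides(self, **overrides) -> "ParameterDistributions":
        """Return a copy with per-parameter (mean, sd, lo, hi) replaced."""
        params = dict(self.params)
        params.update(overrides)
        return replace(self, params=params)


_BP_QUANTITIES = (
    "brachial_SBP", "brachial_DBP", "brachial_MAP", "brachial_PP",
    "aortic_SBP", "aortic_DBP", "aortic_MAP", "aortic_PP",
)


@dataclass(frozen=True)
class ReferenceBPTable:
    """Normative mean/SD (mmHg) for the 8 filtered pressure quantities."""

    values: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        missing = set(_BP_QUANTITIES) - set(self.values)
        if missing:
            raise ValueError(f"missing reference quantities: {sorted(missing)}")
        for q, (_, sd) in self.values.items():
            if sd <= 0:
                raise ValueError(f"{q}: SD must be positive")

    @classmethod
    def default(cls) -> "ReferenceBPTable":
        text = resources.files("elastnet.data").joinpath("reference_bp.yaml").read_text()
        return cls.from_mapping(yaml.safe_load(text))

    @classmethod
    def from_yaml(cls, path: str) -> "ReferenceBPTable":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    @classmethod
    def from_mapping(cls, cfg: dict) -> "ReferenceBPTable":
        vals = {}
        for site in ("brachial", "aortic"):
            for q in ("SBP", "DBP", "MAP", "PP"):
                rec = cfg[site][q]
                vals[f"{site}_{q}"] = (float(rec["mean"]), float(rec["sd"]))
        return cls(vals)


@dataclass
class VirtualSubject:
    """One sampled parameter set with its simulated waveforms and verdict."""

    params: dict[str, float]
    brachial_wave: Optional[PressureWave]
    aortic_wave: Optional[PressureWave]
    brachial_summary: Optional[BPSummary]
    aortic_summary: Optional[BPSummary]
    E_es_true: float
    accepted: bool
    reject_reason: str = ""
    stroke_volume: float = np.nan
    ejection_fraction: float = np.nan


@dataclass
class Cohort:
    """Generation-ordered collection of virtual subjects."""

    subjects: list[VirtualSubject]
    seed: int
    n_requested: int

    @property
    def n_accepted(self) -> int:
        return sum(s.accepted for s in self.subjects)

    @property
    def accepted(self) -> list[VirtualSubject]:
        return [s for s in self.subjects if s.accepted]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row = dict(s.params)
            row["E_es_true"] = s.E_es_true
            row["accepted"] = s.accepted
            row["reject_reason"] = s.reject_reason
            row["stroke_volume"] = s.stroke_volume
            row["ejection_fraction"] = s.ejection_fraction
            for summ, site in ((s.brachial_summary, "brachial"), (s.aortic_summary, "aortic")):
                for q in ("SBP", "DBP", "MAP", "PP"):
                    row[f"{site}_{q}"] = getattr(summ, q) if summ is not None else np.nan
            rows.append(row)
        return pd.DataFrame(rows)

    def waveform_matrix(self, site: str = "brachial") -> tuple[np.ndarray, np.ndarray]:
        """(waves, periods) of the accepted subjects at ``site``."""
        attr = "brachial_wave" if site == "brachial" else "aortic_wave"
        waves = np.stack([getattr(s, attr).samples for s in self.accepted])
        periods = np.array([getattr(s, attr).period for s in self.accepted])
        return waves, periods

    def e_es_true(self) -> np.ndarray:
        return np.array([s.E_es_true for s in self.accepted])


def sample_parameters(
    n: int, dist: Optional[ParameterDistributions] = None, seed: int = 0
) -> pd.DataFrame:
    """Draw ``n`` parameter sets from the truncated Gaussians.

    Each parameter is drawn independently; out-of-bound draws are redrawn
    until inside. Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    dist = dist or ParameterDistributions()
    rng = np.random.default_rng(seed)
    cols = {}
    for name in PARAM_NAMES:
        mean, sd, lo, hi = dist.params[name]
        x = rng.normal(mean, sd, size=n)
        bad = (x < lo) | (x > hi)
        while np.any(bad):
            x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
            bad = (x < lo) | (x > hi)
        cols[name] = x
    return pd.DataFrame(cols)


def derive_scales(params: dict[str, float] | pd.Series,
                  dist: Optional[ParameterDistributions] = None):
    """(height_scale, diameter_scale, Ct_scale) for one parameter set.

    Lengths scale with height relative to the 180 cm reference, all
    diameters with the sampled aortic diameter relative to its reference,
    and terminal compliances follow distensibility (wall properties are
    altered simultaneously along the tree and at the terminals).
    """
    dist = dist or ParameterDistributions()
    return (
        float(params["height"]) / dist.ref_height,
        float(params["diameter"]) / dist.ref_diameter,
        float(params["distensibility"]) / dist.ref_distensibility,
    )


def plausibility_filter(
    brachial: BPSummary, aortic: BPSummary, ref: Optional[ReferenceBPTable] = None
) -> tuple[bool, str]:
    """Check the 8 pressure summaries against mean +/- 2.807 SD (inclusive).

    Returns (accepted, reason); ``reason`` names the first violated
    quantity, checked in the fixed order brachial SBP/DBP/MAP/PP then
    aortic SBP/DBP/MAP/PP.
    """
    ref = ref or ReferenceBPTable.default()
    values = {**{f"brachial_{q}": v for q, v in brachial.as_dict().items()},
              **{f"aortic_{q}": v for q, v in aortic.as_dict().items()}}
    for q in _BP_QUANTITIES:
        if not np.isfinite(values[q]):
            return False, q
        mean, sd = ref.values[q]
        if abs(values[q] - mean) > PLAUSIBILITY_Z * sd:
            return False, q
    return True, ""


def generate_cohort(
    n: int,
    dist: Optional[ParameterDistributions] = None,
    ref: Optional[ReferenceBPTable] = None,
    solver: Optional[SolverSettings] = None,
    seed: int = 0,
    blood: Optional[BloodProperties] = None,
    tree_config: Optional[dict] = None,
    V_d: float = 15.0,
    R_ven: float = 0.003,
    R_valve: float = 0.006,
    keep_rejected_waves: bool = False,
    progress: Optional[Callable[[int, int], None]] = None,
) -> Cohort:
    """Sample, simulate and filter ``n`` virtual subjects.

    Simulator failures are recorded as rejections (reasons ``diverged``,
    ``non_converged`` or ``systole_exceeds_cycle``), never raised. Waves
    of rejected subjects are dropped unless ``keep_rejected_waves``.
    """
    dist = dist or ParameterDistributions()
    ref = ref or ReferenceBPTable.default()
    solver = solver or SolverSettings()
    blood = blood or BloodProperties()
    table = sample_parameters(n, dist, seed)

    subjects: list[VirtualSubject] = []
    for i, row in table.iterrows():
        p = row.to_dict()
        height_scale, diam_scale, ct_scale = derive_scales(p, dist)

        def rejected(reason: str) -> VirtualSubject:
            return VirtualSubject(
                params=p, brachial_wave=None, aortic_wave=None,
                brachial_summary=None, aortic_summary=None,
                E_es_true=p["E_es"], accepted=False, reject_reason=reason,
            )

        T_ms = 60000.0 / p["HR"]
        if p["t_es"] * (1.0 + RELAXATION_RATIO) >= T_ms:
            subjects.append(rejected("systole_exceeds_cycle"))
            continue
        if p["E_es"] <= p["E_ed"]:
            # independent Gaussians can cross; such a heart cannot eject
            subjects.append(rejected("e_es_below_e_ed"))
            continue

        v = VentricleParams(
            E_es=p["E_es"], E_ed=p["E_ed"], V_d=V_d, P_fill=p["P_fill"],
            t_es=p["t_es"], HR=p["HR"], R_ven=R_ven, R_valve=R_valve,
        )
        tree = build_default_tree(
            height=dist.ref_height * height_scale,
            aortic_diameter_scale=diam_scale,
            distensibility=p["distensibility"],
            TPR=p["TPR"],
            Ct_scale=ct_scale,
            config=tree_config,
        )
        try:
            res = simulate(v, tree, blood, solver)
        except SimulationDivergedError:
            subjects.append(rejected("diverged"))
            continue
        if not res.converged:
            subjects.append(rejected("non_converged"))
            continue

        brach = res.pressure["left_brachial"]
        aorta = res.pressure["aortic_root"]
        bs = bp_summary(brach, "left_brachial")
        asum = bp_summary(aorta, "aortic_root")
        ok, reason = plausibility_filter(bs, asum, ref)
        subjects.append(
            VirtualSubject(
                params=p,
                brachial_wave=brach if (ok or keep_rejected_waves) else None,
                aortic_wave=aorta if (ok or keep_rejected_waves) else None,
                brachial_summary=bs, aortic_summary=asum,
                E_es_true=p["E_es"], accepted=ok, reject_reason=reason,
                stroke_volume=res.stroke_volume,
                ejection_fraction=res.ejection_fraction,
            )
        )
        if progress is not None:
            progress(i + 1, n)
    return Cohort(subjects=subjects, seed=seed, n_requested=n)
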