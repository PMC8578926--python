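"""Agreement and accuracy statistics for elastance predictions.

Covers the regression line (ordinary least squares of predicted on
reference), Pearson correlation with its Wald-t p-value, RMSE and
range-normalized RMSE, Bland-Altman bias with 1.96-SD limits of
agreement, error-threshold fractions, and the SNR-sweep report that
re-corrupts the raw test waves, rebuilds the channels with the frozen
training scalers, and re-evaluates the trained network at each noise
level.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocessing import WaveformMatrix, add_awgn, make_channels

__all__ = [
    "AgreementReport",
    "pearson_r",
    "nrmse",
    "bland_altman",
    "error_fractions",
    "compute_agreement",
    "noise_sweep_report",
    "sweep_table",
    "DEFAULT_SNR_LIST",
]

DEFAULT_SNR_LIST = (70.0, 60.0, 50.0, 40.0, 30.0)
DEFAULT_THRESHOLDS = (0.05, 0.5)


@dataclass
class AgreementReport:
    """All agreement statistics for one (model, condition) run.

    Elastance units (mmHg/ml) except r, slope and the percent nRMSE.
    ``frac_abs_lt`` maps an absolute-error threshold to the fraction of
    subjects whose |error| is strictly below it.
    """

    label: str
    n: int
    slope: float
    intercept: float
    r: float
    p_value: float
    RMSE: float
    nRMSE: float
    bias: float
    loa_low: float
    loa_high: float
    pred_mean: float
    pred_sd: float
    frac_abs_lt: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-12 <= self.r <= 1.0 + 1e-12):
            raise ValueError("r must lie in [-1, 1]")
        if self.nRMSE < 0:
            raise ValueError("nRMSE must be >= 0")
        if not (self.loa_low <= self.bias <= self.loa_high):
            raise ValueError("limits of agreement must bracket the bias")

    def to_json(self) -> str:
        d = asdict(self)
        d["frac_abs_lt"] = {str(k): v for k, v in self.frac_abs_lt.items()}
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "AgreementReport":
        d = json.loads(text)
        d["frac_abs_lt"] = {float(k): v for k, v in d["frac_abs_lt"].items()}
        return cls(**d)


def pearson_r(pred: np.ndarray, ref: np.ndarray) -> tuple[float, float]:
    """Sample Pearson correlation and two-sided p-value.

    p follows the t statistic r*sqrt((n-2)/(1-r^2)) on n-2 degrees of
    freedom (Wald test).
    """
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.size < 3:
        raise ValueError("need n >= 3")
    if np.std(pred) == 0 or np.std(ref) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(pred, ref)
    return float(r), float(p)


def nrmse(pred: np.ndarray, ref: np.ndarray) -> float:
    """RMSE normalized by the reference range, percent."""
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    rng = np.max(ref) - np.min(ref)
    if rng <= 0:
        raise ValueError("reference range is zero")
    rmse = float(np.sqrt(np.mean((pred - ref) ** 2)))
    return 100.0 * rmse / float(rng)


def bland_altman(pred: np.ndarray, ref: np.ndarray) -> tuple[float, float, float]:
    """(bias, loa_low, loa_high) of the differences predicted - reference.

    LoA = bias +/- 1.96 SD of the differences (n-1 denominator).
    """
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.size < 2:
        raise ValueError("need n >= 2")
    d = pred - ref
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def error_fractions(
    pred: np.ndarray, ref: np.ndarray, thresholds: Sequence[float]
) -> dict[float, float]:
    """Fraction of subjects with |pred - ref| strictly below each threshold."""
    err = np.abs(np.asarray(pred, dtype=float) - np.asarray(ref, dtype=float))
    out = {}
    for t in thresholds:
        if t <= 0:
            raise ValueError("thresholds must be positive")
        out[float(t)] = float(np.mean(err < t))
    return out


def compute_agreement(
    pred: np.ndarray,
    ref: np.ndarray,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    label: str = "",
) -> AgreementReport:
    """Assemble the full agreement report for one prediction run."""
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    lr = stats.linregress(ref, pred)  # predicted regressed on reference
    r, p = pearson_r(pred, ref)
    bias, lo, hi = bland_altman(pred, ref)
    return AgreementReport(
        label=label,
        n=int(pred.size),
        slope=float(lr.slope),
        intercept=float(lr.intercept),
        r=r,
        p_value=p,
        RMSE=float(np.sqrt(np.mean((pred - ref) ** 2))),
        nRMSE=nrmse(pred, ref),
        bias=bias,
        loa_low=lo,
        loa_high=hi,
        pred_mean=float(np.mean(pred)),
        pred_sd=float(np.std(pred, ddof=1)),
        frac_abs_lt=error_fractions(pred, ref, thresholds),
    )


def noise_sweep_report(
    results,
    raw_test_waves: np.ndarray,
    test_periods: np.ndarray,
    y_test: np.ndarray,
    scalers: dict,
    mode: str,
    snr_list: Sequence[float] = DEFAULT_SNR_LIST,
    seed: int = 0,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> dict[str, AgreementReport]:
    """Evaluate a trained regressor on clean and noise-corrupted test waves.

    For each SNR the raw (mmHg) test pressure waves are corrupted with
    seeded white Gaussian noise, the derivative channel is recomputed
    from the noisy wave (the corruption propagates through the central
    differences), both channels are renormalized with the frozen
    training scalers, and the full agreement report is computed.
    Reports are keyed 'clean' and 'snr_<value>'.
    """
    y_test = np.asarray(y_test, dtype=float)
    reports: dict[str, AgreementReport] = {}

    def eval_waves(waves: np.ndarray, label: str) -> AgreementReport:
        wm = WaveformMatrix(values=waves, periods=test_periods)
        X = make_channels(wm, mode, scalers)
        return compute_agreement(results.predict(X), y_test, thresholds, label=label)

    reports["clean"] = eval_waves(raw_test_waves, "clean")
    for k, snr in enumerate(snr_list):
        rng = np.random.default_rng(seed + k)
        noisy = add_awgn(raw_test_waves, snr, rng)
        key = f"snr_{int(snr) if float(snr).is_integer() else snr}"
        reports[key] = eval_waves(noisy, key)
    return reports


def sweep_table(reports_by_model: dict[str, dict[str, AgreementReport]]) -> pd.DataFrame:
    """Flatten sweep reports into a table (one row per model x condition)."""
    rows = []
    for model_name, reports in reports_by_model.items():
        for cond, rep in reports.items():
            rows.append(
                {
                    "model": model_name,
                    "condition": cond,
                    "n": rep.n,
                    "slope": rep.slope,
                    "intercept": rep.intercept,
                    "r": rep.r,
                    "p_value": rep.p_value,
                    "RMSE": rep.RMSE,
                    "nRMSE_pct": rep.nRMSE,
                    "bias": rep.bias,
                    "loa_low": rep.loa_low,
                    "loa_high": rep.loa_high,
                    "pred_mean": rep.pred_mean,
                    "pred_sd": rep.pred_sd,
                    **{f"frac_lt_{t}": v for t, v in rep.frac_abs_lt.items()},
                }
            )
    return pd.DataFrame(rows)
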