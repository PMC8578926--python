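"""Waveform preprocessing and corruption.

Single-cycle pressure waves are resampled to 200 uniform samples,
differentiated with periodic central differences (the wave is one full
cardiac cycle, so the endpoints wrap), min-max normalized per time point
with statistics fitted on the training partition only, and stacked into
one- or two-channel model inputs. White Gaussian noise at a prescribed
SNR (measured-power convention) emulates measurement error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from sklearn.preprocessing import MinMaxScaler

from .solver import PressureWave

__all__ = [
    "WaveformMatrix",
    "ScalerState",
    "SplitIndices",
    "resample_to_200",
    "time_derivative",
    "minmax_fit",
    "minmax_apply",
    "minmax_inverse",
    "make_channels",
    "fit_channel_scalers",
    "split_60_20_20",
    "add_awgn",
    "N_SAMPLES",
]

N_SAMPLES = 200


@dataclass
class WaveformMatrix:
    """n_subjects x 200 waveform samples plus per-subject periods."""

    values: np.ndarray
    periods: np.ndarray
    channel_tag: Literal["pressure", "derivative"] = "pressure"

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.periods = np.atleast_1d(np.asarray(self.periods, dtype=float))
        if self.values.shape[1] != N_SAMPLES:
            raise ValueError(f"expected {N_SAMPLES} columns, got {self.values.shape[1]}")
        if self.values.shape[0] != self.periods.shape[0]:
            raise ValueError("values and periods disagree on the number of subjects")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("waveform values must be finite")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def resample_to_200(wave: PressureWave) -> np.ndarray:
    """Linearly resample one cycle to 200 uniformly spaced samples.

    The input samples are treated as uniform over [0, period); the query
    grid is j*period/200, so an input that already has 200 uniform
    samples is returned unchanged and the first output sample equals the
    first input sample. The wrap interval interpolates toward the first
    sample at t = period.
    """
    s = np.asarray(wave.samples, dtype=float)
    n = s.size
    if n < 2:
        raise ValueError("need at least 2 samples to resample")
    t_in = np.arange(n + 1) * (wave.period / n)
    s_ext = np.concatenate([s, s[:1]])  # periodic closure
    t_out = np.arange(N_SAMPLES) * (wave.period / N_SAMPLES)
    return np.interp(t_out, t_in, s_ext)


def time_derivative(samples: np.ndarray, period: float) -> np.ndarray:
    """Periodic central-difference time derivative, mmHg/s.

    f'[n] = (f[n+1] - f[n-1]) / (2 tau) with tau = period/200 and
    periodic wrap-around at the endpoints. Works on a single wave (200,)
    or a stack (n, 200); for a stack, ``period`` may be per-row.
    """
    x = np.asarray(samples, dtype=float)
    if x.shape[-1] != N_SAMPLES:
        raise ValueError(f"expected {N_SAMPLES} samples, got {x.shape[-1]}")
    period = np.asarray(period, dtype=float)
    if np.any(period <= 0):
        raise ValueError("period must be positive")
    tau = period / N_SAMPLES
    if x.ndim == 2 and tau.ndim == 1:
        tau = tau[:, None]
    return (np.roll(x, -1, axis=-1) - np.roll(x, 1, axis=-1)) / (2.0 * tau)


@dataclass
class ScalerState:
    """Per-column min/max fitted on the training partition.

    Backed by sklearn's MinMaxScaler; columns with zero range on the
    fitting partition are mapped to 0.0 on transform.
    """

    data_min: np.ndarray
    data_max: np.ndarray

    def __post_init__(self) -> None:
        self.data_min = np.asarray(self.data_min, dtype=float)
        self.data_max = np.asarray(self.data_max, dtype=float)
        if np.any(self.data_max < self.data_min):
            raise ValueError("max must be >= min per column")

    @property
    def constant_columns(self) -> np.ndarray:
        return self.data_max == self.data_min


def minmax_fit(train_values: np.ndarray) -> ScalerState:
    """Fit per-column min/max on the training rows only."""
    x = np.atleast_2d(np.asarray(train_values, dtype=float))
    if x.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    sk = MinMaxScaler().fit(x)
    return ScalerState(data_min=sk.data_min_, data_max=sk.data_max_)


def minmax_apply(values: np.ndarray, state: ScalerState) -> np.ndarray:
    """x' = (x - min) / (max - min) per column, without clipping.

    Training rows land in [0, 1] by construction; validation/test values
    outside the fitted range are kept as-is (may leave [0, 1]). Constant
    columns map to 0.0.
    """
    x = np.atleast_2d(np.asarray(values, dtype=float))
    if x.shape[1] != state.data_min.shape[0]:
        raise ValueError("column count does not match fitted state")
    denom = state.data_max - state.data_min
    safe = np.where(denom > 0, denom, 1.0)
    out = (x - state.data_min) / safe
    out[:, state.constant_columns] = 0.0
    return out


def minmax_inverse(values: np.ndarray, state: ScalerState) -> np.ndarray:
    """Inverse of :func:`minmax_apply` on non-constant columns."""
    x = np.atleast_2d(np.asarray(values, dtype=float))
    denom = state.data_max - state.data_min
    return x * np.where(denom > 0, denom, 0.0) + state.data_min


@dataclass(frozen=True)
class SplitIndices:
    """Disjoint 60/20/20 train/validation/test index lists."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        n = self.train.size + self.validation.size + self.test.size
        union = np.concatenate([self.train, self.validation, self.test])
        if np.unique(union).size != n:
            raise ValueError("split indices must be disjoint and cover each row once")


def split_60_20_20(n: int, seed: int = 0) -> SplitIndices:
    """Random 60/20/20 partition of range(n).

    Validation and test sizes round 0.2 n to the nearest integer; the
    training set takes the remainder (n = 3748 gives 2248/750/750).
    """
    if n < 5:
        raise ValueError("need n >= 5 to split 60/20/20")
    n_val = int(round(0.2 * n))
    n_test = int(round(0.2 * n))
    perm = np.random.default_rng(seed).permutation(n)
    return SplitIndices(
        train=perm[: n - n_val - n_test],
        validation=perm[n - n_val - n_test : n - n_test],
        test=perm[n - n_test :],
        seed=seed,
    )


def fit_channel_scalers(
    pressure: WaveformMatrix,
    train_idx: np.ndarray,
    mode: Literal["one_channel", "two_channel"],
) -> dict[str, ScalerState]:
    """Fit the per-channel min-max scalers on the training rows.

    The derivative channel is computed from the raw (pre-normalization)
    pressure and gets its own scaler, so both channels end up on
    commensurate scales.
    """
    scalers = {"pressure": minmax_fit(pressure.values[train_idx])}
    if mode == "two_channel":
        deriv = time_derivative(pressure.values, pressure.periods)
        scalers["derivative"] = minmax_fit(deriv[train_idx])
    elif mode != "one_channel":
        raise ValueError(f"unknown mode {mode!r}")
    return scalers


def make_channels(
    pressure: WaveformMatrix,
    mode: Literal["one_channel", "two_channel"],
    scalers: dict[str, ScalerState],
) -> np.ndarray:
    """Stack normalized channels into an (n, C, 200) input array.

    Channel 0 is the normalized pressure; channel 1 (two-channel mode)
    is the normalized periodic central-difference derivative, computed
    from the raw pressure before normalization.
    """
    if pressure.n == 0:
        return np.empty((0, 2 if mode == "two_channel" else 1, N_SAMPLES))
    chans = [minmax_apply(pressure.values, scalers["pressure"])]
    if mode == "two_channel":
        deriv = time_derivative(pressure.values, pressure.periods)
        chans.append(minmax_apply(deriv, scalers["derivative"]))
    elif mode != "one_channel":
        raise ValueError(f"unknown mode {mode!r}")
    return np.stack(chans, axis=1)


def add_awgn(samples: np.ndarray, snr_db: float, seed: Optional[int | np.random.Generator] = None) -> np.ndarray:
    """Add white Gaussian noise at the given SNR (dB), measured-power.

    The noise variance is P_sig / 10^(snr_db/10) with P_sig the mean
    square of the input — per row if ``samples`` is 2-D (each subject's
    wave carries its own power). ``snr_db >= 200`` returns the input
    unchanged (a copy).
    """
    x = np.asarray(samples, dtype=float)
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite")
    if snr_db >= 200.0:
        return x.copy()
    p_sig = np.mean(x * x, axis=-1, keepdims=True)
    if np.any(p_sig <= 0):
        raise ValueError("zero-power input has no defined SNR")
    sigma = np.sqrt(p_sig / 10.0 ** (snr_db / 10.0))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return x + sigma * rng.standard_normal(x.shape)
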