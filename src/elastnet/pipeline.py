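"""End-to-end orchestration and solver-free test fixtures.

`run_pipeline` composes the full study: virtual-cohort generation,
preprocessing into one- and two-channel datasets, training of both
regressors, clean evaluation and the SNR sweep, with every stage driven
by its own seed so that, e.g., changing the noise seed cannot perturb
cohort generation. `generate_toy_fixtures` produces parametric pulse
shapes with labels that are a known smooth function of the waveform, a
learnable substrate for tests that must not depend on the hemodynamic
solver.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib.metadata import version
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .architecture import CNNArchitecture, TrainingConfig
from .cohort import Cohort, ParameterDistributions, ReferenceBPTable, generate_cohort
from .io import save_cohort_hdf5, save_dataset_hdf5
from .metrics import DEFAULT_SNR_LIST, noise_sweep_report, sweep_table
from .model import ElastanceRegressor, save_checkpoint
from .preprocessing import (
    WaveformMatrix,
    fit_channel_scalers,
    make_channels,
    split_60_20_20,
)
from .solver import SolverSettings

logger = logging.getLogger("elastnet")

__all__ = ["PipelineConfig", "ToyPulse", "generate_toy_fixtures", "run_pipeline",
           "ensure_accepted_cohort", "preprocess_cohort"]


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run."""

    n_subjects: int = 10000
    min_accepted: Optional[int] = 2000
    cohort_seed: int = 1
    split_seed: int = 2
    init_seed: int = 3
    noise_seed: int = 4
    snr_list: tuple[float, ...] = DEFAULT_SNR_LIST
    solver: SolverSettings = field(default_factory=SolverSettings)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    distributions: ParameterDistributions = field(default_factory=ParameterDistributions)
    reference_bp: Optional[ReferenceBPTable] = None
    out_dir: Optional[str] = None
    models: tuple[str, ...] = ("cnn1", "cnn2")

    def config_hash(self) -> str:
        def default(o):
            if hasattr(o, "__dict__"):
                return o.__dict__
            if isinstance(o, (np.ndarray,)):
                return o.tolist()
            return str(o)

        blob = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class ToyPulse:
    """Parametric single-cycle pulse: raised-cosine upstroke to DBP + PP
    at t_peak, then exponential diastolic decay with time constant tau.

    The waveform minimum is exactly DBP (attained at t = 0) and the
    maximum is DBP + PP (at t_peak)."""

    DBP: float = 75.0
    PP: float = 45.0
    period: float = 0.9
    t_peak: float = 0.30
    tau: float = 0.35

    def waveform(self, n: int = 200) -> np.ndarray:
        t = np.arange(n) * self.period / n
        up = 0.5 * (1.0 - np.cos(np.pi * t / self.t_peak))
        down = np.exp(-(t - self.t_peak) / self.tau)
        return self.DBP + self.PP * np.where(t <= self.t_peak, up, down)

    @property
    def max_upstroke_slope(self) -> float:
        """Analytic maximum of the upstroke derivative, mmHg/s."""
        return self.PP * np.pi / (2.0 * self.t_peak)


def toy_label(pulse: ToyPulse) -> float:
    """Deterministic smooth function of (PP, max upstroke slope)."""
    return 0.4 + 0.03 * pulse.PP + 0.002 * pulse.max_upstroke_slope


def generate_toy_fixtures(
    n: int, seed: int = 0, noise_sd: float = 0.05
) -> tuple[WaveformMatrix, np.ndarray]:
    """n toy pulses (200 samples each) with labels = toy_label + noise."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    waves = np.empty((n, 200))
    periods = np.empty(n)
    labels = np.empty(n)
    for i in range(n):
        p = ToyPulse(
            DBP=rng.normal(75.0, 8.0),
            PP=float(np.clip(rng.normal(45.0, 10.0), 15.0, 80.0)),
            period=float(np.clip(rng.normal(0.9, 0.1), 0.6, 1.2)),
            t_peak=float(np.clip(rng.normal(0.30, 0.04), 0.15, 0.45)),
            tau=float(np.clip(rng.normal(0.35, 0.08), 0.15, 0.6)),
        )
        waves[i] = p.waveform()
        periods[i] = p.period
        labels[i] = toy_label(p) + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
    return WaveformMatrix(values=waves, periods=periods), labels


def ensure_accepted_cohort(
    min_accepted: int,
    seed: int,
    chunk: int = 2000,
    max_requested: int = 20000,
    dist: Optional[ParameterDistributions] = None,
    ref: Optional[ReferenceBPTable] = None,
    solver: Optional[SolverSettings] = None,
) -> Cohort:
    """Generate seeded chunks until at least ``min_accepted`` subjects pass.

    Chunks use seeds seed, seed+1, ... so the result is reproducible and
    extendable; subjects keep generation order.
    """
    subjects = []
    requested = 0
    accepted = 0
    k = 0
    while accepted < min_accepted:
        if requested >= max_requested:
            raise RuntimeError(
                f"only {accepted} accepted after {requested} requested "
                f"(acceptance rate too low for min_accepted={min_accepted})"
            )
        if requested == 0:
            n = chunk
        else:
            # size later chunks from the observed acceptance rate (+10%)
            rate = max(accepted / requested, 0.02)
            n = int(np.ceil((min_accepted - accepted) / rate * 1.1))
            n = max(200, n)
        n = min(n, max_requested - requested)
        c = generate_cohort(n, dist=dist, ref=ref, solver=solver, seed=seed + k)
        subjects.extend(c.subjects)
        requested += n
        accepted += c.n_accepted
        logger.info("cohort chunk %d: %d/%d accepted (total %d/%d)",
                    k, c.n_accepted, n, accepted, requested)
        k += 1
    return Cohort(subjects=subjects, seed=seed, n_requested=requested)


def preprocess_cohort(cohort: Cohort, mode: str, split_seed: int):
    """Split accepted subjects 60/20/20 and build normalized channels.

    Returns (X, y, split, scalers, raw_waves, periods)."""
    waves, periods = cohort.waveform_matrix("brachial")
    y = cohort.e_es_true()
    wm = WaveformMatrix(values=waves, periods=periods)
    split = split_60_20_20(wm.n, seed=split_seed)
    scalers = fit_channel_scalers(wm, split.train, mode)
    X = make_channels(wm, mode, scalers)
    return X, y, split, scalers, waves, periods


def reference_study(
    seed: int = 1,
    min_accepted: int = 2000,
    max_requested: int = 16000,
    max_epochs: int = 400,
    snr_list: tuple[float, ...] = DEFAULT_SNR_LIST,
    cohort: Optional[Cohort] = None,
) -> dict:
    """The full in silico study at its reference conditions.

    Generates a plausibility-filtered cohort of at least ``min_accepted``
    subjects, trains both regressors with the standard recipe (Adam,
    lr 1e-3, batch grid {32, 64, 128}, epochs tuned on validation), and
    evaluates clean + SNR-swept test performance. Stage seeds derive from
    ``seed``: cohort seed, split seed+1, init seed+2, noise seed+3.
    Returns {'cohort': ..., 'cnn1': {...}, 'cnn2': {...}} where each model
    entry carries the fitted results, the clean report, the sweep reports
    and the test-set absolute errors.
    """
    if cohort is None:
        cohort = ensure_accepted_cohort(
            min_accepted, seed, chunk=2500, max_requested=max_requested
        )
    out: dict = {"cohort": cohort, "seed": seed}
    for name, mode, arch in (
        ("cnn1", "one_channel", CNNArchitecture.cnn1()),
        ("cnn2", "two_channel", CNNArchitecture.cnn2()),
    ):
        X, y, split, scalers, raw, periods = preprocess_cohort(cohort, mode, seed + 1)
        cfg = TrainingConfig(max_epochs=max_epochs, seed=seed + 2)
        results = ElastanceRegressor.from_dataset(X, y, split, arch, cfg).fit()
        pred = results.predict(X[split.test])
        y_test = y[split.test]
        reports = noise_sweep_report(
            results, raw[split.test], periods[split.test], y_test,
            scalers, mode, snr_list=snr_list, seed=seed + 3,
        )
        out[name] = {
            "results": results,
            "reports": reports,
            "clean": reports["clean"],
            "pred": pred,
            "y_test": y_test,
            "abs_err": np.abs(pred - y_test),
        }
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full study; returns an in-memory bundle and writes files.

    The bundle maps model name -> {results, reports, scalers, ...} plus
    cohort-level entries; when ``config.out_dir`` is set the cohort
    table, waveform store, datasets, checkpoints and the sweep table are
    persisted there with seeds and the config hash embedded.
    """
    meta = {
        "config_hash": config.config_hash(),
        "version": version("elastnet"),
        "seeds": {
            "cohort": config.cohort_seed,
            "split": config.split_seed,
            "init": config.init_seed,
            "noise": config.noise_seed,
        },
    }
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        (out / "reports").mkdir(exist_ok=True)

    logger.info("stage=cohort requested=%s", config.n_subjects)
    if config.min_accepted:
        cohort = ensure_accepted_cohort(
            config.min_accepted, config.cohort_seed,
            chunk=min(config.n_subjects, 2000),
            max_requested=config.n_subjects,
            dist=config.distributions, ref=config.reference_bp, solver=config.solver,
        )
    else:
        cohort = generate_cohort(
            config.n_subjects, dist=config.distributions, ref=config.reference_bp,
            solver=config.solver, seed=config.cohort_seed,
        )
    logger.info("stage=cohort accepted=%d/%d", cohort.n_accepted, cohort.n_requested)
    for s in cohort.subjects:
        if not s.accepted:
            logger.debug("stage=cohort rejected reason=%s", s.reject_reason)

    bundle: dict = {"cohort": cohort, "meta": meta}
    if out:
        cohort.to_dataframe().assign(config_hash=meta["config_hash"]).to_csv(
            out / "cohort.csv", index=False
        )
        save_cohort_hdf5(cohort, str(out / "cohort.h5"), meta=meta)

    mode_of = {"cnn1": "one_channel", "cnn2": "two_channel"}
    arch_of = {"cnn1": CNNArchitecture.cnn1, "cnn2": CNNArchitecture.cnn2}
    reports_by_model = {}
    for name in config.models:
        mode = mode_of[name]
        X, y, split, scalers, raw, periods = preprocess_cohort(
            cohort, mode, config.split_seed
        )
        if out:
            save_dataset_hdf5(
                str(out / f"dataset_{name}.h5"), X, y, split, scalers,
                config.split_seed, meta=meta,
            )
        logger.info("stage=train model=%s n_train=%d", name, split.train.size)
        reg = ElastanceRegressor.from_dataset(
            X, y, split, arch_of[name](), config.training
        )
        results = reg.fit(seed=config.init_seed)
        logger.info(
            "stage=train model=%s batch_size=%d epochs=%d val_mse=%.5f",
            name, results.batch_size, results.epochs, results.val_mse,
        )
        reports = noise_sweep_report(
            results, raw[split.test], periods[split.test], y[split.test],
            scalers, mode, snr_list=config.snr_list, seed=config.noise_seed,
        )
        reports_by_model[name] = reports
        bundle[name] = {
            "results": results,
            "reports": reports,
            "scalers": scalers,
            "split": split,
            "X": X,
            "y": y,
            "raw_waves": raw,
            "periods": periods,
        }
        if out:
            save_checkpoint(results, str(out / f"model_{name}.ckpt.npz"))
            for cond, rep in reports.items():
                (out / "reports" / f"{name}_{cond}.json").write_text(rep.to_json())

    table = sweep_table(reports_by_model)
    table.insert(0, "config_hash", meta["config_hash"])
    bundle["table"] = table
    if out:
        table.to_csv(out / "table5.csv", index=False)
        (out / "run_meta.json").write_text(json.dumps(meta, indent=2))
    return bundle
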