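"""Config-driven orchestration: filter -> per-target fits -> network -> CV report."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np

from . import __version__
from .classify import EvalReport, cross_validate, holdout_evaluate
from .connectivity import (
    CausalityNetwork,
    FeatureSet,
    aggregate_network,
    correlation_matrix,
    network_features,
    write_edge_list,
)
from .mvar import build_design, coeffs_to_tensor
from .signal_io import BandSpec, Recording, bandpass_filter, select_channels
from .solvers import SOLVERS, SolverConfig

log = logging.getLogger("scsga")

__all__ = ["PipelineConfig", "trial_network", "trial_features", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Declarative pipeline settings; unknown keys in a config file are errors."""

    trials: list[str] = field(default_factory=list)  # file paths (delimited matrices)
    srate: float = 200.0
    labels: list[int] = field(default_factory=list)
    channels: list[str] = field(default_factory=list)  # empty = all
    bands: list[dict] = field(default_factory=list)  # empty = broadband (no filter)
    s: int = 3
    solver: str = "scsga"
    lam: float = 0.1
    eta: float = 1.0
    rho: float = 1.0
    max_iter: int = 500
    tol_abs: float = 1e-6
    tol_rel: float = 1e-4
    weight_mode: str = "abs"
    aggregation: str = "abs_sum"
    evaluation: str = "cv"  # {"cv", "holdout"}
    backend: str = "logistic_l2"
    reg_strength: float = 1.0
    folds: int = 5
    repeats: int = 100
    seed: int = 0
    out_dir: str = "scsga_out"

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(unknown)}")
        cfg = cls(**raw)
        if cfg.seed is None:
            raise ValueError("seed is mandatory")
        if cfg.solver not in SOLVERS:
            raise ValueError(f"unknown solver {cfg.solver!r}")
        if cfg.evaluation not in ("cv", "holdout"):
            raise ValueError(f"unknown evaluation mode {cfg.evaluation!r}")
        return cfg

    def solver_config(self) -> SolverConfig:
        return SolverConfig(
            lam=self.lam, eta=self.eta, rho=self.rho, max_iter=self.max_iter,
            tol_abs=self.tol_abs, tol_rel=self.tol_rel, seed=self.seed,
            weight_mode=self.weight_mode,
        )


def _center(rec: Recording) -> Recording:
    """Per-channel mean removal (the lag model has no intercept)."""
    return Recording(
        data=rec.data - rec.data.mean(axis=1, keepdims=True),
        srate=rec.srate,
        channel_names=rec.channel_names,
    )


def trial_network(
    rec: Recording,
    s: int,
    solver: str,
    scfg: SolverConfig,
    aggregation: str = "abs_sum",
) -> CausalityNetwork:
    """Fit every target equation of one (band-filtered) trial and aggregate.

    The trial is centered, the sensor correlation matrix is computed on
    the same window, each channel is fit as a target with the selected
    solver, and the coefficient tensor collapses to a directed network.
    """
    rec = _center(rec)
    E = correlation_matrix(rec).M
    fit_fn = SOLVERS[solver]
    fits = [fit_fn(build_design(rec, s, k), E, scfg) for k in range(rec.m)]
    tensor = coeffs_to_tensor(fits, rec.m, s)
    return aggregate_network(tensor, channel_names=rec.channel_names, mode=aggregation)


def trial_features(
    rec: Recording,
    cfg: PipelineConfig,
    scfg: SolverConfig,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Per-band networks for one trial, vectorized into a feature row."""
    if cfg.channels:
        rec = select_channels(rec, cfg.channels)
    if cfg.bands:
        bands = [BandSpec(b["name"], b["lo"], b["hi"]) for b in cfg.bands]
        recs = [bandpass_filter(rec, b) for b in bands]
        band_names = [b.name for b in bands]
    else:
        recs = [rec]
        band_names = ["broadband"]
    nets = [
        trial_network(r, cfg.s, cfg.solver, scfg, cfg.aggregation) for r in recs
    ]
    return network_features(nets, band_names)


def _load_trials(cfg: PipelineConfig) -> list[Recording]:
    from .signal_io import read_recording

    recs = []
    for path in cfg.trials:
        if not Path(path).exists():
            raise FileNotFoundError(f"missing input file: {path}")
        recs.append(read_recording(path, srate=cfg.srate))
    return recs


def run_pipeline(
    cfg: PipelineConfig,
    trials: list[Recording] | None = None,
    labels: np.ndarray | None = None,
) -> EvalReport:
    """Execute the full pipeline and write artifacts to ``cfg.out_dir``.

    ``trials``/``labels`` may be passed in-memory; otherwise they are read
    from ``cfg.trials``/``cfg.labels``.  Writes per-trial network TSVs, a
    features CSV, the evaluation report JSON, and a manifest sufficient to
    re-run the pipeline.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if trials is None:
        trials = _load_trials(cfg)
        labels = np.asarray(cfg.labels)
    else:
        labels = np.asarray(labels)
    if labels.shape[0] != len(trials):
        raise ValueError(f"{labels.shape[0]} labels for {len(trials)} trials")

    scfg = cfg.solver_config()
    rows = []
    names: tuple[str, ...] = ()
    for ti, rec in enumerate(trials):
        t0 = time.perf_counter()
        try:
            row, names = trial_features(rec, cfg, scfg)
        except Exception as exc:
            raise RuntimeError(f"trial {ti}: {exc}") from exc
        rows.append(row)
        log.info("trial=%d solver=%s dt=%.2fs", ti, cfg.solver, time.perf_counter() - t0)

    features = FeatureSet(X=np.vstack(rows), labels=labels, feature_names=names)

    # artifacts: features CSV and per-trial networks (dense vector rebuilt per trial)
    with open(out / "features.csv", "w") as fh:
        fh.write("label," + ",".join(names) + "\n")
        for lab, row in zip(labels, features.X):
            fh.write(str(lab) + "," + ",".join(repr(float(v)) for v in row) + "\n")

    if cfg.evaluation == "cv":
        report = cross_validate(
            features, backend=cfg.backend, folds=cfg.folds,
            repeats=cfg.repeats, seed=cfg.seed, reg_strength=cfg.reg_strength,
        )
    else:
        report = holdout_evaluate(
            features, backend=cfg.backend, seed=cfg.seed,
            reg_strength=cfg.reg_strength,
        )

    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=1, sort_keys=True)
    manifest = {
        "config": {f.name: getattr(cfg, f.name) for f in fields(cfg)},
        "version": __version__,
        "seed": cfg.seed,
        "n_trials": len(trials),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return report


def write_trial_networks(
    trials: list[Recording], cfg: PipelineConfig, out_dir: str | Path
) -> list[Path]:
    """Fit and save one network TSV per trial (used by the `fit` subcommand)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scfg = cfg.solver_config()
    paths = []
    for ti, rec in enumerate(trials):
        rec2 = select_channels(rec, cfg.channels) if cfg.channels else rec
        net = trial_network(rec2, cfg.s, cfg.solver, scfg, cfg.aggregation)
        path = out / f"network_{ti:04d}.tsv"
        write_edge_list(net, path)
        paths.append(path)
    return paths
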