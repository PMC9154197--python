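"""Experiment configuration, runners and result serialisation.

A single JSON or TOML config names an experiment and provides the model,
forcing and numerics blocks; ``run_experiment`` dispatches to the runner
and returns a ``ResultBundle`` of tables plus metadata (package version,
config hash, seed).  Deterministic runners reproduce their tables
bit-for-bit under identical config and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Dict, Optional

import numpy as np
import pandas as pd

from . import __version__
from .forcing import ForcingSpec, SquarePulse, VonMisesInput
from .meanfield import (LimitCycle, ModelParams, find_limit_cycle,
                        integral_mean_rates, ei_latency, integrate_trajectory)
from .phase import solve_adjoint

__all__ = [
    "ConfigError",
    "ExperimentConfig",
    "ResultBundle",
    "run_experiment",
    "write_results",
]

EXPERIMENTS = (
    "oscillation-characterization",
    "staircase",
    "tongue",
    "ctc-sweep",
    "competition",
    "switch-prc",
    "qif-validation",
)


class ConfigError(ValueError):
    """Invalid experiment configuration."""


def _check_keys(block: Dict[str, Any], allowed, where: str) -> None:
    unknown = set(block) - set(allowed)
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


def _model_from_dict(d: Dict[str, Any]) -> ModelParams:
    names = [f.name for f in fields(ModelParams)]
    _check_keys(d, names, "model block")
    try:
        return ModelParams(**d)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def _forcing_from_dict(d: Dict[str, Any]) -> ForcingSpec:
    _check_keys(d, ("inputs", "pulse", "drive_e", "drive_i"), "forcing block")
    inputs = []
    for blk in d.get("inputs", []):
        _check_keys(blk, ("A", "T", "kappa", "mu"), "forcing input")
        inputs.append(VonMisesInput(**blk))
    pulse = None
    if "pulse" in d and d["pulse"] is not None:
        _check_keys(d["pulse"], ("amplitude", "duration", "onset"), "pulse")
        pulse = SquarePulse(**d["pulse"])
    return ForcingSpec(inputs=tuple(inputs), pulse=pulse,
                       drive_e=d.get("drive_e", True),
                       drive_i=d.get("drive_i", True))


@dataclass
class ExperimentConfig:
    """Validated configuration of one experiment run."""

    experiment: str
    model: ModelParams = field(default_factory=ModelParams)
    forcing: ForcingSpec = field(default_factory=ForcingSpec)
    numerics: Dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    out: Optional[str] = None

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ConfigError(
                f"unknown experiment {self.experiment!r}; "
                f"available: {', '.join(EXPERIMENTS)}")

    @classmethod
    def from_dict(cls, d: Dict[str, Any]) -> "ExperimentConfig":
        _check_keys(d, ("experiment", "model", "forcing", "numerics",
                        "seed", "out"), "config")
        if "experiment" not in d:
            raise ConfigError("config must name an experiment")
        return cls(
            experiment=d["experiment"],
            model=_model_from_dict(d.get("model", {})),
            forcing=_forcing_from_dict(d.get("forcing", {})),
            numerics=dict(d.get("numerics", {})),
            seed=int(d.get("seed", 0)),
            out=d.get("out"),
        )

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix == ".toml":
            import tomllib

            data = tomllib.loads(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data)

    def canonical_dict(self) -> Dict[str, Any]:
        d = {
            "experiment": self.experiment,
            "model": asdict(self.model),
            "forcing": {
                "inputs": [asdict(i) for i in self.forcing.inputs],
                "pulse": asdict(self.forcing.pulse) if self.forcing.pulse else None,
                "drive_e": self.forcing.drive_e,
                "drive_i": self.forcing.drive_i,
            },
            "numerics": self.numerics,
            "seed": self.seed,
        }
        return d

    def hash(self) -> str:
        blob = json.dumps(self.canonical_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ResultBundle:
    """Tables plus provenance metadata for one experiment run."""

    tables: Dict[str, pd.DataFrame]
    metadata: Dict[str, Any]

    def table_hash(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.tables):
            h.update(name.encode())
            h.update(self.tables[name].to_csv(index=False).encode())
        return h.hexdigest()[:16]


# ----------------------------------------------------------------------
# runners
# ----------------------------------------------------------------------

def _cycle_and_iprc(cfg: ExperimentConfig):
    cycle = find_limit_cycle(cfg.model)
    if cycle is None:
        raise RuntimeError("model parameters give no limit cycle")
    return cycle, solve_adjoint(cycle)


def _run_characterize(cfg: ExperimentConfig) -> Dict[str, pd.DataFrame]:
    num = cfg.numerics
    values = num.get("Ie_values", list(np.arange(7.0, 15.0 + 0.5, 1.0)))
    rows = []
    for ie in values:
        cyc = find_limit_cycle(cfg.model.with_drives(Ie=float(ie)))
        if cyc is None:
            rows.append((ie, np.nan, np.nan, np.nan, np.nan, np.nan, False))
            continue
        re, ri = integral_mean_rates(cyc)
        lat, phase = ei_latency(cyc)
        rows.append((ie, 1000.0 / cyc.period, re, ri, lat, phase, True))
    df = pd.DataFrame(rows, columns=["Ie_ext_bar", "freq_Hz", "R_e", "R_i",
                                     "latency_ms", "relative_phase",
                                     "oscillating"])
    return {"characterization": df}


def _run_staircase(cfg: ExperimentConfig) -> Dict[str, pd.DataFrame]:
    from .locking import devils_staircase

    num = cfg.numerics
    cycle, iprc = _cycle_and_iprc(cfg)
    lo, hi, n = num.get("T_grid", (0.8, 1.2, 81))
    ratios = np.linspace(lo, hi, int(n))
    df = devils_staircase(iprc, num.get("A", 0.05), num.get("kappa", 2.0),
                          ratios)
    return {"staircase": df}


def _run_tongue(cfg: ExperimentConfig) -> Dict[str, pd.DataFrame]:
    from .locking import tongue_boundary_continuation

    num = cfg.numerics
    cycle, iprc = _cycle_and_iprc(cfg)
    tongue = tongue_boundary_continuation(
        int(num.get("p", 1)), int(num.get("q", 1)), iprc,
        num.get("kappa", 2.0), A_max=num.get("A_max", 0.2))
    rows = []
    for side, arr in (("left", tongue.left), ("right", tongue.right)):
        for T_over, A, theta in arr:
            rows.append((T_over, A, theta, side))
    df = pd.DataFrame(rows, columns=["T_over_Tstar", "A", "theta", "side"])
    return {"tongue": df}


def _run_ctc_sweep(cfg: ExperimentConfig) -> Dict[str, pd.DataFrame]:
    from .ctc import tongue_section_sweep

    num = cfg.numerics
    cycle, iprc = _cycle_and_iprc(cfg)
    A_values = num.get("A_values", [0.05, 0.1, 0.15, 0.2])
    df = tongue_section_sweep(int(num.get("p", 1)), int(num.get("q", 1)),
                              A_values, num.get("kappa", 2.0), cfg.model,
                              cycle, iprc, n_T=int(num.get("n_T", 10)))
    return {"ctc_factors": df}


def _run_competition(cfg: ExperimentConfig) -> Dict[str, pd.DataFrame]:
    from .competition import robustness_scan

    num = cfg.numerics
    cycle, iprc = _cycle_and_iprc(cfg)
    mode = num.get("mode", "unequal")
    df = robustness_scan(
        cycle, iprc, mode,
        kappa2_values=num.get("kappa2_values", [0.01, 0.1, 1.0, 10.0, 20.0]),
        ratio_values=num.get("ratio_values",
                             list(np.linspace(0.5, 1.5, 11))),
        T1_over_Tstar=num.get("T1_over_Tstar", 0.845),
        kappa1=num.get("kappa1", 2.0),
        A1=num.get("A1", 0.1), A2=num.get("A2", 0.1),
        n_iter=int(num.get("n_iter", 1000)),
        threshold=num.get("threshold", 0.8))
    return {"competition": df}


def _run_switch_prc(cfg: ExperimentConfig) -> Dict[str, pd.DataFrame]:
    from .competition import pulse_switch_prc

    num = cfg.numerics
    cycle, iprc = _cycle_and_iprc(cfg)
    grid = np.linspace(0.0, 1.0, int(num.get("phase_grid", 21)),
                       endpoint=False)
    results = pulse_switch_prc(cfg.model, cycle, iprc, phase_grid=grid,
                               kappa=num.get("kappa", 2.0),
                               A=num.get("A", 0.1),
                               T_over_Tstar=num.get("T_over_Tstar", 0.84))
    df = pd.DataFrame([asdict(r) for r in results])
    return {"switch_prc": df}


def _run_qif_validation(cfg: ExperimentConfig) -> Dict[str, pd.DataFrame]:
    from .qif import QIFParams, empirical_rate, simulate_qif

    num = cfg.numerics
    N = int(num.get("N", 2000))
    dt = float(num.get("dt", 5e-4))
    t_end = float(num.get("t_end", 80.0))
    qp = QIFParams(model=cfg.model, N_e=N, N_i=N,
                   eta_mode=num.get("eta_mode", "deterministic"),
                   seed=cfg.seed)
    raster, _ = simulate_qif(qp, cfg.forcing, t_end=t_end, dt=dt)
    rate_e = empirical_rate(raster, population="e")
    rate_i = empirical_rate(raster, population="i")
    traj = integrate_trajectory(np.array([0.05, -1.0, 0, 0, 0.05, -1.0, 0, 0]),
                                (0.0, t_end), cfg.model, cfg.forcing,
                                n_samples=len(rate_e.t))
    df = pd.DataFrame({
        "t": rate_e.t,
        "qif_r_e": rate_e.rate,
        "qif_r_i": rate_i.rate,
        "mf_r_e": np.interp(rate_e.t, traj.t, traj["r_e"]),
        "mf_r_i": np.interp(rate_i.t, traj.t, traj["r_i"]),
    })
    rmse = float(np.sqrt(np.mean((df.qif_r_e - df.mf_r_e) ** 2)))
    summary = pd.DataFrame({"rmse_r_e": [rmse],
                            "peak_r_e": [float(df.mf_r_e.max())]})
    return {"rates": df, "summary": summary}


_RUNNERS = {
    "oscillation-characterization": _run_characterize,
    "staircase": _run_staircase,
    "tongue": _run_tongue,
    "ctc-sweep": _run_ctc_sweep,
    "competition": _run_competition,
    "switch-prc": _run_switch_prc,
    "qif-validation": _run_qif_validation,
}


def run_experiment(config: ExperimentConfig) -> ResultBundle:
    """Dispatch to the named runner and wrap its tables with metadata."""
    runner = _RUNNERS.get(config.experiment)
    if runner is None:
        raise ConfigError(
            f"unknown experiment {config.experiment!r}; "
            f"available: {', '.join(EXPERIMENTS)}")
    np.random.seed(config.seed % (2 ** 31))
    tables = runner(config)
    meta = {
        "package": "pingctc",
        "version": __version__,
        "experiment": config.experiment,
        "config_hash": config.hash(),
        "seed": config.seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    return ResultBundle(tables=tables, metadata=meta)


def write_results(bundle: ResultBundle, outdir) -> Dict[str, Path]:
    """Write each table as CSV plus a JSON metadata sidecar; returns the
    paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: Dict[str, Path] = {}
    for name, df in bundle.tables.items():
        p = outdir / f"{name}.csv"
        try:
            df.to_csv(p, index=False)
        except OSError as exc:
            raise OSError(f"could not write table to {p}: {exc}") from exc
        written[name] = p
    meta_path = outdir / "metadata.json"
    meta = dict(bundle.metadata)
    meta["table_hash"] = bundle.table_hash()
    meta_path.write_text(json.dumps(meta, indent=2))
    written["metadata"] = meta_path
    return written
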