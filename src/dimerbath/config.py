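"""Run configuration, named presets and the simulate/analyze dispatch.

A :class:`RunConfig` is a flat record of the model choice and every physical
and numerical parameter; presets freeze the parameter sets used for the
reference experiments (short-range collisional baths at r0 = 0.08, mu = 1e3,
gamma = 10, D = 1, k = 1e6; oscillator baths at omega_bar = 100, m = 1e-3).
Configs load from YAML/JSON files with a ``preset`` inheritance key; CLI
flags override file values. Every run is reproducible from its config and
seed, both of which are embedded in the output report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path
from typing import Optional

from . import _kernels
from .errors import ConfigurationError
from .model_core import LangevinParams, SpringParams, simulate_langevin_dimer
from .samplers import ShortRangeBathParams

log = logging.getLogger("dimerbath")

MODELS = ("langevin", "short_range", "short_mixed", "long_range",
          "long_mixed")


@dataclasses.dataclass
class RunConfig:
    model: str = "langevin"
    mode: Optional[str] = None      # one_bath/two_bath (short), two_bath/shared/split (long)
    integrator: str = "euler_maruyama"   # langevin model only
    # physical parameters (dimensionless units)
    M: float = 1.0
    D: float = 1.0
    gamma: float = 10.0
    k: float = 1e6
    ell0: float = 0.32
    r0: float = 0.08
    mu: float = 1e3
    L: float = 0.32
    m: float = 1e-3
    omega_bar: float = 100.0
    N1: int = 10000
    N2: int = 10000
    # numerics
    dt: float = 1e-6
    tmax: float = 1.0
    sample_interval: float = 1e-3
    burn_in: Optional[float] = None
    seed: int = 0
    out: Optional[str] = None
    preset: Optional[str] = None

    @property
    def spring(self) -> SpringParams:
        return SpringParams(k=self.k, ell0=self.ell0)

    @property
    def langevin(self) -> LangevinParams:
        return LangevinParams(M=self.M, D=self.D, gamma=self.gamma)

    @property
    def bath(self) -> ShortRangeBathParams:
        return ShortRangeBathParams(r0=self.r0, mu=self.mu, gamma=self.gamma,
                                    D=self.D)

    def effective_burn_in(self) -> float:
        return 0.5 * self.tmax if self.burn_in is None else self.burn_in


PRESETS: dict[str, dict] = {
    # short-range collisional bath, one frame around the dimer
    "fig3_one_bath": dict(model="short_range", mode="one_bath", r0=0.08,
                          gamma=10.0, D=1.0, mu=1e3, k=1e6, ell0=0.32,
                          L=0.72, dt=1e-6, tmax=100.0),
    # short-range, one frame per monomer
    "fig3_two_bath": dict(model="short_range", mode="two_bath", r0=0.08,
                          gamma=10.0, D=1.0, mu=1e3, k=1e6, ell0=0.32,
                          L=0.32, dt=1e-6, tmax=100.0),
    # mixed resolution: monomer 1 in explicit solvent, monomer 2 Langevin
    "fig4_mixed": dict(model="short_mixed", r0=0.08, gamma=10.0, D=1.0,
                       mu=1e3, k=1e6, ell0=0.32, L=0.32, dt=1e-6,
                       tmax=500.0),
    # oscillator baths
    "fig5_two_bath": dict(model="long_range", mode="two_bath",
                          omega_bar=100.0, N1=10000, N2=10000, m=1e-3, M=1.0,
                          gamma=10.0, D=1.0, k=1e6, ell0=0.32, dt=1e-5,
                          tmax=200.0),
    "fig5_shared": dict(model="long_range", mode="shared", omega_bar=100.0,
                        N1=10000, N2=10000, m=1e-3, M=1.0, gamma=10.0, D=1.0,
                        k=1e6, ell0=0.32, dt=1e-5, tmax=200.0),
    "fig5_split": dict(model="long_range", mode="split", omega_bar=100.0,
                       N1=5000, N2=5000, m=1e-3, M=1.0, gamma=10.0, D=1.0,
                       k=1e6, ell0=0.32, dt=1e-5, tmax=200.0),
    # mixed resolution with the oscillator bath on monomer 1
    "fig6_mixed": dict(model="long_mixed", omega_bar=100.0, N1=100000,
                       m=1e-3, M=1.0, gamma=10.0, D=1.0, k=1e6, ell0=0.32,
                       dt=1e-5, tmax=1000.0),
    # macroscopic Langevin benchmark (BBK handles the stiff spring at this dt)
    "langevin_ref": dict(model="langevin", integrator="bbk", gamma=10.0,
                         D=1.0, k=1e6, ell0=0.32, M=1.0, dt=1e-4,
                         tmax=200.0),
}


def validate(cfg: RunConfig) -> RunConfig:
    if cfg.model not in MODELS:
        raise ConfigurationError(f"unknown model {cfg.model!r}")
    if cfg.dt <= 0 or cfg.tmax <= 0:
        raise ConfigurationError("dt and tmax must be positive")
    if cfg.dt * cfg.gamma >= 1.0:
        raise ConfigurationError("dt*gamma >= 1: unstable step")
    if cfg.model in ("short_range", "short_mixed"):
        if cfg.L <= 2.0 * cfg.r0:
            raise ConfigurationError(
                f"constraint L > 2*r0 violated (L={cfg.L}, r0={cfg.r0})")
        if cfg.model == "short_range" and cfg.mode not in ("one_bath",
                                                           "two_bath"):
            raise ConfigurationError(
                "short_range model needs mode one_bath or two_bath")
        if cfg.mode == "one_bath" and cfg.L < cfg.ell0 + 2.0 * cfg.r0:
            raise ConfigurationError(
                "one-bath frame must enclose the dimer: L >= ell0 + 2*r0")
        p0 = _kernels._influx_probability(
            cfg.bath.lambda_mu, cfg.bath.sigma_mu, cfg.L, cfg.dt, 0.0)
        if 6.0 * p0 > 0.5:
            raise ConfigurationError(
                f"constraint 6*p_in <= 0.5 violated (6*p_in = {6 * p0:.3g}); "
                "reduce dt")
        if 6.0 * p0 > 0.1:
            warnings.warn(
                f"6*p_in = {6 * p0:.3g} > 0.1: simultaneous boundary "
                "entries are neglected a few percent of the time",
                stacklevel=2)
    if cfg.model in ("long_range", "long_mixed"):
        if cfg.model == "long_range" and cfg.mode not in ("two_bath",
                                                          "shared", "split"):
            raise ConfigurationError(
                "long_range model needs mode two_bath, shared or split")
        if cfg.dt * cfg.omega_bar > 0.1:
            raise ConfigurationError(
                "constraint dt*omega_bar <= 0.1 violated; reduce dt")
    return cfg


def load_config(source, **overrides) -> RunConfig:
    """Build a validated RunConfig from a preset name, a YAML/JSON file, or
    a plain dict; keyword overrides win."""
    data: dict = {}
    if isinstance(source, RunConfig):
        data = dataclasses.asdict(source)
    elif isinstance(source, dict):
        data = dict(source)
    elif source is not None:
        name = str(source)
        if name in PRESETS:
            data = dict(PRESETS[name], preset=name)
        else:
            path = Path(name)
            if not path.exists():
                raise ConfigurationError(
                    f"{name!r} is neither a preset nor a config file; "
                    f"presets: {sorted(PRESETS)}")
            if path.suffix in (".yaml", ".yml"):
                import yaml

                data = yaml.safe_load(path.read_text()) or {}
            else:
                data = json.loads(path.read_text())
    base = data.pop("preset", None)
    if base is not None and base in PRESETS:
        merged = dict(PRESETS[base])
        merged.update(data)
        data = merged
        data["preset"] = base
    data.update({k: v for k, v in overrides.items() if v is not None})
    fields = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return validate(RunConfig(**data))


def run(cfg: RunConfig) -> dict:
    """Dispatch a configured run; write trajectory, JSON report and log.

    Returns the report dict (which includes the output paths when
    ``cfg.out`` is set).
    """
    from .estimators import (diffusion_from_trajectory, estimate_mean_length)

    validate(cfg)
    log.info("run model=%s mode=%s seed=%d tmax=%g dt=%g",
             cfg.model, cfg.mode, cfg.seed, cfg.tmax, cfg.dt)
    if cfg.model == "langevin":
        traj = simulate_langevin_dimer(
            cfg.spring, cfg.langevin, cfg.tmax, cfg.dt, seed=cfg.seed,
            integrator=cfg.integrator, sample_interval=cfg.sample_interval)
    elif cfg.model in ("short_range", "short_mixed"):
        from .short_range_bath import simulate_short_range

        mode = "mixed" if cfg.model == "short_mixed" else cfg.mode
        traj = simulate_short_range(
            mode, cfg.spring, cfg.bath, cfg.tmax, cfg.dt, cfg.L,
            seed=cfg.seed, M=cfg.M, sample_interval=cfg.sample_interval)
    else:
        from .long_range_bath import simulate_long_range

        mode = "mixed" if cfg.model == "long_mixed" else cfg.mode
        N = cfg.N1 if mode in ("shared", "mixed") else (cfg.N1, cfg.N2)
        traj = simulate_long_range(
            cfg.spring, cfg.langevin, cfg.omega_bar, N, cfg.m, mode,
            cfg.tmax, dt=cfg.dt, seed=cfg.seed,
            sample_interval=cfg.sample_interval)

    burn = cfg.effective_burn_in()
    res = estimate_mean_length(traj, burn_in=burn)
    report = {
        "config": {k: v for k, v in dataclasses.asdict(cfg).items()
                   if v is not None},
        "seed": cfg.seed,
        "L_d": {"value": res.value, "ci_low": res.ci_low,
                "ci_high": res.ci_high, "confidence": res.confidence},
        "n_samples": len(traj),
    }
    try:
        dd, se = diffusion_from_trajectory(traj, upper=1.0, burn_in=burn)
        report["D_d"] = {"value": dd, "se": se, "upper": 1.0}
    except ValueError:
        log.warning("trajectory too short for a VACF diffusion estimate")
    if "counters" in traj.metadata:
        report["counters"] = traj.metadata["counters"]
    if cfg.out:
        out = Path(cfg.out)
        traj.save(out)
        rpath = out.with_suffix(".report.json")
        rpath.write_text(json.dumps(report, indent=2))
        report["trajectory_path"] = str(out)
        report["report_path"] = str(rpath)
        log.info("wrote %s and %s", out, rpath)
    return report
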