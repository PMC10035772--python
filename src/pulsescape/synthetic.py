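"""In-silico pulse-escape experiments.

Generates raw per-axon traces with the statistical structure of the real
assay — biphasic escape kinetics from the six-state model, shot noise
from a finite filament count, per-exposure photobleaching, dark-state
recovery of the post-activation frame, multiplicative measurement noise,
axon-to-axon kinetic variability, and an optional permanently stationary
subpopulation — so the whole analysis chain can be exercised without any
microscopy data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .curves import DecayCurve, RawTrace
from .forward import SimulationConfig, simulate_pulse_escape
from .params import (
    DEFAULT_GEOMETRY,
    DEFAULT_MOTILITY,
    PULSE_ESCAPE_SCHEDULE_MIN,
    TIBIAL_NERVE_RATES,
    MotilityParams,
    RateConstants,
    WindowGeometry,
)

__all__ = ["GeneratorConfig", "generate_pulse_escape_dataset", "generate_bleach_series",
           "write_dataset", "DEFAULT_K_BLEACH"]

#: Per-exposure bleach rate giving a 13% decline over 11 exposures.
DEFAULT_K_BLEACH = math.log(1.0 / 0.87) / 11.0


@dataclass
class GeneratorConfig:
    """Study conditions of the emulated experiment.

    Defaults reproduce the adult-tibial-nerve regime: 48 axons imaged at
    the standard schedule, rate constants extracted from that preparation,
    a bleach rate giving 13% fade over the 11 timed exposures, and a 15%
    dark-state recovery between the post-activation and 1-minute frames.
    ``stationary_fraction`` pins that fraction of filaments outside the
    state chain entirely (the literal stationary-network hypothesis);
    ``axon_variability_cv`` applies one shared log-normal multiplier
    (mean 1) to the four identifiable rates per axon, which rescales each
    axon's kinetic clock without changing its occupancies.
    """

    rates: RateConstants = TIBIAL_NERVE_RATES
    motility: MotilityParams = DEFAULT_MOTILITY
    geom: WindowGeometry = DEFAULT_GEOMETRY
    n_axons: int = 48
    nf_per_axon: int = 500
    noise_cv: float = 0.03
    k_bleach: float = DEFAULT_K_BLEACH
    dark_state_recovery: float = 0.15
    stationary_fraction: float = 0.0
    axon_variability_cv: float = 0.2
    schedule_min: tuple = PULSE_ESCAPE_SCHEDULE_MIN
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("noise_cv", "dark_state_recovery", "stationary_fraction",
                     "axon_variability_cv"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
        if self.k_bleach < 0:
            raise ValueError("k_bleach must be >= 0")
        if self.n_axons < 1 or self.nf_per_axon < 1:
            raise ValueError("n_axons and nf_per_axon must be >= 1")

    def to_dict(self) -> dict:
        return {
            "rates": self.rates.to_dict(),
            "motility": self.motility.to_dict(),
            "geometry": self.geom.to_dict(),
            "n_axons": self.n_axons,
            "nf_per_axon": self.nf_per_axon,
            "noise_cv": self.noise_cv,
            "k_bleach": self.k_bleach,
            "dark_state_recovery": self.dark_state_recovery,
            "stationary_fraction": self.stationary_fraction,
            "axon_variability_cv": self.axon_variability_cv,
            "schedule_min": list(self.schedule_min),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorConfig":
        kwargs = dict(data)
        if "rates" in kwargs:
            kwargs["rates"] = RateConstants.from_dict(kwargs["rates"])
        if "motility" in kwargs:
            kwargs["motility"] = MotilityParams.from_dict(kwargs["motility"])
        if "geometry" in kwargs:
            kwargs["geom"] = WindowGeometry.from_dict(kwargs.pop("geometry"))
        if "schedule_min" in kwargs:
            kwargs["schedule_min"] = tuple(kwargs["schedule_min"])
        return cls(**kwargs)


def _lognormal_mean_one(rng: np.random.Generator, cv: float, size=None):
    """Log-normal multiplier with mean 1 and the given coefficient of variation."""
    if cv == 0.0:
        return np.ones(size) if size is not None else 1.0
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


def generate_pulse_escape_dataset(cfg: GeneratorConfig) -> list:
    """Simulate raw traces for ``cfg.n_axons`` axons; seeded, reproducible.

    Frame sequence per axon: ``pre`` (exposure 0, residual unactivated
    fluorescence), ``post`` (exposure 1, t = 0, attenuated by the
    dark-state deficit), then the timed frames of the schedule (exposures
    2, 3, ...).  Window occupancy comes from the event-driven simulation
    of ``nf_per_axon`` filaments (minus the pinned stationary ones, which
    contribute a constant), multiplied by the bleach factor ``exp(-k n)``
    and log-normal measurement noise.
    """
    rng = np.random.default_rng(cfg.seed)
    schedule_s = np.array([60.0 * m for m in cfg.schedule_min])
    sample_times = np.concatenate([[0.0], schedule_s])
    traces = []
    for _ in range(cfg.n_axons):
        axon_seed = int(rng.integers(0, 2**31 - 1))
        mult = float(_lognormal_mean_one(rng, cfg.axon_variability_cv))
        rates = RateConstants(
            gamma01=cfg.rates.gamma01 * mult,
            gamma10=cfg.rates.gamma10 * mult,
            gamma_on=cfg.rates.gamma_on * mult,
            gamma_off=cfg.rates.gamma_off * mult,
            gamma_ar=cfg.rates.gamma_ar * mult,
            gamma_ra=cfg.rates.gamma_ra * mult,
        )
        n_stationary = int(rng.binomial(cfg.nf_per_axon, cfg.stationary_fraction))
        n_mobile = cfg.nf_per_axon - n_stationary
        if n_mobile > 0:
            sim_cfg = SimulationConfig(
                n_filaments=n_mobile,
                duration=float(sample_times[-1]),
                sample_times=tuple(sample_times),
                seed=axon_seed,
                solver="monte_carlo",
            )
            mc = simulate_pulse_escape(rates, cfg.motility, cfg.geom, sim_cfg)
            counts = mc.values * n_mobile
        else:
            counts = np.zeros(sample_times.size)
        occupancy = (counts + n_stationary) / cfg.nf_per_axon

        labels = ["pre", "post"] + [f"{m:g}" for m in cfg.schedule_min]
        times = np.concatenate([[np.nan, 0.0], schedule_s])
        exposures = np.arange(len(labels), dtype=float)
        intensity = np.empty(len(labels))
        scale = float(cfg.nf_per_axon)
        intensity[0] = 0.05 * scale  # residual pre-activation fluorescence
        signal = np.concatenate([[occupancy[0] / (1.0 + cfg.dark_state_recovery)],
                                 occupancy[1:]])
        intensity[1:] = scale * signal * np.exp(-cfg.k_bleach * exposures[1:])
        noise = _lognormal_mean_one(rng, cfg.noise_cv, size=len(labels))
        traces.append(RawTrace(labels, times, intensity * noise, exposures))
    return traces


def generate_bleach_series(cfg: GeneratorConfig, n_exposures: int = 11,
                           n_axons: int = 46) -> list:
    """Transport-free calibration series: constant occupancy, bleach + noise.

    Emulates imaging the centre of a large activated region where
    transport cannot change the window content.  Returns one
    ``DecayCurve`` per axon whose ``times`` axis is the exposure count
    0..n_exposures (inclusive, so ``n_exposures`` bleaching intervals).
    """
    if n_exposures < 2:
        raise ValueError("need at least 2 exposures to calibrate bleaching")
    rng = np.random.default_rng(cfg.seed + 1)
    n = np.arange(n_exposures + 1, dtype=float)
    out = []
    for _ in range(n_axons):
        brightness = float(_lognormal_mean_one(rng, 0.2))
        noise = _lognormal_mean_one(rng, cfg.noise_cv, size=n.size)
        out.append(DecayCurve(n, brightness * np.exp(-cfg.k_bleach * n) * noise))
    return out


def write_dataset(cfg: GeneratorConfig, out_dir: str | Path) -> Path:
    """Write traces/, bleach/ and manifest.json for exact re-generation."""
    out = Path(out_dir)
    (out / "traces").mkdir(parents=True, exist_ok=True)
    (out / "bleach").mkdir(parents=True, exist_ok=True)
    for i, trace in enumerate(generate_pulse_escape_dataset(cfg)):
        trace.to_csv(out / "traces" / f"axon_{i:03d}.csv")
    for i, series in enumerate(generate_bleach_series(cfg)):
        series.to_csv(out / "bleach" / f"axon_{i:03d}.csv")
    (out / "manifest.json").write_text(json.dumps(cfg.to_dict(), indent=2) + "\n")
    return out
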