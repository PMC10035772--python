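"""Parameter containers for the six-state stop-and-go transport model.

The model describes axonal neurofilament transport as a continuous-time
Markov chain over six states: moving anterogradely (``a``) or retrogradely
(``r``), pausing on-track (``a0``, ``r0``) and pausing off-track (``ap``,
``rp``).  Moving filaments advect at the bout velocity of their direction;
pausing filaments are immobile.  Four rate constants are identifiable from
pulse-escape kinetics (mobilisation ``gamma01``, pausing ``gamma10``,
on-tracking ``gamma_on`` and off-tracking ``gamma_off``); the reversal
rates ``gamma_ar``/``gamma_ra`` only set the directional split, which the
direction-blind pulse-escape observables cannot constrain.

Units are seconds and micrometres throughout; reporting-level conversions
(minutes, mm/day) happen only in :mod:`pulsescape.kinetics`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "RateConstants",
    "MotilityParams",
    "WindowGeometry",
    "StateDistribution",
    "KineticSummary",
    "TIBIAL_NERVE_RATES",
    "DEFAULT_MOTILITY",
    "DEFAULT_GEOMETRY",
    "PULSE_ESCAPE_SCHEDULE_MIN",
    "load_config",
    "dump_config",
]

#: Imaging schedule of a pulse-escape experiment, minutes post-activation.
PULSE_ESCAPE_SCHEDULE_MIN = (1.0, 2.5, 5.0, 10.0, 15.0, 30.0, 60.0, 90.0, 120.0, 150.0, 180.0)

#: 1 um/s expressed in mm/day (86400 s/day x 1e-3 mm/um).
UM_PER_S_TO_MM_PER_DAY = 86.4


@dataclass(frozen=True)
class RateConstants:
    """Transition rates of the six-state model, all in 1/s.

    Parameters
    ----------
    gamma01 : float
        On-track pause -> moving (mobilisation within the on-track cycle).
    gamma10 : float
        Moving -> on-track pause (end of a movement bout).
    gamma_on : float
        Off-track pause -> on-track pause (re-engagement with the track).
    gamma_off : float
        On-track pause -> off-track pause.
    gamma_ar, gamma_ra : float
        Directional reversal rates (anterograde -> retrograde and back),
        acting from the pausing states only.  Default zero: on the
        pulse-escape timescale bout direction is persistent, and the
        observables are blind to direction in any case.
    """

    gamma01: float
    gamma10: float
    gamma_on: float
    gamma_off: float
    gamma_ar: float = 0.0
    gamma_ra: float = 0.0

    def __post_init__(self) -> None:
        for name in ("gamma01", "gamma10", "gamma_on", "gamma_off", "gamma_ar", "gamma_ra"):
            value = getattr(self, name)
            if not (value >= 0.0):
                raise ValueError(f"rate constant {name} must be >= 0, got {value!r}")

    def require_positive(self, *names: str) -> None:
        """Raise ``ValueError`` naming any of *names* that is not > 0."""
        for name in names:
            if getattr(self, name) <= 0.0:
                raise ValueError(f"rate constant {name} must be > 0 for this computation")

    @property
    def reversal_ratio(self) -> float:
        """gamma_ra / gamma_ar, the anterograde:retrograde balance knob."""
        if self.gamma_ar == 0.0:
            raise ValueError("reversal_ratio undefined when gamma_ar = 0")
        return self.gamma_ra / self.gamma_ar

    def scaled(self, factor: float) -> "RateConstants":
        """All six rates multiplied by *factor* (a pure clock rescaling)."""
        return RateConstants(*(factor * getattr(self, f) for f in (
            "gamma01", "gamma10", "gamma_on", "gamma_off", "gamma_ar", "gamma_ra")))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RateConstants":
        known = {f: data[f] for f in ("gamma01", "gamma10", "gamma_on", "gamma_off") }
        for opt in ("gamma_ar", "gamma_ra"):
            if opt in data:
                known[opt] = data[opt]
        return cls(**known)


@dataclass(frozen=True)
class MotilityParams:
    """Bout velocities and the anterograde/retrograde split of moving time.

    ``v_a`` and ``v_r`` are the on-track bout velocities in um/s (``v_r``
    non-positive; zero speeds model metabolically arrested transport);
    ``p_dir_a`` is the fraction of moving filaments moving anterogradely,
    measured by the pulse-spread companion method.
    """

    v_a: float = 0.5
    v_r: float = -0.5
    p_dir_a: float = 0.6

    def __post_init__(self) -> None:
        if not self.v_a >= 0:
            raise ValueError(f"v_a must be >= 0 (anterograde), got {self.v_a!r}")
        if not self.v_r <= 0:
            raise ValueError(f"v_r must be <= 0 (retrograde), got {self.v_r!r}")
        if not 0.0 <= self.p_dir_a <= 1.0:
            raise ValueError(f"p_dir_a must lie in [0, 1], got {self.p_dir_a!r}")

    @property
    def p_dir_r(self) -> float:
        return 1.0 - self.p_dir_a

    @property
    def mean_bout_speed(self) -> float:
        """Direction-weighted mean speed |v| of a moving filament, um/s."""
        return self.p_dir_a * self.v_a + self.p_dir_r * (-self.v_r)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "MotilityParams":
        return cls(**{k: data[k] for k in ("v_a", "v_r", "p_dir_a") if k in data})


@dataclass(frozen=True)
class WindowGeometry:
    """Activation-window extent and the simulated axon domain around it.

    The window spans ``[0, window_length]``; the simulated domain extends
    ``domain_margin`` beyond each edge with absorbing far boundaries.  The
    default margin (10x the window) keeps boundary losses negligible over
    12 h at physiological rates.
    """

    window_length: float = 5.0
    domain_margin: float = 50.0

    def __post_init__(self) -> None:
        if not self.window_length > 0:
            raise ValueError("window_length must be > 0")
        if not self.domain_margin >= 0:
            raise ValueError("domain_margin must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "WindowGeometry":
        return cls(**{k: data[k] for k in ("window_length", "domain_margin") if k in data})


@dataclass(frozen=True)
class StateDistribution:
    """Occupancies of the aggregated chain plus optional directional split.

    ``f_moving + f_pause_on + f_pause_off == 1``.  The six-entry
    directional form (``a, r, a0, r0, ap, rp``) is populated on demand and
    each directional pair sums to its aggregate.
    """

    f_moving: float
    f_pause_on: float
    f_pause_off: float
    directional: tuple | None = None  # (a, r, a0, r0, ap, rp)

    def as_array(self):
        import numpy as np

        return np.array([self.f_moving, self.f_pause_on, self.f_pause_off])

    def directional_array(self):
        import numpy as np

        if self.directional is None:
            raise ValueError("directional split not populated")
        return np.array(self.directional)


@dataclass(frozen=True)
class KineticSummary:
    """Derived transport summaries at reporting units.

    Percentages are on 0-100 scale; pauses in minutes, bouts in seconds,
    net velocity in mm/day.
    """

    pct_time_off_track: float
    pct_time_on_track: float
    mean_off_track_pause: float
    mean_on_track_pause: float
    pct_time_moving: float
    mean_bout_duration: float
    p_a: float
    p_r: float
    net_velocity: float

    def to_dict(self) -> dict:
        return asdict(self)


#: Rate constants extracted from adult mouse tibial nerve pulse-escape data.
TIBIAL_NERVE_RATES = RateConstants(
    gamma01=3.72e-3, gamma10=2.01e-1, gamma_on=1.34e-4, gamma_off=2.21e-4
)

DEFAULT_MOTILITY = MotilityParams()
DEFAULT_GEOMETRY = WindowGeometry()


def load_config(path: str | Path) -> dict:
    """Read a flat JSON/YAML config into parameter objects.

    Recognised keys are the gamma symbols plus ``v_a``, ``v_r``,
    ``p_dir_a``, ``window_length`` and ``domain_margin``; they may appear
    at top level or under ``rates`` / ``motility`` / ``geometry`` blocks.
    Returns a dict with ``rates``, ``motility`` and ``geometry`` entries.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} does not contain a mapping")
    flat = dict(data)
    for block in ("rates", "motility", "geometry", "generator"):
        if isinstance(data.get(block), dict):
            flat.update(data[block])
    out = {}
    if any(k in flat for k in ("gamma01", "gamma10", "gamma_on", "gamma_off")):
        out["rates"] = RateConstants.from_dict(flat)
    out["motility"] = MotilityParams.from_dict(flat)
    out["geometry"] = WindowGeometry.from_dict(flat)
    out["raw"] = data
    return out


def dump_config(path: str | Path, rates: RateConstants | None = None,
                motility: MotilityParams | None = None,
                geometry: WindowGeometry | None = None,
                extra: dict | None = None) -> None:
    """Serialise parameter objects to a flat JSON/YAML config block."""
    path = Path(path)
    flat: dict = {}
    for obj in (rates, motility, geometry):
        if obj is not None:
            flat.update(obj.to_dict())
    if extra:
        flat.update(extra)
    if path.suffix == ".json":
        path.write_text(json.dumps(flat, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(flat, sort_keys=False))
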