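"""Forward models of the pulse-escape experiment.

Two independent routes compute the fluorescence remaining in the
activation window as tagged filaments transport out of it:

* :func:`expected_decay` — a deterministic solver for the spatial
  advection–reaction master equation of the six state densities on a 1-D
  grid, using Strang splitting with an exact (matrix-exponential) reaction
  substep and upwind advection.  With the default time step the Courant
  number is exactly 1 and advection is exact, so the scheme has no
  numerical diffusion.
* :func:`simulate_pulse_escape` — an event-driven stochastic simulation of
  individual filaments with competing exponential clocks (no time
  discretisation of dwell times).

Both start from filaments distributed uniformly in the window with states
drawn from the stationary distribution of the state chain: the fast decay
phase is carried by filaments that happen to be on-track at activation.

:func:`modal_decay` solves the same master equation restricted to the
window (plus a re-entry margin when reversals are enabled) by dense
eigendecomposition; it returns the whole curve for microseconds per time
point and powers the inverse procedure in :mod:`pulsescape.extraction`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .curves import DecayCurve
from .kinetics import reaction_matrix
from .params import (
    PULSE_ESCAPE_SCHEDULE_MIN,
    MotilityParams,
    RateConstants,
    WindowGeometry,
)

__all__ = [
    "SimulationConfig",
    "expected_decay",
    "simulate_pulse_escape",
    "modal_decay",
    "long_term_decay_constant",
    "initial_slope",
    "initial_slope_analytic",
]

_DEFAULT_SAMPLES_S = tuple(60.0 * m for m in PULSE_ESCAPE_SCHEDULE_MIN)


@dataclass
class SimulationConfig:
    """Run-level knobs shared by the two solvers.

    ``sample_times`` are seconds post-activation, strictly increasing and
    within ``[0, duration]``.  ``grid_spacing``/``time_step`` apply to the
    grid solver only; the default time step is ``grid_spacing / max|v|``
    which makes advection exact.
    """

    n_filaments: int = 50_000
    duration: float = 10_800.0
    sample_times: tuple = _DEFAULT_SAMPLES_S
    seed: int = 0
    solver: str = "grid"
    grid_spacing: float = 0.25
    time_step: float | None = None

    def __post_init__(self) -> None:
        st = np.asarray(self.sample_times, dtype=float)
        if st.size == 0:
            raise ValueError("sample_times must not be empty")
        if np.any(np.diff(st) <= 0):
            raise ValueError("sample_times must be strictly increasing")
        if st[0] < 0 or st[-1] > self.duration + 1e-9:
            raise ValueError("sample_times must lie within [0, duration]")
        if self.n_filaments < 1:
            raise ValueError("n_filaments must be >= 1")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be > 0")
        if self.time_step is not None and self.time_step <= 0:
            raise ValueError("time_step must be > 0")
        if self.solver not in ("grid", "monte_carlo"):
            raise ValueError(f"unknown solver {self.solver!r}")
        self.sample_times = tuple(st)


def _occupancy_limits(rates: RateConstants) -> np.ndarray:
    """Aggregate (moving, on-pause, off-pause) occupancies, allowing zero rates.

    Matches :func:`pulsescape.kinetics.steady_state` when all required
    rates are positive, and takes the long-run limit when mobilisation or
    re-engagement rates vanish (everything accumulates in the pauses).
    """
    g01, g10, gon, goff = rates.gamma01, rates.gamma10, rates.gamma_on, rates.gamma_off
    if gon == 0.0 and goff > 0.0:
        return np.array([0.0, 0.0, 1.0])
    w_m = 0.0 if g01 == 0.0 else g01 / g10
    w_pp = 0.0 if goff == 0.0 else goff / gon
    w = np.array([w_m, 1.0, w_pp])
    return w / w.sum()


def _initial_state_probs(rates: RateConstants, motility: MotilityParams) -> np.ndarray:
    """Six-state probabilities at photoactivation (stationary, split by direction)."""
    agg = _occupancy_limits(rates)
    if rates.gamma_ar > 0.0 or rates.gamma_ra > 0.0:
        q = rates.gamma_ra / (rates.gamma_ar + rates.gamma_ra)
    else:
        q = motility.p_dir_a
    return np.array([
        q * agg[0], (1 - q) * agg[0],
        q * agg[1], (1 - q) * agg[1],
        q * agg[2], (1 - q) * agg[2],
    ])


# ---------------------------------------------------------------------------
# deterministic grid solver
# ---------------------------------------------------------------------------

def expected_decay(
    rates: RateConstants,
    motility: MotilityParams,
    geom: WindowGeometry,
    cfg: SimulationConfig,
    boundary: str = "absorbing",
    return_mass: bool = False,
) -> DecayCurve:
    """Deterministic window-fluorescence decay from the spatial master equation.

    The six state densities live on a uniform grid over
    ``[-margin, window + margin]``.  Each step applies half a reaction
    step (exact, via the 6x6 matrix exponential of the generator), one
    upwind advection step for the two moving states, and another half
    reaction step.  Far boundaries are absorbing by default;
    ``boundary="reflecting"`` folds out-flowing mass into the opposite
    moving state at the wall (mass-conservation validation mode).

    Raises a ``ValueError`` with the admissible step if the CFL condition
    ``v * dt / dx <= 1`` is violated, and warns if more than 0.1% of the
    initial mass is absorbed at the far boundaries (margin too small).
    """
    if cfg.solver != "grid":
        raise ValueError("expected_decay requires cfg.solver == 'grid'")
    if boundary not in ("absorbing", "reflecting"):
        raise ValueError(f"unknown boundary {boundary!r}")
    L, margin, dx = geom.window_length, geom.domain_margin, cfg.grid_spacing
    n = int(round((L + 2 * margin) / dx))
    x = -margin + (np.arange(n) + 0.5) * dx
    window = ((x > 0.0) & (x < L)).astype(float)

    speeds = np.array([motility.v_a, motility.v_r, 0, 0, 0, 0], dtype=float)
    vmax = np.max(np.abs(speeds))
    dt = cfg.time_step if cfg.time_step is not None else (dx / vmax if vmax > 0 else 1.0)
    courant = np.abs(speeds) * dt / dx
    if np.any(courant > 1.0 + 1e-9):
        raise ValueError(
            f"CFL violation: v*dt/dx = {courant.max():.3f} > 1; "
            f"use time_step <= {dx / vmax:.6g} s"
        )
    c_a, c_r = courant[0], courant[1]

    Q = reaction_matrix(rates)
    P_half = expm(Q * dt / 2.0)
    pi = _initial_state_probs(rates, motility)
    U = pi[:, None] * (window / L)[None, :]

    times = np.asarray(cfg.sample_times)
    out = np.zeros(times.size)
    done = np.zeros(times.size, dtype=bool)
    wdx = window * dx
    occ_prev = float((U @ wdx).sum())
    if times[0] == 0.0:
        out[0] = occ_prev
        done[0] = True
    mass = [float(U.sum() * dx)]

    t = 0.0
    n_steps = int(np.ceil(times[-1] / dt - 1e-9))
    for _ in range(n_steps):
        U = P_half @ U
        # upwind advection of the moving states; Courant 1 is an exact shift
        ua, ur = U[0], U[1]
        out_right = c_a * ua[-1]
        out_left = c_r * ur[0]
        ua[1:] += c_a * (ua[:-1] - ua[1:])
        ua[0] -= c_a * ua[0]
        ur[:-1] += c_r * (ur[1:] - ur[:-1])
        ur[-1] -= c_r * ur[-1]
        if boundary == "reflecting":
            U[1, -1] += out_right
            U[0, 0] += out_left
        U = P_half @ U
        t_new = t + dt
        occ = float((U @ wdx).sum())
        hit = (~done) & (times > t) & (times <= t_new + 1e-9)
        if np.any(hit):
            out[hit] = occ_prev + (occ - occ_prev) * (times[hit] - t) / dt
            done[hit] = True
        if return_mass:
            mass.append(float(U.sum() * dx))
        occ_prev, t = occ, t_new

    curve = DecayCurve(times.copy(), np.clip(out, 0.0, None))
    if return_mass:
        return curve, np.asarray(mass)
    return curve


# ---------------------------------------------------------------------------
# event-driven Monte Carlo
# ---------------------------------------------------------------------------

def simulate_pulse_escape(
    rates: RateConstants,
    motility: MotilityParams,
    geom: WindowGeometry,
    cfg: SimulationConfig,
) -> DecayCurve:
    """Stochastic pulse-escape simulation with exact event-driven kinetics.

    Each filament carries a position and one of the six states; dwell
    times are exponential with the state's total exit rate and the next
    state is drawn from the competing transition rates, so dwell-time
    statistics are exact (no time-step bias).  Moving filaments advect at
    their bout velocity between events.  The value at each sample time is
    the fraction of filaments inside the window; filaments that cross the
    far domain boundary are counted as permanently departed, with a
    warning if they exceed 0.1% of the population while reversals make
    re-entry possible (without reversals a departed filament can never
    return, so far-boundary absorption is exact).

    Bit-reproducible for a fixed ``cfg.seed``.
    """
    if cfg.solver != "monte_carlo":
        raise ValueError("simulate_pulse_escape requires cfg.solver == 'monte_carlo'")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_filaments
    L, margin = geom.window_length, geom.domain_margin

    Q = reaction_matrix(rates)
    exit_rates = -np.diag(Q)
    trans = Q - np.diag(np.diag(Q))  # off-diagonal: trans[dst, src]
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = trans / exit_rates[None, :]
    probs[:, exit_rates == 0.0] = 0.0
    cum = np.cumsum(probs.T, axis=1)  # cum[src, :] over destinations
    speeds = np.array([motility.v_a, motility.v_r, 0, 0, 0, 0], dtype=float)

    pi = _initial_state_probs(rates, motility)
    state = rng.choice(6, size=n, p=pi / pi.sum())
    x = rng.uniform(0.0, L, size=n)
    t = np.zeros(n)
    absorbed = np.zeros(n, dtype=bool)

    times = np.asarray(cfg.sample_times)
    pos = np.full((times.size, n), np.nan)
    for j, ts in enumerate(times):
        if ts == 0.0:
            pos[j] = x

    duration = cfg.duration
    active = t < duration
    while np.any(active):
        lam = exit_rates[state]
        with np.errstate(divide="ignore"):
            dt = np.where(lam > 0.0, rng.exponential(1.0, size=n) / np.where(lam > 0, lam, 1.0),
                          np.inf)
        dt[~active] = 0.0
        t_event = t + dt
        t_stop = np.minimum(t_event, duration)
        v = speeds[state]
        for j, ts in enumerate(times):
            if ts == 0.0:
                continue
            hit = active & (t < ts) & (ts <= t_stop)
            if np.any(hit):
                pos[j, hit] = x[hit] + v[hit] * (ts - t[hit])
        x = x + v * (t_stop - t)
        t = t_stop
        newly_out = active & ((x < -margin) | (x > L + margin))
        if np.any(newly_out):
            absorbed |= newly_out
            x[newly_out] = np.inf  # permanently departed
        transition = active & (t_event < duration) & ~newly_out
        if np.any(transition):
            u = rng.uniform(size=n)
            nxt = (u[:, None] <= cum[state]).argmax(axis=1)
            state[transition] = nxt[transition]
        active = active & (t < duration) & ~newly_out

    n_absorbed = int(absorbed.sum())
    reentry_possible = rates.gamma_ar > 0.0 or rates.gamma_ra > 0.0
    if reentry_possible and n_absorbed > 0.001 * n:
        warnings.warn(
            f"{n_absorbed}/{n} filaments reached the domain boundary; "
            "domain_margin may be too small", stacklevel=2,
        )
    inside = (pos > 0.0) & (pos < L)
    values = inside.mean(axis=1)
    return DecayCurve(times.copy(), values, n_axons=None)


# ---------------------------------------------------------------------------
# modal (eigendecomposition) solver on the window-restricted domain
# ---------------------------------------------------------------------------

def _directional_operator(g01, g10, gon, goff, speed, n, dx):
    """Upwind 3-state operator (moving, on-pause, off-pause) on n cells."""
    R = np.array([
        [-g10, g01, 0.0],
        [g10, -(g01 + goff), gon],
        [0.0, goff, -gon],
    ])
    M = np.kron(R, np.eye(n))
    adv = (np.diag(-np.ones(n)) + np.diag(np.ones(n - 1), -1)) * (speed / dx)
    M[:n, :n] += adv
    return M


def _modal_curve_from_operator(M, u0, weights, times):
    lam, V = np.linalg.eig(M)
    coef = np.linalg.solve(V, u0)
    proj = (weights @ V) * coef
    tt = np.asarray(times, dtype=float)
    return np.real(np.exp(np.outer(tt, lam)) @ proj)


def modal_decay(
    rates: RateConstants,
    motility: MotilityParams,
    window_length: float = 5.0,
    times=None,
    dx: float = 0.125,
    reentry_margin: float = 25.0,
) -> np.ndarray:
    """Window occupancy at *times* via dense eigendecomposition.

    Without reversals the two directional chains decouple and a filament
    that leaves the window can never re-enter, so the master equation
    restricted to the window alone (absorbing immediately outside) is
    exact and tiny: each direction is a 3-state upwind operator on the
    window grid.  With reversals the full six-state operator on
    ``[-reentry_margin, window + reentry_margin]`` is used instead.

    Returns occupancy normalised to 1 at activation.
    """
    if times is None:
        times = np.asarray(_DEFAULT_SAMPLES_S)
    g01, g10, gon, goff = rates.gamma01, rates.gamma10, rates.gamma_on, rates.gamma_off
    agg = _occupancy_limits(rates)
    if rates.gamma_ar == 0.0 and rates.gamma_ra == 0.0:
        n = max(int(round(window_length / dx)), 2)
        u0 = np.concatenate([agg[0] * np.ones(n), agg[1] * np.ones(n), agg[2] * np.ones(n)])
        u0 /= n
        w = np.ones(3 * n)
        speeds = (motility.v_a, -motility.v_r)
        shares = (motility.p_dir_a, motility.p_dir_r)
        total = np.zeros(np.asarray(times).size)
        cache = {}
        for speed, share in zip(speeds, shares):
            if share == 0.0:
                continue
            if speed not in cache:
                M = _directional_operator(g01, g10, gon, goff, speed, n, dx)
                cache[speed] = _modal_curve_from_operator(M, u0, w, times)
            total = total + share * cache[speed]
        return total
    # coupled six-state operator with re-entry margin
    L, m = window_length, reentry_margin
    n = int(round((L + 2 * m) / dx))
    x = -m + (np.arange(n) + 0.5) * dx
    win = ((x > 0) & (x < L)).astype(float)
    Q = reaction_matrix(rates)
    M = np.kron(Q, np.eye(n))
    adv_f = (np.diag(-np.ones(n)) + np.diag(np.ones(n - 1), -1)) * (motility.v_a / dx)
    adv_b = (np.diag(-np.ones(n)) + np.diag(np.ones(n - 1), 1)) * (-motility.v_r / dx)
    M[:n, :n] += adv_f
    M[n:2 * n, n:2 * n] += adv_b
    pi = _initial_state_probs(rates, motility)
    u0 = np.concatenate([pi[s] * win for s in range(6)])
    u0 /= win.sum()
    w = np.concatenate([win] * 6)
    return _modal_curve_from_operator(M, u0, w, times)


def _slowest_mode(rates: RateConstants, motility: MotilityParams,
                  window_length: float, dx: float = 0.125,
                  reentry_margin: float = 25.0) -> float:
    """Asymptotic window-escape rate: slowest eigenvalue of the window operator."""
    g01, g10, gon, goff = rates.gamma01, rates.gamma10, rates.gamma_on, rates.gamma_off
    if rates.gamma_ar == 0.0 and rates.gamma_ra == 0.0:
        n = max(int(round(window_length / dx)), 2)
        slow = np.inf
        for speed, share in ((motility.v_a, motility.p_dir_a), (-motility.v_r, motility.p_dir_r)):
            if share == 0.0:
                continue
            M = _directional_operator(g01, g10, gon, goff, speed, n, dx)
            slow = min(slow, -np.max(np.linalg.eigvals(M).real))
        return float(slow)
    L, m = window_length, reentry_margin
    n = int(round((L + 2 * m) / dx))
    Q = reaction_matrix(rates)
    M = np.kron(Q, np.eye(n))
    adv_f = (np.diag(-np.ones(n)) + np.diag(np.ones(n - 1), -1)) * (motility.v_a / dx)
    adv_b = (np.diag(-np.ones(n)) + np.diag(np.ones(n - 1), 1)) * (-motility.v_r / dx)
    M[:n, :n] += adv_f
    M[n:2 * n, n:2 * n] += adv_b
    return float(-np.max(np.linalg.eigvals(M).real))


# ---------------------------------------------------------------------------
# model observables
# ---------------------------------------------------------------------------

def initial_slope_analytic(rates: RateConstants, motility: MotilityParams,
                           geom: WindowGeometry) -> float:
    """Exact -dy/dt at t -> 0+: the advective flux of moving filaments out
    of a uniformly filled window, ``(f_a*v_a + f_r*|v_r|) / L``."""
    pi = _initial_state_probs(rates, motility)
    return float((pi[0] * motility.v_a + pi[1] * (-motility.v_r)) / geom.window_length)


def initial_slope(rates: RateConstants, motility: MotilityParams,
                  geom: WindowGeometry, fd_window: float = 30.0,
                  grid_spacing: float = 0.25) -> float:
    """Initial decay slope estimated by finite differences on the grid solution.

    Uses the drop of window occupancy over the first ``fd_window`` seconds
    (default 30 s, short against the fast escape phase).  Zero motility
    gives zero slope.
    """
    if motility.v_a == 0.0 and motility.v_r == 0.0:
        return 0.0
    cfg = SimulationConfig(sample_times=(fd_window,), duration=fd_window,
                           grid_spacing=grid_spacing, solver="grid")
    curve = expected_decay(rates, motility, geom, cfg)
    return float((1.0 - curve.values[0]) / fd_window)


def long_term_decay_constant(
    rates: RateConstants,
    motility: MotilityParams,
    geom: WindowGeometry,
    method: str = "slope",
    horizon: float = 43_200.0,
    grid_spacing: float = 0.25,
) -> float:
    """Asymptotic exponential rate of the model decay, 1/s.

    ``method="slope"`` regresses log-occupancy over the last factor-of-e
    of the decay within *horizon* (12 h default) using the modal solution;
    ``method="eigen"`` returns the slowest eigenvalue of the discretised
    window-escape operator.  The slow spectrum is a quasi-continuous band
    just below ``gamma_on``, so the eigenvalue bounds the slope estimate
    from above; at physiological rates they differ by a few percent (the
    truly asymptotic mode dominates only at unobservably long times).
    Non-decaying configurations (zero motility) return 0.
    """
    if motility.v_a == 0.0 and motility.v_r == 0.0:
        return 0.0
    if method == "eigen":
        return _slowest_mode(rates, motility, geom.window_length, dx=grid_spacing / 2.0)
    if method != "slope":
        raise ValueError(f"unknown method {method!r}")
    times = np.geomspace(horizon / 64.0, horizon, 40)
    y = modal_decay(rates, motility, geom.window_length, times, dx=grid_spacing / 2.0)
    y = np.clip(y, 1e-300, None)
    if y[-1] > 0.999:
        return 0.0
    lo = y[-1]
    sel = y <= lo * np.e
    if sel.sum() < 2:
        sel[-2:] = True
    coeffs = np.polyfit(times[sel], np.log(y[sel]), 1)
    return float(-coeffs[0])
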