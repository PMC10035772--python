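"""Double-exponential decay fitting and the derived pulse-escape observables.

The decay of window fluorescence is modelled as

    y(t) = A exp(-a t) + B exp(-b t) + C,          A, B, C >= 0,

where, after normalising by ``A + B + C``, ``A/(A+B+C)`` and ``B/(A+B+C)``
are the fractions of filaments in the rapidly and slowly escaping phases
at the reference time and ``C/(A+B+C)`` is the fraction in a hypothetical
stationary (never-departing) state.  The two observables passed to the
inverse procedure are the initial slope ``(aA + bB)/(A+B+C)`` and the
long-term decay constant ``b``.

Fitting is deterministic: a variable-projection grid search over the two
rates (amplitudes solved by non-negative least squares at each grid node)
seeds a bounded Levenberg–Marquardt polish.  ``DoubleExponentialDecay``
and ``BleachCalibration`` follow the scikit-learn estimator protocol so
they compose with pipelines and model selection; the module-level
functions are thin wrappers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares, nnls

from .curves import DecayCurve

__all__ = [
    "DoubleExpFit",
    "DoubleExponentialDecay",
    "BleachCalibration",
    "fit_double_exponential",
    "observables",
    "extrapolate",
    "fit_bleach_calibration",
]


@dataclass(frozen=True)
class DoubleExpFit:
    """Fitted parameters of the biphasic decay, canonically ordered a >= b."""

    A: float
    B: float
    C: float
    a: float
    b: float
    sse: float

    def __post_init__(self) -> None:
        if min(self.A, self.B, self.C) < 0:
            raise ValueError("amplitudes A, B, C must be non-negative")
        if self.a < self.b:
            raise ValueError("rates must be canonically ordered a >= b")

    @property
    def total(self) -> float:
        return self.A + self.B + self.C

    @property
    def fast_fraction(self) -> float:
        return self.A / self.total

    @property
    def slow_fraction(self) -> float:
        return self.B / self.total

    @property
    def plateau_fraction(self) -> float:
        return self.C / self.total

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.A * np.exp(-self.a * t) + self.B * np.exp(-self.b * t) + self.C

    def to_dict(self) -> dict:
        slope, slow = observables(self)
        return {
            "A": self.A, "B": self.B, "C": self.C, "a": self.a, "b": self.b,
            "sse": self.sse,
            "fast_fraction": self.fast_fraction,
            "slow_fraction": self.slow_fraction,
            "plateau_fraction": self.plateau_fraction,
            "initial_slope": slope,
            "long_term_constant": slow,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _design(t: np.ndarray, rates: tuple) -> np.ndarray:
    cols = [np.exp(-r * t) for r in rates]
    cols.append(np.ones_like(t))
    return np.column_stack(cols)


def _nnls_sse(t: np.ndarray, y: np.ndarray, rates: tuple) -> tuple:
    X = _design(t, rates)
    amps, rnorm = nnls(X, y)
    return amps, rnorm ** 2


class DoubleExponentialDecay:
    """Least-squares fit of ``A e^{-at} + B e^{-bt} + C`` with A, B, C >= 0.

    Parameters
    ----------
    rate_grid_min, rate_grid_max, rate_grid_size : float, float, int
        Logarithmic multi-start grid for the two rate constants, 1/s.
        The default spans 1e-5 to 1e-1, bracketing both pulse-escape
        phases with margin.
    n_polish : int
        Number of best grid nodes polished with bounded least squares.
    weighted : bool
        If true and the curve carries SDs, weight residuals by 1/SD.

    Attributes (after :meth:`fit`)
    ------------------------------
    A_, B_, C_, a_, b_ : float
        Parameters with canonical ordering ``a_ >= b_``.
    sse_ : float
        Residual sum of squares.
    fit_ : DoubleExpFit
        The result bundle used by the functional API.
    """

    def __init__(self, rate_grid_min: float = 1e-5, rate_grid_max: float = 1e-1,
                 rate_grid_size: int = 25, n_polish: int = 3, weighted: bool = False):
        self.rate_grid_min = rate_grid_min
        self.rate_grid_max = rate_grid_max
        self.rate_grid_size = rate_grid_size
        self.n_polish = n_polish
        self.weighted = weighted

    # -- sklearn protocol -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "rate_grid_min": self.rate_grid_min,
            "rate_grid_max": self.rate_grid_max,
            "rate_grid_size": self.rate_grid_size,
            "n_polish": self.n_polish,
            "weighted": self.weighted,
        }

    def set_params(self, **params) -> "DoubleExponentialDecay":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    @staticmethod
    def _validate(X, y):
        t = np.asarray(X, dtype=float)
        if t.ndim == 2 and t.shape[1] == 1:
            t = t[:, 0]
        if t.ndim != 1:
            raise ValueError("X must be a 1-D array of times (or a single column)")
        y = np.asarray(y, dtype=float)
        if y.shape != t.shape:
            raise ValueError("y must match X in length")
        return t, y

    def fit(self, X, y, sample_weight=None) -> "DoubleExponentialDecay":
        """Fit to times *X* (seconds) and normalised fluorescence *y*."""
        t, y = self._validate(X, y)
        if t.size < 6:
            raise ValueError("need at least 6 time points to fit 5 parameters")
        w = None
        if sample_weight is not None:
            w = np.sqrt(np.asarray(sample_weight, dtype=float))

        grid = np.geomspace(self.rate_grid_min, self.rate_grid_max, self.rate_grid_size)
        yw = y if w is None else y * w
        candidates = []
        for i, fast in enumerate(grid):
            for slow in grid[: i + 1]:
                X_ = _design(t, (fast, slow))
                if w is not None:
                    X_ = X_ * w[:, None]
                amps, rnorm = nnls(X_, yw)
                candidates.append((rnorm ** 2, fast, slow, amps))
        candidates.sort(key=lambda c: c[0])

        def residuals(p):
            A, B, C, fa, sl = p
            r = A * np.exp(-fa * t) + B * np.exp(-sl * t) + C - y
            return r if w is None else r * w

        best = None
        for sse0, fast, slow, amps in candidates[: self.n_polish]:
            p0 = [amps[0], amps[1], amps[2], fast, slow]
            sol = least_squares(
                residuals, p0, bounds=([0, 0, 0, 0, 0], [np.inf] * 5),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
            sse = float(np.sum(sol.fun ** 2))
            if best is None or sse < best[0]:
                best = (sse, sol.x)
        sse, (A, B, C, fa, sl) = best
        if fa < sl:
            A, B, fa, sl = B, A, sl, fa
        if fa > 0 and abs(fa - sl) <= 1e-6 * fa:
            warnings.warn(
                "degenerate biphasic fit (a ~ b); collapsing to a single "
                "exponential plus plateau", stacklevel=2,
            )
            A, B = A + B, 0.0
            sl = fa
        self.A_, self.B_, self.C_ = float(A), float(B), float(C)
        self.a_, self.b_ = float(fa), float(sl)
        self.sse_ = float(sse)
        self.fit_ = DoubleExpFit(self.A_, self.B_, self.C_, self.a_, self.b_, self.sse_)
        return self

    def predict(self, X) -> np.ndarray:
        t = np.asarray(X, dtype=float)
        if t.ndim == 2 and t.shape[1] == 1:
            t = t[:, 0]
        return self.fit_(t)

    def score(self, X, y) -> float:
        """Coefficient of determination, for sklearn model-selection duty."""
        t, y = self._validate(X, y)
        resid = y - self.fit_(t)
        denom = np.sum((y - y.mean()) ** 2)
        return 1.0 - float(np.sum(resid ** 2)) / denom if denom > 0 else 0.0


def fit_double_exponential(curve: DecayCurve, weighted: bool = False,
                           **params) -> DoubleExpFit:
    """Fit the biphasic decay model to a curve; see :class:`DoubleExponentialDecay`."""
    est = DoubleExponentialDecay(weighted=weighted, **params)
    sw = None
    if weighted and curve.sd is not None:
        sd = np.where(curve.sd > 0, curve.sd, np.inf)
        sw = 1.0 / sd ** 2
    est.fit(curve.times, curve.values, sample_weight=sw)
    return est.fit_


def observables(fit: DoubleExpFit) -> tuple:
    """The two pulse-escape observables of a fit.

    Returns ``((a*A + b*B)/(A+B+C), b)`` — the initial slope of the decay
    normalised so y(0) = 1, and the long-term decay constant.
    """
    total = fit.total
    if total == 0:
        raise ValueError("A + B + C = 0: observables undefined")
    return ((fit.a * fit.A + fit.b * fit.B) / total, fit.b)


def extrapolate(fit: DoubleExpFit, t) -> np.ndarray | float:
    """Evaluate the fitted decay at time(s) *t* seconds (t >= 0)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("extrapolation times must be >= 0")
    out = fit(t)
    return float(out) if out.ndim == 0 else out


class BleachCalibration:
    """Per-exposure photobleaching rate from a transport-free calibration.

    Fits the mean intensity across axons to ``I0 * exp(-k n)`` in the
    cumulative exposure count ``n`` (not wall-clock time: each 488 nm
    exposure bleaches the same fraction regardless of spacing).

    Attributes: ``rate_`` (per-exposure k), ``scale_`` (I0).
    """

    def __init__(self):
        pass

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params) -> "BleachCalibration":
        if params:
            raise ValueError(f"unknown parameters {sorted(params)}")
        return self

    def fit(self, X, y) -> "BleachCalibration":
        n = np.asarray(X, dtype=float)
        if n.ndim == 2 and n.shape[1] == 1:
            n = n[:, 0]
        y = np.asarray(y, dtype=float)
        if n.shape != y.shape or n.ndim != 1:
            raise ValueError("X (exposure counts) and y (intensities) must match")
        if n.size < 2:
            raise ValueError("need at least two exposures to calibrate")
        # log-linear start, nonlinear polish
        pos = y > 0
        slope, intercept = np.polyfit(n[pos], np.log(y[pos]), 1)

        def residuals(p):
            scale, k = p
            return scale * np.exp(-k * n) - y

        sol = least_squares(residuals, [np.exp(intercept), -slope],
                            xtol=1e-14, ftol=1e-14)
        self.scale_, self.rate_ = float(sol.x[0]), float(sol.x[1])
        if self.rate_ < -1e-12:
            raise ValueError(
                "mean intensity rises with exposure count: not a valid "
                "photobleaching calibration"
            )
        self.rate_ = max(self.rate_, 0.0)
        return self

    def predict(self, X) -> np.ndarray:
        n = np.asarray(X, dtype=float)
        return self.scale_ * np.exp(-self.rate_ * n)


def fit_bleach_calibration(curves: list, exposures=None) -> float:
    """Per-exposure bleach rate k from calibration series.

    *curves* are per-axon intensity series indexed by exposure number
    (``DecayCurve.times`` holds the exposure count).  The per-axon series
    are averaged pointwise and the mean is fit to a single exponential in
    exposure count.  Returns k such that intensity ∝ exp(-k n).
    """
    if not curves:
        raise ValueError("no calibration curves given")
    if exposures is None:
        exposures = curves[0].times
    exposures = np.asarray(exposures, dtype=float)
    stack = []
    for c in curves:
        if len(c) != exposures.size:
            raise ValueError("calibration curves must share the exposure grid")
        stack.append(c.values)
    mean = np.mean(stack, axis=0)
    est = BleachCalibration().fit(exposures, mean)
    return est.rate_
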