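"""Raw-trace preprocessing: bleach correction, dark-state normalisation, averaging.

The pipeline order is bleach-correct -> normalise -> average.  The first
two are multiplicative and therefore commute; averaging requires a shared
time grid (no resampling is attempted).
"""

from __future__ import annotations

import numpy as np

from .curves import DecayCurve, RawTrace

__all__ = ["correct_photobleach", "normalize_dark_state", "average_curves"]

#: Time of the normalisation reference frame, seconds post-activation.
REFERENCE_TIME_S = 60.0


def correct_photobleach(trace: RawTrace, k_bleach: float) -> RawTrace:
    """Undo per-exposure photobleaching: divide intensity by exp(-k * n).

    ``n`` is the cumulative 488 nm exposure count of each frame.  The
    correction is multiplicative and order-preserving; ``k = 0`` is the
    identity.
    """
    if k_bleach < 0:
        raise ValueError("k_bleach must be >= 0")
    corrected = trace.intensities * np.exp(k_bleach * trace.exposure_index)
    return RawTrace(list(trace.frame_labels), trace.times_s.copy(), corrected,
                    trace.exposure_index.copy())


def normalize_dark_state(trace: RawTrace) -> DecayCurve:
    """Normalise to the 1-minute frame and drop the pre/post frames.

    paGFP fluorescence rises ~15% during the first minute after
    activation as molecules relax out of a dark state, so the first
    quantitatively comparable frame is the one at 1 min.  The returned
    curve is divided by that frame's intensity and its time origin is
    moved to it (t = 0 at 1 min post-activation).
    """
    timed = trace.timed_mask()
    times = trace.times_s[timed]
    values = trace.intensities[timed]
    ref = np.flatnonzero(np.isclose(times, REFERENCE_TIME_S, rtol=0, atol=1e-6))
    if ref.size == 0:
        raise ValueError(
            "trace has no frame at 1 min post-activation: cannot apply the "
            "dark-state normalisation"
        )
    i0 = int(ref[0])
    keep = times >= REFERENCE_TIME_S - 1e-6
    return DecayCurve(times[keep] - REFERENCE_TIME_S, values[keep] / values[i0])


def average_curves(curves: list) -> DecayCurve:
    """Pointwise mean of per-axon curves sharing one time grid.

    Returns the mean curve with the across-axon SD (ddof = 1) and the
    axon count recorded.  Mismatched time grids raise; no resampling.
    """
    if not curves:
        raise ValueError("no curves to average")
    t0 = curves[0].times
    for c in curves[1:]:
        if len(c) != len(t0) or not np.allclose(c.times, t0, rtol=0, atol=1e-9):
            raise ValueError("curves must share an identical time grid to average")
    stack = np.vstack([c.values for c in curves])
    sd = stack.std(axis=0, ddof=1) if len(curves) > 1 else np.zeros(len(t0))
    return DecayCurve(t0.copy(), stack.mean(axis=0), sd=sd, n_axons=len(curves))
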