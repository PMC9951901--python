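"""Induction-time analysis of lipid-oxidation kinetic curves.

Conjugated dienes (CDs), the primary oxidation products of unsaturated
lipids, absorb at 233 nm; their accumulation with time shows a slow lag
(initiation) phase followed by rapid propagation.  Oxidative stability is
quantified by the induction time tau_IND: the abscissa of the intersection
of two straight lines fitted by least squares to the lag and propagation
phases.  The breakpoint is chosen by exhaustive search over all two-segment
splits, minimizing the total residual sum of squares.  tau_IND is invariant
under affine transformations of the signal axis and equivariant under affine
transformations of the time axis, so it does not matter whether raw
absorbance or a relative %-increase signal is analyzed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, NoBreakpointError, NormalizationError

__all__ = [
    "OxidationCurve",
    "InductionResult",
    "percent_delta_cd",
    "induction_time",
    "effectiveness_ratio",
]


@dataclass(frozen=True)
class OxidationCurve:
    """Conjugated-diene signal versus time.

    ``time`` in hours, strictly increasing; ``signal`` in absorbance units
    (or %ΔCD).  ``true_induction_time`` is generator metadata when the curve
    is synthetic.
    """

    time: np.ndarray
    signal: np.ndarray
    label: str = ""
    true_induction_time: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, float))
        object.__setattr__(self, "signal", np.asarray(self.signal, float))
        if self.time.shape != self.signal.shape or self.time.ndim != 1:
            raise ValueError("time and signal must be 1-D arrays of equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal must be finite")

    def __len__(self) -> int:
        return self.time.size


@dataclass(frozen=True)
class InductionResult:
    """Two-segment fit of an oxidation curve and the extracted tau_IND."""

    tau_ind: float
    lag_slope: float
    lag_intercept: float
    prop_slope: float
    prop_intercept: float
    breakpoint_index: int  # number of points in the lag segment
    residual_sum_squares: float

    def to_dict(self) -> dict:
        return {
            "tau_ind_h": self.tau_ind,
            "lag_slope": self.lag_slope,
            "lag_intercept": self.lag_intercept,
            "prop_slope": self.prop_slope,
            "prop_intercept": self.prop_intercept,
            "breakpoint_index": self.breakpoint_index,
            "residual_sum_squares": self.residual_sum_squares,
        }


def percent_delta_cd(signal: np.ndarray, reference: float | None = None) -> np.ndarray:
    """Relative conjugated-diene increase, 100*(A_t - A_0)/A_0.

    ``reference`` defaults to the first point.  This is an affine transform
    of the raw signal, so induction times computed from either are equal.
    """
    signal = np.asarray(signal, float)
    ref = float(signal[0]) if reference is None else float(reference)
    if ref <= 0:
        raise NormalizationError(f"reference absorbance must be positive, got {ref}")
    return 100.0 * (signal - ref) / ref


def _line_fit(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line; returns (slope, intercept, sse)."""
    n = t.size
    tm, ym = t.mean(), y.mean()
    stt = np.sum((t - tm) ** 2)
    if stt == 0:
        return 0.0, ym, float(np.sum((y - ym) ** 2))
    slope = float(np.sum((t - tm) * (y - ym)) / stt)
    intercept = float(ym - slope * tm)
    sse = float(np.sum((y - slope * t - intercept) ** 2))
    return slope, intercept, sse


def induction_time(
    curve: OxidationCurve,
    min_segment: int = 3,
    parallel_tol: float = 1e-12,
) -> InductionResult:
    """Extract tau_IND by the two-straight-line intersection method.

    Every breakpoint leaving at least ``min_segment`` points per side is
    tried; lines are fitted by least squares to each side and the split with
    the smallest total SSE wins.  tau_IND is the abscissa of the
    intersection of the two winning lines.
    """
    t, y = curve.time, curve.signal
    n = t.size
    if n < 2 * min_segment:
        raise InsufficientDataError(
            f"need at least {2 * min_segment} points for two {min_segment}-point segments"
        )
    best = None
    for k in range(min_segment, n - min_segment + 1):
        m1, b1, s1 = _line_fit(t[:k], y[:k])
        m2, b2, s2 = _line_fit(t[k:], y[k:])
        sse = s1 + s2
        if best is None or sse < best[0]:
            best = (sse, k, m1, b1, m2, b2)
    sse, k, m1, b1, m2, b2 = best
    scale = max(abs(m1), abs(m2), 1.0)
    if abs(m2 - m1) <= parallel_tol * scale:
        raise NoBreakpointError("lag and propagation lines are parallel within tolerance")
    if m2 <= m1:
        raise NoBreakpointError(
            f"propagation slope ({m2:g}) does not exceed lag slope ({m1:g})"
        )
    tau = (b1 - b2) / (m2 - m1)
    if not (t[0] - (t[-1] - t[0]) <= tau <= t[-1] + (t[-1] - t[0])):
        raise NoBreakpointError(f"intersection at {tau:g} h far outside the observed range")
    return InductionResult(float(tau), m1, b1, m2, b2, k, sse)


def effectiveness_ratio(
    curve_ao: OxidationCurve,
    curve_control: OxidationCurve,
    min_segment: int = 3,
) -> float:
    """tau_IND(antioxidant) / tau_IND(control); > 1 indicates inhibition."""
    tau_ao = induction_time(curve_ao, min_segment=min_segment).tau_ind
    tau_ctrl = induction_time(curve_control, min_segment=min_segment).tau_ind
    return tau_ao / tau_ctrl
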