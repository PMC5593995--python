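"""Conditioning of raw phase-shift recordings and reversal-point detection.

A raw recording is a dense phase series (nominally 2700 samples over a
54 min infusion) contaminated by respiration- and cardiac-cycle
fluctuation.  Conditioning reduces it to a short block series aligned to
the injected-blood axis: block averaging over consecutive samples
removes the periodic fluctuation, and normalization to a pre-injection
baseline expresses the signal on a percent-of-baseline scale (~100).

The reversal point — the injected blood volume at which the phase
trajectory switches from falling to rising — marks the approach of
cerebrospinal-fluid compensation failure and is located here from a
low-order polynomial fit of the block series.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.polynomial import Polynomial

from .schedule import InjectionSchedule

logger = logging.getLogger(__name__)

__all__ = [
    "RawMIPSSeries",
    "BlockSeries",
    "ReversalAnalysis",
    "pre_injection_baseline",
    "block_smooth",
    "normalize",
    "first_derivative",
    "fit_polynomial",
    "PolynomialFit",
    "detect_reversal",
]

DEFAULT_BLOCK_SIZE = 300
DEFAULT_FIT_DEGREE = 4  # lowest degree representing one interior minimum plus a curvature change


@dataclass
class RawMIPSSeries:
    """Timestamped phase-shift samples for one animal run.

    ``time_s`` is seconds relative to the start of the infusion, so a
    pre-injection baseline segment has negative times.
    """

    time_s: np.ndarray
    phase_deg: np.ndarray
    animal_id: str = ""
    schedule: InjectionSchedule | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.phase_deg = np.asarray(self.phase_deg, dtype=float)
        if self.time_s.shape != self.phase_deg.shape or self.time_s.ndim != 1:
            raise ValueError("time and phase must be 1D arrays of equal length")
        if self.time_s.size and np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        if not (np.all(np.isfinite(self.time_s)) and np.all(np.isfinite(self.phase_deg))):
            raise ValueError("raw series contains non-finite values")


@dataclass
class BlockSeries:
    """Block-averaged values keyed by injected blood volume."""

    blood_ml: np.ndarray
    time_min: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        self.blood_ml = np.asarray(self.blood_ml, dtype=float)
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if not (self.blood_ml.shape == self.time_min.shape == self.value.shape):
            raise ValueError("blood_ml, time_min and value must have equal length")
        if self.blood_ml.ndim != 1:
            raise ValueError("block series fields must be 1D")
        if self.blood_ml.size > 1 and np.any(np.diff(self.blood_ml) <= 0):
            raise ValueError("blood_ml must be strictly increasing")

    @property
    def n_blocks(self) -> int:
        return self.blood_ml.size


def pre_injection_baseline(raw: RawMIPSSeries) -> float:
    """Mean phase over the pre-injection segment (samples at t < 0)."""
    pre = raw.phase_deg[raw.time_s < 0]
    if pre.size == 0:
        raise ValueError("series has no pre-injection samples (t < 0)")
    return float(pre.mean())


def block_smooth(
    raw: RawMIPSSeries,
    block_size: int = DEFAULT_BLOCK_SIZE,
    schedule: InjectionSchedule | None = None,
) -> BlockSeries:
    """Average consecutive samples into blocks keyed to injected blood.

    Only infusion samples (t >= 0) are smoothed; a pre-injection
    baseline segment, if present, is ignored here (see
    :func:`pre_injection_baseline`).  A trailing partial block is
    dropped with a warning.  Blood per block is the schedule's value at
    the block-end time; when the block count matches the schedule's
    sampling grid the schedule's printed blood grid is used so tables
    align exactly with the cohort fixtures.
    """
    if block_size < 1:
        raise ValueError("block_size must be a positive integer")
    schedule = schedule or raw.schedule
    if schedule is None:
        raise ValueError("an injection schedule is required to assign blood volumes")

    keep = raw.time_s >= 0
    t = raw.time_s[keep]
    x = raw.phase_deg[keep]
    n_blocks, rem = divmod(x.size, block_size)
    if n_blocks == 0:
        raise ValueError(f"fewer samples ({x.size}) than one block ({block_size})")
    if rem:
        msg = f"dropping trailing partial block of {rem} samples (block_size={block_size})"
        warnings.warn(msg, stacklevel=2)
        logger.warning(msg)
        t = t[: n_blocks * block_size]
        x = x[: n_blocks * block_size]

    means = x.reshape(n_blocks, block_size).mean(axis=1)
    t_end_min = t.reshape(n_blocks, block_size)[:, -1] / 60.0
    sched_t = np.asarray(schedule.sample_times, dtype=float)
    if n_blocks == sched_t.size and np.allclose(t_end_min, sched_t, atol=0.5):
        blood = schedule.sample_blood
        t_end_min = sched_t
    else:
        blood = schedule.blood_at(t_end_min)
    return BlockSeries(blood_ml=blood, time_min=t_end_min, value=means)


def normalize(series: BlockSeries, baseline_value: float) -> BlockSeries:
    """Rescale a block series to percent of a baseline value.

    ``value -> 100 * value / baseline_value``; normalizing an
    already-normalized series with baseline 100 is the identity.
    """
    if not np.isfinite(baseline_value) or baseline_value <= 0:
        raise ValueError("baseline_value must be positive and finite")
    return replace(series, value=100.0 * series.value / baseline_value)


def first_derivative(series: BlockSeries) -> np.ndarray:
    """Forward finite differences d(value)/d(blood), length n-1.

    Element ``i`` is indexed to the left block ``i``.
    """
    if series.n_blocks < 2:
        raise ValueError("need at least 2 points to differentiate")
    db = np.diff(series.blood_ml)
    if np.any(db == 0):
        raise ValueError("duplicate blood_ml values")
    return np.diff(series.value) / db


@dataclass
class PolynomialFit:
    """Least-squares polynomial fit of a block series in blood volume."""

    poly: Polynomial  # coefficients in the unscaled blood domain
    fitted: np.ndarray  # fit evaluated at the series' blood points
    derivative_poly: Polynomial
    derivative_values: np.ndarray  # analytic derivative at the blood points
    degree: int

    @property
    def coefficients(self) -> np.ndarray:
        """Polynomial coefficients, ascending order, unscaled domain."""
        return self.poly.coef


def fit_polynomial(series: BlockSeries, degree: int = DEFAULT_FIT_DEGREE) -> PolynomialFit:
    """Fit a polynomial in blood volume and return its analytic derivative.

    Exact interpolation is excluded: ``degree`` must be below the number
    of points.
    """
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if degree >= series.n_blocks:
        raise ValueError(
            f"degree {degree} must be below the number of points ({series.n_blocks})"
        )
    # fit in a scaled window for conditioning, convert back to the data domain
    poly = Polynomial.fit(series.blood_ml, series.value, deg=degree).convert()
    dpoly = poly.deriv()
    return PolynomialFit(
        poly=poly,
        fitted=poly(series.blood_ml),
        derivative_poly=dpoly,
        derivative_values=dpoly(series.blood_ml),
        degree=degree,
    )


@dataclass
class ReversalAnalysis:
    """Reversal-point analysis of a conditioned phase series.

    ``reversal_blood_ml`` is the blood-axis location of the trajectory
    minimum (the fitted curve's minimum snapped to the sampling grid);
    ``zero_crossing_blood_ml`` is the continuous falling-to-rising zero
    crossing of the fitted derivative, when one exists.  The reversal
    section is the index range strictly after the maximum of the
    finite-difference derivative — the segment on which the signal sits
    outside the overall falling trend.  Monotone series carry no
    reversal and the corresponding fields are ``None``.
    """

    reversal_blood_ml: float | None
    derivative: np.ndarray
    derivative_max_index: int
    reversal_section: range
    zero_crossing_blood_ml: float | None
    fit: PolynomialFit

    @property
    def has_reversal(self) -> bool:
        return self.reversal_blood_ml is not None


def _falling_to_rising_root(dpoly: Polynomial, lo: float, hi: float) -> float | None:
    """First real root of the derivative in (lo, hi) with a sign change − to +."""
    roots = dpoly.roots()
    real = np.sort(roots[np.abs(roots.imag) < 1e-9].real)
    eps = 1e-9 * max(abs(lo), abs(hi), 1.0)
    for r in real:
        if lo + eps < r < hi - eps:
            span = min(r - lo, hi - r) / 2.0
            if dpoly(r - span) < 0 < dpoly(r + span):
                return float(r)
    return None


def detect_reversal(series: BlockSeries, degree: int = DEFAULT_FIT_DEGREE) -> ReversalAnalysis:
    """Locate the falling-to-rising reversal of a conditioned series.

    The finite-difference derivative and its maximum (earliest index on
    ties) define the reversal section.  The reversal point is the blood
    value at the minimum of the (already block-averaged) series —
    earliest index on plateau ties — which on grid points coincides
    with the minimum of the fitted trajectory whenever the fit tracks
    the series; the fitted derivative additionally yields the
    continuous falling-to-rising zero crossing.  A monotone series, or
    a minimum at an endpoint, is reported as having no reversal rather
    than an artifactual endpoint.
    """
    if series.n_blocks < 4:
        raise ValueError("need at least 4 points for reversal analysis")
    deriv = first_derivative(series)
    dmax = int(np.argmax(deriv))
    section = range(dmax + 1, series.n_blocks)
    fit = fit_polynomial(series, degree=degree)

    diffs = np.diff(series.value)
    monotone = bool(np.all(diffs <= 0) or np.all(diffs >= 0))

    reversal = None
    zero_crossing = None
    if not monotone:
        idx = int(np.argmin(series.value))
        if 0 < idx < series.n_blocks - 1:
            reversal = float(series.blood_ml[idx])
            zero_crossing = _falling_to_rising_root(
                fit.derivative_poly, float(series.blood_ml[0]), float(series.blood_ml[-1])
            )
    return ReversalAnalysis(
        reversal_blood_ml=reversal,
        derivative=deriv,
        derivative_max_index=dmax,
        reversal_section=section,
        zero_crossing_blood_ml=zero_crossing,
        fit=fit,
    )
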