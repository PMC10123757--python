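"""Envelope curve, work to fracture, and the alpha* strain-shift parameter.

The envelope interpolates the maximum true-stress points of all cycles
(prepended with the origin) and approximates the monotonic tensile curve
of the fiber: the stress-strain behaviour beyond a given strain is
independent of the previous loading history, so the cycle maxima trace
the curve a conventional test would have produced.

The alpha* parameter registers a stress-strain curve against a reference
curve from a maximum-supercontracted fiber by translating it along the
strain axis until (1) the true stresses of both curves concur and (2) the
local slopes at the concurrence point differ by less than a tolerance
(20% by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .kinematics import TrueCurve
from .segmentation import Cycle

__all__ = ["EnvelopeCurve", "AlphaStarResult", "envelope_curve", "work_to_fracture", "alpha_star"]


@dataclass
class EnvelopeCurve:
    """Piecewise-linear envelope through the cycle maxima, starting at (0, 0)."""

    strain: np.ndarray
    stress: np.ndarray

    def __post_init__(self):
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if len(self.strain) != len(self.stress) or len(self.strain) < 2:
            raise DomainError("envelope needs at least 2 knots of equal length")
        if not (np.all(np.isfinite(self.strain)) and np.all(np.isfinite(self.stress))):
            raise DomainError("non-finite envelope knots")
        if np.any(np.diff(self.strain) <= 0):
            raise DomainError("envelope knot strains must be strictly increasing")
        if abs(self.strain[0]) > 1e-12 or abs(self.stress[0]) > 1e-12:
            raise DomainError("envelope must start at the origin")

    def __call__(self, eps):
        eps = np.asarray(eps, dtype=float)
        if np.any(eps < self.strain[0] - 1e-12) or np.any(eps > self.strain[-1] + 1e-12):
            raise DomainError("envelope queried outside its knot range")
        return np.interp(eps, self.strain, self.stress)


def envelope_curve(cycles: list[Cycle]) -> EnvelopeCurve:
    """Envelope through the per-cycle (eps_max, sigma_max) points."""
    if not cycles:
        raise DomainError("need at least one complete cycle")
    eps = np.array([c.eps_max for c in cycles], dtype=float)
    sig = np.array([c.sigma_max for c in cycles], dtype=float)
    if np.any(np.diff(eps) <= 0):
        raise DomainError("cycle maximum strains must be strictly increasing")
    return EnvelopeCurve(np.concatenate([[0.0], eps]), np.concatenate([[0.0], sig]))


def work_to_fracture(envelope: EnvelopeCurve) -> float:
    """Area below the envelope over its full knot range (MJ/m^3)."""
    return float(np.trapezoid(envelope.stress, envelope.strain))


@dataclass
class AlphaStarResult:
    """Outcome of the alpha* search."""

    alpha_star: float | None
    concurrence_strain: float | None
    slope_ratio: float | None
    converged: bool


def _local_slope(strain: np.ndarray, stress: np.ndarray, at: float, half_window: float = 0.01) -> float:
    """Slope from a linear fit over samples within +/- half_window of ``at``."""
    mask = np.abs(strain - at) <= half_window
    if int(mask.sum()) < 2:
        i = int(np.argmin(np.abs(strain - at)))
        lo, hi = max(0, i - 1), min(len(strain), i + 2)
        mask = np.zeros(len(strain), dtype=bool)
        mask[lo:hi] = True
    coeffs = np.polyfit(strain[mask], stress[mask], 1)
    return float(coeffs[0])


def _concurrence(ref: TrueCurve, cur: TrueCurve, delta: float, slope_tolerance: float):
    """Crossing of (reference - curve shifted left by delta), or None.

    Returns (eps_cross, slope_ratio, admissible).
    """
    lo = max(float(ref.strain[0]), float(cur.strain[0]) - delta)
    hi = min(float(ref.strain[-1]), float(cur.strain[-1]) - delta)
    if hi <= lo:
        return None
    grid = np.unique(np.concatenate([
        ref.strain[(ref.strain >= lo) & (ref.strain <= hi)],
        cur.strain[(cur.strain - delta >= lo) & (cur.strain - delta <= hi)] - delta,
    ]))
    if len(grid) < 2:
        return None
    r = np.interp(grid, ref.strain, ref.stress)
    c = np.interp(grid + delta, cur.strain, cur.stress)
    d = r - c
    eps_cross = None
    zero = np.flatnonzero(np.abs(d) <= 1e-12 * max(1.0, float(np.max(np.abs(r)))))
    if len(zero):
        eps_cross = float(grid[int(zero[0])])
    else:
        sign_change = np.flatnonzero(d[:-1] * d[1:] < 0)
        if len(sign_change):
            i = int(sign_change[0])
            t = d[i] / (d[i] - d[i + 1])
            eps_cross = float(grid[i] + t * (grid[i + 1] - grid[i]))
    if eps_cross is None:
        return None
    s_ref = _local_slope(ref.strain, ref.stress, eps_cross)
    s_cur = _local_slope(cur.strain, cur.stress, eps_cross + delta)
    if s_ref == 0.0:
        ratio = np.inf if s_cur != 0.0 else 0.0
    else:
        ratio = abs(s_cur / s_ref - 1.0)
    return eps_cross, float(ratio), bool(ratio < slope_tolerance)


def alpha_star(
    curve: TrueCurve,
    reference: TrueCurve,
    slope_tolerance: float = 0.20,
    shift_grid: float = 1e-4,
    *,
    max_shift: float | None = None,
    refine_tol: float = 1e-6,
    signed: bool = False,
) -> AlphaStarResult:
    """Strain shift aligning ``curve`` with a supercontracted ``reference``.

    The curve of interest is translated toward smaller strain by
    ``delta >= 0`` (a stiffer, strain-hardened curve registers onto the
    compliant supercontracted reference at a positive shift).  The
    smallest shift for which the stress difference changes sign somewhere
    in the overlapping support *and* the local slopes at that crossing
    agree within ``slope_tolerance`` is returned, scanned on
    ``shift_grid`` and refined by bisection to ``refine_tol``.  With
    ``signed=True`` negative shifts are scanned too, in order of
    increasing magnitude.
    """
    for c in (curve, reference):
        if len(c) < 2 or np.any(np.diff(c.strain) <= 0):
            raise DomainError("curves need >= 2 points with strictly increasing strain")
    if max_shift is None:
        max_shift = float(curve.strain[-1] - reference.strain[0])
    positive = np.arange(0.0, max_shift + shift_grid / 2, shift_grid)
    if signed:
        deltas = np.empty(2 * len(positive) - 1)
        deltas[0] = 0.0
        deltas[1::2] = positive[1:]
        deltas[2::2] = -positive[1:]
    else:
        deltas = positive
    for delta in deltas:
        hit = _concurrence(reference, curve, float(delta), slope_tolerance)
        if hit is not None and hit[2]:
            if delta != 0.0:
                # refine toward the last inadmissible shift of the same sign
                sign = 1.0 if delta > 0 else -1.0
                lo, hi = abs(delta) - shift_grid, abs(delta)
                while hi - lo > refine_tol:
                    mid = 0.5 * (lo + hi)
                    h = _concurrence(reference, curve, sign * mid, slope_tolerance)
                    if h is not None and h[2]:
                        hi = mid
                    else:
                        lo = mid
                hit = _concurrence(reference, curve, sign * hi, slope_tolerance) or hit
                delta = sign * hi
            return AlphaStarResult(float(delta), hit[0], hit[1], True)
    return AlphaStarResult(None, None, None, False)
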