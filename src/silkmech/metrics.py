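"""Per-cycle mechanical metrics: modulus, proportional-limit yield, energies.

All quantities are evaluated on true stress-true strain branches.

* The elastic modulus is the initial slope of the loading branch,
  fitted by ordinary least squares over a short strain window just above
  the load onset.
* The yield stress is the proportional limit: the stress at the first
  intersection of the loading curve with a straight line anchored at
  (onset strain, 0) whose slope is 95% of the cycle's elastic modulus.
* The absorbed energy is the area below the loading branch; the
  dissipated energy is the area enclosed by the hysteresis loop; the
  recovered energy is the area enclosed between one cycle's unloading
  branch and the next cycle's reloading branch.  Energy densities are in
  MJ/m^3, numerically MPa times strain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError
from .kinematics import TrueCurve
from .segmentation import Cycle

__all__ = [
    "CycleMetrics",
    "elastic_modulus",
    "yield_stress",
    "absorbed_energy",
    "dissipated_energy",
    "recovered_energy",
    "RecoveredEnergy",
    "shoelace_area",
]

DEFAULT_MODULUS_WINDOW = 0.01
DEFAULT_YIELD_FRACTION = 0.95
MIN_FIT_POINTS = 5


@dataclass
class CycleMetrics:
    """Scalar metrics of one loading-unloading cycle."""

    index: int
    eps_init: float
    eps_max: float
    sigma_max: float
    modulus: float
    fit_r2: float
    yield_stress: float | None
    yield_strain: float | None
    absorbed: float
    dissipated: float | None
    recovered_from_prev: float | None
    concur: bool = False
    complete: bool = True


def elastic_modulus(
    loading: TrueCurve,
    window: float = DEFAULT_MODULUS_WINDOW,
    *,
    onset_threshold: float = 0.0,
) -> tuple[float, float]:
    """Initial slope of the loading branch by least squares.

    The fit uses the samples whose strain lies within ``window`` of the
    first point above ``onset_threshold`` (intercept left free).  Returns
    ``(slope in MPa, r^2)``.
    """
    strain, stress = loading.strain, loading.stress
    above = np.flatnonzero(stress > onset_threshold)
    if len(above) == 0:
        raise DomainError("no loading sample above the onset threshold")
    i0 = int(above[0])
    eps0 = strain[i0]
    mask = (strain >= eps0) & (strain <= eps0 + window)
    mask[:i0] = False
    if int(mask.sum()) < MIN_FIT_POINTS:
        # shrink to whatever span is available but keep at least MIN_FIT_POINTS
        hi = min(i0 + MIN_FIT_POINTS, len(strain))
        mask = np.zeros_like(mask)
        mask[i0:hi] = True
        if int(mask.sum()) < MIN_FIT_POINTS:
            raise DomainError("fewer than 5 points available for the modulus fit")
    res = stats.linregress(strain[mask], stress[mask])
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue) ** 2
    return float(res.slope), r2


def yield_stress(
    loading: TrueCurve,
    modulus: float,
    *,
    eps_init: float | None = None,
    fraction: float = DEFAULT_YIELD_FRACTION,
) -> tuple[float, float] | None:
    """Proportional-limit yield point.

    Intersects the loading curve with the straight line through
    ``(eps_init, 0)`` of slope ``fraction * modulus``; the first
    positive-to-nonpositive sign change of the stress difference (with
    linear interpolation between samples) is the yield point.  The curve
    leaves the anchor *above* the line (its initial slope exceeds
    ``fraction`` of itself), so requiring a strictly positive difference
    before the crossing discards the trivial contact at the anchor.

    Returns ``(yield stress MPa, yield strain)`` or ``None`` when the
    curve never comes back down to the line (no yield in the cycle).
    """
    if modulus <= 0:
        raise DomainError("modulus must be positive")
    strain, stress = loading.strain, loading.stress
    if eps_init is None:
        eps_init = float(strain[0])

    line = fraction * modulus * (strain - eps_init)
    diff = stress - line
    idx = np.flatnonzero((diff[:-1] > 0) & (diff[1:] <= 0))
    if len(idx) == 0:
        return None
    i = int(idx[0])
    # linear interpolation of the sign change between samples i and i+1
    t = diff[i] / (diff[i] - diff[i + 1])
    eps_y = strain[i] + t * (strain[i + 1] - strain[i])
    sig_y = fraction * modulus * (eps_y - eps_init)
    return float(sig_y), float(eps_y)


def absorbed_energy(loading: TrueCurve) -> float:
    """Area below the loading branch up to the cycle's maximum strain (MJ/m^3).

    Negative stresses (slack or noise) are clipped to zero before
    integration, so a zero-stress prefix contributes nothing.
    """
    if len(loading) < 2:
        raise DomainError("need at least 2 loading samples")
    if np.any(np.diff(loading.strain) < -1e-12):
        raise DomainError("loading strain must be non-decreasing")
    return float(np.trapezoid(np.clip(loading.stress, 0.0, None), loading.strain))


def shoelace_area(strain: np.ndarray, stress: np.ndarray) -> float:
    """Absolute area of the closed polygon with vertices (strain, stress)."""
    x = np.asarray(strain, dtype=float)
    y = np.asarray(stress, dtype=float)
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def dissipated_energy(cycle: Cycle) -> float | None:
    """Area enclosed by the loading and unloading branches (MJ/m^3).

    Computed as the shoelace area of the polygon traced by the loading
    branch followed by the reversed unloading branch, dropped vertically
    to zero stress at both ends so the closure runs along the strain
    axis (branches trimmed at an onset threshold would otherwise close
    along a spurious chord at threshold height).  Equals the absorbed
    energy minus the area below the unloading branch.  Returns ``None``
    for an incomplete cycle (empty unloading branch).
    """
    if len(cycle.unloading) < 2:
        return None
    x = np.concatenate([
        cycle.loading.strain,
        cycle.unloading.strain[1:],
        [cycle.unloading.strain[-1], cycle.loading.strain[0]],
    ])
    y = np.concatenate([cycle.loading.stress, cycle.unloading.stress[1:], [0.0, 0.0]])
    return shoelace_area(x, np.clip(y, 0.0, None))


@dataclass
class RecoveredEnergy:
    """Energy recovered between consecutive cycles (MJ/m^3) and a
    concurrence flag for the case in which the unloading and reloading
    branches retrace each other (fully recovered hysteresis loop)."""

    value: float
    concur: bool


def recovered_energy(
    prev: Cycle,
    nxt: Cycle,
    *,
    concur_rtol: float = 1e-3,
) -> RecoveredEnergy:
    """Area enclosed between ``prev``'s unloading and ``nxt``'s reloading.

    Both branches are interpolated on the union of their strain samples
    over ``[nxt.eps_init, prev.eps_max]`` and extended with zero stress
    beyond their own zero-stress ends, which closes the lens at the
    bottom.  When the reloading branch starts below the strain at which
    the previous unloading went slack, the enclosed area is the energy
    the relaxed fiber made available again.

    ``concur`` is set when the two branches coincide within
    ``concur_rtol`` of the cycle stress scale (the limit in which the
    loop energy is fully recovered).
    """
    if len(prev.unloading) < 2 or len(nxt.loading) < 2:
        raise DomainError("both branches must be non-empty")
    # unloading runs from eps_max down; flip to ascending strain
    u_eps = prev.unloading.strain[::-1]
    u_sig = np.clip(prev.unloading.stress[::-1], 0.0, None)
    order = np.argsort(u_eps, kind="stable")
    u_eps, u_sig = u_eps[order], u_sig[order]
    l_eps = nxt.loading.strain
    l_sig = np.clip(nxt.loading.stress, 0.0, None)

    lo = float(nxt.eps_init)
    hi = float(prev.eps_max)
    if hi <= max(lo, float(l_eps[0])):
        warnings.warn("branches do not overlap in strain; recovered energy set to 0", stacklevel=2)
        return RecoveredEnergy(0.0, False)

    grid = np.unique(np.concatenate([u_eps, l_eps]))
    grid = grid[(grid >= lo) & (grid <= hi)]
    u = np.interp(grid, u_eps, u_sig, left=0.0, right=float(u_sig[-1]))
    l = np.interp(grid, l_eps, l_sig, left=0.0, right=float(l_sig[-1]))
    area = abs(float(np.trapezoid(l - u, grid)))
    scale = max(prev.sigma_max, nxt.sigma_max)
    concur = bool(np.max(np.abs(l - u)) <= concur_rtol * scale) if scale > 0 else True
    return RecoveredEnergy(area, concur)
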