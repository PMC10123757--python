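"""Engineering and true stress-strain conversion.

Engineering magnitudes are referenced to the supercontracted state:
``s = F / A0`` and ``e = dL / L0``.  True magnitudes follow from the
constant-volume hypothesis:

.. math::

    \\sigma = s\\,(1 + e), \\qquad \\varepsilon = \\ln(1 + e).

The inverse map (``e = exp(eps) - 1``, ``s = sigma / (1 + e)``) is exact and
is used by the synthetic generator to emit machine records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .records import FiberGeometry, TensileRecord

__all__ = [
    "EngCurve",
    "TrueCurve",
    "engineering_from_record",
    "true_from_engineering",
    "engineering_from_true",
    "record_from_engineering",
    "nominal_strain_rate",
]

# 1 N / um^2 = 1e12 Pa; stress is carried in MPa.
_N_PER_UM2_TO_MPA = 1.0e6


@dataclass
class EngCurve:
    """Engineering stress (MPa) vs engineering strain (dimensionless)."""

    strain: np.ndarray
    stress: np.ndarray
    time: np.ndarray | None = None
    sample_id: str = "sample"

    def __post_init__(self):
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.time is not None:
            self.time = np.asarray(self.time, dtype=float)
            if len(self.time) != len(self.strain):
                raise DomainError("time and strain must have equal length")
        if len(self.strain) != len(self.stress):
            raise DomainError("strain and stress must have equal length")
        if not (np.all(np.isfinite(self.strain)) and np.all(np.isfinite(self.stress))):
            raise DomainError("non-finite values in curve")
        if np.any(self.strain <= -1.0):
            raise DomainError("engineering strain must exceed -1")

    def __len__(self) -> int:
        return len(self.strain)


@dataclass
class TrueCurve:
    """True stress (MPa) vs true strain (dimensionless, referenced to L0)."""

    strain: np.ndarray
    stress: np.ndarray
    time: np.ndarray | None = None
    sample_id: str = "sample"

    def __post_init__(self):
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.time is not None:
            self.time = np.asarray(self.time, dtype=float)
            if len(self.time) != len(self.strain):
                raise DomainError("time and strain must have equal length")
        if len(self.strain) != len(self.stress):
            raise DomainError("strain and stress must have equal length")
        if not (np.all(np.isfinite(self.strain)) and np.all(np.isfinite(self.stress))):
            raise DomainError("non-finite values in curve")

    def __len__(self) -> int:
        return len(self.strain)


def engineering_from_record(record: TensileRecord, geometry: FiberGeometry) -> EngCurve:
    """Convert a machine record to an engineering stress-strain curve.

    ``s = F / A0`` (N over um^2, reported in MPa) and ``e = dL / L0``.
    Negative displacements (slack) pass through unchanged.
    """
    a0 = geometry.area_sc
    l0 = geometry.length_sc
    if a0 <= 0 or l0 <= 0:
        raise DomainError("geometry must have positive area and length")
    stress = record.force / a0 * _N_PER_UM2_TO_MPA
    strain = record.displacement / l0
    return EngCurve(strain=strain, stress=stress, time=record.time.copy(), sample_id=record.sample_id)


def true_from_engineering(curve: EngCurve) -> TrueCurve:
    """Apply the constant-volume conversion ``sigma = s(1+e)``, ``eps = ln(1+e)``."""
    if np.any(curve.strain <= -1.0):
        raise DomainError("engineering strain must exceed -1")
    one_plus_e = 1.0 + curve.strain
    return TrueCurve(
        strain=np.log(one_plus_e),
        stress=curve.stress * one_plus_e,
        time=None if curve.time is None else curve.time.copy(),
        sample_id=curve.sample_id,
    )


def engineering_from_true(curve: TrueCurve) -> EngCurve:
    """Inverse of :func:`true_from_engineering` (exact)."""
    e = np.expm1(curve.strain)
    return EngCurve(
        strain=e,
        stress=curve.stress / (1.0 + e),
        time=None if curve.time is None else curve.time.copy(),
        sample_id=curve.sample_id,
    )


def record_from_engineering(curve: EngCurve, geometry: FiberGeometry, sample_id: str | None = None) -> TensileRecord:
    """Emit a machine record from an engineering curve (generator back-end)."""
    if curve.time is None:
        raise DomainError("a time base is required to emit a machine record")
    return TensileRecord(
        time=curve.time,
        displacement=curve.strain * geometry.length_sc,
        force=curve.stress * geometry.area_sc / _N_PER_UM2_TO_MPA,
        sample_id=sample_id or curve.sample_id,
    )


def nominal_strain_rate(crosshead_speed: float, gauge_length: float) -> float:
    """Nominal strain rate (1/min) from crosshead speed (mm/min) and gauge (mm)."""
    if crosshead_speed <= 0 or gauge_length <= 0:
        raise DomainError("speed and gauge length must be strictly positive")
    return crosshead_speed / gauge_length
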