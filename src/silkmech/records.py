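"""Raw tensile-machine records, fiber geometry, and results-table I/O.

A tensile test of a single silk fiber is recorded by the machine as a
time / crosshead-displacement / force series.  The specimen geometry is
carried separately: the cross-sectional area is measured on the
forcibly-silked fiber (``A_FS``) from micrographs, while stresses and
strains are referenced to the state after maximum supercontraction
(length ``L0``, area ``A0``).  Because supercontraction conserves fiber
volume, ``A0 = A_FS * L_FS / L0``.

Canonical units throughout the package: force N, length mm, time s,
area um^2, stress MPa, energy density MJ/m^3 (numerically equal to
MPa times strain).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import DomainError, FormatError, InsufficientDataError

__all__ = [
    "TensileRecord",
    "FiberGeometry",
    "ResultsTable",
    "supercontracted_area",
    "read_tensile_record",
    "read_geometry",
    "write_results",
    "read_results",
]

#: Default column names expected in a machine export.
DEFAULT_COLUMNS = {"time": "time_s", "displacement": "displacement_mm", "force": "force_N"}

#: Column order of the per-cycle results table.
RESULTS_COLUMNS = [
    "cycle",
    "eps_init",
    "eps_max",
    "sigma_max_MPa",
    "modulus_MPa",
    "fit_r2",
    "yield_MPa",
    "yield_strain",
    "absorbed_MJm3",
    "dissipated_MJm3",
    "recovered_MJm3",
    "concur",
    "complete",
]


def supercontracted_area(area_fs: float, length_fs: float, length_sc: float) -> float:
    """Cross-sectional area after maximum supercontraction, by volume conservation.

    Parameters
    ----------
    area_fs : float
        Cross-sectional area of the forcibly-silked fiber (um^2).
    length_fs : float
        Length of the forcibly-silked fiber (mm).
    length_sc : float
        Length after maximum supercontraction (mm).

    Returns
    -------
    float
        Supercontracted area ``A0 = A_FS * L_FS / L0`` in um^2.
    """
    if area_fs <= 0 or length_fs <= 0 or length_sc <= 0:
        raise DomainError("geometry values must be strictly positive")
    if length_sc > length_fs:
        warnings.warn(
            "length_sc > length_fs: fiber lengthened rather than supercontracted",
            stacklevel=2,
        )
    return area_fs * length_fs / length_sc


@dataclass(frozen=True)
class FiberGeometry:
    """Specimen geometry of a single fiber.

    Attributes
    ----------
    area_fs : float
        Forcibly-silked cross-sectional area (um^2).
    length_fs : float
        Forcibly-silked length (mm).
    length_sc : float
        Gauge length after maximum supercontraction, ``L0`` (mm).
    """

    area_fs: float
    length_fs: float
    length_sc: float

    def __post_init__(self):
        if self.area_fs <= 0 or self.length_fs <= 0 or self.length_sc <= 0:
            raise DomainError("geometry values must be strictly positive")

    @property
    def area_sc(self) -> float:
        """Supercontracted cross-section ``A0`` (um^2)."""
        return supercontracted_area(self.area_fs, self.length_fs, self.length_sc)

    @classmethod
    def from_diameter(cls, diameter_fs: float, length_fs: float, length_sc: float) -> "FiberGeometry":
        """Build from a forcibly-silked diameter (um), assuming a circular section."""
        if diameter_fs <= 0:
            raise DomainError("diameter must be strictly positive")
        return cls(math.pi * (diameter_fs / 2.0) ** 2, length_fs, length_sc)

    def to_dict(self) -> dict:
        return {
            "area_fs_um2": self.area_fs,
            "length_fs_mm": self.length_fs,
            "length_sc_mm": self.length_sc,
        }


@dataclass
class TensileRecord:
    """Raw machine record: time (s), crosshead displacement (mm), force (N).

    The crosshead displacement stands in for the extension of the fiber
    (the fiber compliance dominates the load train, so no extensometer
    correction is applied).
    """

    time: np.ndarray
    displacement: np.ndarray
    force: np.ndarray
    sample_id: str = "sample"

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        n = len(self.time)
        if len(self.displacement) != n or len(self.force) != n:
            raise FormatError("time, displacement and force must have equal length")
        if n < 2:
            raise InsufficientDataError("a tensile record needs at least 2 samples")
        for name, arr in (("time", self.time), ("displacement", self.displacement), ("force", self.force)):
            if not np.all(np.isfinite(arr)):
                raise FormatError(f"non-finite values in {name}")
        if np.any(np.diff(self.time) <= 0):
            raise FormatError("time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time)

    def to_frame(self, columns: dict | None = None) -> pd.DataFrame:
        cols = dict(DEFAULT_COLUMNS, **(columns or {}))
        return pd.DataFrame(
            {
                cols["time"]: self.time,
                cols["displacement"]: self.displacement,
                cols["force"]: self.force,
            }
        )

    def write(self, path, *, delimiter: str = ",", columns: dict | None = None) -> None:
        self.to_frame(columns).to_csv(path, sep=delimiter, index=False, float_format="%.12g")


def read_tensile_record(
    path,
    *,
    delimiter: str = ",",
    columns: dict | None = None,
    sample_id: str | None = None,
) -> TensileRecord:
    """Read a delimiter-separated machine record.

    ``columns`` maps the roles ``time`` / ``displacement`` / ``force`` to the
    header names used by the export (defaults: ``time_s``, ``displacement_mm``,
    ``force_N``).  Rows with non-finite entries are dropped with a warning;
    duplicated time stamps keep the first occurrence.
    """
    cols = dict(DEFAULT_COLUMNS, **(columns or {}))
    df = pd.read_csv(path, sep=delimiter)
    for role in ("time", "displacement", "force"):
        if cols[role] not in df.columns:
            raise FormatError(f"missing column {cols[role]!r} (role: {role})")
    df = df[[cols["time"], cols["displacement"], cols["force"]]].apply(pd.to_numeric, errors="coerce")
    n_raw = len(df)
    df = df.dropna()
    df = df[np.isfinite(df).all(axis=1)]
    n_bad = n_raw - len(df)
    if n_bad:
        warnings.warn(f"dropped {n_bad} rows with non-finite entries", stacklevel=2)
    dup = df[cols["time"]].duplicated(keep="first")
    if dup.any():
        warnings.warn(f"dropped {int(dup.sum())} rows with duplicated time stamps", stacklevel=2)
        df = df[~dup]
    if len(df) < 2:
        raise InsufficientDataError(f"fewer than 2 valid rows in {path}")
    return TensileRecord(
        time=df[cols["time"]].to_numpy(),
        displacement=df[cols["displacement"]].to_numpy(),
        force=df[cols["force"]].to_numpy(),
        sample_id=sample_id or str(path),
    )


def read_geometry(path) -> FiberGeometry:
    """Read a geometry sidecar (YAML-style key: value text).

    Accepts either ``area_fs_um2`` or ``diameter_fs_um`` (circular section),
    plus ``length_fs_mm`` and ``length_sc_mm``.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise FormatError(f"geometry sidecar {path} is not a key/value mapping")
    try:
        length_fs = float(data["length_fs_mm"])
        length_sc = float(data["length_sc_mm"])
    except KeyError as exc:
        raise FormatError(f"geometry sidecar missing key {exc.args[0]!r}") from None
    if "area_fs_um2" in data:
        return FiberGeometry(float(data["area_fs_um2"]), length_fs, length_sc)
    if "diameter_fs_um" in data:
        return FiberGeometry.from_diameter(float(data["diameter_fs_um"]), length_fs, length_sc)
    raise FormatError("geometry sidecar needs area_fs_um2 or diameter_fs_um")


def write_geometry(geometry: FiberGeometry, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(geometry.to_dict(), fh, sort_keys=False)


@dataclass
class ResultsTable:
    """Per-cycle metrics keyed by cycle index (contiguous from 1)."""

    frame: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=RESULTS_COLUMNS))

    def __post_init__(self):
        missing = [c for c in RESULTS_COLUMNS if c not in self.frame.columns]
        if missing:
            raise FormatError(f"results table missing columns {missing}")
        self.frame = self.frame[RESULTS_COLUMNS].reset_index(drop=True)
        idx = self.frame["cycle"].to_numpy()
        if len(idx) and (len(set(idx)) != len(idx) or not np.array_equal(idx, np.arange(1, len(idx) + 1))):
            raise FormatError("cycle indices must be unique and contiguous from 1")

    def __len__(self) -> int:
        return len(self.frame)

    def write(self, path, *, delimiter: str = ",") -> None:
        write_results(self, path, delimiter=delimiter)

    @classmethod
    def read(cls, path, *, delimiter: str = ",") -> "ResultsTable":
        return read_results(path, delimiter=delimiter)


def write_results(table: ResultsTable, path, *, delimiter: str = ",") -> None:
    """Write the per-cycle results table as delimiter-separated text."""
    table.frame.to_csv(path, sep=delimiter, index=False, float_format="%.12g")


def read_results(path, *, delimiter: str = ",") -> ResultsTable:
    df = pd.read_csv(path, sep=delimiter)
    if df.empty and list(df.columns) == RESULTS_COLUMNS:
        return ResultsTable()
    for col in ("concur", "complete"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    if "cycle" in df.columns:
        df["cycle"] = df["cycle"].astype(int)
    return ResultsTable(df)
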