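"""Least-squares trends of modulus and yield stress versus cycle onset strain."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError
from .records import ResultsTable

__all__ = ["TrendFit", "linear_trend", "endpoint_summary"]


@dataclass
class TrendFit:
    """Ordinary least-squares line y = slope * x + intercept."""

    slope: float
    intercept: float
    r2: float
    n: int

    def value_at(self, x: float) -> float:
        return self.slope * x + self.intercept


def linear_trend(x, y) -> TrendFit:
    """OLS fit of y (MPa) against x (strain).

    A zero-variance response is fitted as a flat line with ``r2 = 0`` by
    convention; degenerate x (all equal) raises a domain error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise DomainError("need at least 2 (x, y) pairs")
    if np.ptp(x) == 0:
        raise DomainError("x values are all equal; trend undefined")
    if np.ptp(y) == 0:
        return TrendFit(0.0, float(y[0]), 0.0, len(x))
    res = stats.linregress(x, y)
    return TrendFit(float(res.slope), float(res.intercept), float(res.rvalue) ** 2, len(x))


def endpoint_summary(metrics: ResultsTable, fit_modulus: TrendFit | None, fit_yield: TrendFit | None) -> dict:
    """Fitted modulus and yield stress at the first and last cycles' onset strains.

    Endpoints are read off the fitted lines, not the raw per-cycle values.
    A single-cycle table has no trend; its raw values are reported with a
    ``degenerate`` flag.
    """
    df = metrics.frame
    if df.empty:
        raise DomainError("empty results table")
    eps_first = float(df["eps_init"].iloc[0])
    eps_last = float(df["eps_init"].iloc[-1])
    out = {
        "onset_first": eps_first,
        "onset_last": eps_last,
        "n_cycles": int(len(df)),
        "degenerate": len(df) < 2,
    }
    if len(df) < 2:
        out["modulus_first_MPa"] = out["modulus_last_MPa"] = float(df["modulus_MPa"].iloc[0])
        y = df["yield_MPa"].iloc[0]
        out["yield_first_MPa"] = out["yield_last_MPa"] = None if np.isnan(y) else float(y)
        return out
    if fit_modulus is not None:
        out["modulus_first_MPa"] = fit_modulus.value_at(eps_first)
        out["modulus_last_MPa"] = fit_modulus.value_at(eps_last)
        out["modulus_trend_r2"] = fit_modulus.r2
    if fit_yield is not None:
        out["yield_first_MPa"] = fit_yield.value_at(eps_first)
        out["yield_last_MPa"] = fit_yield.value_at(eps_last)
        out["yield_trend_r2"] = fit_yield.r2
    return out
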