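"""Split a multi-cycle true stress-strain record into loading-unloading cycles.

A cyclic test alternates: take up slack, load to the target strain, unload
until the fiber goes slack again, hold the grips at the gauge length while
the fiber relaxes, repeat.  Only the portions where the fiber actually
carries load belong to a cycle; slack travel and relaxation holds sit at
(near-)zero stress and are discarded.

Cycle boundaries are found from contiguous runs of samples whose stress
exceeds an onset threshold.  Each run is extended by one sample on either
side so that every loading branch starts at, and every unloading branch
ends at, the last/first sample at or below the threshold.  The split point
between the two branches is the per-cycle stress maximum (later index on
ties).  An optional time-gap cue additionally cuts runs across long holds,
for records in which the stress never returns below the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, SegmentationError
from .kinematics import TrueCurve

__all__ = ["Cycle", "segment_cycles", "onset_strain", "default_onset_threshold"]

#: Minimum samples per branch for metrics to be meaningful.
DEFAULT_MIN_POINTS = 10

#: A hold of at least this many seconds at near-zero load is a boundary cue.
DEFAULT_HOLD_GAP_S = 60.0


@dataclass
class Cycle:
    """One loading-unloading cycle in true stress-strain coordinates."""

    index: int
    loading: TrueCurve
    unloading: TrueCurve
    eps_init: float
    eps_max: float
    sigma_max: float
    complete: bool = True

    def __post_init__(self):
        if self.eps_init > self.eps_max + 1e-12:
            raise DomainError("eps_init must not exceed eps_max")


def default_onset_threshold(stress: np.ndarray, absolute: float = 0.5, relative: float = 0.01) -> float:
    """Mixed absolute/relative rule: max(absolute, relative * global stress max)."""
    smax = float(np.max(stress)) if len(stress) else 0.0
    return max(absolute, relative * smax)


def segment_cycles(
    curve: TrueCurve,
    onset_threshold: float | None = None,
    min_points: int = DEFAULT_MIN_POINTS,
    *,
    use_time_gaps: bool = False,
    hold_gap_s: float = DEFAULT_HOLD_GAP_S,
) -> list[Cycle]:
    """Segment a continuous record into ordered loading-unloading cycles.

    Parameters
    ----------
    curve : TrueCurve
        Full-test true stress-strain series (time optional).
    onset_threshold : float, optional
        Stress level (MPa) separating "loaded" from "slack"; defaults to
        ``max(0.5 MPa, 1% of the global stress maximum)``.
    min_points : int
        Runs shorter than this are ignored as noise; branches shorter than
        this flag the cycle incomplete.
    use_time_gaps : bool
        Additionally cut cycles at time gaps >= ``hold_gap_s`` (for logs in
        which stress does not drop below the threshold between cycles).

    Returns
    -------
    list of :class:`Cycle`
        Ordered by time.  A final monotone ramp yields a cycle with an
        empty unloading branch, flagged incomplete.
    """
    if len(curve) < max(2, min_points):
        raise SegmentationError("record shorter than min_points")
    if curve.time is not None and np.any(np.diff(curve.time) < 0):
        raise SegmentationError("time must be non-decreasing")

    stress = curve.stress
    thr = default_onset_threshold(stress) if onset_threshold is None else float(onset_threshold)

    above = stress > thr
    if not np.any(above):
        return []

    # contiguous runs of above-threshold samples
    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1

    # debounce: noise makes the stress hover around the threshold near the
    # onset and the unloading tail, splitting a cycle's run.  Merge across
    # gaps shorter than min_points unless the later run reaches a new strain
    # maximum (then it is a genuine next loading, not a tail fragment).
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if (
            merged
            and s - merged[-1][1] - 1 < min_points
            and curve.strain[e] < curve.strain[merged[-1][1]]
        ):
            merged[-1][1] = int(e)
        else:
            merged.append([int(s), int(e)])
    runs = [(s, e) for s, e in merged if e - s + 1 >= min_points]

    if use_time_gaps and curve.time is not None:
        cut_runs = []
        for s, e in runs:
            gaps = np.flatnonzero(np.diff(curve.time[s : e + 1]) >= hold_gap_s)
            lo = s
            for g in gaps:
                cut_runs.append((lo, s + int(g)))
                lo = s + int(g) + 1
            cut_runs.append((lo, e))
        runs = [(s, e) for s, e in cut_runs if e - s + 1 >= min_points]

    cycles: list[Cycle] = []
    for k, (s, e) in enumerate(runs, start=1):
        lo = max(s - 1, 0)
        hi = min(e + 1, len(stress) - 1)
        # keep exactly one at/below-threshold sample at each end, and never
        # reach into a neighbouring run
        if cycles and lo <= runs[k - 2][1]:
            lo = s
        sl = slice(lo, hi + 1)
        seg_strain = curve.strain[sl]
        seg_stress = stress[sl]
        seg_time = None if curve.time is None else curve.time[sl]

        amax = int(np.flatnonzero(seg_stress == seg_stress.max())[-1])
        # under stress noise the argmax may sit a sample or two past the
        # strain turning point; keep the monotone subsequence of each branch
        keep_l = seg_strain[: amax + 1] >= np.maximum.accumulate(seg_strain[: amax + 1])
        keep_u = seg_strain[amax:] <= np.minimum.accumulate(seg_strain[amax:])
        loading = TrueCurve(
            seg_strain[: amax + 1][keep_l],
            seg_stress[: amax + 1][keep_l],
            time=None if seg_time is None else seg_time[: amax + 1][keep_l],
            sample_id=curve.sample_id,
        )
        unloading = TrueCurve(
            seg_strain[amax:][keep_u],
            seg_stress[amax:][keep_u],
            time=None if seg_time is None else seg_time[amax:][keep_u],
            sample_id=curve.sample_id,
        )
        complete = len(unloading) >= min_points and seg_stress[-1] <= thr
        cycles.append(
            Cycle(
                index=k,
                loading=loading,
                unloading=unloading,
                eps_init=onset_strain_of_branch(loading, thr),
                eps_max=float(max(seg_strain.max(), seg_strain[amax])),
                sigma_max=float(seg_stress[amax]),
                complete=complete,
            )
        )
    return cycles


def onset_strain_of_branch(loading: TrueCurve, onset_threshold: float, sustain: int = 3) -> float:
    """Strain at which the branch departs from (near-)zero load.

    Returns the strain of the last sample at or below the threshold before
    the first sustained exceedance; if the branch already starts above the
    threshold, its first strain.
    """
    if len(loading) == 0:
        raise DomainError("empty loading branch")
    stress = loading.stress
    above = stress > onset_threshold
    if not np.any(above):
        raise DomainError("no sample above the onset threshold")
    n = len(stress)
    idx = None
    for i in np.flatnonzero(above):
        j = min(n, i + sustain)
        if np.all(above[i:j]):
            idx = int(i)
            break
    if idx is None:
        idx = int(np.flatnonzero(above)[0])
    if idx == 0:
        return float(loading.strain[0])
    return float(loading.strain[idx - 1])


def onset_strain(cycle: Cycle, onset_threshold: float) -> float:
    """Onset strain of a cycle's loading branch (see :func:`onset_strain_of_branch`)."""
    return onset_strain_of_branch(cycle.loading, onset_threshold)


def concatenate_cycles(cycles: list[Cycle]) -> TrueCurve:
    """Rebuild a continuous curve from cycle branches (loading then unloading).

    Used for idempotence checks: re-segmenting the result reproduces the
    same cycles.
    """
    if not cycles:
        raise SegmentationError("no cycles to concatenate")
    strain, stress = [], []
    for c in cycles:
        strain.append(c.loading.strain)
        stress.append(c.loading.stress)
        if len(c.unloading) > 1:
            strain.append(c.unloading.strain[1:])
            stress.append(c.unloading.stress[1:])
    s = np.concatenate(strain)
    return TrueCurve(s, np.concatenate(stress), time=np.arange(len(s), dtype=float), sample_id=cycles[0].loading.sample_id)
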