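"""Descriptive analytics of trajectory ensembles.

Rise and fall periods summarize response dynamics: within each monotone
segment of a trajectory (delimited by interior extrema), the rise (fall)
period is the time needed to traverse from a low to a high fraction of
the segment's span — the control-theoretic 10-90% rise-time convention
by default. Trajectory densities are per-time-step histograms over the
ensemble with pointwise central quantile envelopes, and relative
adaptations normalize each member to its own untreated (t = 0) value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory import TrajectoryEnsemble

__all__ = [
    "PeriodSummary",
    "DensityMap",
    "rise_fall_periods",
    "summarize_periods",
    "trajectory_density",
    "relative_adaptation",
]


@dataclass
class PeriodSummary:
    quantity: str
    event: str  # 'rise' or 'fall'
    durations: np.ndarray  # one per contributing member
    n_missing: int  # members without this event

    @property
    def median(self) -> float:
        return float(np.median(self.durations)) if self.durations.size else np.nan

    @property
    def mad(self) -> float:
        if not self.durations.size:
            return np.nan
        return float(np.median(np.abs(self.durations - np.median(self.durations))))


@dataclass
class DensityMap:
    quantity: str
    times: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray  # (n_bins, N+1)
    envelope_lower: np.ndarray  # (N+1,)
    envelope_upper: np.ndarray
    coverage: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.counts,
            index=pd.Index(self.bin_edges[:-1], name="bin_lower"),
            columns=pd.Index(np.round(self.times, 10), name="time"),
        )
        return df


def _segment_breakpoints(values: np.ndarray, prominence_frac: float) -> list[int]:
    """Indices of interior extrema delimiting monotone segments.

    Candidate extrema are slope sign changes; extrema whose excursion
    relative to both neighboring breakpoints is below ``prominence_frac``
    of the trajectory's global range are discarded (noise filter).
    """
    n = len(values)
    d = np.diff(values)
    candidates = [0]
    for i in range(1, n - 1):
        left = d[i - 1]
        right = d[i]
        if left == 0 and right == 0:
            continue
        if left * right < 0 or (left == 0) != (right == 0):
            candidates.append(i)
    candidates.append(n - 1)
    vrange = float(values.max() - values.min())
    if vrange == 0:
        return []
    thresh = prominence_frac * vrange
    # iteratively drop the least prominent interior breakpoint
    changed = True
    while changed and len(candidates) > 2:
        changed = False
        for k in range(1, len(candidates) - 1):
            i_prev, i, i_next = candidates[k - 1], candidates[k], candidates[k + 1]
            prom = min(
                abs(values[i] - values[i_prev]), abs(values[i] - values[i_next])
            )
            if prom < thresh:
                del candidates[k]
                changed = True
                break
    return candidates


def rise_fall_periods(
    values: np.ndarray,
    times: np.ndarray,
    low_frac: float = 0.1,
    high_frac: float = 0.9,
    *,
    prominence_frac: float = 0.01,
) -> list[tuple[str, float]]:
    """Rise/fall durations of the monotone segments of one trajectory.

    Within each monotone segment between consecutive extrema, the
    crossing times of ``start + low_frac * span`` and
    ``start + high_frac * span`` are located by linear interpolation
    between grid points; the duration is their difference. Returns a
    list of ('rise' | 'fall', duration) in time order; a constant
    trajectory yields [].
    """
    if not 0.0 < low_frac < high_frac < 1.0:
        raise ValueError("need 0 < low_frac < high_frac < 1")
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    breakpoints = _segment_breakpoints(values, prominence_frac)
    events: list[tuple[str, float]] = []
    for a, b in zip(breakpoints[:-1], breakpoints[1:]):
        v0, v1 = values[a], values[b]
        if v1 == v0:
            continue
        lo_level = v0 + low_frac * (v1 - v0)
        hi_level = v0 + high_frac * (v1 - v0)
        t_lo = _first_crossing(times, values, a, b, lo_level)
        t_hi = _first_crossing(times, values, a, b, hi_level)
        if t_lo is None or t_hi is None:
            continue
        events.append(("rise" if v1 > v0 else "fall", t_hi - t_lo))
    return events


def _first_crossing(times, values, a, b, level) -> float | None:
    """First time in segment [a, b] at which the trajectory meets ``level``."""
    for i in range(a, b):
        y0, y1 = values[i], values[i + 1]
        if y0 == level:
            return float(times[i])
        if (y0 - level) * (y1 - level) < 0 or y1 == level:
            frac = (level - y0) / (y1 - y0)
            return float(times[i] + frac * (times[i + 1] - times[i]))
    return None


def summarize_periods(
    ensemble: TrajectoryEnsemble,
    quantities: list[str],
    low_frac: float = 0.1,
    high_frac: float = 0.9,
    *,
    prominence_frac: float = 0.01,
) -> list[PeriodSummary]:
    """Median +/- MAD of rise and fall durations across ensemble members.

    Per member and event type the dominant event (the one belonging to
    the largest-span segment, approximated by the longest duration) is
    used; members lacking an event type are excluded and counted.
    """
    summaries = []
    times = ensemble.times
    for q in quantities:
        mat = ensemble.quantity_matrix(q)
        per_event: dict[str, list[float]] = {"rise": [], "fall": []}
        missing = {"rise": 0, "fall": 0}
        for row in mat:
            events = rise_fall_periods(
                row, times, low_frac, high_frac, prominence_frac=prominence_frac
            )
            for etype in ("rise", "fall"):
                durs = [d for e, d in events if e == etype]
                if durs:
                    per_event[etype].append(max(durs))
                else:
                    missing[etype] += 1
        for etype in ("rise", "fall"):
            summaries.append(
                PeriodSummary(
                    quantity=q,
                    event=etype,
                    durations=np.asarray(per_event[etype]),
                    n_missing=missing[etype],
                )
            )
    return summaries


def trajectory_density(
    ensemble: TrajectoryEnsemble,
    quantity: str,
    n_value_bins: int = 50,
    coverage: float = 0.95,
) -> DensityMap:
    """Per-time-step histogram of member values plus central envelope.

    Bin edges are shared across time steps (global value range); the
    envelope is the pointwise empirical [(1-coverage)/2, (1+coverage)/2]
    quantile band, so coverage=1 reduces to the per-step min/max.
    """
    if len(ensemble) < 2:
        raise ValueError("density needs at least 2 members")
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must lie in (0, 1]")
    mat = ensemble.quantity_matrix(quantity)
    lo, hi = float(mat.min()), float(mat.max())
    if hi == lo:
        hi = lo + max(abs(lo), 1.0) * 1e-12
    edges = np.linspace(lo, hi, n_value_bins + 1)
    n_steps = mat.shape[1]
    counts = np.empty((n_value_bins, n_steps), dtype=int)
    for n in range(n_steps):
        counts[:, n], _ = np.histogram(mat[:, n], bins=edges)
    q_lo, q_hi = (1.0 - coverage) / 2.0, (1.0 + coverage) / 2.0
    if coverage == 1.0:
        lower, upper = mat.min(axis=0), mat.max(axis=0)
    else:
        lower = np.quantile(mat, q_lo, axis=0)
        upper = np.quantile(mat, q_hi, axis=0)
    return DensityMap(
        quantity=quantity,
        times=ensemble.times,
        bin_edges=edges,
        counts=counts,
        envelope_lower=lower,
        envelope_upper=upper,
        coverage=coverage,
    )


def relative_adaptation(
    ensemble: TrajectoryEnsemble, quantity: str
) -> tuple[np.ndarray, list[int]]:
    """Member trajectories normalized to their own untreated (t=0) value.

    Returns (matrix of shape (n_kept, N+1), indices of excluded members
    whose t=0 value is zero).
    """
    mat = ensemble.quantity_matrix(quantity)
    base = mat[:, 0]
    excluded = [int(i) for i in np.flatnonzero(base == 0)]
    kept = np.flatnonzero(base != 0)
    return mat[kept] / base[kept, None], excluded
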