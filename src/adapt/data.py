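"""Longitudinal snapshot data and Monte Carlo spline interpolants.

Phenotype snapshots — per-observable tables of (time, mean, SD) — are
turned into continuous optimization targets by fitting cubic smoothing
splines through the means. Experimental uncertainty is propagated by a
Monte Carlo scheme: each resample draws new "means" from Gaussian(mean,
SD) per cell and refits the spline, yielding a collection of interpolants
d(t) whose spread reflects the data noise. The SD envelope sigma(t) is
interpolated piecewise-linearly between measurement times and floored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline, make_smoothing_spline

__all__ = [
    "ObservableSeries",
    "ExperimentalDataset",
    "InterpolantSet",
    "sample_replicate",
    "fit_smoothing_spline",
    "build_interpolant_collection",
]

#: additive floor applied to standard deviations on load
DEFAULT_SD_ABS_FLOOR = 1e-6
#: relative floor: sd >= rel_floor * |mean|
DEFAULT_SD_REL_FLOOR = 1e-3
#: positivity floor for clamped Gaussian draws of positive observables
DEFAULT_VALUE_FLOOR = 1e-9


@dataclass(frozen=True)
class ObservableSeries:
    """Snapshot series for one observable: times (days), means, SDs."""

    name: str
    times: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    n_replicates: int | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        m = np.asarray(self.means, dtype=float)
        s = np.asarray(self.sds, dtype=float)
        if not (len(t) == len(m) == len(s)):
            raise ValueError(f"{self.name}: times/means/sds length mismatch")
        if len(np.unique(t)) != len(t) or np.any(np.diff(t) <= 0):
            raise ValueError(f"{self.name}: times must be unique and sorted")
        if np.any(s < 0):
            raise ValueError(f"{self.name}: negative standard deviation")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "means", m)
        object.__setattr__(self, "sds", s)


class ExperimentalDataset:
    """Collection of observable snapshot series sharing a treatment horizon.

    SDs are floored on construction at ``max(abs_floor, rel_floor * |mean|)``
    so weighted costs are always well defined.
    """

    def __init__(
        self,
        series: Sequence[ObservableSeries],
        *,
        sd_abs_floor: float = DEFAULT_SD_ABS_FLOOR,
        sd_rel_floor: float = DEFAULT_SD_REL_FLOOR,
        positive: bool = True,
    ):
        if not series:
            raise ValueError("dataset needs at least one observable")
        floored = []
        for s in series:
            floor = np.maximum(sd_abs_floor, sd_rel_floor * np.abs(s.means))
            floored.append(
                ObservableSeries(
                    s.name, s.times, s.means, np.maximum(s.sds, floor), s.n_replicates
                )
            )
        self._series: dict[str, ObservableSeries] = {s.name: s for s in floored}
        if len(self._series) != len(series):
            raise ValueError("duplicate observable names")
        self.sd_abs_floor = sd_abs_floor
        self.sd_rel_floor = sd_rel_floor
        self.positive = positive

    @property
    def observables(self) -> tuple[str, ...]:
        return tuple(self._series)

    def __getitem__(self, name: str) -> ObservableSeries:
        return self._series[name]

    def __iter__(self):
        return iter(self._series.values())

    def __len__(self) -> int:
        return len(self._series)

    @property
    def t_max(self) -> float:
        return max(float(s.times[-1]) for s in self)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self:
            for t, m, sd in zip(s.times, s.means, s.sds):
                rows.append(
                    {"observable": s.name, "time": t, "mean": m, "sd": sd,
                     "n": s.n_replicates}
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kwargs) -> "ExperimentalDataset":
        required = {"observable", "time", "mean", "sd"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"dataset table missing columns: {sorted(missing)}")
        series = []
        for name, grp in df.groupby("observable", sort=False):
            grp = grp.sort_values("time")
            n = None
            if "n" in grp.columns and grp["n"].notna().all():
                n = int(grp["n"].iloc[0])
            series.append(
                ObservableSeries(
                    str(name),
                    grp["time"].to_numpy(float),
                    grp["mean"].to_numpy(float),
                    grp["sd"].to_numpy(float),
                    n,
                )
            )
        return cls(series, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "ExperimentalDataset":
        return cls.from_frame(pd.read_csv(path), **kwargs)


def sample_replicate(
    dataset: ExperimentalDataset,
    rng: np.random.Generator,
    *,
    value_floor: float = DEFAULT_VALUE_FLOOR,
) -> ExperimentalDataset:
    """Draw a Gaussian resample of the dataset means; SDs are kept.

    Each cell is replaced by an independent draw from Gaussian(mean, SD).
    For positive-valued observables, draws below ``value_floor`` are
    clamped to the floor; clamp counts are recorded on the returned
    dataset as ``clamp_log`` (observable -> count).
    """
    clamp_log: dict[str, int] = {}
    series = []
    for s in dataset:
        draws = rng.normal(s.means, s.sds)
        if dataset.positive:
            n_clamped = int(np.sum(draws < value_floor))
            if n_clamped:
                clamp_log[s.name] = n_clamped
            draws = np.maximum(draws, value_floor)
        series.append(ObservableSeries(s.name, s.times, draws, s.sds, s.n_replicates))
    out = ExperimentalDataset(
        series,
        sd_abs_floor=dataset.sd_abs_floor,
        sd_rel_floor=dataset.sd_rel_floor,
        positive=dataset.positive,
    )
    out.clamp_log = clamp_log
    return out


def fit_smoothing_spline(
    times: np.ndarray,
    values: np.ndarray,
    weights: np.ndarray | None = None,
    smoothing: float | None = 0.9,
) -> BSpline:
    """Fit a cubic smoothing spline at smoothing level ``p`` in (0, 1].

    Minimizes  p * sum_i w_i (y_i - f(t_i))^2 + (1-p) * integral f''(t)^2 dt,
    i.e. p=1 interpolates the points and p->0 approaches the weighted
    least-squares straight line. Internally the penalty is passed to
    :func:`scipy.interpolate.make_smoothing_spline` as lam = (1-p)/p.
    ``smoothing=None`` selects the penalty by generalized cross-validation.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(times) < 4:
        raise ValueError(
            "smoothing spline needs at least 4 points; for sparser series "
            "use a lower-order interpolant (e.g. piecewise linear) instead"
        )
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if np.any(weights <= 0):
            raise ValueError("weights must be positive")
    if smoothing is None:
        if len(times) < 5:
            raise ValueError("GCV smoothing selection needs at least 5 points")
        return make_smoothing_spline(times, values, w=weights, lam=None)
    if not 0.0 < smoothing <= 1.0:
        raise ValueError("smoothing must lie in (0, 1]")
    lam = (1.0 - smoothing) / smoothing
    if len(times) >= 5:
        return make_smoothing_spline(times, values, w=weights, lam=lam)
    return _smoothing_spline_small(times, values, weights, lam)


def _smoothing_spline_small(x, y, w, lam):
    """Penalized natural cubic spline for few points (< 5).

    Solves (W + lam*K) f = W y with the Green-Silverman roughness matrix
    K = Q R^{-1} Q^T, then returns the natural cubic interpolant of the
    fitted values (a smoothing spline equals that interpolant).
    """
    from scipy.interpolate import CubicSpline

    n = len(x)
    if w is None:
        w = np.ones(n)
    h = np.diff(x)
    if lam == 0.0:
        return CubicSpline(x, y, bc_type="natural")
    Q = np.zeros((n, n - 2))
    R = np.zeros((n - 2, n - 2))
    for j in range(n - 2):
        Q[j, j] = 1.0 / h[j]
        Q[j + 1, j] = -1.0 / h[j] - 1.0 / h[j + 1]
        Q[j + 2, j] = 1.0 / h[j + 1]
        R[j, j] = (h[j] + h[j + 1]) / 3.0
        if j + 1 < n - 2:
            R[j, j + 1] = R[j + 1, j] = h[j + 1] / 6.0
    K = Q @ np.linalg.solve(R, Q.T)
    f = np.linalg.solve(np.diag(w) + lam * K, w * y)
    return CubicSpline(x, f, bc_type="natural")


@dataclass
class InterpolantSet:
    """One Monte Carlo draw of data interpolants: d(t) and sigma(t) per observable.

    ``values`` maps observable -> cubic smoothing spline through (resampled)
    means; ``sigma(name, t)`` linearly interpolates the measured SDs and
    floors them at ``max(abs_floor, rel_floor * |d(t)|)``.
    """

    t_span: tuple[float, float]
    values: Mapping[str, BSpline]
    sd_knots: Mapping[str, tuple[np.ndarray, np.ndarray]]  # times, sds
    sd_abs_floor: float
    sd_rel_floor: float
    provenance: dict = field(default_factory=dict)

    @property
    def observables(self) -> tuple[str, ...]:
        return tuple(self.values)

    def value(self, name: str, t) -> np.ndarray | float:
        t_clipped = np.clip(t, *self.t_span)
        return self.values[name](t_clipped)

    def sd(self, name: str, t) -> np.ndarray | float:
        times, sds = self.sd_knots[name]
        s = np.interp(np.clip(t, *self.t_span), times, sds)
        floor = np.maximum(self.sd_abs_floor, self.sd_rel_floor * np.abs(self.value(name, t)))
        return np.maximum(s, floor)


def _build_one(
    dataset: ExperimentalDataset,
    sd_source: ExperimentalDataset,
    smoothing: float,
    provenance: dict,
) -> InterpolantSet:
    values = {}
    sd_knots = {}
    t_lo = min(float(s.times[0]) for s in dataset)
    t_hi = max(float(s.times[-1]) for s in dataset)
    for s in dataset:
        # inverse-variance weights, normalized to mean 1 so the smoothing
        # level keeps a consistent meaning across observables and scales
        weights = 1.0 / np.square(s.sds)
        weights = weights / weights.mean()
        try:
            values[s.name] = fit_smoothing_spline(s.times, s.means, weights, smoothing)
        except ValueError as exc:
            raise ValueError(f"observable {s.name!r}: {exc}") from exc
        ref = sd_source[s.name]
        sd_knots[s.name] = (ref.times, ref.sds)
    return InterpolantSet(
        (t_lo, t_hi),
        values,
        sd_knots,
        dataset.sd_abs_floor,
        dataset.sd_rel_floor,
        provenance,
    )


def build_interpolant_collection(
    dataset: ExperimentalDataset,
    n_samples: int,
    smoothing: float,
    rng: np.random.Generator,
    *,
    resample: bool = True,
) -> list[InterpolantSet]:
    """Monte Carlo collection of spline interpolant sets.

    Each member refits smoothing splines through an independent Gaussian
    resample of the snapshot means (``resample=False`` uses the original
    means, e.g. for noiseless self-consistency checks). The SD envelope
    sigma(t) is built once from the original, un-resampled SDs.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    out = []
    for i in range(n_samples):
        src = sample_replicate(dataset, rng) if resample else dataset
        prov = {
            "sample_index": i,
            "smoothing": smoothing,
            "resampled": resample,
            "clamps": getattr(src, "clamp_log", {}),
        }
        out.append(_build_one(src, dataset, smoothing, prov))
    return out
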