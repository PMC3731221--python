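"""Time-resolved multi-parametric sensitivity analysis (MPSA).

At every time step the ensemble provides samples of each model quantity
(parameter, state or flux) together with the corresponding output of
interest. Samples are classified acceptable/unacceptable by comparing
the output against its ensemble mean; the quantity's sensitivity is the
Kolmogorov-Smirnov distance between the cumulative distributions of the
two classes over the quantity-sorted sample order. K lies in [0, 1]:
large K means membership in the good/bad output class correlates
strongly with that quantity's value, i.e. the output is sensitive to it.
Significance is judged against the asymptotic two-sample critical value
from the Kolmogorov distribution. Batching over random subsamples of the
ensemble gives an uncertainty band on each K profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectory import TrajectoryEnsemble

__all__ = [
    "SensitivityProfile",
    "classify_by_mean",
    "ks_distance",
    "critical_value",
    "timecourse_sensitivity",
    "batch_sensitivity",
]


@dataclass
class SensitivityProfile:
    """Per-time-step KS sensitivity of one quantity w.r.t. one output."""

    quantity: str
    output: str
    times: np.ndarray
    ks: np.ndarray  # (N+1,)
    n_acceptable: np.ndarray  # (N+1,) ints
    n_unacceptable: np.ndarray
    critical_values: np.ndarray
    degenerate: np.ndarray  # bool flags: one class empty at that step
    batch_ks: np.ndarray | None = None  # (n_batches, N+1)
    batch_spread: np.ndarray | None = None  # per-step std over batches
    provenance: dict = field(default_factory=dict)

    @property
    def mean_ks(self) -> float:
        """Time-averaged K over non-degenerate steps."""
        ok = ~self.degenerate
        return float(np.mean(self.ks[ok])) if ok.any() else 0.0


def classify_by_mean(output_samples: np.ndarray) -> np.ndarray:
    """Label samples acceptable (True) iff strictly below the sample mean.

    Ties at the mean count as unacceptable; the KS distance downstream is
    invariant to swapping the two labels, so the convention only pins
    down reproducibility.
    """
    out = np.asarray(output_samples, dtype=float)
    if out.size < 2:
        raise ValueError("need at least 2 samples to classify")
    return out < out.mean()


def ks_distance(param_samples: np.ndarray, labels: np.ndarray) -> float:
    """Two-class KS distance over the parameter-sorted sample order.

    Sort all samples by the quantity value, accumulate the cumulative
    fraction of acceptable (S_a) and unacceptable (S_u) samples along the
    sorted order, and return sup |S_a - S_u|. An empty class yields 0
    (degenerate; flagged by the callers).
    """
    x = np.asarray(param_samples, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if x.shape != labels.shape:
        raise ValueError("param_samples and labels must have the same shape")
    n_a = int(labels.sum())
    n_u = int(labels.size - n_a)
    if n_a == 0 or n_u == 0:
        return 0.0
    order = np.argsort(x, kind="stable")
    xs = x[order]
    acc = labels[order]
    s_a = np.cumsum(acc) / n_a
    s_u = np.cumsum(~acc) / n_u
    # evaluate the supremum only at the upper edge of tied-value groups,
    # so samples sharing a value never split across the CDF step
    group_end = np.empty(xs.size, dtype=bool)
    group_end[:-1] = xs[1:] != xs[:-1]
    group_end[-1] = True
    return float(np.max(np.abs(s_a[group_end] - s_u[group_end])))


def critical_value(n_acceptable: int, n_unacceptable: int, alpha: float = 0.05) -> float:
    """Asymptotic two-sample KS critical value at significance ``alpha``.

    c(alpha) * sqrt((n_a + n_u) / (n_a * n_u)) with
    c(alpha) = sqrt(-ln(alpha / 2) / 2).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if n_acceptable < 1 or n_unacceptable < 1:
        raise ValueError("both class counts must be >= 1")
    c = np.sqrt(-0.5 * np.log(alpha / 2.0))
    return float(c * np.sqrt((n_acceptable + n_unacceptable) / (n_acceptable * n_unacceptable)))


def _profile_from_matrices(
    q: np.ndarray, o: np.ndarray, times: np.ndarray, alpha: float,
    quantity: str, output: str,
) -> SensitivityProfile:
    n_steps = q.shape[1]
    ks = np.zeros(n_steps)
    n_a = np.zeros(n_steps, dtype=int)
    n_u = np.zeros(n_steps, dtype=int)
    crit = np.full(n_steps, np.nan)
    degenerate = np.zeros(n_steps, dtype=bool)
    for n in range(n_steps):
        labels = classify_by_mean(o[:, n])
        n_a[n] = labels.sum()
        n_u[n] = labels.size - n_a[n]
        if n_a[n] == 0 or n_u[n] == 0:
            degenerate[n] = True
            continue
        ks[n] = ks_distance(q[:, n], labels)
        crit[n] = critical_value(n_a[n], n_u[n], alpha)
    return SensitivityProfile(
        quantity=quantity, output=output, times=times, ks=ks,
        n_acceptable=n_a, n_unacceptable=n_u,
        critical_values=crit, degenerate=degenerate,
    )


def timecourse_sensitivity(
    ensemble: TrajectoryEnsemble,
    quantity: str,
    output: str,
    *,
    alpha: float = 0.05,
) -> SensitivityProfile:
    """KS sensitivity of ``quantity`` w.r.t. ``output`` at every time step.

    Selectors are ``kind:name`` strings resolved against the ensemble's
    model (see :meth:`TrajectoryEnsemble.quantity_matrix`).
    """
    if len(ensemble) < 10:
        raise ValueError("MPSA needs an ensemble of at least 10 members")
    q = ensemble.quantity_matrix(quantity)
    o = ensemble.quantity_matrix(output)
    return _profile_from_matrices(q, o, ensemble.times, alpha, quantity, output)


def batch_sensitivity(
    ensemble: TrajectoryEnsemble,
    quantity: str,
    output: str,
    n_batches: int,
    batch_size: int,
    rng: np.random.Generator,
    *,
    alpha: float = 0.05,
) -> SensitivityProfile:
    """Batched KS profile: mean over random subsamples plus per-step spread.

    Batches are drawn without replacement when the ensemble is at least
    ``batch_size`` strong, otherwise with replacement (recorded in
    provenance). The returned ``ks`` is the batch mean; ``batch_spread``
    the per-step standard deviation over batches.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    warnings = []
    if batch_size < 10:
        warnings.append("batch_size < 10: KS estimates will be noisy")
    q = ensemble.quantity_matrix(quantity)
    o = ensemble.quantity_matrix(output)
    n_members = q.shape[0]
    with_replacement = n_members < batch_size
    profiles = []
    for _ in range(n_batches):
        idx = rng.choice(n_members, size=batch_size, replace=with_replacement)
        profiles.append(
            _profile_from_matrices(q[idx], o[idx], ensemble.times, alpha, quantity, output)
        )
    batch_ks = np.stack([p.ks for p in profiles])
    batch_crit = np.stack([p.critical_values for p in profiles])
    degenerate = np.stack([p.degenerate for p in profiles]).all(axis=0)
    ref = profiles[0]
    with np.errstate(invalid="ignore"):
        crit = np.nanmean(batch_crit, axis=0)
    return SensitivityProfile(
        quantity=quantity, output=output, times=ensemble.times,
        ks=batch_ks.mean(axis=0),
        n_acceptable=ref.n_acceptable, n_unacceptable=ref.n_unacceptable,
        critical_values=crit,
        degenerate=degenerate,
        batch_ks=batch_ks,
        batch_spread=batch_ks.std(axis=0),
        provenance={
            "n_batches": n_batches,
            "batch_size": batch_size,
            "with_replacement": with_replacement,
            "warnings": warnings,
        },
    )
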