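"""Percentile and BCa bootstrap confidence intervals for score-class risks.

The statistic of interest is the outcome proportion within a score class.
Resampling draws whole training sets with replacement (class membership is
recomputed per replicate), so class sizes vary across replicates as they
would across hypothetical repeated cohorts.  The bias-corrected and
accelerated (BCa) interval adjusts the percentile levels with a bias
coefficient z0 (from the fraction of replicate statistics below the
original estimate, midrank convention for ties) and an acceleration
coefficient a (from the leave-one-patient-out jackknife).

Resample stream contract: for seed ``s`` and sample size ``n``, the B
replicate index rows are ``numpy.random.default_rng(s).integers(0, n,
size=(B, n))``.  All per-class statistics share this single stream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import Cohort
from .model import ScoreModel
from .pooling import PoolingPlan, identity_plan

__all__ = [
    "BootstrapDistribution",
    "BcaDiagnostics",
    "ScoreClassStats",
    "percentile_interval",
    "bias_correction",
    "jackknife_acceleration",
    "bca_adjusted_levels",
    "bca_interval",
    "score_class_cis",
    "class_table",
]


@dataclass(frozen=True)
class BootstrapDistribution:
    """Replicate statistics from B bootstrap resamples."""

    estimates: np.ndarray
    B_requested: int
    theta_hat: float

    @property
    def B_effective(self) -> int:
        return len(self.estimates)


@dataclass(frozen=True)
class BcaDiagnostics:
    z0: float
    a: float
    alpha1: float
    alpha2: float


@dataclass(frozen=True)
class ScoreClassStats:
    """One score class: observed risk and its bootstrap confidence interval."""

    label: str
    lo_score: int
    hi_score: int
    n: int
    pct_occurrence: float
    proportion: float
    ci_low: float
    ci_high: float
    method: str = "bca"
    B_effective: int = 0
    diagnostics: BcaDiagnostics | None = None
    test_proportion: float | None = None
    test_n: int | None = None


def _nearest_rank(sorted_estimates: np.ndarray, alpha: float) -> float:
    """Empirical alpha-quantile by the nearest-rank (ceiling) rule.

    The returned endpoint is always an actual replicate value, matching the
    reading of a percentile interval as "the bootstrap estimates which lie
    on" the requested percentiles.
    """
    b = len(sorted_estimates)
    # tolerance guards float noise in alpha * b (e.g. 0.025 * 1000)
    k = int(np.ceil(alpha * b - 1e-9))
    k = min(max(k, 1), b)
    return float(sorted_estimates[k - 1])


def percentile_interval(estimates, level: float = 0.95) -> tuple[float, float]:
    """Simple percentile bootstrap interval (nearest-rank endpoints)."""
    est = np.sort(np.asarray(
        estimates.estimates if isinstance(estimates, BootstrapDistribution) else estimates,
        dtype=float,
    ))
    if len(est) < 40:
        raise ValueError(
            f"need at least 40 effective replicates for a {level:.0%} "
            f"percentile interval, got {len(est)}"
        )
    alpha = (1.0 - level) / 2.0
    return _nearest_rank(est, alpha), _nearest_rank(est, 1.0 - alpha)


def bias_correction(estimates: np.ndarray, theta_hat: float) -> float:
    """Bias-correction coefficient z0, midrank tie convention, clamped.

    z0 = Phi^-1[(#{theta* < theta_hat} + 0.5 #{theta* = theta_hat}) / B];
    fractions of exactly 0 or 1 are clamped to 1/(2B) and 1 - 1/(2B).
    """
    b = len(estimates)
    frac = (np.sum(estimates < theta_hat) + 0.5 * np.sum(estimates == theta_hat)) / b
    frac = min(max(frac, 1.0 / (2 * b)), 1.0 - 1.0 / (2 * b))
    return float(norm.ppf(frac))

def jackknife_acceleration(jack_values) -> float:
    """Acceleration a from leave-one-out statistics; 0 for a flat jackknife."""
    jv = np.asarray(jack_values, dtype=float)
    dev = jv.mean() - jv
    denom = (dev**2).sum() ** 1.5
    if denom == 0:
        return 0.0
    return float((dev**3).sum() / (6.0 * denom))


def bca_adjusted_levels(z0: float, a: float, level: float = 0.95) -> tuple[float, float]:
    """BCa-adjusted percentile levels alpha1 < alpha2.

    alpha_k = Phi(z0 + (z0 + z_k) / (1 - a (z0 + z_k))) for the nominal
    normal quantiles z_k; a non-positive denominator pushes the level to
    the corresponding extreme.
    """
    alphas = []
    tail = (1.0 - level) / 2.0
    for zk in (norm.ppf(tail), norm.ppf(1.0 - tail)):
        zz = z0 + zk
        denom = 1.0 - a * zz
        if denom <= 0:
            alphas.append(1.0 - 1e-12 if zz > 0 else 1e-12)
        else:
            alphas.append(float(np.clip(norm.cdf(z0 + zz / denom), 1e-12, 1 - 1e-12)))
    return alphas[0], alphas[1]


def _bca_from_distribution(
    dist: BootstrapDistribution, a: float, level: float
) -> tuple[float, float, BcaDiagnostics]:
    est = np.sort(dist.estimates)
    z0 = bias_correction(est, dist.theta_hat)
    a1, a2 = bca_adjusted_levels(z0, a, level)
    return (
        _nearest_rank(est, a1),
        _nearest_rank(est, a2),
        BcaDiagnostics(z0=z0, a=a, alpha1=a1, alpha2=a2),
    )


def bca_interval(
    sample,
    statistic,
    B: int = 1000,
    level: float = 0.95,
    seed=None,
    vectorized: bool = False,
    return_distribution: bool = False,
):
    """BCa bootstrap confidence interval for ``statistic(sample)``.

    Parameters
    ----------
    sample : array-like
        One observation per entry (rows for 2-D input).
    statistic : callable
        Maps a sample to a scalar; may return NaN for resamples where it
        is undefined (such replicates are dropped).  With
        ``vectorized=True`` it must accept an ``axis`` keyword and reduce
        a (B, n) matrix along its last axis (e.g. ``numpy.mean``).
    B, level, seed :
        Replicate count (default 1000), confidence level, RNG seed (int,
        SeedSequence or Generator) driving the documented resample stream.

    Returns ``(low, high, BcaDiagnostics)``; with
    ``return_distribution=True`` the :class:`BootstrapDistribution` is
    appended.
    """
    x = np.asarray(sample, dtype=float)
    n = x.shape[0]
    if B < 1:
        raise ValueError("B must be >= 1")
    theta_hat = float(statistic(x))
    if np.isnan(theta_hat):
        raise ValueError("statistic undefined on the original sample")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    if vectorized:
        est = np.asarray(statistic(x[idx], axis=-1), dtype=float)
    else:
        est = np.array([statistic(x[row]) for row in idx], dtype=float)
    est = est[~np.isnan(est)]
    if len(est) == 0:
        raise ValueError("statistic undefined on every bootstrap resample")
    if len(est) < B:
        warnings.warn(
            f"statistic undefined on {B - len(est)} of {B} resamples",
            stacklevel=2,
        )
    # leave-one-out jackknife for the acceleration coefficient
    if vectorized:
        loo = np.broadcast_to(x, (n, n))[~np.eye(n, dtype=bool)].reshape(n, n - 1)
        jack = np.asarray(statistic(loo, axis=-1), dtype=float)
    else:
        jack = np.array(
            [statistic(np.delete(x, i, axis=0)) for i in range(n)], dtype=float
        )
    a = jackknife_acceleration(jack[~np.isnan(jack)])
    dist = BootstrapDistribution(np.sort(est), B, theta_hat)
    low, high, diag = _bca_from_distribution(dist, a, level)
    if return_distribution:
        return low, high, diag, dist
    return low, high, diag


def score_class_cis(
    train: Cohort,
    model: ScoreModel,
    plan: PoolingPlan | None = None,
    B: int = 1000,
    level: float = 0.95,
    seed=None,
    test: Cohort | None = None,
) -> list[ScoreClassStats]:
    """Per-score-class outcome proportions with BCa confidence intervals.

    The resampling unit is the entire training set: each of the B
    replicates redraws n patients with replacement and recomputes every
    class proportion, so all classes share the same replicate stream.
    Replicates in which a class is empty are dropped for that class (a
    warning below 0.9 B effective replicates, an error below 0.5 B).
    ``plan=None`` uses one class per observed score value.
    """
    scores = model.score(train.X)
    y = train.y.to_numpy()
    n = len(y)
    if plan is None:
        plan = identity_plan(scores, model.max_score)
    cls = plan.assign(scores)
    k = plan.n_classes
    counts = np.bincount(cls, minlength=k)
    if (counts == 0).any():
        empty = [plan.labels[i] for i in np.flatnonzero(counts == 0)]
        raise ValueError(
            f"score class(es) {empty} empty in the original training set; "
            "class definition invalid"
        )
    events = np.bincount(cls, weights=y, minlength=k)
    theta = events / counts

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    # replicate-by-class member and event counts via flattened bincount
    flat = (cls[idx] + np.arange(B)[:, None] * k).ravel()
    rep_counts = np.bincount(flat, minlength=B * k).reshape(B, k)
    rep_events = np.bincount(flat, weights=y[idx].ravel(), minlength=B * k).reshape(B, k)

    if test is not None:
        t_scores = model.score(test.X)
        t_cls = plan.assign(t_scores)
        t_counts = np.bincount(t_cls, minlength=k)
        t_events = np.bincount(t_cls, weights=test.y.to_numpy(), minlength=k)

    out: list[ScoreClassStats] = []
    for c in range(k):
        nonempty = rep_counts[:, c] > 0
        est = rep_events[nonempty, c] / rep_counts[nonempty, c]
        b_eff = len(est)
        if b_eff < 0.5 * B:
            raise ValueError(
                f"class {plan.labels[c]!r} empty in {B - b_eff} of {B} "
                "replicates; too small to bootstrap"
            )
        if b_eff < 0.9 * B:
            warnings.warn(
                f"class {plan.labels[c]!r} empty in {B - b_eff} of {B} "
                f"replicates (B_effective={b_eff})",
                stacklevel=2,
            )
        # closed-form leave-one-patient-out jackknife of the class proportion
        if counts[c] > 1:
            in_c = cls == c
            jack = np.full(n, theta[c])
            jack[in_c & (y == 1)] = (events[c] - 1) / (counts[c] - 1)
            jack[in_c & (y == 0)] = events[c] / (counts[c] - 1)
        else:
            jack = np.full(n, theta[c])  # flat: acceleration 0
        a = jackknife_acceleration(jack)
        dist = BootstrapDistribution(np.sort(est), B, float(theta[c]))
        low, high, diag = _bca_from_distribution(dist, a, level)
        out.append(
            ScoreClassStats(
                label=plan.labels[c],
                lo_score=plan.bounds[c][0],
                hi_score=plan.bounds[c][1],
                n=int(counts[c]),
                pct_occurrence=100.0 * counts[c] / n,
                proportion=float(theta[c]),
                ci_low=low,
                ci_high=high,
                method="bca",
                B_effective=b_eff,
                diagnostics=diag,
                test_proportion=(
                    float(t_events[c] / t_counts[c])
                    if test is not None and t_counts[c] > 0
                    else None
                ),
                test_n=int(t_counts[c]) if test is not None else None,
            )
        )
    return out


def class_table(stats: list[ScoreClassStats]) -> pd.DataFrame:
    """Tabular twin of the per-class whisker diagrams (TSV-ready)."""
    return pd.DataFrame.from_records(
        [
            {
                "class_label": s.label,
                "lo_score": s.lo_score,
                "hi_score": s.hi_score,
                "n": s.n,
                "pct_occurrence": s.pct_occurrence,
                "proportion": s.proportion,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
                "B_effective": s.B_effective,
                "z0": s.diagnostics.z0 if s.diagnostics else None,
                "a": s.diagnostics.a if s.diagnostics else None,
                "test_proportion": s.test_proportion,
                "test_n": s.test_n,
            }
            for s in stats
        ]
    )
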