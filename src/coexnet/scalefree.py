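"""Scale-free diagnostics: discrete power-law fit with a Kolmogorov–Smirnov
goodness-of-fit test.

Node degrees are positive integers, so the discrete power law
P(X = x) = x^(-alpha) / zeta(alpha, xmin) for x >= xmin is fitted by maximum
likelihood. The lower cut-off xmin is chosen by scanning the attained degree
values and minimising the KS distance between the empirical tail CDF and the
fitted CDF. An optional semi-parametric bootstrap draws synthetic datasets
(body resampled from the data below xmin, tail from the fitted law), refits
each from scratch, and reports the fraction of synthetic KS distances at
least as large as the observed one; small p-values reject the power-law
hypothesis.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import optimize, special

__all__ = ["PowerLawFit", "powerlaw_fit_ks", "sample_discrete_powerlaw"]

_ALPHA_BOUNDS = (1.000001, 10.0)


class DegenerateDegreesError(ValueError):
    """All degrees identical: the power-law fit is undefined."""


@dataclass
class PowerLawFit:
    """Result of the discrete power-law tail fit."""

    alpha: float
    xmin: int
    ks_distance: float
    n_tail: int
    p_value: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _tail_nll(alpha: float, xmin: int, n: int, sum_log: float) -> float:
    return n * np.log(special.zeta(alpha, xmin)) + alpha * sum_log


def _fit_alpha(tail: np.ndarray, xmin: int) -> float:
    n = len(tail)
    sum_log = float(np.log(tail).sum())
    res = optimize.minimize_scalar(
        _tail_nll, bounds=_ALPHA_BOUNDS, args=(xmin, n, sum_log), method="bounded"
    )
    return float(res.x)


def _ks_distance(tail: np.ndarray, alpha: float, xmin: int) -> float:
    vals, counts = np.unique(tail, return_counts=True)
    ecdf = np.cumsum(counts) / counts.sum()
    z0 = special.zeta(alpha, xmin)
    model = 1.0 - special.zeta(alpha, vals + 1.0) / z0
    return float(np.max(np.abs(ecdf - model)))


def _scan(degrees: np.ndarray, min_tail_distinct: int) -> tuple[float, int, float, int]:
    """Exhaustive xmin scan: MLE alpha per candidate, keep the smallest KS."""
    values = np.unique(degrees)
    candidates = [
        int(v) for v in values if len(values[values >= v]) >= min_tail_distinct
    ]
    if not candidates:
        # small or coarse samples: fall back to any xmin leaving >= 2 values
        candidates = [int(v) for v in values if len(values[values >= v]) >= 2]
    if not candidates:
        raise DegenerateDegreesError("all degrees equal; power-law fit undefined")
    best = None
    for xmin in candidates:
        tail = degrees[degrees >= xmin]
        alpha = _fit_alpha(tail, xmin)
        d = _ks_distance(tail, alpha, xmin)
        if best is None or d < best[2]:
            best = (alpha, xmin, d, len(tail))
    return best


def sample_discrete_powerlaw(
    n: int, alpha: float, xmin: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n variates from the discrete power law (continuous-approximation
    inverse transform, rounded — accurate except very near xmin)."""
    u = rng.random(n)
    x = np.floor((xmin - 0.5) * (1.0 - u) ** (-1.0 / (alpha - 1.0)) + 0.5)
    return x.astype(np.int64)


def sample_discrete_powerlaw_exact(
    n: int, alpha: float, xmin: int, rng: np.random.Generator, support_max: int = 10**6
) -> np.ndarray:
    """Exact inverse-CDF sampler over a truncated support (tail mass beyond
    ``support_max`` is folded into the last point; negligible for alpha > 2)."""
    support = np.arange(xmin, support_max + 1, dtype=np.float64)
    pmf = support ** (-alpha)
    cdf = np.cumsum(pmf)
    cdf /= cdf[-1]
    idx = np.searchsorted(cdf, rng.random(n), side="left")
    return (idx + xmin).astype(np.int64)


def powerlaw_fit_ks(
    degrees,
    bootstrap_reps: int = 0,
    seed: int = 0,
    min_tail_distinct: int = 10,
) -> PowerLawFit:
    """Fit a discrete power law to a degree multiset and optionally test it.

    Parameters
    ----------
    degrees : array-like of positive ints
        Node degrees (zeros are dropped: isolated nodes carry no tail
        information).
    bootstrap_reps : int
        Number of semi-parametric bootstrap replicates; 0 skips the p-value.
    min_tail_distinct : int
        Candidate xmin values must leave at least this many distinct degree
        values in the tail (relaxed automatically for coarse samples).

    Returns
    -------
    PowerLawFit
        alpha (tail exponent), xmin, KS distance, tail size and, when
        requested, the bootstrap p-value (fraction of synthetic KS distances
        >= the observed one; p < 0.05 rejects the power law).
    """
    degrees = np.asarray(degrees, dtype=np.int64)
    degrees = degrees[degrees >= 1]
    if degrees.size == 0:
        raise ValueError("no positive degrees to fit")
    if np.unique(degrees).size == 1:
        raise DegenerateDegreesError("all degrees equal; power-law fit undefined")
    if bootstrap_reps < 0:
        raise ValueError("bootstrap_reps must be >= 0")

    alpha, xmin, d_obs, n_tail = _scan(degrees, min_tail_distinct)
    p_value = None
    if bootstrap_reps > 0:
        rng = np.random.default_rng(seed)
        n = len(degrees)
        body = degrees[degrees < xmin]
        p_tail = n_tail / n
        exceed = 0
        for _ in range(bootstrap_reps):
            take_tail = rng.random(n) < p_tail
            k_tail = int(take_tail.sum())
            parts = []
            if k_tail:
                parts.append(sample_discrete_powerlaw(k_tail, alpha, xmin, rng))
            k_body = n - k_tail
            if k_body:
                if body.size:
                    parts.append(rng.choice(body, size=k_body, replace=True))
                else:
                    parts.append(sample_discrete_powerlaw(k_body, alpha, xmin, rng))
            synth = np.concatenate(parts)
            if np.unique(synth).size == 1:
                continue
            _, _, d_synth, _ = _scan(synth, min_tail_distinct)
            if d_synth >= d_obs:
                exceed += 1
        p_value = exceed / bootstrap_reps
    return PowerLawFit(alpha=alpha, xmin=int(xmin), ks_distance=d_obs,
                       n_tail=int(n_tail), p_value=p_value)
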