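"""Semi-analytic stationary analysis of the Hill toy model.

The enzyme ``E`` obeys a linear birth-death-diffusion system, whose
stationary law is product-form Poisson: the domain total is
Poisson(``alpha = k_s*L/k_d``) and the pooled count of any ``m``
adjacent bins is Poisson(``alpha*m/K``).  Because ``P``'s synthesis is
driven by ``E`` (no feedback) and its degradation is first order, the
stationary mean of ``P`` follows from the expected synthesis propensity
by linearity.  These closed/series forms are exact for the toy model and
serve as the fast oracle against which both stochastic engines are
validated, and they reproduce the discretization breakdown: on a fine
grid the mean synthesis propensity degenerates to
``k_syn*h*(1 - exp(-alpha/K)) ~ k_syn*h*alpha/K``, making the total
product linear in the discretization size ``h``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .kinetics import hill_term
from .model_core import TOY_DEFAULTS, ToyModelParams

__all__ = [
    "ToyParams",
    "toy_params",
    "total_E_pmf",
    "empty_bin_prob",
    "mean_syn_propensity_exact",
    "mean_P_exact",
    "hybrid_mean_P_exact",
    "jensen_gap",
    "validity_threshold",
    "loglog_slope",
    "deterministic_mean_P",
]


@dataclass(frozen=True)
class ToyParams:
    """Rate constants plus the Michaelis constant of the toy model.

    ``alpha = k_s*L/k_d`` (mean stationary total of E) is derived, not
    stored.
    """

    k_s: float = TOY_DEFAULTS.k_s
    k_d: float = TOY_DEFAULTS.k_d
    k_syn: float = TOY_DEFAULTS.k_syn
    k_deg: float = TOY_DEFAULTS.k_deg
    L: float = TOY_DEFAULTS.L
    K_m: float = 25.0
    n_hill: float = TOY_DEFAULTS.n_hill

    def __post_init__(self) -> None:
        for f in ("k_d", "k_deg", "L", "K_m"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be > 0")
        for f in ("k_s", "k_syn"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")

    @property
    def alpha(self) -> float:
        return self.k_s * self.L / self.k_d


def toy_params(K_m: float = 25.0, **overrides: float) -> ToyParams:
    """Convenience constructor mirroring the builder defaults."""
    return replace(ToyParams(K_m=K_m), **overrides)


def _trunc(mean: float) -> int:
    """Series truncation point: mean + 20*sqrt(mean) + 50 (tail < 1e-12)."""
    return int(math.ceil(mean + 20.0 * math.sqrt(mean) + 50.0))


def total_E_pmf(params: ToyParams, n: int | np.ndarray) -> float | np.ndarray:
    """Stationary pmf of the total enzyme count: Poisson(alpha) at ``n``."""
    return stats.poisson.pmf(n, params.alpha)


def empty_bin_prob(params: ToyParams, K: int, m: int = 1) -> float:
    """Probability that a window of ``m`` adjacent bins (of ``K``) is empty of E.

    Equals ``exp(-alpha*m/K)``: the pooled window count is
    Poisson(alpha*m/K), which is also the closed form of the
    binomial-thinning series ``sum_n P_E(n) (1 - m/K)**n``.
    """
    if not (1 <= m <= K):
        raise ValueError(f"need 1 <= m <= K, got m={m}, K={K}")
    return math.exp(-params.alpha * m / K)


def mean_syn_propensity_exact(params: ToyParams, K: int, m: int = 1) -> float:
    """Exact stationary mean of the (smoothed) Hill synthesis propensity in one bin.

    Evaluates ``k_syn*h * E[ n^nh / ((m*K_m*h)^nh + n^nh) ]`` with the
    pooled window count ``n ~ Poisson(alpha*m/K)``, the exact marginal of
    the product-form stationary law.  The series is truncated where the
    Poisson tail is below 1e-12.
    """
    if not (1 <= m <= K):
        raise ValueError(f"need 1 <= m <= K, got m={m}, K={K}")
    h = params.L / K
    lam = params.alpha * m / K
    if lam == 0:
        return 0.0
    N = _trunc(lam)
    n = np.arange(1, N + 1)
    pmf = stats.poisson.pmf(n, lam)
    K_m_eff = m * params.K_m * h
    hill = 1.0 / (1.0 + (K_m_eff / n) ** params.n_hill)
    return float(params.k_syn * h * np.sum(pmf * hill))


def mean_P_exact(params: ToyParams, K: int, m: int = 1) -> float:
    """Exact stationary mean of the total product count over all ``K`` bins.

    ``P`` is a linear birth-death species driven by the stationary E
    field, so ``<P> = K * <a_syn per bin> / k_deg`` exactly.  In the
    fine-grid limit (``K`` above the validity threshold) this converges
    to the linear law ``(k_syn/k_deg)*alpha*h`` (window ``m``:
    ``(k_syn L/k_deg)(k_s L/k_d)(m/K)``).
    """
    return K * mean_syn_propensity_exact(params, K, m) / params.k_deg


def hybrid_mean_P_exact(params: ToyParams) -> float:
    """Slow-scale prediction of the hybrid engine's stationary mean total P.

    With diffusion treated as an infinitely fast deterministic subsystem,
    each bin holds ``n/K`` enzymes whenever the domain total is ``n``, so
    the total synthesis propensity is the whole-domain Hill rate
    ``k_syn*L * n^nh/((K_m*L)^nh + n^nh)`` — independent of ``K``.
    Averaging over ``n ~ Poisson(alpha)`` and dividing by ``k_deg``:

        <P> = (k_syn*L/k_deg) * E[ hill(n; K_m*L) ]
    """
    lam = params.alpha
    N = _trunc(lam)
    n = np.arange(1, N + 1)
    pmf = stats.poisson.pmf(n, lam)
    hill = 1.0 / (1.0 + (params.K_m * params.L / n) ** params.n_hill)
    return float(params.k_syn * params.L / params.k_deg * np.sum(pmf * hill))


def jensen_gap(params: ToyParams) -> tuple[float, float]:
    """(E[f(n)], f(E[n])) for the whole-domain Hill rate under n ~ Poisson(alpha).

    ``f(n) = k_syn*L * n^nh/((K_m*L)^nh + n^nh)``.  The two components
    differ for the nonlinear Hill ``f`` — the Jensen gap between the
    slow-scale averaged propensity and the deterministic (mean-field)
    propensity.  Where ``f`` is convex (enzyme levels below ``K_m*L``)
    the averaged propensity exceeds the propensity of the average.
    """
    lam = params.alpha
    scale = params.k_syn * params.L
    averaged = hybrid_mean_P_exact(params) * params.k_deg
    of_average = scale * hill_term(lam, params.K_m * params.L, params.n_hill)
    return averaged, of_average


def validity_threshold(params: ToyParams) -> float:
    """Critical bin count ``max{2*L*K_m, 3*alpha}``.

    For ``K`` above this threshold both fine-grid approximations (Hill
    term ~= 1 for any occupied bin, at 5% tolerance; rare multiple
    occupancy) hold and the switch-like dynamics degenerate to the
    linear law.
    """
    return max(2.0 * params.L * params.K_m, 3.0 * params.alpha)


def loglog_slope(h_values: np.ndarray, means: np.ndarray) -> float:
    """OLS slope of ``log(mean)`` against ``log(h)``.

    Used to quantify the fine-grid scaling of the mean total product
    (slope 1 = linear in the discretization size).
    """
    h = np.asarray(h_values, dtype=float)
    y = np.asarray(means, dtype=float)
    if h.shape != y.shape or h.ndim != 1 or len(h) < 3:
        raise ValueError("need >= 3 paired (h, mean) points")
    if (h <= 0).any() or (y <= 0).any():
        raise ValueError("h values and means must all be positive")
    slope, _ = np.polyfit(np.log(h), np.log(y), 1)
    return float(slope)


def deterministic_mean_P(params: ToyParams) -> float:
    """Steady state of the well-mixed deterministic (ODE) limit.

        P* = (k_syn*L/k_deg) * alpha^nh / ((K_m*L)^nh + alpha^nh)

    This is the mean-field reference the hybrid engine's stochastic mean
    is compared against; the difference is the Jensen gap.
    """
    if params.k_syn == 0:
        return 0.0
    return (params.k_syn * params.L / params.k_deg
            * hill_term(params.alpha, params.K_m * params.L, params.n_hill))
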