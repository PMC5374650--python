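"""Propensity evaluation, spatial smoothing windows, and the convergent window size.

Hill propensities on a fine grid lose their switch-like character: once
``K_m*h <= 0.5`` the Hill term jumps from 0 (empty bin) to >= 0.94 (one
molecule), so the mean synthesis propensity degenerates to a linear
function of the bin occupancy.  Smoothing pools the enzyme population
over a window of ``m`` contiguous bins, restoring intermediate values;
the convergent policy grows ``m`` as ``h`` shrinks so that the pooled
dynamics never re-enter the degenerate regime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model_core import Grid1D, HillKinetics, ModelDefinition, SystemState

__all__ = [
    "Window",
    "hill_term",
    "smoothing_window",
    "smoothed_hill_propensity",
    "convergent_m",
    "all_propensities",
]


@dataclass(frozen=True)
class Window:
    """A contiguous run of bins over which an enzyme population is pooled.

    ``members`` always contains ``center``; under periodic boundaries the
    indices are stored post-wrap (so the run is contiguous modulo K).
    """

    center: int
    members: tuple[int, ...]

    @property
    def m_eff(self) -> int:
        """Effective window size (member count after boundary clipping)."""
        return len(self.members)


def _ratio_pow(ratio: float, n_hill: float) -> float:
    """``ratio**n_hill``, via an explicit multiplication chain for small
    integer exponents.  The stochastic kernel uses the same chain, so the
    two paths agree bit-for-bit."""
    ni = int(n_hill)
    if ni == n_hill and 1 <= ni <= 32:
        r = ratio
        for _ in range(ni - 1):
            r *= ratio
        return r
    return ratio ** n_hill


def hill_term(n: float, K_m_eff: float, n_hill: float = 4.0) -> float:
    """Hill activation fraction ``n**n_hill / (K_m_eff**n_hill + n**n_hill)``.

    ``n`` is a copy number (or pooled copy number), ``K_m_eff`` the
    half-saturation threshold in the same count units.  Monotone
    non-decreasing in ``n``, zero at ``n = 0``, bounded in [0, 1).
    """
    if K_m_eff <= 0:
        raise ValueError(f"K_m_eff must be > 0, got {K_m_eff!r}")
    if n < 0:
        raise ValueError(f"count must be >= 0, got {n!r}")
    if n == 0:
        return 0.0
    # Divide through by n**n_hill for overflow safety at large n.
    return 1.0 / (1.0 + _ratio_pow(K_m_eff / n, n_hill))


def smoothing_window(i: int, m: int, grid: Grid1D) -> Window:
    """The centred window of nominal size ``m`` around bin ``i``.

    The window spans ``[i - floor((m-1)/2), i + ceil((m-1)/2)]``.  Under
    reflecting boundaries it is clipped to the grid (``m_eff`` may then
    be < m near the edges); under periodic boundaries it wraps.
    """
    K = grid.K
    if not (1 <= m <= K):
        raise ValueError(f"window size m={m} must lie in [1, K={K}]")
    if not (0 <= i < K):
        raise IndexError(f"bin index {i} out of range for K={K}")
    lo = i - (m - 1) // 2
    hi = i + (m - 1) - (m - 1) // 2  # i + ceil((m-1)/2)
    if grid.boundary == "periodic":
        members = tuple(j % K for j in range(lo, hi + 1))
    else:
        members = tuple(range(max(lo, 0), min(hi, K - 1) + 1))
    return Window(center=i, members=members)


def smoothed_hill_propensity(state: SystemState, i: int, kin: HillKinetics,
                             window: Window, grid: Grid1D,
                             enzyme_index: int) -> float:
    """Hill synthesis propensity in bin ``i`` from the pooled window population.

    With pooled count ``n = sum_j E_j`` over the window's ``m_eff`` bins,

        a = k_syn * h * n**n_hill / ((m_eff * K_m * h)**n_hill + n**n_hill)

    The threshold scales with ``m_eff`` (the actual member count, not the
    nominal m), so clipped boundary windows stay unbiased analogues of
    the interior formula; with ``m_eff == 1`` this reduces exactly to the
    raw per-bin propensity.
    """
    n = int(state.counts[enzyme_index, list(window.members)].sum())
    K_m_eff = window.m_eff * kin.K_m * grid.h
    return kin.k_syn * grid.h * hill_term(n, K_m_eff, kin.n_hill)


def convergent_m(K_m: float, h: float, L: float, alpha: float,
                 K_max: int | None = None) -> int:
    """Window size for the convergent smoothing policy.

        m = ceil( max{ 0.5/(K_m*h), 0.33*L/(alpha*h) } )

    chosen as the smallest window for which neither degeneracy condition
    (per-window half-saturation below half a molecule; mean window
    occupancy below a third of a molecule) holds.  The result is clamped
    to [1, K_max]; the corresponding reaction radius is ``rho = m*h``.
    """
    if not (K_m > 0 and h > 0 and L > 0 and alpha > 0):
        raise ValueError("convergent_m needs positive K_m, h, L, alpha")
    m = math.ceil(max(0.5 / (K_m * h), 0.33 * L / (alpha * h)))
    m = max(m, 1)
    if K_max is not None:
        m = min(m, int(K_max))
    return m


def _reaction_propensity(state: SystemState, model: ModelDefinition,
                         r_index: int, i: int) -> float:
    """Propensity of reaction channel ``r_index`` in bin ``i``."""
    r = model.reactions[r_index]
    h = model.grid.h
    if r.kind == "zeroth_order":
        return r.rate * h
    if r.kind == "first_order":
        return r.rate * float(state.counts[model.species_index(r.reactant), i])
    # hill
    kin = r.hill
    win = smoothing_window(i, min(model.smoothing.m, model.grid.K), model.grid)
    return smoothed_hill_propensity(state, i, kin, win, model.grid,
                                    model.species_index(kin.enzyme))


def all_propensities(state: SystemState, model: ModelDefinition) -> np.ndarray:
    """The full channel-rate vector for the direct-method SSA.

    Channel ordering (fixed; the stochastic engine uses the same order):

    1. Reaction channels, bin-major: for each bin ``i`` in 0..K-1, each
       reaction in model order.
    2. Diffusion channels, species-major then bin-major then direction:
       for each species, for each bin, the left hop then the right hop,
       each at per-direction rate ``D/h**2 * count``.  Hops that would
       leave a reflecting domain are present with rate 0 (fixed layout),
       so an interior bin's two directions sum to ``2*D/h**2 * count``.

    Raises ``ValueError`` on a corrupted (negative-count) state.
    """
    if (state.counts < 0).any():
        raise ValueError("corrupted state: negative counts")
    K = model.grid.K
    n_rx = len(model.reactions)
    nsp = model.n_species
    out = np.zeros(K * n_rx + nsp * K * 2, dtype=float)
    for i in range(K):
        for j in range(n_rx):
            out[i * n_rx + j] = _reaction_propensity(state, model, j, i)
    if K > 1:
        inv_h2 = 1.0 / model.grid.h ** 2
        periodic = model.grid.boundary == "periodic"
        base = K * n_rx
        for s, sp in enumerate(model.species):
            d = sp.D * inv_h2
            for i in range(K):
                left_ok = periodic or i > 0
                right_ok = periodic or i < K - 1
                c = float(state.counts[s, i])
                out[base + (s * K + i) * 2] = d * c if left_ok else 0.0
                out[base + (s * K + i) * 2 + 1] = d * c if right_ok else 0.0
    return out
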