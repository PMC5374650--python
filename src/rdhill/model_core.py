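"""Data model for 1D compartment-based reaction-diffusion systems.

A spatial domain of length ``L`` is partitioned into ``K`` compartments
("bins") of size ``h = L/K``.  Molecules within a bin are well stirred;
reactions fire inside a bin and diffusion is modelled as hopping between
adjacent bins at per-molecule rate ``D/h**2`` per direction.

The module defines the immutable model description (grid, species,
reaction channels, smoothing policy) plus the mutable ``SystemState``
(integer copy numbers per bin), and builders for the two benchmark
systems used throughout the package:

* a two-species toy gene-expression model in which an enzyme ``E`` is
  synthesised and degraded and drives synthesis of a product ``P``
  through a Hill function, and
* a pure-diffusion chain of ``K`` bins with an attached readout reaction,
  used for slow-scale (fast-diffusion) analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Mapping, Sequence

import numpy as np

__all__ = [
    "Grid1D",
    "SpeciesSpec",
    "HillKinetics",
    "ReactionChannel",
    "SmoothingPolicy",
    "ModelDefinition",
    "SystemState",
    "ToyModelParams",
    "TOY_DEFAULTS",
    "build_toy_model",
    "build_chain_model",
    "apply_channel",
]

_REL_TOL = 1e-12


# ---------------------------------------------------------------------------
# Grid and species
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Grid1D:
    """A uniform 1D grid of ``K`` compartments covering a domain of length ``L``.

    Attributes
    ----------
    L : float
        Domain length (arbitrary length units).
    K : int
        Number of compartments (>= 1).
    boundary : {"reflecting", "periodic"}
        Boundary condition for diffusion hops.  Reflecting (default)
        means edge bins have a single neighbour; periodic wraps.
    """

    L: float
    K: int
    boundary: Literal["reflecting", "periodic"] = "reflecting"

    def __post_init__(self) -> None:
        if not (isinstance(self.K, (int, np.integer)) and self.K >= 1):
            raise ValueError(f"K must be a positive integer, got {self.K!r}")
        if not (self.L > 0 and math.isfinite(self.L)):
            raise ValueError(f"L must be positive and finite, got {self.L!r}")
        if self.boundary not in ("reflecting", "periodic"):
            raise ValueError(f"unknown boundary {self.boundary!r}")

    @property
    def h(self) -> float:
        """Compartment (discretization) size ``L/K``."""
        return self.L / self.K

    def neighbors(self, i: int) -> tuple[int, ...]:
        """Indices of bins reachable from bin ``i`` by one diffusion hop."""
        if self.K == 1:
            return ()
        if self.boundary == "periodic":
            return ((i - 1) % self.K, (i + 1) % self.K)
        out = []
        if i > 0:
            out.append(i - 1)
        if i < self.K - 1:
            out.append(i + 1)
        return tuple(out)


@dataclass(frozen=True)
class SpeciesSpec:
    """A chemical species with a diffusion coefficient.

    ``D`` is in length^2/time; ``D == 0`` means the species is immobile.
    """

    name: str
    D: float = 0.0

    def __post_init__(self) -> None:
        if not self.name or not isinstance(self.name, str):
            raise ValueError("species name must be a non-empty string")
        if self.D < 0 or not math.isfinite(self.D):
            raise ValueError(f"diffusion coefficient must be >= 0, got {self.D!r}")


# ---------------------------------------------------------------------------
# Kinetic laws and channels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HillKinetics:
    """Parameters of a Hill-type synthesis propensity.

    In a bin of size ``h`` holding ``E_i`` copies of the regulating
    enzyme, the propensity is

        k_syn * h * E_i**n / ((K_m*h)**n + E_i**n)

    ``k_syn`` is a maximal rate density (molecules/length/time), ``K_m``
    a Michaelis constant in concentration units (molecules/length) so
    that ``K_m*h`` is the half-saturation copy number of a bin, and
    ``n_hill`` the Hill exponent (cooperativity).
    """

    k_syn: float
    K_m: float
    n_hill: float = 4.0
    enzyme: str = "E"

    def __post_init__(self) -> None:
        if self.k_syn < 0:
            raise ValueError("k_syn must be >= 0")
        if self.K_m <= 0:
            raise ValueError("K_m must be > 0")
        if self.n_hill < 1:
            raise ValueError("Hill exponent must be >= 1")


@dataclass(frozen=True)
class ReactionChannel:
    """One reaction channel, replicated in every bin.

    kind
        ``zeroth_order``: propensity ``rate * h`` per bin (a rate
        density integrated over the bin); ``first_order``: propensity
        ``rate * count`` of the single reactant; ``hill``: Hill-function
        synthesis regulated by ``hill.enzyme``.
    nu
        Per-species state-change map applied in the firing bin.
    reactant
        Species whose copy number enters a first-order propensity.
    """

    name: str
    kind: Literal["zeroth_order", "first_order", "hill"]
    nu: Mapping[str, int]
    rate: float = 0.0
    reactant: str | None = None
    hill: HillKinetics | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("zeroth_order", "first_order", "hill"):
            raise ValueError(f"unknown channel kind {self.kind!r}")
        if self.kind == "first_order" and self.reactant is None:
            raise ValueError(f"channel {self.name!r}: first_order needs a reactant")
        if self.kind == "hill" and self.hill is None:
            raise ValueError(f"channel {self.name!r}: hill kind needs HillKinetics")
        if self.kind != "hill" and self.rate < 0:
            raise ValueError(f"channel {self.name!r}: rate must be >= 0")
        for sp, dv in self.nu.items():
            if int(dv) != dv:
                raise ValueError(f"channel {self.name!r}: nu[{sp!r}] must be integer")


@dataclass(frozen=True)
class SmoothingPolicy:
    """Spatial smoothing policy for Hill propensities.

    mode
        ``none``: raw per-bin propensity (m = 1).
        ``fixed``: pool the enzyme population over a centred window of
        ``m`` bins before evaluating the Hill term.
        ``convergent``: ``m`` chosen from the discretization size so the
        smoothed dynamics stay correct as ``h -> 0``; the concrete ``m``
        is resolved at model-build time (see ``kinetics.convergent_m``)
        and stored here.
    """

    mode: Literal["none", "fixed", "convergent"] = "none"
    m: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("none", "fixed", "convergent"):
            raise ValueError(f"unknown smoothing mode {self.mode!r}")
        if int(self.m) != self.m or self.m < 1:
            raise ValueError(f"window size m must be a positive integer, got {self.m!r}")
        if self.mode == "none" and self.m != 1:
            raise ValueError("smoothing mode 'none' requires m = 1")

    def rho(self, h: float) -> float:
        """Reaction radius ``rho = m*h``."""
        return self.m * h


# ---------------------------------------------------------------------------
# Model definition and state
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelDefinition:
    """A complete simulatable 1D reaction-diffusion system."""

    grid: Grid1D
    species: tuple[SpeciesSpec, ...]
    reactions: tuple[ReactionChannel, ...]
    smoothing: SmoothingPolicy = field(default_factory=SmoothingPolicy)

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "reactions", tuple(self.reactions))
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError("duplicate species names")
        declared = set(names)
        for r in self.reactions:
            refs = set(r.nu)
            if r.reactant is not None:
                refs.add(r.reactant)
            if r.hill is not None:
                refs.add(r.hill.enzyme)
            missing = refs - declared
            if missing:
                raise ValueError(
                    f"channel {r.name!r} references undeclared species {sorted(missing)}"
                )
        if self.smoothing.m > self.grid.K:
            raise ValueError("smoothing window m cannot exceed the bin count K")

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    def species_index(self, name: str) -> int:
        return self.species_names.index(name)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def initial_state(self, counts: Mapping[str, Sequence[int] | int] | None = None,
                      t: float = 0.0) -> "SystemState":
        """Build a SystemState; ``counts`` maps species to a total spread
        as evenly as possible over bins, or to an explicit per-bin array."""
        K = self.grid.K
        arr = np.zeros((self.n_species, K), dtype=np.int64)
        if counts:
            for name, val in counts.items():
                n = self.species_index(name)
                v = np.asarray(val)
                if v.ndim == 0:
                    total = int(v)
                    base, extra = divmod(total, K)
                    arr[n, :] = base
                    arr[n, :extra] += 1
                else:
                    if v.shape != (K,):
                        raise ValueError(f"per-bin counts for {name!r} must have length {K}")
                    arr[n, :] = v
        return SystemState(t=t, counts=arr)


@dataclass
class SystemState:
    """Copy numbers of every species in every bin at one time point.

    ``counts`` has shape ``(n_species, K)`` and is integer and
    non-negative at all times in the stochastic engines.
    """

    t: float
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a (n_species, K) array")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    def copy(self) -> "SystemState":
        return SystemState(t=self.t, counts=self.counts.copy())

    def totals(self) -> np.ndarray:
        """Per-species totals over the whole domain."""
        return self.counts.sum(axis=1)


class IllegalTransitionError(RuntimeError):
    """A channel fired from a state where it was infeasible (engine bug)."""


def apply_channel(state: SystemState, model: ModelDefinition, channel_index: int,
                  bin_index: int, *, direction: int | None = None) -> SystemState:
    """Apply one firing of a reaction or diffusion channel and return the new state.

    ``channel_index`` in ``[0, len(model.reactions))`` selects a reaction
    fired in ``bin_index``.  ``channel_index == len(model.reactions) + s``
    selects a diffusion hop of species ``s`` out of ``bin_index`` in
    ``direction`` (-1 left, +1 right), honouring the grid's boundary.
    Diffusion conserves the species total exactly.

    Raises
    ------
    IllegalTransitionError
        If the firing would drive any copy number negative, or the hop
        leaves the domain under reflecting boundaries.
    """
    n_rx = len(model.reactions)
    K = model.grid.K
    if not (0 <= bin_index < K):
        raise IndexError(f"bin index {bin_index} out of range for K={K}")
    new = state.copy()
    if channel_index < n_rx:
        r = model.reactions[channel_index]
        for sp, dv in r.nu.items():
            n = model.species_index(sp)
            new.counts[n, bin_index] += dv
            if new.counts[n, bin_index] < 0:
                raise IllegalTransitionError(
                    f"firing {r.name!r} in bin {bin_index} drives {sp} negative"
                )
    else:
        s = channel_index - n_rx
        if not (0 <= s < model.n_species):
            raise IndexError(f"channel index {channel_index} out of range")
        if direction not in (-1, 1):
            raise ValueError("diffusion hop needs direction -1 or +1")
        j = bin_index + direction
        if model.grid.boundary == "periodic":
            j %= K
        elif not (0 <= j < K):
            raise IllegalTransitionError(
                f"hop from bin {bin_index} leaves the reflecting domain"
            )
        if new.counts[s, bin_index] == 0:
            raise IllegalTransitionError(
                f"diffusion hop of {model.species_names[s]} from empty bin {bin_index}"
            )
        new.counts[s, bin_index] -= 1
        new.counts[s, j] += 1
    return new


# ---------------------------------------------------------------------------
# Benchmark model builders
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyModelParams:
    """Rate constants of the two-species toy gene-expression model.

    Defaults are the benchmark set used throughout:
    D_E = 1.0, k_s = 2.5, k_d = 0.1, k_syn = 5.0, k_deg = 0.05, L = 1.0.
    D_P is not independently constrained (total-P statistics do not
    depend on it, since P degradation is first order and position
    independent); it defaults to D_E.
    """

    k_s: float = 2.5
    k_d: float = 0.1
    k_syn: float = 5.0
    k_deg: float = 0.05
    D_E: float = 1.0
    D_P: float = 1.0
    L: float = 1.0
    n_hill: float = 4.0

    @property
    def alpha(self) -> float:
        """Mean total enzyme copy number at stationarity, ``k_s*L/k_d``."""
        return self.k_s * self.L / self.k_d


TOY_DEFAULTS = ToyModelParams()


def build_toy_model(K: int, K_m: float,
                    overrides: Mapping[str, float] | None = None,
                    smoothing: SmoothingPolicy | str = "none",
                    boundary: str = "reflecting") -> ModelDefinition:
    """Build the two-species Hill toy model on ``K`` bins.

    Reactions per bin i (h = L/K):

        0 -> E_i          a1 = k_s * h
        E_i -> 0          a2 = k_d * E_i
        0 -[E_i]-> P_i    a3 = k_syn * h * E_i^4 / ((K_m*h)^4 + E_i^4)
        P_i -> 0          a4 = k_deg * P_i
        E_i -> E_(i+-1)   per-direction rate D_E/h^2 per molecule
        P_i -> P_(i+-1)   per-direction rate D_P/h^2 per molecule

    Parameters
    ----------
    K : int
        Number of compartments.
    K_m : float
        Michaelis constant (concentration units; the per-bin
        half-saturation count is ``K_m*h``).
    overrides : mapping, optional
        Overrides for any ``ToyModelParams`` field.
    smoothing : SmoothingPolicy or {"none", "fixed:<m>", "convergent"}
        Smoothing policy; the string ``"convergent"`` resolves the
        window size from (K_m, h, L, alpha) at build time.
    """
    if not (isinstance(K, (int, np.integer)) and K >= 1):
        raise ValueError(f"K must be a positive integer, got {K!r}")
    if not (K_m > 0):
        raise ValueError(f"K_m must be > 0, got {K_m!r}")
    p = replace(TOY_DEFAULTS, **dict(overrides or {}))
    grid = Grid1D(L=p.L, K=int(K), boundary=boundary)  # type: ignore[arg-type]

    if isinstance(smoothing, str):
        from .kinetics import convergent_m  # deferred: kinetics imports this module

        if smoothing == "none":
            pol = SmoothingPolicy("none", 1)
        elif smoothing == "convergent":
            m = convergent_m(K_m, grid.h, p.L, p.alpha, K_max=grid.K)
            pol = SmoothingPolicy("convergent", m)
        elif smoothing.startswith("fixed:"):
            pol = SmoothingPolicy("fixed", int(smoothing.split(":", 1)[1]))
        else:
            raise ValueError(f"unknown smoothing spec {smoothing!r}")
    else:
        pol = smoothing

    hill = HillKinetics(k_syn=p.k_syn, K_m=K_m, n_hill=p.n_hill, enzyme="E")
    reactions = (
        ReactionChannel("E_synthesis", "zeroth_order", {"E": +1}, rate=p.k_s),
        ReactionChannel("E_degradation", "first_order", {"E": -1}, rate=p.k_d,
                        reactant="E"),
        ReactionChannel("P_synthesis", "hill", {"P": +1}, hill=hill),
        ReactionChannel("P_degradation", "first_order", {"P": -1}, rate=p.k_deg,
                        reactant="P"),
    )
    return ModelDefinition(
        grid=grid,
        species=(SpeciesSpec("E", p.D_E), SpeciesSpec("P", p.D_P)),
        reactions=reactions,
        smoothing=pol,
    )


def build_chain_model(K: int, D: float,
                      f: Callable[[float], float] | Literal["identity", "zero"] = "identity",
                      n_total: int = 0, L: float = 1.0,
                      readout_scale: float = 1.0) -> ModelDefinition:
    """Build the pure-diffusion chain X_1 <-> X_2 <-> ... <-> X_K.

    A single species ``X`` (``n_total`` molecules) hops between adjacent
    bins at jump rate ``d = D/h**2`` per molecule per direction, and a
    readout reaction producing ``P`` fires in each bin with propensity
    ``f(x_i)``.  ``f`` may be ``"identity"`` (propensity
    ``readout_scale * x_i``, a first-order channel), ``"zero"`` (no
    readout), or a callable used by analysis code (not simulatable by
    the mass-action engines).

    At diffusive equilibrium the per-bin mean is ``<x_i> = n_total/K``.
    """
    if not (isinstance(K, (int, np.integer)) and K >= 2):
        raise ValueError(f"chain model needs K >= 2, got {K!r}")
    if n_total < 0:
        raise ValueError("n_total must be >= 0")
    grid = Grid1D(L=L, K=int(K))
    species = (SpeciesSpec("X", D), SpeciesSpec("P", 0.0))
    reactions: tuple[ReactionChannel, ...]
    if f == "identity":
        reactions = (ReactionChannel("readout", "first_order", {"P": +1},
                                     rate=readout_scale, reactant="X"),)
    elif f == "zero":
        reactions = ()
    elif callable(f):
        # Custom readouts are used by the slow-scale analysis layer only.
        reactions = ()
    else:
        raise ValueError(f"unknown readout spec {f!r}")
    return ModelDefinition(grid=grid, species=species, reactions=reactions)
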