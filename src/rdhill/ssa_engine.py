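"""Exact stochastic simulation (direct-method SSA) of the RDME system.

Every reaction channel in every bin and every per-direction diffusion
hop is an explicit channel.  Each event consumes two uniform draws from
a seeded Mersenne-Twister stream — first the waiting time
``tau = -log(r1)/a_tot``, then the channel, chosen as the smallest index
whose running propensity sum exceeds ``r2*a_tot``.  Channel ordering is
fixed by :func:`rdhill.kinetics.all_propensities`.

Two implementations share that contract and the same random stream:

* :func:`simulate_ssa` — a numba-compiled kernel that maintains the
  channel propensities incrementally (each affected entry recomputed
  exactly from the current state) and samples channels through a Fenwick
  prefix-sum tree in O(log C) per event, with a periodic full rebuild to
  keep accumulated rounding at the 1e-12 level over billions of events.
* :func:`simulate_ssa_reference` — a plain-Python direct method that
  recomputes the whole propensity vector every event; used to validate
  the kernel trajectory-for-trajectory on small runs.

Both are bit-reproducible given the same seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .kinetics import all_propensities
from .model_core import ModelDefinition, SystemState

__all__ = [
    "Trajectory",
    "StationarySample",
    "InsufficientDataError",
    "simulate_ssa",
    "simulate_ssa_reference",
    "sample_stationary",
]


class InsufficientDataError(RuntimeError):
    """Fewer stationary samples than required for the requested statistic."""


@dataclass
class Trajectory:
    """Fixed-interval snapshots of a simulated system.

    ``counts`` has shape ``(n_snapshots, n_species, K)``; integer for the
    exact SSA, floating point for the hybrid engine.  ``times`` is
    strictly increasing and starts at 0 with the initial state.
    """

    times: np.ndarray
    counts: np.ndarray
    species_names: tuple[str, ...]
    seed: int
    n_events: int = 0
    engine: str = "ssa"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.counts):
            raise ValueError("times and counts length mismatch")
        if len(self.times) and (np.diff(self.times) <= 0).any():
            raise ValueError("snapshot times must be strictly increasing")

    def species_index(self, name: str) -> int:
        return self.species_names.index(name)

    def totals(self, species: str) -> np.ndarray:
        """Domain total of one species at every snapshot."""
        return self.counts[:, self.species_index(species), :].sum(axis=1)

    def state_at(self, index: int) -> SystemState:
        return SystemState(t=float(self.times[index]),
                           counts=np.asarray(self.counts[index], dtype=np.int64))


@dataclass
class StationarySample:
    """Post-burn-in, thinned snapshots used for equilibrium statistics."""

    times: np.ndarray
    counts: np.ndarray  # (n_samples, n_species, K)
    species_names: tuple[str, ...]

    def species_index(self, name: str) -> int:
        return self.species_names.index(name)

    @property
    def n_samples(self) -> int:
        return len(self.times)

    def totals(self, species: str) -> np.ndarray:
        return self.counts[:, self.species_index(species), :].sum(axis=1)

    def per_bin_counts(self, species: str) -> np.ndarray:
        """All (sample, bin) counts of one species, shape (n_samples, K)."""
        return self.counts[:, self.species_index(species), :]

    def mean_total(self, species: str) -> float:
        return float(self.totals(species).mean())

    def sem_total(self, species: str, n_batches: int = 20) -> float:
        """Standard error of the mean total, by non-overlapping batch means.

        Batch means absorb the autocorrelation of consecutive thinned
        samples; with ``n_batches`` batches the estimate carries
        ``n_batches - 1`` degrees of freedom.
        """
        x = self.totals(species)
        nb = min(n_batches, len(x) // 2)
        if nb < 2:
            raise InsufficientDataError("need at least 4 samples for a batch SE")
        usable = (len(x) // nb) * nb
        batches = x[:usable].reshape(nb, -1).mean(axis=1)
        return float(batches.std(ddof=1) / math.sqrt(nb))

    def empty_bin_fraction(self, species: str) -> float:
        """Fraction of (sample, bin) cells holding zero molecules."""
        return float((self.per_bin_counts(species) == 0).mean())


# ---------------------------------------------------------------------------
# Model -> flat arrays for the kernel
# ---------------------------------------------------------------------------

def _model_tables(model: ModelDefinition):
    n_rx = len(model.reactions)
    nsp = model.n_species
    rx_kind = np.zeros(n_rx, dtype=np.int8)
    rx_rate = np.zeros(n_rx, dtype=np.float64)
    rx_reactant = np.full(n_rx, -1, dtype=np.int64)
    nu = np.zeros((n_rx, nsp), dtype=np.int64)
    hill_enz = np.full(n_rx, -1, dtype=np.int64)
    hill_ksyn = np.zeros(n_rx, dtype=np.float64)
    hill_Km = np.zeros(n_rx, dtype=np.float64)
    hill_nh = np.zeros(n_rx, dtype=np.float64)
    for j, r in enumerate(model.reactions):
        for sp, dv in r.nu.items():
            nu[j, model.species_index(sp)] = dv
        if r.kind == "zeroth_order":
            rx_kind[j] = 0
            rx_rate[j] = r.rate
        elif r.kind == "first_order":
            rx_kind[j] = 1
            rx_rate[j] = r.rate
            rx_reactant[j] = model.species_index(r.reactant)
        else:
            rx_kind[j] = 2
            hill_enz[j] = model.species_index(r.hill.enzyme)
            hill_ksyn[j] = r.hill.k_syn
            hill_Km[j] = r.hill.K_m
            hill_nh[j] = r.hill.n_hill
    d_over_h2 = np.array([s.D / model.grid.h ** 2 for s in model.species])
    m = min(model.smoothing.m, model.grid.K)
    win_a = (m - 1) // 2          # bins to the left of the centre
    win_b = (m - 1) - win_a       # bins to the right
    # CSR lists of the channels that read each species (hot-path lookup)
    fo_start = np.zeros(nsp + 1, dtype=np.int64)   # first-order, by reactant
    hl_start = np.zeros(nsp + 1, dtype=np.int64)   # hill, by enzyme
    fo_idx_l: list[int] = []
    hl_idx_l: list[int] = []
    for s in range(nsp):
        for j in range(n_rx):
            if rx_kind[j] == 1 and rx_reactant[j] == s:
                fo_idx_l.append(j)
            elif rx_kind[j] == 2 and hill_enz[j] == s:
                hl_idx_l.append(j)
        fo_start[s + 1] = len(fo_idx_l)
        hl_start[s + 1] = len(hl_idx_l)
    fo_idx = np.array(fo_idx_l, dtype=np.int64)
    hl_idx = np.array(hl_idx_l, dtype=np.int64)
    return (rx_kind, rx_rate, rx_reactant, nu, hill_enz, hill_ksyn, hill_Km,
            hill_nh, d_over_h2, win_a, win_b, fo_start, fo_idx, hl_start,
            hl_idx)


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _hill_prop(counts, i, K, h, periodic, win_a, win_b, enz, ksyn, Km, nh):
    # pooled count over the centred window, clipped (reflecting) or wrapped
    if periodic:
        n = 0
        for j in range(i - win_a, i + win_b + 1):
            n += counts[enz, j % K]
        m_eff = win_a + win_b + 1
    else:
        lo = i - win_a
        if lo < 0:
            lo = 0
        hi = i + win_b
        if hi > K - 1:
            hi = K - 1
        n = 0
        for j in range(lo, hi + 1):
            n += counts[enz, j]
        m_eff = hi - lo + 1
    if n == 0:
        return 0.0
    K_m_eff = m_eff * Km * h
    ratio = K_m_eff / n
    # multiplication chain for integer exponents, bit-matching
    # kinetics._ratio_pow
    ni = np.int64(nh)
    if ni == nh and 1 <= ni <= 32:
        r = ratio
        for _ in range(ni - 1):
            r *= ratio
    else:
        r = ratio ** nh
    return ksyn * h * (1.0 / (1.0 + r))


@njit(cache=True, inline="always")
def _rx_prop(counts, i, j, K, h, periodic, win_a, win_b,
             rx_kind, rx_rate, rx_reactant,
             hill_enz, hill_ksyn, hill_Km, hill_nh):
    k = rx_kind[j]
    if k == 0:
        return rx_rate[j] * h
    elif k == 1:
        return rx_rate[j] * counts[rx_reactant[j], i]
    else:
        return _hill_prop(counts, i, K, h, periodic, win_a, win_b,
                          hill_enz[j], hill_ksyn[j], hill_Km[j], hill_nh[j])


@njit(cache=True, inline="always")
def _fen_set(tree, props, size_p2, idx, val):
    delta = val - props[idx]
    props[idx] = val
    i = idx + 1
    while i <= size_p2:
        tree[i] += delta
        i += i & (-i)


@njit(cache=True)
def _fen_rebuild(tree, props, size_p2):
    tree[:] = 0.0
    for idx in range(props.shape[0]):
        v = props[idx]
        i = idx + 1
        while i <= size_p2:
            tree[i] += v
            i += i & (-i)


@njit(cache=True, inline="always")
def _fen_find(tree, size_p2, target):
    # smallest 0-based idx with prefix_sum(idx) > target (strict: zero-
    # propensity channels are never selected except at the float edge)
    pos = 0
    rem = target
    bit = size_p2
    while bit > 0:
        nxt = pos + bit
        if nxt <= size_p2 and tree[nxt] <= rem:
            rem -= tree[nxt]
            pos = nxt
        bit >>= 1
    return pos


@njit(cache=True, inline="always")
def _ifen_add(itree, size_p2, idx, delta):
    i = idx + 1
    while i <= size_p2:
        itree[i] += delta
        i += i & (-i)


@njit(cache=True, inline="always")
def _ifen_find(itree, size_p2, K, d, rem):
    # diffusion-block descent: integer bin weights scaled by the float
    # jump rate d on the fly; returns (bin, remainder-within-bin)
    pos = 0
    bit = size_p2
    while bit > 0:
        nxt = pos + bit
        if nxt <= size_p2:
            w = d * itree[nxt]
            if w <= rem:
                rem -= w
                pos = nxt
        bit >>= 1
    if pos >= K:
        pos = K - 1
    return pos, rem


@njit(cache=True)
def _recompute_rx(props, counts, K, n_rx, h, periodic, win_a, win_b,
                  rx_kind, rx_rate, rx_reactant,
                  hill_enz, hill_ksyn, hill_Km, hill_nh):
    for i in range(K):
        for j in range(n_rx):
            props[i * n_rx + j] = _rx_prop(
                counts, i, j, K, h, periodic, win_a, win_b,
                rx_kind, rx_rate, rx_reactant,
                hill_enz, hill_ksyn, hill_Km, hill_nh)


@njit(cache=True, inline="always")
def _refresh_channel(tree, props, size_p2, counts, b, j, K, n_rx, h, periodic,
                     win_a, win_b, rx_kind, rx_rate, rx_reactant,
                     hill_enz, hill_ksyn, hill_Km, hill_nh):
    val = _rx_prop(counts, b, j, K, h, periodic, win_a, win_b,
                   rx_kind, rx_rate, rx_reactant,
                   hill_enz, hill_ksyn, hill_Km, hill_nh)
    _fen_set(tree, props, size_p2, b * n_rx + j, val)


@njit(cache=True, inline="always")
def _refresh_species_at_bin(tree, props, size_p2, counts, b, s, K, n_rx, h,
                            periodic, win_a, win_b, rx_kind, rx_rate,
                            rx_reactant, hill_enz, hill_ksyn, hill_Km,
                            hill_nh, include_hill):
    # refresh first-order channels reading species s in bin b, and (for
    # reaction events) every hill channel whose window covers b
    for j in range(n_rx):
        k = rx_kind[j]
        if k == 1:
            if rx_reactant[j] == s:
                _refresh_channel(tree, props, size_p2, counts, b, j, K, n_rx,
                                 h, periodic, win_a, win_b, rx_kind, rx_rate,
                                 rx_reactant, hill_enz, hill_ksyn, hill_Km,
                                 hill_nh)
        elif k == 2 and include_hill and hill_enz[j] == s:
            lo = b - win_b
            hi = b + win_a
            for bb in range(lo, hi + 1):
                if periodic:
                    w = bb % K
                elif bb < 0 or bb > K - 1:
                    continue
                else:
                    w = bb
                _refresh_channel(tree, props, size_p2, counts, w, j, K, n_rx,
                                 h, periodic, win_a, win_b, rx_kind, rx_rate,
                                 rx_reactant, hill_enz, hill_ksyn, hill_Km,
                                 hill_nh)


@njit(cache=True)
def _ssa_kernel(counts, t_end, dt, n_samples, seed,
                rx_kind, rx_rate, rx_reactant, nu,
                hill_enz, hill_ksyn, hill_Km, hill_nh,
                d_over_h2, win_a, win_b, h, periodic, rebuild_every,
                fo_start, fo_idx, hl_start, hl_idx):
    nsp, K = counts.shape
    n_rx = rx_kind.shape[0]
    C_r = K * n_rx
    m_window = win_a + win_b + 1

    p2r = 1
    while p2r < max(C_r, 1):
        p2r *= 2
    props = np.zeros(C_r, dtype=np.float64)
    tree = np.zeros(p2r + 1, dtype=np.float64)
    _recompute_rx(props, counts, K, n_rx, h, periodic, win_a, win_b,
                  rx_kind, rx_rate, rx_reactant,
                  hill_enz, hill_ksyn, hill_Km, hill_nh)
    _fen_rebuild(tree, props, p2r)

    # integer Fenwick per species over bins; weight = directions * count
    p2k = 1
    while p2k < K:
        p2k *= 2
    dirs = np.zeros(K, dtype=np.int64)
    if K > 1:
        for i in range(K):
            nd = 0
            if periodic or i > 0:
                nd += 1
            if periodic or i < K - 1:
                nd += 1
            dirs[i] = nd
    itree = np.zeros((nsp, p2k + 1), dtype=np.int64)
    wtot = np.zeros(nsp, dtype=np.int64)
    for s in range(nsp):
        for i in range(K):
            w = dirs[i] * counts[s, i]
            if w != 0:
                _ifen_add(itree[s], p2k, i, w)
            wtot[s] += w

    rec = np.zeros((n_samples, nsp, K), dtype=np.int64)

    np.random.seed(seed)
    t = 0.0
    i_rec = 0
    n_events = 0
    rebuild_ctr = rebuild_every
    while True:
        T_R = tree[p2r]
        atot = T_R
        for s in range(nsp):
            atot += d_over_h2[s] * wtot[s]
        if atot <= 0.0:
            while i_rec < n_samples:
                rec[i_rec] = counts
                i_rec += 1
            break
        r1 = np.random.random()
        r2 = np.random.random()
        t_new = t - np.log(r1) / atot
        while i_rec < n_samples and i_rec * dt < t_new and i_rec * dt <= t_end:
            rec[i_rec] = counts
            i_rec += 1
        if t_new > t_end:
            break
        t = t_new
        target = r2 * atot

        if target < T_R:
            # ---- reaction event ----
            mu = _fen_find(tree, p2r, target)
            if mu >= C_r:
                mu = C_r - 1
            i = mu // n_rx
            j = mu - i * n_rx
            for s in range(nsp):
                dv = nu[j, s]
                if dv != 0:
                    counts[s, i] += dv
                    if dirs[i] != 0:
                        _ifen_add(itree[s], p2k, i, dirs[i] * dv)
                        wtot[s] += dirs[i] * dv
                    _refresh_species_at_bin(
                        tree, props, p2r, counts, i, s, K, n_rx, h, periodic,
                        win_a, win_b, rx_kind, rx_rate, rx_reactant,
                        hill_enz, hill_ksyn, hill_Km, hill_nh, True)
        else:
            # ---- diffusion hop ----
            rem = target - T_R
            s = 0
            while s < nsp - 1:
                block = d_over_h2[s] * wtot[s]
                if rem < block:
                    break
                rem -= block
                s += 1
            d = d_over_h2[s]
            i, rem = _ifen_find(itree[s], p2k, K, d, rem)
            if counts[s, i] == 0:
                # float-edge fallback (target rounded past the last
                # positive channel): step to the nearest occupied bin
                lo = i
                while lo > 0 and counts[s, lo] == 0:
                    lo -= 1
                if counts[s, lo] == 0:
                    lo = i
                    while lo < K - 1 and counts[s, lo] == 0:
                        lo += 1
                i = lo
                rem = 0.0
            # within the bin: left channel first, then right
            left_ok = periodic or i > 0
            go_right = True
            if left_ok:
                if d * counts[s, i] > rem:
                    go_right = False
            if go_right:
                j2 = i + 1
                if j2 > K - 1:
                    j2 = 0 if periodic else i - 1
            else:
                j2 = i - 1 if i > 0 else K - 1
            counts[s, i] -= 1
            counts[s, j2] += 1
            _ifen_add(itree[s], p2k, i, -dirs[i])
            _ifen_add(itree[s], p2k, j2, dirs[j2])
            wtot[s] += dirs[j2] - dirs[i]
            # first-order channels reading s in the two bins
            for q in range(fo_start[s], fo_start[s + 1]):
                j = fo_idx[q]
                _refresh_channel(tree, props, p2r, counts, i, j, K, n_rx, h,
                                 periodic, win_a, win_b, rx_kind, rx_rate,
                                 rx_reactant, hill_enz, hill_ksyn, hill_Km,
                                 hill_nh)
                _refresh_channel(tree, props, p2r, counts, j2, j, K, n_rx, h,
                                 periodic, win_a, win_b, rx_kind, rx_rate,
                                 rx_reactant, hill_enz, hill_ksyn, hill_Km,
                                 hill_nh)
            # hill windows whose pooled count changed: those containing
            # exactly one endpoint of the hop (none if the window spans
            # the whole domain)
            if m_window < K and hl_start[s] != hl_start[s + 1]:
                if j2 == i + 1 or (periodic and j2 == (i + 1) % K):
                    b_lose = i - win_b
                    b_gain = i + 1 + win_a
                else:
                    b_lose = i + win_a
                    b_gain = i - 1 - win_b
                for bb in (b_lose, b_gain):
                    if periodic:
                        b = bb % K
                    elif bb < 0 or bb > K - 1:
                        continue
                    else:
                        b = bb
                    for q in range(hl_start[s], hl_start[s + 1]):
                        _refresh_channel(
                            tree, props, p2r, counts, b, hl_idx[q], K, n_rx, h,
                            periodic, win_a, win_b, rx_kind, rx_rate,
                            rx_reactant, hill_enz, hill_ksyn, hill_Km,
                            hill_nh)
        n_events += 1
        rebuild_ctr -= 1
        if rebuild_ctr == 0:
            rebuild_ctr = rebuild_every
            _recompute_rx(props, counts, K, n_rx, h, periodic, win_a, win_b,
                          rx_kind, rx_rate, rx_reactant,
                          hill_enz, hill_ksyn, hill_Km, hill_nh)
            _fen_rebuild(tree, props, p2r)
    return rec, n_events, i_rec


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def _check_initial(model: ModelDefinition, initial: SystemState) -> None:
    if initial.counts.shape != (model.n_species, model.grid.K):
        raise ValueError(
            f"initial state shape {initial.counts.shape} does not match "
            f"model ({model.n_species}, {model.grid.K})"
        )


def simulate_ssa(model: ModelDefinition, initial: SystemState, t_end: float,
                 seed: int, record_interval: float = 1.0) -> Trajectory:
    """Run the direct-method SSA to ``t_end`` and record interval snapshots.

    Snapshots are taken at ``0, dt, 2*dt, ...`` (state held constant
    between events).  Identical ``(model, initial, t_end, seed)`` give a
    bit-identical trajectory.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if record_interval <= 0:
        raise ValueError("record_interval must be > 0")
    _check_initial(model, initial)
    (rx_kind, rx_rate, rx_reactant, nu, hill_enz, hill_ksyn, hill_Km,
     hill_nh, d_over_h2, win_a, win_b, fo_start, fo_idx, hl_start,
     hl_idx) = _model_tables(model)
    n_samples = int(math.floor(t_end / record_interval + 1e-9)) + 1
    counts = initial.counts.astype(np.int64).copy()
    rec, n_events, i_rec = _ssa_kernel(
        counts, float(t_end), float(record_interval), n_samples, int(seed),
        rx_kind, rx_rate, rx_reactant, nu,
        hill_enz, hill_ksyn, hill_Km, hill_nh,
        d_over_h2, int(win_a), int(win_b), float(model.grid.h),
        model.grid.boundary == "periodic", np.int64(1) << 20,
        fo_start, fo_idx, hl_start, hl_idx)
    times = np.arange(i_rec) * record_interval
    return Trajectory(times=times, counts=rec[:i_rec],
                      species_names=model.species_names, seed=int(seed),
                      n_events=int(n_events), engine="ssa")


def simulate_ssa_reference(model: ModelDefinition, initial: SystemState,
                           t_end: float, seed: int,
                           record_interval: float = 1.0) -> Trajectory:
    """Plain-Python direct method recomputing every propensity each event.

    Consumes the same random stream as :func:`simulate_ssa` (legacy
    Mersenne-Twister, two draws per event) and follows the same
    channel-ordering and selection rule, so short runs can be compared
    snapshot-for-snapshot with the compiled kernel.  Only practical for
    small event counts.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    _check_initial(model, initial)
    rng = np.random.RandomState(seed)
    n_rx = len(model.reactions)
    K = model.grid.K
    nsp = model.n_species
    state = initial.copy()
    dt = record_interval
    n_samples = int(math.floor(t_end / dt + 1e-9)) + 1
    rec = np.zeros((n_samples, nsp, K), dtype=np.int64)
    i_rec = 0
    t = 0.0
    n_events = 0
    nu_tab = np.zeros((n_rx, nsp), dtype=np.int64)
    for j, r in enumerate(model.reactions):
        for sp, dv in r.nu.items():
            nu_tab[j, model.species_index(sp)] = dv
    while True:
        props = all_propensities(state, model)
        atot = props.sum()
        if atot <= 0.0:
            while i_rec < n_samples:
                rec[i_rec] = state.counts
                i_rec += 1
            break
        r1 = rng.random_sample()
        r2 = rng.random_sample()
        t_new = t - math.log(r1) / atot
        while i_rec < n_samples and i_rec * dt < t_new and i_rec * dt <= t_end:
            rec[i_rec] = state.counts
            i_rec += 1
        if t_new > t_end:
            break
        t = t_new
        cum = np.cumsum(props)
        mu = int(np.searchsorted(cum, r2 * atot, side="right"))
        if mu < K * n_rx:
            i, j = divmod(mu, n_rx)
            state.counts[:, i] += nu_tab[j]
            if (state.counts[:, i] < 0).any():
                raise RuntimeError("engine bug: negative count")
        else:
            rem = mu - K * n_rx
            si, d01 = divmod(rem, 2)
            s, i = divmod(si, K)
            j2 = i + (d01 * 2 - 1)
            if model.grid.boundary == "periodic":
                j2 %= K
            state.counts[s, i] -= 1
            state.counts[s, j2] += 1
        n_events += 1
    times = np.arange(i_rec) * dt
    return Trajectory(times=times, counts=rec[:i_rec],
                      species_names=model.species_names, seed=int(seed),
                      n_events=n_events, engine="ssa-reference")


def sample_stationary(traj: Trajectory, burn_in: float,
                      interval: float | None = None) -> StationarySample:
    """Thin a trajectory to post-burn-in samples for equilibrium statistics.

    Keeps snapshots at times ``burn_in, burn_in + interval, ...``;
    ``interval`` defaults to (and must be an integer multiple of) the
    trajectory's recording interval.

    Raises
    ------
    InsufficientDataError
        If fewer than 2 samples survive.
    """
    times = traj.times
    if len(times) < 2:
        raise InsufficientDataError("trajectory has fewer than 2 snapshots")
    dt = float(times[1] - times[0])
    if interval is None:
        stride = 1
    else:
        stride = int(round(interval / dt))
        if stride < 1 or abs(stride * dt - interval) > 1e-9 * max(1.0, interval):
            raise ValueError(
                f"interval {interval} is not a multiple of the recording "
                f"interval {dt}")
    start = int(np.searchsorted(times, burn_in - 1e-12))
    idx = np.arange(start, len(times), stride)
    if len(idx) < 2:
        raise InsufficientDataError(
            f"only {len(idx)} stationary samples (burn_in={burn_in}, "
            f"interval={interval}); need >= 2")
    return StationarySample(times=times[idx], counts=traj.counts[idx],
                            species_names=traj.species_names)
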