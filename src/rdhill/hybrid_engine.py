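"""Hybrid ODE/SSA simulation: deterministic diffusion, stochastic reactions.

Diffusion channels (the fast subset, by default) are integrated as the
linear ODE system ``x_i' = d*(x_{i-1} - 2*x_i + x_{i+1})`` (reflecting
edges drop the missing neighbour; periodic wraps), while reaction
channels (the slow subset) fire stochastically.  The time to the next
slow firing solves

    integral_t^{t+tau} a_tot(x(s)) ds + log(r1) = 0,

with ``a_tot`` the summed slow propensities along the deterministic fast
flow; equivalently the augmented variable ``z' = a_tot(x)``,
``z(t) = log(r1)`` crosses zero at the firing time.  The channel is then
selected as in the SSA — smallest index whose running propensity sum at
``t + tau`` exceeds ``r2 * a_tot`` — and its integer stoichiometry is
applied to the continuous state.  A degradation firing in a sparsely
occupied bin may briefly drive that bin negative; the fast flow smooths
the dip away, and species *totals* remain exactly integer (diffusion
conserves them and every firing moves them by the integer stoichiometry),
which is what keeps the hybrid mass balance exact.  Propensities are
evaluated with per-bin values clamped at zero (first-order ones on the
raw species totals, which are the physical molecule counts).

Because the slow propensities see the *relaxed* (uniform) enzyme profile
rather than 0/1 bin occupancies, the stationary mean product is
independent of the discretization — the slow-scale limit.

Two interchangeable integrators realize the method:

* ``method="spectral"`` (default): the fast subsystem is linear, so it
  is propagated exactly in the diffusion eigenbasis (DCT-II modes under
  reflecting boundaries, Fourier modes under periodic ones);
  ``z(t)`` is accumulated by composite Simpson quadrature on a geometric
  time grid that resolves the post-firing relaxation transient, and the
  crossing is bracketed and refined to relative time tolerance 1e-9.
* ``method="lsoda"``: the augmented system ``(x, z)`` is handed to the
  LSODA stiff/non-stiff solver with event detection on ``z = 0`` — the
  classical realization.  The integral variable can be excluded from the
  error-control vector (default) or included.

Both draw (r1, r2) per firing from the same seeded stream, so they
sample the identical stochastic process; the spectral path is the fast
one (no stiffness limit from the diffusion eigenvalues ``~4D/h**2``).

Smoothing policies are ignored here: the continuous relaxation already
supplies intermediate enzyme levels, so the raw Hill propensity is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .kinetics import _ratio_pow
from .model_core import ModelDefinition, SystemState
from .ssa_engine import Trajectory

__all__ = [
    "HybridPartition",
    "simulate_hybrid",
    "fast_relaxation_profile",
]


@dataclass(frozen=True)
class HybridPartition:
    """Assignment of channels to the fast (ODE) and slow (SSA) subsets.

    The default partition puts every diffusion channel in the fast
    subset and every reaction channel in the slow subset.  ``rtol`` /
    ``atol`` are integrator tolerances (used by the LSODA path and as
    the quadrature tolerance scale of the spectral path); ``control_z``
    adds the integral variable to the LSODA error-control vector (off by
    default — z is a bookkeeping integral and the root does not need it).
    """

    fast_diffusion: bool = True
    rtol: float = 1e-6
    atol: float = 1e-8
    control_z: bool = False

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("integrator tolerances must be > 0")


# ---------------------------------------------------------------------------
# slow-propensity evaluation on continuous states
# ---------------------------------------------------------------------------

def _hybrid_tables(model: ModelDefinition):
    n_rx = len(model.reactions)
    nsp = model.n_species
    rx_kind = np.zeros(n_rx, dtype=np.int8)
    rx_rate = np.zeros(n_rx)
    rx_reactant = np.full(n_rx, -1, dtype=np.int64)
    nu = np.zeros((n_rx, nsp), dtype=np.int64)
    hill_enz = np.full(n_rx, -1, dtype=np.int64)
    hill_ksyn = np.zeros(n_rx)
    hill_Km = np.zeros(n_rx)
    hill_nh = np.zeros(n_rx)
    for j, r in enumerate(model.reactions):
        for sp, dv in r.nu.items():
            nu[j, model.species_index(sp)] = dv
        if r.kind == "zeroth_order":
            rx_kind[j], rx_rate[j] = 0, r.rate
        elif r.kind == "first_order":
            rx_kind[j], rx_rate[j] = 1, r.rate
            rx_reactant[j] = model.species_index(r.reactant)
        else:
            rx_kind[j] = 2
            hill_enz[j] = model.species_index(r.hill.enzyme)
            hill_ksyn[j], hill_Km[j], hill_nh[j] = (r.hill.k_syn, r.hill.K_m,
                                                    r.hill.n_hill)
    return rx_kind, rx_rate, rx_reactant, nu, hill_enz, hill_ksyn, hill_Km, hill_nh


def _hill_sum(e: np.ndarray, Km_eff: float, nh: float) -> float:
    """Sum over bins of the Hill fraction, negatives treated as empty."""
    e = e[e > 0.0]
    if e.size == 0:
        return 0.0
    ratio = Km_eff / e
    ni = int(nh)
    if ni == nh and 1 <= ni <= 32:
        r = ratio
        for _ in range(ni - 1):
            r = r * ratio
    else:
        r = ratio ** nh
    return float(np.sum(1.0 / (1.0 + r)))


def _slow_atot(x: np.ndarray, h: float, K: int, tabs) -> float:
    """Total slow propensity: zeroth/first-order on (raw-total) counts,
    Hill on clamped per-bin values."""
    rx_kind, rx_rate, rx_reactant, _, hill_enz, hill_ksyn, hill_Km, hill_nh = tabs
    tot = 0.0
    for j in range(len(rx_kind)):
        if rx_kind[j] == 0:
            tot += rx_rate[j] * h * K
        elif rx_kind[j] == 1:
            tot += rx_rate[j] * float(x[rx_reactant[j]].sum())
        else:
            tot += hill_ksyn[j] * h * _hill_sum(x[hill_enz[j]],
                                                hill_Km[j] * h, hill_nh[j])
    return tot


def _slow_per_channel(x: np.ndarray, h: float, K: int, tabs) -> np.ndarray:
    """Per-channel propensities (bin-major, reactions in model order) for
    channel selection; per-bin values clamped at zero."""
    rx_kind, rx_rate, rx_reactant, _, hill_enz, hill_ksyn, hill_Km, hill_nh = tabs
    n_rx = len(rx_kind)
    xc = np.maximum(x, 0.0)
    out = np.empty(K * n_rx)
    for j in range(n_rx):
        if rx_kind[j] == 0:
            out[j::n_rx] = rx_rate[j] * h
        elif rx_kind[j] == 1:
            out[j::n_rx] = rx_rate[j] * xc[rx_reactant[j]]
        else:
            e = xc[hill_enz[j]]
            Km_eff = hill_Km[j] * h
            vals = np.zeros(K)
            pos = e > 0.0
            if pos.any():
                ratio = Km_eff / e[pos]
                nh = hill_nh[j]
                ni = int(nh)
                if ni == nh and 1 <= ni <= 32:
                    r = ratio.copy()
                    for _ in range(ni - 1):
                        r *= ratio
                else:
                    r = ratio ** nh
                vals[pos] = 1.0 / (1.0 + r)
            out[j::n_rx] = hill_ksyn[j] * h * vals
    return out


def _select_and_fire(x: np.ndarray, h: float, K: int, n_rx: int, tabs,
                     nu: np.ndarray, r2: float) -> int:
    """Pick the slow channel at the firing time and apply its stoichiometry."""
    a = _slow_per_channel(x, h, K, tabs)
    atot = a.sum()
    if atot <= 0.0:
        return -1
    mu = int(np.searchsorted(np.cumsum(a), r2 * atot, side="right"))
    mu = min(mu, K * n_rx - 1)
    i, j = divmod(mu, n_rx)
    x[:, i] += nu[j]
    return mu


# ---------------------------------------------------------------------------
# exact propagator of the fast (diffusion) subsystem
# ---------------------------------------------------------------------------

class _DiffusionPropagator:
    """Exact evolution of x' = d*(Laplacian)x in the diffusion eigenbasis.

    Reflecting boundaries diagonalize in DCT-II cosine modes with
    eigenvalues ``lambda_k = 4d sin^2(pi k / 2K)``; periodic boundaries
    in Fourier modes with ``lambda_k = 4d sin^2(pi k / K)``.  Mode 0 is
    the conserved total.
    """

    def __init__(self, K: int, d: float, periodic: bool):
        self.K = K
        self.d = d
        self.periodic = periodic
        if periodic:
            k = np.arange(K // 2 + 1)
            self.lam = 4.0 * d * np.sin(np.pi * k / K) ** 2
        else:
            k = np.arange(K)
            self.lam = 4.0 * d * np.sin(np.pi * k / (2.0 * K)) ** 2

    def coeffs(self, x: np.ndarray) -> np.ndarray:
        if self.periodic:
            return sfft.rfft(x)
        return sfft.dct(x, type=2, norm="ortho")

    def evolve(self, c0: np.ndarray, t: float) -> np.ndarray:
        c = c0 * np.exp(-self.lam * t)
        if self.periodic:
            return sfft.irfft(c, n=self.K)
        return sfft.idct(c, type=2, norm="ortho")

    @property
    def slowest_rate(self) -> float:
        return float(self.lam[1]) if len(self.lam) > 1 else 0.0


def fast_relaxation_profile(model: ModelDefinition, n_total: float) -> np.ndarray:
    """Equilibrium of the fast diffusion ODE subsystem for one species.

    Diffusion conserves the total and relaxes any profile to the uniform
    one, so the per-bin mean is ``n_total / K`` under reflecting or
    periodic boundaries.
    """
    K = model.grid.K
    return np.full(K, n_total / K)


# ---------------------------------------------------------------------------
# the hybrid loop
# ---------------------------------------------------------------------------

def simulate_hybrid(model: ModelDefinition, initial: SystemState, t_end: float,
                    seed: int, partition: HybridPartition | None = None,
                    record_interval: float = 1.0,
                    method: str = "spectral") -> Trajectory:
    """Run the hybrid ODE/SSA method to ``t_end``.

    Per iteration: draw ``r1, r2``; evolve the fast (diffusion) ODEs
    together with ``z' = a_tot(x)`` from ``z = log(r1)`` until the root
    ``z = 0`` marks the next slow firing at ``t + tau``; select the slow
    channel (smallest index with running sum > ``r2 * a_tot`` at the
    firing time) and apply its stoichiometry; repeat.  Snapshots of the
    continuous state are recorded at multiples of ``record_interval``.

    ``method`` picks the fast-subsystem integrator: ``"spectral"``
    (exact eigenbasis propagation, default) or ``"lsoda"`` (stiff ODE
    solver with event detection).  With an empty fast subset the total
    slow propensity is constant between firings and ``tau =
    -log(r1)/a_tot`` is used directly, reducing the method to the direct
    SSA on continuous counts.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if initial.counts.shape != (model.n_species, model.grid.K):
        raise ValueError("initial state does not match model dimensions")
    if method not in ("spectral", "lsoda"):
        raise ValueError(f"unknown hybrid method {method!r}")
    partition = partition or HybridPartition()
    tabs = _hybrid_tables(model)
    nu = tabs[3]
    n_rx = len(tabs[0])
    K = model.grid.K
    nsp = model.n_species
    h = model.grid.h
    periodic = model.grid.boundary == "periodic"
    rng = np.random.RandomState(seed)

    D = np.array([s.D for s in model.species])
    d_jump = D / h ** 2
    fast = partition.fast_diffusion and K > 1 and (d_jump > 0).any()

    x = initial.counts.astype(float).copy()

    dt = record_interval
    n_samples = int(math.floor(t_end / dt + 1e-9)) + 1
    rec = np.zeros((n_samples, nsp, K))
    rec[0] = x

    if not fast:
        t = 0.0
        i_rec = 1
        n_events = 0
        while t < t_end:
            r1 = rng.random_sample()
            r2 = rng.random_sample()
            atot = _slow_atot(x, h, K, tabs)
            if atot <= 0.0:
                break
            t_new = t - math.log(r1) / atot
            while i_rec < n_samples and i_rec * dt < min(t_new, t_end) + 1e-12:
                rec[i_rec] = x
                i_rec += 1
            if t_new > t_end:
                break
            t = t_new
            if _select_and_fire(x, h, K, n_rx, tabs, nu, r2) < 0:
                break
            n_events += 1
        while i_rec < n_samples:
            rec[i_rec] = x
            i_rec += 1
    elif method == "spectral":
        n_events = _run_spectral(model, partition, x, t_end, rng, tabs, nu,
                                 n_rx, h, K, nsp, periodic, d_jump,
                                 rec, dt, n_samples)
    else:
        n_events = _run_lsoda(model, partition, x, t_end, rng, tabs, nu,
                              n_rx, h, K, nsp, periodic, d_jump,
                              rec, dt, n_samples)

    times = np.arange(n_samples) * dt
    traj = Trajectory(times=times, counts=rec,
                      species_names=model.species_names, seed=int(seed),
                      n_events=n_events, engine=f"hybrid-{method}")
    _check_totals(traj, model)
    return traj


def _check_totals(traj: Trajectory, model: ModelDefinition) -> None:
    final = traj.counts[-1]
    if final.sum(axis=1).min() < -1e-6:
        raise RuntimeError("hybrid state invalid: a species total went negative")


def _run_spectral(model, partition, x, t_end, rng, tabs, nu, n_rx, h, K,
                  nsp, periodic, d_jump, rec, dt, n_samples):
    """Exact-propagator hybrid loop (shared conventions with the LSODA path)."""
    props = [_DiffusionPropagator(K, d_jump[s], periodic) if d_jump[s] > 0
             else None for s in range(nsp)]
    lam_max = max((4.0 * d_jump[s] for s in range(nsp) if d_jump[s] > 0),
                  default=0.0)
    rx_kind, rx_rate, rx_reactant, _, hill_enz, hill_ksyn, hill_Km, hill_nh = tabs
    # only Hill channels whose enzyme diffuses make a_tot time-varying;
    # zeroth/first-order terms depend on conserved totals alone
    hill_js = [j for j in range(len(rx_kind)) if rx_kind[j] == 2]
    t = 0.0
    i_rec = 1
    n_events = 0

    while t < t_end:
        r1 = rng.random_sample()
        r2 = rng.random_sample()
        z0 = math.log(r1)
        coeffs = [props[s].coeffs(x[s]) if props[s] is not None else x[s].copy()
                  for s in range(nsp)]
        horizon = t_end - t

        a_const = 0.0
        for j in range(len(rx_kind)):
            if rx_kind[j] == 0:
                a_const += rx_rate[j] * h * K
            elif rx_kind[j] == 1:
                a_const += rx_rate[j] * float(x[rx_reactant[j]].sum())
        const_hill = []   # (j, value) for immobile enzymes
        moving_hill = []  # j for diffusing enzymes
        for j in hill_js:
            s = hill_enz[j]
            if props[s] is None:
                a_const += hill_ksyn[j] * h * _hill_sum(
                    x[s], hill_Km[j] * h, hill_nh[j])
            else:
                moving_hill.append(j)

        def atot_at(tau: float) -> float:
            a = a_const
            for j in moving_hill:
                s = hill_enz[j]
                e = props[s].evolve(coeffs[s], tau)
                a += hill_ksyn[j] * h * _hill_sum(e, hill_Km[j] * h,
                                                  hill_nh[j])
            return a

        a_prev = atot_at(0.0)
        # geometric quadrature grid: resolves the post-firing transient
        # (fastest mode ~1/lam_max) and expands toward the firing scale
        tau_prev = 0.0
        z = z0
        step = (0.25 / lam_max) if lam_max > 0 else horizon
        step = min(step, horizon)
        fired = False
        tau = horizon
        while True:
            tau_next = min(tau_prev + step, horizon)
            mid = 0.5 * (tau_prev + tau_next)
            a_mid = atot_at(mid)
            a_next = atot_at(tau_next)
            dz = (tau_next - tau_prev) * (a_prev + 4.0 * a_mid + a_next) / 6.0
            if z + dz >= 0.0:
                # bracketed: refine with a fine cumulative-Simpson grid
                tau = _refine_root(atot_at, tau_prev, tau_next, z, a_prev)
                fired = True
                break
            z += dz
            tau_prev = tau_next
            a_prev = a_next
            if tau_next >= horizon:
                break
            step *= 2.0
        t_stop = t + (tau if fired else horizon)
        _record_spectral(rec, dt, n_samples, t, t_stop, coeffs, props,
                         nsp, K, i_rec)
        i_rec = _advance_irec(i_rec, dt, n_samples, t_stop)
        for s in range(nsp):
            x[s] = (props[s].evolve(coeffs[s], t_stop - t)
                    if props[s] is not None else coeffs[s])
        t = t_stop
        if not fired:
            break
        if _select_and_fire(x, h, K, n_rx, tabs, nu, r2) < 0:
            break
        n_events += 1
    # hold the final state for any remaining snapshots
    while i_rec < n_samples:
        rec[i_rec] = x
        i_rec += 1
    return n_events


def _advance_irec(i_rec: int, dt: float, n_samples: int, t_stop: float) -> int:
    while i_rec < n_samples and i_rec * dt < t_stop + 1e-12:
        i_rec += 1
    return i_rec


def _record_spectral(rec, dt, n_samples, t_seg, t_stop, coeffs, props, nsp, K,
                     i_rec) -> None:
    """Fill snapshots falling inside (t_seg, t_stop] from the propagator."""
    j = i_rec
    while j < n_samples and j * dt < t_stop + 1e-12:
        ts = j * dt - t_seg
        for s in range(nsp):
            rec[j, s] = (props[s].evolve(coeffs[s], ts)
                         if props[s] is not None else coeffs[s])
        j += 1


def _refine_root(atot_at, tau_lo, tau_hi, z_lo, a_lo) -> float:
    """Locate z(tau) = 0 inside a bracketing step.

    Builds an 8-interval cumulative-Simpson table of z on [tau_lo,
    tau_hi] and inverts it with a bracketed Brent solve on the locally
    interpolated z(tau); the result is accurate to ~1e-9 relative in
    time (z is monotone since a_tot >= 0).
    """
    n_sub = 8
    taus = np.linspace(tau_lo, tau_hi, 2 * n_sub + 1)
    a_vals = np.empty(2 * n_sub + 1)
    a_vals[0] = a_lo
    for i in range(1, 2 * n_sub + 1):
        a_vals[i] = atot_at(taus[i])
    z_tab = np.empty(n_sub + 1)
    z_tab[0] = z_lo
    hstep = (tau_hi - tau_lo) / n_sub
    for i in range(n_sub):
        z_tab[i + 1] = z_tab[i] + hstep * (
            a_vals[2 * i] + 4.0 * a_vals[2 * i + 1] + a_vals[2 * i + 2]) / 6.0
    if z_tab[-1] < 0.0:
        return tau_hi
    idx = int(np.searchsorted(z_tab, 0.0))
    idx = max(1, min(idx, n_sub))
    lo, hi = taus[2 * (idx - 1)], taus[2 * idx]
    z_a = z_tab[idx - 1]
    a0, a1m, a1 = a_vals[2 * (idx - 1)], a_vals[2 * idx - 1], a_vals[2 * idx]

    def z_local(tt):
        # quadratic reconstruction of a(t) on the sub-interval, integrated
        u = (tt - lo) / (hi - lo)
        c0, c1, c2 = a0, -3.0 * a0 + 4.0 * a1m - a1, 2.0 * a0 - 4.0 * a1m + 2.0 * a1
        return z_a + (hi - lo) * (c0 * u + c1 * u * u / 2.0 + c2 * u ** 3 / 3.0)

    if z_local(hi) <= 0.0 or z_local(lo) >= 0.0:
        return hi if z_local(hi) <= 0.0 else lo
    return float(brentq(z_local, lo, hi, xtol=1e-9 * max(abs(hi), 1e-6),
                        rtol=8.881784197001252e-16))


def _run_lsoda(model, partition, x, t_end, rng, tabs, nu, n_rx, h, K, nsp,
               periodic, d_jump, rec, dt, n_samples):
    """Classical realization: LSODA on the augmented (x, z) system with
    event detection on the z = 0 crossing."""
    t = 0.0
    i_rec = 1
    n_events = 0

    def diffusion_rhs(xm):
        dx = np.empty_like(xm)
        if periodic:
            dx[:] = np.roll(xm, 1, axis=1) + np.roll(xm, -1, axis=1) - 2.0 * xm
        else:
            dx[:, 1:-1] = xm[:, :-2] + xm[:, 2:] - 2.0 * xm[:, 1:-1]
            dx[:, 0] = xm[:, 1] - xm[:, 0]
            dx[:, -1] = xm[:, -2] - xm[:, -1]
        return d_jump[:, None] * dx

    def rhs(_t, y):
        xm = y[:-1].reshape(nsp, K)
        dy = np.empty_like(y)
        dy[:-1] = diffusion_rhs(xm).ravel()
        dy[-1] = _slow_atot(xm, h, K, tabs)
        return dy

    def z_root(_t, y):
        return y[-1]

    z_root.terminal = True
    z_root.direction = 1

    while t < t_end:
        r1 = rng.random_sample()
        r2 = rng.random_sample()
        y0 = np.concatenate([x.ravel(), [math.log(r1)]])
        atol = np.full(y0.size, partition.atol)
        if not partition.control_z:
            atol[-1] = 1e9  # effectively removes z from error control
        sol = solve_ivp(rhs, (t, t_end), y0, method="LSODA", events=z_root,
                        rtol=partition.rtol, atol=atol, lband=1, uband=1,
                        dense_output=True)
        if not sol.success:
            raise RuntimeError(
                f"fast-subsystem integration failed at t={t}: {sol.message}")
        fired = len(sol.t_events[0]) > 0
        t_stop = float(sol.t_events[0][0]) if fired else float(sol.t[-1])
        while i_rec < n_samples and i_rec * dt < t_stop + 1e-12:
            ys = sol.sol(min(i_rec * dt, t_stop))
            rec[i_rec] = ys[:-1].reshape(nsp, K)
            i_rec += 1
        if not fired:
            x[:, :] = sol.y[:-1, -1].reshape(nsp, K)
            t = t_end
            break
        x[:, :] = sol.y_events[0][0][:-1].reshape(nsp, K)
        t = t_stop
        if _select_and_fire(x, h, K, n_rx, tabs, nu, r2) < 0:
            break
        n_events += 1
    while i_rec < n_samples:
        rec[i_rec] = x
        i_rec += 1
    return n_events
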