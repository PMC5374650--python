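# rdhill

Compartment-based stochastic simulation of 1D reaction–diffusion systems
with Hill-function kinetics — and the tools to see where, and why, that
combination breaks down.

## The problem

Gene-regulatory switches are routinely modelled with Hill rate laws,
`V·Eⁿ/(K_mⁿ + Eⁿ)`, and spatial stochastic models are routinely built on
the reaction–diffusion master equation (RDME): partition the domain of
length `L` into `K` compartments of size `h = L/K`, let reactions fire
inside compartments and molecules hop between neighbours at rate
`D/h²`.  The two do not mix at fine discretization.  Once a compartment
rarely holds more than one enzyme molecule (`K_m·h ≤ 0.5` and
`α/K < 1/3`, where `α` is the mean total enzyme count), the Hill term
evaluates to either 0 (empty bin) or ≥ 0.94 (occupied bin): the switch
degenerates into a linear function of the local occupancy, and the mean
product count becomes proportional to `h` — refine the mesh and the
product vanishes.

`rdhill` implements, for a two-species benchmark system (enzyme `E`
synthesized and degraded at rates `k_s`, `k_d`; product `P` synthesized
through a Hill function of `E` and degraded at `k_deg`):

* an **exact direct-method SSA** over all reaction and diffusion
  channels (numba-compiled, Fenwick-tree channel selection; a plain
  Python reference implementation shares its random stream and is used
  to validate it trajectory-for-trajectory);
* **population smoothing** of Hill propensities over a window of `m`
  bins — fixed `m`, or the *convergent* choice
  `m = ⌈max{0.5/(K_m·h), 0.33·L/(α·h)}⌉` that grows the reaction radius
  `ρ = m·h` as the mesh refines;
* a **hybrid ODE/SSA engine**: diffusion integrated deterministically
  (exact eigenbasis propagator, or LSODA with root-finding), reactions
  fired stochastically at times solving
  `∫ a_tot(x(s)) ds + log r₁ = 0`;
* a **semi-analytic stationary layer**: the enzyme field's stationary
  law is product-form Poisson, which gives exact series expressions for
  the mean synthesis propensity, the mean product count (smoothed or
  not), the slow-scale (hybrid) prediction, the Jensen gap
  `⟨f(x)⟩ ≠ f(⟨x⟩)`, and the breakdown threshold
  `K > max{2LK_m, 3α}` — the fast oracle every engine is tested against.

## Worked example

```python
import rdhill as rh

params = rh.toy_params(K_m=25.0)     # k_s=2.5, k_d=0.1, k_syn=5, k_deg=0.05, L=1
print(rh.validity_threshold(params))  # 75.0  -> grids finer than K=75 break

# exact stationary mean product: well-mixed vs a fine grid
print(rh.mean_P_exact(params, 1))     # 48.486488833427345
print(rh.mean_P_exact(params, 1000))  # 2.4690078439706897  (~ linear law 2.5)

# simulate and compare against the oracle
model = rh.build_toy_model(K=8, K_m=25.0)
traj = rh.simulate_ssa(model, model.initial_state({"E": 25}),
                       t_end=2200.0, seed=12, record_interval=5.0)
samp = rh.sample_stationary(traj, burn_in=200.0, interval=20.0)
print(samp.mean_total("P"), rh.mean_P_exact(params, 8))
# 47.48514851485149 44.864655255725594

# the hybrid engine is discretization-independent (K_m=50: mean ~ 7)
print(rh.hybrid_mean_P_exact(rh.toy_params(K_m=50.0)))  # 6.958160203619321
```

The first two `mean_P_exact` values show the breakdown: the well-mixed
system holds ~48.5 product molecules, the K=1000 grid only ~2.5 — a
20-fold loss that is purely a discretization artifact.  The hybrid
engine (or its slow-scale closed form, last line) removes the artifact:
its mean stays near 7 for `K_m=50` at any `K`.  That value exceeds the
deterministic steady state `100/17 ≈ 5.88` because the Poisson-distributed
enzyme total passes through a convex region of the Hill curve — the
Jensen gap, `rh.jensen_gap(params)`.

A command line mirrors the library:

```bash
rdhill analyze --km 25 --k-grid 128,256,512,1024   # oracle table + slope
rdhill simulate --engine hybrid --km 50 --K 100 --seed 1
rdhill sweep --engine ssa --k-grid 8,16,32 --km 25 --seed 1
rdhill reproduce --seed 1                          # quick pass/fail re-check
```

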