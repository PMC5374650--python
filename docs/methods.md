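# Methods

## Model

The benchmark system is a 1D domain of length `L` split into `K`
compartments ("bins") of size `h = L/K`.  Within bin `i` (copy numbers
`E_i`, `P_i`) the reaction channels and propensities are

| channel | propensity |
|---|---|
| `∅ → E_i` | `a₁ = k_s·h` |
| `E_i → ∅` | `a₂ = k_d·E_i` |
| `∅ →(E_i) P_i` | `a₃ = k_syn·h · E_iⁿ/((K_m·h)ⁿ + E_iⁿ)` |
| `P_i → ∅` | `a₄ = k_deg·P_i` |
| `E_i → E_{i±1}` | `D_E/h²` per molecule per direction |
| `P_i → P_{i±1}` | `D_P/h²` per molecule per direction |

Zeroth-order rates are densities (scale with `h`); `K_m` is a
concentration (molecules/length), so the per-bin half-saturation count
is `K_m·h`.  Default parameters: `k_s = 2.5`, `k_d = 0.1`,
`k_syn = 5.0`, `k_deg = 0.05`, `D_E = 1.0`, `L = 1.0`, Hill exponent
`n = 4`.  The derived mean total enzyme is `α = k_s·L/k_d = 25`.

Boundaries are reflecting by default (edge bins hop in one direction at
`D/h²`; interior bins in two, summing to `2D/h²`), which preserves the
uniform stationary enzyme distribution; periodic boundaries are
available.  `D_P` is not constrained by any total-count statistic
(degradation of `P` is first-order and position-independent), so it
defaults to `D_E` and may be set to 0 to halve event counts in runs
where only totals are measured.

## Exact stationary analysis (the oracle)

The enzyme subsystem — zeroth-order birth per bin, linear death, linear
diffusion — is a migration network whose stationary law is product-form:
each bin is independently Poisson(`α/K`), the domain total is
Poisson(`α`), and the pooled count of any `m` adjacent bins is
Poisson(`αm/K`).  This subsumes the binomial-thinning argument for the
empty-bin probability (`e^{-αm/K}`) and makes the layer exact rather
than approximate.  Because `P` does not feed back on `E` and is itself
linear given the synthesis drive, stationary means follow exactly:

* mean per-bin synthesis propensity: `k_syn·h · E[hill(n; m·K_m·h)]`
  with `n ~ Poisson(αm/K)`; series truncated at
  `λ + 20√λ + 50` (tail < 1e-12);
* mean total product: `K/k_deg` times that;
* slow-scale (hybrid) prediction:
  `(k_syn·L/k_deg) · E[hill(n; K_m·L)]`, `n ~ Poisson(α)` — independent
  of `K`;
* deterministic (mean-field) steady state:
  `(k_syn·L/k_deg) · hill(α; K_m·L)`; the difference from the
  slow-scale value is the Jensen gap (`hill` is convex below its
  inflection, so sub-threshold enzyme levels push the stochastic mean
  above the deterministic one).

The breakdown threshold `K > max{2LK_m, 3α}` marks where both
fine-grid approximations (occupied-bin Hill term ≈ 1 at 5% tolerance;
rare multiple occupancy) hold and the mean product collapses to the
linear law `(k_syn/k_deg)·α·h`.

## Exact SSA engine

Direct method over all channels, two uniform draws per event (waiting
time first, then channel), channel chosen as the smallest index whose
running propensity sum exceeds `r₂·a_tot` in a fixed documented
ordering (reactions bin-major, then per-species per-bin per-direction
hops).  The RNG is the Mersenne Twister in NumPy-legacy configuration,
so the compiled kernel and the pure-Python reference implementation
consume identical streams; tests assert snapshot-for-snapshot equality
between the two on short runs (reflecting and periodic, smoothed and
not).

The kernel keeps the propensity vector incrementally: each affected
entry is recomputed exactly from the current state (values identical to
a full recompute), while prefix sums live in a Fenwick tree (float for
reaction channels, integer per-species trees for diffusion weights —
the latter drift-free by construction).  The float tree is rebuilt from
scratch every 2²⁰ events, bounding accumulated rounding at ~1e-12
relative over the longest runs used anywhere in the package.  A full
recompute-per-event selection would be bit-identical only if it summed
in the same order; the package treats "same seed ⇒ same trajectory" and
"propensity values exact" as the reproducibility contract and verifies
the reference-vs-kernel equality empirically.

Smoothing: a Hill propensity may pool the enzyme population over a
centred window of `m` contiguous bins, with threshold `m_eff·K_m·h`.
Centred windows were chosen because diffusion is symmetric and the
choice of placement is otherwise open; at reflecting boundaries the
window clips and `m_eff < m` keeps the clipped propensity an unbiased
analogue of the interior formula.  The convergent policy resolves
`m = ⌈max{0.5/(K_m·h), 0.33·L/(α·h)}⌉` at model-build time (the
constant 0.33 is used verbatim rather than 1/3, for reproducibility of
the printed rule) and clamps at `K`, where smoothing degenerates to the
well-mixed propensity.

## Hybrid ODE/SSA engine

Diffusion channels form the fast subset and are integrated as ODEs;
reactions stay stochastic.  Firing times solve
`∫ₜ^{t+τ} a_tot(x(s)) ds + log r₁ = 0`, implemented as the augmented
variable `z' = a_tot(x)`, `z(t) = log r₁`, stopped at the upward
crossing `z = 0`.  Channel selection happens at the firing time `t+τ`
(the standard convention for this method family; the alternative —
propensities at `t` — is not distinguished by any test here).  After a
firing, `r₁` is redrawn and `z` reset.

Two integrators realize the same process:

* **spectral** (default): between firings the fast subsystem is linear,
  so it is propagated exactly in the diffusion eigenbasis (DCT-II
  cosine modes, eigenvalues `4D/h²·sin²(πk/2K)`, under reflecting
  boundaries; Fourier modes under periodic).  `z` is accumulated by
  composite Simpson quadrature on a geometric time grid starting at
  `0.25/λ_max` (resolving the post-firing relaxation transient) and
  growing ×2 per step; the bracketing step is refined with an
  8-interval cumulative-Simpson table and a bracketed Brent solve,
  giving the crossing to ~1e-9 relative in time.
* **lsoda**: LSODA on the augmented `(x, z)` system with event
  detection — the classical realization, kept as an independent check.
  The integral variable is excluded from the error-control vector by
  default (switchable); the Jacobian is treated as banded, which is
  exact for the diffusion block (the dense `z` row does not feed back
  into `x`, so its omission cannot bias the solution, only Newton
  convergence).

The two paths agree to ~1e-12 in species totals with identical firing
sequences on test problems; the spectral path is used for production
because the diffusion stiffness (`λ_max = 4D/h²`, ~4·10⁶ at `K = 1000`)
does not limit it.

Slow propensities are evaluated on the continuous state: zeroth- and
first-order ones on the raw species totals (exactly integer between
firings, since diffusion conserves totals and firings add integer
stoichiometries), Hill ones on per-bin values clamped at zero.  A
degradation firing in a bin holding less than one molecule briefly
drives that bin negative; the dip relaxes diffusively and total counts
stay exact.  Clamping the dip away instead would destroy mass balance —
each firing must remove exactly one molecule globally.  Consequently
the "per-bin values stay non-negative" picture holds only up to these
transient firing dips, which the engine monitors at the level that
matters (species totals must stay non-negative).

Smoothing policies are ignored by the hybrid engine: the continuous
relaxed enzyme profile already supplies the intermediate values that
smoothing exists to recover.

## Synthetic data / study conditions

There is no external data; the model builders *are* the data
generators.  Simulation protocols default to: burn-in 200 time units
(ten relaxation times of the slowest linear mode, `1/k_deg = 20`),
sampling interval 20 (one relaxation time), replicate seeds = base
seed + index.  Stationary standard errors use non-overlapping batch
means (20 batches), which absorb residual autocorrelation of thinned
samples.

Problem sizes used by the validation suite were chosen to keep the full
run in the tens of minutes on one core while leaving every statistical
band meaningful: SSA-vs-oracle at `K ∈ {1,4,8,16}` over 2200 time
units; per-bin Poisson statistics at `K = 16` with 10⁴ samples thinned
at the enzyme-total relaxation time (run with `D_E = 0.2, D_P = 0` —
the product-form law under test is provably independent of `D`, so
reducing it removes only uninformative diffusion events); the smoothed
spot check at `K = 200` over 1500 time units, thinned so batch means
span several product relaxation times (again with reduced `D`, for the
same reason); hybrid runs
at `K ∈ {10,100,1000}`, 10 replicates × 1200 time units.  What these
runs demonstrate is agreement between engines and the exact stationary
layer under the stated model — they do not probe features absent from
the model (no feedback of `P` on `E`, no bimolecular reactions, one
spatial dimension, spatially homogeneous parameters).

## Known limitations and observed discrepancies

* The convergent-smoothing rule keeps the pooled window mean pinned
  near `max{0.5·α/K_m, 0.33}` molecules.  The exact analysis therefore
  gives a *flat but biased* fine-grid plateau: ~77% of the well-mixed
  mean at `K_m = 25`, and several times the well-mixed mean at
  `K_m = 50` (a window of radius ~0.013·L has a scaled threshold of
  only ~0.66 molecules, which local occupancy spikes exceed easily even
  though the global enzyme level sits far below `K_m·L`).  The
  qualitative claim that adaptive-radius smoothing "stays accurate for
  all h" does not survive quantification at the 10% level; the
  validation suite records this as a failing check by design rather
  than loosening the tolerance (see the test docstring).
* Smoothing applies to Hill propensities only; kernel-weighted
  (non-uniform) windows and smoothing of other rate laws are out of
  scope, as are 2D/3D domains, bimolecular mesh corrections, and
  tau-leaping-style accelerations.
* The hybrid engine assumes the fast subset is pure diffusion; there is
  no automatic fast/slow partitioning.
* `all_propensities` and the reference SSA are O(channels) per event
  and exist for validation, not production.
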