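# eprtools

Inference of entropy production rates from trajectory data, for
bead-spring chains driven by unequal heat baths.

## The problem

A chain of `n` overdamped beads, coupled by springs of stiffness `k` and
anchored to walls at both ends, moves in baths of different temperatures
(friction `γ`, units `k_B = 1`):

    dx/dt = A x + F ξ(t),   A = (k/γ)·tridiag(1, −2, 1),
    F = diag(√(2Tᵢ/γ)),     D = F Fᵀ/2.

Unequal temperatures break detailed balance: the stationary state carries
probability currents and continuously produces entropy at rate

    Ṡ_ss = Tr{A D⁻¹ A C − C⁻¹ D},     A C + C Aᵀ + 2D = 0,

which for two beads reduces to `k (T_h − T_c)² / (4 γ T_h T_c)`.  The
package is for researchers in stochastic thermodynamics and active-matter
biophysics who want to quantify — not just detect — irreversibility from
time-series data.  Three strategies are implemented:

1. **Spatial average** — estimate the density `ρ̂`, current `ĵ` and
   force `F̂ = ĵᵀD⁻¹/ρ̂` on a grid, then integrate `F̂·ĵ` over space.
2. **Temporal average** — the Stratonovich sum
   `(1/τ_obs) Σ F̂((xᵢ+xᵢ₋₁)/2)·(xᵢ−xᵢ₋₁)` along the path.
3. **TUR bounds** — for any weighting field `d(x)`, the generalized
   current `j_d` obeys the thermodynamic uncertainty relation
   `Ṡ_ss ≥ 2⟨j_d⟩²/(Δτ·Var j_d)`; its cumulants are measured from
   trajectory windows, or computed exactly on a lattice discretization
   as derivatives of the tilted-operator maximum eigenvalue, and the
   weighting is optimized by Metropolis sampling in a Gaussian basis.

## Worked example

```python
import eprtools as ep

model = ep.build_chain(2, k=1.0, gamma=1.0, temps=(250.0, 25.0))
state = model.steady_state()
print(state.epr, state.heat_flow)          # 2.025 56.25

traj = ep.euler_maruyama(model, ep.draw_steady_initial(model, 1),
                         dt=1e-3, n_steps=2_000_000, seed=1)
fit = ep.EntropyProductionModel(traj, model).fit("tur",
                                                 force=state, window=100.0)
print(fit.summary())
```

prints

```
2.0250000000000004 56.25
Entropy production rate estimate
============================================
method                                   tur
tau_obs                                 2000
estimate (k_B/time)                  1.38322
standard error                      0.454895
window                                   100
n windows                                 20
current mean                         2.08103
current variance                   0.0625722
analytic EPR                           2.025
============================================
```

The analytic dissipation rate of this chain is 2.025 k_B/time; the mean
of the entropy-production current (2.08 ± noise) estimates it directly,
while the TUR bound certifies `Ṡ_ss ≥ 1.38` from the current's
fluctuations alone — about 68 % of the truth, consistent with the exact
lattice tightness η ≈ 0.67 at this strong driving.  Near equilibrium
(`T_c/T_h → 1`) the bound becomes tight (η → 1).

A command-line layer exposes the same pipeline
(`eprtools simulate|estimate|epr|tur|ldt|optimize|sweep`); every run
echoes its parameters and seeds as JSON for reproducibility.

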