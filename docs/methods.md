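# Methods

## Model

The system is a chain of `n ≥ 2` overdamped beads in one dimension,
coupled to nearest neighbours and to rigid walls at both ends by linear
springs of stiffness `k`, each bead immersed in its own bath of
temperature `Tᵢ` exerting friction `γ`.  With `k_B = 1` (temperatures
stored as energies), the displacement vector obeys the Langevin equation
`dx/dt = A x + F ξ` with `A = (k/γ)·tridiag(1, −2, 1)` (Hurwitz for all
`n`) and `F = diag(√(2Tᵢ/γ))`; the associated Fokker-Planck diffusion
tensor is `D = F Fᵀ/2 = diag(Tᵢ/γ)`.  "Linearly ramped" temperatures are
linear interpolation inclusive of both endpoint values.

The stationary state is the zero-mean Gaussian whose covariance solves
the Lyapunov equation `A C + C Aᵀ + 2D = 0`, solved densely
(Bartels–Stewart via `scipy.linalg.solve_continuous_lyapunov`); no
iterative solver is needed at these sizes.  From `C` follow the
stationary current `j_ss(x) = (A + D C⁻¹) x ρ_ss(x)`, the conjugate
thermodynamic force `F(x) = (A + D C⁻¹ x)ᵀ D⁻¹` (linear in `x`), the
local dissipation `σ̇_ss = F·j_ss ≥ 0`, and the total rate
`Ṡ_ss = Tr{A D⁻¹ A C − C⁻¹ D}`, which for two beads equals
`k(T_h−T_c)²/(4γT_hT_c)` with heat flow `Q̇ = k(T_h−T_c)/(4γ)`.

## Simulation

*Continuous space.*  The Euler scheme
`x_{i+1} = x_i + A x_i Δt + F η`, `η ~ N(0, Δt I)`, default
`Δt = 10⁻³` (a warning fires when `Δt·max|eig A| ≥ 0.1`).  Because the
model is linear, steady-state initial conditions are drawn exactly from
`N(0, C)` rather than by burn-in (a burn-in variant exists for
generality).  The inner loop is numba-compiled with a numpy fallback;
noise is generated in bounded chunks so arbitrarily long runs use
constant memory per chunk.

*Discrete space.*  Configuration space is truncated to a rectangular box
and discretized; jumps connect nearest neighbours with rates
`W(x → x ± hₐeₐ) = D_aa/hₐ² ± (Ax)ₐ/(2hₐ)`, the standard discretization
whose generator converges to the Fokker-Planck operator as `h → 0`
(verified by moment tests).  Edges leaving the box are dropped
(reflecting walls — probability-preserving).  Construction fails loudly
if any rate is negative, which happens when the box extends into
drift-dominated territory for the chosen resolution; the default
two-bead box is `[−50,50]×[−20,20]` with 200×200 sites (about 4σ of the
reference stationary state), and `model_lattice` builds ±`n_sigma`·σ
boxes for other parameters.  Coarse grids need proportionally smaller
boxes (e.g. the 60×60 optimization grid uses a 3σ box).  Jump
trajectories are sampled exactly with the Gillespie algorithm
(numba-compiled; waiting times exponential in the site's exit rate).

## Field estimation

Histogram estimators bin the samples on a 100×100 grid (same box).
Smooth estimators use a Gaussian kernel for the density and the
separable Epanechnikov product kernel for the current regression, with
per-dimension bandwidths from the Bowman–Azzalini rule
`b = (4/(N(d+2)))^{1/(d+4)} σ̃/0.6745`.  Two robust scales σ̃ are
offered: the mixed form `√(MAD(|v|)·MAD(xⱼ))` (central-difference speed
magnitudes times positions) and the plain per-dimension position MAD.
The mixed form's scale grows like `Δt^{-1/4}` through the velocity
factor; in five dimensions it yields bandwidths wider than the
stationary spread, so grid-free kernel regression defaults to the
position MAD.  Both are exposed; neither is asserted as canonical.

On grids, smooth-kernel estimates are computed by histogramming and then
convolving with the discretized kernel — exact up to the bin width,
which is several times smaller than any bandwidth used here.  The
current estimate is the kernel-weighted mean of central-difference
velocities `(x_{i+1}−x_{i−1})/(2Δt)` times the density estimate; the
plug-in force is `F̂ = ĵᵀD⁻¹/ρ̂`, restricted to bins with at least 5 raw
samples (flagged bins contribute zero to spatial sums and force
lookups — extrapolating the estimate beyond the data produces spurious
values, so exclusion is the conservative choice).

Where grids are infeasible (five beads), `KernelForceField` performs
exact point-wise Epanechnikov regression of the velocities with a
KD-tree; in the plug-in force the density cancels (`ĵ/ρ̂` is the local
mean velocity), so only the regression matters.  **In-sample exclusion:**
when the force is evaluated at midpoints of the same trajectory it was
trained on, training samples within 2 steps of the evaluation step are
excluded from the neighbourhood — the central-difference velocity at the
query's own step shares the step's noise increment, and without the
exclusion temporal functionals acquire an `O(1/Δt)` upward bias that
dwarfs the signal.

## Direct estimators

The spatial average is the Riemann sum of `F̂·ĵ` over estimated bins;
the temporal average is the Stratonovich midpoint sum divided by
`τ_obs`, with nearest-bin force lookup (bilinear interpolation was
considered and rejected as an unforced complication; the bin width is
well below the force's variation scale).  Error bars come from 10
independent replicate trajectories.  Both estimators converge to `Ṡ_ss`,
the temporal one faster — the spatial sum weights poorly-sampled regions
equally, the temporal sum samples space exactly where the data are.

## Currents and TUR bounds

A weighting field `d(x)` defines the generalized current
`J_d = Σ d(midpoint)·Δx` (continuous paths) or the sum of antisymmetric
edge weights `d_{x→x+h} = d(x+h/2)·h` (lattice paths).  Trajectories are
split into non-overlapping windows of length `Δτ` (overlap would bias
the variance); the TUR bound is `2⟨j_d⟩²/(Δτ·Var j_d)` with `Δτ` the
window length.  Default `Δτ = 100·γ/k`, far beyond the slowest
relaxation time `γ/k`, where the variance has reached diffusive scaling.
The squared sample mean is debiased by `Var/n_windows` (floored at 0):
with finite windows the raw square overestimates `⟨j_d⟩²` by exactly the
variance of the mean, which near equilibrium can push the "lower bound"
above the true rate.  The raw plug-in is available via a flag.

## Exact cumulants (tilted operator)

On the lattice, the scaled cumulant generating function φ(λ) of a
current is the maximum eigenvalue of the generator with off-diagonals
multiplied by `e^{λd}` (diagonal unchanged).  Central differences give
`⟨j_d⟩ = φ'(0)` (step `δλ = 10⁻⁵`) and `φ''(0)` (its own step, default
`10⁻²`): in double precision the curvature signal `φ''δλ²` at `10⁻⁵`
sits at the eigensolver's noise floor, while the truncation error of the
wider step, `O(φ⁗δλ²/12)`, is far below every tolerance used here.
φ(0) is computed as a consistency check (must vanish) and subtracted
from the second difference.

Eigenvalues are found by shift-invert Arnoldi iteration (`scipy`
`eigs`, deterministic uniform start vector, warm restarts): the sought
eigenvalue lies within `|λ|·max|d|` of zero while the rest of the
spectrum sits beyond the relaxation gap `≈ k/γ`, so a shift of `k/(2γ)`
isolates it and delivers near-machine absolute accuracy.  Matrices with
at most 400 states use a dense solve.  Exact tightness
`η = Ṡ_TUR^(F)/Ṡ_ss` is restricted to two beads (the state count
explodes for longer chains).  At a fixed box the lattice cumulants carry
a truncation floor from the reflecting walls (≈0.07 % at 4σ); φ'(0)
converges to `Ṡ_ss` only when spacing and box are refined together.

## Weight-field optimization

`d(x)` is parameterized by `M = 100` Gaussians: `M/2` free centres
uniform over the box, breadths `B_ii = (0.1·axis length)²`, each free
Gaussian carrying an *n-vector* weight (the scalar-envelope form is
recovered per component); the other `M/2` sit at the mirrored positions
with negated weights so `d(−x) = −d(x)` exactly.  Metropolis sampling
targets `exp(β·Ṡ_TUR^(d))` with `β = 5000`: free weights are perturbed
by uniform noise of half-width 0.5 (random start, weights initialized
uniform on [−1,1]) or 0.05 (perturbative start about the analytic force,
weights initialized at zero), run for 500 steps.  Ratios are always
evaluated from exact lattice cumulants — optimizing a ratio estimated
from a single trajectory rewards that trajectory's sampling noise
(over-optimization); a cross-validated sampled mode (optimize on one
trajectory, score on an independent one) is provided for completeness.
Non-finite proposals are rejected and logged; the best-so-far ratio is
monotone by construction.

## Synthetic-data conditions and problem sizes

All validation data are generated by the package's own simulators under
the reference conditions: two beads with `k = γ = 1`, `T = (250, 25)`
(`Ṡ_ss = 2.025`), `Δt = 10⁻³`, 10 replicates for error bars, and the
five-bead linear ramp 25→250 at `τ_obs = 1200`.  The test suite uses
`τ_obs ∈ {2·10³, 10⁴}` for the convergence study, Gillespie runs of
`τ_obs = 2000` on the 100×100 lattice (window 40), 500-step Metropolis
runs on the 60×60/3σ grid, and 3 bandwidth scales × 5 replicates for the
five-bead bandwidth study with kernel regression on a 20 000-sample
training subset evaluated on every 40th step.  The bandwidth scales
(1, 2, 4 × rule of thumb) span the rule-of-thumb and over-smoothed
regimes; below the rule of thumb, five-dimensional neighbourhoods at
this data volume are nearly empty and both estimators degenerate to the
same few-sample noise, which probes sample starvation rather than
bandwidth sensitivity.

What the Gaussian linear model does *not* emulate: nonlinear or
multiplicative forces, measurement noise, hidden degrees of freedom, and
non-stationarity — all present in real tracking data.  Passing tests
demonstrate correctness of the estimators under the model's assumptions,
not robustness to those complications.

## Known limitations

- The spatial estimator is impractical beyond d ≈ 3; it is provided for
  two beads only in practice.
- Near equilibrium the sampled TUR bound has vanishing signal-to-noise;
  resolving the saturation η → 1 by sampling would need ~10⁹ steps, so
  that claim is verified exactly on the lattice instead.
- The lattice machinery (exact cumulants, optimization) is limited to
  two beads by state-count growth.
- Kernel estimates on grids are binned approximations; exact only up to
  the bin width.
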