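# Methods

## Model

`elastochain` treats a polypeptide fragment as a freely jointed chain (FJC):
`N` rigid links of length `a` with free rotation at the joints, in thermal
equilibrium at temperature `T`. The constitutive force–extension law is

    F = (k_B·T / a) · L⁻¹(L / (N·a)),      L(x) = coth(x) − 1/x,

the purely entropic elasticity of an ideal chain: zero force at zero
end-to-end distance, divergence at the contour length `L_max = N·a`, and a
slope that never decreases (the elastomeric signature). The model carries no
enthalpic stretching, no excluded volume, no sequence chemistry: the
glycine-rich fragments are represented only through their chain statistics.

Derived quantities:

- `L_max = N·a`; given a printed contour length, `N = round(L_max/a)` (ties
  away from zero; the unrounded quotient is kept for diagnostics).
- Equilibrium end-to-end distance `⟨L⟩ = √N·a`. This is the random-walk
  root-mean-square value (`⟨L²⟩ = N·a²`). Some presentations of the model
  write the equilibrium distance as `N·a`, but the numerical outputs that
  accompany that statement (31.4 Å for N = 15, a = 8.1 Å; 37 Å for N = 21)
  are `√N·a`, so the square-root form is what this package implements.
  Note the distinction from the mean *magnitude* of the end-to-end vector,
  which for an ideal chain is `√(8/3π)·√N·a ≈ 0.92·√N·a`; which of the two
  a reported simulation average corresponds to is generally ambiguous, and
  the package's tolerance choices for simulator checks cover the gap.
- Hidden length `L_hl = L_max − ⟨L⟩` and its ratio `L_hl/⟨L⟩`. Where a
  measured zero-force grand mean is available it is used *unrounded*; this
  reproduces the published 79 Å and 106 Å exactly at display rounding.

Units are pN, Å, K and ps everywhere; `k_B = 0.1380649 pN·Å/K` (the SI
value converted; 1 J = 1e22 pN·Å), so `k_B·T = 41.14 pN·Å` at 298 K.

## Numerics of the Langevin pair

`langevin(x)` evaluates `coth(x) − 1/x` via `1/tanh(x) − 1/x`; below
`|x| < 1e-4` the Taylor series `x/3 − x³/45` avoids catastrophic
cancellation (the two branches agree to ~1e-11 at the threshold).
`inverse_langevin(y)` is defined for `|y| < 1` and raises a
`FullExtensionError` outside (the force diverges at full extension). For
`|y| < 1e-6` it uses the series inverse `3y + 1.8y³`; otherwise Brent
root-finding on a bracket grown from the Padé estimate
`y(3 − y²)/(1 − y²)`, followed by a Newton polish to a residual of 1e-10
(default `tol`). Round trips hold to 1e-9 over `x ∈ [−10, 10]` and
`y ∈ (−0.999, 0.999)`.

## Synthetic data

Two generators replace atomistic pulling simulations at the resolution the
analysis consumes — per-frame Cα-trace conformations and end-to-end
distances. What they deliberately do *not* emulate: solvent and ions,
sequence-dependent energetics, secondary-structure formation, bond rupture,
and realistic absolute time scales. Tests passing on these generators
demonstrate the correctness of the analysis chain and the internal
consistency of the FJC treatment, not the behaviour of real peptides.

**Exact sampler** (`sample_fjc_end_to_end`). Under a constant force `F`
along z, the links of an FJC decouple and each polar cosine follows
`p(c) ∝ exp(f̃·c)` with reduced force `f̃ = F·a/(k_B·T)`. Sampling is by
inverse CDF in the overflow-safe form `c = 1 + ln(u + (1−u)e^(−2f̃))/f̃`,
`u ∈ (0, 1]`; azimuths are uniform; at `F = 0` links are uniform on the
sphere. The mean fractional *axial* extension is exactly `L(f̃)` — this
sampler is the package's internal oracle for everything else. Force–
extension curves built from it record the axial mean (the statistic the
closed form describes); magnitude means exceed axial means at low force and
would bias the fitted link length upward (~7% at the 16-force desk scale).

**Brownian dynamics** (`simulate_trajectory`). Overdamped Euler–Maruyama
dynamics of `N+1` beads joined by harmonic bonds of rest length `a`:

    x ← x + (f/γ)·dt + √(2·k_B·T·dt/γ)·ξ,   ξ ~ N(0, 1) per coordinate,

with constant forces −F/+F on the two end beads along z and the fully
extended conformation as the start (the analogue of relaxing from a
β-pleated geometry). Defaults: bond stiffness `k = 200 k_B·T/Å²` (bond
fluctuations ±0.07 Å, and at 600 pN the per-bond stretch `F/k` ≈ 0.07 Å,
keeping the chain within 0.1% of `L_max`), reduced friction `γ = 1
pN·ps/Å`, 1000 saved frames per run. The timestep, if not given, is the
largest value satisfying two guards: per-step RMS displacement
`√(6·k_B·T·dt/γ) < 0.1·a` (the coarse-sampling guard) and
`dt ≤ 0.25·γ/k_phys` (Euler stability/accuracy for the stiffest bond mode
— the binding constraint at the default stiffness, giving dt ≈ 3e-5 ps).
Violating either raises a `ConfigurationError` before the run. The numba
kernel is a pure function of its seed; identical seeds give bit-identical
trajectories.

Because the printed contour lengths are not integer multiples of the link
length (118.1/8.1 = 14.58), the CLI renders each fragment's chain with
`N = round(L_max/a)` links of length `L_max/N` (7.873 Å and 7.929 Å), so the
simulated contour equals the fragment's `L_max` and ladder curves respect
the curve invariant `mean L ≤ 1.02·L_max`.

**Run lengths.** The integrated autocorrelation time of `R²` for the
15-link chain is ≈5 ps (measured once on a long run), and the zero-force
relaxation from full extension takes ≈40 ps. The default 3e6-step run
(≈90 ps at the stiff-bond timestep) suffices for qualitative behaviour;
statistics-grade comparisons against the exact sampler use three replicates
of 2e7 steps at bond stiffness 20 k_B·T/Å² (≈6,000 ps each, pooled ⟨R²⟩
standard error ≈2%), since the zero-force chain statistics are insensitive
to bond stiffness (the harmonic correction to ⟨R²⟩ is ~0.2% at k = 20)
while the stable timestep scales inversely with it. The near-full-extension
check (600 pN within 5% of `L_max`) keeps the stiff default it genuinely
requires.

## Trajectory analysis

End-to-end series are first-to-last bead distances per frame. RMSD series
use least-squares rigid superposition (Kabsch via SVD, proper rotation
enforced) against the fixed extended starting conformation; for the
collinear reference the optimal rotation is degenerate but the minimised
RMSD remains well defined. Superposition is implemented on the Cα trace —
the synthetic model's full resolution.

Equilibration is detected by RMSD stabilisation: the first sliding window
(default 100 frames, 10% of a run) whose standard deviation falls below
`rel_tol = 0.25` of the whole-series standard deviation. Both parameters are
configurable; the defaults assume the transient occupies a material fraction
of the series (as in runs that equilibrate halfway through). For long runs
that are stationary almost from the start the criterion cannot trigger — the
detector then returns the last admissible window with `converged=False`, and
the pipeline falls back to a fixed 10% burn-in.

Per-trajectory summaries are the mean and sample SD (n−1) of `L` over the
equilibrated window. Replicates combine as the arithmetic mean of the
per-trajectory means with the *standard error* (sample SD/√n) as the
displayed spread — this is the convention that reproduces the published
±3/±5 Å (the replicate SDs themselves are 5.3 and 8.3 Å); both statistics
are retained.

## Force–extension fitting

Per-force records (force, mean L, SD, frame count) assemble into a validated
curve (strictly increasing forces; duplicates merged by pooled mean and
pooled within+between variance; no point above `1.02·L_max`). The link
length is fitted in the extension domain — the protocol controls force and
measures length — minimising `Σ wᵢ(Lᵢ − L_max·L(Fᵢ·a/k_B·T))²` with
`wᵢ = 1/sdᵢ²` (unit weights if any SD is zero), by a 0.05 Å grid scan over
the bounds (default 2–20 Å) refined with bounded minimisation to 1e-4 Å.
A fit landing at a bound sets a warning flag. The zero-force point is
excluded: the model's mean end-to-end *vector* vanishes at `F = 0`, whereas
a measured zero-force `⟨L⟩` is a magnitude mean. A joint mode pools
residuals across fragments to fit one shared link length. The fit is
scale-consistent (multiplying forces and temperature by the same factor
leaves `a` unchanged) and recovers noiseless ground truth to well under
0.01 Å anywhere in the bounds.

`analyze_fragment` assembles the full report: fitted (or pinned) `a`,
`N`, theoretical `√N·a`, measured equilibrium grand mean, hidden length and
ratio from the unrounded mean, and the smallest ladder force whose mean
extension reaches 99.5% of `L_max` (absent if never reached). Display
rounding follows the published precision — one decimal below ~37 Å, nearest
integer above — while raw double precision is kept throughout.

## Known limitations

- The maximum sustainable forces of real fragments (≈250/400 pN) are
  outcomes of atomistic simulations and enter only as packaged constants;
  the bead–spring chain has no rupture mechanism.
- The BD integrator is first-order; its bond-fluctuation variance is
  inflated by ~14% at the default timestep factor (irrelevant to chain
  statistics but visible in bond-level observables).
- No worm-like-chain or extensible-FJC variants; no bootstrap uncertainty
  on the fitted link length (residuals only).
- The equilibration detector is a stabilisation heuristic, not a
  changepoint method; it assumes a visible transient.
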