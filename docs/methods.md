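# Methods note

This note records the model definitions, unit conventions, numerical
choices, and limitations behind `etpath`. Everything quantitative stated
here is computed by the test suite or `scripts/acceptance.py`.

## Units and constants

- Energies in kcal/mol throughout the library, except the tunneling-ruler
  barrier, which the ruler formula takes in eV
  (`KCAL_PER_EV = 23.061`).
- `KB_KCAL = 0.0019872` kcal/mol/K; default temperature 298.15 K
  (titration generators default to 300 K).
- Distances in Å; redox potentials in mV; Faraday constant
  23.061 kcal/mol/V.

## Marcus crossing (`etpath.marcus`)

Reactant and product diabats are parameterized on a dimensionless
transfer coordinate x:

    E_R(x) = λ_r x²,    E_P(x) = ΔG + λ_p (x − 1)²

The activation energy is E_R at the lowest-energy crossing, found from
the quadratic `(λ_r − λ_p) x² + 2 λ_p x − (λ_p + ΔG) = 0`. When two
crossings exist, the one of lower reactant energy (smaller |x|) is taken.
A crossing at x < 0 marks the inverted region. The reverse barrier obeys
detailed balance, `E‡_rev = E‡_fwd − ΔG`, exactly.

Edge cases are rejected, not patched: non-positive λ, and parameter sets
whose parabolas never intersect (nested parabolas; possible when
λ_r ≠ λ_p) raise `ValueError`. At ΔG = −λ (symmetric case) the crossing
sits at the reactant minimum x = 0 and the barrier is exactly zero.

The equal-curvature identity `ΔG‡ = (ΔG + λ)²/4λ` is verified to 1e-9
relative, and the general solution to 1e-4 kcal/mol against an
independent dense-grid + root-refinement oracle over random triples.

## Tunneling ruler and velocities

    log10 k_ET = 15.0 − 0.6 R − 12.4 ΔG‡[eV]
    log10 v_ET = log10 k_ET + log10(abundance)

Negative barriers are rejected rather than clamped; abundances must lie
in (0, 1]. `rank_pathways` sorts by velocity, flags the fastest donor per
acceptor, converts a donor with missing abundance into an error record
(never silently dropped), and reports a ±1 σ distance band when a
distance standard deviation is given. Rounding to one decimal happens
only in the report/IO layer, never inside computations.

## Titration microstates (`etpath.titration`)

Microstate energy over binary occupancies x ∈ {0,1}ⁿ
(1 = deprotonated / reduced):

    E(x) = Σᵢ xᵢ eᵢ + Σ_{i<j} xᵢ xⱼ Wᵢⱼ
    eᵢ = ln10 · k_B T (pKaᵢ − pH)   (proton sites)
    eᵢ = F (E_h − E°ᵢ) / 1000       (redox sites, potentials in mV)

With this sign convention a lone proton site reproduces
Henderson–Hasselbalch exactly (deprotonated fraction ½ at pH = pKa,
increasing with pH). The interaction matrix must be symmetric with zero
diagonal.

Exact occupancies come from vectorized 2ⁿ enumeration (n ≤ 20). The
Monte Carlo path is a numba-compiled single-site-flip Metropolis kernel:
10 % burn-in, block averaging over 10 blocks for standard errors,
per-grid-point seeds drawn from one master seed. At 10⁶ steps the MC
occupancies of coupled ≤ 12-site systems match enumeration within 0.01
(typically within 5 × 10⁻⁴). Redox midpoint shifts are computed from
exact occupancy-vs-E_h scans (default 800 mV window, 20 mV step) with
linear interpolation at the half-occupancy crossing; midpoints outside
the window are flagged, not extrapolated.

## Outer-sphere reorganization (`etpath.reorg`)

From a reactant-ensemble vertical-gap trajectory (default 20 %
equilibration discarded, ≥ 100 frames enforced):

    λ_var    = Var(ΔE) / (2 k_B T)
    λ_Stokes = ⟨ΔE⟩_R − ΔG

Standard errors come from a moving-block bootstrap (200 resamples) with
block length 20× the integrated autocorrelation time
(initial-positive-sequence estimator), so correlated frames are not
treated as independent. On synthetic linear-response series with
λ = 5 kcal/mol and n = 10⁵ frames both estimators recover λ within 2 %
and agree within 3 pooled standard errors; the variance/Stokes ratio
("linearity ratio") is ~1 under Gaussian statistics. `corrected_activation`
adds λ_out to both parabolas (λ_total = λ_inner + λ_out per state) and
reports the barrier increment.

## WHAM (`etpath.wham`)

Standard self-consistent histogram iteration over harmonic-bias windows:
global bin grid anchored at `floor(min/Δ)·Δ`, first window offset pinned
to zero, empty interior bins detected and reported as an error naming the
gap interval (no silent interpolation across unsampled regions).
Convergence tolerance 1e-6 on the offsets, max 10⁵ iterations,
non-convergence reported honestly in the result. The PMF is min-anchored;
`binding_depth` is the unbound-plateau mean minus the bound-region
minimum. With the standard protocol (15 windows, 0.7 Å spacing,
k = 14 kcal/mol/Å², 10⁴ samples/window) a known 10 kcal/mol double-well
depth is recovered within 0.5 kcal/mol; the solution also agrees with an
independently implemented binless MBAR estimator on the well-sampled
interior bins.

## Reaction network (`etpath.network`)

Edges are `thermal` (Eyring, prefactor k_B T/h ≈ 6.21 × 10¹² s⁻¹ at
298.15 K; 22.3 kcal/mol ↔ ~1 h⁻¹) or `et` (tunneling ruler, requires a
distance). An optional `lambda_out_increment` adds an outer-sphere
correction to the effective barrier; `spin_allowed=False` excludes a
channel from branching with an explanatory note instead of assigning it a
rate. `branch_ratio` normalizes the allowed channel rates to fractions.
Externally supplied barriers (quantum-chemistry level) enter only through
these rate laws; the library does not recompute them.

## Synthetic generators (`etpath.synth`)

Generator defaults are the study conditions; they are never tuned toward
test passes.

- `gen_gap_series`: AR(1) process with mean ΔG + λ, variance 2 k_B T λ,
  lag-1 coefficient exp(−1/τ) — i.e., exactly the linear-response link
  the estimators assume.
- `gen_titration_system`: random pKa values in a range with Gaussian
  couplings of a set scale (symmetrized, zero diagonal).
- `gen_umbrella_windows`: vectorized Metropolis chains, one per window,
  on the biased potential; burn-in 2000 steps, thinning 5; acceptance
  rates attached for diagnostics.
- `table_fixture`: the packaged nine-couple benchmark (distances,
  activation energies, reactive-form abundances) used by the examples,
  the acceptance script, and the tests.
- `mechanism_network`: the packaged branching network of the downstream
  photochemistry (hydride branches, thiolate quench, oxygen channels).

## Limitations

- The tunneling ruler is an empirical average over protein media; no
  packing or secondary-structure corrections are included.
- Linear-response λ estimators assume Gaussian gap statistics; the
  linearity ratio is the only non-Gaussianity diagnostic provided.
- The titration model has fixed pairwise couplings (no conformational
  relaxation, no Poisson–Boltzmann solver, no structure parsing).
- Branching analysis is a steady-state rate comparison, not a kinetic
  master-equation integration; oxygen channels implicitly assume
  saturating O₂.
- The WHAM implementation is 1-D only.
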