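# Methods

## The model

`despotsim` simulates and fits the steady-state signals used in
multi-component driven-equilibrium T1/T2 (DESPOT-style) myelin water
imaging.  A voxel is modelled as two exchanging water pools: a fast-relaxing
myelin-water pool (F) and a slow-relaxing intra/extra-cellular pool (S),
described by relaxation times T1F, T1S, T2F, T2S, equilibrium fractions
M0F = MWF and M0S = 1 − MWF, and first-order exchange rates k_FS and k_SF
coupled by detailed balance k_FS·M0F = k_SF·M0S (only k_FS is free).

Longitudinal magnetisation evolves as dMz/dt = A·Mz + C with

    A = [[−1/T1F − k_FS,  k_SF        ],      C = (M0F/T1F, M0S/T1S)ᵀ,
         [ k_FS,         −1/T1S − k_SF]],

and transverse magnetisation adds 1/T2 relaxation and precession at the
effective off-resonance angular frequency.  Excitation is an instantaneous
rotation about x.  Two sequences are modelled:

* **SPGR** (spoiled gradient echo): transverse magnetisation is assumed
  perfectly spoiled each TR, so only the longitudinal 2-vector matters.  The
  pre-pulse steady state is Mz⁻ = (I − e^{A·TR} cos α)⁻¹ (e^{A·TR} − I) A⁻¹ C
  and the signal is sin α times the pool sum.
* **bSSFP** (balanced steady-state free precession), in phase-cycled
  (Δφ = 180°) and non-phase-cycled (Δφ = 0°) variants: the full 6-dimensional
  Bloch–McConnell state is propagated; the RF phase-cycling increment adds
  directly to the per-TR precession angle, β = 2πΔf·TR + Δφ.  The steady
  state solves M⁻ = E₆ R_x(α) M⁻ + b and the signal is the magnitude of the
  summed transverse components immediately post-pulse.

Signals are evaluated at the pulse (no echo-time decay): the simulation
study never uses TE, and omitting it only rescales bSSFP signals by a
constant that normalization removes.  Magnetisation-transfer (semisolid)
pools, finite pulse shapes and imperfect spoiling are out of scope.

### Numerical solution

Rather than forming 6×6 matrices per candidate, the free-precession
propagator is block-diagonalised analytically: the transverse x/y pairs are
written as a complex 2-vector (M_x + iM_y per pool) whose propagator is the
closed-form exponential of a complex 2×2 matrix, and the longitudinal pair
uses the real 2×2 exponential.  The steady-state linear system is then
solved by chained 2×2 block elimination.  Everything is expressed as
element-wise numpy algebra over a leading batch axis, so hundreds of
thousands of candidate parameter sets are evaluated per second — this is
what makes the Monte Carlo studies tractable at full fidelity.  The 2×2
exponential uses exp(M) = e^μ(cosh d·I + sinh(d)/d·(M − μI)) with a series
fallback for |d| < 1e−6; singular steady-state systems (impossible for
physical parameters) raise a `NumericalModelError` naming the offending
block.  The closed-form solver is validated in the test suite against
5000-TR discrete propagation from thermal equilibrium (independent
scipy-`expm` implementation) to ≤1e−8 relative error for every built-in
tissue × scheme combination, and against the textbook single-pool closed
forms in the degenerate limits.

### Normalization

Measured SPGR and bSSFP images are normalised to the mean signal of each
sequence before fitting.  The package's default treats SPGR as one
normalization group and pools both bSSFP phase cycles into a second group;
a `per_sequence` switch normalises the three blocks separately.  The model
predictions inside the fitter are normalised with the same grouping as the
data, so the fit is scale-free.

## Built-in study configurations

Five literature search-bound sets (B1–B4 and their widest envelope WPB),
three acquisition schemes (S1: 10+10+10 images at TR 6.5 ms; S2: 8+8+8 at
TR 5.6/4.4 ms; S3: a reduced 6+6+2 scheme at TR 7 ms) and four reference
tissues (HB "human brain", WML white-matter-like, INT intermediate, GML
grey-matter-like) ship as immutable objects.  T2 values are milliseconds in
configuration files (as printed in the literature tables) and seconds
internally; flip angles are degrees, converted to radians at the
computation boundary.  All tissues are on-resonance and lie inside every
bound set.

## Synthetic data

Monte Carlo realizations add i.i.d. real Gaussian noise to the raw forward
signals, then normalise — the order real data would be processed in (a
switch reverses it).  The noise SD is σ = mean SPGR signal / SNR with
SNR = 100 by default, so per-point SNR varies and the bSSFP points sit
higher (their mean exceeds the SPGR mean by a factor of ~1.3–1.6 for the
built-in schemes).  No Rician/magnitude model is applied: the simulated
signals are real-valued and the Gaussian assumption is the one the
simulation study makes.  Each realization draws from its own
`SeedSequence`-derived substream, and experiment drivers key every stream
on the *content* of the cell (tissue values, scheme, bounds, fit
configuration, realization index), so results are bitwise reproducible and
independent of execution order or chunking.  What this generator does not
emulate: spatially correlated noise, coil sensitivity, B1 error, drift, or
magnitude-bias at low SNR — conclusions about those require real data.

## SRC fitting

Stochastic Region Contraction draws `n_candidates` uniform samples inside
the current per-parameter bounds, ranks them by the sum-of-squares residual
against the (normalized) data with stable tie-breaking on draw index,
retains the best `n_retain`, and sets the new bounds to the retained set's
[min, max] widened symmetrically about the interval midpoint by
`expansion_factor`, clipped to the initial bounds.  Convergence requires
(UB − LB)/max(|midpoint|, 1e−12) ≤ `tolerance` for every fitted parameter.
Defaults: 40,000 candidates, 50 retained, ≤30 iterations, 1% tolerance —
the configuration shown in the literature to ensure convergence.  The point
estimate is the per-parameter mean of the final retained set (the
convention of the reference implementations; a best-candidate switch
exists).  The expansion factor is not stated in the source literature;
the default is 1.1 (10% symmetric widening) and it is configurable, with a
sensitivity test in the suite.  With exchange excluded the search is 5-D
and k_FS is pinned (0 for the mismatch study).  Off-resonance can be fitted
as a 7th parameter behind a flag (off by default; bounds ± half the bSSFP
banding period).

A practical caveat measured with this implementation: at the desk-scale
5,000 candidates the retained-set bounds contract by only ~4–8% per
iteration on the six-parameter problem (the low-residual region is a long
correlated valley), so the 30-iteration cap frequently stops the search
before the 1% tolerance is reached and the mean-of-retained estimate
carries a residual offset.  At the full 40,000 candidates the same problems
converge in ~15–20 iterations and noiseless no-exchange data is recovered
to machine precision.  Desk-scale results therefore preserve the direction
and rough size of every bias but not the fine calibration of the
paper-scale profile.

`nlls_fit` wraps scipy's bounded trust-region-reflective least squares,
started at the bound midpoints with `x_scale` set to the bound widths; it
is the conventional local comparator and is noticeably more dispersed than
SRC on degenerate problems because nothing forces it onto a small subset of
the solution manifold.

## Search-space degeneracy tools

The normalized RMS residual η(θ, θ̂) = RMS(S(θ) − S(θ̂))/σ compares the
normalized signal vectors of two parameter sets in units of a notional
noise SD; η = 1 means one noise SD from the truth on average.  σ defaults
to the same mean-SPGR SNR rule applied to the normalized signals, i.e.
σ = 1/SNR (the normalized SPGR block has unit mean).  σ only scales η — it
never changes the ranking of candidates.

`sample_top_solutions` draws uniformly from a bound box (default sampling
count 10⁶ at desk scale; the original study used 2×10⁸) and retains the
exact k = 1000 lowest-η candidates with O(k) memory and full-sort-equivalent
tie-breaking.  Because the retained fraction at 10⁶ samples is 10⁻³ rather
than 5×10⁻⁶, the retained set reaches η ≈ 1.4–3 instead of hugging the
manifold floor; the qualitative contrast between the exchange and
no-exchange cases is preserved, but quantitative concentration statistics
(e.g. how tightly the no-exchange solutions cluster around truth) are
sampling-depth dependent and should be read accordingly.

`kpca_embed` visualises the retained manifold with RBF kernel PCA on the
five z-scored non-exchange parameters, bandwidth from the median-squared-
distance heuristic (the source study does not state its kernel); a linear
kernel and an automatic linear-PCA fallback for degenerate kernels are
provided.  `min_projection_grid` stores the minimum η over random nuisance
draws per 2-D grid cell (nested draw prefixes make the minimum monotone in
the draw count); `planar_cut` evaluates η on a 2-D plane through an anchor
point.  Default grids: 51×51 for projections, 101×101 for cuts — runtime
choices, not physics.

## Monte Carlo experiments

`run_bound_sensitivity`, `run_exchange_mismatch` and `run_parameter_sweep`
drive the fitter over (tissue × scheme × bound-set), (true k_FS × bound-set,
no-exchange model) and (single-parameter increments) grids.  Noise data is
generated once per (tissue, scheme, SNR) cell and shared across bound sets,
isolating the bound-set effect (regeneration per bound set is a switch away
by changing the seed).  Bias is reported as median − truth (the box-plot
view); mean − truth is also emitted.  `summarize_and_export` writes a tidy
per-realization CSV, a per-cell aggregate CSV, box plots and a JSON run
manifest sufficient to reproduce every number.

## Known limitations

* Desk-scale SRC (5,000 candidates) under-converges within the 30-iteration
  cap (see above); paper-scale conclusions should use the `paper` preset.
* The degeneracy statistics of the retained top-1000 depend on sampling
  depth; 10⁶-sample runs overstate the spread of the no-exchange solution
  set relative to exhaustive sampling.
* The simulation noise model is Gaussian on real-valued signals; magnitude
  (Rician) noise, MT effects, imperfect spoiling and B0/B1 non-ideality are
  not modelled.
* In-vivo map reconstruction (NIfTI I/O, masking) is out of scope.
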