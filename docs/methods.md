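# Methods

## Model

Internal protein motion is represented as a continuous-time Markov jump
process on the members of a structural ensemble. The generator `Q` (s^-1)
has nonnegative off-diagonal rates and rows summing to zero; its stationary
distribution `pi` gives the equilibrium member populations. Three
constructions are provided:

* **Uniform N-site jump** — every individual rate is `1/(N tau_ensemble)`,
  giving one zero eigenvalue and `N-1` degenerate eigenvalues
  `-1/tau_ensemble`. One parameter sets the single internal timescale
  regardless of ensemble size.
* **Two-level hierarchy** — members are partitioned into named groups
  (e.g. a slow collective mode's open/closed states). Inter-group rates are
  `1/(N tau_slow)`; intra-group rates in a group of size `N_i` are
  `(1/tau_fast - (1 - N_i/N)/tau_slow)/N_i`, which requires
  `tau_slow >= tau_fast` and yields exactly three distinct eigenvalues
  `{0, -1/tau_slow, -1/tau_fast}` with multiplicities
  `{1, G-1, N-G}` for `G` groups (verified numerically; the multiplicities
  follow from the nested block structure).
* **Rotation processes** — methyl (3-fold) and PHE/TYR ring-flip (2-fold)
  hydrogen exchange, rates `1/(3 tau_methyl)` and `1/(2 tau_aromatic)`,
  composed with the member process by Kronecker sum since the processes are
  kinetically independent. A two-distance asymmetric exchange toy
  (`k_AB = (1-p_A)/tau_ex`, `k_BA = p_A/tau_ex`, nonzero eigenvalue
  `-1/tau_ex` at any population split) supports the averaging-power
  analyses.

For a proton pair the dipolar tensor of each state is encoded as a
5-vector `d_i` in the rank-2 basis, scaled so that
`d_i . d_j = tr(D_i D_j)/6 = P2(cos theta_ij)/(r_i^3 r_j^3)` exactly; this
identity is enforced against the explicit 3x3 trace in tests. Because the
dot product is bilinear, state averaging commutes with it, and the
exponential prefactor of each unique eigenvalue reduces to sums of
`|block-averaged d|^2` terms over nested partitions of the state space with
small integer coefficients (+1/-1 for all schemes here; products of those
for Kronecker sums). This grouped path costs O(s) per unique eigenvalue and
is cross-checked against the O(s^3) eigendecomposition path, which remains
available for arbitrary generators (intended for s up to a few hundred).

Tumbling is isotropic and enters analytically as modified eigenvalues
`lambda'_k = lambda_k - 1/tau_c`. The spectral density is
`J(omega) = 2 sum_k a_k tau'_k/(1 + omega^2 tau'_k^2)` with
`tau'_k = -1/lambda'_k in (0, tau_c]`.

## Relaxation and observables

Auto and cross relaxation rates follow the homonuclear Solomon equations,
`rho = K [J(0) + 3 J(w0) + 6 J(2 w0)]` and `sigma = K [6 J(2 w0) - J(0)]`
with `K = (1/10)(mu0/4pi)^2 hbar^2 gamma_H^4`; the kinetic-ensemble `J`
already carries the `r^-6` dependence (Å^-6 converted to m^-6). The sign
convention places `+sigma` off-diagonal in `R` and propagates
`T(tau_m) = exp(-tau_m R)`; with it, the two-spin cross transfer is
`(1/2)e^{-(rho+sigma)t} - (1/2)e^{-(rho-sigma)t}`, positive in the
spin-diffusion limit where `sigma < 0`. The overall sign/normalization
convention is immaterial for scoring because the uncentered correlation is
scale free; one convention is fixed globally. Theoretical intensities
between groups of magnetically indistinguishable protons (pseudoatoms, Q
notation) are block sums of `T` over both axes, without normalization.

Numerical choices:

* Pairs enter `R` when their ensemble-minimum distance is within 5.5 Å
  (configurable); more distant pairs contribute negligibly at the working
  tolerances.
* Eigenvalue degeneracy clustering uses relative tolerance 1e-8 — the
  structured generators are exactly degenerate, the tolerance only absorbs
  floating-point noise.
* `exp(-tau_m R)` is evaluated by symmetric eigendecomposition, reused
  across mixing times.

## Fitting

Calculated and observed intensities are compared with the uncentered
correlation `R_u = sum(xy)/sqrt(sum x^2 sum y^2)` (scale free, penalizes a
nonzero intercept; optional per-point weights are exposed, default
unweighted, with replicates entering as separate observations). Timescale
optimization runs in log-timescale space (bounds [-30, 0] log-seconds,
max 500 iterations, projected-gradient tolerance 1e-8) with an analytic
gradient: the prefactors `a_k` are independent of the timescales, so only
`tau'_k` varies; the chain rule runs through `J`, `R`, and the matrix
exponential via the eigenbasis divided-difference formula, with the
diagonal limit used when `|mu_i - mu_j| < 1e-12 max|mu|`. The gradient is
verified against central finite differences (1e-4 log-space step) to 1e-5
relative. Default grids mirror the sensitivity of the problem: `tau_c`
log-spaced over 1–50 ns (25 points), `tau_ensemble` over six decades
around the grid center.

The averaging-power analysis fits
`J(0) = 2 tau_c (p_A r_A^-n + (1-p_A) r_B^-n)^{6/n}` to exact `J(0)` values
at populations {0, 0.2, ..., 1.0} by bounded 1-D least squares directly on
`J(0)` (linear residuals; the p_A = 0, 1 endpoints are exact for any n and
anchor the fit). The transition of `n` from 3 to 6 with exchange timescale
is summarized by the hyperbola `n = 3 + 3/(tau_1/2/tau_ex + 1)` fitted over
a 61-point log-spaced `tau_ex` grid spanning `tau_c x 10^+/-3`; `tau_c` is
fixed at 5 ns for these scans (immaterial — results are reported in units
of `tau_c`).

Subensemble selection starts from a random ~50% inclusion and greedily
accepts the single-member swap with the greatest `R_u` improvement, with
timescales warm-started from their previous optimum for every candidate.
The improvement threshold is 1e-9 (guards floating-point loops), ties break
to the lowest member index for determinism, and swaps emptying the set
below two members are rejected. Subensemble size is emergent — no size
penalty is imposed — so outcomes on other data may differ.

## Synthetic data

The synthetic-ensemble generator stands in for refined experimental
ensembles: `n_protons` are placed with minimum separation 2.2 Å at a
density of ~30 Å^3 per proton, and each member displaces them independently
by isotropic Gaussians of a chosen scale (default tests use 0.3–0.6 Å,
typical of well-refined ensemble spread), resampled to keep all distances
>= 1.5 Å. Forward-simulated buildup tables use the experimental design of
the reference dataset (34 mixing times, 5–500 ms in 15 ms steps, 900 MHz)
unless overridden, with multiplicative Gaussian noise.

What the generator does not emulate: covalent connectivity and realistic
proton density gradients, anisotropic or correlated displacements,
rotamer-like multimodality, exchange-broadened linewidths, and any
experimental artifact (baseline, peak overlap, water exchange). Passing
tests therefore demonstrate the correctness and identifiability of the
machinery under the stated kinetic model, not robustness to real-data
systematics.

Test problem sizes (10–15 protons, 6–10 members, grids of a few hundred
points) were chosen as the smallest instances that exercise every code
path with comfortably identifiable parameters.

## Assumptions and limitations

* Uniform initial magnetization, isotropic tumbling independent of internal
  motion, no solvent exchange, no external relaxation sink; consequently
  total deviation magnetization decays only through the modeled network.
* Populations default to uniform (the jump models' stationary state);
  crystallographic altloc occupancies are carried through reading, and
  non-uniform populations enter the prefactor formula through `Pi`, but the
  grouped fast path assumes the uniform-population generators above.
* Only two hierarchy levels; only CH3 methyls and PHE/TYR rings are
  auto-detected (solvent-exchangeable groups such as LYS NH3+ are excluded).
* Input structures must already carry hydrogens; no protonation is
  performed.
* Gradient-based optimization of atomic coordinates is out of scope.
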