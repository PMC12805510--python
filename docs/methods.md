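# Methods

`esfm` implements enhanced-sampling force matching for coarse-grained (CG)
potentials on analytic model systems, together with the exact quadrature
oracles needed to validate every step. This note documents the models, the
estimators, the numerical choices, and what the package's tests do and do
not demonstrate.

## The force-matching problem

A linear, orthogonal mapping `R = M r` (rows orthonormal; applied
identically to positions and forces) reduces an ambient configuration
`r ∈ R^n` to CG coordinates `R`. Thermodynamic consistency requires the CG
model's Boltzmann distribution to equal the marginal of the ambient one,
i.e. the exact CG potential is the potential of mean force (PMF)

    U*(R) = -(1/β) ln ∫ δ(R - M r) e^{-β u(r)} dr + C.

Force matching trains a parametric `U(R; θ)` by minimizing the mean squared
residual between projected instantaneous forces and model forces,

    χ²(θ) = (1/(D·M)) Σ_i ‖ M f(r_i) + ∇U(M r_i; θ) ‖²,

with `D` the CG dimensionality (the normalization is `1/(D·M)` here; in an
all-atom setting `D = 3N`). The loss decomposes into a PMF-error term plus
an irreducible noise floor — the conditional variance of the projected
force given `R`, which depends only on the mapping.

## The central claim: mean-force invariance under CG-coordinate biasing

If a bias `W` depends on the configuration only through the CG coordinates,
the conditional distribution `p(r | R)` is unchanged, hence the conditional
mean force `F(R) = ⟨M f(r)⟩_{r|R}` is invariant. Biased trajectories can
therefore be used for training directly — *without reweighting* — provided
the training forces are recomputed with the unbiased potential
(`f = -∇u`, not the biased `-∇(u + W∘M)`). If the bias touches orthogonal
degrees of freedom, the conditional ensemble is distorted and
self-normalized importance reweighting with `ω = e^{βW}` is required
instead. The package verifies both halves of this statement empirically
against quadrature oracles (the formal proof is not re-derived).

## Model systems

All systems are analytic with exact gradients (verified against central
finite differences at 1e-5 relative tolerance):

* `muller_brown` — the canonical four-Gaussian two-dimensional surface,
  amplitudes (-200, -100, -170, 15), three minima and two saddles. All
  coefficients live in `potential_params` and can be overridden; an
  optional affine transform (per-axis offset/scale plus an energy scale)
  supports reparameterized variants of the surface. The default inverse
  temperature is `β = 0.125`: the barrier between the two lowest minima is
  67.5 energy units ≈ 8.4 kBT, which makes the right-hand basin (~0.8%
  equilibrium occupancy) effectively unreachable for unbiased dynamics —
  the sampling-failure regime the method addresses.
* `double_well_1d` — `u = a (x² - 1)²` with `a = 5`, a 5 kBT barrier at
  `β = 1`; the metadynamics benchmark.
* `harmonic_1d`, `harmonic_2d`, `double_well_harmonic_2d` — closed-form
  sanity systems (separable marginals, known variances).
* `coupled_harmonic_2d` — `u = ½kx x² + ½ky (y - c x)²`: the x-marginal is
  Gaussian with mean force exactly `-kx x` while the projected force
  carries conditional variance exactly `c² ky / β`; used to calibrate
  standard errors and the noise estimator against closed forms.
* `dihedral_chain_4bead` — four beads with stiff harmonic bonds
  (k = 100) and angles (k = 50) plus a cosine dihedral `k_d (1 + cos φ)`,
  `k_d = 2`: a 4 kBT torsional barrier at `β = 1`. Because the dihedral
  rotation generator is exactly orthogonal to bond and angle forces, the
  generalized torque has the closed form `Q = k_d sin φ` frame by frame —
  a machine-precision oracle for the torque estimator.

## Quadrature oracles

For ambient dimension ≤ 2 and a one-dimensional CG coordinate,
`compute_oracle` evaluates the PMF from the log-marginal by trapezoidal
quadrature (2001 points per axis by default), the marginal density, and the
mean force **two independent ways**: (i) a fourth-order finite-difference
derivative of the quadrature PMF, and (ii) the direct conditional average
of the projected force. The two routes must agree to 1e-4 relative L2
(they agree to ~2e-8 at default resolution). Quadrature refuses to run if
the Boltzmann density at any integration boundary exceeds 1e-12 of its
maximum, rather than silently truncating. PMFs are always reported
min-shifted to zero.

## Sampling

The sampler propagates Metropolis-adjusted overdamped Langevin dynamics
(MALA, unit mobility): the Euler–Maruyama proposal
`r' = r - ∇(u + W∘M) dt + √(2dt/β) η` followed by a Metropolis
accept/reject step. The Metropolis correction removes the O(dt) stationary
bias of plain Euler–Maruyama — at Müller-Brown curvatures (~4·10³) that
bias would distort conditional distributions by ~10%, swamping the
statistical tolerances used throughout. Proposals outside `domain_box` are
rejected, which realizes hard walls exactly. Acceptance rates at the
default steps (`dt = 5·10⁻⁵` for Müller-Brown, chosen so `dt` times the
maximum curvature stays well under 0.1) are ≳0.98.

Many chains run in parallel (vectorized); frames are recorded time-major
every `stride` steps after a burn-in (defaults: 10% of the run, stride 10;
the Müller-Brown study uses stride 600 ≈ three within-basin relaxation
times with 500–1000 chains). Initialization is either a grid-based
inverse-CDF draw from the exact (biased) Boltzmann density (dim ≤ 2) or a
reference configuration. All randomness derives from counter-based Philox
streams keyed by the master seed with separate sub-streams for
initialization and dynamics, so identical configurations are bit-for-bit
reproducible and changes to stride or burn-in never alter the trajectory.

Every frame records the applied biased force, the recomputed unbiased force
`-∇u`, the bias force actually applied, the bias energy, and (for static
biases) the importance weight, so the decomposition
`f_biased = f_unbiased + f_bias` holds to 1e-10 frame-wise by construction
and after text round-trips.

**Bias kinds.** Harmonic umbrella `W = κ/2 ‖R - R₀‖²`; static Gaussian
restraint (negative height = a well); well-tempered metadynamics with
deposit rule `h_eff = h·exp(-W_τ(s) β/(γ-1))`, `γ > 1`. During
metadynamics the bias is accumulated on a dense grid (PLUMED-style, 4096
points, linear interpolation) for O(1) per-step evaluation; the deposited
(center, height) list is retained and is the exact definition used by
`bias_energy_and_force`. Importance weights for metadynamics are a
diagnostic computed from the final bias state (last-bias approximation);
training on metadynamics data uses recomputed forces without reweighting,
which is the point of the method. Time-dependent reweighting estimators
are out of scope.

## Estimators

* **Binned mean force** — plain or self-normalized weighted means per bin
  (default 50 uniform bins over the sampled range; bins with fewer than 10
  frames are flagged low-confidence). Standard errors are cluster-robust
  across the independent chains when chain structure is available: in
  Müller-Brown bins where `p(y|x)` is bimodal the conditional y-relaxation
  is slow, frames within one chain are correlated, and the naive `s/√n`
  underestimates the error severalfold. Comparisons against the oracle are
  made on per-frame residuals `G_i - F_oracle(x_i)` binned against zero —
  unlike comparing a bin mean to the oracle at one representative point,
  this is free of within-bin discretization bias at any bin width. The
  3-SE agreement convention follows standard 99.7% coverage.
* **Self-normalized reweighting** — `Σ ω̄ᵢ φᵢ` with Kish effective sample
  size `(Σω)²/Σω²`; degenerate weights (ESS < 2) warn. Overflowing weights
  are normalized in log space (self-normalized estimators are invariant).
* **Generalized torque** — `Q = Σᵢ fᵢ · ∂rᵢ/∂φ` with the displacement
  field defined by a rigid rotation of the distal atom about the central
  bond: volume-preserving, unit rate (`∇φ · ∂r/∂φ = 1` exactly), and
  exactly orthogonal to bond/angle forces. Dihedrals are signed IUPAC
  angles in (-π, π]; the analytic four-point gradient is cross-checked
  against finite differences; collinear triples are flagged invalid.
* **Noise floor** — per-bin conditional variance of the projected force,
  pooled count-weighted; equals the FM loss of the oracle-force "perfect
  model" up to binning error.

## The CG potential and training

`U(R; θ) = s · MLP(φ(R))` with Gaussian RBF features
`φ_j = exp(-‖R - c_j‖²/2σ²)`, two tanh hidden layers (64 units each by
default), K = 64 centers spanning the sampled CG range, σ equal to the
center spacing, and a fixed output scale `s` set to the standard deviation
of the training forces. The predicted force is the exact negative input
gradient (conservative by construction; forward tangent propagation), and
the parameter gradients of the FM loss are evaluated by a hand-derived
adjoint pass through the tangent computation — both verified against
finite differences. No prior potential is used; outside the RBF span the
model extrapolates freely and only warns.

Training is mini-batch Adam (defaults: lr 1e-3, batch 512, 90/10 seeded
train/validation split, plateau-based learning-rate decay and early
stopping). For the Müller-Brown study the validation loss is dominated by
the irreducible force noise (σ ≈ 120 force units, so a 500-frame
validation loss has a standard error of ~900 — larger than any meaningful
PMF-error change), which makes plateau detection fire on noise; the study
schedule therefore disables early stopping and uses a deterministic step
decay (×0.3 at 60% and 85% of a fixed 3000-step budget, lr 3e-3, batch
512), the same budget for every dataset size. Measured accuracy is flat
between 3000 and 12000 steps. For datasets of ≥ 2000 frames the returned
parameters are the Polyak average over the final 15% of epochs (SGD noise,
not overfitting, limits those fits); for smaller datasets the
best-validation checkpoint is kept instead, where it acts as early-stopping
regularization. The final loss never exceeds the initial one (the initial
parameters remain a fallback candidate); a non-finite loss aborts at the
last finite checkpoint.

## Evaluation

* Mean-force RMSE against the oracle over 500 equally spaced points on the
  interval holding 99.9% of the oracle's marginal mass (the interval edges
  are by construction 0.05%-tails where *any* ensemble has sparse
  coverage; errors there are extrapolation-dominated for every model).
* Histogram free energies `F_b = -ln p̂_b` (kBT units, min-shifted, empty
  bins +∞); MSE over commonly occupied bins and
  `KL = Σ p_ref ln(p_ref/p_model)` with an add-half pseudo-count on the
  model histogram only, so basins the model never visits contribute a
  large but finite penalty.
* CG simulations run MALA on the learned potential; a chain whose model
  energy exceeds a threshold (study protocol: 10× the oracle PMF range
  over the evaluation interval, above the model minimum) or which wanders
  a quarter of the span outside the supported interval is counted unstable
  and removed with all of its frames — the exclusion is reported, never
  silent. A bounded RBF network never produces runaway energies, so in
  practice instability manifests as loss of confinement: once a chain
  leaves the region the model has data for, no prior pulls it back and it
  free-diffuses across the escape line within a small fraction of the run.
  Absolute instability counts are therefore high for *all* 1D models
  without priors (neither ensemble covers the outermost 0.05% tails of the
  evaluation interval, and the true surface itself has a barely-1-kBT lip
  between the right basin and the interval edge); the meaningful quantity
  is the difference between training conditions.

## Reference study conditions

The acceptance experiments fix the following conditions (all also the
package defaults):

* Invariance pattern: 2·10⁵ frames per ensemble. Bias on the CG
  coordinate: a Gaussian well (center 0.15, width 0.45, height -70) that
  levels the effective x-profile so biased occupancy is ~69% left basin /
  17% barrier / 14% right basin — the "uniform coverage of basins and
  transition regions" regime. Orthogonal bias: a y-umbrella (κ = 30,
  center 1.2) that pulls the conditional ensemble toward the lower-y
  channel — the channel dominating the unbiased conditionals — so the
  unweighted profile is strongly distorted (≈10 SE) while
  importance-sampling overlap is preserved in every populated bin. (An
  umbrella pulling *away* from the dominant channel starves it entirely
  in barrier-region bins: a conditional-ergodicity gap that reweighting
  cannot repair.)
* Well-tempered metadynamics: double well, h = 0.3, σ = 0.10, τ = 200
  steps, 4·10⁵ steps × 8 chains, histogram from the final 40%; regression
  of the log-histogram against -βA(x) tests the effective-temperature law
  p ∝ exp(-βA/γ). σ is kept below the thermal width (0.16) because the
  converged bias is the free energy smoothed by a σ-Gaussian; wider
  deposits visibly flatten the recovered slope.
* Data efficiency: one biased and one unbiased 20 000-frame pool; the
  unbiased pool starts at the global minimum and never crosses the 8-kBT
  barrier (a faithful emulation of a finite unbiased run that accumulates
  in one basin), while the biased pool covers the whole range. Five
  independently trained models per condition (training seeds only, as in
  the underlying study design); medians over seeds are compared.
* Stability: 5 seeds × 20 CG chains of 20 000 MALA steps at dt = 2·10⁻⁵,
  uniform random initialization over the evaluation interval, escape line
  at 25% of the span beyond it.
* Torque: θ-biased chain (Gaussian well at the dihedral barrier, height
  -3.5, width 0.7), 54 000 frames; recomputed-force torque is compared to
  `k sin φ` per bin, and the uncorrected biased-force torque is required
  to fail the same test.

## What the synthetic systems do and do not show

The generators emulate the structural features that drive the method:
metastable basins separated by multi-kBT barriers, strongly uneven
equilibrium coverage, force noise from marginalized degrees of freedom,
slow conditional (orthogonal) relaxation, and periodic torsional
coordinates. They do not emulate high-dimensional mappings, solvent,
many-body CG interactions, or kinetic properties; passing tests
demonstrate the statistical mechanics of the estimators and the training
objective, not the accuracy of any particular molecular CG model. The
evaluation of real molecular systems with equivariant architectures is
explicitly out of scope.

## Known limitations

* Oracles (and hence quantitative acceptance checks) exist only for
  ambient dimension ≤ 2 with 1D linear CG coordinates; the dihedral chain
  is validated through its closed-form torque instead.
* Metadynamics supports one-dimensional CVs (linear or dihedral).
* The CG simulator is one-dimensional; multi-dimensional learned
  potentials would need a trivial generalization of the integrator.
* The last-bias weight approximation for metadynamics is a diagnostic,
  not a converged free-energy estimator (single-window reweighting only;
  no WHAM/MBAR).
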