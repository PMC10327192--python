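# Methods

This note documents the numerical models behind `svauc`, the defaults
and their rationale, what the synthetic-data generator does and does
not emulate, and the design choices made where more than one reasonable
convention exists.

## Lamm-equation solver (`svauc.lamm`)

The transport of a species with sedimentation coefficient `s` (stored
internally in seconds; 1 S = 1e-13 s in the external API and all files)
and diffusion coefficient `D` in a sector-shaped cell is

    ∂χ/∂t = (1/r) ∂/∂r [ r D ∂χ/∂r − s ω² r² χ ],   m ≤ r ≤ b,

with zero-flux walls and χ(r, 0) = 1.  The solver is a finite-volume
Crank–Nicolson scheme on a fixed radial grid (default 400 nodes) with
smooth sine-map clustering that roughly doubles the node density near
meniscus and bottom, where gradients are steepest.  Face fluxes use
Scharfetter–Gummel exponential fitting: at low cell Péclet number this
reduces to second-order central differencing, at high Péclet number to
upwinding, so profiles stay oscillation-free for weakly diffusing
species without a tuning switch.  The discrete scheme conserves the
mass integral ∫ χ r dr exactly (telescoping fluxes); requested times
are reached by linear interpolation between Crank–Nicolson steps whose
size keeps the sedimenting boundary below one grid cell per step.

Two regimes bypass the grid solve:

* `D = 0` uses the analytic step solution
  χ = exp(−2 s ω² t) for r > m·exp(s ω² t), else 0 (the ls-g\*(s) kernel);
* when the diffusive boundary width √(2Dt) is below half the finest
  grid cell, no discretization can resolve it, and the analytic step is
  the more accurate model.

Accuracy is pinned by tests against an independent method-of-lines
reference (central differences on a 3000-point grid, BDF integration):
on the default grid the profiles agree to about 0.1% of the plateau
over the radial analysis window.  The thin accumulation layer at the
bottom (scale D/(sω²b), reaching χ in the thousands for small D) is
excluded from pointwise comparisons: distribution analyses never
include data that close to the bottom, and its sup-norm is dominated by
layer thickness, not by boundary transport.

The hydrodynamic scaling law converting s to D at constant frictional
ratio is evaluated in CGS units (k = 1.38065e-16 erg/K); the
temperature entering kT is the average of the scan-header temperatures,
since the input XML carries no temperature parameter.  Note on units:
the solvent viscosity parameter (`BufferViscosity`) is in Poise
(g cm⁻¹ s⁻¹); water at 20 °C is 0.01002 P.

## Distribution inversion (`svauc.distribution`)

The design matrix holds one vectorized kernel per s-grid point; the
unknowns are per-grid-point signal loadings w_j = δ_j c(s_j), with δ_j
the trapezoidal quadrature weights of the (possibly non-uniform) grid,
so that Σ w_j is the total fitted boundary signal.

**Systematic noise.**  TI (one free value per radius), RI (one per
scan) and a global constant enter linearly and are eliminated by
orthogonal projection before the solve.  On the complete radius × scan
grid this is ANOVA-style centering: subtracting row means (TI), column
means (RI), or both plus the grand mean (TI+RI, dimension
n_radii + n_scans − 1; the constant lies in both subspaces).  After the
reduced solve the explicit noise vectors are the least-squares fit to
the residual; when the baseline flag accompanies TI (or RI) the rank
deficiency is resolved by reporting the constant separately and
re-centering the vector to zero mean.

**Non-negativity and regularization.**  c ≥ 0 is enforced by active-set
NNLS.  The problem is first reduced by a QR factorization of the
projected design matrix so every regularized subproblem works on an
n_s × n_s core, making the α search cheap.  The regularization penalty
is either

* Tikhonov: ‖L₂ c‖² with L₂ the second-difference (curvature) operator
  on the s-grid, interior rows only (natural boundaries), with divided
  differences for non-uniform grids; or
* maximum entropy: Σ c ln(c/c₀) with the flat prior
  c₀ = (total signal)/(n_s · grid span), minimized by sequential
  quadratic approximation — each step re-weights an augmented NNLS with
  diagonal rows √(α/2c) (up to 15 iterations, relative tolerance 1e-6).

α is set by the standard F-statistics criterion: the admitted SSR is
ssr_min · F_p(df, df) with df = n_points − n_free, where n_free counts
the eliminated noise dimensions plus one per fitted nonlinear
parameter.  Bisection on log₁₀ α over [−8, 8] (≤ 60 iterations) matches
SSR(α) to the bound within 0.1% relative; at p = 0.5 the F median is
exactly 1 and the unregularized NNLS solution is returned.  Baseline
correlation at the smallest s-value can be suppressed by multiplying
the penalty weight of the first grid point by 1e4, a strong prior
pulling c(s_min) to zero unless the data demand otherwise.

## Nonlinear regression (`svauc.regression`)

Only meniscus, bottom and f/f0 are nonlinear; the optimizer sees a 1-3
dimensional landscape with the exact linear solve embedded.  During the
nonlinear iterations the linear solve is unregularized (α = 0): this is
the standard two-stage practice and keeps the objective smooth; the
single regularized solve producing the reported distribution runs once
at the optimum.  Consequences: the reported rmsd is slightly above the
unregularized optimum (by construction of the F bound), and the
convergence log (`FittingStepsText`) records both values so the two
stages are auditable.

* Simplex: Nelder–Mead with a ±2% randomized starting simplex, seeded
  (default 0) for bit-reproducibility; parameter tolerance 1e-6,
  function tolerance 1e-10, at most 600 iterations.  Bounds and the
  meniscus < LeftFitLimit constraint are enforced by penalty values.
* Levenberg–Marquardt: bound-constrained trust-region-reflective
  least squares on the full residual vector, finite-difference Jacobian,
  stopping at ~1e-6 relative rmsd change or 200 outer iterations.

Bottom fitting defaults to off: unless back-diffusion reaches the fit
window the bottom position is not identifiable, and the default fit
window ends well left of it.

## Fit statistics (`svauc.fit_statistics`)

Residuals are flattened scan-major (radii ascending within each scan)
for the Wald–Wolfowitz runs test; zeros are skipped, and an all-one-sign
residual vector yields NaN with a warning.  The histogram statistic is
H = Σ(f_obs − f_gauss)² / Σ f_gauss² over 25 equal bins spanning ±4
sample SDs; because bins are defined in SD units H is invariant under
affine rescaling, and H → 0 for Gaussian residuals.  This H is a local
convention chosen for self-consistency (the statistic is defined, not
merely named), pinned by tests; numerical comparison with other
software's histogram statistics is out of scope.  Temperature QC
reports first/last/mean/range of the scan-header temperatures as a
convection-risk flag.

## Automation protocol (`svauc.automation`)

The three-token command line, the `cGMPSedfitCall` XML dialect, and the
output-file contract are implemented as a strict state machine: parse →
validate (the completion-flag file must not pre-exist) → load → fit →
statistics → write outputs → write flag.  The flag file is created with
`O_EXCL` and contains the handshake string plus one trailing newline
(tests compare newline-insensitively); it is written only after every
other artifact, so a polling driver can treat its existence as a
complete-manifest signal.  Unknown XML tags are preserved verbatim and
echoed; `PassThrough` may itself be an XML fragment and is echoed
verbatim.  Both published spellings of the baseline-suppression switch
are accepted (`SuppressBaselineCorrelation` and the single-p variant).
Mode 112 additionally rejects non-standard tags and any override of the
default regularization type.  `NumberComputationThreads` is accepted
and recorded as an advisory hint; results are independent of its value.
`AutoFit` enables the nonlinear optimization; without it the engine
performs a single evaluation at the starting parameters (the `AutoRun`
behavior), followed in both cases by the final regularized solve.

`ResultParameters.xml` echoes the input schema with post-fit values
(meniscus, bottom, frictional ratio) plus the engine version, file
manifest, loaded scan paths, fit statistics and experiment QC fields.
`~tmppars.<ext>` is a serialized snapshot of the post-fit configuration
sufficient to restore the analysis; `sdist.<ext>` is the single-column
s-grid, readable back via `GridfromFile` for custom-spaced grids.

## Scan files (`svauc.scan_io`)

The text dialect is frozen for fixture stability: line 1 free title;
line 2 `data-type cell temperature rpm time w2t wavelength`; then
`radius value [stddev]` rows (stddev ignored).  File names are 5-digit
zero-padded scan numbers with the channel extension, matched
case-insensitively and written lower-case.  Spike filtering removes
interior points deviating from both neighbors beyond the threshold
(default 0.4) with the same sign; passes repeat to a fixed point so the
filter is idempotent, and removed points are dropped rather than
interpolated.  Scans are aligned on the first scan's radii restricted
to the common radial range by linear interpolation — real instrument
scans share grids, so this is normally the identity.  Filesystem
modification times, when present and strictly increasing, provide
corrected elapsed times relative to the first scan's header time.

## Synthetic data (`svauc.synthetic`)

The generator emulates a constant-speed absorbance-style experiment:
50,000 rpm, 20 °C, ~0.003 cm radial sampling from below the meniscus to
the bottom, Gaussian noise of 0.005 OD, optional sinusoidal/tilted TI
profiles, Gaussian per-scan RI offsets, and an optional narrow optical
spike at the meniscus for testing meniscus pre-estimation.  ω²t headers
equal ω²·t exactly (no acceleration phase).  Everything is
deterministic given the manifest seed, and the manifest is serialized
next to the dataset.

Not emulated: rotor acceleration, pressure/compressibility effects,
optical delay or radial calibration errors, intensity-to-absorbance
conversion artifacts, and non-Gaussian noise.  Passing recovery tests
on these fixtures therefore demonstrates correctness of the inference
machinery under the stated noise model, not robustness to every
instrument pathology; the per-scan rmsd table and QC statistics exist
precisely to surface such pathologies on real data.

Default problem sizes in the test and acceptance runs (15 scans,
~300 radii in the fit window, 45-53 point s-grids) were chosen as the
smallest sets that keep the meniscus and frictional ratio statistically
well determined at the 0.005 OD noise level.

## Known limitations

* Single-channel analyses only; no global multi-dataset fits and no
  two-dimensional c(s, f/f0) distributions.
* The restricted LM variant treats bounds by projection
  (trust-region-reflective); it is not the classical unconstrained LM.
* ls-g\*(s) ignores the bottom accumulation layer (step kernel), so the
  fit window must end left of visible back-diffusion.
* Monte-Carlo confidence bands for c(s) are not implemented.
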