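# Methods

## The harmonic twist–diameter model

The central object is a quadratic free energy per base-pair step in the
twist angle ω (degrees) and the interstrand phosphate–phosphate diameter D
(nm):

    P_bp(Δω, ΔD) = ½ k_ω Δω² + ½ k_D ΔD² + k_ωD Δω ΔD      [k_BT]

with Δω = ω − ω₀ and ΔD = D − D₀. The cross term couples the two modes: for
k_ωD > 0, swelling the diameter underwinds the helix along the line
Δω = −(k_ωD/k_ω) ΔD. The package's reference parameter set for B-DNA at
1 M monovalent salt is ω₀ = 34.82°, D₀ = 2.008 nm, k_ω = 0.18 k_BT/deg²,
k_D = 263 k_BT/nm², k_ωD = 4.5 k_BT/(deg·nm); all of it is configurable.

All stiffnesses are stored in thermal-energy units at a stated
temperature; conversions to pN·nm and kJ/mol are pure functions of T
(`dnatwist.units`). The reference temperature is 295.15 K (22 °C), where
k_BT = 4.075 pN·nm = 2.454 kJ/mol.

Any external force f applied to the diameter coordinate (k_BT/nm per bp)
shifts the equilibrium by the linear response

    Δ⟨D⟩ = +f·k_ω/det,   Δ⟨ω⟩ = −f·k_ωD/det,   det = k_ω k_D − k_ωD².

This single formula carries the whole analysis: the salt-dependent
electrostatic swelling force and the entropic thermal force both enter
through it.

## Synthetic ensembles

`synthetic.sample_ensemble` inverts the harmonic model into a sampling
density: frames are drawn from the bivariate Gaussian whose energy is the
quadratic form above, at molecule level. Each record represents an average
over `n_steps_avg` base-pair steps, so the record-level stiffness is
`n_steps_avg` times the per-bp matrix and the record covariance is its
inverse (in k_BT units). The default `n_steps_avg = 19` corresponds to the
interior steps of a 25-bp duplex with terminal base pairs excluded from
helical-parameter averaging — an inference about common practice, exposed
as a parameter rather than buried.

Forces tilt the density through the closed-form response, which makes
tilted sampling a closed-loop test of the transduction chain: feed a force
in, re-measure the mean, compare with the prediction (the simulated
analogue of adding external radial forces to the phosphates in an
atomistic run).

Temperature acts as an entropic tilt. The generator's `alpha_d` (nm/K) is
the drift of the equilibrium diameter; internally it is converted to the
force f_T = α_D ΔT·det/k_ω so that the diameter mean moves by exactly
α_D ΔT while the twist mean follows along the coupling line of slope
−k_ωD/k_ω. The implied entropy–diameter slope is therefore

    k_SD = α_D · det/k_ω   (in k_BT/(K·nm); × 2.454 for kJ/(mol·K·nm)),

and the default α_D = 3.953×10⁻⁴ nm/K is chosen so that k_SD is exactly
0.146 kJ/(mol·K·nm), the reference value for duplex DNA. Note the marginal
diameter stiffness of the coupled Gaussian is det/k_ω = k_D − k_ωD²/k_ω
(≈ 150.5 k_BT/nm² for the reference constants), not k_D; any estimator
built on diameter marginals sees this effective stiffness, and the package
is consistent about it throughout.

Optional χ and δ dihedral channels are generated as linear functions of
(Δω, ΔD) with a negative diameter slope and positive twist slope plus
independent Gaussian noise. Only that sign structure — the signature of
the backbone torsions that mediate the coupling — is modeled; the
magnitudes are free parameters with no claimed realism.

What the generator does *not* emulate: anharmonicity of real landscapes,
sequence dependence, autocorrelation between simulation frames (records
are i.i.d.), and ion-specific binding. Passing tests therefore establish
the correctness of the estimators on data satisfying the model's own
assumptions, not the accuracy of the harmonic model for any particular
force field or sequence.

## Landscape construction and the elastic fit

`build_pmf2d` bins frames into an n×n histogram (default 10×10 over
mean ± 3.5 sample SD per axis, reproducing ~0.5° × 0.01 nm bins for
19-step-averaged data), takes −ln of the counts and subtracts a constant
so the occupied-bin minimum is exactly 0. Unoccupied bins are masked,
never zero-filled. Bin intervals are half-open [low, high) with a closed
last bin; at these sample sizes the closure convention is immaterial, but
it is fixed and stated.

`QuadraticPMFFit` fits the six-coefficient quadratic surface to the
occupied bins by linear least squares weighted by counts (Var[−ln N] ≈
1/N), then converts coefficients to (ω₀, D₀, k_ω, k_D, k_ωD) and rescales
molecule-level stiffnesses to per-bp. Bins with fewer than 5 counts are
excluded (log of small counts is noise-dominated); the threshold is a
parameter. A linear fit in the quadratic coefficients avoids nonlinear
optimization and its initialization questions.

Binning convolves the density with the bin rectangle, which inflates each
coordinate variance by width²/12 and deflates the fitted stiffnesses by
5–15% at the default binning. The estimator therefore applies Sheppard's
grouped-data correction by default: invert the fitted stiffness to a
covariance, subtract width²/12 from the diagonal, re-invert. With the
correction the fit agrees with the closed-form inverse-covariance
estimator to within ~2% at 5×10⁴ frames and recovers generating constants
without measurable bias; it can be disabled (`sheppard=False`) to obtain
the raw surface fit.

Confidence intervals come from a case-resampling bootstrap over frames
(default 200 replicates). The basic (reverse-percentile) interval is used
rather than the percentile interval: resampling introduces a small median
bias in the stiffnesses, and the basic interval corrects it, giving ~92%
joint coverage of all three constants in calibration runs (vs ~73% for
percentile).

`InverseCovarianceFit` is the independent cross-check: stiffness equals
the inverse sample covariance in k_BT units, exact for Gaussian data in
the large-n limit. The two routes are kept strictly separate so each can
validate the other.

Derived quantities: effective twist stiffness k̃_ω = k_ω − k_ωD²/k_D (the
marginal stiffness of a diameter-relaxed helix — identical to the inverse
marginal twist variance, a Gaussian identity the tests exercise); rod
twist rigidity C = k̃_ω (180/π)² h k_BT with rise h; the backbone-restraint
coupling estimate k_ωD ≈ S_h D₀³ ω₀³/(8 s₀³) from the backbone stretch
modulus S_h and contour s ≈ √((ωD/2)² + h²); and an order-of-magnitude
Young's-modulus conversion of k_D. The latter uses a documented convention
— base-pair disc of height h loaded diametrically with the restoring force
spread over its full lateral surface, E = k_D k_BT/(π h) ≈ 1.0×10⁹ Pa for
the reference stiffness — and is pinned by a regression test as an
order-of-magnitude quantity only; rod-elasticity conventions for a
molecule two phosphates wide legitimately disagree by factors of a few.

## Electrostatic salt response

The interstrand swelling force f_D is computed from a surrogate
counterion-condensation model: two helical point-charge lattices at radius
D/2 with rise 0.331 nm, twist 34.82°/bp and strand phase 154° (the B-DNA
minor-groove offset), each charge carrying the uncondensed Manning
fraction 1/ξ of an elementary charge (ξ = l_B/b with b = 0.17 nm of axial
spacing for the duplex's two phosphates per 0.34 nm; ≈ 0.235 at room
temperature), interacting by the Debye–Hückel pair potential
q² l_B k_BT e^(−κr)/r summed over |Δindex| ≤ 50 and normalized per bp.
f_D = −∂U/∂D by central difference (δD = 10⁻³ nm); the result carries a
convergence flag that trips if doubling the cutoff moves the force by
more than 1%. Δf_D(c) = f_D(c) − f_D(1 M) is referenced to 1 M, where it
is zero by construction, and mapped to (Δω, ΔD) by the linear response.
Δf_D is treated as constant over the small ΔD range involved.

This surrogate is property-accurate, not curve-exact: its tested claims
are the sign (outward), strict monotonic decrease with salt over
[0.01, 1] M, reference zeroing, cutoff convergence, and the closed-loop
agreement between tilted sampling and the closed-form prediction. Its
absolute force scale is sensitive to the condensation treatment
(end effects, groove phasing, dielectric choice) and underestimates
experimental twist-change magnitudes by an order of magnitude; every
geometric constant is exposed for refinement.

## Thermal response

`entropy_vs_diameter` estimates k_SD = ∂S/∂D by finite differences of 1-D
diameter free-energy profiles at two or more temperatures:
S(D) = −[F(D;T₂) − F(D;T₁)]/(T₂ − T₁) on bins occupied at all
temperatures (≥ 100 counts by default), energies converted to kJ/mol
before differencing. Additive, D-independent constants — including the
arbitrary min-zeroing offsets — cancel in the slope, which is obtained by
a count-weighted straight-line fit and reported per base pair by dividing
out the record averaging factor. The temperature-difference estimator was
chosen because it needs only the module's own inputs and is exactly
offset-invariant; an energy/entropy decomposition of a single trajectory
would require information the ensembles do not carry.

`predict_thermal_twist` then evaluates k_T = −k_ωD k_SD/det. With the
reference constants and k_SD = 0.146 kJ/(mol·K·nm) this gives
k_T = −0.0099 °/°C per bp. On synthetic data the recovered k_SD fed
through this formula reproduces the generator's own mean-twist drift with
temperature, and salt-tilted and temperature-shifted ensembles collapse
onto a single twist–diameter line of slope −k_ωD/k_ω — the package's
equivalent of observing that salt and temperature deform DNA through the
same coupling.

## Magnetic-tweezers curve analysis

At low stretching force, applied turns beyond the buckling transition go
into plectonemes and the tether extension falls linearly on both sides of
the torsionally relaxed point. `PlectonemeFit` fits ordinary least-squares
lines to the two wings and intersects them; wings are selected either by
explicit turn intervals or automatically (apex located from the top-5%
extension points, wings at least `cap_halfwidth_guess` turns away, then
one refinement pass that re-centers on the first crossing estimate, which
removes the selection bias a noisy apex causes). Opposite-signed wing
slopes are required — a curve without a bell shape is rejected, and
near-parallel lines (slope difference < 10⁻⁶ µm/turn) are an error rather
than a huge-coordinate result. Twist change between conditions is
Δω = ΔN*·360°/N_bp; only relative twist is ever reported.

The synthetic curve generator uses a piecewise-linear bell (flat apex of
half-width 5 turns, wings of slope 0.05 µm/turn, sampled at integer turns
over ±20 around N*, default extension noise 0.005 µm): only the wings
carry information for the two-line method, so the rounded cap of real
buckling curves is deliberately not modeled. At these settings the
analyzer is exact on noiseless curves (machine precision) and has a
replicate SD of ~0.07 turns, i.e. ~0.002°/bp on a 13.6-kb tether —
comfortably at the 0.01°/bp resolution scale of the measurement it
emulates.

## Pipeline, sizes and determinism

`run_pipeline` composes the stages from a validated config (unit-suffixed
keys; unknown or unsuffixed keys are rejected before any computation) and
writes every intermediate artifact, a metrics JSON and a run log. All
randomness flows from explicit seeds through `numpy.random.default_rng`;
fixed seeds give bit-identical ensembles and byte-identical metrics.

Default problem sizes — 5×10⁴ frames per ensemble, 10×10 bins, 200
bootstrap replicates, 10–50 seeded replicates in the recovery studies —
are the scales at which the statistical properties quoted above were
calibrated; the full test suite and the acceptance script run in a few
minutes on one core at these sizes.

## Known limitations

* The harmonic model is the object of study, not a validated description
  of any particular DNA sequence or force field; all quantitative recovery
  results are conditional on it.
* The electrostatic surrogate's absolute force scale is not trustworthy
  (see above); only its qualitative structure is asserted.
* The Young's-modulus conversion is order-of-magnitude by construction.
* Records are treated as independent; applying the estimators to
  correlated trajectory frames will understate confidence intervals
  unless frames are thinned to the correlation time.
* The MT analyzer implements only the two-line relaxed-point method; no
  buckling physics, force–extension modeling, or melting.
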