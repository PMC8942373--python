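# dnatwist

Twist–diameter coupling analysis of double-stranded DNA.

Changing the salt concentration or the temperature of a buffer measurably
rewinds the DNA double helix: more monovalent salt overwinds it, heating
underwinds it, at roughly −0.01° per base pair per °C. Both effects run
through the same mechanical channel — the duplex diameter. Salt screens the
electrostatic repulsion between the two phosphate backbones and lets the
diameter shrink; heat swells the diameter because a wider duplex has more
conformational entropy; and a cross-term in the helical elastic energy
converts either diameter change into a twist change.

`dnatwist` implements that full analysis chain for anyone working with
conformational ensembles of duplex DNA (from atomistic simulation or any
other source of per-frame helical parameters) or with magnetic-tweezers
rotation–extension data:

* build 2-D potential-of-mean-force (PMF) landscapes over
  (twist ω, diameter D) by Boltzmann inversion of binned densities,
  P(ω, D) = −k_BT ln Ω(ω, D);
* extract the coupled harmonic elastic constants per base-pair step,

  P_bp = ½ k_ω (Δω)² + ½ k_D (ΔD)² + k_ωD Δω ΔD  [k_BT],

  by a count-weighted quadratic surface fit with bootstrap confidence
  intervals, cross-checked by the closed-form inverse-covariance estimator;
* derive the effective twist stiffness k̃_ω = k_ω − k_ωD²/k_D of a
  diameter-relaxed helix, its rod torsional rigidity C in pN·nm², and the
  backbone-stretch estimate of k_ωD;
* predict salt-induced twist changes Δω(c) = −k_ωD Δf_D/(k_ω k_D − k_ωD²)
  from a screened helical line-charge model of the interstrand force Δf_D,
  and temperature-induced changes k_T = −k_ωD k_SD/(k_ω k_D − k_ωD²) from
  the entropy–diameter slope k_SD;
* analyze rotation–extension curves: fit the two linear plectoneme wings,
  locate the torsionally relaxed point N*, and convert shifts between
  conditions into Δω = ΔN*·360°/N_bp;
* generate synthetic ensembles and curves with exactly the statistical
  structure the analysis assumes, so every stage is testable without
  simulations or instruments.

The fitting components are scikit-learn style estimators
(`QuadraticPMFFit`, `InverseCovarianceFit`, `PlectonemeFit`) and compose
with sklearn tooling; module-level functions wrap them for one-call use.

## Worked example

```python
from dnatwist import (fit_quadratic_pmf, effective_twist_stiffness,
                      twist_rigidity, predict_thermal_twist,
                      HelixChargeModel, salt_curve)
from dnatwist.synthetic import GeneratorSpec, sample_ensemble

# 5e4 conformations of a 25-bp duplex (19 interior steps per record),
# drawn from the reference harmonic model at 1 M salt
ens = sample_ensemble(GeneratorSpec(), seed=42)

c = fit_quadratic_pmf(ens, n_bootstrap=200, random_state=0)
print(c.k_omega, c.k_d, c.k_omega_d)
# 0.178 kBT/deg^2, 258.5 kBT/nm^2, 4.41 kBT/(deg nm)
# (95% CI for the coupling: 4.35 - 4.52)

k_eff = effective_twist_stiffness(c)          # 0.1028 kBT/deg^2
print(twist_rigidity(k_eff, rise=0.34))       # 468 pN nm^2

print(predict_thermal_twist(c, k_sd=0.146).k_t)   # -0.00987 deg/C

model = HelixChargeModel()                    # B-DNA helical charge lattice
print(salt_curve(c, model, [0.05, 0.15, 1.0]))
#  c_salt_M  delta_fD_kBT_per_nm  delta_omega_deg  delta_D_nm
#      0.05              0.04796         -0.00796     0.00032
#      0.15              0.02414         -0.00400     0.00016
#      1.00              0.00000          0.00000     0.00000
```

Reading: the landscape fit recovers the elastic constants of the
generating model (coupling 4.41 against a generating value of 4.5, inside
its confidence interval). Relaxing the diameter softens the twist mode
from 0.178 to 0.103 k_BT/deg², i.e. a torsional rigidity of ~470 pN·nm².
The entropy slope 0.146 kJ/(mol·K·nm) predicts thermal underwinding of
−0.0099 °/°C per bp. Lowering salt from 1 M to 0.05 M produces an outward
interstrand force of 0.048 k_BT/nm per bp, which the coupling transduces
into 0.008° of underwinding per bp (the screened-charge model here is a
documented surrogate; its salt trend, not its absolute scale, is the
tested claim).

A `dnatwist` command-line tool exposes the same stages
(`simulate-ensemble`, `pmf`, `fit`, `salt-response`, `thermal-response`,
`mt-analyze`, `run-all`); `run-all` executes the whole pipeline from a
YAML config and writes tables, a metrics JSON and a run log.

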