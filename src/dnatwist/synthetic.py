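"""Synthetic conformational ensembles and rotation-extension curves.

The generator embodies the harmonic twist-diameter model as a sampling
density: frames are drawn from the bivariate Gaussian whose energy (in kBT)
is the quadratic form with molecule-level stiffness K_mol = n_steps_avg ×
K_bp. A force applied to the diameter coordinate (kBT/nm per bp) tilts the
density and shifts the mean by the closed-form linear response

    Δ⟨D⟩ = +f k_ω / (k_ω k_D − k_ωD²),
    Δ⟨ω⟩ = −f k_ωD / (k_ω k_D − k_ωD²),

in per-bp constants — the same response the electrostatic and thermal
predictions use, which makes tilted sampling a closed-loop check of the
whole transduction chain. Temperature shifts the equilibrium diameter
linearly with slope ``alpha_d`` (thermal swelling); the twist mean follows
through the coupling.

Rotation-extension curves are generated as symmetric piecewise-linear
"bells": a flat apex of half-width ``cap_halfwidth`` turns flanked by two
linear plectoneme wings of slope ∓``wing_slope``, plus Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .elastic import ElasticConstants, REFERENCE_CONSTANTS
from .ensemble import ConformationEnsemble
from .mt import RotationExtensionCurve
from .units import T_REF, kbt_kj_mol

__all__ = ["GeneratorSpec", "DihedralCouplings", "sample_ensemble",
           "sample_multitemperature", "synth_rotation_extension",
           "DEFAULT_ALPHA_D", "DEFAULT_N_STEPS_AVG", "tilt_response"]

#: Default averaging span: interior steps of a 25-bp duplex (terminal base
#: pairs excluded from helical-parameter averaging).
DEFAULT_N_STEPS_AVG = 19

#: Default thermal-expansion slope of the equilibrium diameter, nm/K, chosen
#: so that the entropic force driving it corresponds to an entropy-diameter
#: slope of 0.146 kJ/(mol·K·nm) through the linear response of the reference
#: constants: α_D = k_SD·k_ω/(k_ω k_D − k_ωD²) with k_SD in kBT/(K·nm).
DEFAULT_ALPHA_D = 3.953e-4


@dataclass
class DihedralCouplings:
    """Linear model generating backbone dihedrals χ and δ from (Δω, ΔD).

    Each dihedral is mean + slope_omega·Δω + slope_diameter·ΔD + noise; the
    sign structure (negative on diameter, positive on twist) mirrors how the
    glycosidic and sugar-pucker torsions mediate the coupling in B-DNA.
    """

    chi_mean: float = -105.0
    delta_mean: float = 130.0
    slope_omega: float = 2.0      # deg dihedral per deg twist
    slope_diameter: float = -150.0  # deg dihedral per nm diameter
    noise_sd: float = 2.0         # deg

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("dihedral noise SD must be nonnegative")
        if self.slope_diameter >= 0 or self.slope_omega <= 0:
            raise ValueError(
                "dihedral slopes must be negative on diameter and positive on twist")


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic-ensemble generator.

    Parameters
    ----------
    constants : ElasticConstants
        Per-bp stiffness matrix and equilibrium (ω₀, D₀); must be positive
        definite.
    n_frames : int
        Number of conformations to draw (the reference study size is 5×10⁴).
    n_steps_avg : int
        Base-pair steps each record averages over; the record-level
        stiffness is this factor times the per-bp one.
    alpha_d : float
        Temperature drift of the equilibrium diameter, nm/K (0 disables).
    t_ref : float
        Reference temperature at which ⟨D⟩ = D₀, K.
    dihedral_couplings : DihedralCouplings, optional
        If given, χ and δ channels are generated from (Δω, ΔD).
    """

    constants: ElasticConstants = field(
        default_factory=lambda: REFERENCE_CONSTANTS)
    n_frames: int = 50_000
    n_steps_avg: int = DEFAULT_N_STEPS_AVG
    alpha_d: float = 0.0
    t_ref: float = T_REF
    dihedral_couplings: Optional[DihedralCouplings] = None

    def __post_init__(self) -> None:
        if self.n_frames <= 0:
            raise ValueError(f"n_frames must be positive, got {self.n_frames}")
        if self.n_steps_avg < 1:
            raise ValueError("n_steps_avg must be ≥ 1")
        k = self.constants
        if k.k_omega <= 0 or k.k_d <= 0 or k.determinant <= 0:
            raise ValueError("per-bp stiffness matrix must be positive definite")

    def thermal_force(self, temperature: float) -> float:
        """Entropic diameter force at ``temperature``, kBT/nm per bp.

        The force that moves the equilibrium diameter by α_D·(T − T_ref)
        through the linear response: f_T = α_D ΔT (k_ω k_D − k_ωD²)/k_ω.
        """
        k = self.constants
        return (self.alpha_d * (temperature - self.t_ref)
                * k.determinant / k.k_omega)

    def entropy_slope(self) -> float:
        """Entropy-diameter slope implied by α_D, kJ/(mol·K·nm) per bp.

        k_SD = α_D·(k_ω k_D − k_ωD²)/k_ω converted from kBT/(K·nm) at the
        reference temperature.
        """
        k = self.constants
        return (self.alpha_d * k.determinant / k.k_omega
                * kbt_kj_mol(self.t_ref))


def tilt_response(constants: ElasticConstants, tilt_force: float
                  ) -> tuple[float, float]:
    """Closed-form mean shift (Δω, ΔD) under a per-bp diameter force (kBT/nm)."""
    det = constants.determinant
    return (-tilt_force * constants.k_omega_d / det,
            tilt_force * constants.k_omega / det)


def sample_ensemble(spec: GeneratorSpec, temperature: float = T_REF,
                    tilt_force: float = 0.0, seed: int = 0,
                    salt: Optional[float] = None,
                    label: str = "") -> ConformationEnsemble:
    """Draw a conformational ensemble from the tilted harmonic density.

    The record covariance is the inverse molecule-level stiffness
    (n_steps_avg × per-bp, in kBT units); the mean is (ω₀, D₀) shifted by
    the per-bp linear response to the total diameter force — the explicit
    ``tilt_force`` plus the entropic force α_D·ΔT·det/k_ω that drives
    thermal expansion. The diameter mean thus moves by exactly
    α_D·(T − T_ref) and the twist mean follows along the coupling line of
    slope −k_ωD/k_ω. Reproducible given ``seed``.
    """
    k = spec.constants
    total_force = tilt_force + spec.thermal_force(temperature)
    d_omega, d_diam = tilt_response(k, total_force)
    mean = np.array([k.omega0 + d_omega, k.d0 + d_diam])
    cov = k.covariance(spec.n_steps_avg)
    rng = np.random.default_rng(seed)
    frames = rng.multivariate_normal(mean, cov, size=spec.n_frames,
                                     method="cholesky")
    chi = delta = None
    if spec.dihedral_couplings is not None:
        dc = spec.dihedral_couplings
        d_om = frames[:, 0] - k.omega0
        d_di = frames[:, 1] - k.d0
        base = dc.slope_omega * d_om + dc.slope_diameter * d_di
        chi = dc.chi_mean + base + rng.normal(0.0, dc.noise_sd, spec.n_frames)
        delta = dc.delta_mean + base + rng.normal(0.0, dc.noise_sd, spec.n_frames)
    return ConformationEnsemble(
        twist=frames[:, 0], diameter=frames[:, 1], temperature=temperature,
        salt=salt, tilt_force=tilt_force, n_steps_avg=spec.n_steps_avg,
        chi=chi, delta=delta, seed=seed, label=label)


def sample_multitemperature(spec: GeneratorSpec,
                            temperatures: Sequence[float],
                            seed: int = 0) -> list[ConformationEnsemble]:
    """One ensemble per temperature with the diameter drifting at α_D nm/K.

    At least two distinct temperatures are required — a single temperature
    leaves the downstream entropy slope undefined.
    """
    temps = list(temperatures)
    if len(set(temps)) < 2:
        raise ValueError(
            f"need ≥ 2 distinct temperatures, got {sorted(set(temps))}")
    rng = np.random.default_rng(seed)
    out = []
    for t in temps:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        out.append(sample_ensemble(spec, temperature=t, seed=sub_seed,
                                   label=f"T={t:g}K"))
    return out


def synth_rotation_extension(n_turn_star: float, wing_slope: float = 0.05,
                             cap_halfwidth: float = 5.0,
                             apex_extension: float = 4.0,
                             turn_range: float = 20.0,
                             noise_sd: float = 0.0, seed: int = 0,
                             force: float = 0.3,
                             label: str = "") -> RotationExtensionCurve:
    """Piecewise-linear bell-shaped rotation-extension curve with noise.

    Sampled at integer turn offsets over ±``turn_range`` around the
    torsionally relaxed point ``n_turn_star``:

        extension = apex − wing_slope · max(0, |N − N*| − cap_halfwidth) + ε,

    ε ~ N(0, noise_sd²). With no noise the two wings extrapolate to cross
    exactly at N*.

    Parameters
    ----------
    n_turn_star : float
        Location of the torsionally relaxed point, turns.
    wing_slope : float
        Plectoneme slope, µm of extension lost per applied turn (> 0).
    cap_halfwidth : float
        Half-width of the flat apex before buckling, turns.
    apex_extension : float
        Tether extension at the apex, µm.
    turn_range : float
        Sampling half-range around N*, turns (> cap_halfwidth).
    noise_sd : float
        Gaussian extension noise, µm (≥ 0).
    force : float
        Stretching force tag, pN.
    """
    if wing_slope <= 0:
        raise ValueError("wing_slope must be positive")
    if not turn_range > cap_halfwidth > 0:
        raise ValueError("require turn_range > cap_halfwidth > 0")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be nonnegative, got {noise_sd}")
    offsets = np.arange(-round(turn_range), round(turn_range) + 1, dtype=float)
    turns = n_turn_star + offsets
    ext = apex_extension - wing_slope * np.maximum(
        0.0, np.abs(offsets) - cap_halfwidth)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ext = ext + rng.normal(0.0, noise_sd, ext.size)
    ext = np.maximum(ext, 0.0)
    return RotationExtensionCurve(turns=turns, extension=ext, force=force,
                                  label=label)
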