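"""Temperature response of DNA twist through conformational entropy.

The equilibrium diameter sits at the minimum of F_T = U − T·S(D); because a
wider duplex leaves the two strands more conformational freedom, S grows
with D and heating swells the diameter like ordinary thermal expansion. The
entropy-diameter slope k_SD = ∂S/∂D acts through a temperature change ΔT as
an effective diameter force Δf_T = k_SD·ΔT, which the twist-diameter
coupling transduces into underwinding with coefficient

    k_T = Δω/ΔT = −k_ωD k_SD / (k_ω k_D − k_ωD²)      [deg/°C per bp].

k_SD is estimated from 1-D diameter free-energy profiles at two (or more)
temperatures by finite differences, S(D) = −ΔF/ΔT on the overlapping bins;
additive (D-independent) constants cancel in the slope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .elastic import ElasticConstants
from .ensemble import ConformationEnsemble
from .pmf import _auto_edges, _histogram_to_pmf
from .units import kbt_kj_mol

__all__ = ["FreeEnergyProfile1D", "ThermalResponse", "pmf1d_diameter",
           "entropy_vs_diameter", "predict_thermal_twist"]


@dataclass
class FreeEnergyProfile1D:
    """Marginal diameter free-energy profile at one temperature.

    Values are in kBT of ``temperature``, min-zeroed; counts per bin.
    """

    edges: np.ndarray
    values: np.ma.MaskedArray
    counts: np.ndarray
    temperature: float
    n_steps_avg: int = 1

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def values_kj_mol(self) -> np.ma.MaskedArray:
        return self.values * kbt_kj_mol(self.temperature)


@dataclass
class ThermalResponse:
    """Entropy slope, twist temperature coefficient and per-ΔT predictions."""

    k_sd: float                      # kJ/(mol·K·nm), per bp
    k_t: float                       # deg/°C per bp
    k_t_ci95: Optional[tuple] = None
    predictions: Optional[pd.DataFrame] = None  # columns delta_T_K, delta_omega_deg
    diagnostics: Optional[dict] = None


def pmf1d_diameter(ensemble: ConformationEnsemble, n_bins: int = 30,
                   edges: Optional[np.ndarray] = None) -> FreeEnergyProfile1D:
    """Boltzmann inversion of the diameter histogram, min-zeroed, in kBT."""
    d = ensemble.diameter
    if edges is None:
        edges = _auto_edges(d, n_bins)
    counts, edges = np.histogram(d, bins=edges)
    if np.count_nonzero(counts) < 2:
        raise ValueError("fewer than 2 occupied diameter bins")
    return FreeEnergyProfile1D(edges=edges, values=_histogram_to_pmf(counts),
                               counts=counts.astype(int),
                               temperature=ensemble.temperature,
                               n_steps_avg=ensemble.n_steps_avg)


def entropy_vs_diameter(profiles: Sequence[FreeEnergyProfile1D],
                        min_count: int = 100) -> tuple[pd.DataFrame, float, float]:
    """Entropy profile S(D) and its slope k_SD from multi-temperature PMFs.

    S(D) = −[F(D; T₂) − F(D; T₁)]/(T₂ − T₁) on bins occupied at both
    temperatures, with energies converted to kJ/mol first; with more than
    two profiles, consecutive pairs are pooled. The slope k_SD is a
    count-weighted straight-line fit over the central bins (≥ ``min_count``
    frames at every temperature), reported per base pair by dividing out
    the averaging factor of the records.

    Returns
    -------
    (series, k_sd, k_sd_se)
        DataFrame of (diameter, entropy_kj_mol_K), the per-bp slope in
        kJ/(mol·K·nm), and its standard error.
    """
    if len(profiles) < 2:
        raise ValueError("need profiles at ≥ 2 temperatures")
    temps = [p.temperature for p in profiles]
    if len(set(temps)) < 2:
        raise ValueError("temperatures must be distinct")
    n_avg = {p.n_steps_avg for p in profiles}
    if len(n_avg) != 1:
        raise ValueError("profiles mix different n_steps_avg")
    n_avg = n_avg.pop()
    order = np.argsort(temps)
    profiles = [profiles[i] for i in order]

    ref_edges = profiles[0].edges
    for p in profiles[1:]:
        if p.edges.shape != ref_edges.shape or not np.allclose(p.edges, ref_edges):
            raise ValueError(
                "profiles must share bin edges; rebuild with explicit edges")

    rows = []
    for p1, p2 in zip(profiles[:-1], profiles[1:]):
        ok = ((~p1.values.mask) & (~p2.values.mask)
              & (p1.counts >= min_count) & (p2.counts >= min_count))
        if not ok.any():
            raise ValueError(
                f"no overlapping occupied bins between T={p1.temperature} K "
                f"and T={p2.temperature} K")
        f1 = p1.values_kj_mol().data[ok]
        f2 = p2.values_kj_mol().data[ok]
        s = -(f2 - f1) / (p2.temperature - p1.temperature)
        w = np.minimum(p1.counts[ok], p2.counts[ok]).astype(float)
        for d, sv, wv in zip(p1.centers[ok], s, w):
            rows.append({"diameter": d, "entropy_kj_mol_K": sv, "weight": wv})
    series = pd.DataFrame(rows)
    if len(series) < 2:
        raise ValueError("need ≥ 2 overlapping bins to fit an entropy slope")

    x = series["diameter"].to_numpy()
    y = series["entropy_kj_mol_K"].to_numpy()
    w = np.sqrt(series["weight"].to_numpy())
    design = np.column_stack([x, np.ones_like(x)]) * w[:, None]
    coef, *_ = np.linalg.lstsq(design, y * w, rcond=None)
    resid = y * w - design @ coef
    dof = max(len(x) - 2, 1)
    cov = np.linalg.inv(design.T @ design) * (resid @ resid) / dof
    k_sd_mol = float(coef[0])
    se_mol = float(np.sqrt(cov[0, 0]))
    # records average n_steps_avg base-pair steps → per-bp slope
    return series, k_sd_mol / n_avg, se_mol / n_avg


def predict_thermal_twist(constants: ElasticConstants, k_sd: float,
                          delta_t_list: Sequence[float] = (),
                          k_sd_se: Optional[float] = None) -> ThermalResponse:
    """Twist temperature coefficient k_T and per-ΔT twist predictions.

    Parameters
    ----------
    constants : ElasticConstants
        Per-bp constants (positive definite).
    k_sd : float
        Entropy-diameter slope, kJ/(mol·K·nm) per bp; converted internally
        to kBT/(K·nm) at the constants' temperature.
    delta_t_list : sequence of float
        Temperature offsets (K or °C — identical for differences) at which
        Δω = k_T·ΔT is tabulated.
    """
    det = constants.determinant
    if det <= 0:
        raise ValueError("elastic constants must be positive definite")
    k_sd_kbt = k_sd / kbt_kj_mol(constants.temperature)  # kBT/(K·nm)
    k_t = -constants.k_omega_d * k_sd_kbt / det
    preds = pd.DataFrame({
        "delta_T_K": list(delta_t_list),
        "delta_omega_deg": [k_t * dt for dt in delta_t_list]})
    ci = None
    if k_sd_se is not None:
        half = 1.96 * abs(constants.k_omega_d / det) * k_sd_se / kbt_kj_mol(
            constants.temperature)
        ci = (k_t - half, k_t + half)
    return ThermalResponse(k_sd=k_sd, k_t=float(k_t), k_t_ci95=ci,
                           predictions=preds,
                           diagnostics={"det_kbt2": det})
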