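"""Config-driven orchestration of the full twist-diameter analysis.

One configuration document drives: synthetic ensemble generation → 2-D PMF
→ elastic-constant fit → salt response → thermal response → synthetic
magnetic-tweezers comparison. Every stage writes its artifact to the output
directory and the run closes with a JSON metrics file plus a plain-text log
recording seeds, versions and the derived headline numbers (effective twist
stiffness, rod twist rigidity, backbone coupling estimate, k_T). Outputs
are deterministic given the configured seeds.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .elastic import (ElasticConstants, REFERENCE_BACKBONE,
                      backbone_coupling_estimate, effective_twist_stiffness,
                      fit_gaussian_covariance,
                      twist_rigidity, QuadraticPMFFit)
from .electrostatics import HelixChargeModel, salt_curve
from .ensemble import write_ensemble
from .mt import delta_twist_series, fit_plectoneme_lines, write_rotation_curve
from .pmf import build_pmf2d, write_pmf2d
from .synthetic import (GeneratorSpec, sample_ensemble, sample_multitemperature,
                        synth_rotation_extension, DEFAULT_ALPHA_D)
from .thermal import entropy_vs_diameter, pmf1d_diameter, predict_thermal_twist
from .units import T_REF

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Invalid pipeline configuration (missing field, bad unit, bad value)."""


@dataclass
class PipelineConfig:
    """Validated settings of one pipeline run. All units fixed by field name."""

    # generator
    omega0_deg: float = 34.82
    d0_nm: float = 2.008
    k_omega_kbt_deg2: float = 0.18
    k_d_kbt_nm2: float = 263.0
    k_omega_d_kbt_deg_nm: float = 4.5
    n_frames: int = 50_000
    n_steps_avg: int = 19
    alpha_d_nm_per_k: float = DEFAULT_ALPHA_D
    temperature_k: float = T_REF
    # binning / fit
    n_twist_bins: int = 10
    n_diam_bins: int = 10
    min_count: int = 5
    n_bootstrap: int = 200
    # electrostatics
    salt_list_m: Sequence[float] = (0.05, 0.1, 0.15, 0.3, 0.5, 1.0)
    reference_salt_m: float = 1.0
    pair_cutoff: int = 50
    # thermal
    temperature_list_k: Sequence[float] = (285.0, 305.0)
    # magnetic tweezers
    mt_n_bp: int = 13_600
    mt_wing_slope_um: float = 0.05
    mt_cap_halfwidth: float = 5.0
    mt_apex_um: float = 4.0
    mt_turn_range: float = 20.0
    mt_noise_sd_um: float = 0.005
    # bookkeeping
    seed: int = 0
    out_dir: str = "dnatwist_run"
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.schema_version != SCHEMA_VERSION:
            raise ConfigError(
                f"unsupported schema_version {self.schema_version}")
        if self.n_frames <= 0:
            raise ConfigError("n_frames must be positive")
        if len(set(self.temperature_list_k)) < 2:
            raise ConfigError("temperature_list_k needs ≥ 2 distinct values")
        if any(c <= 0 for c in self.salt_list_m) or self.reference_salt_m <= 0:
            raise ConfigError("salt concentrations must be positive")
        det = (self.k_omega_kbt_deg2 * self.k_d_kbt_nm2
               - self.k_omega_d_kbt_deg_nm**2)
        if self.k_omega_kbt_deg2 <= 0 or self.k_d_kbt_nm2 <= 0 or det <= 0:
            raise ConfigError("stiffness matrix must be positive definite")

    def constants(self) -> ElasticConstants:
        return ElasticConstants(
            omega0=self.omega0_deg, d0=self.d0_nm,
            k_omega=self.k_omega_kbt_deg2, k_d=self.k_d_kbt_nm2,
            k_omega_d=self.k_omega_d_kbt_deg_nm,
            temperature=self.temperature_k)

    def generator_spec(self, alpha_d: Optional[float] = None) -> GeneratorSpec:
        return GeneratorSpec(
            constants=self.constants(), n_frames=self.n_frames,
            n_steps_avg=self.n_steps_avg,
            alpha_d=self.alpha_d_nm_per_k if alpha_d is None else alpha_d,
            t_ref=self.temperature_k)


_UNIT_SUFFIXES = ("_deg", "_nm", "_deg2", "_nm2", "_deg_nm", "_k", "_m",
                  "_per_k", "_um", "_kbt")


def load_config(source: Union[str, Path, dict]) -> PipelineConfig:
    """Load and validate a YAML/JSON config; unknown keys are rejected.

    Every physical field name carries its unit as a suffix, so a document
    with a bare key like ``omega0`` fails validation rather than being
    silently interpreted.
    """
    if isinstance(source, dict):
        doc = dict(source)
    else:
        doc = yaml.safe_load(Path(source).read_text())
        if not isinstance(doc, dict):
            raise ConfigError("config document must be a mapping")
    valid = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(doc) - valid
    if unknown:
        hints = [k for k in unknown
                 if any(k + s in valid for s in _UNIT_SUFFIXES)
                 or any(v.startswith(k + "_") for v in valid)]
        msg = f"unknown config keys: {sorted(unknown)}"
        if hints:
            msg += f" (missing unit suffix? e.g. {hints[0]!r})"
        raise ConfigError(msg)
    try:
        return PipelineConfig(**doc)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the metrics dictionary.

    Artifacts written to ``config.out_dir``: the reference ensemble and PMF,
    constants JSON, salt-response and thermal tables, the MT comparison
    table, ``metrics.json`` and ``run.log``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"dnatwist {__version__} on python "
                      f"{platform.python_version()}, numpy {np.__version__}",
                      f"seed {config.seed}"]
    metrics: dict = {"seed": config.seed, "version": __version__}
    rng = np.random.default_rng(config.seed)

    def stage_seed() -> int:
        return int(rng.integers(0, 2**31 - 1))

    def fail(stage, exc):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # --- stage 1: reference ensemble and PMF ------------------------------
    try:
        spec = config.generator_spec(alpha_d=0.0)
        ens = sample_ensemble(spec, temperature=config.temperature_k,
                              seed=stage_seed(), salt=config.reference_salt_m,
                              label="reference")
        write_ensemble(out / "ensemble_reference.tsv", ens)
        pmf = build_pmf2d(ens, config.n_twist_bins, config.n_diam_bins)
        write_pmf2d(out / "pmf2d_reference.tsv", pmf)
        log.append(f"stage ensemble+pmf: {ens.n_frames} frames, "
                   f"{int((~pmf.values.mask).sum())} occupied bins")
    except Exception as exc:
        fail("ensemble+pmf", exc)

    # --- stage 2: elastic fit ---------------------------------------------
    try:
        fitter = QuadraticPMFFit(
            n_twist_bins=config.n_twist_bins, n_diam_bins=config.n_diam_bins,
            n_steps_avg=config.n_steps_avg, min_count=config.min_count,
            n_bootstrap=config.n_bootstrap, temperature=config.temperature_k,
            random_state=stage_seed())
        fitter.fit(ens.as_array())
        constants = fitter.constants_
        constants.to_json(out / "elastic_constants.json")
        cov_constants = fit_gaussian_covariance(ens)
        k_eff = effective_twist_stiffness(constants)
        rigidity = twist_rigidity(k_eff, rise=0.34,
                                  temperature=config.temperature_k)
        backbone = backbone_coupling_estimate(REFERENCE_BACKBONE,
                                              config.temperature_k)
        metrics["elastic"] = {
            "k_omega": constants.k_omega, "k_D": constants.k_d,
            "k_omegaD": constants.k_omega_d,
            "k_omegaD_covariance_route": cov_constants.k_omega_d,
            "effective_twist_stiffness_kbt_deg2": k_eff,
            "twist_rigidity_pn_nm2": rigidity,
            "backbone_coupling_estimate_kbt_deg_nm": backbone,
        }
        log.append(
            f"stage elastic: k_omegaD {constants.k_omega_d:.3f} "
            f"(covariance route {cov_constants.k_omega_d:.3f}); "
            f"effective twist stiffness {k_eff:.4f} kBT/deg^2; "
            f"twist rigidity {rigidity:.0f} pN nm^2; "
            f"backbone estimate {backbone:.2f} kBT/(deg nm)")
    except Exception as exc:
        fail("elastic_fit", exc)

    # --- stage 3: salt response -------------------------------------------
    try:
        model = HelixChargeModel(radius=config.d0_nm / 2.0,
                                 twist_per_bp=config.omega0_deg,
                                 pair_cutoff=config.pair_cutoff)
        salt_df = salt_curve(constants, model, list(config.salt_list_m),
                             config.reference_salt_m, config.temperature_k)
        salt_df.to_csv(out / "salt_response.tsv", sep="\t", index=False)
        metrics["salt"] = {
            "c_list_M": list(map(float, config.salt_list_m)),
            "delta_omega_deg": salt_df["delta_omega_deg"].tolist()}
        log.append("stage salt: delta_omega "
                   + ", ".join(f"{c:g} M -> {w:+.4f} deg"
                               for c, w in zip(salt_df["c_salt_M"],
                                               salt_df["delta_omega_deg"])))
    except Exception as exc:
        fail("salt_response", exc)

    # --- stage 4: thermal response ----------------------------------------
    try:
        thermal_spec = config.generator_spec()
        ensembles = sample_multitemperature(
            thermal_spec, list(config.temperature_list_k), seed=stage_seed())
        edges = None
        profiles = []
        for e in ensembles:
            prof = pmf1d_diameter(e, edges=edges) if edges is not None \
                else pmf1d_diameter(e)
            if edges is None:
                edges = prof.edges
            profiles.append(prof)
        series, k_sd, k_sd_se = entropy_vs_diameter(profiles)
        response = predict_thermal_twist(constants, k_sd,
                                         delta_t_list=[-10, 0, 10],
                                         k_sd_se=k_sd_se)
        report = pd.DataFrame({
            "T_K": [e.temperature for e in ensembles],
            "mean_D_nm": [e.diameter.mean() for e in ensembles],
            "mean_twist_deg": [e.twist.mean() for e in ensembles]})
        report.to_csv(out / "thermal_report.tsv", sep="\t", index=False)
        (out / "thermal_response.json").write_text(json.dumps({
            "k_SD_kj_mol_K_nm": response.k_sd,
            "k_SD_se": k_sd_se,
            "k_T_deg_per_C": response.k_t,
            "k_T_ci95": response.k_t_ci95}, indent=2))
        metrics["thermal"] = {"k_SD_kj_mol_K_nm": response.k_sd,
                              "k_T_deg_per_C": response.k_t}
        log.append(f"stage thermal: k_SD {response.k_sd:.4f} kJ/(mol K nm), "
                   f"k_T {response.k_t:+.5f} deg/C")
    except Exception as exc:
        fail("thermal_response", exc)

    # --- stage 5: synthetic MT comparison ---------------------------------
    try:
        base_turns = 0.0
        measurements = []
        generated = []
        for _, row in salt_df.iterrows():
            # relaxed point shifts with the predicted twist change
            n_star = base_turns + row["delta_omega_deg"] * config.mt_n_bp / 360.0
            curve = synth_rotation_extension(
                n_turn_star=n_star, wing_slope=config.mt_wing_slope_um,
                cap_halfwidth=config.mt_cap_halfwidth,
                apex_extension=config.mt_apex_um,
                turn_range=config.mt_turn_range,
                noise_sd=config.mt_noise_sd_um, seed=stage_seed(),
                label=f"{row['c_salt_M']:g} M")
            write_rotation_curve(
                out / f"mt_curve_{row['c_salt_M']:g}M.tsv", curve)
            generated.append(n_star)
            measurements.append(fit_plectoneme_lines(curve,
                                                     n_bp=config.mt_n_bp))
        table = delta_twist_series(
            measurements, reference_label=f"{config.reference_salt_m:g} M")
        table["predicted_delta_omega_deg"] = salt_df["delta_omega_deg"].to_numpy()
        table.to_csv(out / "mt_comparison.tsv", sep="\t", index=False)
        resid = (table["delta_omega_deg_per_bp"]
                 - table["predicted_delta_omega_deg"]).abs().max()
        metrics["mt"] = {
            "max_abs_recovery_error_deg": float(resid),
            "recovered_delta_omega_deg":
                table["delta_omega_deg_per_bp"].tolist()}
        log.append(f"stage mt: max |recovered - predicted| {resid:.4f} deg/bp")
    except Exception as exc:
        fail("mt_comparison", exc)

    (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
    (out / "run.log").write_text("\n".join(log) + "\n")
    return metrics
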