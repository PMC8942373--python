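"""Conformational ensembles of per-frame (twist, diameter) records.

An ensemble holds per-frame helical observables of a DNA duplex: the twist
angle ω (degrees per base-pair step) and the interstrand phosphate-phosphate
diameter D (nm), optionally together with the backbone dihedral angles χ and
δ. Each record is an average over ``n_steps_avg`` base-pair steps, so the
molecule-level stiffness seen in the record fluctuations is ``n_steps_avg``
times the per-base-pair stiffness.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

__all__ = ["ConformationEnsemble", "EnsembleParseError", "read_ensemble", "write_ensemble"]

_REQUIRED_COLUMNS = ("twist_deg", "diameter_nm")
_OPTIONAL_COLUMNS = ("chi_deg", "delta_deg")


class EnsembleParseError(ValueError):
    """Raised when an ensemble file is malformed; carries the offending line."""

    def __init__(self, message: str, line_number: Optional[int] = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass
class ConformationEnsemble:
    """Per-frame (twist, diameter[, χ, δ]) samples with condition metadata.

    Parameters
    ----------
    twist : ndarray
        Twist angle per base-pair step, degrees. Must lie in (0, 90).
    diameter : ndarray
        Interstrand phosphate-phosphate diameter, nm. Must be positive.
    temperature : float
        Absolute temperature of the condition, K.
    salt : float, optional
        1:1 salt concentration tag, mol/L.
    tilt_force : float
        External force applied to the diameter coordinate, kBT/nm per bp
        (0 for an unperturbed ensemble).
    n_steps_avg : int
        Number of base-pair steps each record averages over (≥ 1).
    chi, delta : ndarray, optional
        Backbone dihedral angles, degrees.
    seed : int, optional
        Seed used to generate the ensemble, if synthetic.
    """

    twist: np.ndarray
    diameter: np.ndarray
    temperature: float = 295.15
    salt: Optional[float] = None
    tilt_force: float = 0.0
    n_steps_avg: int = 1
    chi: Optional[np.ndarray] = None
    delta: Optional[np.ndarray] = None
    seed: Optional[int] = None
    label: str = ""

    def __post_init__(self) -> None:
        self.twist = np.asarray(self.twist, dtype=float)
        self.diameter = np.asarray(self.diameter, dtype=float)
        if self.twist.ndim != 1 or self.diameter.ndim != 1:
            raise ValueError("twist and diameter must be 1-D arrays")
        if self.twist.size != self.diameter.size:
            raise ValueError("twist and diameter must have equal length")
        if self.twist.size < 1:
            raise ValueError("ensemble must contain at least one frame")
        if not np.all((self.twist > 0.0) & (self.twist < 90.0)):
            raise ValueError("twist angles must lie in (0°, 90°)")
        if not np.all(self.diameter > 0.0):
            raise ValueError("all diameters must be positive")
        if int(self.n_steps_avg) < 1:
            raise ValueError(f"n_steps_avg must be ≥ 1, got {self.n_steps_avg}")
        self.n_steps_avg = int(self.n_steps_avg)
        for name in ("chi", "delta"):
            val = getattr(self, name)
            if val is not None:
                val = np.asarray(val, dtype=float)
                if val.shape != self.twist.shape:
                    raise ValueError(f"{name} must match the frame count")
                setattr(self, name, val)

    @property
    def n_frames(self) -> int:
        return self.twist.size

    def channels(self) -> dict[str, np.ndarray]:
        """Available named channels (twist, diameter and any dihedrals)."""
        out = {"twist": self.twist, "diameter": self.diameter}
        if self.chi is not None:
            out["chi"] = self.chi
        if self.delta is not None:
            out["delta"] = self.delta
        return out

    def as_array(self) -> np.ndarray:
        """Frames as an (n, 2) array of columns [twist_deg, diameter_nm]."""
        return np.column_stack([self.twist, self.diameter])

    def to_frame(self) -> pd.DataFrame:
        data = {"frame": np.arange(self.n_frames, dtype=int),
                "twist_deg": self.twist, "diameter_nm": self.diameter}
        if self.chi is not None:
            data["chi_deg"] = self.chi
        if self.delta is not None:
            data["delta_deg"] = self.delta
        return pd.DataFrame(data)


def write_ensemble(path: Union[str, Path], ensemble: ConformationEnsemble) -> None:
    """Write an ensemble as TSV with a comment-prefixed metadata header."""
    path = Path(path)
    lines = [f"# temperature_K\t{ensemble.temperature!r}",
             f"# n_steps_avg\t{ensemble.n_steps_avg}",
             f"# tilt_force_kBT_per_nm\t{ensemble.tilt_force!r}"]
    if ensemble.salt is not None:
        lines.append(f"# salt_M\t{ensemble.salt!r}")
    if ensemble.seed is not None:
        lines.append(f"# seed\t{ensemble.seed}")
    if ensemble.label:
        lines.append(f"# label\t{ensemble.label}")
    buf = io.StringIO()
    ensemble.to_frame().to_csv(buf, sep="\t", index=False, float_format="%.10g")
    path.write_text("\n".join(lines) + "\n" + buf.getvalue())


def read_ensemble(path: Union[str, Path]) -> ConformationEnsemble:
    """Read an ensemble written by :func:`write_ensemble`.

    Raises
    ------
    EnsembleParseError
        On a malformed header line, a missing required column, or a
        non-numeric cell; the error names the line number.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    header_rows = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("#"):
                break
            header_rows += 1
            body = line[1:].strip()
            if "\t" not in body:
                raise EnsembleParseError(
                    f"metadata header must be '# key<TAB>value', got {body!r}", lineno)
            key, value = body.split("\t", 1)
            meta[key.strip()] = value.strip()

    try:
        df = pd.read_csv(path, sep="\t", skiprows=header_rows)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise EnsembleParseError(f"could not parse table: {exc}") from exc

    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise EnsembleParseError(f"missing required column {col!r}",
                                     header_rows + 1)
    for col in _REQUIRED_COLUMNS + tuple(c for c in _OPTIONAL_COLUMNS if c in df.columns):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(vals.isna().to_numpy())[0]
        if bad.size:
            # +2: 1-based, plus the column-header row
            raise EnsembleParseError(
                f"non-numeric value in column {col!r}",
                header_rows + 2 + int(bad[0]))
        df[col] = vals

    def _get_float(key: str, default=None):
        if key in meta:
            return float(meta[key])
        return default

    return ConformationEnsemble(
        twist=df["twist_deg"].to_numpy(),
        diameter=df["diameter_nm"].to_numpy(),
        temperature=_get_float("temperature_K", 295.15),
        salt=_get_float("salt_M"),
        tilt_force=_get_float("tilt_force_kBT_per_nm", 0.0),
        n_steps_avg=int(meta.get("n_steps_avg", 1)),
        chi=df["chi_deg"].to_numpy() if "chi_deg" in df.columns else None,
        delta=df["delta_deg"].to_numpy() if "delta_deg" in df.columns else None,
        seed=int(meta["seed"]) if "seed" in meta else None,
        label=meta.get("label", ""),
    )
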