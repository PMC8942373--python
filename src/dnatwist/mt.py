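"""Magnetic-tweezers rotation-extension curve analysis.

At low stretching force a torsionally strained DNA tether absorbs applied
turns into plectonemes, so the bead extension falls linearly with turns on
both sides of the torsionally relaxed point. Fitting a straight line to
each plectoneme wing and intersecting the two lines locates the relaxed
point N*; shifts of N* between buffer conditions convert to twist change
per base pair through Δω = ΔN*·360°/N_bp. Only relative twist is ever
reported — the absolute register of the tether is not observable.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = ["RotationExtensionCurve", "TwistMeasurement", "PlectonemeFit",
           "fit_plectoneme_lines", "twist_from_turns", "delta_twist_series",
           "read_rotation_curve", "write_rotation_curve"]

#: Slopes closer than this (µm/turn) are treated as parallel — no crossing.
PARALLEL_TOL = 1e-6


@dataclass
class RotationExtensionCurve:
    """(turns, extension) series at fixed force.

    Turns are signed and strictly increasing; extensions are nonnegative µm.
    """

    turns: np.ndarray
    extension: np.ndarray
    force: float = 0.3
    label: str = ""

    def __post_init__(self) -> None:
        self.turns = np.asarray(self.turns, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        if self.turns.ndim != 1 or self.turns.shape != self.extension.shape:
            raise ValueError("turns and extension must be matching 1-D arrays")
        if self.turns.size < 2:
            raise ValueError("curve needs at least 2 points")
        if not np.all(np.diff(self.turns) > 0):
            raise ValueError("turns must be strictly increasing")
        if np.any(self.extension < 0):
            raise ValueError("extensions must be nonnegative")


@dataclass
class TwistMeasurement:
    """Result of the two-line relaxed-point fit of one curve.

    ``n_turn_star`` is the abscissa where the two wing lines cross;
    ``delta_omega_vs_reference`` is populated by :func:`delta_twist_series`
    once a reference condition is chosen.
    """

    n_turn_star: float
    left_line: tuple[float, float]    # (slope, intercept), µm/turn & µm
    right_line: tuple[float, float]
    left_rms_residual: float
    right_rms_residual: float
    n_bp: int
    label: str = ""
    delta_omega_vs_reference: Optional[float] = None

    def to_json(self) -> str:
        return json.dumps({
            "n_turn_star": self.n_turn_star,
            "left_line": list(self.left_line),
            "right_line": list(self.right_line),
            "left_rms_residual": self.left_rms_residual,
            "right_rms_residual": self.right_rms_residual,
            "n_bp": self.n_bp, "label": self.label,
            "delta_omega_vs_reference": self.delta_omega_vs_reference,
        }, indent=2)


def twist_from_turns(n_turn_star: float, n_bp: int) -> float:
    """Convert turns to twist per base pair: ω = N*·360°/N_bp."""
    if n_bp <= 0:
        raise ValueError(f"n_bp must be positive, got {n_bp}")
    return n_turn_star * 360.0 / n_bp


class PlectonemeFit(BaseEstimator, RegressorMixin):
    """Two-line plectoneme fit locating the torsionally relaxed point.

    ``fit(X, y)`` takes applied turns (X, shape (n,) or (n, 1)) and
    extensions (y, µm). Wing points are chosen either from explicit turn
    intervals or automatically: the apex is the midpoint of the turns of the
    top 5% extensions, and points at least ``cap_halfwidth_guess`` turns
    away on each side form the wings. Each wing gets an ordinary
    least-squares line; their crossing is ``n_turn_star_``.

    Parameters
    ----------
    wing_selector : "auto" or ((l_lo, l_hi), (r_lo, r_hi))
        Explicit turn intervals for the left and right wings, or "auto".
    cap_halfwidth_guess : float
        Apex half-width excluded from the wings in auto mode, turns.
    n_bp : int
        Tether length in base pairs, used for the turns→twist conversion.
    """

    def __init__(self, wing_selector="auto", cap_halfwidth_guess: float = 6.0,
                 apex_quantile: float = 0.95, n_bp: int = 13_600):
        self.wing_selector = wing_selector
        self.cap_halfwidth_guess = cap_halfwidth_guess
        self.apex_quantile = apex_quantile
        self.n_bp = n_bp

    def _select_wings(self, turns, ext, center=None):
        if self.wing_selector == "auto":
            if center is None:
                top = ext >= np.quantile(ext, self.apex_quantile)
                center = 0.5 * (turns[top].min() + turns[top].max())
            left = turns <= center - self.cap_halfwidth_guess
            right = turns >= center + self.cap_halfwidth_guess
        else:
            (l_lo, l_hi), (r_lo, r_hi) = self.wing_selector
            left = (turns >= l_lo) & (turns <= l_hi)
            right = (turns >= r_lo) & (turns <= r_hi)
        return left, right

    def fit(self, X, y) -> "PlectonemeFit":
        turns = np.asarray(X, dtype=float).reshape(-1)
        ext = np.asarray(y, dtype=float).reshape(-1)
        if turns.shape != ext.shape:
            raise ValueError("turns and extension must have matching length")
        # in auto mode a second pass re-centers the apex on the first
        # crossing estimate, removing the selection bias of a noisy apex
        n_passes = 2 if self.wing_selector == "auto" else 1
        center = None
        for _ in range(n_passes):
            left, right = self._select_wings(turns, ext, center)
            if left.sum() < 3 or right.sum() < 3:
                raise ValueError(
                    f"each wing needs ≥ 3 points (got {int(left.sum())} left, "
                    f"{int(right.sum())} right)")
            lines = []
            resids = []
            for sel in (left, right):
                coef = np.polyfit(turns[sel], ext[sel], 1)
                pred = np.polyval(coef, turns[sel])
                lines.append((float(coef[0]), float(coef[1])))
                resids.append(float(np.sqrt(np.mean((ext[sel] - pred)**2))))
            (sl, il), (sr, ir) = lines
            # extension rises toward the apex: left wing up, right wing down
            if not (sl > 0 > sr):
                raise ValueError(
                    "no plectoneme regime detected: wing slopes "
                    f"({sl:.4g}, {sr:.4g}) are not opposite-signed")
            if abs(sl - sr) < PARALLEL_TOL:
                raise ValueError("wing lines are parallel; no crossing")
            center = (ir - il) / (sl - sr)
        self.n_turn_star_ = center
        self.left_line_, self.right_line_ = lines
        self.left_rms_residual_, self.right_rms_residual_ = resids
        self.wing_masks_ = (left, right)
        return self

    def predict(self, X) -> np.ndarray:
        """Two-line model extension (lower envelope of the wing lines)."""
        turns = np.asarray(X, dtype=float).reshape(-1)
        left = np.polyval(self.left_line_, turns)
        right = np.polyval(self.right_line_, turns)
        return np.minimum(left, right)

    def measurement(self, label: str = "") -> TwistMeasurement:
        return TwistMeasurement(
            n_turn_star=float(self.n_turn_star_),
            left_line=self.left_line_, right_line=self.right_line_,
            left_rms_residual=self.left_rms_residual_,
            right_rms_residual=self.right_rms_residual_,
            n_bp=self.n_bp, label=label)


def fit_plectoneme_lines(curve: RotationExtensionCurve,
                         wing_selector="auto",
                         n_bp: int = 13_600, **kwargs) -> TwistMeasurement:
    """Fit both plectoneme wings of a curve and locate the relaxed point."""
    est = PlectonemeFit(wing_selector=wing_selector, n_bp=n_bp, **kwargs)
    est.fit(curve.turns, curve.extension)
    return est.measurement(label=curve.label)


def delta_twist_series(measurements: Sequence[TwistMeasurement],
                       reference_label: str) -> pd.DataFrame:
    """Twist change per bp of each condition relative to a reference.

    Δω(condition) = (N*_cond − N*_ref)·360°/N_bp; the reference row is 0
    exactly. All measurements must share the same tether length.
    """
    by_label = {m.label: m for m in measurements}
    if reference_label not in by_label:
        raise ValueError(f"reference condition {reference_label!r} not present")
    n_bps = {m.n_bp for m in measurements}
    if len(n_bps) != 1:
        raise ValueError(f"mismatched n_bp across measurements: {sorted(n_bps)}")
    ref = by_label[reference_label]
    rows = []
    for m in measurements:
        delta = twist_from_turns(m.n_turn_star - ref.n_turn_star, m.n_bp)
        m.delta_omega_vs_reference = delta
        rows.append({"condition": m.label, "n_turn_star": m.n_turn_star,
                     "delta_omega_deg_per_bp": delta})
    return pd.DataFrame(rows)


def write_rotation_curve(path: Union[str, Path],
                         curve: RotationExtensionCurve) -> None:
    path = Path(path)
    header = [f"# force_pN\t{curve.force!r}"]
    if curve.label:
        header.append(f"# label\t{curve.label}")
    buf = io.StringIO()
    pd.DataFrame({"turns": curve.turns, "extension_um": curve.extension}
                 ).to_csv(buf, sep="\t", index=False, float_format="%.10g")
    path.write_text("\n".join(header) + "\n" + buf.getvalue())


def read_rotation_curve(path: Union[str, Path]) -> RotationExtensionCurve:
    path = Path(path)
    meta = {}
    skip = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line[1:].strip()
            if "\t" in body:
                k, v = body.split("\t", 1)
                meta[k.strip()] = v.strip()
    df = pd.read_csv(path, sep="\t", skiprows=skip)
    for col in ("turns", "extension_um"):
        if col not in df.columns:
            raise ValueError(f"rotation-curve file missing column {col!r}")
    return RotationExtensionCurve(
        turns=df["turns"].to_numpy(float),
        extension=df["extension_um"].to_numpy(float),
        force=float(meta.get("force_pN", 0.3)),
        label=meta.get("label", ""))
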