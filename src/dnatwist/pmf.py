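"""Potential-of-mean-force landscapes over (twist, diameter).

The 2-D landscape is the Boltzmann inversion of the binned conformational
density: P(ω, D) = −kBT ln Ω(ω, D), shifted by a constant so its minimum
over occupied bins is exactly zero. Unoccupied bins are masked, never
zero-filled. Conditional 1-D slices and the conditional-mean-twist line
expose the twist-diameter coupling directly: for a harmonic landscape the
mean twist falls along a straight line of slope −k_ωD/k_ω in the diameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .ensemble import ConformationEnsemble

__all__ = ["PMF2D", "PMF1D", "build_pmf2d", "conditional_pmf_twist",
           "conditional_mean_twist", "correlation_matrix", "write_pmf2d"]


def _frames(ensemble) -> np.ndarray:
    if isinstance(ensemble, ConformationEnsemble):
        return ensemble.as_array()
    X = np.asarray(ensemble, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("expected an ensemble or an (n, 2) array")
    return X


@dataclass
class PMF2D:
    """Binned 2-D free-energy surface in kBT.

    ``values`` is a masked array over (twist bin, diameter bin); masked
    entries are unoccupied. The occupied-bin minimum is exactly 0.
    """

    twist_edges: np.ndarray
    diameter_edges: np.ndarray
    values: np.ma.MaskedArray
    counts: np.ndarray

    @property
    def twist_centers(self) -> np.ndarray:
        return 0.5 * (self.twist_edges[:-1] + self.twist_edges[1:])

    @property
    def diameter_centers(self) -> np.ndarray:
        return 0.5 * (self.diameter_edges[:-1] + self.diameter_edges[1:])

    @property
    def n_frames(self) -> int:
        return int(self.counts.sum())


@dataclass
class PMF1D:
    """Binned 1-D free-energy profile in kBT, min-zeroed.

    ``window`` describes the conditioning applied to the parent ensemble
    (e.g. a diameter interval), empty for a plain marginal.
    """

    edges: np.ndarray
    values: np.ma.MaskedArray
    counts: np.ndarray
    window: str = ""

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def quadratic_fit(self, min_count: int = 5) -> tuple[float, float]:
        """Weighted quadratic fit; returns (curvature, minimum location).

        The curvature is the coefficient of x² (so a profile k x²/2 returns
        k/2); weights are √counts on bins with ≥ ``min_count`` frames.
        """
        ok = (~self.values.mask) & (self.counts >= min_count)
        if ok.sum() < 3:
            raise ValueError("need at least 3 usable bins for a quadratic fit")
        x, y = self.centers[ok], self.values.data[ok]
        w = np.sqrt(self.counts[ok].astype(float))
        design = np.column_stack([x**2, x, np.ones_like(x)])
        (a, b, _c), *_ = np.linalg.lstsq(design * w[:, None], y * w, rcond=None)
        if a <= 0:
            raise ValueError(f"profile is not convex (curvature {a:.3g})")
        return float(a), float(-b / (2 * a))


def _auto_edges(x: np.ndarray, n_bins: int, n_sd: float = 3.5) -> np.ndarray:
    mu, sd = x.mean(), x.std()
    if sd == 0:
        raise ValueError("degenerate axis: zero variance")
    return np.linspace(mu - n_sd * sd, mu + n_sd * sd, n_bins + 1)


def _histogram_to_pmf(counts: np.ndarray) -> np.ma.MaskedArray:
    occupied = counts > 0
    with np.errstate(divide="ignore"):
        values = -np.log(counts, where=occupied,
                         out=np.zeros_like(counts, dtype=float))
    values = np.ma.MaskedArray(values, mask=~occupied)
    values -= values.min()
    return values


def build_pmf2d(ensemble, n_twist_bins: int = 10, n_diam_bins: int = 10,
                ranges: Optional[Sequence] = None) -> PMF2D:
    """Bin an ensemble into a min-zeroed 2-D PMF over (twist, diameter).

    Parameters
    ----------
    ensemble : ConformationEnsemble or (n, 2) array
        Columns [twist_deg, diameter_nm].
    n_twist_bins, n_diam_bins : int
        Bin counts (≥ 2 each).
    ranges : ((t_lo, t_hi), (d_lo, d_hi)) or explicit edge arrays, optional
        Default: sample mean ± 3.5 SD on each axis. Frames outside the
        ranges are dropped (counts then sum to the in-range frame count).
    """
    X = _frames(ensemble)
    if X.shape[0] < 1:
        raise ValueError("ensemble is empty")
    if n_twist_bins < 2 or n_diam_bins < 2:
        raise ValueError("need at least 2 bins per axis")
    if ranges is None:
        t_edges = _auto_edges(X[:, 0], n_twist_bins)
        d_edges = _auto_edges(X[:, 1], n_diam_bins)
    else:
        t_spec, d_spec = ranges
        t_spec, d_spec = np.asarray(t_spec, float), np.asarray(d_spec, float)
        t_edges = t_spec if t_spec.size > 2 else np.linspace(*t_spec, n_twist_bins + 1)
        d_edges = d_spec if d_spec.size > 2 else np.linspace(*d_spec, n_diam_bins + 1)
    counts, t_edges, d_edges = np.histogram2d(X[:, 0], X[:, 1],
                                              bins=[t_edges, d_edges])
    if counts.sum() == 0:
        raise ValueError("all frames fall outside the requested ranges")
    if np.count_nonzero(counts) < 2:
        raise ValueError("only one occupied bin; surface fit impossible")
    return PMF2D(twist_edges=t_edges, diameter_edges=d_edges,
                 values=_histogram_to_pmf(counts), counts=counts.astype(int))


def conditional_pmf_twist(ensemble, diameter_window: Sequence[float],
                          n_bins: int = 10, min_frames: int = 100) -> PMF1D:
    """1-D twist PMF of the frames whose diameter lies in ``diameter_window``.

    For a harmonic landscape the minimum location of this conditional profile
    moves to smaller twist as the window center grows (negative coupling),
    and its curvature is the conditional twist stiffness k_ω/2 per record.
    """
    X = _frames(ensemble)
    lo, hi = float(diameter_window[0]), float(diameter_window[1])
    sel = (X[:, 1] >= lo) & (X[:, 1] < hi)
    if sel.sum() == 0:
        raise ValueError(f"no frames with diameter in [{lo}, {hi}) nm")
    if sel.sum() < min_frames:
        raise ValueError(
            f"only {int(sel.sum())} frames in diameter window [{lo}, {hi}) nm; "
            f"need ≥ {min_frames}")
    twist = X[sel, 0]
    edges = _auto_edges(twist, n_bins)
    counts, edges = np.histogram(twist, bins=edges)
    return PMF1D(edges=edges, values=_histogram_to_pmf(counts),
                 counts=counts.astype(int),
                 window=f"{lo} <= D < {hi} nm")


def conditional_mean_twist(ensemble, n_diam_bins: int = 10,
                           min_count: int = 10) -> pd.DataFrame:
    """Mean twist per diameter bin with a weighted straight-line fit.

    Returns a DataFrame of (diameter, mean_twist, sem, count) with the fit
    stored in ``df.attrs['slope']`` / ``['intercept']`` / ``['slope_se']``.
    For harmonic fluctuations the slope estimates −k_ωD/k_ω.
    """
    X = _frames(ensemble)
    edges = _auto_edges(X[:, 1], n_diam_bins)
    idx = np.clip(np.digitize(X[:, 1], edges) - 1, 0, n_diam_bins - 1)
    rows = []
    for b in range(n_diam_bins):
        sel = idx == b
        n = int(sel.sum())
        if n < min_count:
            continue
        tw = X[sel, 0]
        # within-bin mean diameter, not the bin center: regressing on the
        # center shrinks the slope at the range edges
        rows.append({"diameter": X[sel, 1].mean(),
                     "mean_twist": tw.mean(),
                     "sem": tw.std(ddof=1) / np.sqrt(n) if n > 1 else np.inf,
                     "count": n})
    if len(rows) < 3:
        raise ValueError(
            f"only {len(rows)} occupied diameter bins; need ≥ 3 for a line")
    df = pd.DataFrame(rows)
    w = 1.0 / df["sem"].to_numpy()**2
    design = np.column_stack([df["diameter"], np.ones(len(df))])
    wd = design * np.sqrt(w)[:, None]
    coef, *_ = np.linalg.lstsq(wd, df["mean_twist"].to_numpy() * np.sqrt(w),
                               rcond=None)
    cov = np.linalg.inv(wd.T @ wd)
    df.attrs["slope"] = float(coef[0])
    df.attrs["intercept"] = float(coef[1])
    df.attrs["slope_se"] = float(np.sqrt(cov[0, 0]))
    return df


def correlation_matrix(ensemble: ConformationEnsemble,
                       channels: Optional[Sequence[str]] = None
                       ) -> pd.DataFrame:
    """Pearson correlations between the requested channels.

    Channels are any of twist, diameter, chi, delta present in the ensemble.
    In B-DNA the glycosidic χ and the sugar pucker δ dihedrals correlate
    negatively with the diameter and positively with the twist — diameter
    swelling and underwinding proceed through the same backbone motion.
    """
    available = ensemble.channels()
    if channels is None:
        channels = list(available)
    missing = [c for c in channels if c not in available]
    if missing:
        raise ValueError(f"channels not present in ensemble: {missing}")
    if ensemble.n_frames < 3:
        raise ValueError("need at least 3 frames for correlations")
    data = np.column_stack([available[c] for c in channels])
    sd = data.std(axis=0)
    constant = [c for c, s in zip(channels, sd) if s == 0]
    if constant:
        raise ValueError(f"constant channel(s), correlation undefined: {constant}")
    corr = np.corrcoef(data, rowvar=False)
    return pd.DataFrame(corr, index=list(channels), columns=list(channels))


def write_pmf2d(path: Union[str, Path], pmf: PMF2D) -> None:
    """Export a 2-D PMF in long TSV format; masked bins written as NA."""
    tw, dm = np.meshgrid(pmf.twist_centers, pmf.diameter_centers, indexing="ij")
    vals = pmf.values.filled(np.nan)
    df = pd.DataFrame({
        "twist_center": tw.ravel(), "diameter_center": dm.ravel(),
        "pmf_kBT": vals.ravel(), "count": pmf.counts.ravel()})
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.8g")
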