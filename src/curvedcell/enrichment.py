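"""Curvature-enrichment profiles: area-weighted conditional expectation of
per-cell-normalised intensity given Gaussian curvature, averaged over a
population.

The per-cell computation is: total surface intensity I_tot = Σ I_j·A_j,
mean density I* = I_tot / ΣA_j, then the conditional expectation
E[I/I* | K] per curvature bin, each face contributing its area as weight.
Because each cell is normalised by its own I*, the profile is invariant to
per-cell illumination scale, and the law of total expectation guarantees
Σ_K P(K)·E[I/I*|K] = 1 exactly for every cell.  The population profile is
the unweighted mean over cells per bin, with its SEM; it is smoothed with
a cubic smoothing spline and truncated where too little surface area at
that curvature exists in the population (availability threshold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_smoothing_spline

from .geometry import CellSurface

DEFAULT_K_BIN_WIDTH = 0.25   # μm⁻²
DEFAULT_CUTOFF = 2.0         # μm⁻²
DEFAULT_P_THRESHOLD = 5e-3


def _check_cell(cell: CellSurface) -> None:
    if cell.face_intensity is None:
        raise ValueError(f"cell {cell.cell_id!r} has no intensity")
    if np.any(cell.face_intensity < 0):
        raise ValueError(f"cell {cell.cell_id!r} has negative intensities")


def total_intensity(cell: CellSurface) -> float:
    """Total surface-integrated intensity Σ_j I_j·A_j (a.u.·μm²)."""
    _check_cell(cell)
    return float((cell.face_intensity * cell.face_area).sum())


def mean_density(cell: CellSurface) -> float:
    """Average surface density I* = I_tot / ΣA (a.u.)."""
    area = cell.total_area
    if area <= 0:
        raise ValueError("zero surface area")
    return total_intensity(cell) / area


def curvature_bins(
    cells, width: float = DEFAULT_K_BIN_WIDTH, pad: float = 0.0
) -> np.ndarray:
    """Half-open curvature bin edges covering the pooled observed range."""
    lo = min(float(c.face_curvature.min()) for c in cells) - pad
    hi = max(float(c.face_curvature.max()) for c in cells) + pad
    lo = np.floor(lo / width) * width
    hi = np.ceil(hi / width) * width
    n = max(1, int(round((hi - lo) / width)))
    return lo + width * np.arange(n + 1)


def joint_distribution(
    cell: CellSurface,
    intensity_edges: np.ndarray | None = None,
    curvature_edges: np.ndarray | None = None,
):
    """Area-weighted joint distribution P_i(I/I*, K) of one cell.

    Each face contributes A_j/ΣA to exactly one (I/I*, K) bin; faces
    outside the bin range are assigned to the nearest edge bin rather than
    dropped.  Returns ``(P, intensity_edges, curvature_edges)`` with
    P.sum() == 1.
    """
    _check_cell(cell)
    istar = mean_density(cell)
    if istar <= 0:
        raise ValueError("zero mean density")
    rel = cell.face_intensity / istar
    k = cell.face_curvature
    if intensity_edges is None:
        intensity_edges = np.linspace(0.0, 4.0, 51)
    if curvature_edges is None:
        curvature_edges = curvature_bins([cell])
    iw = np.clip(np.digitize(rel, intensity_edges) - 1, 0, len(intensity_edges) - 2)
    kw = np.clip(np.digitize(k, curvature_edges) - 1, 0, len(curvature_edges) - 2)
    P = np.zeros((len(intensity_edges) - 1, len(curvature_edges) - 1))
    np.add.at(P, (iw, kw), cell.face_area)
    P /= cell.face_area.sum()
    return P, np.asarray(intensity_edges), np.asarray(curvature_edges)


def conditional_expectation(
    cell: CellSurface, curvature_edges: np.ndarray
):
    """E[I/I* | K] per curvature bin, with the bin availability P_i(K).

    Computed as the area-weighted mean of I/I* over the faces in each
    curvature bin — the intensity-bin-width → 0 limit of applying Bayes'
    rule to the discretised joint distribution.  Bins where the cell has
    no surface area are NaN (absent, not zero) with availability 0.
    """
    _check_cell(cell)
    istar = mean_density(cell)
    rel = cell.face_intensity / istar
    k = cell.face_curvature
    kw = np.clip(np.digitize(k, curvature_edges) - 1, 0, len(curvature_edges) - 2)
    nbins = len(curvature_edges) - 1
    area = np.zeros(nbins)
    mass = np.zeros(nbins)
    np.add.at(area, kw, cell.face_area)
    np.add.at(mass, kw, cell.face_area * rel)
    with np.errstate(invalid="ignore", divide="ignore"):
        expectation = np.where(area > 0, mass / area, np.nan)
    availability = area / cell.face_area.sum()
    return expectation, availability


@dataclass
class EnrichmentProfile:
    """Population-averaged relative concentration versus Gaussian curvature.

    ``mean`` is the unweighted mean across cells of E[I/I*|K] per bin (1 =
    uniform coverage); ``sem`` its standard error over contributing cells;
    ``p_avail`` the mean per-cell surface-area probability of the bin;
    ``mask`` is True where the bin survives the availability truncation.
    ``smoothed`` is filled by :func:`smooth_and_truncate`.
    """

    k_edges: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_cells: np.ndarray
    p_avail: np.ndarray
    mask: np.ndarray
    smoothed: np.ndarray | None = None

    @property
    def k_centers(self) -> np.ndarray:
        return 0.5 * (self.k_edges[:-1] + self.k_edges[1:])

    def plot(self, ax=None, label=None):
        """Enrichment curve with ±1 SEM band over the untruncated range."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = self.k_centers[self.mask]
        y = (self.smoothed if self.smoothed is not None else self.mean)[self.mask]
        s = self.sem[self.mask]
        ax.fill_between(x, y - s, y + s, alpha=0.3)
        ax.plot(x, y, label=label)
        ax.axhline(1.0, color="k", lw=0.5, ls=":")
        ax.set_xlabel("Gaussian curvature K (μm$^{-2}$)")
        ax.set_ylabel("relative concentration")
        return ax

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "K_center": self.k_centers,
                "mean": self.mean,
                "sem": self.sem,
                "n_cells": self.n_cells,
                "p_avail": self.p_avail,
                "truncated": (~self.mask).astype(int),
                "smoothed": self.smoothed
                if self.smoothed is not None
                else np.full_like(self.mean, np.nan),
            }
        )


def population_profile(
    cells,
    curvature_edges: np.ndarray | None = None,
    bin_width: float = DEFAULT_K_BIN_WIDTH,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> EnrichmentProfile:
    """Average per-cell conditional expectations across a population.

    A bin a cell has no area in contributes nothing from that cell, so the
    number of contributing cells varies per bin.  SEM is SD/√n over the
    contributing cells (0 for a single contributor).
    """
    cells = list(cells)
    if not cells:
        raise ValueError("need at least one cell")
    if curvature_edges is None:
        curvature_edges = curvature_bins(cells, width=bin_width)
    per_cell = []
    avail = []
    for c in cells:
        e, p = conditional_expectation(c, curvature_edges)
        per_cell.append(e)
        avail.append(p)
    E = np.vstack(per_cell)
    P = np.vstack(avail)
    present = np.isfinite(E)
    n = present.sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(np.where(present, E, np.nan), axis=0)
        sd = np.nanstd(np.where(present, E, np.nan), axis=0, ddof=1)
    sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), 0.0)
    p_avail = P.mean(axis=0)
    mask = (p_avail > p_threshold) & (n > 0)
    return EnrichmentProfile(
        k_edges=np.asarray(curvature_edges),
        mean=mean,
        sem=sem,
        n_cells=n,
        p_avail=p_avail,
        mask=mask,
    )


def smooth_and_truncate(
    profile: EnrichmentProfile, p_threshold: float = DEFAULT_P_THRESHOLD
) -> EnrichmentProfile:
    """Cubic-smoothing-spline fit of the profile, reported only where the
    pooled curvature availability exceeds ``p_threshold``.

    The spline is weighted by 1/SEM² (bins with SEM = 0 get the largest
    finite weight present) and its smoothing parameter is chosen by
    generalized cross-validation.  With fewer than 4 surviving bins the
    unsmoothed means are returned with a warning.
    """
    mask = (profile.p_avail > p_threshold) & (profile.n_cells > 0)
    x = profile.k_centers[mask]
    y = profile.mean[mask]
    smoothed = np.full_like(profile.mean, np.nan)
    if mask.sum() < 4:
        warnings.warn(
            f"only {int(mask.sum())} bins survive truncation; returning unsmoothed",
            stacklevel=2,
        )
        smoothed[mask] = y
    else:
        sem = profile.sem[mask]
        pos = sem[sem > 0]
        w = 1.0 / np.square(np.where(sem > 0, sem, pos.min() if len(pos) else 1.0))
        w = w / w.mean()
        try:
            spl = make_smoothing_spline(x, y, w=w)
            smoothed[mask] = spl(x)
        except Exception:   # degenerate spacing: fall back to the raw means
            smoothed[mask] = y
    return EnrichmentProfile(
        k_edges=profile.k_edges,
        mean=profile.mean,
        sem=profile.sem,
        n_cells=profile.n_cells,
        p_avail=profile.p_avail,
        mask=mask,
        smoothed=smoothed,
    )


@dataclass
class EnrichmentScalars:
    """Population-mean relative concentration below and above a curvature cutoff."""

    below: float
    above: float
    cutoff: float = DEFAULT_CUTOFF
    n_below: int = 0
    n_above: int = 0


def enrichment_scalars(cells, cutoff: float = DEFAULT_CUTOFF) -> EnrichmentScalars:
    """Mean of I/I* over faces below/above the curvature cutoff, per cell,
    then averaged across cells.

    A cell with no faces on one side of the cutoff contributes only to the
    other scalar.  Computed from the untruncated per-cell values.
    """
    lows, highs = [], []
    for c in cells:
        _check_cell(c)
        rel = c.face_intensity / mean_density(c)
        below = c.face_curvature < cutoff
        if below.any():
            lows.append(float(np.average(rel[below], weights=c.face_area[below])))
        if (~below).any():
            highs.append(float(np.average(rel[~below], weights=c.face_area[~below])))
    return EnrichmentScalars(
        below=float(np.mean(lows)) if lows else float("nan"),
        above=float(np.mean(highs)) if highs else float("nan"),
        cutoff=cutoff,
        n_below=len(lows),
        n_above=len(highs),
    )
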