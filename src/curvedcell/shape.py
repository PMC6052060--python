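"""Cylindrical-uniformity metrics: IDD, strain comparisons, volume binning.

The intracellular diameter deviation (IDD) is the coefficient of variation
of the diameter measured along a cell's centerline: SD(diameter profile) /
mean(diameter), with the spherical pole caps excluded.  Small IDD means a
uniform cylinder; irregular rods and round cells score progressively
higher.  Being a coefficient of variation, IDD is invariant to uniform
scaling of the cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh

from .geometry import CellSurface, CenterlineProfile, centerline_profile


@dataclass
class ShapeRecord:
    """Per-cell shape summary."""

    cell_id: str
    idd: float
    mean_diameter_um: float
    volume: float          # μm³
    surface_area: float    # μm²
    degenerate: bool = False

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class ComparisonRow:
    """A strain-pair shape comparison: ΔIDD = IDD(strain1) − IDD(strain2).

    Positive ΔIDD means strain 1 is more irregular than strain 2.
    """

    strain1: str
    strain2: str
    observed_didd: float
    predicted_didd: float | None = None
    n1: int = 0
    n2: int = 0
    delta_features: dict | None = None


def _as_mesh(cell) -> trimesh.Trimesh:
    return cell.mesh if isinstance(cell, CellSurface) else cell


def idd(cell, n_samples: int = 80, profile: CenterlineProfile | None = None) -> float:
    """Intracellular diameter deviation of one cell.

    With one (mean) diameter per centerline position, the per-position SD
    of repeated diameter measurements collapses and the estimator reduces
    to SD of the diameter profile divided by its mean.
    """
    if profile is None:
        profile = centerline_profile(_as_mesh(cell), n_samples=n_samples)
    d = profile.diameters
    if len(d) < 3:
        raise ValueError("too few diameter samples for IDD")
    return float(d.std() / d.mean())


def shape_record(cell: CellSurface, n_samples: int = 80) -> ShapeRecord:
    """Measure IDD, mean diameter, volume, and surface area of one cell."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        profile = centerline_profile(cell.mesh, n_samples=n_samples)
    return ShapeRecord(
        cell_id=cell.cell_id,
        idd=idd(cell, profile=profile),
        mean_diameter_um=float(profile.diameters.mean()),
        volume=cell.volume,
        surface_area=cell.total_area,
        degenerate=profile.degenerate,
    )


def _mean_idd(records) -> tuple[float, int]:
    vals = [r.idd for r in records]
    if not vals:
        raise ValueError("empty strain: no shape records")
    return float(np.mean(vals)), len(vals)


def delta_idd(
    strain1_records,
    strain2_records,
    strain1: str = "strain1",
    strain2: str = "strain2",
) -> ComparisonRow:
    """ΔIDD between two strains as the difference of their mean IDDs."""
    m1, n1 = _mean_idd(list(strain1_records))
    m2, n2 = _mean_idd(list(strain2_records))
    return ComparisonRow(
        strain1=strain1,
        strain2=strain2,
        observed_didd=m1 - m2,
        n1=n1,
        n2=n2,
    )


def bin_by_volume(records, edges) -> pd.DataFrame:
    """Group shape records into volume bins; emits per-bin counts and means.

    Bins are half-open [lo, hi); records outside the outermost edges fall
    into the open-ended end bins.  Empty bins are kept.
    """
    records = list(records)
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 1:
        raise ValueError("need at least one bin edge")
    df = pd.DataFrame([r.as_dict() for r in records])
    if df.empty:
        raise ValueError("no records to bin")
    idx = np.digitize(df["volume"].to_numpy(), edges)
    df["volume_bin"] = idx
    out = (
        df.groupby("volume_bin")
        .agg(
            n=("cell_id", "size"),
            mean_idd=("idd", "mean"),
            mean_volume=("volume", "mean"),
            mean_diameter=("mean_diameter_um", "mean"),
        )
        .reindex(range(len(edges) + 1))
    )
    out["n"] = out["n"].fillna(0).astype(int)
    return out
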