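"""Equi-volume cortical depth levels, depth sampling, and ROI selection.

Depth is expressed as a fraction from the pial surface: 0% = pial/CSF
border, 100% = white/grey-matter boundary.  The grey matter is divided into
``n_compartments`` of equal tissue volume, yielding ``n_compartments + 1``
depth boundaries at which statistics are sampled.  On flat geometry the
equi-volume rule reduces to equidistant spacing; on curved (annular or
spherical shell) geometry boundaries crowd towards the surface with the
larger circumference, compensating curvature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

N_COMPARTMENTS = 10
R2_THRESHOLD = 0.15
EPI_INTENSITY_THRESHOLD = 7000.0
ECC_BANDS = {"centre": (1.0, 3.0), "edge": (3.5, 4.0)}


@dataclass(frozen=True)
class Geometry:
    """Per-column cortical geometry descriptor.

    ``kind`` is 'flat', 'annular' or 'spherical'; curved kinds require outer
    (pial) and inner (white-matter) radii with r_pial > r_wm > 0.
    """

    kind: str = "flat"
    r_pial: float | None = None
    r_wm: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("flat", "annular", "spherical"):
            raise ValueError(f"unknown geometry kind {self.kind!r}")
        if self.kind != "flat":
            if self.r_pial is None or self.r_wm is None:
                raise ValueError("curved geometry requires r_pial and r_wm")
            if not (self.r_pial > self.r_wm > 0):
                raise ValueError("need r_pial > r_wm > 0")


@dataclass
class DepthLevels:
    """Equi-volume depth boundaries (fractions from the pial surface)."""

    boundaries: np.ndarray  # ascending, boundaries[0] = 0 (pial), [-1] = 1 (WM)
    geometry: Geometry

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if b[0] != 0.0 or b[-1] != 1.0:
            raise ValueError("boundaries must span [0, 1]")
        if np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        self.boundaries = b

    @property
    def n_compartments(self) -> int:
        return len(self.boundaries) - 1


def equivolume_boundaries(geometry: Geometry, n_compartments: int = N_COMPARTMENTS) -> DepthLevels:
    """Place ``n_compartments + 1`` boundaries so that every compartment holds
    equal tissue volume.

    For an annulus the j-th boundary radius is
    r_j = sqrt(r_wm² + (j/n)(r_pial² − r_wm²)); a spherical shell uses the
    cube-root analogue; flat geometry gives equidistant fractions.
    """
    if n_compartments < 1:
        raise ValueError("need at least one compartment")
    n = n_compartments
    j = np.arange(n + 1)
    if geometry.kind == "flat":
        frac = j / n
    else:
        rp, rw = geometry.r_pial, geometry.r_wm
        if geometry.kind == "annular":
            r = np.sqrt(rw**2 + (j / n) * (rp**2 - rw**2))
        else:  # spherical
            r = np.cbrt(rw**3 + (j / n) * (rp**3 - rw**3))
        # depth fraction measured from the pial surface inward
        frac = (rp - r[::-1]) / (rp - rw)
        frac[0], frac[-1] = 0.0, 1.0  # exact endpoints
    return DepthLevels(frac, geometry)


def compartment_volumes(levels: DepthLevels) -> np.ndarray:
    """Closed-form compartment volumes (per unit length/angle) for checking
    the equal-volume property."""
    g = levels.geometry
    b = levels.boundaries
    if g.kind == "flat":
        return np.diff(b)
    r = g.r_pial - b * (g.r_pial - g.r_wm)  # radius at each boundary, pial→WM
    if g.kind == "annular":
        areas = np.pi * (r[:-1] ** 2 - r[1:] ** 2)
    else:
        areas = 4.0 / 3.0 * np.pi * (r[:-1] ** 3 - r[1:] ** 3)
    return areas


def sample_across_depth(
    statistic: np.ndarray,
    voxel_depth_fractions: np.ndarray,
    depth_levels: DepthLevels,
) -> np.ndarray:
    """Interpolate a per-voxel statistic at the depth boundaries.

    ``statistic`` is (n_columns, n_voxel_depths); ``voxel_depth_fractions``
    gives each voxel layer's depth fraction (ascending, 0 = pial).  Linear
    interpolation along depth per column (the lattice analogue of the
    trilinear sampling used on real volumes); returns
    (n_columns, n_boundaries).
    """
    stat = np.atleast_2d(np.asarray(statistic, dtype=float))
    zf = np.asarray(voxel_depth_fractions, dtype=float)
    if stat.shape[1] != len(zf):
        raise ValueError("statistic depth axis does not match voxel depths")
    if np.any(np.diff(zf) <= 0):
        raise ValueError("voxel depth fractions must be strictly increasing")
    out = np.empty((stat.shape[0], len(depth_levels.boundaries)))
    for i in range(stat.shape[0]):
        out[i] = np.interp(depth_levels.boundaries, zf, stat[i])
    return out


def profiles_to_frame(
    profiles: np.ndarray,
    depth_levels: DepthLevels,
    column_ids: Iterable | None = None,
    **labels,
) -> pd.DataFrame:
    """Long-format table (column, depth_fraction, value [, labels])."""
    profiles = np.atleast_2d(profiles)
    if column_ids is None:
        column_ids = np.arange(profiles.shape[0])
    rows = []
    for cid, prof in zip(column_ids, profiles):
        for f, v in zip(depth_levels.boundaries, prof):
            rows.append({"column": cid, "depth_fraction": f, "value": v, **labels})
    return pd.DataFrame(rows)


@dataclass
class ROISelection:
    """Outcome of the quantitative ROI criteria (all-or-none per column)."""

    included: list
    band: str
    criteria: dict

    def __contains__(self, column) -> bool:
        return column in self.included


def select_roi(
    table: pd.DataFrame,
    band: str,
    r2_threshold: float = R2_THRESHOLD,
    intensity_threshold: float = EPI_INTENSITY_THRESHOLD,
    ecc_bands: dict = ECC_BANDS,
    areas: Iterable[str] | None = None,
) -> ROISelection:
    """Apply the quantitative ROI criteria to a per-column, per-depth table.

    ``table`` needs columns: column, depth_fraction, r_squared,
    epi_intensity, eccentricity (and optionally area).  A column is included
    iff its median-over-depth R² exceeds ``r2_threshold``, its minimum
    mean-EPI intensity over depth is ≥ ``intensity_threshold``, and its
    median eccentricity falls inside the requested band; the decision applies
    to the entire cortical segment (all depths) at once.
    """
    if band not in ecc_bands:
        raise ValueError(f"unknown band {band!r}; expected one of {sorted(ecc_bands)}")
    needed = {"column", "r_squared", "epi_intensity", "eccentricity"}
    missing = needed - set(table.columns)
    if missing:
        raise ValueError(f"table is missing columns: {sorted(missing)}")
    df = table
    if areas is not None and "area" in df.columns:
        df = df[df["area"].isin(list(areas))]

    lo, hi = ecc_bands[band]
    agg = df.groupby("column").agg(
        med_r2=("r_squared", "median"),
        min_intensity=("epi_intensity", "min"),
        med_ecc=("eccentricity", "median"),
    )
    keep = (
        (agg["med_r2"] > r2_threshold)
        & (agg["min_intensity"] >= intensity_threshold)
        & (agg["med_ecc"] >= lo)
        & (agg["med_ecc"] <= hi)
    )
    return ROISelection(
        included=list(agg.index[keep]),
        band=band,
        criteria={
            "r2_threshold": r2_threshold,
            "intensity_threshold": intensity_threshold,
            "ecc_band": (lo, hi),
        },
    )
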