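"""Back-projection of unit statistics into the visual field.

Each unit k contributes its statistic p_k weighted by its Gaussian pRF
evaluated at every visual-field pixel; the map is normalised by the pRF
density (the plain sum of the Gaussians), so the value at pixel (i, j) is

    V_ij = Σ_k M_ijk · p_k / Σ_k M_ijk ,

a pRF-weighted mean of the unit statistics.  No smoothing is applied.
Pixels where the density falls below a floor (by default 1% of its peak)
are masked as unsupported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .grid import VisualFieldGrid

DEFAULT_DENSITY_FLOOR = 0.01  # fraction of the peak pRF density


@dataclass
class VisualFieldProjection:
    """pRF-density-normalised statistic map over the visual field."""

    values: np.ndarray  # (n_px, n_px) V_ij; NaN outside the mask
    density: np.ndarray  # (n_px, n_px) Σ_k M_ijk
    mask: np.ndarray  # bool, True where the density supports the estimate
    grid: VisualFieldGrid
    density_floor: float

    def __post_init__(self) -> None:
        if self.values.shape != self.density.shape or self.values.shape != self.mask.shape:
            raise ValueError("values, density and mask must share one shape")
        if np.any(self.density < 0):
            raise ValueError("pRF density cannot be negative")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("masked-in values must be finite")


def _as_model_arrays(prf_models) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(prf_models, pd.DataFrame):
        x0 = prf_models["x0"].to_numpy(dtype=float)
        y0 = prf_models["y0"].to_numpy(dtype=float)
        sg = prf_models["sigma"].to_numpy(dtype=float)
    else:
        arr = np.asarray(prf_models, dtype=float)
        x0, y0, sg = arr[:, 0], arr[:, 1], arr[:, 2]
    if np.any(~np.isfinite(sg)) or np.any(sg <= 0):
        raise ValueError("all pRF widths must be finite and positive")
    return x0, y0, sg


def project_to_visual_field(
    prf_models,
    psc_values: np.ndarray,
    grid: VisualFieldGrid,
    density_floor: float = DEFAULT_DENSITY_FLOOR,
) -> VisualFieldProjection:
    """Project per-unit statistics into visual space.

    ``prf_models`` is a DataFrame with x0/y0/sigma columns (or an (n, 3)
    array); ``psc_values`` holds one statistic per unit.  ``density_floor``
    is relative to the peak density.
    """
    x0, y0, sg = _as_model_arrays(prf_models)
    p = np.asarray(psc_values, dtype=float)
    if len(p) != len(x0):
        raise ValueError("need exactly one statistic per pRF model")
    if len(p) == 0:
        raise ValueError("cannot project an empty model set")

    x, y = grid.mesh()
    num = np.zeros_like(x)
    den = np.zeros_like(x)
    chunk = 512
    for i0 in range(0, len(p), chunk):
        sl = slice(i0, i0 + chunk)
        m = np.exp(
            -(
                (x[None, :, :] - x0[sl, None, None]) ** 2
                + (y[None, :, :] - y0[sl, None, None]) ** 2
            )
            / (2.0 * sg[sl, None, None] ** 2)
        )
        num += np.tensordot(p[sl], m, axes=1)
        den += m.sum(axis=0)

    mask = den >= density_floor * den.max()
    values = np.full_like(den, np.nan)
    values[mask] = num[mask] / den[mask]
    return VisualFieldProjection(values, den, mask, grid, density_floor)


def pool_projections(
    per_subject_models: Sequence,
    per_subject_psc: Sequence[np.ndarray],
    grid: VisualFieldGrid,
    density_floor: float = DEFAULT_DENSITY_FLOOR,
) -> VisualFieldProjection:
    """Group-level projection by concatenating all subjects' pRF models and
    statistics before normalisation (not an average of per-subject maps)."""
    if len(per_subject_models) != len(per_subject_psc):
        raise ValueError("need one statistic vector per subject model set")
    frames = []
    for m in per_subject_models:
        x0, y0, sg = _as_model_arrays(m)
        frames.append(pd.DataFrame({"x0": x0, "y0": y0, "sigma": sg}))
    pooled_models = pd.concat(frames, ignore_index=True)
    pooled_psc = np.concatenate([np.asarray(p, dtype=float) for p in per_subject_psc])
    return project_to_visual_field(pooled_models, pooled_psc, grid, density_floor)
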