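"""Population receptive field (pRF) estimation.

Each unit's visual-field sensitivity is a 2D isotropic Gaussian with centre
(x0, y0) and width σ (degrees).  The forward model integrates the stimulus
aperture against the Gaussian per volume and convolves with the HRF; fitting
is an exhaustive grid search over (x0, y0, σ) with the amplitude solved by
least squares per candidate, selecting the candidate with maximal R².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .glm import HRFSpec, double_gamma_hrf
from .grid import VisualFieldGrid
from .stimulus import ApertureMovie

R2_THRESHOLD = 0.15  # downstream ROI inclusion: median-over-depth R² must exceed this


@dataclass(frozen=True)
class PRFModel:
    """Fitted 2D Gaussian pRF of a single unit."""

    x0: float
    y0: float
    sigma: float
    amplitude: float
    r_squared: float  # NaN flags a degenerate (zero-variance) fit

    def __post_init__(self) -> None:
        if not np.isnan(self.sigma) and self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def eccentricity(self) -> float:
        return float(np.hypot(self.x0, self.y0))

    @property
    def polar_angle_deg(self) -> float:
        return float(np.degrees(np.arctan2(self.y0, self.x0)))

    @property
    def valid(self) -> bool:
        return bool(np.isfinite(self.r_squared))


@dataclass
class PRFGridSpec:
    """Candidate parameter grids for the exhaustive search."""

    x_candidates: np.ndarray
    y_candidates: np.ndarray
    sigma_candidates: np.ndarray
    hrf_spec: HRFSpec = HRFSpec()

    def __post_init__(self) -> None:
        self.x_candidates = np.atleast_1d(np.asarray(self.x_candidates, dtype=float))
        self.y_candidates = np.atleast_1d(np.asarray(self.y_candidates, dtype=float))
        self.sigma_candidates = np.atleast_1d(np.asarray(self.sigma_candidates, dtype=float))
        if self.x_candidates.size == 0 or self.y_candidates.size == 0:
            raise ValueError("candidate grids must be non-empty")
        if np.any(self.sigma_candidates <= 0):
            raise ValueError("sigma candidates must be positive")

    @classmethod
    def from_extent(
        cls,
        extent_deg: float,
        n_xy: int = 11,
        sigmas: tuple[float, float, int] = (0.2, 2.0, 5),
        hrf_spec: HRFSpec = HRFSpec(),
    ) -> "PRFGridSpec":
        """Default grid: x/y spanning the stimulus extent, σ log-spaced."""
        half = extent_deg / 2.0
        xy = np.linspace(-half, half, n_xy)
        sg = np.geomspace(sigmas[0], sigmas[1], sigmas[2])
        return cls(xy, xy, sg, hrf_spec)

    def candidates(self) -> np.ndarray:
        """(n_candidates, 3) array of (x0, y0, sigma), σ varying fastest."""
        xs, ys, ss = np.meshgrid(
            self.x_candidates, self.y_candidates, self.sigma_candidates, indexing="ij"
        )
        return np.column_stack([xs.ravel(), ys.ravel(), ss.ravel()])


def gaussian_field(x0: float, y0: float, sigma: float, grid: VisualFieldGrid) -> np.ndarray:
    """Sample the unit's Gaussian sensitivity profile on the pixel grid."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x, y = grid.mesh()
    return np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / (2.0 * sigma**2))


def bin_movie_to_volumes(
    movie: ApertureMovie, tr: float, n_volumes: int | None = None
) -> np.ndarray:
    """Average aperture frames within each TR bin → (n_volumes, n, n)."""
    frames_per_vol = movie.frame_rate * tr
    if n_volumes is None:
        n_volumes = int(round(movie.n_frames / frames_per_vol))
    out = np.empty((n_volumes, movie.frames.shape[1], movie.frames.shape[2]))
    for v in range(n_volumes):
        i0 = int(round(v * frames_per_vol))
        i1 = max(int(round((v + 1) * frames_per_vol)), i0 + 1)
        out[v] = movie.frames[i0:min(i1, movie.n_frames)].mean(axis=0)
    return out


def prf_predicted_timecourse(
    prf: PRFModel | tuple[float, float, float],
    apertures: np.ndarray,
    grid: VisualFieldGrid,
    hrf: np.ndarray,
) -> np.ndarray:
    """Predicted response: per-volume aperture–Gaussian overlap, convolved
    with the HRF (sampled at TR).  Amplitude is left free (unit scale)."""
    if isinstance(prf, PRFModel):
        x0, y0, sigma = prf.x0, prf.y0, prf.sigma
    else:
        x0, y0, sigma = prf
    g = gaussian_field(x0, y0, sigma, grid)
    overlap = np.tensordot(apertures, g, axes=([1, 2], [0, 1]))
    return np.convolve(overlap, hrf)[: len(overlap)]


def _predictions_for_grid(
    grid_spec: PRFGridSpec, apertures: np.ndarray, grid: VisualFieldGrid, tr: float
) -> np.ndarray:
    """(n_candidates, n_volumes) HRF-convolved predictions for all candidates."""
    cands = grid_spec.candidates()
    n_vol = apertures.shape[0]
    flat_ap = apertures.reshape(n_vol, -1)  # (T, P)
    x, y = grid.mesh()
    xf, yf = x.ravel(), y.ravel()
    hrf = double_gamma_hrf(tr, grid_spec.hrf_spec)

    preds = np.empty((len(cands), n_vol))
    chunk = 256
    for i0 in range(0, len(cands), chunk):
        c = cands[i0 : i0 + chunk]
        g = np.exp(
            -(
                (xf[None, :] - c[:, 0:1]) ** 2 + (yf[None, :] - c[:, 1:2]) ** 2
            )
            / (2.0 * c[:, 2:3] ** 2)
        )  # (chunk, P)
        preds[i0 : i0 + chunk] = g @ flat_ap.T
    conv = signal.fftconvolve(preds, hrf[None, :], axes=1)[:, :n_vol]
    return conv


def fit_prf_grid(
    timecourses: np.ndarray,
    apertures: np.ndarray,
    grid: VisualFieldGrid,
    grid_spec: PRFGridSpec,
    tr: float,
) -> list[PRFModel]:
    """Exhaustive grid search; amplitude by least squares per candidate.

    ``timecourses`` is (n_volumes,) or (n_volumes × units).  Ties in R² are
    broken towards the smallest σ, then the smallest eccentricity.  Units
    with zero temporal variance are flagged (R² = NaN).
    """
    y = np.asarray(timecourses, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if y.shape[0] != apertures.shape[0]:
        raise ValueError("time course length does not match the aperture volumes")

    preds = _predictions_for_grid(grid_spec, apertures, grid, tr)
    cands = grid_spec.candidates()
    # centre both sides: amplitude + implicit intercept regression
    pc = preds - preds.mean(axis=1, keepdims=True)
    pvar = (pc**2).sum(axis=1)
    pvar_safe = np.where(pvar > 0, pvar, np.inf)

    yc = y - y.mean(axis=0, keepdims=True)
    yvar = (yc**2).sum(axis=0)

    cov = pc @ yc  # (n_candidates, units)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = cov**2 / (pvar_safe[:, None] * yvar[None, :])
    amp = cov / pvar_safe[:, None]

    ecc = np.hypot(cands[:, 0], cands[:, 1])
    models: list[PRFModel] = []
    for u in range(y.shape[1]):
        if yvar[u] <= 0:
            models.append(PRFModel(np.nan, np.nan, np.nan, np.nan, np.nan))
            continue
        r2u = r2[:, u]
        best = np.nanmax(r2u)
        tied = np.flatnonzero(r2u >= best - 1e-12)
        # smallest sigma, then smallest eccentricity
        order = np.lexsort((ecc[tied], cands[tied, 2]))
        k = tied[order[0]]
        models.append(
            PRFModel(
                x0=float(cands[k, 0]),
                y0=float(cands[k, 1]),
                sigma=float(cands[k, 2]),
                amplitude=float(amp[k, u]),
                r_squared=float(r2u[k]),
            )
        )
    return models


def models_to_frame(models: list[PRFModel]) -> pd.DataFrame:
    """Tabulate fitted pRFs (one row per unit)."""
    return pd.DataFrame(
        {
            "x0": [m.x0 for m in models],
            "y0": [m.y0 for m in models],
            "sigma": [m.sigma for m in models],
            "amplitude": [m.amplitude for m in models],
            "r_squared": [m.r_squared for m in models],
        }
    )


def derive_retinotopy(prf_map: pd.DataFrame) -> pd.DataFrame:
    """Add eccentricity (deg) and polar angle (deg, CCW from +x) columns.

    Undefined fits (NaN parameters) propagate as missing values.
    """
    out = prf_map.copy()
    out["eccentricity"] = np.hypot(out["x0"], out["y0"])
    out["polar_angle_deg"] = np.degrees(np.arctan2(out["y0"], out["x0"]))
    return out
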