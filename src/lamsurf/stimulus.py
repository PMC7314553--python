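"""Stimulus construction for the surface-motion experiment.

The main experiment contrasts three conditions that are pixel-identical in the
left visual hemifield: a 'Pac-Man' disk whose removed sector ('mouth') rocks
sinusoidally about the right horizontal meridian (motion induction), the same
figure frozen (static control), and a pair of wedges of which only the right
one rotates (dynamic control).  This module renders binary aperture movies for
those conditions and for the bar stimuli of the pRF-mapping run, generates
block-design run schedules, decorrelates fixation-target events from the
stimulus predictor, synthesises the random texture background, and evaluates
the display's pixel-to-luminance calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import VisualFieldGrid

# Geometry of the main experiment (degrees of visual angle unless noted).
STIMULUS_DIAMETER_DEG = 7.5
MOUTH_ARC_DEG = 70.0
ROTATING_WEDGE_ARC_DEG = 65.0
STATIONARY_WEDGE_ARC_DEG = 220.0
ROTATION_AMPLITUDE_DEG = 35.0
ROTATION_FREQ_HZ = 0.85

# Main-experiment block design (seconds).
TR_S = 2.079
BLOCK_DURATION_S = 10.4
REST_DURATIONS_S = (18.7, 20.8, 22.9)
INITIAL_REST_S = 20.8
N_BLOCKS = 16

# Fixation-target events.
TARGET_DURATION_S = 0.8
TARGET_MEAN_ITI_S = 30.0
TARGET_ITI_RANGE_S = 10.0
TARGET_GUARD_S = 15.0
TARGET_R_MAX = 0.001

# Display calibration: cubic map from PsychoPy pixel units in [-1, 1] to
# luminance in cd/m^2, fitted to photometer measurements of the projector.
CALIBRATION_COEFFS = (-78.8, 78.7, 317.2, 163.3)


@dataclass
class ApertureMovie:
    """Binary stimulus occupancy on a visual-field pixel grid.

    ``frames[t, iy, ix]`` is 1 where the stimulus covers the pixel centre at
    frame ``t``.  The grid is square and centred on fixation.
    """

    frames: np.ndarray  # (n_frames, n_px, n_px), values in [0, 1]
    grid: VisualFieldGrid
    frame_rate: float  # frames / s

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame rate must be positive")
        f = np.asarray(self.frames, dtype=float)
        if f.ndim != 3 or f.shape[1] != f.shape[2]:
            raise ValueError("frames must be (n_frames, n, n) with a square grid")
        if f.shape[1] != self.grid.n_pixels:
            raise ValueError("frame size does not match the grid")
        if f.min() < 0 or f.max() > 1:
            raise ValueError("aperture values must lie in [0, 1]")
        self.frames = f

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def deg_per_pixel(self) -> float:
        return self.grid.deg_per_pixel

    @property
    def centre(self) -> tuple[int, int]:
        return self.grid.centre_px

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    def occupied_fraction(self, frame: int = 0) -> float:
        """Fraction of the full disk-circumscribing grid covered at a frame."""
        return float(self.frames[frame].mean())

    def save_npz(self, path) -> None:
        np.savez_compressed(
            path,
            frames=self.frames.astype(np.uint8),
            extent_deg=self.grid.extent_deg,
            deg_per_pixel=self.grid.deg_per_pixel,
            frame_rate=self.frame_rate,
        )

    @classmethod
    def load_npz(cls, path) -> "ApertureMovie":
        with np.load(path) as z:
            grid = VisualFieldGrid(float(z["extent_deg"]), float(z["deg_per_pixel"]))
            return cls(z["frames"].astype(float), grid, float(z["frame_rate"]))


def _wrap_angle_deg(a: np.ndarray) -> np.ndarray:
    """Wrap angles to (-180, 180]."""
    return (np.asarray(a) + 180.0) % 360.0 - 180.0


def _polar(grid: VisualFieldGrid) -> tuple[np.ndarray, np.ndarray]:
    x, y = grid.mesh()
    r = np.hypot(x, y)
    ang = np.degrees(np.arctan2(y, x))
    return r, ang


def mouth_angle(t: np.ndarray | float, amplitude_deg: float, freq_hz: float) -> np.ndarray:
    """Sinusoidal angular position of the mouth/wedge centre at time t (s)."""
    return amplitude_deg * np.sin(2.0 * np.pi * freq_hz * np.asarray(t, dtype=float))


def _check_movie_geometry(diameter_deg: float, grid: VisualFieldGrid, frame_rate: float) -> None:
    if diameter_deg <= 0:
        raise ValueError("diameter must be positive")
    if frame_rate <= 0:
        raise ValueError("frame rate must be positive")
    if grid.extent_deg < diameter_deg:
        raise ValueError(
            f"grid extent {grid.extent_deg}° does not cover the stimulus "
            f"(diameter {diameter_deg}°)"
        )


def render_pacman_movie(
    diameter_deg: float = STIMULUS_DIAMETER_DEG,
    mouth_arc_deg: float = MOUTH_ARC_DEG,
    rot_amplitude_deg: float = ROTATION_AMPLITUDE_DEG,
    rot_freq_hz: float = ROTATION_FREQ_HZ,
    duration_s: float = BLOCK_DURATION_S,
    grid: VisualFieldGrid | None = None,
    frame_rate: float = 30.0,
    static: bool = False,
) -> ApertureMovie:
    """Render the Pac-Man aperture movie.

    Frame ``t`` is a disk of ``diameter_deg`` minus a sector of
    ``mouth_arc_deg`` whose centre angle follows θ(t) = A·sin(2πft) about the
    right horizontal meridian.  ``static=True`` freezes θ at 0 (static
    control).  A pixel is occupied when its centre lies inside the shape.
    """
    if grid is None:
        grid = VisualFieldGrid(extent_deg=diameter_deg + 0.5, deg_per_pixel=0.05)
    _check_movie_geometry(diameter_deg, grid, frame_rate)
    if not 0 <= mouth_arc_deg < 360:
        raise ValueError("mouth arc must lie in [0, 360)")

    n_frames = int(round(duration_s * frame_rate))
    t = np.arange(n_frames) / frame_rate
    theta = np.zeros(n_frames) if static else mouth_angle(t, rot_amplitude_deg, rot_freq_hz)

    r, ang = _polar(grid)
    disk = r <= diameter_deg / 2.0
    frames = np.empty((n_frames, grid.n_pixels, grid.n_pixels), dtype=float)
    for i, th in enumerate(theta):
        if mouth_arc_deg > 0:
            in_mouth = np.abs(_wrap_angle_deg(ang - th)) <= mouth_arc_deg / 2.0
            frames[i] = disk & ~in_mouth
        else:
            frames[i] = disk
    return ApertureMovie(frames, grid, frame_rate)


def render_dynamic_control_movie(
    stationary_arc_deg: float = STATIONARY_WEDGE_ARC_DEG,
    rotating_arc_deg: float = ROTATING_WEDGE_ARC_DEG,
    rot_amplitude_deg: float = ROTATION_AMPLITUDE_DEG,
    rot_freq_hz: float = ROTATION_FREQ_HZ,
    duration_s: float = BLOCK_DURATION_S,
    grid: VisualFieldGrid | None = None,
    frame_rate: float = 30.0,
    diameter_deg: float = STIMULUS_DIAMETER_DEG,
) -> ApertureMovie:
    """Render the dynamic-control movie: a stationary left wedge plus a
    rotating right wedge whose centre follows the Pac-Man mouth sinusoid.

    The stationary wedge is centred on the left horizontal meridian (180°);
    the configuration errors out if the wedges would overlap at any frame.
    """
    if grid is None:
        grid = VisualFieldGrid(extent_deg=diameter_deg + 0.5, deg_per_pixel=0.05)
    _check_movie_geometry(diameter_deg, grid, frame_rate)
    for arc in (stationary_arc_deg, rotating_arc_deg):
        if not 0 < arc < 360:
            raise ValueError("wedge arcs must lie in (0, 360)")
    if stationary_arc_deg + rotating_arc_deg >= 360:
        raise ValueError("combined wedge arcs must be < 360°")
    # closest approach of wedge edges over the rotation cycle
    gap = (180.0 - stationary_arc_deg / 2.0) - (abs(rot_amplitude_deg) + rotating_arc_deg / 2.0)
    if gap < 0:
        raise ValueError("rotating and stationary wedges overlap at rotation extremes")

    n_frames = int(round(duration_s * frame_rate))
    t = np.arange(n_frames) / frame_rate
    theta = mouth_angle(t, rot_amplitude_deg, rot_freq_hz)

    r, ang = _polar(grid)
    disk = r <= diameter_deg / 2.0
    stationary = disk & (np.abs(_wrap_angle_deg(ang - 180.0)) <= stationary_arc_deg / 2.0)
    frames = np.empty((n_frames, grid.n_pixels, grid.n_pixels), dtype=float)
    for i, th in enumerate(theta):
        rotating = disk & (np.abs(_wrap_angle_deg(ang - th)) <= rotating_arc_deg / 2.0)
        frames[i] = stationary | rotating
    return ApertureMovie(frames, grid, frame_rate)


def render_bar_apertures(
    bar_width_deg: float = 1.25,
    n_orientations: int = 4,
    n_positions: int = 8,
    grid: VisualFieldGrid | None = None,
) -> tuple[ApertureMovie, pd.DataFrame]:
    """Render the pRF-mapping bar apertures, one frame per configuration.

    Bars at ``n_orientations`` orientations (evenly spaced over 180°) step
    through ``n_positions`` offsets perpendicular to their orientation,
    spanning the mapped field.  Returns the movie (frame order = the
    configuration index) and a table with the orientation and offset of each
    configuration.
    """
    if grid is None:
        grid = VisualFieldGrid(extent_deg=8.0, deg_per_pixel=0.1)
    if n_orientations < 1 or n_positions < 1:
        raise ValueError("need at least one orientation and one position")
    if bar_width_deg <= 0 or bar_width_deg > grid.extent_deg:
        raise ValueError("bar width must be positive and within the field extent")

    x, y = grid.mesh()
    half_span = (grid.extent_deg - bar_width_deg) / 2.0
    if n_positions == 1:
        offsets = np.array([0.0])
    else:
        offsets = np.linspace(-half_span, half_span, n_positions)
    orientations = np.arange(n_orientations) * (180.0 / n_orientations)

    frames = []
    rows = []
    for ori in orientations:
        # signed distance of each pixel from the bar axis (perpendicular offset)
        normal = np.radians(ori + 90.0)
        proj = x * np.cos(normal) + y * np.sin(normal)
        for off in offsets:
            frames.append((np.abs(proj - off) <= bar_width_deg / 2.0).astype(float))
            rows.append({"orientation_deg": ori, "offset_deg": off})
    movie = ApertureMovie(np.stack(frames), grid, frame_rate=1.0)
    index = pd.DataFrame(rows)
    index.index.name = "config"
    return movie, index


# ---------------------------------------------------------------------------
# Run schedules
# ---------------------------------------------------------------------------

def _duration_to_trs(duration_s: float, tr_s: float, tol_frac: float = 0.05) -> int:
    """Snap a duration to an integer TR count; error beyond ``tol_frac`` TRs."""
    n = duration_s / tr_s
    k = int(round(n))
    if k < 1 or abs(n - k) > tol_frac:
        raise ValueError(
            f"duration {duration_s} s is not an integer multiple of TR {tr_s} s"
        )
    return k


@dataclass
class RunSchedule:
    """Block-design schedule of one functional run, aligned to the TR grid."""

    conditions: list[str]
    onsets_s: np.ndarray  # block onsets, seconds
    durations_s: np.ndarray  # block durations, seconds
    tr_s: float
    n_volumes: int
    initial_rest_s: float

    def __post_init__(self) -> None:
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        self.durations_s = np.asarray(self.durations_s, dtype=float)
        if len(self.conditions) != len(self.onsets_s) or len(self.onsets_s) != len(
            self.durations_s
        ):
            raise ValueError("conditions, onsets and durations must have equal length")
        if np.any(np.diff(self.onsets_s) <= 0):
            raise ValueError("block onsets must be strictly increasing")
        ends = self.onsets_s + self.durations_s
        if np.any(self.onsets_s[1:] < ends[:-1] - 1e-9):
            raise ValueError("blocks overlap")
        for v in np.concatenate([self.onsets_s, self.durations_s]):
            _duration_to_trs(v, self.tr_s) if v > 0 else None

    @property
    def duration_s(self) -> float:
        return self.n_volumes * self.tr_s

    @property
    def onset_volumes(self) -> np.ndarray:
        return np.rint(self.onsets_s / self.tr_s).astype(int)

    @property
    def duration_volumes(self) -> np.ndarray:
        return np.rint(self.durations_s / self.tr_s).astype(int)

    def to_events(self) -> pd.DataFrame:
        """BIDS-style events table (onset / duration / trial_type)."""
        return pd.DataFrame(
            {
                "onset": self.onsets_s,
                "duration": self.durations_s,
                "trial_type": self.conditions,
            }
        )

    @classmethod
    def from_events(
        cls, events: pd.DataFrame, tr_s: float, n_volumes: int, initial_rest_s: float
    ) -> "RunSchedule":
        return cls(
            conditions=list(events["trial_type"]),
            onsets_s=events["onset"].to_numpy(),
            durations_s=events["duration"].to_numpy(),
            tr_s=tr_s,
            n_volumes=n_volumes,
            initial_rest_s=initial_rest_s,
        )


def make_run_schedule(
    n_blocks: int = N_BLOCKS,
    block_dur_s: float = BLOCK_DURATION_S,
    rest_durations_s: tuple[float, ...] = REST_DURATIONS_S,
    initial_rest_s: float = INITIAL_REST_S,
    tr_s: float = TR_S,
    seed: int | None = 0,
    condition: str = "stimulus",
) -> RunSchedule:
    """Build one run: fixed initial rest, then blocks alternating with
    variable rests drawn counterbalanced over ``rest_durations_s``.

    Counts per rest duration are as equal as possible; any remainder goes to
    the middle duration(s), and the order is shuffled by ``seed``.  The run
    ends with a closing rest, giving ``n_blocks + 1`` rest periods in total.
    """
    if not rest_durations_s:
        raise ValueError("rest_durations_s must be non-empty")
    rng = np.random.default_rng(seed)
    block_trs = _duration_to_trs(block_dur_s, tr_s) if n_blocks else 0
    initial_trs = _duration_to_trs(initial_rest_s, tr_s)
    rest_trs = [_duration_to_trs(d, tr_s) for d in rest_durations_s]

    order = np.argsort(rest_durations_s)
    counts = np.full(len(rest_trs), n_blocks // len(rest_trs))
    remainder = n_blocks - counts.sum()
    # remainder to the middle duration(s), spreading outward if > 1
    for i in range(remainder):
        counts[order[(len(order) // 2 + i) % len(order)]] += 1
    rests = np.repeat(np.arange(len(rest_trs)), counts)
    rng.shuffle(rests)

    onsets, durations, conditions = [], [], []
    t_vol = initial_trs
    for b in range(n_blocks):
        onsets.append(t_vol * tr_s)
        durations.append(block_trs * tr_s)
        conditions.append(condition)
        t_vol += block_trs
        t_vol += rest_trs[rests[b]]
    n_volumes = t_vol
    return RunSchedule(
        conditions=conditions,
        onsets_s=np.array(onsets),
        durations_s=np.array(durations),
        tr_s=tr_s,
        n_volumes=int(n_volumes),
        initial_rest_s=initial_trs * tr_s,
    )


# ---------------------------------------------------------------------------
# Fixation-target events, decorrelated from the stimulus predictor
# ---------------------------------------------------------------------------

@dataclass
class TargetEvents:
    """Fixation-dot colour-change events of one run."""

    onsets_s: np.ndarray
    duration_s: float
    achieved_r: float
    n_iterations: int
    seed: int | None = None

    def to_events(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset": self.onsets_s,
                "duration": np.full(len(self.onsets_s), self.duration_s),
                "trial_type": ["target"] * len(self.onsets_s),
            }
        )


def _boxcar(onsets_s, durations_s, total_s, dt) -> np.ndarray:
    n = int(round(total_s / dt))
    x = np.zeros(n)
    for on, du in zip(np.atleast_1d(onsets_s), np.atleast_1d(durations_s)):
        i0 = int(round(on / dt))
        i1 = int(round((on + du) / dt))
        x[i0:min(i1, n)] = 1.0
    return x


def predictor_correlation(
    schedule: RunSchedule,
    target_onsets_s: np.ndarray,
    target_duration_s: float = TARGET_DURATION_S,
    hrf_kernel: np.ndarray | None = None,
    dt: float = 0.1,
) -> float:
    """Pearson correlation between the HRF-convolved stimulus and target
    predictors, evaluated on a fine time grid."""
    from .glm import double_gamma_hrf

    if len(np.atleast_1d(target_onsets_s)) == 0:
        return 0.0
    if hrf_kernel is None:
        hrf_kernel = double_gamma_hrf(tr=dt)
    total = schedule.duration_s
    stim = _boxcar(schedule.onsets_s, schedule.durations_s, total, dt)
    targ = _boxcar(target_onsets_s, np.full(len(target_onsets_s), target_duration_s), total, dt)
    ps = np.convolve(stim, hrf_kernel)[: len(stim)]
    pt = np.convolve(targ, hrf_kernel)[: len(targ)]
    if ps.std() == 0 or pt.std() == 0:
        return 0.0
    return float(np.corrcoef(ps, pt)[0, 1])


def _draw_target_onsets(rng, total_s, mean_iti, iti_range, guard_s, duration_s):
    onsets = []
    t = guard_s + rng.uniform(0.0, mean_iti - iti_range)
    while t + duration_s <= total_s - guard_s:
        onsets.append(t)
        t += rng.uniform(mean_iti - iti_range, mean_iti + iti_range)
    return np.array(onsets)


def decorrelate_target_events(
    schedule: RunSchedule,
    hrf_kernel: np.ndarray | None = None,
    mean_iti_s: float = TARGET_MEAN_ITI_S,
    iti_range_s: float = TARGET_ITI_RANGE_S,
    r_max: float = TARGET_R_MAX,
    max_iter: int = 100_000,
    seed: int | None = 0,
    duration_s: float = TARGET_DURATION_S,
    dt: float = 0.1,
) -> TargetEvents:
    """Rejection-sample target onsets until the HRF-convolved target predictor
    is decorrelated (|r| < ``r_max``) from the stimulus predictor.

    Onsets have a mean inter-trial interval of ``mean_iti_s`` (uniform within
    ±``iti_range_s``) and avoid the first/last 15 s of the run.  Raises after
    ``max_iter`` failed draws, reporting the best |r| achieved.
    """
    if r_max <= 0:
        raise ValueError("r_max must be positive")
    rng = np.random.default_rng(seed)
    if mean_iti_s >= schedule.duration_s - 2 * TARGET_GUARD_S:
        return TargetEvents(np.array([]), duration_s, 0.0, 0, seed)

    # precompute the fixed side of the correlation once
    from .glm import double_gamma_hrf

    if hrf_kernel is None:
        hrf_kernel = double_gamma_hrf(tr=dt)
    total = schedule.duration_s
    stim = _boxcar(schedule.onsets_s, schedule.durations_s, total, dt)
    ps = np.convolve(stim, hrf_kernel)[: len(stim)]
    ps_c = ps - ps.mean()
    ps_norm = np.linalg.norm(ps_c)

    best_r = np.inf
    for it in range(1, max_iter + 1):
        onsets = _draw_target_onsets(
            rng, schedule.duration_s, mean_iti_s, iti_range_s, TARGET_GUARD_S, duration_s
        )
        if len(onsets) == 0:
            return TargetEvents(onsets, duration_s, 0.0, it, seed)
        targ = _boxcar(onsets, np.full(len(onsets), duration_s), total, dt)
        pt = np.convolve(targ, hrf_kernel)[: len(targ)]
        pt_c = pt - pt.mean()
        denom = ps_norm * np.linalg.norm(pt_c)
        r = float(ps_c @ pt_c / denom) if denom > 0 else 0.0
        if abs(r) < abs(best_r):
            best_r = r
        if abs(r) < r_max:
            return TargetEvents(onsets, duration_s, float(r), it, seed)
    raise RuntimeError(
        f"decorrelation failed after {max_iter} iterations; best |r| = {abs(best_r):.3g}"
    )


# ---------------------------------------------------------------------------
# Background texture and display calibration
# ---------------------------------------------------------------------------

@dataclass
class TexturePattern:
    """Random-noise background texture (8-bit intensity units)."""

    image: np.ndarray
    gauss_mean: float
    gauss_sd: float
    kernel_px: int
    seed: int | None


def generate_texture(
    shape_px: tuple[int, int] = (256, 256),
    gauss_mean: float = 40.0,
    gauss_sd: float = 60.0,
    kernel_px: int = 6,
    seed: int | None = 0,
    clip_before_filter: bool = True,
) -> TexturePattern:
    """Draw i.i.d. Gaussian pixel intensities, clip to [0, 255], and smooth
    with a uniform box filter of ``kernel_px`` × ``kernel_px``.

    ``clip_before_filter=False`` filters the unclipped noise and clips the
    result instead; either order keeps intensities within the 8-bit range.
    """
    if kernel_px < 1:
        raise ValueError("kernel size must be >= 1")
    if any(s <= 0 for s in shape_px):
        raise ValueError("shape must be positive")
    rng = np.random.default_rng(seed)
    noise = rng.normal(gauss_mean, gauss_sd, size=shape_px)
    if clip_before_filter:
        noise = np.clip(noise, 0.0, 255.0)
    img = ndimage.uniform_filter(noise, size=kernel_px, mode="reflect") if kernel_px > 1 else noise
    if not clip_before_filter:
        img = np.clip(img, 0.0, 255.0)
    return TexturePattern(img, gauss_mean, gauss_sd, kernel_px, seed)


@dataclass(frozen=True)
class DisplayCalibration:
    """Cubic pixel-to-luminance map y = c3·x³ + c2·x² + c1·x + c0."""

    coeffs: tuple[float, float, float, float] = CALIBRATION_COEFFS

    def __call__(self, x) -> np.ndarray | float:
        return pixel_to_luminance(x, self.coeffs)


def pixel_to_luminance(x, coeffs: tuple[float, float, float, float] = CALIBRATION_COEFFS):
    """Evaluate the display calibration cubic (cd/m²) at pixel value ``x``
    (PsychoPy convention, range −1…1).  Out-of-range inputs are evaluated but
    flagged with a warning."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr < -1.0) or np.any(arr > 1.0):
        warnings.warn("pixel value outside the calibrated range [-1, 1]", stacklevel=2)
    out = np.polyval(coeffs, arr)
    return float(out) if np.isscalar(x) else out
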