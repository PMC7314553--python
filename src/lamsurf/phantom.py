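"""Ground-truthed synthetic laminar fMRI data.

The phantom is a 'flattened cortex': a lattice of cortical columns, each
with an area label (V1/V2/V3), a true Gaussian pRF, and a laminar neural
amplitude (percent signal change) per condition and response component
(sustained, transient).  It emulates the statistical structure of the study
data: retinotopically organised responses with a negative sustained signal
inside the surface representation (the elevated texture-background baseline
story: the uniform figure drives less activity than the texture it
replaces), a positive transient response at the stimulus edge, a small
(~0.3%) condition increment localised in depth for the motion-induction
condition, venous draining toward the pial surface, and subject-level
variability.

Every simulated voxel time course is reproducible from the truth tables and
the seed; writing and re-reading a dataset is bit-exact.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .depth import DepthLevels, Geometry, equivolume_boundaries
from .drain import LeakageModel, flip_profile, forward_drain
from .glm import HRFSpec, build_design_matrix
from .grid import VisualFieldGrid
from .prf import prf_predicted_timecourse, double_gamma_hrf
from .stimulus import RunSchedule, TargetEvents, render_bar_apertures

CONDITIONS = ("motion", "static", "dynamic")
COMPONENTS = ("sustained", "transient")

# stimulus geometry used to assign columns to surface-interior vs edge
STIMULUS_RADIUS_DEG = 3.75


@dataclass
class PhantomSpec:
    """Study conditions the phantom reproduces by default.

    Eccentricity levels are chosen to populate both ROI bands (centre 1–3°,
    edge 3.5–4.0°) plus one level outside the stimulus; polar angles span
    the left hemifield (the physically constant stimulus half, represented
    in the right hemisphere).  Laminar amplitudes are in percent signal
    change: a uniform negative sustained response inside the surface, a
    positive transient at the edge, and a depth-localised increment for the
    motion-induction condition peaking at ~25% depth in V1, ~50% in V2 and
    ~40% in V3.
    """

    areas: tuple[str, ...] = ("V1", "V2", "V3")
    ecc_levels_deg: tuple[float, ...] = (1.25, 1.75, 2.25, 2.75, 3.6, 3.75, 3.9, 4.3)
    n_angles: int = 6
    angle_range_deg: tuple[float, float] = (110.0, 250.0)
    n_compartments: int = 10  # 11 depth levels
    sustained_interior_pct: float = -2.5
    transient_edge_pct: float = 2.0
    # motion-condition sustained increment: area -> (peak depth fraction, amplitude %)
    increments: dict = field(
        default_factory=lambda: {"V1": (0.25, 0.3), "V2": (0.50, 0.3), "V3": (0.40, 0.3)}
    )
    increment_width: float = 0.10  # Gaussian bump width over depth fraction
    interior_max_ecc: float = 3.3
    edge_band: tuple[float, float] = (3.4, 4.1)
    sigma_base: dict = field(default_factory=lambda: {"V1": 0.3, "V2": 0.5, "V3": 0.7})
    sigma_per_ecc: float = 0.1  # pRF width grows with eccentricity
    epi_intensity: float = 10000.0
    intensity_jitter_sd: float = 0.1  # fractional spatial variation of mean EPI ('anatomy')
    anatomy_seed: int = 7777  # fixed: the anatomy is part of the phantom, not the noise
    conditions: tuple[str, ...] = CONDITIONS

    def __post_init__(self) -> None:
        if self.n_compartments < 1:
            raise ValueError("need at least one depth compartment")
        for area, (d0, _) in self.increments.items():
            if area not in self.areas:
                raise ValueError(f"increment names unknown area {area!r}")
            if not 0 <= d0 <= 1:
                raise ValueError("increment depth fraction must lie in [0, 1]")
        for a in self.areas:
            if a not in self.sigma_base:
                raise ValueError(f"sigma_base missing area {a!r}")


@dataclass
class AcquisitionModel:
    """Scanner/noise parameters of the simulated acquisition."""

    tr_s: float = 2.079
    noise_sd_pct: float = 0.5  # stationary white+AR(1) noise SD, % of baseline
    ar1: float = 0.3
    drift_amp_pct: float = 0.5  # slow cosine drift amplitude, % of baseline
    drift_period_s: float = 100.0
    subject_sd: float = 0.15  # SD of the multiplicative subject amplitude effect
    baseline: float = 10000.0  # mean EPI signal within the brain

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise ValueError("TR must be positive")
        if self.noise_sd_pct < 0:
            raise ValueError("noise SD must be non-negative")
        if not abs(self.ar1) < 1:
            raise ValueError("|AR(1) coefficient| must be < 1")


@dataclass
class CorticalPhantom:
    """Lattice phantom with per-column truth."""

    columns: pd.DataFrame  # column, area, x0, y0, sigma, ecc, band, epi_intensity
    truth: dict  # (condition, component) -> (n_columns, n_depths), pial-first
    depth_levels: DepthLevels
    spec: PhantomSpec
    baseline_map: np.ndarray = None  # (n_columns, n_depths) mean-EPI intensity

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    @property
    def n_depths(self) -> int:
        return len(self.depth_levels.boundaries)

    @property
    def depth_fractions(self) -> np.ndarray:
        return self.depth_levels.boundaries

    def truth_table(self) -> pd.DataFrame:
        """Long-format truth table (column, condition, component, depth, amp)."""
        rows = []
        for (cond, comp), arr in sorted(self.truth.items()):
            for c in range(arr.shape[0]):
                for d, f in enumerate(self.depth_fractions):
                    rows.append(
                        {
                            "column": c,
                            "condition": cond,
                            "component": comp,
                            "depth_fraction": f,
                            "amplitude_pct": arr[c, d],
                        }
                    )
        return pd.DataFrame(rows)

    def truth_hash(self) -> str:
        h = hashlib.sha256()
        for key in sorted(self.truth):
            h.update(str(key).encode())
            h.update(np.ascontiguousarray(self.truth[key]).tobytes())
        h.update(self.columns.to_csv(index=False).encode())
        return h.hexdigest()


def build_phantom(spec: PhantomSpec | None = None) -> CorticalPhantom:
    """Construct the lattice phantom from a spec.

    Retinotopy is a smooth polar map per area; interior columns receive the
    negative sustained amplitude, edge columns the positive transient, and
    the motion condition additionally a depth-localised sustained increment.
    """
    spec = spec or PhantomSpec()
    levels = equivolume_boundaries(Geometry("flat"), spec.n_compartments)
    depth = levels.boundaries
    n_depths = len(depth)

    rows = []
    for area in spec.areas:
        for ecc in spec.ecc_levels_deg:
            for ang in np.linspace(*spec.angle_range_deg, spec.n_angles):
                x0 = ecc * np.cos(np.radians(ang))
                y0 = ecc * np.sin(np.radians(ang))
                sigma = spec.sigma_base[area] + spec.sigma_per_ecc * ecc
                if ecc <= spec.interior_max_ecc:
                    band = "interior"
                elif spec.edge_band[0] <= ecc <= spec.edge_band[1]:
                    band = "edge"
                else:
                    band = "outside"
                rows.append(
                    {
                        "area": area,
                        "x0": x0,
                        "y0": y0,
                        "sigma": sigma,
                        "ecc": ecc,
                        "band": band,
                        "epi_intensity": spec.epi_intensity,
                    }
                )
    columns = pd.DataFrame(rows)
    columns.insert(0, "column", np.arange(len(columns)))

    interior = (columns["band"] == "interior").to_numpy()
    edge = (columns["band"] == "edge").to_numpy()
    truth: dict = {}
    for cond in spec.conditions:
        sust = np.zeros((len(columns), n_depths))
        trans = np.zeros((len(columns), n_depths))
        sust[interior, :] = spec.sustained_interior_pct
        trans[edge, :] = spec.transient_edge_pct
        if cond == "motion":
            for area, (d0, amp) in spec.increments.items():
                in_area = (columns["area"] == area).to_numpy() & interior
                bump = amp * np.exp(-((depth - d0) ** 2) / (2.0 * spec.increment_width**2))
                sust[in_area, :] += bump[None, :]
        truth[(cond, "sustained")] = sust
        truth[(cond, "transient")] = trans

    # 'anatomical' spatial structure of the mean EPI image; fixed by the phantom
    # spec's anatomy seed so every run of a phantom shares one reference image
    anat_rng = np.random.default_rng(spec.anatomy_seed)
    jitter = 1.0 + spec.intensity_jitter_sd * anat_rng.standard_normal(
        (len(columns), n_depths)
    )
    baseline_map = columns["epi_intensity"].to_numpy()[:, None] * jitter
    return CorticalPhantom(columns, truth, levels, spec, baseline_map)


# ---------------------------------------------------------------------------
# Run simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedRun:
    """One simulated functional run.

    ``data`` is (n_voxels × n_volumes) raw signal; voxel index =
    column · n_depths + depth index (pial-first within a column).
    """

    data: np.ndarray
    schedule: RunSchedule
    condition: str
    seed: int
    amplitude_scale: float
    target_events: TargetEvents | None = None

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]


def voxel_index_map(phantom: CorticalPhantom) -> pd.DataFrame:
    """Voxel ↔ (column, depth) lookup standing in for surface sampling."""
    n_d = phantom.n_depths
    idx = np.arange(phantom.n_columns * n_d)
    return pd.DataFrame(
        {
            "voxel": idx,
            "column": idx // n_d,
            "depth_index": idx % n_d,
            "depth_fraction": phantom.depth_fractions[idx % n_d],
        }
    )


def _ar1_noise(rng, shape, sd, ar1):
    """Stationary AR(1) noise with marginal SD ``sd``."""
    white = rng.normal(0.0, sd, size=shape)
    if ar1 == 0:
        return white
    out = np.empty_like(white)
    out[..., 0] = white[..., 0]
    innov_sd = np.sqrt(1.0 - ar1**2)
    for t in range(1, shape[-1]):
        out[..., t] = ar1 * out[..., t - 1] + innov_sd * white[..., t]
    return out


def simulate_run(
    phantom: CorticalPhantom,
    schedule: RunSchedule,
    leakage: LeakageModel,
    acquisition: AcquisitionModel,
    seed: int | None,
    amplitude_scale: float = 1.0,
    target_events: TargetEvents | None = None,
    hrf_spec: HRFSpec = HRFSpec(),
) -> SimulatedRun:
    """Simulate one run of the given condition.

    Per column and depth, the neural response is the truth-amplitude-scaled
    sustained boxcar plus onset/offset transients; the laminar amplitude
    vector passes through the draining forward model, is convolved with the
    double-gamma HRF (via the same regressor construction the GLM uses, so a
    noiseless run is an exact linear model), and AR(1)+white noise and a
    slow cosine drift are added on top of the mean-EPI baseline.
    """
    if seed is None:
        raise ValueError("a seed is mandatory (reproducibility)")
    if leakage.n_depths != phantom.n_depths:
        raise ValueError("leakage dimension does not match the phantom depths")
    cond = schedule.conditions[0]
    if any(c != cond for c in schedule.conditions):
        raise ValueError("a run must present a single condition")
    if (cond, "sustained") not in phantom.truth:
        raise ValueError(f"phantom has no truth for condition {cond!r}")

    rng = np.random.default_rng(seed)
    design = build_design_matrix(schedule, target_events, hrf_spec)
    x_sust = design.matrix[f"{cond}_sustained"].to_numpy()
    x_trans = design.matrix[f"{cond}_transient"].to_numpy()

    n_vox = phantom.n_columns * phantom.n_depths
    t_axis = np.arange(schedule.n_volumes) * schedule.tr_s

    pct = np.zeros((n_vox, schedule.n_volumes))
    for comp, x in (("sustained", x_sust), ("transient", x_trans)):
        amp_local = phantom.truth[(cond, comp)] * amplitude_scale  # (col, depth) pial-first
        amp_obs = flip_profile(forward_drain(flip_profile(amp_local), leakage))
        pct += amp_obs.reshape(n_vox, 1) * x[None, :]

    b = (
        phantom.baseline_map.reshape(n_vox, 1)
        if phantom.baseline_map is not None
        else np.full((n_vox, 1), acquisition.baseline)
    )
    data = b * (1.0 + pct / 100.0)
    if acquisition.drift_amp_pct > 0:
        phase = rng.uniform(0, 2 * np.pi, size=(n_vox, 1))
        drift = acquisition.drift_amp_pct / 100.0 * np.cos(
            2 * np.pi * t_axis[None, :] / acquisition.drift_period_s + phase
        )
        data += b * drift
    if acquisition.noise_sd_pct > 0:
        data += b * (acquisition.noise_sd_pct / 100.0) * _ar1_noise(
            rng, (n_vox, schedule.n_volumes), 1.0, acquisition.ar1
        )
    return SimulatedRun(data, schedule, cond, seed, amplitude_scale, target_events)


@dataclass
class SimulatedPRFRun:
    """Simulated pRF-mapping run: bar apertures binned per volume."""

    data: np.ndarray  # (n_columns, n_volumes) raw signal
    apertures: np.ndarray  # (n_volumes, n_px, n_px)
    grid: VisualFieldGrid
    config_sequence: np.ndarray  # per-volume configuration index, -1 = rest
    tr_s: float
    seed: int


def simulate_prf_run(
    phantom: CorticalPhantom,
    acquisition: AcquisitionModel,
    seed: int | None,
    n_repetitions: int = 12,
    rest_volumes: int = 16,
    response_amp_pct: float = 2.0,
    noise_sd_pct: float | None = None,
    bar_grid: VisualFieldGrid | None = None,
    hrf_spec: HRFSpec = HRFSpec(),
) -> SimulatedPRFRun:
    """Simulate a bar-mapping run from the phantom's true pRFs.

    The 32 bar configurations are each shown ``n_repetitions`` times for one
    TR in random order; ``rest_volumes`` empty volumes pad the run (half at
    the start, half at the end), reproducing the 400-volume run length at
    the default settings.  Response amplitude is ``response_amp_pct`` at the
    maximal aperture–pRF overlap per column.
    """
    if seed is None:
        raise ValueError("a seed is mandatory (reproducibility)")
    rng = np.random.default_rng(seed)
    movie, _ = render_bar_apertures(grid=bar_grid)
    n_cfg = movie.n_frames
    seq = np.repeat(np.arange(n_cfg), n_repetitions)
    rng.shuffle(seq)
    pre = rest_volumes // 2
    post = rest_volumes - pre
    config_sequence = np.concatenate(
        [np.full(pre, -1), seq, np.full(post, -1)]
    )
    n_vol = len(config_sequence)

    blank = np.zeros_like(movie.frames[0])
    apertures = np.stack(
        [movie.frames[c] if c >= 0 else blank for c in config_sequence]
    )
    hrf = double_gamma_hrf(acquisition.tr_s, hrf_spec)

    noise_sd = acquisition.noise_sd_pct if noise_sd_pct is None else noise_sd_pct
    b = acquisition.baseline
    data = np.empty((phantom.n_columns, n_vol))
    for i, row in phantom.columns.iterrows():
        ts = prf_predicted_timecourse(
            (row["x0"], row["y0"], row["sigma"]), apertures, movie.grid, hrf
        )
        peak = np.abs(ts).max()
        resp = response_amp_pct * ts / peak if peak > 0 else ts
        data[i] = b * (1.0 + resp / 100.0)
    if noise_sd > 0:
        data += b / 100.0 * _ar1_noise(
            rng, (phantom.n_columns, n_vol), noise_sd, acquisition.ar1
        )
    return SimulatedPRFRun(data, apertures, movie.grid, config_sequence, acquisition.tr_s, seed)


# ---------------------------------------------------------------------------
# Dataset container and I/O
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """A complete simulated dataset: runs plus the truth that generated them."""

    phantom: CorticalPhantom
    runs: list  # list of (subject, SimulatedRun)
    leakage: LeakageModel
    acquisition: AcquisitionModel
    seed: int
    subject_scales: dict = field(default_factory=dict)


def simulate_dataset(
    phantom: CorticalPhantom,
    leakage: LeakageModel,
    acquisition: AcquisitionModel,
    seed: int,
    n_subjects: int = 9,
    runs_per_condition: int = 2,
    conditions: tuple[str, ...] | None = None,
    schedule_kwargs: dict | None = None,
) -> SyntheticDataset:
    """Simulate a group dataset: per subject, ``runs_per_condition`` runs of
    each condition, with a multiplicative subject amplitude effect drawn
    from N(1, subject_sd)."""
    if seed is None:
        raise ValueError("a seed is mandatory (reproducibility)")
    from .stimulus import make_run_schedule

    conditions = conditions or phantom.spec.conditions
    schedule_kwargs = schedule_kwargs or {}
    rng = np.random.default_rng(seed)
    runs = []
    scales = {}
    for s in range(n_subjects):
        scale = float(max(1.0 + acquisition.subject_sd * rng.standard_normal(), 0.1))
        scales[f"sub-{s + 1:02d}"] = scale
        for cond in conditions:
            for r in range(runs_per_condition):
                run_seed = int(rng.integers(0, 2**31 - 1))
                schedule = make_run_schedule(
                    seed=run_seed, condition=cond, tr_s=acquisition.tr_s, **schedule_kwargs
                )
                run = simulate_run(
                    phantom, schedule, leakage, acquisition, run_seed, scale
                )
                runs.append((f"sub-{s + 1:02d}", run))
    return SyntheticDataset(phantom, runs, leakage, acquisition, seed, scales)


def _run_to_nifti(run: SimulatedRun, phantom: CorticalPhantom) -> nib.Nifti1Image:
    n_d = phantom.n_depths
    vol = run.data.reshape(phantom.n_columns, n_d, 1, run.n_volumes)
    return nib.Nifti1Image(vol.astype(np.float64), np.eye(4))


def write_dataset(dataset: SyntheticDataset, out_dir) -> Path:
    """Write NIfTI volumes, events tables, truth tables (TSV), the leakage
    matrix and a manifest JSON with the seed and all parameters."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    phantom = dataset.phantom

    phantom.columns.to_csv(out / "columns.tsv", sep="\t", index=False)
    phantom.truth_table().to_csv(out / "truth.tsv", sep="\t", index=False)
    voxel_index_map(phantom).to_csv(out / "voxel_map.tsv", sep="\t", index=False)
    dataset.leakage.to_tsv(out / "leakage.tsv")

    run_records = []
    counters: dict = {}
    for subject, run in dataset.runs:
        counters[subject] = counters.get(subject, 0) + 1
        stem = f"{subject}_run-{counters[subject]:02d}_{run.condition}"
        nib.save(_run_to_nifti(run, phantom), out / f"{stem}_bold.nii")
        events = run.schedule.to_events()
        if run.target_events is not None:
            events = pd.concat([events, run.target_events.to_events()], ignore_index=True)
            events = events.sort_values("onset", ignore_index=True)
        events.to_csv(out / f"{stem}_events.tsv", sep="\t", index=False)
        run_records.append(
            {
                "subject": subject,
                "condition": run.condition,
                "seed": run.seed,
                "amplitude_scale": run.amplitude_scale,
                "file": f"{stem}_bold.nii",
                "events": f"{stem}_events.tsv",
                "n_volumes": run.n_volumes,
                "tr_s": run.schedule.tr_s,
                "initial_rest_s": run.schedule.initial_rest_s,
            }
        )

    manifest = {
        "seed": dataset.seed,
        "truth_hash": phantom.truth_hash(),
        "acquisition": asdict(dataset.acquisition),
        "subject_scales": dataset.subject_scales,
        "runs": run_records,
        "n_columns": phantom.n_columns,
        "n_depths": phantom.n_depths,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def read_run(path) -> np.ndarray:
    """Read a run written by :func:`write_dataset` back to (voxels × time)."""
    vol = np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
    nx, ny, nz, nt = vol.shape
    return vol.reshape(nx * ny * nz, nt)
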