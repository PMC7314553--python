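"""End-to-end orchestration: simulate → pRF → GLM → ROI → depth profiles →
deconvolve → project → stats, with QC gates, a manifest, and figures.

The pipeline runs entirely on the synthetic phantom; every stage uses the
public module functions, so the orchestration here is plumbing plus
bookkeeping (seeds, exclusions, output files).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import depth as depth_mod
from . import glm as glm_mod
from . import qc as qc_mod
from . import stats as stats_mod
from .drain import LeakageModel, deconvolve_drain, flip_profile
from .grid import VisualFieldGrid
from .phantom import (
    AcquisitionModel,
    CorticalPhantom,
    PhantomSpec,
    build_phantom,
    simulate_prf_run,
    simulate_run,
    voxel_index_map,
)
from .prf import PRFGridSpec, fit_prf_grid, models_to_frame
from .projection import pool_projections
from .stimulus import decorrelate_target_events, make_run_schedule


@dataclass
class PipelineConfig:
    """All stage parameters, seeds and QC thresholds of one pipeline run."""

    seed: int = 0
    n_subjects: int = 10
    runs_per_condition: int = 1
    conditions: tuple[str, ...] = ("motion", "static", "dynamic")
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    acquisition: AcquisitionModel = field(default_factory=AcquisitionModel)
    leak_fraction: float = 0.3
    include_targets: bool = True
    target_r_max: float = 0.001
    hit_probability: float = 0.98
    qc_spatial_r: float = qc_mod.SPATIAL_R_THRESHOLD
    qc_hit_rate: float = qc_mod.HIT_RATE_THRESHOLD
    fit_prf: bool = True
    prf_noise_sd_pct: float = 0.2
    prf_grid_n_xy: int = 9
    prf_grid_sigmas: tuple[float, float, int] = (0.3, 1.2, 4)
    projection_deg_per_px: float = 0.25
    make_figures: bool = False
    era_window_s: float = 27.0

    def to_yaml(self, path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "phantom" in d and isinstance(d["phantom"], dict):
            ph = d["phantom"]
            for key in ("areas", "ecc_levels_deg", "angle_range_deg", "conditions", "edge_band"):
                if key in ph and isinstance(ph[key], list):
                    ph[key] = tuple(ph[key])
            if "increments" in ph:
                ph["increments"] = {k: tuple(v) for k, v in ph["increments"].items()}
            d["phantom"] = PhantomSpec(**ph)
        if "acquisition" in d and isinstance(d["acquisition"], dict):
            d["acquisition"] = AcquisitionModel(**d["acquisition"])
        for key in ("conditions", "prf_grid_sigmas"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PipelineResult:
    """Report bundle of one pipeline run."""

    config: PipelineConfig
    profiles: pd.DataFrame  # subject, area, band, condition, depth_fraction, psc (deconvolved)
    contrasts: dict  # area -> contrast DataFrame (motion - dynamic, centre band)
    peak_calls: dict  # area -> list of per-subject PeakCall
    chisq: tuple | None
    lrt: object | None
    onsets: dict  # (area, band) -> onset volume index or None
    qc_report: pd.DataFrame
    prf_fits: pd.DataFrame | None
    projections: dict  # condition -> VisualFieldProjection
    manifest: dict


def _sha256_of_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()


def _simulate_behaviour(rng, targets, hit_probability, rt_s=0.6):
    hits = rng.random(len(targets.onsets_s)) < hit_probability
    return targets.onsets_s[hits] + rt_s


def run_pipeline(config: PipelineConfig, out_dir=None) -> PipelineResult:
    """Execute the full analysis chain on a freshly simulated dataset."""
    rng = np.random.default_rng(config.seed)
    phantom = build_phantom(config.phantom)
    leakage = LeakageModel.uniform(phantom.n_depths, config.leak_fraction)
    acq = config.acquisition
    vmap = voxel_index_map(phantom)
    n_depths = phantom.n_depths
    depth_fr = phantom.depth_fractions

    # ---- simulate + QC + GLM, subject by subject -------------------------
    qc_rows = []
    psc_records = []  # (subject, condition, component, (n_col, n_depth) PSC)
    era_store: dict = {}
    subject_prf = {}
    subjects = [f"sub-{i + 1:02d}" for i in range(config.n_subjects)]
    for subject in subjects:
        scale = float(max(1.0 + acq.subject_sd * rng.standard_normal(), 0.1))
        sub_psc: dict = {}
        for cond in config.conditions:
            for rep in range(config.runs_per_condition):
                run_seed = int(rng.integers(0, 2**31 - 1))
                schedule = make_run_schedule(seed=run_seed, condition=cond, tr_s=acq.tr_s)
                targets = None
                if config.include_targets:
                    targets = decorrelate_target_events(
                        schedule, r_max=config.target_r_max, seed=run_seed
                    )
                run = simulate_run(phantom, schedule, leakage, acq, run_seed, scale, targets)

                # QC gates
                vols = run.data.T  # (T, voxels)
                ref = vols.mean(axis=0)
                sc = qc_mod.qc_spatial_correlation(vols, ref, config.qc_spatial_r)
                hr = qc_mod.QCResult(True, 1.0, config.qc_hit_rate)
                if targets is not None and len(targets.onsets_s):
                    responses = _simulate_behaviour(rng, targets, config.hit_probability)
                    hr = qc_mod.qc_hit_rate(
                        targets.onsets_s, responses, threshold=config.qc_hit_rate
                    )
                excluded = not (sc.passed and hr.passed)
                qc_rows.append(
                    {
                        "subject": subject,
                        "condition": cond,
                        "run": rep + 1,
                        "spatial_r": sc.value,
                        "hit_rate": hr.value,
                        "excluded": excluded,
                        "reason": sc.reason or hr.reason,
                    }
                )
                if excluded:
                    continue

                design = glm_mod.build_design_matrix(schedule, targets)
                fit = glm_mod.fit_glm(run.data.T, design)
                psc = fit.psc()
                for comp in ("sustained", "transient"):
                    col = f"{cond}_{comp}"
                    arr = psc[col].to_numpy().reshape(phantom.n_columns, n_depths)
                    sub_psc.setdefault((cond, comp), []).append(arr)

                # event-related averages of ROI-mean raw signal (V1 bands)
                for band in ("interior", "edge"):
                    sel = (
                        (phantom.columns["area"] == "V1")
                        & (phantom.columns["band"] == band)
                    ).to_numpy()
                    vox = np.flatnonzero(np.repeat(sel, n_depths))
                    if len(vox) == 0:
                        continue
                    roi_ts = run.data[vox].mean(axis=0)
                    era = glm_mod.event_related_average(
                        roi_ts, schedule, config.era_window_s
                    )
                    era_store.setdefault((subject, band), []).append(era.mean)

        for key, arrays in sub_psc.items():
            psc_records.append((subject, *key, np.mean(arrays, axis=0)))

        # pRF mapping run + fit
        if config.fit_prf:
            prf_seed = int(rng.integers(0, 2**31 - 1))
            prf_run = simulate_prf_run(
                phantom, acq, prf_seed, noise_sd_pct=config.prf_noise_sd_pct
            )
            grid_spec = PRFGridSpec.from_extent(
                prf_run.grid.extent_deg,
                n_xy=config.prf_grid_n_xy,
                sigmas=config.prf_grid_sigmas,
            )
            models = fit_prf_grid(
                prf_run.data.T, prf_run.apertures, prf_run.grid, grid_spec, acq.tr_s
            )
            fits = models_to_frame(models)
        else:  # fall back to the phantom's true pRFs
            fits = phantom.columns[["x0", "y0", "sigma"]].copy()
            fits["amplitude"] = 1.0
            fits["r_squared"] = 1.0
        fits.insert(0, "column", np.arange(phantom.n_columns))
        fits["subject"] = subject
        subject_prf[subject] = fits

    qc_report = pd.DataFrame(qc_rows)
    prf_fits = pd.concat(subject_prf.values(), ignore_index=True)

    # ---- ROI selection and depth profiles --------------------------------
    mean_epi = phantom.baseline_map  # reference anatomy shared by all runs
    profile_rows = []
    for subject, cond, comp, psc_arr in psc_records:
        fits = subject_prf[subject]
        ecc = np.hypot(fits["x0"], fits["y0"]).to_numpy()
        r2 = fits["r_squared"].to_numpy()
        table = pd.DataFrame(
            {
                "column": vmap["column"],
                "depth_fraction": vmap["depth_fraction"],
                "r_squared": r2[vmap["column"]],
                "epi_intensity": mean_epi.reshape(-1),
                "eccentricity": ecc[vmap["column"]],
                "area": phantom.columns["area"].to_numpy()[vmap["column"]],
            }
        )
        for area in config.phantom.areas:
            for band, use_comp in (("centre", "sustained"), ("edge", "transient")):
                if comp != use_comp:
                    continue
                roi = depth_mod.select_roi(table, band, areas=[area])
                if not roi.included:
                    continue
                sel = np.asarray(roi.included, dtype=int)
                prof_observed = psc_arr[sel].mean(axis=0)  # pial-first
                prof_local = flip_profile(
                    deconvolve_drain(flip_profile(prof_observed), leakage)
                )
                for f, v in zip(depth_fr, prof_local):
                    profile_rows.append(
                        {
                            "subject": subject,
                            "area": area,
                            "band": band,
                            "condition": cond,
                            "depth_fraction": f,
                            "psc": v,
                        }
                    )
    profiles = pd.DataFrame(
        profile_rows,
        columns=["subject", "area", "band", "condition", "depth_fraction", "psc"],
    )

    # ---- group statistics -------------------------------------------------
    contrasts = {}
    peak_calls = {}
    centre = profiles[profiles["band"] == "centre"]
    have_pair = {"motion", "dynamic"} <= set(config.conditions)
    for area in config.phantom.areas:
        sub = centre[centre["area"] == area]
        if not have_pair or sub.empty:
            continue
        # drop subjects that lost a condition to QC exclusion
        per_cond = sub.groupby("subject")["condition"].agg(set)
        complete = per_cond.index[per_cond.apply(lambda s: {"motion", "dynamic"} <= s)]
        sub = sub[sub["subject"].isin(complete)]
        if sub["subject"].nunique() < 2:
            continue
        contrasts[area] = stats_mod.condition_contrast(sub, "motion", "dynamic")
        per_subject = contrasts[area].attrs["per_subject"]
        calls = []
        for subject, grp in per_subject.groupby("subject"):
            grp = grp.sort_values("depth_fraction")
            calls.append(
                stats_mod.classify_peak(
                    grp["delta_psc"].to_numpy(), grp["depth_fraction"].to_numpy()
                )
            )
        peak_calls[area] = calls

    chisq = None
    if len(peak_calls) >= 2:
        try:
            chisq = stats_mod.superficial_ratio_chisq(peak_calls)
        except ValueError:
            chisq = None

    lrt = None
    if len(config.conditions) >= 2 and len(config.phantom.areas) >= 2 and not centre.empty:
        full = [
            "area",
            "condition",
            "depth_fraction",
            "area:condition",
            "area:depth_fraction",
            "condition:depth_fraction",
        ]
        null = [t for t in full if t != "area:condition"]
        lrt = stats_mod.lme_interaction_lrt(
            centre.rename(columns={"area": "area"}), full, null
        )

    onsets = {}
    for band in ("interior", "edge"):
        stack = [
            np.mean(v, axis=0) for (s, b), v in era_store.items() if b == band
        ]
        if len(stack) >= 2:
            n_min = min(len(x) for x in stack)
            # drop the pre-onset baseline volume (identically zero by
            # construction); onset indices count volumes since block onset
            arr = np.vstack([x[1:n_min] for x in stack])
            onsets[("V1", band)] = stats_mod.detect_response_onset(arr)

    # ---- visual-field projections (pooled over subjects) ------------------
    projections = {}
    proj_grid = VisualFieldGrid(extent_deg=9.0, deg_per_pixel=config.projection_deg_per_px)
    for cond in config.conditions:
        per_models, per_psc = [], []
        for subject, c, comp, psc_arr in psc_records:
            if c != cond or comp != "sustained":
                continue
            fits = subject_prf[subject]
            ok = np.isfinite(fits["sigma"].to_numpy()) & (fits["sigma"].to_numpy() > 0)
            per_models.append(fits.loc[ok, ["x0", "y0", "sigma"]])
            per_psc.append(psc_arr[ok].mean(axis=1))  # averaged over depth levels
        if per_models:
            projections[cond] = pool_projections(per_models, per_psc, proj_grid)

    manifest = {
        "seed": config.seed,
        "config": asdict(config),
        "truth_hash": phantom.truth_hash(),
        "profiles_sha256": _sha256_of_frame(profiles) if not profiles.empty else None,
        "qc_sha256": _sha256_of_frame(qc_report) if not qc_report.empty else None,
        "n_runs_excluded": int(qc_report["excluded"].sum()) if not qc_report.empty else 0,
    }

    result = PipelineResult(
        config=config,
        profiles=profiles,
        contrasts=contrasts,
        peak_calls=peak_calls,
        chisq=chisq,
        lrt=lrt,
        onsets=onsets,
        qc_report=qc_report,
        prf_fits=prf_fits,
        projections=projections,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.profiles.to_csv(out / "depth_profiles.tsv", sep="\t", index=False)
    result.qc_report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
    if result.prf_fits is not None:
        result.prf_fits.to_csv(out / "prf_fits.tsv", sep="\t", index=False)
    report = {
        "chisq": (
            {"statistic": result.chisq[0], "df": result.chisq[1], "p": result.chisq[2]}
            if result.chisq
            else None
        ),
        "lrt": (
            {
                "statistic": result.lrt.statistic,
                "df": result.lrt.df,
                "p": result.lrt.p_value,
            }
            if result.lrt
            else None
        ),
        "onsets": {f"{a}_{b}": (int(v) if v is not None else None) for (a, b), v in result.onsets.items()},
        "peak_depths": {
            area: [c.peak_depth_fraction for c in calls]
            for area, calls in result.peak_calls.items()
        },
    }
    (out / "group_stats.json").write_text(json.dumps(report, indent=2))
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2, default=str))
    for area, con in result.contrasts.items():
        con.to_csv(out / f"contrast_motion-dynamic_{area}.tsv", sep="\t", index=False)
    if result.config.make_figures:
        _write_figures(result, out)


def _write_figures(result: PipelineResult, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if result.contrasts:
        fig, ax = plt.subplots(figsize=(5, 4))
        for area, con in result.contrasts.items():
            ax.errorbar(
                con["depth_fraction"] * 100, con["mean"], yerr=con["sem"], label=area
            )
        ax.set_xlabel("cortical depth (% from pial surface)")
        ax.set_ylabel("Δ PSC (motion − dynamic)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "depth_profiles.png", dpi=120)
        plt.close(fig)
    for cond, proj in result.projections.items():
        fig, ax = plt.subplots(figsize=(4.5, 4))
        half = proj.grid.extent_deg / 2
        im = ax.imshow(
            proj.values, origin="lower", extent=(-half, half, -half, half), cmap="RdBu_r"
        )
        fig.colorbar(im, ax=ax, label="PSC (%)")
        ax.set_title(f"visual-field projection: {cond}")
        fig.tight_layout()
        fig.savefig(out / f"projection_{cond}.png", dpi=120)
        plt.close(fig)
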