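"""General linear model for the block-design runs.

Each stimulus condition is modelled with two haemodynamic predictors: a
sustained one (boxcar over the block, HRF-convolved) and a transient one
(delta functions at block onset and offset sharing one beta).  Fixation-target
events enter as a single nuisance predictor.  Both the regressors and the
data are high-pass filtered by projection onto a discrete-cosine drift basis
(cutoff 35 s), and betas are converted to percent signal change relative to
the mean signal of the initial pre-stimulus baseline (first 20.8 s of the
run).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stimulus import RunSchedule, TargetEvents

HIGHPASS_CUTOFF_S = 35.0
BASELINE_WINDOW_S = 20.8


@dataclass(frozen=True)
class HRFSpec:
    """Canonical double-gamma haemodynamic response parameters (seconds)."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    length_s: float = 32.0


def double_gamma_hrf(tr: float, spec: HRFSpec = HRFSpec()) -> np.ndarray:
    """Sample the canonical double-gamma HRF at multiples of ``tr``.

    The kernel is the difference of two gamma densities, normalised so the
    continuous-time peak equals 1; sampling at any grid therefore subsamples
    one fixed underlying function.
    """
    if tr <= 0:
        raise ValueError("TR must be positive")
    if spec.peak_dispersion <= 0 or spec.undershoot_dispersion <= 0:
        raise ValueError("dispersions must be positive")

    def f(t):
        g1 = sps.gamma.pdf(t, spec.peak_delay / spec.peak_dispersion, scale=spec.peak_dispersion)
        g2 = sps.gamma.pdf(
            t, spec.undershoot_delay / spec.undershoot_dispersion, scale=spec.undershoot_dispersion
        )
        return g1 - spec.undershoot_ratio * g2

    # continuous-time peak, located near the mode of the positive gamma
    t_dense = np.arange(0.0, spec.length_s, 1e-3)
    peak = f(t_dense).max()
    t = np.arange(0.0, spec.length_s, tr)
    return f(t) / peak


def dct_drift_basis(n_volumes: int, tr: float, cutoff_s: float) -> np.ndarray:
    """Discrete-cosine drift basis (including the constant) with all periods
    ≥ ``cutoff_s``; columns are orthonormal."""
    if cutoff_s <= 2 * tr:
        raise ValueError("high-pass cutoff must exceed 2 TR")
    order = int(np.floor(2.0 * n_volumes * tr / cutoff_s))
    t = np.arange(n_volumes)
    basis = [np.full(n_volumes, 1.0 / np.sqrt(n_volumes))]
    for k in range(1, order + 1):
        c = np.cos(np.pi * k * (t + 0.5) / n_volumes)
        basis.append(c / np.linalg.norm(c))
    return np.column_stack(basis)


def highpass_filter(data: np.ndarray, tr: float, cutoff_s: float = HIGHPASS_CUTOFF_S) -> np.ndarray:
    """Project out slow discrete-cosine drifts (and the mean).

    ``data`` may be 1-D (time) or 2-D (time × units).  Idempotent: the filter
    is an orthogonal projection.
    """
    x = np.asarray(data, dtype=float)
    one_d = x.ndim == 1
    if one_d:
        x = x[:, None]
    basis = dct_drift_basis(x.shape[0], tr, cutoff_s)
    filtered = x - basis @ (basis.T @ x)
    return filtered[:, 0] if one_d else filtered


@dataclass
class DesignMatrix:
    """Task regressors of one run, with the high-pass filter they carry.

    ``matrix`` holds unfiltered regressors (each scaled to unit peak so betas
    are in raw-signal units of peak response); ``filtered()`` applies the
    drift projection used at fit time.
    """

    matrix: pd.DataFrame
    tr_s: float
    hp_cutoff_s: float
    scales: dict[str, float] = field(default_factory=dict)

    @property
    def n_volumes(self) -> int:
        return len(self.matrix)

    @property
    def columns(self) -> list[str]:
        return list(self.matrix.columns)

    def filtered(self) -> pd.DataFrame:
        vals = highpass_filter(self.matrix.to_numpy(), self.tr_s, self.hp_cutoff_s)
        return pd.DataFrame(vals, columns=self.matrix.columns)


def _convolve_downsample(
    fine: np.ndarray, hrf_fine: np.ndarray, dt: float, n_volumes: int, step: int
):
    # dt factor: discrete sum approximates the continuous convolution integral
    conv = np.convolve(fine, hrf_fine)[: len(fine)] * dt
    return conv[::step][:n_volumes]


def build_design_matrix(
    schedule: RunSchedule,
    target_events: TargetEvents | None = None,
    hrf_spec: HRFSpec = HRFSpec(),
    hp_cutoff_s: float = HIGHPASS_CUTOFF_S,
    dt: float = 0.0,
) -> DesignMatrix:
    """Build the run's design: per condition a sustained (boxcar) and a
    transient (onset+offset delta) HRF-convolved column, plus one column for
    the target events.

    Regressors are constructed on a fine grid (``dt`` defaults to TR/21) and
    sampled at volume acquisition times; each column is scaled to unit peak.
    """
    tr = schedule.tr_s
    if dt <= 0:
        dt = tr / 21.0
    step = int(round(tr / dt))
    dt = tr / step
    n_fine = schedule.n_volumes * step
    hrf_fine = double_gamma_hrf(dt, hrf_spec)

    onsets = schedule.onsets_s
    durations = schedule.durations_s
    ends = onsets + durations
    if np.any(onsets[1:] < ends[:-1] - 1e-9):
        raise ValueError("blocks overlap")

    cols: dict[str, np.ndarray] = {}
    scales: dict[str, float] = {}
    for cond in dict.fromkeys(schedule.conditions):  # preserve order, unique
        sel = [i for i, c in enumerate(schedule.conditions) if c == cond]
        boxcar = np.zeros(n_fine)
        deltas = np.zeros(n_fine)
        for i in sel:
            i0 = int(round(onsets[i] / dt))
            i1 = min(int(round(ends[i] / dt)), n_fine)
            boxcar[i0:i1] = 1.0
            deltas[i0] += 1.0 / dt  # unit-area impulse at onset
            if i1 < n_fine:
                deltas[i1] += 1.0 / dt  # and at offset
        for name, fine in ((f"{cond}_sustained", boxcar), (f"{cond}_transient", deltas)):
            reg = _convolve_downsample(fine, hrf_fine, dt, schedule.n_volumes, step)
            peak = np.abs(reg).max()
            scales[name] = float(peak) if peak > 0 else 1.0
            cols[name] = reg / scales[name] if peak > 0 else reg

    if target_events is not None and len(target_events.onsets_s) > 0:
        tfine = np.zeros(n_fine)
        for on in target_events.onsets_s:
            i0 = int(round(on / dt))
            i1 = min(int(round((on + target_events.duration_s) / dt)), n_fine)
            tfine[i0:i1] = 1.0
        reg = _convolve_downsample(tfine, hrf_fine, dt, schedule.n_volumes, step)
        peak = np.abs(reg).max()
        scales["target"] = float(peak) if peak > 0 else 1.0
        cols["target"] = reg / scales["target"] if peak > 0 else reg

    return DesignMatrix(pd.DataFrame(cols), tr, hp_cutoff_s, scales)


@dataclass
class GLMResult:
    """Per-unit OLS fit of the task design."""

    betas: pd.DataFrame  # (units × columns), raw-signal units of peak response
    residual_variance: np.ndarray  # per unit
    baseline_mean: np.ndarray  # per unit, raw signal in the baseline window
    design_columns: list[str]

    def psc(self) -> pd.DataFrame:
        """Percent signal change per column: 100 · beta / baseline mean.

        Units with non-positive baseline are flagged with NaN.
        """
        base = np.where(self.baseline_mean > 0, self.baseline_mean, np.nan)
        return 100.0 * self.betas.div(base, axis=0)


def fit_glm(
    timecourses: np.ndarray,
    design: DesignMatrix,
    baseline_window_s: float = BASELINE_WINDOW_S,
) -> GLMResult:
    """Ordinary least squares on high-pass-filtered data and design.

    ``timecourses`` is (n_volumes,) or (n_volumes × units) of raw signal.
    The same drift projection is applied to both sides, so drift terms need
    not (and must not) appear as design columns.  Raises on rank deficiency,
    naming the collinear columns.
    """
    y = np.asarray(timecourses, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if y.shape[0] != design.n_volumes:
        raise ValueError("time course length does not match the design")

    x = design.filtered().to_numpy()
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify offending columns via QR pivoting on the Gram matrix
        _, r = np.linalg.qr(x)
        bad = [design.columns[i] for i in range(x.shape[1]) if abs(r[i, i]) < 1e-10]
        raise np.linalg.LinAlgError(f"design is rank deficient; collinear columns: {bad}")

    yf = highpass_filter(y, design.tr_s, design.hp_cutoff_s)
    betas, _, _, _ = np.linalg.lstsq(x, yf, rcond=None)
    resid = yf - x @ betas
    dof = max(x.shape[0] - x.shape[1] - 1, 1)
    resvar = (resid**2).sum(axis=0) / dof

    n_base = int(round(baseline_window_s / design.tr_s))
    if n_base < 1 or n_base > y.shape[0]:
        raise ValueError("baseline window must lie within the run")
    baseline = y[:n_base].mean(axis=0)
    return GLMResult(
        betas=pd.DataFrame(betas.T, columns=design.columns),
        residual_variance=resvar,
        baseline_mean=baseline,
        design_columns=design.columns,
    )


def to_percent_signal_change(
    betas: np.ndarray | pd.DataFrame,
    raw_timecourse: np.ndarray,
    tr_s: float,
    baseline_window_s: float = BASELINE_WINDOW_S,
):
    """PSC = 100 · beta / mean(raw signal over the initial baseline window).

    Returns NaN (flagged) where the baseline mean is not positive.
    """
    y = np.asarray(raw_timecourse, dtype=float)
    n_base = int(round(baseline_window_s / tr_s))
    if n_base < 1 or n_base > y.shape[0]:
        raise ValueError("baseline window must lie within the run")
    base = y[:n_base].mean(axis=0)
    base = np.where(base > 0, base, np.nan)
    return 100.0 * np.asarray(betas) / base


@dataclass
class EventRelatedAverage:
    """Across-repetition mean time course locked to block onset."""

    mean: np.ndarray  # (window volumes,), percent signal change
    sem: np.ndarray
    n_repetitions: int
    tr_s: float
    segments: np.ndarray = field(repr=False, default=None)  # (reps × window)


def event_related_average(
    timecourse: np.ndarray,
    schedule: RunSchedule,
    window_s: float,
    n_baseline_vols: int = 1,
) -> EventRelatedAverage:
    """Average the response across block repetitions.

    Each segment starts ``n_baseline_vols`` volumes before a block onset and
    spans ``window_s``; it is expressed as percent signal change relative to
    the mean of its pre-block baseline volumes.
    """
    y = np.asarray(timecourse, dtype=float)
    tr = schedule.tr_s
    win = int(round(window_s / tr))
    onsets = schedule.onset_volumes
    if len(onsets) < 2:
        raise ValueError("need at least 2 block repetitions")
    if len(onsets) > 1 and win > np.diff(onsets).min() + n_baseline_vols:
        raise ValueError("window does not fit between consecutive blocks")

    segs = []
    for ov in onsets:
        i0 = ov - n_baseline_vols
        i1 = i0 + win
        if i0 < 0 or i1 > len(y):
            continue
        seg = y[i0:i1]
        base = seg[:n_baseline_vols].mean()
        if base <= 0:
            raise ValueError("non-positive pre-block baseline")
        segs.append(100.0 * (seg - base) / base)
    if len(segs) < 2:
        raise ValueError("need at least 2 block repetitions inside the run")
    segs = np.asarray(segs)
    mean = segs.mean(axis=0)
    sem = segs.std(axis=0, ddof=1) / np.sqrt(len(segs))
    return EventRelatedAverage(mean, sem, len(segs), tr, segs)
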