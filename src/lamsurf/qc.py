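"""Run-level quality-control gates.

Two quantitative exclusion criteria guard the depth analysis: a spatial
correlation check for head motion / image instability (mean volume-to-
reference Pearson r must reach 0.95), and a behavioural fixation check (at
least 70% of fixation-target colour changes must have been reported).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SPATIAL_R_THRESHOLD = 0.95
HIT_RATE_THRESHOLD = 0.70
RESPONSE_WINDOW_S = 2.0


@dataclass(frozen=True)
class QCResult:
    passed: bool
    value: float  # mean spatial r, or hit rate
    threshold: float
    reason: str = ""


def qc_spatial_correlation(
    run_volumes: np.ndarray,
    reference_volume: np.ndarray,
    threshold: float = SPATIAL_R_THRESHOLD,
    mask: np.ndarray | None = None,
) -> QCResult:
    """Mean Pearson correlation of each volume against the reference over
    in-mask voxels; the run fails iff the mean r falls below ``threshold``."""
    vols = np.asarray(run_volumes, dtype=float)  # (n_volumes, n_voxels) or (T, ...)
    vols = vols.reshape(vols.shape[0], -1)
    ref = np.asarray(reference_volume, dtype=float).ravel()
    if mask is not None:
        m = np.asarray(mask).ravel().astype(bool)
        if not m.any():
            raise ValueError("empty mask")
        vols = vols[:, m]
        ref = ref[m]
    if vols.shape[1] != ref.size:
        raise ValueError("reference volume does not match the run volumes")
    ref_c = ref - ref.mean()
    ref_n = np.linalg.norm(ref_c)
    v_c = vols - vols.mean(axis=1, keepdims=True)
    v_n = np.linalg.norm(v_c, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (v_c @ ref_c) / (v_n * ref_n)
    mean_r = float(np.nanmean(r))
    passed = mean_r >= threshold
    return QCResult(passed, mean_r, threshold, "" if passed else "mean spatial r below threshold")


def qc_hit_rate(
    target_onsets_s: np.ndarray,
    response_times_s: np.ndarray,
    window_s: float = RESPONSE_WINDOW_S,
    threshold: float = HIT_RATE_THRESHOLD,
) -> QCResult:
    """Fraction of targets answered within ``window_s`` after their onset.

    Greedy earliest matching: each response credits at most one target and
    each target is credited at most once.  Zero targets → undefined, flagged
    as failed with a reason.
    """
    targets = np.sort(np.asarray(target_onsets_s, dtype=float))
    responses = np.sort(np.asarray(response_times_s, dtype=float))
    if len(targets) == 0:
        return QCResult(False, float("nan"), threshold, "no targets: hit rate undefined")
    hits = 0
    ri = 0
    for t in targets:
        while ri < len(responses) and responses[ri] < t:
            ri += 1
        if ri < len(responses) and responses[ri] <= t + window_s:
            hits += 1
            ri += 1
    rate = hits / len(targets)
    passed = rate >= threshold
    return QCResult(passed, float(rate), threshold, "" if passed else "hit rate below threshold")
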