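"""Draining-vein forward model and spatial deconvolution.

Gradient-echo BOLD is biased towards the cortical surface because ascending
veins carry deoxygenated blood from deep layers upward.  The forward model is
linear: the observed signal at a depth is the local signal plus a weighted
sum of the signals at all deeper depths,

    observed_i = local_i + Σ_{j < i} W[i, j] · local_j,

with depths indexed deep → superficial (index 0 = white-matter boundary) and
W lower-triangular with unit diagonal.  Deconvolution inverts this by
sequential substitution from the deepest level upward, subtracting the
estimated contribution of all deeper levels — algebraically a triangular
solve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class LeakageModel:
    """Depth-to-depth signal-carryover weights.

    ``weights`` is (n_depths × n_depths), lower-triangular with unit diagonal
    in deep→superficial ordering; off-diagonal entries are ≥ 0 fractions of a
    deeper depth's signal carried to a more superficial one.
    """

    weights: np.ndarray
    provenance: str = "custom"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.allclose(np.triu(w, 1), 0.0):
            raise ValueError("weights must be lower-triangular (deep → superficial)")
        if not np.allclose(np.diag(w), 1.0):
            raise ValueError("diagonal must be 1 (each depth carries its own signal)")
        if np.any(w[np.tril_indices_from(w, -1)] < 0):
            raise ValueError("off-diagonal leakage weights must be non-negative")
        self.weights = w

    @property
    def n_depths(self) -> int:
        return self.weights.shape[0]

    @classmethod
    def uniform(cls, n_depths: int, leak_fraction: float = 0.3) -> "LeakageModel":
        """Cumulative-drain model: a fraction ``leak_fraction`` of every
        depth's signal is carried to each more superficial depth."""
        if not 0 <= leak_fraction:
            raise ValueError("leak fraction must be non-negative")
        w = np.eye(n_depths) + leak_fraction * np.tril(np.ones((n_depths, n_depths)), -1)
        return cls(w, provenance="uniform-cumulative")

    @classmethod
    def identity(cls, n_depths: int) -> "LeakageModel":
        return cls(np.eye(n_depths), provenance="identity")

    @classmethod
    def from_tsv(cls, path) -> "LeakageModel":
        w = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)
        return cls(w, provenance=str(path))

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.weights).to_csv(path, sep="\t", header=False, index=False)


def _check_dims(profile: np.ndarray, leakage: LeakageModel) -> np.ndarray:
    p = np.asarray(profile, dtype=float)
    if p.shape[-1] != leakage.n_depths:
        raise ValueError(
            f"profile has {p.shape[-1]} depths but the leakage model has {leakage.n_depths}"
        )
    return p


def forward_drain(local_profile: np.ndarray, leakage: LeakageModel) -> np.ndarray:
    """Apply the draining forward model: observed = W · local.

    ``local_profile`` is (..., n_depths) ordered deep → superficial.
    """
    p = _check_dims(local_profile, leakage)
    return p @ leakage.weights.T


def deconvolve_drain(observed_profile: np.ndarray, leakage: LeakageModel) -> np.ndarray:
    """Recover the local profile by sequential substitution, deepest first.

    For each depth i (from deep to superficial) the estimated contribution of
    all deeper levels is subtracted:
        local_i = observed_i − Σ_{j<i} W[i, j] · local_j.
    Equal to solving W·x = observed; asserts the unit-diagonal contract.
    """
    if not np.allclose(np.diag(leakage.weights), 1.0):
        raise ValueError("deconvolution requires a unit-diagonal leakage model")
    p = _check_dims(observed_profile, leakage)
    squeeze = p.ndim == 1
    obs = np.atleast_2d(p)
    w = leakage.weights
    local = np.empty_like(obs)
    for i in range(leakage.n_depths):
        local[:, i] = obs[:, i] - local[:, :i] @ w[i, :i]
    return local[0] if squeeze else local


def flip_profile(profile: np.ndarray) -> np.ndarray:
    """Convert between internal (deep-first) and display (pial-first, i.e.
    0% depth = pial surface) ordering of the depth axis."""
    return np.asarray(profile)[..., ::-1]
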