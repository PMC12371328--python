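"""Timepoint-level missingness: evaluation masks (MCAR, MNAR) and the
conditional/target split used for self-supervised training.

Missingness operates on whole timepoints — the deployment scenario is a
missed stool collection, not a dropped taxon.  Every subject always retains
at least one conditional timepoint so imputation stays well-posed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .preprocess import shannon_index
from .profiles import TaxonProfile

__all__ = ["TimepointMask", "mcar_mask", "mnar_mask", "training_split",
           "RATIO_GRID"]

#: missing-ratio grid used both for evaluation sweeps and self-supervision
RATIO_GRID = np.round(np.arange(0.1, 1.0, 0.1), 1)


@dataclass
class TimepointMask:
    target: np.ndarray   # [S, L] 1 = hidden, to be imputed
    cond: np.ndarray     # [S, L] 1 = given to the model
    ratio: float         # nominal missing ratio r

    def __post_init__(self):
        self.target = np.asarray(self.target, dtype=np.int8)
        self.cond = np.asarray(self.cond, dtype=np.int8)
        if np.any(self.target & self.cond):
            raise ValueError("target and conditional masks overlap")

    def validate_against(self, observed: np.ndarray) -> None:
        observed = np.asarray(observed, dtype=np.int8)
        if not np.array_equal(self.target | self.cond, observed):
            raise ValueError("target ∪ cond must equal the observed set")
        if np.any(self.cond.sum(axis=1) < 1):
            raise ValueError("every subject needs ≥1 conditional timepoint")


def _bernoulli_rows(observed: np.ndarray, r: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Per-subject Bernoulli(r) target draws over observed timepoints,
    redrawn until each subject has ≥1 target and ≥1 conditional."""
    S, L = observed.shape
    target = np.zeros((S, L), dtype=np.int8)
    for s in range(S):
        obs_idx = np.flatnonzero(observed[s])
        if obs_idx.size < 2:
            raise ValueError(f"subject {s} has <2 observed timepoints")
        while True:
            draw = rng.random(obs_idx.size) < r
            if 0 < draw.sum() < obs_idx.size:
                break
        target[s, obs_idx[draw]] = 1
    return target


def mcar_mask(observed: np.ndarray, r: float, seed: int) -> TimepointMask:
    """Missing-completely-at-random mask: each observed timepoint is hidden
    independently with probability ``r`` (with a redraw guarantee keeping at
    least one target and one conditional timepoint per subject)."""
    if not 0 < r < 1:
        raise ValueError("r must be in (0, 1)")
    observed = np.asarray(observed, dtype=np.int8)
    rng = np.random.default_rng(seed)
    target = _bernoulli_rows(observed, r, rng)
    cond = observed & ~target
    return TimepointMask(target, cond, r)


def mnar_mask(profile: TaxonProfile, r: float) -> TimepointMask:
    """Missing-not-at-random mask: per subject the ⌈r·L_obs⌉ observed
    timepoints with the *highest* Shannon diversity are hidden (capped at
    L_obs − 1). Deterministic; diversity ties break toward the earlier
    timepoint."""
    if not 0 < r < 1:
        raise ValueError("r must be in (0, 1)")
    observed = np.asarray(profile.observed, dtype=np.int8)
    S, L = observed.shape
    target = np.zeros((S, L), dtype=np.int8)
    for s in range(S):
        obs_idx = np.flatnonzero(observed[s])
        if obs_idx.size < 2:
            raise ValueError(f"subject {s} has <2 observed timepoints")
        H = []
        for l in obs_idx:
            row = profile.values[s, l]
            H.append(shannon_index(row) if row.sum() > 0 else -math.inf)
        k = min(math.ceil(r * obs_idx.size), obs_idx.size - 1)
        # sort by descending H; ties keep earlier timepoint first
        order = sorted(range(obs_idx.size), key=lambda i: (-H[i], obs_idx[i]))
        chosen = [obs_idx[i] for i in order[:k]]
        target[s, chosen] = 1
    cond = observed & ~target
    return TimepointMask(target, cond, r)


def training_split(observed: np.ndarray, rng: np.random.Generator) -> TimepointMask:
    """Self-supervised conditional/target split: per subject a ratio is drawn
    uniformly from the 0.1…0.9 grid and applied as an MCAR draw.  Called
    afresh every training iteration."""
    observed = np.asarray(observed, dtype=np.int8)
    S, L = observed.shape
    target = np.zeros((S, L), dtype=np.int8)
    for s in range(S):
        r = float(rng.choice(RATIO_GRID))
        target[s:s + 1] = _bernoulli_rows(observed[s:s + 1], r, rng)
    cond = observed & ~target
    return TimepointMask(target, cond, float("nan"))
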