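"""Core containers for longitudinal taxon-abundance data.

A :class:`TaxonProfile` holds relative abundances for S subjects observed at
(up to) L shared timepoints over K taxa, together with a subject × timepoint
observation mask — a 0 marks a stool sample that was never collected.
:class:`ClrTensor` is the centred log-ratio working representation that the
diffusion model trains on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TaxonProfile", "PhylumMap", "ClrTensor", "FeatureOrdering"]


@dataclass
class TaxonProfile:
    values: np.ndarray          # [S, L, K] relative-abundance fractions
    subject_ids: list[str]
    timepoints: list[float]     # ordinal ages, e.g. months
    feature_labels: list[str]
    observed: np.ndarray        # [S, L] binary; 1 = timepoint sampled

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.observed = np.asarray(self.observed)
        S, L, K = self.values.shape
        if len(self.subject_ids) != S or len(self.timepoints) != L \
                or len(self.feature_labels) != K:
            raise ValueError("label lengths do not match tensor shape")
        if len(set(self.subject_ids)) != S:
            raise ValueError("duplicate subject_ids")
        if L < 2:
            raise ValueError("at least two timepoints required")
        if np.any(self.values < 0):
            raise ValueError("negative abundance")
        obs = self.observed.astype(bool)
        sums = self.values[obs].sum(axis=-1)
        if sums.size and (np.any(sums <= 0) or np.any(sums > 1 + 1e-9)):
            raise ValueError("observed rows must sum into (0, 1]")

    @property
    def shape(self):
        return self.values.shape

    def copy(self) -> "TaxonProfile":
        return TaxonProfile(
            self.values.copy(), list(self.subject_ids), list(self.timepoints),
            list(self.feature_labels), self.observed.copy(),
        )


@dataclass
class PhylumMap:
    """Feature → phylum assignment plus the contiguous block layout."""

    phylum_of: dict[int, str]               # feature index -> phylum name
    blocks: list[tuple[str, int, int]]      # (phylum, start, stop) half-open

    def __post_init__(self):
        covered = sorted(i for _, a, b in self.blocks for i in range(a, b))
        k = len(self.phylum_of)
        if covered != list(range(k)):
            raise ValueError("blocks must partition the feature axis")

    @property
    def block_ranges(self) -> list[tuple[int, int]]:
        return [(a, b) for _, a, b in self.blocks]


@dataclass
class ClrTensor:
    """clr-transformed abundances; rows at observed timepoints sum to zero."""

    values: np.ndarray          # [S, L, K]
    pseudo_count: float
    subject_ids: list[str] = field(default_factory=list)
    timepoints: list[float] = field(default_factory=list)
    observed: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.pseudo_count <= 0:
            raise ValueError("pseudo_count must be positive")


@dataclass
class FeatureOrdering:
    """Permutation placing correlated taxa adjacently within phylum blocks."""

    permutation: np.ndarray                 # new position i holds old feature permutation[i]
    scores: np.ndarray                      # geometric-mean |rho| per original feature
    blocks: list[tuple[str, int, int]]      # block layout in the permuted space

    def __post_init__(self):
        perm = np.asarray(self.permutation)
        if sorted(perm.tolist()) != list(range(perm.size)):
            raise ValueError("permutation must be a bijection")
        self.permutation = perm

    def apply(self, values: np.ndarray, axis: int = -1) -> np.ndarray:
        return np.take(values, self.permutation, axis=axis)

    def invert(self, values: np.ndarray, axis: int = -1) -> np.ndarray:
        inv = np.argsort(self.permutation)
        return np.take(values, inv, axis=axis)

    @property
    def phylum_map(self) -> PhylumMap:
        phylum_of = {}
        for name, a, b in self.blocks:
            for i in range(a, b):
                phylum_of[i] = name
        return PhylumMap(phylum_of, list(self.blocks))
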