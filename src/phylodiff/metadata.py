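"""Host-metadata conditioning via a feature tokenizer.

Each categorical variable (country, allergy status, …) gets a learned
embedding table; the value's one-hot selects a row which is added to a bias,
yielding a d-dimensional token (d = 8 by default).  Tokens are injected into
the denoiser either as extra pseudo-feature columns ("spatial", width
K + n·d) or as extra constant channels ("channel", C + n·d channels).
Metadata are static per subject and broadcast over time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nn import Module, Tensor, concatenate

__all__ = [
    "MetadataTable",
    "FeatureTokenizer",
    "concat_spatial",
    "concat_channel",
    "DEFAULT_EMBED_DIM",
]

DEFAULT_EMBED_DIM = 8
UNKNOWN = "<unknown>"


@dataclass
class MetadataTable:
    """Subject-level categorical covariates with stable integer coding.

    Index 0 of every vocabulary is reserved for values unseen at fit time,
    so inference on new subjects never fails.
    """

    subjects: list[str]
    variables: list[str]
    vocabularies: dict[str, list[str]]      # per variable; level 0 is UNKNOWN
    codes: np.ndarray                       # [S, n] integer level codes
    _row_of: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int64)
        self._row_of = {s: i for i, s in enumerate(self.subjects)}

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, variables: list[str] | None = None,
                       subject_col: str = "subject_id") -> "MetadataTable":
        if subject_col not in df.columns:
            raise ValueError(f"metadata needs a {subject_col!r} column")
        if variables is None:
            variables = [c for c in df.columns if c != subject_col]
        subjects = df[subject_col].astype(str).tolist()
        vocabularies: dict[str, list[str]] = {}
        codes = np.zeros((len(subjects), len(variables)), dtype=np.int64)
        for j, var in enumerate(variables):
            levels = [UNKNOWN] + sorted(df[var].astype(str).unique().tolist())
            vocabularies[var] = levels
            lut = {lv: i for i, lv in enumerate(levels)}
            codes[:, j] = [lut[v] for v in df[var].astype(str)]
        return cls(subjects, list(variables), vocabularies, codes)

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    def codes_for(self, subject_ids: list[str]) -> np.ndarray:
        """Integer codes [len(ids) × n]; unknown subjects map to level 0."""
        out = np.zeros((len(subject_ids), len(self.variables)), dtype=np.int64)
        for i, s in enumerate(subject_ids):
            row = self._row_of.get(str(s))
            if row is not None:
                out[i] = self.codes[row]
        return out

    def encode_value(self, variable: str, value: str) -> int:
        levels = self.vocabularies[variable]
        try:
            return levels.index(str(value))
        except ValueError:
            return 0


class FeatureTokenizer(Module):
    """Per-variable embedding: token = b + one-hot(value)ᵀ W ∈ R^d."""

    def __init__(self, vocab_sizes: list[int], d: int = DEFAULT_EMBED_DIM,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.d = d
        self.weights = [
            Tensor(rng.normal(0, 1.0 / np.sqrt(d), (v, d)), requires_grad=True)
            for v in vocab_sizes
        ]
        self.biases = [Tensor(np.zeros(d), requires_grad=True) for _ in vocab_sizes]

    def parameters(self):
        return [*self.weights, *self.biases]

    def tokenize(self, value_code: int, variable: int) -> Tensor:
        """Embed one categorical value of one variable -> vector [d]."""
        if not 0 <= variable < len(self.weights):
            raise IndexError(f"unknown variable index {variable}")
        return self.weights[variable][int(value_code)] + self.biases[variable]

    def __call__(self, codes: np.ndarray) -> Tensor:
        """Embed a batch of code rows [B, n] -> concatenated tokens [B, n·d]."""
        codes = np.asarray(codes, dtype=np.int64)
        pieces = [self.weights[v][codes[:, v]] + self.biases[v]
                  for v in range(len(self.weights))]
        return concatenate(pieces, axis=1)


def _broadcast_cols(emb: Tensor, B: int, C: int, L: int) -> Tensor:
    # [B, nd] -> [B, C, L, nd]
    nd = emb.shape[1]
    return emb.reshape(B, 1, 1, nd) * Tensor(np.ones((1, C, L, 1)))


def concat_spatial(hidden: Tensor, emb: Tensor) -> Tensor:
    """Append metadata tokens along the feature axis.

    hidden [B, C, L, K] + emb [B, n·d] -> [B, C, L, K + n·d]; the original
    K feature columns are untouched.
    """
    B, C, L, _ = hidden.shape
    if emb.shape[0] != B:
        raise ValueError("batch size mismatch between hidden and embeddings")
    if emb.shape[1] == 0:
        return hidden
    return concatenate([hidden, _broadcast_cols(emb, B, C, L)], axis=3)


def concat_channel(hidden: Tensor, emb: Tensor) -> Tensor:
    """Append metadata tokens as constant planes along the channel axis.

    hidden [B, C, L, K] + emb [B, n·d] -> [B, C + n·d, L, K].
    """
    B, C, L, K = hidden.shape
    if emb.shape[0] != B:
        raise ValueError("batch size mismatch between hidden and embeddings")
    nd = emb.shape[1]
    if nd == 0:
        return hidden
    planes = emb.reshape(B, nd, 1, 1) * Tensor(np.ones((1, 1, L, K)))
    return concatenate([hidden, planes], axis=1)
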