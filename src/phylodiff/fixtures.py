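"""Synthetic compositional time-series cohorts.

The generator emulates the statistical structure longitudinal microbiome
profiles exhibit: compositionality (rows on the simplex), temporal
autocorrelation, within-phylum correlation, zero inflation from a detection
floor, and host-metadata effects.  A logistic-normal construction is used —
per subject a latent Gaussian field with AR(1) dependence across time and
equicorrelation within phylum blocks is pushed through a softmax — because
it gives independent control of the temporal and block correlations on the
latent scale, which a Dirichlet would entangle.

Sparsity is induced by the same 0.01% detection filter the preprocessing
applies: a ``sparsity_target`` fraction of taxa are made rare (strongly
negative baseline), so their abundances usually fall below the floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .downstream import renormalize_with_redistribution
from .metadata import MetadataTable
from .preprocess import ABUNDANCE_FILTER_THRESHOLD
from .profiles import TaxonProfile

__all__ = ["FixtureSpec", "generate", "golden_small"]

# rank scaffolding for generated taxonomy strings
_PHYLA = ["Firmicutes", "Bacteroidetes", "Proteobacteria", "Actinobacteria",
          "Verrucomicrobia", "Fusobacteria", "Spirochaetes", "Tenericutes"]


@dataclass
class FixtureSpec:
    S: int = 20
    L: int = 5
    K: int = 24
    phyla: list[int] = field(default_factory=lambda: [10, 8, 6])
    ar_rho: float = 0.7                 # lag-1 autocorrelation of the latents
    block_corr: float = 0.4             # within-phylum latent equicorrelation
    sparsity_target: float = 0.3        # expected zero fraction after filtering
    subject_sd: float = 0.6             # subject random-intercept scale
    base_sd: float = 1.2                # spread of per-taxon baselines
    rare_shift: float = -7.0            # baseline offset applied to rare taxa
    metadata_vars: list[tuple[str, list[str], float]] = field(
        default_factory=lambda: [("country", ["EST", "FIN", "RUS"], 0.8),
                                 ("milk_allergy", ["no", "yes"], 1.2)]
    )
    label_var: str = "milk_allergy"     # metadata variable doubling as outcome
    observed_fraction: float = 1.0      # fraction of timepoints sampled
    seed: int = 0

    def __post_init__(self):
        if sum(self.phyla) != self.K:
            raise ValueError("phylum block sizes must sum to K")
        if not 0 <= self.ar_rho < 1:
            raise ValueError("ar_rho must be in [0, 1)")
        if not 0 <= self.block_corr < 1:
            raise ValueError("block_corr must be in [0, 1)")


def _taxonomy_labels(spec: FixtureSpec) -> tuple[list[str], list[str]]:
    labels, phyla = [], []
    for b, size in enumerate(spec.phyla):
        phylum = _PHYLA[b % len(_PHYLA)]
        for j in range(size):
            labels.append(
                f"k__Bacteria|p__{phylum}|c__C{b}|o__O{b}|f__F{b}|"
                f"g__G{b}_{j}|s__Species_{b}_{j}"
            )
            phyla.append(phylum)
    return labels, phyla


def _block_noise(rng: np.random.Generator, L: int, spec: FixtureSpec) -> np.ndarray:
    """[L × K] innovations with within-block equicorrelation ``block_corr``."""
    c = spec.block_corr
    out = np.empty((L, spec.K))
    start = 0
    for size in spec.phyla:
        shared = rng.standard_normal((L, 1))
        own = rng.standard_normal((L, size))
        out[:, start:start + size] = np.sqrt(c) * shared + np.sqrt(1 - c) * own
        start += size
    return out


def generate(spec: FixtureSpec, return_latents: bool = False):
    """Generate a cohort; returns (profile, metadata, binary labels) and,
    with ``return_latents=True``, also the [S × L × K] latent AR(1) field —
    useful for checking that generator moments recover the requested parameters
    (time-series of length 5 are too short to estimate autocorrelation from
    the compositions without severe centring bias)."""
    rng = np.random.default_rng(spec.seed)
    labels_tax, _ = _taxonomy_labels(spec)
    S, L, K = spec.S, spec.L, spec.K

    # per-taxon baselines; a sparsity_target fraction of taxa are rare
    base = rng.normal(0.0, spec.base_sd, K)
    n_rare = int(round(spec.sparsity_target * K))
    rare_idx = rng.choice(K, size=n_rare, replace=False)
    base[rare_idx] += spec.rare_shift

    # metadata assignments and their latent effects
    meta_rows = {}
    effect = np.zeros((S, K))
    affected = {}
    for name, vocab, eff in spec.metadata_vars:
        assign = rng.choice(len(vocab), size=S)
        meta_rows[name] = [vocab[a] for a in assign]
        # each non-reference level shifts a dedicated slice of common taxa
        common = np.setdiff1d(np.arange(K), rare_idx)
        chosen = rng.choice(common, size=max(2, K // 6), replace=False)
        affected[name] = (chosen, assign)
        for lvl in range(1, len(vocab)):
            effect[np.ix_(assign == lvl, chosen)] += eff * lvl

    rho = spec.ar_rho
    values = np.empty((S, L, K))
    latents = np.empty((S, L, K))
    for s in range(S):
        intercept = rng.normal(0.0, spec.subject_sd, K)
        innov = _block_noise(rng, L, spec)
        z = np.empty((L, K))
        z[0] = innov[0]
        for l in range(1, L):
            z[l] = rho * z[l - 1] + np.sqrt(1 - rho**2) * innov[l]
        latents[s] = z
        logit = base[None, :] + intercept[None, :] + effect[s][None, :] + z
        e = np.exp(logit - logit.max(axis=1, keepdims=True))
        comp = e / e.sum(axis=1, keepdims=True)
        for l in range(L):
            values[s, l] = renormalize_with_redistribution(
                comp[l], threshold=ABUNDANCE_FILTER_THRESHOLD)

    observed = np.ones((S, L), dtype=np.int8)
    if spec.observed_fraction < 1.0:
        for s in range(S):
            n_drop = int(round((1 - spec.observed_fraction) * L))
            n_drop = min(n_drop, L - 2)
            if n_drop > 0:
                drop = rng.choice(L, size=n_drop, replace=False)
                observed[s, drop] = 0

    subject_ids = [f"S{s:03d}" for s in range(S)]
    profile = TaxonProfile(values, subject_ids, list(range(L)), labels_tax, observed)

    meta_df = pd.DataFrame({"subject_id": subject_ids, **meta_rows})
    metadata = MetadataTable.from_dataframe(meta_df)

    # binary outcome: 1 for any non-reference level of the label variable
    if spec.label_var in meta_rows:
        _, assign = affected[spec.label_var]
        y = (assign > 0).astype(np.int8)
    else:
        y = rng.integers(0, 2, size=S).astype(np.int8)
    if return_latents:
        return profile, metadata, y, latents
    return profile, metadata, y


def golden_small() -> tuple[TaxonProfile, MetadataTable, np.ndarray]:
    """The repository's deterministic golden dataset: 12 subjects, 5
    timepoints, 24 taxa in 3 phyla, 2 metadata variables, binary labels."""
    spec = FixtureSpec(S=12, L=5, K=24, phyla=[10, 8, 6], ar_rho=0.7,
                       block_corr=0.4, sparsity_target=0.3, seed=20240117)
    return generate(spec)
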