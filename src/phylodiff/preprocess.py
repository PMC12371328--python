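"""Preprocessing: taxonomy parsing, low-abundance filtering, the centred
log-ratio (clr) transform, and correlation-driven feature ordering.

The clr transform maps a composition x to ln(x+δ) − mean_k ln(x+δ), where the
pseudo-count δ is half the smallest strictly positive abundance over the
fitting (training) set.  Using a single global δ keeps the train and test
transforms identical and avoids information leakage.

Feature ordering groups taxa by phylum and, within each phylum, sorts them by
the geometric mean of their absolute pairwise Spearman correlations so that
correlated taxa sit next to each other — the layout the per-phylum
convolutions in the denoiser rely on.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .profiles import ClrTensor, FeatureOrdering, TaxonProfile

__all__ = [
    "TaxonomyError",
    "parse_taxonomy",
    "filter_low_abundance",
    "clr_transform",
    "inverse_clr",
    "order_features",
    "group_by_phylum",
    "shannon_index",
    "zero_proportion",
    "ABUNDANCE_FILTER_THRESHOLD",
]

#: relative abundances below 0.01% are treated as sequencing noise
ABUNDANCE_FILTER_THRESHOLD = 1e-4


class TaxonomyError(ValueError):
    pass


def parse_taxonomy(label: str) -> tuple[str, str]:
    """Extract (phylum, species) from a pipe-delimited rank string.

    Labels look like ``k__Bacteria|p__Firmicutes|...|s__Blautia_producta``.
    A missing species token yields ``"unclassified"``; a missing phylum token
    raises :class:`TaxonomyError`.
    """
    tokens = label.split("|")
    phylum = None
    species = None
    for tok in tokens:
        tok = tok.strip()
        if tok.startswith("p__"):
            phylum = tok[3:]
        elif tok.startswith("s__"):
            species = tok[3:]
    if phylum is None or phylum == "":
        raise TaxonomyError(f"unassignable phylum: {label!r}")
    if species is None or species == "":
        species = "unclassified"
    return phylum, species


def filter_low_abundance(profile: TaxonProfile,
                         threshold: float = ABUNDANCE_FILTER_THRESHOLD) -> TaxonProfile:
    """Replace relative abundances strictly below ``threshold`` with 0."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    out = profile.copy()
    out.values[out.values < threshold] = 0.0
    return out


def _fitting_values(profile: TaxonProfile, fitting_subjects=None) -> np.ndarray:
    idx = np.arange(len(profile.subject_ids)) if fitting_subjects is None \
        else np.asarray(fitting_subjects)
    obs = profile.observed.astype(bool)[idx]
    return profile.values[idx][obs]


def compute_pseudo_count(profile: TaxonProfile, fitting_subjects=None) -> float:
    """δ = half the smallest strictly positive abundance in the fitting set."""
    vals = _fitting_values(profile, fitting_subjects)
    positive = vals[vals > 0]
    if positive.size == 0:
        raise ValueError("degenerate profile: no positive abundance in fitting set")
    return 0.5 * float(positive.min())


def clr_transform(profile: TaxonProfile, pseudo_count: float | None = None,
                  fitting_subjects=None) -> ClrTensor:
    """Centred log-ratio transform of every observed timepoint.

    Parameters
    ----------
    pseudo_count
        Pre-computed δ (e.g. fitted on training folds).  When ``None``, δ is
        computed from ``fitting_subjects`` (default: all subjects).
    """
    if pseudo_count is None:
        pseudo_count = compute_pseudo_count(profile, fitting_subjects)
    if pseudo_count <= 0:
        raise ValueError("pseudo_count must be positive")
    shifted = profile.values + pseudo_count
    logs = np.log(shifted)
    clr = logs - logs.mean(axis=-1, keepdims=True)
    clr = clr * profile.observed.astype(bool)[:, :, None]  # zeros at unsampled timepoints
    return ClrTensor(
        values=clr,
        pseudo_count=pseudo_count,
        subject_ids=list(profile.subject_ids),
        timepoints=list(profile.timepoints),
        observed=profile.observed.copy(),
    )


def inverse_clr(z: np.ndarray, refilter: bool = False,
                threshold: float = ABUNDANCE_FILTER_THRESHOLD) -> np.ndarray:
    """Map clr coordinates back to the simplex: exp(z) / Σ exp(z).

    With ``refilter=True`` entries falling below the low-abundance threshold
    are re-zeroed and the row renormalized, mirroring the preprocessing
    filter so diversity diagnostics see comparable sparsity.
    """
    z = np.asarray(z, dtype=np.float64)
    shifted = z - z.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    comp = e / e.sum(axis=-1, keepdims=True)
    if refilter:
        comp = np.where(comp < threshold, 0.0, comp)
        sums = comp.sum(axis=-1, keepdims=True)
        if np.any(sums == 0):
            raise ValueError("refiltering removed every taxon in a row")
        comp = comp / sums
    return comp


def group_by_phylum(phyla: list[str]) -> list[tuple[str, list[int]]]:
    """Group feature indices by phylum; blocks ordered by descending size,
    ties broken alphabetically. Within a block the input order is kept."""
    groups: dict[str, list[int]] = {}
    for i, p in enumerate(phyla):
        groups.setdefault(p, []).append(i)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return ordered


def _block_scores(rows: np.ndarray) -> np.ndarray:
    """Geometric-mean |Spearman rho| per feature within one block.

    ``rows`` is [N pooled samples × m features].  Self-correlation is
    excluded.  A constant feature has undefined rank correlation: it scores
    0 (sorting to the block edge), and its undefined pairs are dropped from
    the other features' geometric means rather than counted as zeros.
    """
    m = rows.shape[1]
    if m == 1:
        return np.ones(1)
    # Spearman = Pearson on ranks; corrcoef keeps matrix shape and yields
    # NaN for zero-variance features
    ranks = rankdata(rows, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.asarray(np.corrcoef(ranks, rowvar=False), dtype=np.float64)
    # rank variance is exactly zero for constant features (value variance
    # may be polluted by float representation noise)
    valid = ranks.std(axis=0) > 0
    scores = np.empty(m)
    for j in range(m):
        if not valid[j]:
            scores[j] = 0.0
            continue
        partners = [p for p in range(m) if p != j and valid[p]]
        if not partners:
            scores[j] = 1.0
            continue
        absr = np.abs(rho[j, partners])
        scores[j] = float(np.prod(absr) ** (1.0 / len(partners)))
    return scores


def order_features(clr_rows: np.ndarray, phyla: list[str]) -> FeatureOrdering:
    """Build the phylum-block feature permutation from training-fold data.

    Parameters
    ----------
    clr_rows
        [N × K] matrix of clr values pooled over the training subjects'
        observed timepoints.  Using training data only prevents leakage.
    phyla
        Phylum name per feature (profile order).
    """
    clr_rows = np.asarray(clr_rows, dtype=np.float64)
    K = clr_rows.shape[1]
    if len(phyla) != K:
        raise ValueError("phyla length must match feature count")
    scores = np.empty(K)
    permutation: list[int] = []
    blocks: list[tuple[str, int, int]] = []
    for name, members in group_by_phylum(list(phyla)):
        block_scores = _block_scores(clr_rows[:, members])
        for idx, s in zip(members, block_scores):
            scores[idx] = s
        # stable sort, descending score, ties keep input feature order
        order = sorted(range(len(members)), key=lambda i: -block_scores[i])
        start = len(permutation)
        permutation.extend(members[i] for i in order)
        blocks.append((name, start, len(permutation)))
    return FeatureOrdering(np.asarray(permutation), scores, blocks)


def shannon_index(p: np.ndarray) -> float:
    """Shannon diversity H = −Σ q ln q of a (possibly unnormalised) row."""
    p = np.asarray(p, dtype=np.float64)
    total = p.sum()
    if total <= 0:
        raise ValueError("degenerate composition: all zero")
    q = p / total
    q = q[q > 0]
    return float(-(q * np.log(q)).sum())


def zero_proportion(p: np.ndarray) -> float:
    """Fraction of exactly-zero entries in a composition row."""
    p = np.asarray(p)
    if p.size == 0:
        raise ValueError("empty composition")
    return float((p == 0).sum() / p.size)
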