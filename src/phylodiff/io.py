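"""Readers and writers for the table formats used across the package.

The abundance format follows MetaPhlAn-style output: a TSV whose first
column holds the taxonomy string and whose remaining columns are samples
named ``<subject>_<timepoint>``.  Values may be fractions or percentages;
columns summing to ≈100 are auto-detected and divided by 100.  Subject ×
timepoint combinations absent from the header are recorded as unobserved in
the profile's mask.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .diffusion import (
    DenoiserConfig,
    NoiseSchedule,
    PhylumDenoiser,
    ImputationResult,
)
from .metadata import MetadataTable
from .preprocess import inverse_clr, parse_taxonomy
from .profiles import FeatureOrdering, TaxonProfile

__all__ = [
    "read_abundance",
    "write_abundance",
    "read_metadata",
    "write_mask",
    "read_mask",
    "write_ordering",
    "write_imputed",
    "save_checkpoint",
    "load_checkpoint",
]


def _parse_sample_id(column: str) -> tuple[str, float]:
    if "_" not in column:
        raise ValueError(f"unparseable sample ID {column!r}; expected <subject>_<timepoint>")
    subject, _, tp = column.rpartition("_")
    try:
        return subject, float(tp)
    except ValueError as exc:
        raise ValueError(f"unparseable sample ID {column!r}") from exc


def read_abundance(path) -> TaxonProfile:
    """Read an abundance TSV into a TaxonProfile (fractions, masked)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate sample column {dup!r}")
    pairs = [_parse_sample_id(c) for c in df.columns]
    subjects = sorted({s for s, _ in pairs})
    timepoints = sorted({t for _, t in pairs})
    s_of = {s: i for i, s in enumerate(subjects)}
    t_of = {t: i for i, t in enumerate(timepoints)}
    K = df.shape[0]
    values = np.zeros((len(subjects), len(timepoints), K))
    observed = np.zeros((len(subjects), len(timepoints)), dtype=np.int8)
    mat = df.to_numpy(dtype=np.float64)
    # percentage auto-detection: column totals near 100
    col_sums = mat.sum(axis=0)
    for j, (s, t) in enumerate(pairs):
        col = mat[:, j]
        if col_sums[j] > 50:   # percentages, not fractions
            col = col / 100.0
        values[s_of[s], t_of[t]] = col
        observed[s_of[s], t_of[t]] = 1
    labels = df.index.astype(str).tolist()
    for lbl in labels:
        parse_taxonomy(lbl)   # fail fast on unassignable phyla
    return TaxonProfile(values, subjects, timepoints, labels, observed)


def write_abundance(profile: TaxonProfile, path) -> None:
    cols, data = [], []
    for i, s in enumerate(profile.subject_ids):
        for j, t in enumerate(profile.timepoints):
            if profile.observed[i, j]:
                tp = int(t) if float(t).is_integer() else t
                cols.append(f"{s}_{tp}")
                data.append(profile.values[i, j])
    df = pd.DataFrame(np.asarray(data).T, index=profile.feature_labels, columns=cols)
    df.index.name = "taxonomy"
    df.to_csv(path, sep="\t")


def read_metadata(path, variables: list[str] | None = None) -> MetadataTable:
    return MetadataTable.from_dataframe(pd.read_csv(path), variables)


def write_mask(mask: np.ndarray, subject_ids: list[str], path) -> None:
    pd.DataFrame(np.asarray(mask, dtype=int), index=subject_ids).to_csv(
        path, sep="\t", header=False)


def read_mask(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", header=None, index_col=0)
    return df.to_numpy(dtype=np.int8), df.index.astype(str).tolist()


def write_ordering(ordering: FeatureOrdering, feature_labels: list[str], path) -> None:
    rows = [(feature_labels[old], rank)
            for rank, old in enumerate(ordering.permutation)]
    pd.DataFrame(rows, columns=["feature", "rank"]).to_csv(path, sep="\t", index=False)


def write_imputed(result: ImputationResult, profile: TaxonProfile,
                  path, scale: str = "clr") -> None:
    """Write the point estimate in the abundance-table layout; a sidecar TSV
    (``<path>.imputed.tsv``) marks which timepoints were imputed."""
    if scale not in ("clr", "abundance"):
        raise ValueError("scale must be 'clr' or 'abundance'")
    values = result.point
    if scale == "abundance":
        values = inverse_clr(values)
    cols, data = [], []
    sidecar = []
    for i, s in enumerate(profile.subject_ids):
        for j, t in enumerate(profile.timepoints):
            if result.target_mask.cond[i, j] or result.target_mask.target[i, j]:
                tp = int(t) if float(t).is_integer() else t
                cols.append(f"{s}_{tp}")
                data.append(values[i, j])
                if result.target_mask.target[i, j]:
                    sidecar.append({"subject_id": s, "timepoint": t})
    df = pd.DataFrame(np.asarray(data).T, index=profile.feature_labels, columns=cols)
    df.index.name = "taxonomy"
    df.to_csv(path, sep="\t")
    pd.DataFrame(sidecar).to_csv(str(path) + ".imputed.tsv", sep="\t", index=False)


# --------------------------------------------------------------------------
# checkpoints
# --------------------------------------------------------------------------

CHECKPOINT_SCHEMA = 1


def save_checkpoint(path, denoiser: PhylumDenoiser, sched: NoiseSchedule,
                    ordering: FeatureOrdering, pseudo_count: float,
                    feature_labels: list[str], timepoints: list[float]) -> None:
    """Single-file archive: config, ordering, schedule and weights."""
    meta = {
        "schema": CHECKPOINT_SCHEMA,
        "config": vars(denoiser.config),
        "blocks": ordering.blocks,
        "permutation": ordering.permutation.tolist(),
        "scores": ordering.scores.tolist(),
        "pseudo_count": pseudo_count,
        "feature_labels": feature_labels,
        "timepoints": list(timepoints),
        "schedule": {"T": sched.T, "beta": sched.beta.tolist()},
        "n_features": denoiser.K,
        "n_timepoints": denoiser.L,
        "vocab_sizes": [w.data.shape[0] for w in denoiser.tokenizer.weights]
        if denoiser.tokenizer is not None else None,
    }
    arrays = {f"w{i}": a for i, a in enumerate(denoiser.state_arrays())}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path):
    """Returns (denoiser, schedule, ordering, pseudo_count, meta dict)."""
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        arrays = [z[f"w{i}"] for i in range(len(z.files) - 1)]
    if meta["schema"] != CHECKPOINT_SCHEMA:
        raise ValueError(f"unsupported checkpoint schema {meta['schema']}")
    config = DenoiserConfig(**meta["config"])
    ordering = FeatureOrdering(
        np.asarray(meta["permutation"]), np.asarray(meta["scores"]),
        [tuple(b) for b in meta["blocks"]])
    beta = np.asarray(meta["schedule"]["beta"])
    alpha = 1.0 - beta
    sched = NoiseSchedule(meta["schedule"]["T"], beta, alpha, np.cumprod(alpha))
    denoiser = PhylumDenoiser(config, ordering.phylum_map.block_ranges,
                              meta["n_features"], meta["n_timepoints"],
                              vocab_sizes=meta.get("vocab_sizes"))
    denoiser.load_state_arrays(arrays)
    return denoiser, sched, ordering, float(meta["pseudo_count"]), meta
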