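"""Subject-level cross-validation and the missing-ratio × missingness-type
experiment grid.

Per fold the pipeline is fitted on training subjects only: the clr
pseudo-count, the correlation-driven feature ordering, and (for the learned
method) the denoiser weights.  Evaluation masks are drawn on the held-out
subjects, imputations computed, and the mean absolute error over the K taxa
of each hidden timepoint (clr scale) aggregated: timepoints within subject,
subjects within fold, then mean (SD) across folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import baselines as _baselines
from .diffusion import (
    DenoiserConfig,
    PhylumDenoiser,
    TrainConfig,
    impute,
    make_schedule,
    train,
)
from .missingness import TimepointMask, mcar_mask, mnar_mask
from .preprocess import clr_transform, compute_pseudo_count, order_features, parse_taxonomy
from .profiles import TaxonProfile

__all__ = ["FoldAssignment", "mae", "kfold_subjects", "run_sweep", "SweepConfig"]


@dataclass
class FoldAssignment:
    fold_of: dict[str, int]
    k: int

    def subjects_in(self, fold: int) -> list[str]:
        return [s for s, f in self.fold_of.items() if f == fold]


def mae(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean absolute error over the feature axis: (1/K)·Σ|y_i − ŷ_i|."""
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.shape != y_pred.shape:
        raise ValueError("shape mismatch")
    if y_true.size == 0:
        raise ValueError("empty vectors")
    return float(np.abs(y_true - y_pred).mean())


def kfold_subjects(subject_ids: list[str], k: int = 5,
                   seed: int = 0) -> FoldAssignment:
    """Random subject-level fold assignment with sizes differing by ≤1.
    All timepoints of a subject share its fold, so no leakage across folds."""
    n = len(subject_ids)
    if n < k:
        raise ValueError("fewer subjects than folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_of = {subject_ids[order[i]]: i % k for i in range(n)}
    return FoldAssignment(fold_of, k)


@dataclass
class SweepConfig:
    structures: list[str] = field(default_factory=lambda: ["MCAR", "MNAR"])
    ratios: list[float] = field(default_factory=lambda: [0.3])
    methods: list[str] = field(default_factory=lambda: ["diffusion", "linear", "locf", "mean"])
    k: int = 5
    seed: int = 0
    denoiser: DenoiserConfig = field(
        default_factory=lambda: DenoiserConfig(channels=48, residual_layers=2))
    training: TrainConfig = field(
        default_factory=lambda: TrainConfig(epochs=500, batch=8))
    schedule_T: int = 25
    n_draws: int = 25


def _subject_indices(profile: TaxonProfile, names: list[str]) -> np.ndarray:
    lut = {s: i for i, s in enumerate(profile.subject_ids)}
    return np.asarray([lut[s] for s in names])


def _fit_fold(profile: TaxonProfile, train_idx: np.ndarray):
    """Fit pseudo-count, clr transform, feature ordering and per-feature
    standardization on one fold's training subjects.

    The denoiser trains on per-feature standardized clr values (zero mean,
    unit variance over the training rows) — the ε-objective assumes the data
    scale is commensurate with the injected standard normal noise — and
    predictions are mapped back to the clr scale before scoring.
    """
    delta = compute_pseudo_count(profile, train_idx)
    clr = clr_transform(profile, pseudo_count=delta)
    obs = profile.observed.astype(bool)
    train_rows = clr.values[train_idx][obs[train_idx]]
    phyla = [parse_taxonomy(lbl)[0] for lbl in profile.feature_labels]
    ordering = order_features(train_rows, phyla)
    mu = train_rows.mean(axis=0)
    sd = train_rows.std(axis=0)
    sd[sd < 1e-8] = 1.0
    return clr, ordering, mu, sd


def _evaluate_mask(values_pred: np.ndarray, values_true: np.ndarray,
                   mask: TimepointMask) -> float:
    """Per-subject mean over hidden timepoints of the feature-wise MAE,
    then mean over subjects."""
    per_subject = []
    for s in range(values_true.shape[0]):
        targets = np.flatnonzero(mask.target[s])
        if targets.size == 0:
            continue
        errs = [mae(values_true[s, l], values_pred[s, l]) for l in targets]
        per_subject.append(float(np.mean(errs)))
    return float(np.mean(per_subject))


def run_sweep(profile: TaxonProfile, config: SweepConfig | None = None,
              metadata=None) -> pd.DataFrame:
    """Run the full method × structure × ratio grid under subject-level
    cross-validation; returns one row per cell with mean and SD of the
    per-fold MAEs (clr scale)."""
    config = config or SweepConfig()
    folds = kfold_subjects(profile.subject_ids, config.k, config.seed)
    ages = np.asarray(profile.timepoints, dtype=np.float64)
    needs_model = any(m == "diffusion" for m in config.methods)
    sched = make_schedule(T=config.schedule_T)
    meta_codes_all = (metadata.codes_for(profile.subject_ids)
                      if metadata is not None else None)
    vocab_sizes = ([len(metadata.vocabularies[v]) for v in metadata.variables]
                   if metadata is not None else None)

    # per-fold state
    fold_maes: dict[tuple[str, float, str], list[float]] = {}
    for f in range(config.k):
        test_names = folds.subjects_in(f)
        train_names = [s for s in profile.subject_ids if s not in set(test_names)]
        train_idx = _subject_indices(profile, train_names)
        test_idx = _subject_indices(profile, test_names)
        clr, ordering, mu, sd = _fit_fold(profile, train_idx)
        x_all = ordering.apply(clr.values)          # ordering-space clr
        mu_o, sd_o = ordering.apply(mu), ordering.apply(sd)
        obs_exp = profile.observed.astype(bool)[:, :, None]
        x_std = ((x_all - mu_o) / sd_o) * obs_exp   # standardized, zero where unsampled
        denoiser = None
        if needs_model:
            rng = np.random.default_rng(config.seed * 1000 + f)
            denoiser = PhylumDenoiser(
                config.denoiser, ordering.phylum_map.block_ranges,
                profile.values.shape[2], profile.values.shape[1],
                vocab_sizes=vocab_sizes
                if config.denoiser.metadata_strategy != "none" else None,
                rng=rng)
            hyper = TrainConfig(epochs=config.training.epochs,
                                lr=config.training.lr,
                                batch=config.training.batch,
                                lr_decay=config.training.lr_decay,
                                seed=config.seed * 1000 + f)
            codes_tr = (meta_codes_all[train_idx]
                        if meta_codes_all is not None
                        and config.denoiser.metadata_strategy != "none" else None)
            train(x_std[train_idx], profile.observed[train_idx],
                  denoiser, sched, hyper, codes_tr)

        test_profile = TaxonProfile(
            profile.values[test_idx], test_names, profile.timepoints,
            profile.feature_labels, profile.observed[test_idx])
        x_test = x_all[test_idx]
        for structure in config.structures:
            for r in config.ratios:
                if structure == "MCAR":
                    mask = mcar_mask(test_profile.observed, r,
                                     seed=config.seed * 7919 + f)
                elif structure == "MNAR":
                    mask = mnar_mask(test_profile, r)
                else:
                    raise ValueError(f"unknown structure {structure!r}")
                cond_exp = mask.cond.astype(bool)
                x_masked = x_test * cond_exp[:, :, None]
                for method in config.methods:
                    if method == "diffusion":
                        codes_te = (meta_codes_all[test_idx]
                                    if meta_codes_all is not None
                                    and config.denoiser.metadata_strategy != "none"
                                    else None)
                        x_std_masked = x_std[test_idx] * cond_exp[:, :, None]
                        res = impute(denoiser, x_std_masked, mask, sched,
                                     n_draws=config.n_draws,
                                     seed=config.seed * 7919 + f,
                                     metadata_codes=codes_te)
                        pred = res.point * sd_o + mu_o   # back to clr scale
                        pred = np.where(cond_exp[:, :, None], x_test, pred)
                    elif method in _baselines.BASELINES:
                        pred = _baselines.impute_tensor(
                            x_masked, mask.cond, method, ages)
                    else:
                        raise KeyError(f"method {method!r} not registered")
                    score = _evaluate_mask(pred, x_test, mask)
                    fold_maes.setdefault((structure, r, method), []).append(score)

    rows = []
    for (structure, r, method), scores in fold_maes.items():
        rows.append({
            "structure": structure, "ratio": r, "method": method,
            "mae_mean": float(np.mean(scores)),
            "mae_sd": float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0,
            "folds": len(scores),
            "fold_maes": [float(s) for s in scores],
        })
    return pd.DataFrame(rows)
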