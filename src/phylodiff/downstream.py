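"""Downstream predictive task: cohort simulation by bootstrap resampling
plus measurement noise, zero-redistribution renormalization, a bidirectional
recurrent classifier over the time axis, and ROC/PR AUC scoring.

The simulation mimics augmenting a small cohort for supervised training:
subjects are split 7:3 into disjoint train/test pools, each pool is
bootstrapped (210 train / 90 test samples by default), and light Gaussian
measurement noise is added before renormalising back onto the simplex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import auc as _auc, precision_recall_curve, roc_auc_score

from .nn import Adam, GRU, Linear, Module, Tensor, concatenate, no_grad
from .profiles import TaxonProfile

__all__ = [
    "SimCohort",
    "renormalize_with_redistribution",
    "simulate_cohort",
    "BiRNNClassifier",
    "train_birnn",
    "roc_auc",
    "pr_auc",
]


# --------------------------------------------------------------------------
# simulation
# --------------------------------------------------------------------------

@dataclass
class SimCohort:
    samples: np.ndarray         # [N, L, K] compositions
    labels: np.ndarray          # [N] binary
    is_train: np.ndarray        # [N] bool
    provenance: np.ndarray      # [N] source-subject index

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.is_train = np.asarray(self.is_train, dtype=bool)
        self.provenance = np.asarray(self.provenance)


def renormalize_with_redistribution(p: np.ndarray, threshold: float = 1e-4
                                    ) -> np.ndarray:
    """Zero out entries below ``threshold`` and spread the removed mass
    equally over the remaining nonzero entries.

    The total is preserved exactly, so a row that summed to 1 before the
    zero-setting still sums to 1 afterwards, with exact zeros kept exact.
    """
    p = np.asarray(p, dtype=np.float64)
    if np.any(p < 0):
        raise ValueError("composition entries must be non-negative")
    below = p < threshold
    removed = p[below].sum()
    out = np.where(below, 0.0, p)
    nz = out > 0
    n_nz = int(nz.sum())
    if n_nz == 0:
        raise ValueError("all entries fell below the threshold")
    out[nz] += removed / n_nz
    return out


def simulate_cohort(profiles: TaxonProfile, labels: np.ndarray,
                    n_train: int = 210, n_test: int = 90, seed: int = 0,
                    noise_mean_range: tuple[float, float] = (1e-4, 2e-4),
                    noise_sd: float = 1e-4) -> SimCohort:
    """Bootstrap a labelled cohort from complete subject profiles.

    Subjects are split 7:3 into disjoint train/test pools; samples are then
    drawn with replacement within each pool.  Per simulated sample a noise
    mean μ is drawn uniformly from ``noise_mean_range`` and N(μ, noise_sd²)
    noise is added to every abundance entry; negatives are clipped to zero
    and each timepoint row is renormalised with zero redistribution.
    """
    labels = np.asarray(labels)
    S = len(profiles.subject_ids)
    if labels.shape[0] != S:
        raise ValueError("one label per subject required")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(S)
    n_train_subj = int(round(0.7 * S))
    train_pool, test_pool = perm[:n_train_subj], perm[n_train_subj:]
    if train_pool.size == 0 or test_pool.size == 0:
        raise ValueError("both subject pools must be non-empty")

    def _draw(pool: np.ndarray, n: int, is_train: bool):
        picks = rng.choice(pool, size=n, replace=True)
        rows = []
        for s in picks:
            comp = profiles.values[s].copy()
            if noise_sd > 0 or noise_mean_range[1] > 0:
                mu = rng.uniform(*noise_mean_range)
                comp = comp + rng.normal(mu, noise_sd, comp.shape)
            comp = np.clip(comp, 0.0, None)
            # normalise back onto the simplex, then re-apply the detection
            # floor with its mass redistributed over the surviving taxa
            comp = comp / comp.sum(axis=-1, keepdims=True)
            comp = np.stack([renormalize_with_redistribution(row)
                             for row in comp])
            rows.append(comp)
        return np.stack(rows), labels[picks], np.full(n, is_train), picks

    tr = _draw(train_pool, n_train, True)
    te = _draw(test_pool, n_test, False)
    return SimCohort(
        samples=np.concatenate([tr[0], te[0]]),
        labels=np.concatenate([tr[1], te[1]]),
        is_train=np.concatenate([tr[2], te[2]]),
        provenance=np.concatenate([tr[3], te[3]]),
    )


# --------------------------------------------------------------------------
# bidirectional recurrent classifier
# --------------------------------------------------------------------------

class BiRNNClassifier(Module):
    """Bidirectional GRU over the timepoint sequence followed by a dense
    sigmoid unit for binary outcome prediction."""

    def __init__(self, d_in: int, hidden: int = 64,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.fwd = GRU(d_in, hidden, rng)
        self.bwd = GRU(d_in, hidden, rng)
        self.head = Linear(2 * hidden, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = concatenate([self.fwd(x), self.bwd(x, reverse=True)], axis=1)
        return self.head(h).sigmoid().reshape(x.shape[0])

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        with no_grad():
            return self(Tensor(x)).data


@dataclass
class BiRNNHyper:
    hidden: int = 64
    epochs: int = 100
    lr: float = 1e-3
    batch: int = 32
    seed: int = 0


def train_birnn(x: np.ndarray, y: np.ndarray,
                hyper: BiRNNHyper | None = None) -> BiRNNClassifier:
    """Fit the classifier with binary cross-entropy on [N, L, K] sequences
    (clr scale recommended). Raises if only one class is present."""
    hyper = hyper or BiRNNHyper()
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    rng = np.random.default_rng(hyper.seed)
    model = BiRNNClassifier(x.shape[2], hyper.hidden, rng)
    opt = Adam(model.parameters(), lr=hyper.lr)
    N = x.shape[0]
    for _ in range(hyper.epochs):
        order = rng.permutation(N)
        for start in range(0, N, hyper.batch):
            idx = order[start:start + hyper.batch]
            p = model(Tensor(x[idx]))
            yt = Tensor(y[idx])
            eps = 1e-9
            loss = -(yt * (p + eps).log()
                     + (1.0 - yt) * (1.0 - p + eps).log()).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
    return model


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def _check_classes(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return labels


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability that a random positive outranks a random negative
    (ties count one half)."""
    labels = _check_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores)))


def pr_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve by trapezoidal integration."""
    labels = _check_classes(labels)
    precision, recall, _ = precision_recall_curve(labels, np.asarray(scores))
    return float(_auc(recall, precision))
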