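"""Classical per-feature time-series imputers used as comparators.

All three run on the clr scale, per subject and per feature, and operate on
the *age* axis (actual timepoint values), which matters for cohorts sampled
on a non-uniform grid.  Observed entries are never altered.
"""

from __future__ import annotations

import numpy as np

__all__ = ["linear_interpolation", "locf", "mean_impute", "impute_tensor",
           "BASELINES"]


def _check(series: np.ndarray, observed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    series = np.asarray(series, dtype=np.float64)
    observed = np.asarray(observed, dtype=bool)
    if series.shape != observed.shape:
        raise ValueError("series and observed flags must have equal length")
    if not observed.any():
        raise ValueError("no observed points")
    return series, observed


def linear_interpolation(series: np.ndarray, observed: np.ndarray,
                         ages: np.ndarray | None = None) -> np.ndarray:
    """Straight-line interpolation between nearest observed neighbours on the
    age axis; leading/trailing gaps take the nearest observed value."""
    series, observed = _check(series, observed)
    ages = np.arange(series.size, dtype=np.float64) if ages is None \
        else np.asarray(ages, dtype=np.float64)
    out = series.copy()
    gaps = ~observed
    # np.interp clamps outside the observed range = nearest-value fallback
    out[gaps] = np.interp(ages[gaps], ages[observed], series[observed])
    return out


def locf(series: np.ndarray, observed: np.ndarray,
         ages: np.ndarray | None = None) -> np.ndarray:
    """Last observation carried forward; leading gaps are back-filled with
    the first observed value."""
    series, observed = _check(series, observed)
    out = series.copy()
    last = series[observed][0]   # backward fill for leading gaps
    for l in range(series.size):
        if observed[l]:
            last = series[l]
        else:
            out[l] = last
    return out


def mean_impute(series: np.ndarray, observed: np.ndarray,
                ages: np.ndarray | None = None) -> np.ndarray:
    """Fill every gap with the subject's mean over observed values."""
    series, observed = _check(series, observed)
    out = series.copy()
    out[~observed] = series[observed].mean()
    return out


BASELINES = {
    "linear": linear_interpolation,
    "locf": locf,
    "mean": mean_impute,
}


def impute_tensor(values: np.ndarray, cond: np.ndarray, method: str,
                  ages: np.ndarray | None = None) -> np.ndarray:
    """Apply a baseline imputer feature-wise over a [S, L, K] clr tensor.

    ``cond`` is the [S, L] conditional (given) timepoint mask; all other
    timepoints are treated as gaps to fill.
    """
    fn = BASELINES.get(method)
    if fn is None:
        raise KeyError(f"unknown baseline {method!r}")
    values = np.asarray(values, dtype=np.float64)
    cond = np.asarray(cond, dtype=bool)
    S, L, K = values.shape
    out = values.copy()
    for s in range(S):
        obs = cond[s]
        if not obs.any():
            raise ValueError(f"subject {s} has no conditional timepoints")
        for k in range(K):
            out[s, :, k] = fn(values[s, :, k], obs, ages)
    # observed entries must pass through untouched
    out[cond] = values[cond]
    return out
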