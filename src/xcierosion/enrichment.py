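"""Hypergeometric enrichment of a protein subset for high-abundance /
high-peptide membership, with a uniform-resampling null.

The question: is a subset of proteins (e.g. those significantly increased
at the protein level without an mRNA increase) enriched for proteins above
the 75th percentile of copy number, or of Razor + unique peptide count,
relative to the detected universe?  The analytic answer is the
hypergeometric upper tail; the simulation answer redraws random subsets of
the same size from the universe and records how many members exceed the
threshold in each draw.

Membership uses ">= threshold" by default (with a strict ">" mode), and the
percentile is the linear-interpolation quantile — the thresholds this
yields are convention-dependent, which is why the convention is pinned.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .utils import substream


@dataclass
class EnrichmentConfig:
    percentile: float = 75.0
    n_iterations: int = 100_000
    strict_threshold: bool = False  # ">" instead of ">="
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.percentile < 100.0:
            raise ValueError("percentile must lie in (0, 100)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class EnrichmentResult:
    metric: str
    threshold: float
    universe_size: int
    subset_size: int
    n_above_in_universe: int
    observed_count: int
    expected_count: float
    hypergeom_p: float
    empirical_p: float
    null_mean: float
    null_sd: float
    null_quantiles: dict


def percentile_threshold(values, percentile: float) -> float:
    """Linear-interpolation quantile of the finite values."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("cannot take a percentile of an empty vector")
    return float(np.percentile(arr, percentile, method="linear"))


def hypergeom_sf(k_observed: int, K_successes: int, n_draws: int, N_universe: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K_successes <= N_universe and 0 <= n_draws <= N_universe):
        raise ValueError("inconsistent hypergeometric counts")
    if k_observed < 0:
        raise ValueError("k_observed must be >= 0")
    return float(stats.hypergeom.sf(k_observed - 1, N_universe, K_successes, n_draws))


def _null_counts(
    flags: np.ndarray, subset_size: int, n_iterations: int, rng: np.random.Generator
) -> np.ndarray:
    """Counts of flagged members in uniform subsets without replacement.

    Each iteration ranks the universe by independent uniform keys and takes
    the top ``subset_size`` — a uniform draw of a subset.  Batched to bound
    memory.
    """
    N = flags.size
    counts = np.empty(n_iterations, dtype=np.int64)
    batch = max(1, min(n_iterations, int(2e7) // max(N, 1)))
    done = 0
    while done < n_iterations:
        b = min(batch, n_iterations - done)
        keys = rng.random((b, N))
        idx = np.argpartition(keys, subset_size - 1, axis=1)[:, :subset_size]
        counts[done:done + b] = flags[idx].sum(axis=1)
        done += b
    return counts


def resample_null(
    membership_flags, subset_size: int, observed_count: int,
    config: EnrichmentConfig | None = None, metric: str = "",
    threshold: float = np.nan, rng: np.random.Generator | None = None,
) -> EnrichmentResult:
    """Resampling null for the above-threshold count of a random subset.

    ``membership_flags`` marks, over the detected universe, the proteins at
    or above the threshold.  The add-one estimator
    (1 + #{draws >= observed}) / (n_iterations + 1) never returns an exact
    zero.  Deterministic given the config seed.
    """
    config = config or EnrichmentConfig()
    flags = np.asarray(membership_flags, dtype=bool)
    N = flags.size
    K = int(flags.sum())
    if subset_size > N:
        raise ValueError(f"subset_size {subset_size} exceeds universe size {N}")
    if rng is None:
        rng = substream(config.seed, "enrichment_null")
    null = _null_counts(flags, subset_size, config.n_iterations, rng)
    empirical_p = (1.0 + np.sum(null >= observed_count)) / (config.n_iterations + 1.0)
    qs = np.percentile(null, [2.5, 25, 50, 75, 97.5])
    return EnrichmentResult(
        metric=metric,
        threshold=float(threshold),
        universe_size=N,
        subset_size=int(subset_size),
        n_above_in_universe=K,
        observed_count=int(observed_count),
        expected_count=subset_size * K / N,
        hypergeom_p=hypergeom_sf(observed_count, K, subset_size, N),
        empirical_p=float(empirical_p),
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if len(null) > 1 else 0.0,
        null_quantiles={"q2.5": qs[0], "q25": qs[1], "median": qs[2], "q75": qs[3], "q97.5": qs[4]},
    )


def enrichment_analysis(
    metric_values: pd.Series,
    subset_ids,
    config: EnrichmentConfig | None = None,
    metric_name: str = "",
) -> EnrichmentResult:
    """End-to-end enrichment: threshold the universe metric at the
    configured percentile, count subset members above it, and compare the
    hypergeometric p with the resampling null."""
    config = config or EnrichmentConfig()
    universe = metric_values.dropna()
    subset = [s for s in subset_ids if s in universe.index]
    if not subset:
        raise ValueError("subset has no members in the universe")
    thr = percentile_threshold(universe.to_numpy(), config.percentile)
    if config.strict_threshold:
        flags = universe.to_numpy() > thr
    else:
        flags = universe.to_numpy() >= thr
    member = pd.Series(flags, index=universe.index)
    observed = int(member[subset].sum())
    return resample_null(
        flags, len(subset), observed, config=config,
        metric=metric_name or str(metric_values.name), threshold=thr,
    )
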