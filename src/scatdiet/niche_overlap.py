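"""Pianka's niche overlap with a breadth-retaining randomization null.

The null model permutes each utilization vector's entries independently
across resource categories (zeros included), so the multiset of utilization
values — and hence each species' niche breadth — is conserved exactly.
Observed-value uncertainty comes from a scat bootstrap: scats are resampled
with replacement within each species and the metric profile and overlap are
recomputed per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .data_model_io import OverlapResult, ScatComposition
from .diet_metrics import compute_foo, compute_wpoo

__all__ = [
    "pianka",
    "densify",
    "null_distribution",
    "bootstrap_ci",
    "overlap_analysis",
]


def densify(
    p: Mapping[str, float], q: Mapping[str, float]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Align two sparse utilization mappings over their union support."""
    union = sorted(set(p) | set(q))
    pv = np.array([p.get(t, 0.0) for t in union], dtype=float)
    qv = np.array([q.get(t, 0.0) for t in union], dtype=float)
    return pv, qv, union


def _as_vectors(p, q) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(p, Mapping) or isinstance(q, Mapping):
        if not (isinstance(p, Mapping) and isinstance(q, Mapping)):
            raise TypeError("p and q must both be mappings or both be vectors")
        pv, qv, _ = densify(p, q)
        return pv, qv
    pv = np.asarray(p, dtype=float)
    qv = np.asarray(q, dtype=float)
    if pv.shape != qv.shape:
        raise ValueError(f"utilization vectors differ in length: {pv.shape} vs {qv.shape}")
    return pv, qv


def pianka(p, q) -> float:
    """Pianka's overlap O = Σ p_i q_i / sqrt(Σ p_i² Σ q_i²), in [0, 1].

    Scale-invariant in each argument, so raw FOO vectors (which need not sum
    to one) and normalized vectors give identical overlap.
    """
    pv, qv = _as_vectors(p, q)
    if (pv < 0).any() or (qv < 0).any():
        raise ValueError("utilization vectors must be nonnegative")
    denom = np.sqrt((pv**2).sum() * (qv**2).sum())
    if denom == 0:
        raise ValueError("utilization vectors must have positive sum")
    return float(np.clip((pv * qv).sum() / denom, 0.0, 1.0))


@dataclass
class NullSummary:
    null_mean: float
    null_ci: tuple[float, float]
    p_value: float
    samples: np.ndarray


def null_distribution(
    p, q, n_iterations: int = 10000, seed: int | np.random.Generator = 0
) -> NullSummary:
    """Monte-Carlo null distribution of Pianka under within-vector permutation.

    Each iteration independently permutes p's and q's entries across the
    resource categories and records the overlap of the permuted pair.  The
    one-tailed p-value uses the add-one estimator
    ``(1 + #{null >= observed}) / (n_iterations + 1)``.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    pv, qv = _as_vectors(p, q)
    observed = pianka(pv, qv)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    p_norm2 = float((pv**2).sum())
    q_norm2 = float((qv**2).sum())
    denom = np.sqrt(p_norm2 * q_norm2)
    samples = np.empty(n_iterations)
    for i in range(n_iterations):
        pp = rng.permutation(pv)
        qq = rng.permutation(qv)
        samples[i] = (pp * qq).sum() / denom
    samples = np.clip(samples, 0.0, 1.0)
    lo, hi = np.percentile(samples, [2.5, 97.5])
    p_value = (1 + int((samples >= observed - 1e-12).sum())) / (n_iterations + 1)
    return NullSummary(
        null_mean=float(samples.mean()),
        null_ci=(float(lo), float(hi)),
        p_value=float(p_value),
        samples=samples,
    )


def bootstrap_ci(
    compositions_a: Sequence[ScatComposition],
    compositions_b: Sequence[ScatComposition],
    metric: str = "wpoo",
    n_boot: int = 10000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Percentile CI for observed overlap from a within-species scat bootstrap.

    Bootstrap replicates in which a species' resample ends up with empty
    support are discarded (and counted in the log); with one scat per species
    the interval degenerates to the observed value.
    """
    if not compositions_a or not compositions_b:
        raise ValueError("need at least one scat per species")
    if metric not in ("foo", "wpoo"):
        raise ValueError(f"metric must be 'foo' or 'wpoo', got {metric!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    profile_fn = compute_foo if metric == "foo" else compute_wpoo

    values = []
    n_a, n_b = len(compositions_a), len(compositions_b)
    for _ in range(n_boot):
        sample_a = [compositions_a[i] for i in rng.integers(0, n_a, n_a)]
        sample_b = [compositions_b[i] for i in rng.integers(0, n_b, n_b)]
        pa, pb = profile_fn(sample_a), profile_fn(sample_b)
        if not pa or not pb:
            continue
        values.append(pianka(pa, pb))
    if not values:
        raise ValueError("all bootstrap replicates had empty support")
    lo, hi = np.percentile(values, [2.5, 97.5])
    return float(lo), float(hi)


def overlap_analysis(
    compositions_a: Sequence[ScatComposition],
    compositions_b: Sequence[ScatComposition],
    metric: str = "wpoo",
    n_iterations: int = 10000,
    n_boot: int = 10000,
    seed: int = 0,
) -> OverlapResult:
    """Observed Pianka overlap with bootstrap CI and permutation null."""
    profile_fn = compute_foo if metric == "foo" else compute_wpoo
    pa, pb = profile_fn(compositions_a), profile_fn(compositions_b)
    observed = pianka(pa, pb)
    rng = np.random.default_rng(seed)
    null = null_distribution(pa, pb, n_iterations=n_iterations, seed=rng)
    ci = bootstrap_ci(
        compositions_a, compositions_b, metric=metric, n_boot=n_boot, seed=rng
    )
    return OverlapResult(
        metric=metric,
        o_observed=observed,
        observed_ci=ci,
        null_mean=null.null_mean,
        null_ci=null.null_ci,
        p_value=null.p_value,
        n_iterations=n_iterations,
        seed=seed,
    )
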