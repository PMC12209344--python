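"""Incidence-based rarefaction, extrapolation and the Chao2 richness estimator.

The sampling unit is the scat.  Interpolated expected richness at t units is

    S(t) = sum_i [ 1 - C(T - Y_i, t) / C(T, t) ]

with C(a, b) = 0 when a < b; extrapolation beyond T uses the Chao2 estimate
of undetected richness.  Binomial coefficients are evaluated in log space so
large T cannot overflow.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .data_model_io import (
    IncidenceFrequencies,
    RarefactionCurve,
    ScatComposition,
    ScatStatus,
)

__all__ = [
    "incidence_frequencies",
    "rarefy_interpolate",
    "chao2",
    "extrapolate",
    "rarefaction_curve",
]


def incidence_frequencies(compositions: Sequence[ScatComposition]) -> IncidenceFrequencies:
    """Count, per taxon, the number of scats containing it."""
    if not compositions:
        raise ValueError("need at least one assigned scat")
    for comp in compositions:
        if comp.status is not ScatStatus.ASSIGNED:
            raise ValueError(f"scat {comp.scat_id!r} is not assigned")
    y: dict[str, int] = {}
    for comp in compositions:
        for taxon in comp.diet_items:
            y[taxon] = y.get(taxon, 0) + 1
    return IncidenceFrequencies(T=len(compositions), Y=y)


def _log_choose_ratio(a: int, t: int, T: int) -> float:
    """log[ C(a, t) / C(T, t) ] for 0 <= t <= a <= T."""
    return (
        gammaln(a + 1)
        - gammaln(a - t + 1)
        - gammaln(T + 1)
        + gammaln(T - t + 1)
    )


def rarefy_interpolate(freqs: IncidenceFrequencies, t: int) -> float:
    """Expected richness in a random subset of t of the T sampling units."""
    T = freqs.T
    if not (1 <= t <= T):
        raise ValueError(f"t must be in 1..{T} for interpolation, got {t}")
    s = 0.0
    for y in freqs.Y.values():
        a = T - y
        if a < t:
            s += 1.0  # C(T-Y_i, t) = 0: taxon always present
        else:
            s += 1.0 - math.exp(_log_choose_ratio(a, t, T))
    return s


def chao2(freqs: IncidenceFrequencies) -> tuple[float, float]:
    """Chao2 asymptotic richness; returns (estimate, undetected Q0_hat).

    Uses the classic form Q1²/(2 Q2) when Q2 > 0 and the bias-corrected form
    Q1 (Q1 - 1) / (2 (Q2 + 1)) otherwise, both with the (T-1)/T correction.
    """
    T = freqs.T
    if T < 2:
        raise ValueError("Chao2 requires at least 2 sampling units")
    q1, q2 = freqs.q1, freqs.q2
    if q2 > 0:
        q0_hat = (T - 1) / T * q1**2 / (2 * q2)
    else:
        q0_hat = (T - 1) / T * q1 * (q1 - 1) / (2 * (q2 + 1))
    return freqs.s_obs + q0_hat, q0_hat


def extrapolate(freqs: IncidenceFrequencies, t_star: int) -> float:
    """Expected richness t_star units beyond the observed T."""
    if t_star < 0:
        raise ValueError("t_star must be nonnegative")
    s_obs = freqs.s_obs
    _, q0_hat = chao2(freqs)
    if q0_hat == 0:
        return float(s_obs)
    q1 = freqs.q1
    rate = q1 / (q1 + freqs.T * q0_hat)
    return s_obs + q0_hat * (1.0 - (1.0 - rate) ** t_star)


def _richness_grid(freqs: IncidenceFrequencies, t_grid: Sequence[int]) -> list[float]:
    return [
        rarefy_interpolate(freqs, t) if t <= freqs.T else extrapolate(freqs, t - freqs.T)
        for t in t_grid
    ]


def rarefaction_curve(
    compositions: Sequence[ScatComposition],
    t_grid: Sequence[int] | None = None,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> RarefactionCurve:
    """Full interpolated/extrapolated curve with scat-bootstrap CI bands.

    Defaults to a grid of 1..2T.  CI bands resample scats with replacement
    and take the 2.5/97.5 percentiles of the recomputed curves.
    """
    freqs = incidence_frequencies(compositions)
    T = freqs.T
    if t_grid is None:
        t_grid = list(range(1, 2 * T + 1))
    t_grid = [int(t) for t in t_grid]
    if not t_grid:
        raise ValueError("t_grid must be nonempty")
    if min(t_grid) < 1:
        raise ValueError("t_grid entries must be >= 1")

    s_hat = _richness_grid(freqs, t_grid)
    est, q0_hat = chao2(freqs) if T >= 2 else (float(freqs.s_obs), 0.0)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    boot = np.empty((n_boot, len(t_grid)))
    comps = list(compositions)
    for b in range(n_boot):
        resample = [comps[i] for i in rng.integers(0, T, T)]
        bfreqs = incidence_frequencies(resample)
        # grid positions beyond the resample's T extrapolate from its own Chao2
        boot[b] = _richness_grid(bfreqs, t_grid)
    lo, hi = np.percentile(boot, [2.5, 97.5], axis=0)
    ci = [(float(a), float(b)) for a, b in zip(lo, hi)]

    return RarefactionCurve(
        T=T,
        t_grid=list(t_grid),
        s_hat=s_hat,
        ci=ci,
        chao2=est,
        q0_hat=q0_hat,
    )
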