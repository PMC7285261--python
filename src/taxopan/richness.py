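"""Cluster-richness rarefaction and extrapolation with Chao-type correction.

Each genome is one sampling unit belonging to exactly one cluster
(species or phylogenomic group), so cluster sizes form an abundance
vector.  Expected richness at a smaller sample size is hypergeometric
rarefaction; beyond the observed sample size it is extrapolated with the
Chao1 estimate of unseen clusters.  Percentile bootstrap bands quantify
sampling uncertainty.

Notation: ``n`` genomes, ``S_obs`` observed clusters, ``f1``/``f2`` the
numbers of clusters seen in exactly one / exactly two genomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .clustering import Partition

__all__ = [
    "AbundanceVector",
    "ChaoEstimate",
    "RarefactionCurve",
    "partition_to_abundance",
    "interpolate",
    "chao_unseen",
    "extrapolate",
    "richness_estimate",
    "bootstrap_band",
    "read_abundance",
]


@dataclass(frozen=True)
class AbundanceVector:
    """Cluster sizes (genomes per cluster), the unit of richness analysis."""

    x: tuple[int, ...]

    def __post_init__(self) -> None:
        x = tuple(int(v) for v in self.x)
        if not x:
            raise ValueError("abundance vector is empty")
        if any(v < 1 for v in x):
            raise ValueError("all cluster sizes must be >= 1")
        object.__setattr__(self, "x", x)

    @property
    def n(self) -> int:
        """Total genomes sampled."""
        return sum(self.x)

    @property
    def s_obs(self) -> int:
        """Observed number of clusters."""
        return len(self.x)

    @property
    def f1(self) -> int:
        """Singleton clusters (size exactly 1)."""
        return sum(1 for v in self.x if v == 1)

    @property
    def f2(self) -> int:
        """Doubleton clusters (size exactly 2)."""
        return sum(1 for v in self.x if v == 2)


@dataclass(frozen=True)
class ChaoEstimate:
    """Chao1 unseen-cluster estimate ``f0`` and asymptotic total richness."""

    f0: float
    total: float


@dataclass(frozen=True)
class RarefactionCurve:
    """Point estimates and bootstrap band of expected cluster richness."""

    m: np.ndarray = field(repr=False)
    estimate: np.ndarray = field(repr=False)
    ci_lo: np.ndarray = field(repr=False)
    ci_hi: np.ndarray = field(repr=False)
    regime: tuple[str, ...]
    n_boot: int
    level: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "m": self.m,
                "estimate": self.estimate,
                "ci_lo": self.ci_lo,
                "ci_hi": self.ci_hi,
                "regime": list(self.regime),
            }
        )


def partition_to_abundance(p: Partition) -> AbundanceVector:
    """Cluster sizes of a partition, order irrelevant."""
    return AbundanceVector(tuple(sorted(p.sizes(), reverse=True)))


def _log_choose(a: np.ndarray, b: float) -> np.ndarray:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def interpolate(x: AbundanceVector, m: int) -> float:
    """Expected clusters in a random subsample of ``m`` of the n genomes.

    ``S(m) = S_obs - sum_i C(n - x_i, m) / C(n, m)`` evaluated in
    log-space; S(n) = S_obs and S(1) = 1 because the clusters partition
    the genomes.
    """
    n = x.n
    if not 1 <= m <= n:
        raise ValueError(f"m must lie in [1, {n}], got {m}")
    xi = np.array(x.x)
    keep = (n - xi) >= m
    if not keep.any():
        return float(x.s_obs)
    absent = np.exp(_log_choose((n - xi[keep]).astype(float), m) - _log_choose(float(n), m))
    return float(x.s_obs - absent.sum())


def chao_unseen(x: AbundanceVector) -> ChaoEstimate:
    """Chao1 estimate of the number of unseen clusters.

    Uses ``f0 = ((n-1)/n) f1^2 / (2 f2)`` when doubletons exist and the
    bias-corrected ``((n-1)/n) f1 (f1 - 1) / (2 (f2 + 1))`` otherwise.
    """
    n, f1, f2 = x.n, x.f1, x.f2
    if f2 > 0:
        f0 = (n - 1) / n * f1**2 / (2 * f2)
    else:
        f0 = (n - 1) / n * f1 * (f1 - 1) / (2 * (f2 + 1))
    return ChaoEstimate(f0=float(f0), total=float(x.s_obs + f0))


def extrapolate(x: AbundanceVector, m: int) -> float:
    """Expected clusters when sampling is extended to ``m > n`` genomes.

    ``S(n + m*) = S_obs + f0 [1 - (1 - f1 / (n f0 + f1))^{m*}]`` with
    ``m* = m - n``; continuous at ``m = n`` and saturating at
    ``S_obs + f0``.
    """
    n = x.n
    if m <= n:
        raise ValueError(f"extrapolation requires m > n = {n}, got {m}")
    f0 = chao_unseen(x).f0
    f1 = x.f1
    if f1 == 0 or f0 == 0:
        warnings.warn(
            "no singleton clusters: extrapolated richness is flat at S_obs",
            stacklevel=2,
        )
        return float(x.s_obs)
    mstar = m - n
    return float(x.s_obs + f0 * (1.0 - (1.0 - f1 / (n * f0 + f1)) ** mstar))


def richness_estimate(x: AbundanceVector, m: int) -> float:
    """Expected clusters at any sample size (interpolated or extrapolated)."""
    if m <= x.n:
        return interpolate(x, m)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return extrapolate(x, m)


def _bootstrap_probabilities(x: AbundanceVector) -> np.ndarray:
    """Cell probabilities of the bootstrap assemblage.

    Observed clusters keep their relative abundances scaled by the
    estimated sample coverage; the unseen probability mass is split
    equally over ``ceil(f0)`` extra clusters.
    """
    n, f1, f2 = x.n, x.f1, x.f2
    f0 = chao_unseen(x).f0
    if f1 > 0:
        coverage = 1.0 - (f1 / n) * ((n - 1) * f1 / ((n - 1) * f1 + 2 * f2))
    else:
        coverage = 1.0
    xi = np.array(x.x, dtype=float)
    seen = coverage * xi / n
    n_unseen = int(ceil(f0)) if f0 > 0 else 0
    if n_unseen == 0:
        return seen / seen.sum()
    unseen = np.full(n_unseen, (1.0 - coverage) / n_unseen)
    p = np.concatenate([seen, unseen])
    return p / p.sum()


def bootstrap_band(
    x: AbundanceVector,
    m_grid: np.ndarray | list[int],
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> RarefactionCurve:
    """Percentile bootstrap band for the richness curve on ``m_grid``.

    Each replicate resamples ``n`` genomes from the bootstrap assemblage
    (observed clusters plus Chao-estimated unseen ones) and recomputes
    the full interpolation/extrapolation curve.  Deterministic under
    ``seed``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    m_grid = np.asarray(m_grid, dtype=int)
    if (m_grid < 1).any():
        raise ValueError("all m must be >= 1")
    n = x.n
    rng = np.random.default_rng(seed)
    probs = _bootstrap_probabilities(x)
    curves = np.empty((n_boot, m_grid.size))
    for b in range(n_boot):
        counts = rng.multinomial(n, probs)
        xb = AbundanceVector(tuple(int(c) for c in counts if c > 0))
        curves[b] = [richness_estimate(xb, int(m)) for m in m_grid]
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(curves, alpha, axis=0)
    hi = np.quantile(curves, 1.0 - alpha, axis=0)
    point = np.array([richness_estimate(x, int(m)) for m in m_grid])
    regime = tuple(
        "observed" if m == n else ("interpolated" if m < n else "extrapolated")
        for m in m_grid
    )
    return RarefactionCurve(
        m=m_grid,
        estimate=point,
        ci_lo=np.minimum(lo, point),
        ci_hi=np.maximum(hi, point),
        regime=regime,
        n_boot=n_boot,
        level=level,
    )


def read_abundance(path: str | Path) -> AbundanceVector:
    """Read an abundance TSV: one cluster size per line (optional header)."""
    sizes: list[int] = []
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        tok = ln.strip()
        if not tok:
            continue
        if lineno == 1 and not tok.lstrip("-").isdigit():
            continue
        sizes.append(int(tok))
    return AbundanceVector(tuple(sizes))
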