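"""Spearman correlations and their subsampling-based standard errors.

The variance of a pairwise Spearman correlation within one condition is
estimated by recomputing the correlation on many small subsamples of the
N samples and taking the standard error of the mean of those values.  So
that the subsample correlations are as close to independent as possible,
the subsamples are *pair-unique*: no two samples ever co-occur in more
than one subsample.  The deterministic greedy construction is:

1. order the samples 1..N;
2. first pass: consecutive disjoint blocks of size n (1..n, n+1..2n, ...);
3. for each initiating point n* = 1..N, grow a subsample starting from
   {n*} by scanning the samples in order and adding any sample that has
   never co-occurred with a current member, emitting the subsample
   whenever it reaches size n and restarting from the same n*;
4. advance n* when no further full subsample can be formed; stop after
   n* = N.  Incomplete subsamples are discarded.

A subsample size near sqrt(N) maximises the number of subsamples; sizes
below 7 make the per-subsample Spearman coarse, so the default is
``max(7, floor(sqrt(N)))`` and fewer than 49 samples triggers a warning.
When a condition has too few samples for subsampling, sigma may instead
be set to a constant fallback (0, or 1 when neither condition can be
subsampled).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SubsampleDesign",
    "PairCorrelations",
    "rank_transform",
    "spearman_rho",
    "generate_subsample_design",
    "default_subsample_size",
    "pair_correlation_profile",
    "expected_spurious_perfect_correlations",
    "RECOMMENDED_MIN_SAMPLES",
]

#: below this many samples the subsample SEM becomes unreliable
RECOMMENDED_MIN_SAMPLES = 49


@dataclass(frozen=True)
class SubsampleDesign:
    """Pair-unique subsamples of size n drawn from N ordered samples.

    ``subsamples`` holds 0-based index tuples; any unordered pair of
    indices co-occurs in at most one subsample.
    """

    N: int
    n: int
    subsamples: tuple[tuple[int, ...], ...]

    @property
    def m(self) -> int:
        """Number of subsamples."""
        return len(self.subsamples)

    def validate(self) -> None:
        """Assert the defining pair-uniqueness property (used in tests)."""
        seen: set[tuple[int, int]] = set()
        for sub in self.subsamples:
            if len(set(sub)) != self.n:
                raise AssertionError(f"subsample {sub} is not {self.n} "
                                     "distinct indices")
            for i, a in enumerate(sub):
                for b in sub[i + 1:]:
                    pair = (a, b) if a < b else (b, a)
                    if pair in seen:
                        raise AssertionError(f"pair {pair} co-occurs twice")
                    seen.add(pair)


def rank_transform(x: np.ndarray) -> np.ndarray:
    """Ranks 1..len(x) with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to rank")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite value in rank input")
    return stats.rankdata(x, method="average")


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman correlation: Pearson correlation of the rank vectors.

    Returns NaN (the undefined marker) when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    rx = rank_transform(x)
    ry = rank_transform(y)
    sx = rx - rx.mean()
    sy = ry - ry.mean()
    vx = float(sx @ sx)
    vy = float(sy @ sy)
    if vx == 0.0 or vy == 0.0:
        return float("nan")
    return float(np.clip((sx @ sy) / math.sqrt(vx * vy), -1.0, 1.0))


def default_subsample_size(N: int) -> int:
    """floor(sqrt(N)) clipped to at least 7 (and at most N)."""
    return min(max(7, int(math.isqrt(N))), N)


def generate_subsample_design(N: int, n: int) -> SubsampleDesign:
    """Build the deterministic pair-unique subsample design for (N, n).

    See the module docstring for the algorithm.  For example, N=100 with
    n=8 starts with the 12 disjoint blocks 1-8, 9-16, ..., 89-96 before
    the greedy passes add cross-block subsamples.
    """
    if n < 2:
        raise ValueError(f"subsample size must be >= 2, got {n}")
    if n > N:
        raise ValueError(f"subsample size {n} exceeds sample count {N}")

    used = np.zeros((N, N), dtype=bool)  # symmetric pair-used matrix
    subsamples: list[tuple[int, ...]] = []

    def emit(members: list[int]) -> None:
        arr = np.array(members)
        used[np.ix_(arr, arr)] = True
        subsamples.append(tuple(members))

    # first pass: consecutive disjoint blocks; remainder points are left
    # for the greedy passes
    for start in range(0, N - n + 1, n):
        emit(list(range(start, start + n)))

    # greedy passes from each initiating point
    for init in range(N):
        while True:
            current = [init]
            for cand in range(N):
                if cand == init:
                    continue
                if not used[cand, current].any():
                    current.append(cand)
                    if len(current) == n:
                        break
            if len(current) == n:
                emit(current)
            else:
                break  # no full subsample from this initiating point

    return SubsampleDesign(N=N, n=n, subsamples=tuple(subsamples))


@dataclass
class PairCorrelations:
    """Full-sample Spearman rho and subsample SEM sigma for every gene pair.

    ``rho`` and ``sigma`` are symmetric (n_genes x n_genes) arrays; the
    diagonal is meaningless and set to NaN.  Pairs involving a gene that
    is constant over the full sample carry NaN rho and are excluded from
    scoring downstream.
    """

    condition_label: str
    gene_ids: list[str]
    rho: np.ndarray
    sigma: np.ndarray
    n_subsamples: int
    subsample_size: int
    subsampling_used: bool

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def _rank_correlation_matrix(values: np.ndarray) -> np.ndarray:
    """All-pairs Spearman correlation of the rows of a gene x sample block.

    Rows that are constant get NaN against every partner.
    """
    ranks = stats.rankdata(values, axis=1, method="average")
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    constant = norms == 0
    norms[constant] = 1.0
    unit = centered / norms[:, None]
    corr = unit @ unit.T
    np.clip(corr, -1.0, 1.0, out=corr)
    corr[constant, :] = np.nan
    corr[:, constant] = np.nan
    return corr


def pair_correlation_profile(m: ExpressionMatrix,
                             design: SubsampleDesign | None,
                             sigma_fallback: float = 0.0) -> PairCorrelations:
    """Compute rho (full sample) and sigma (subsample SEM) per gene pair.

    sigma for a pair is the sample standard deviation (denominator m-1)
    of its per-subsample Spearman values, divided by sqrt(m), where m
    counts the subsamples on which the value is defined (neither gene
    constant within the subsample).  Pairs with fewer than two defined
    values, and all pairs when ``design`` is None, get ``sigma_fallback``.
    """
    if sigma_fallback < 0:
        raise ValueError("sigma_fallback must be non-negative")
    if m.n_samples < RECOMMENDED_MIN_SAMPLES:
        logger.warning(
            "%s: %d samples is below the recommended minimum of %d for "
            "reliable subsample standard errors",
            m.condition_label or "condition", m.n_samples,
            RECOMMENDED_MIN_SAMPLES)

    P = m.n_genes
    rho = _rank_correlation_matrix(m.values)
    np.fill_diagonal(rho, np.nan)

    if design is None:
        sigma = np.full((P, P), float(sigma_fallback))
        np.fill_diagonal(sigma, np.nan)
        return PairCorrelations(m.condition_label, list(m.gene_ids), rho,
                                sigma, 0, 0, False)

    if design.N != m.n_samples:
        raise ValueError(f"design built for N={design.N} but matrix has "
                         f"{m.n_samples} samples")
    if design.m < 2:
        raise ValueError("need at least 2 subsamples for a standard error")

    # streaming moments over subsamples to avoid an (m, P, P) stack
    count = np.zeros((P, P))
    total = np.zeros((P, P))
    total_sq = np.zeros((P, P))
    for sub in design.subsamples:
        r = _rank_correlation_matrix(m.values[:, list(sub)])
        ok = np.isfinite(r)
        r = np.where(ok, r, 0.0)
        count += ok
        total += r
        total_sq += r * r

    with np.errstate(invalid="ignore", divide="ignore"):
        mean = total / count
        var = (total_sq - count * mean ** 2) / (count - 1)
        var = np.maximum(var, 0.0)  # guard tiny negative round-off
        sigma = np.sqrt(var) / np.sqrt(count)
    sigma[count < 2] = sigma_fallback
    np.fill_diagonal(sigma, np.nan)

    return PairCorrelations(m.condition_label, list(m.gene_ids), rho, sigma,
                            design.m, design.n, True)


def expected_spurious_perfect_correlations(n_genes: int,
                                           n_samples: int) -> float:
    """Expected count of spuriously perfect Spearman correlations.

    Two uncorrelated length-N sequences have probability 1/N! of a
    perfect rank agreement, so among G genes one expects
    G(G-1)/(2 N!) perfect correlations by chance — e.g. about 12 for
    1000 genes with 8 samples each.  A caution against tiny N.
    """
    if n_genes < 2 or n_samples < 1:
        raise ValueError("need at least 2 genes and 1 sample")
    pairs = n_genes * (n_genes - 1) / 2.0
    return pairs / math.factorial(n_samples)
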