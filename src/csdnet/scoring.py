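"""C/S/D gene-pair scores, sampled-maxima cutoffs, and link classification.

For a gene pair with Spearman correlations rho1, rho2 in the two
conditions and subsample standard errors sigma1, sigma2, with
d = sqrt(sigma1^2 + sigma2^2):

    C = |rho1 + rho2| / d                      (conserved)
    S = ||rho1| - |rho2|| / d                  (specific)
    D = (|rho1| + |rho2| - |rho1 + rho2|) / d  (differentiated)

C is large when both correlations are strong with the same sign, S when
only one is strong, and D when both are strong with opposite signs.  The
three scores follow very different distributions, so fixed cutoffs are
not comparable across them.  Instead, each score's cutoff X_p is the
average of the maxima of m random draws of size L from its own empirical
distribution; the shared importance level is p = 1/L.  This p ranks
scores on a common scale — it is not a significance level against any
null hypothesis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdSet",
    "csd_scores",
    "score_pairs",
    "sample_max_threshold",
    "determine_thresholds",
    "classify_pairs",
    "DEFAULT_L",
    "DEFAULT_DRAWS",
]

DEFAULT_L = 100_000  # draw size; importance level p = 1/L = 1e-5
DEFAULT_DRAWS = 100

SCORE_COLUMNS = ["gene_a", "gene_b", "rho1", "sigma1", "rho2", "sigma2",
                 "C", "S", "D"]


@dataclass(frozen=True)
class ThresholdSet:
    """Cutoffs X_C, X_S, X_D at a common importance level p = 1/L."""

    X_C: float
    X_S: float
    X_D: float
    L: int
    m: int
    seed: int

    @property
    def p(self) -> float:
        return 1.0 / self.L

    def cutoff(self, score_type: str) -> float:
        return {"C": self.X_C, "S": self.X_S, "D": self.X_D}[score_type]


def csd_scores(rho1, rho2, sigma1, sigma2):
    """Compute (C, S, D) for scalars or broadcastable arrays.

    A zero denominator (both sigmas zero for a pair, e.g. when
    subsampling was impossible in both conditions and the fallback sigma
    is 0) is replaced by 1 so that the scores degrade to the plain
    numerators.
    """
    rho1 = np.asarray(rho1, dtype=float)
    rho2 = np.asarray(rho2, dtype=float)
    sigma1 = np.asarray(sigma1, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    for name, arr in (("rho1", rho1), ("rho2", rho2),
                      ("sigma1", sigma1), ("sigma2", sigma2)):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite {name}")
    if np.any(np.abs(rho1) > 1 + 1e-12) or np.any(np.abs(rho2) > 1 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    if np.any(sigma1 < 0) or np.any(sigma2 < 0):
        raise ValueError("standard errors must be non-negative")

    d = np.sqrt(sigma1 ** 2 + sigma2 ** 2)
    d = np.where(d == 0, 1.0, d)
    abs_sum = np.abs(rho1 + rho2)
    C = abs_sum / d
    S = np.abs(np.abs(rho1) - np.abs(rho2)) / d
    D = (np.abs(rho1) + np.abs(rho2) - abs_sum) / d
    if C.ndim == 0:
        return float(C), float(S), float(D)
    return C, S, D


def score_pairs(pc1, pc2) -> pd.DataFrame:
    """Score every gene pair from two per-condition correlation profiles.

    Both profiles must cover the same genes in the same order (use
    ``align_matrices`` upstream).  Pairs where either condition's
    correlation is undefined (a constant gene) are dropped with a logged
    count.  Returns a DataFrame with columns gene_a, gene_b (a < b),
    rho1, sigma1, rho2, sigma2, C, S, D.
    """
    if pc1.gene_ids != pc2.gene_ids:
        raise ValueError("correlation profiles cover different gene sets; "
                         "align the matrices first")
    genes = np.array(pc1.gene_ids)
    P = len(genes)
    iu, ju = np.triu_indices(P, k=1)
    rho1 = pc1.rho[iu, ju]
    rho2 = pc2.rho[iu, ju]
    sigma1 = pc1.sigma[iu, ju]
    sigma2 = pc2.sigma[iu, ju]

    ok = np.isfinite(rho1) & np.isfinite(rho2)
    dropped = int((~ok).sum())
    if dropped:
        logger.info("score_pairs: dropped %d pairs with undefined "
                    "correlations (constant genes)", dropped)
    iu, ju = iu[ok], ju[ok]
    rho1, rho2, sigma1, sigma2 = rho1[ok], rho2[ok], sigma1[ok], sigma2[ok]

    C, S, D = csd_scores(rho1, rho2, sigma1, sigma2)
    a = genes[iu]
    b = genes[ju]
    swap = a > b
    a2 = np.where(swap, b, a)
    b2 = np.where(swap, a, b)
    return pd.DataFrame({
        "gene_a": a2, "gene_b": b2,
        "rho1": rho1, "sigma1": sigma1,
        "rho2": rho2, "sigma2": sigma2,
        "C": C, "S": S, "D": D,
    })


def sample_max_threshold(scores, L: int, m: int = DEFAULT_DRAWS,
                         seed: int = 0, replace: bool = False) -> float:
    """Average of the maxima of m draws of size L from a score list.

    Draws are without replacement within a draw by default (different
    draws may overlap); deterministic given the seed.
    """
    scores = np.asarray(scores, dtype=float)
    M = scores.size
    if M == 0:
        raise ValueError("empty score list")
    if L < 1:
        raise ValueError("draw size must be >= 1")
    if not replace and L > M:
        raise ValueError(f"draw size {L} exceeds the {M} available scores")
    if m < 1:
        raise ValueError("need at least one draw")
    rng = np.random.default_rng(seed)
    maxima = np.empty(m)
    for i in range(m):
        idx = rng.choice(M, size=L, replace=replace)
        maxima[i] = scores[idx].max()
    return float(maxima.mean())


def determine_thresholds(score_table: pd.DataFrame, L: int = DEFAULT_L,
                         m: int = DEFAULT_DRAWS, seed: int = 0,
                         replace: bool = False) -> ThresholdSet:
    """Sampled-maxima cutoffs for the C, S and D score distributions.

    The three distributions are summarised to the log (they have
    noticeably different locations and spreads, which is why a common
    fixed cutoff would not work).
    """
    cut = {}
    for i, col in enumerate(("C", "S", "D")):
        values = score_table[col].to_numpy()
        logger.info("%s-score distribution: n=%d mean=%.4g median=%.4g "
                    "sd=%.4g max=%.4g", col, values.size, values.mean(),
                    np.median(values), values.std(ddof=1), values.max())
        cut[col] = sample_max_threshold(values, L=L, m=m, seed=seed + i,
                                        replace=replace)
    return ThresholdSet(X_C=cut["C"], X_S=cut["S"], X_D=cut["D"],
                        L=L, m=m, seed=seed)


def classify_pairs(score_table: pd.DataFrame,
                   th: ThresholdSet) -> pd.DataFrame:
    """Assign each above-cutoff pair a single link type.

    A pair exceeding several cutoffs (possible at permissive importance
    levels) is assigned the type with the largest score/cutoff ratio,
    which is invariant to rescaling the thresholds; the multi-hit count
    is logged.  Returns columns gene_a, gene_b, type, score, rho1, rho2.
    """
    ratios = np.column_stack([
        score_table["C"].to_numpy() / th.X_C,
        score_table["S"].to_numpy() / th.X_S,
        score_table["D"].to_numpy() / th.X_D,
    ])
    hits = ratios > 1.0
    n_hits = hits.sum(axis=1)
    multi = int((n_hits > 1).sum())
    if multi:
        logger.info("classify_pairs: %d pairs exceeded more than one "
                    "cutoff; assigned by largest score/cutoff ratio", multi)
    keep = n_hits >= 1
    types = np.array(["C", "S", "D"])[ratios[keep].argmax(axis=1)]
    sub = score_table.loc[keep]
    scores = sub[["C", "S", "D"]].to_numpy()[np.arange(keep.sum()),
                                             ratios[keep].argmax(axis=1)]
    out = pd.DataFrame({
        "gene_a": sub["gene_a"].to_numpy(),
        "gene_b": sub["gene_b"].to_numpy(),
        "type": types,
        "score": scores,
        "rho1": sub["rho1"].to_numpy(),
        "rho2": sub["rho2"].to_numpy(),
    })
    counts = out["type"].value_counts()
    logger.info("classify_pairs: %d C, %d S, %d D links",
                counts.get("C", 0), counts.get("S", 0), counts.get("D", 0))
    return out
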