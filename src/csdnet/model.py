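"""The CSD model object and its fitted results.

`CSD` holds two aligned condition-specific expression matrices and the
estimation settings; `fit()` runs correlation + subsampling, C/S/D
scoring, sampled-maxima thresholding and network assembly, returning a
`CSDResults` with the score table, thresholds, typed network, node
summaries and a text `summary()`.

    >>> model = CSD.from_files("cortex.tsv", "basal_ganglia.tsv")
    >>> res = model.fit(importance_size=100_000, seed=0)
    >>> print(res.summary())
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import correlation as corr
from . import network as netmod
from . import scoring
from .io import (ExpressionMatrix, align_matrices, filter_genes,
                 read_expression_table, write_network_files)

logger = logging.getLogger(__name__)

__all__ = ["CSD", "CSDResults"]


class CSD:
    """Differential co-expression model over two conditions.

    Parameters
    ----------
    expr1, expr2 : ExpressionMatrix
        One expression matrix per condition.  Genes are aligned on
        construction (intersection, condition-1 row order); sample
        counts may differ between conditions.
    subsample_size : int, optional
        Size n of the pair-unique subsamples used for the correlation
        standard errors; the same n is applied to both conditions.
        Default: ``max(7, floor(sqrt(min(N1, N2))))``.
    use_subsampling : bool
        When False (or when a condition has fewer samples than the
        subsample size), sigma falls back to ``sigma_fallback`` for that
        condition; when both conditions lack subsampling the score
        denominator degrades to 1.
    sigma_fallback : float
        The constant sigma used where subsampling is unavailable.
    """

    def __init__(self, expr1: ExpressionMatrix, expr2: ExpressionMatrix,
                 subsample_size: int | None = None,
                 use_subsampling: bool = True,
                 sigma_fallback: float = 0.0):
        self.expr1, self.expr2 = align_matrices(expr1, expr2)
        if subsample_size is None:
            subsample_size = corr.default_subsample_size(
                min(self.expr1.n_samples, self.expr2.n_samples))
        if subsample_size < 2:
            raise ValueError("subsample size must be >= 2")
        self.subsample_size = int(subsample_size)
        self.use_subsampling = bool(use_subsampling)
        self.sigma_fallback = float(sigma_fallback)

    @classmethod
    def from_files(cls, path1, path2, dialect: str = "tsv",
                   keep_ids: set[str] | None = None,
                   **kwargs) -> "CSD":
        """Build the model from two expression tables on disk, with an
        optional gene keep-list (e.g. protein-coding ids)."""
        m1 = read_expression_table(path1, dialect=dialect)
        m2 = read_expression_table(path2, dialect=dialect)
        if keep_ids is not None:
            m1 = filter_genes(m1, keep_ids)
            m2 = filter_genes(m2, keep_ids)
        return cls(m1, m2, **kwargs)

    def _design_for(self, n_samples: int):
        if not self.use_subsampling or n_samples < self.subsample_size:
            if n_samples < self.subsample_size:
                logger.warning(
                    "condition with %d samples cannot support subsample "
                    "size %d; sigma falls back to %g", n_samples,
                    self.subsample_size, self.sigma_fallback)
            return None
        design = corr.generate_subsample_design(n_samples,
                                                self.subsample_size)
        if design.m < 2:
            return None
        return design

    def fit(self, importance_size: int = scoring.DEFAULT_L,
            n_draws: int = scoring.DEFAULT_DRAWS, seed: int = 0,
            replace: bool = False) -> "CSDResults":
        """Estimate correlations, score pairs, threshold and assemble.

        ``importance_size`` is the draw size L of the sampled-maxima
        cutoff; the shared importance level is p = 1/L.  L may not
        exceed the number of scored pairs unless ``replace`` is set.
        """
        design1 = self._design_for(self.expr1.n_samples)
        design2 = self._design_for(self.expr2.n_samples)
        pc1 = corr.pair_correlation_profile(self.expr1, design1,
                                            self.sigma_fallback)
        pc2 = corr.pair_correlation_profile(self.expr2, design2,
                                            self.sigma_fallback)
        scores = scoring.score_pairs(pc1, pc2)
        thresholds = scoring.determine_thresholds(
            scores, L=importance_size, m=n_draws, seed=seed, replace=replace)
        typed = scoring.classify_pairs(scores, thresholds)
        network = netmod.assemble_network(typed)
        return CSDResults(model=self, correlations=(pc1, pc2),
                          scores=scores, thresholds=thresholds,
                          typed_pairs=typed, network=network)


@dataclass
class CSDResults:
    """Fitted CSD analysis: scores, cutoffs, and the typed network."""

    model: CSD
    correlations: tuple
    scores: pd.DataFrame
    thresholds: scoring.ThresholdSet
    typed_pairs: pd.DataFrame
    network: netmod.TypedNetwork
    _summaries: list = field(default=None, repr=False)

    @property
    def node_summaries(self) -> list[netmod.NodeSummary]:
        if self._summaries is None and self.network.n_nodes:
            self._summaries = netmod.node_summaries(self.network)
        return self._summaries or []

    @property
    def components(self) -> list[tuple[int, int]]:
        return netmod.component_decomposition(self.network)

    def hub_report(self, top_n: int = 5):
        return netmod.hub_report(self.network, top_n)

    def node_table(self) -> pd.DataFrame:
        """Per-node degrees, homogeneity, link-type fractions and class."""
        rows = []
        for s in self.node_summaries:
            fc, fs, fd = s.fractions
            rows.append({"gene": s.gene, "k": s.k, "k_C": s.k_C,
                         "k_S": s.k_S, "k_D": s.k_D, "H": s.H,
                         "frac_C": fc, "frac_S": fs, "frac_D": fd,
                         "class": netmod.degree_class(s.k)})
        return pd.DataFrame(rows)

    def venn_partition(self) -> dict[str, int]:
        return netmod.venn_partition(self.node_summaries)

    def save(self, prefix) -> tuple[Path, Path]:
        """Write the edge and node attribute TSVs (Cytoscape-ready)."""
        return write_network_files(self.network, prefix)

    def summary(self) -> str:
        m = self.model
        pc1, pc2 = self.correlations
        counts = self.network.edge_type_counts()
        comps = self.components
        lines = [
            "CSD differential co-expression analysis",
            "=" * 55,
            f"condition 1: {m.expr1.condition_label or 'cond1':<20} "
            f"{m.expr1.n_samples:>5} samples",
            f"condition 2: {m.expr2.condition_label or 'cond2':<20} "
            f"{m.expr2.n_samples:>5} samples",
            f"genes (aligned): {m.expr1.n_genes}",
            f"scored pairs:    {len(self.scores)}",
            f"subsampling:     n={m.subsample_size}, "
            f"m1={pc1.n_subsamples if pc1.subsampling_used else '-'}, "
            f"m2={pc2.n_subsamples if pc2.subsampling_used else '-'}",
            f"importance:      p = 1/{self.thresholds.L} = "
            f"{self.thresholds.p:.3g}  ({self.thresholds.m} draws)",
            f"cutoffs:         X_C={self.thresholds.X_C:.4g}  "
            f"X_S={self.thresholds.X_S:.4g}  X_D={self.thresholds.X_D:.4g}",
            f"links:           {counts['C']} C / {counts['S']} S / "
            f"{counts['D']} D  ({self.network.n_edges} total)",
            f"nodes:           {self.network.n_nodes}",
        ]
        if comps:
            gn, ge = comps[0]
            lines.append(
                f"giant component: {gn} nodes "
                f"({100 * gn / self.network.n_nodes:.1f}%), {ge} edges "
                f"({100 * ge / max(self.network.n_edges, 1):.1f}%); "
                f"{len(comps)} components")
        if self.node_summaries:
            h = np.array([s.H for s in self.node_summaries])
            lines.append(f"homogeneity:     mean H = {h.mean():.3f} "
                         f"(min {h.min():.3f})")
            hubs = self.hub_report(3)["overall"]
            top = ", ".join(f"{r.gene} (k={r.k})"
                            for r in hubs.itertuples(index=False))
            lines.append(f"top hubs:        {top}")
        return "\n".join(lines)
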