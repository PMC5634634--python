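"""Ground-truth benchmark: perturbed regulatory networks, simulated
expression, and ROC evaluation of the C/S/D score rankings.

The benchmark builds a signed, weighted, directed regulatory network,
perturbs a fraction of its edges (removals and activator/repressor sign
flips) to create a second condition, simulates expression under both
networks, runs the full scoring pipeline, and asks whether each score
ranks its own kind of perturbation highly:

* unchanged edges are ground-truth C pairs,
* removed edges are ground-truth S pairs (co-expression lost),
* sign-flipped edges are ground-truth D pairs (correlation sign change).

Expression follows a linear-Gaussian structural model: each sample is a
fixed point of x = A x + e with A[target, regulator] the signed edge
weight and e standard-normal exogenous input, plus independent
observation noise proportional to each gene's signal spread.  The model
keeps exactly the sign/strength correlation structure the scores
consume; it does not emulate mRNA kinetics, saturation, or burst noise.
Detection is inherently partial — perturbing one edge in a connected
network often barely moves the pairwise correlation — so evaluation is
by AUC margins over chance, not by near-perfect recovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .correlation import (default_subsample_size, generate_subsample_design,
                          pair_correlation_profile)
from .io import ExpressionMatrix
from .scoring import score_pairs

logger = logging.getLogger(__name__)

__all__ = [
    "SignedRegulatoryNetwork",
    "BenchmarkConfig",
    "BenchmarkResult",
    "generate_signed_network",
    "rescale_network",
    "perturb_network",
    "simulate_expression",
    "roc_curve",
    "run_benchmark",
]

LABELS = ("C", "S", "D")


@dataclass
class SignedRegulatoryNetwork:
    """Directed regulator -> target edges with sign (+1/-1) and weight > 0."""

    genes: list[str]
    edges: list[tuple[str, str, int, float]]  # (regulator, target, sign, |w|)
    weakly_connected: bool = True

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def weight_matrix(self) -> np.ndarray:
        """A with A[target, regulator] = sign * |weight|."""
        pos = {g: i for i, g in enumerate(self.genes)}
        A = np.zeros((self.n_genes, self.n_genes))
        for reg, tgt, sign, w in self.edges:
            A[pos[tgt], pos[reg]] += sign * w
        return A


def generate_signed_network(n_genes: int, n_edges: int,
                            seed: int = 0) -> SignedRegulatoryNetwork:
    """Preferential-attachment-style signed regulatory network.

    The first ``n_genes - 1`` edges attach each new gene to an existing
    one (degree-biased), making the network weakly connected whenever
    enough edges are requested; the rest are degree-biased pairs.  No
    self-loops; reciprocal regulator/target pairs are avoided until the
    requested density forces them.  Signs are +1/-1 with probability 1/2,
    weight magnitudes Uniform(0.2, 1.0).  Deterministic given the seed.
    """
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    if n_edges < 1:
        raise ValueError("need at least 1 edge")
    if n_edges > n_genes * (n_genes - 1):
        raise ValueError(
            f"{n_edges} edges requested but at most "
            f"{n_genes * (n_genes - 1)} directed non-self edges exist")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    degree = np.ones(n_genes)  # +1 smoothing so new genes are reachable
    used_arcs: set[tuple[int, int]] = set()
    used_pairs: set[tuple[int, int]] = set()
    arcs: list[tuple[int, int]] = []
    allow_reciprocal = n_edges > n_genes * (n_genes - 1) // 2

    def add(reg: int, tgt: int) -> None:
        arcs.append((reg, tgt))
        used_arcs.add((reg, tgt))
        used_pairs.add((min(reg, tgt), max(reg, tgt)))
        degree[reg] += 1
        degree[tgt] += 1

    # spanning phase: connect gene i to a degree-biased earlier gene
    for i in range(1, min(n_genes, n_edges + 1)):
        w = degree[:i] / degree[:i].sum()
        partner = int(rng.choice(i, p=w))
        if rng.random() < 0.5:
            add(partner, i)
        else:
            add(i, partner)

    # densification phase: degree-biased distinct pairs
    attempts = 0
    max_attempts = 200 * max(n_edges, n_genes)
    while len(arcs) < n_edges and attempts < max_attempts:
        attempts += 1
        w = degree / degree.sum()
        pick = rng.choice(n_genes, size=2, replace=False)
        reg, tgt = int(pick[0]), int(pick[1])
        # half the time, bias the target towards high-degree genes
        if rng.random() < 0.5:
            tgt = int(rng.choice(n_genes, p=w))
        if tgt == reg or (reg, tgt) in used_arcs:
            continue
        pair = (min(reg, tgt), max(reg, tgt))
        if pair in used_pairs and not allow_reciprocal:
            continue
        add(reg, tgt)
    if len(arcs) < n_edges:
        # deterministic fill over the remaining feasible arcs
        for reg in range(n_genes):
            for tgt in range(n_genes):
                if len(arcs) == n_edges:
                    break
                if reg == tgt or (reg, tgt) in used_arcs:
                    continue
                pair = (min(reg, tgt), max(reg, tgt))
                if pair in used_pairs and not allow_reciprocal:
                    continue
                add(reg, tgt)
        if len(arcs) < n_edges:  # reciprocals were the only option left
            for reg in range(n_genes):
                for tgt in range(n_genes):
                    if len(arcs) == n_edges:
                        break
                    if reg != tgt and (reg, tgt) not in used_arcs:
                        add(reg, tgt)

    signs = rng.choice([1, -1], size=n_edges)
    weights = rng.uniform(0.2, 1.0, size=n_edges)
    edges = [(genes[r], genes[t], int(s), float(w))
             for (r, t), s, w in zip(arcs, signs, weights)]
    net = SignedRegulatoryNetwork(genes=genes, edges=edges)
    net.weakly_connected = _weakly_connected(net)
    if not net.weakly_connected:
        logger.warning("generated network is not weakly connected")
    return net


def _weakly_connected(net: SignedRegulatoryNetwork) -> bool:
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(net.genes)
    g.add_edges_from((r, t) for r, t, _, _ in net.edges)
    return nx.is_connected(g) if g.number_of_nodes() else True


def rescale_network(net: SignedRegulatoryNetwork,
                    spectral_radius: float = 0.75) -> SignedRegulatoryNetwork:
    """Scale weight magnitudes so the |A| spectral radius hits a target.

    rho(A) <= rho(|A|), so bounding |A| below 1 guarantees the fixed
    point of x = A x + e exists for the network *and* for any
    sign-flipped or edge-removed perturbation of it (same magnitudes).
    """
    A = np.abs(net.weight_matrix())
    radius = float(np.max(np.abs(np.linalg.eigvals(A))))
    if radius == 0:
        return net
    factor = spectral_radius / radius
    edges = [(r, t, s, w * factor) for r, t, s, w in net.edges]
    return SignedRegulatoryNetwork(genes=list(net.genes), edges=edges,
                                   weakly_connected=net.weakly_connected)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def perturb_network(net: SignedRegulatoryNetwork, frac_remove: float = 0.05,
                    frac_flip: float = 0.05, seed: int = 0
                    ) -> tuple[SignedRegulatoryNetwork, dict]:
    """Remove and sign-flip random disjoint edge sets; label the pairs.

    round(frac*|E|) edges (half away from zero) are removed, the same
    rule selects distinct other edges for sign flips.  Returns the
    condition-2 network and a ground-truth map from the unordered gene
    pair of every condition-1 edge to 'C' (unchanged), 'S' (removed) or
    'D' (flipped).  If the rare reciprocal pair carries conflicting edge
    fates, D takes precedence over S over C for the pair label.
    """
    if frac_remove < 0 or frac_flip < 0 or frac_remove + frac_flip > 1:
        raise ValueError("fractions must be non-negative and sum to <= 1")
    E = net.n_edges
    n_remove = _round_half_away(frac_remove * E)
    n_flip = _round_half_away(frac_flip * E)
    if n_remove + n_flip > E:
        raise ValueError("perturbation counts exceed the edge count")
    rng = np.random.default_rng(seed)
    order = rng.permutation(E)
    removed = set(order[:n_remove].tolist())
    flipped = set(order[n_remove:n_remove + n_flip].tolist())

    edges2 = []
    fates = []  # per edge: C/S/D
    for i, (r, t, s, w) in enumerate(net.edges):
        if i in removed:
            fates.append("S")
        elif i in flipped:
            fates.append("D")
            edges2.append((r, t, -s, w))
        else:
            fates.append("C")
            edges2.append((r, t, s, w))

    precedence = {"C": 0, "S": 1, "D": 2}
    truth: dict[tuple[str, str], str] = {}
    for (r, t, _, _), fate in zip(net.edges, fates):
        pair = (r, t) if r < t else (t, r)
        if pair not in truth or precedence[fate] > precedence[truth[pair]]:
            truth[pair] = fate
    net2 = SignedRegulatoryNetwork(genes=list(net.genes), edges=edges2)
    net2.weakly_connected = _weakly_connected(net2)
    return net2, truth


def simulate_expression(net: SignedRegulatoryNetwork, n_samples: int = 200,
                        noise_sd: float = 0.1, seed: int = 0,
                        condition_label: str = "") -> ExpressionMatrix:
    """Draw samples from the linear-Gaussian fixed point x = A x + e.

    e is standard normal per gene and sample; observation noise with
    standard deviation ``noise_sd`` times each gene's signal sd is added
    afterwards.  Errors out when the weight matrix is unstable
    (spectral radius >= 1) — rescale with :func:`rescale_network`.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    A = net.weight_matrix()
    radius = float(np.max(np.abs(np.linalg.eigvals(A))))
    if radius >= 1.0:
        raise ValueError(
            f"weight matrix is unstable (spectral radius {radius:.3f} >= 1);"
            " rescale the network (rescale_network) before simulating")
    rng = np.random.default_rng(seed)
    P = net.n_genes
    e = rng.standard_normal((P, n_samples))
    x = np.linalg.solve(np.eye(P) - A, e)
    if noise_sd > 0:
        scale = x.std(axis=1, keepdims=True)
        x = x + rng.standard_normal((P, n_samples)) * (noise_sd * scale)
    return ExpressionMatrix(
        gene_ids=list(net.genes),
        sample_ids=[f"s{i:04d}" for i in range(n_samples)],
        values=x,
        condition_label=condition_label,
    )


def roc_curve(scores, labels) -> tuple[np.ndarray, float]:
    """Threshold-sweep ROC with tied scores grouped; trapezoid AUC.

    ``labels`` is a boolean array marking the positives.  Returns the
    (FPR, TPR) step points (including (0,0) and (1,1)) and the AUC,
    which equals the Mann-Whitney probability that a random positive
    outscores a random negative (ties counting half).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # group ties: keep only the last index of each distinct score
    distinct = np.r_[s[1:] != s[:-1], True]
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(~y)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


@dataclass
class BenchmarkConfig:
    """Desk-scale defaults mirror the perturbation design: 10% of edges
    modified (half removed, half sign-flipped) and 200 expression samples
    per condition."""

    n_genes: int = 200
    n_edges: int = 480
    frac_remove: float = 0.05
    frac_flip: float = 0.05
    n_samples: int = 200
    noise_sd: float = 0.1
    n_repeats: int = 5
    seed: int = 0
    subsample_size: int | None = None  # None: max(7, floor(sqrt(N)))
    spectral_radius: float = 0.75
    shuffle_labels: bool = False  # negative control


@dataclass
class BenchmarkResult:
    config: BenchmarkConfig
    auc: dict  # score type -> list of per-repeat AUCs
    mean_auc: dict  # score type -> float
    roc_grid: np.ndarray  # common FPR grid
    mean_roc: dict  # score type -> mean TPR on the grid
    label_counts: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        rows = []
        for t in LABELS:
            vals = np.array(self.auc[t])
            rows.append({"score": t, "mean_auc": vals.mean(),
                         "sd_auc": vals.std(ddof=1) if len(vals) > 1 else 0.0,
                         "n_repeats": len(vals)})
        return pd.DataFrame(rows)


def _benchmark_repeat(cfg: BenchmarkConfig, seed: int):
    """One generate -> perturb -> simulate -> score pass; returns the
    score table restricted to ground-truth pairs plus their labels."""
    net = rescale_network(
        generate_signed_network(cfg.n_genes, cfg.n_edges, seed=seed),
        cfg.spectral_radius)
    net2, truth = perturb_network(net, cfg.frac_remove, cfg.frac_flip,
                                  seed=seed + 1)
    expr1 = simulate_expression(net, cfg.n_samples, cfg.noise_sd,
                                seed=seed + 2, condition_label="cond1")
    expr2 = simulate_expression(net2, cfg.n_samples, cfg.noise_sd,
                                seed=seed + 3, condition_label="cond2")
    n_sub = cfg.subsample_size or default_subsample_size(cfg.n_samples)
    design = generate_subsample_design(cfg.n_samples, n_sub)
    pc1 = pair_correlation_profile(expr1, design)
    pc2 = pair_correlation_profile(expr2, design)
    table = score_pairs(pc1, pc2)
    key = pd.Series(list(zip(table["gene_a"], table["gene_b"])))
    labels = key.map(truth)
    keep = labels.notna().to_numpy()
    return table.loc[keep].reset_index(drop=True), \
        labels[keep].reset_index(drop=True)


def run_benchmark(cfg: BenchmarkConfig | None = None) -> BenchmarkResult:
    """Full benchmark: repeated simulate-and-score passes, ROC per score.

    Per repeat and score type t, the positives are the ground-truth
    t-labeled pairs and the negatives all other labeled (directly
    regulated) pairs; AUCs and interpolated ROC curves are averaged over
    repeats.  ``cfg.shuffle_labels`` permutes the labels within each
    repeat as a chance-level control.
    """
    cfg = cfg or BenchmarkConfig()
    grid = np.linspace(0.0, 1.0, 101)
    auc: dict[str, list[float]] = {t: [] for t in LABELS}
    tprs: dict[str, list[np.ndarray]] = {t: [] for t in LABELS}
    label_counts = []
    for rep in range(cfg.n_repeats):
        rep_seed = cfg.seed + 1000 * rep
        table, labels = _benchmark_repeat(cfg, rep_seed)
        if cfg.shuffle_labels:
            rng = np.random.default_rng(rep_seed + 17)
            labels = pd.Series(rng.permutation(labels.to_numpy()))
        label_counts.append(labels.value_counts().to_dict())
        for t in LABELS:
            y = (labels == t).to_numpy()
            points, a = roc_curve(table[t].to_numpy(), y)
            auc[t].append(a)
            tprs[t].append(np.interp(grid, points[:, 0], points[:, 1]))
        logger.info("benchmark repeat %d: AUC C=%.3f S=%.3f D=%.3f", rep,
                    auc["C"][-1], auc["S"][-1], auc["D"][-1])
    return BenchmarkResult(
        config=cfg,
        auc=auc,
        mean_auc={t: float(np.mean(auc[t])) for t in LABELS},
        roc_grid=grid,
        mean_roc={t: np.mean(np.vstack(tprs[t]), axis=0) for t in LABELS},
        label_counts=label_counts,
    )
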