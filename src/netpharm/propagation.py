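"""Random walk with restart (RWR) and its signed variant (SRWR).

RWR measures the network influence of a seed gene set: a walker follows a
uniformly random out-edge with probability ``1 - c`` and teleports back to
the seed restart distribution with probability ``c``.  Its stationary
probability vector is the influence vector.

SRWR propagates the *direction* of a perturbation over a signed signaling
network.  The walker carries a sign: crossing an inhibitory (-1) edge flips
it, crossing an activating (+1) edge keeps it, and on restart the walker
regains the original sign of its seed.  Tracking the positive and negative
sign channels separately gives per-node scores ``p`` and ``n`` and an
activation score ``r = p - n``; negative ``r`` marks net predicted
inhibition by the seeded perturbation.

The coupled fixed point solved here is::

    p = (1-c) (W+^T p + W-^T n + D(p, n) q+) + c q+
    n = (1-c) (W-^T p + W+^T n + D(p, n) q-) + c q-

where W+/W- route each node's uniform out-transition mass through its
positive/negative out-edges, q+/q- split the restart distribution by seed
sign, and D is the probability mass sitting on dangling (out-degree-zero)
nodes, which returns to the restart distribution with the seeds' original
signs — the walker can only "jump back to its starting node", so mass is
conserved at 1.  Summing the two equations recovers the unsigned RWR
equation, so p + n always equals the sign-blind influence vector.

No balance-attenuation parameters are used: the walker is the plain
sign-flipping one (equivalent to attenuation factors fixed at 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import scipy.sparse as sp

from netpharm.graph_io import GeneSet, Interactome, SignedDiGraph, UNKNOWN_SIGN


class ConvergenceError(RuntimeError):
    """Power iteration failed to reach the tolerance within max_iter."""


@dataclass
class SeedAssignment:
    """Signed seed genes with restart weights (uniform by default).

    ``signs`` maps gene -> +1 (activated by the drug) or -1 (inhibited).
    Seeds carrying the unknown-sign sentinel are treated as +1 with a
    warning.  ``weights``, when given, must cover exactly the seed genes and
    is normalized to sum to 1.
    """

    signs: dict[str, int]
    weights: dict[str, float] | None = None

    @classmethod
    def from_gene_set(cls, genes: GeneSet | Mapping[str, int], sign: int = 1):
        if isinstance(genes, GeneSet):
            return cls({g: sign for g in genes.members})
        return cls(dict(genes))

    def __post_init__(self) -> None:
        if not self.signs:
            raise ValueError("seed assignment is empty")
        unknown = sorted(g for g, s in self.signs.items() if s == UNKNOWN_SIGN)
        if unknown:
            warnings.warn(
                f"{len(unknown)} seed(s) with unknown sign treated as +1: "
                f"{unknown[:5]}{'...' if len(unknown) > 5 else ''}",
                stacklevel=2,
            )
            self.signs = {
                g: (1 if s == UNKNOWN_SIGN else s) for g, s in self.signs.items()
            }
        bad = {g: s for g, s in self.signs.items() if s not in (1, -1)}
        if bad:
            raise ValueError(f"invalid seed signs: {bad}")
        if self.weights is not None:
            if set(self.weights) != set(self.signs):
                raise ValueError("weights must cover exactly the seed genes")
            total = float(sum(self.weights.values()))
            if total <= 0:
                raise ValueError("seed weights must have positive sum")
            self.weights = {g: w / total for g, w in self.weights.items()}

    def restricted_to(self, nodes: set[str]) -> tuple["SeedAssignment", int]:
        """Intersect seeds with ``nodes``; returns (assignment, n_dropped)."""
        kept = {g: s for g, s in self.signs.items() if g in nodes}
        dropped = len(self.signs) - len(kept)
        if not kept:
            raise ValueError("no seed node is present in the propagation graph")
        w = None
        if self.weights is not None:
            w = {g: self.weights[g] for g in kept}
        return SeedAssignment(kept, w), dropped


@dataclass
class PropagationConfig:
    """Solver settings: restart probability c, L1 tolerance, iteration cap.

    The restart probability defaults to 0.75.  Tolerance applies to the L1
    change of the concatenated (p, n) vector between sweeps.
    """

    restart_probability: float = 0.75
    tolerance: float = 1e-10
    max_iterations: int = 10_000

    def __post_init__(self) -> None:
        if not (0.0 < self.restart_probability <= 1.0):
            raise ValueError("restart_probability must be in (0, 1]")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class InfluenceVector:
    """Stationary RWR probability per node (non-negative, sums to 1)."""

    nodes: list[str]
    scores: np.ndarray
    n_seeds_dropped: int = 0

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.nodes, self.scores.tolist()))

    def __getitem__(self, node: str) -> float:
        return float(self.scores[self.nodes.index(node)])


@dataclass
class SignedScores:
    """SRWR output: positive channel p, negative channel n, activation r = p - n."""

    nodes: list[str]
    p: np.ndarray
    n: np.ndarray
    n_seeds_dropped: int = 0
    r: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.r = self.p - self.n

    def as_dict(self) -> dict[str, tuple[float, float, float]]:
        return {
            v: (float(self.p[i]), float(self.n[i]), float(self.r[i]))
            for i, v in enumerate(self.nodes)
        }

    def activation(self, node: str) -> float:
        return float(self.r[self.nodes.index(node)])


def _node_order(graph: SignedDiGraph | Interactome) -> list[str]:
    return sorted(graph.nodes)


def _transition_matrices(
    graph: SignedDiGraph | Interactome, nodes: list[str]
) -> tuple[sp.csr_matrix, sp.csr_matrix, np.ndarray]:
    """(W+, W-, dangling mask) with W row-stochastic over out-edges.

    Undirected graphs are treated as each edge running both ways with sign
    +1.  W[i, j] = 1/outdeg(i) for each out-edge i->j; the sign of the edge
    decides whether the entry lands in W+ or W-.
    """
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    if isinstance(graph, SignedDiGraph):
        triples = graph.edges
    else:
        triples = []
        for pair in graph.edges:
            a, b = sorted(pair)
            triples.append((a, b, 1))
            triples.append((b, a, 1))
    outdeg = np.zeros(n)
    for u, _, _ in triples:
        outdeg[index[u]] += 1
    rows_p, cols_p, rows_m, cols_m = [], [], [], []
    vals_p, vals_m = [], []
    for u, v, s in triples:
        i, j = index[u], index[v]
        w = 1.0 / outdeg[i]
        if s == 1:
            rows_p.append(i), cols_p.append(j), vals_p.append(w)
        else:
            rows_m.append(i), cols_m.append(j), vals_m.append(w)
    w_pos = sp.csr_matrix((vals_p, (rows_p, cols_p)), shape=(n, n))
    w_neg = sp.csr_matrix((vals_m, (rows_m, cols_m)), shape=(n, n))
    dangling = outdeg == 0
    return w_pos, w_neg, dangling


def _restart_vectors(
    seeds: SeedAssignment, nodes: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    q_pos = np.zeros(n)
    q_neg = np.zeros(n)
    if seeds.weights is None:
        w = 1.0 / len(seeds.signs)
        weights = {g: w for g in seeds.signs}
    else:
        weights = seeds.weights
    for g, s in seeds.signs.items():
        (q_pos if s == 1 else q_neg)[index[g]] += weights[g]
    return q_pos, q_neg


def srwr(
    graph: SignedDiGraph,
    seeds: SeedAssignment,
    config: PropagationConfig | None = None,
) -> SignedScores:
    """Signed random walk with restart on a signed directed network."""
    config = config or PropagationConfig()
    nodes = _node_order(graph)
    seeds, dropped = seeds.restricted_to(set(nodes))
    w_pos, w_neg, dangling = _transition_matrices(graph, nodes)
    q_pos, q_neg = _restart_vectors(seeds, nodes)
    c = config.restart_probability

    wp_t = w_pos.T.tocsr()
    wm_t = w_neg.T.tocsr()
    p = q_pos.copy()
    n = q_neg.copy()
    for _ in range(config.max_iterations):
        d_mass = float(p[dangling].sum() + n[dangling].sum())
        p_new = (1 - c) * (wp_t @ p + wm_t @ n + d_mass * q_pos) + c * q_pos
        n_new = (1 - c) * (wm_t @ p + wp_t @ n + d_mass * q_neg) + c * q_neg
        resid = float(np.abs(p_new - p).sum() + np.abs(n_new - n).sum())
        p, n = p_new, n_new
        if resid < config.tolerance:
            return SignedScores(nodes, p, n, dropped)
    raise ConvergenceError(
        f"SRWR did not converge in {config.max_iterations} iterations "
        f"(last L1 residual {resid:.3e})"
    )


def rwr(
    graph: SignedDiGraph | Interactome,
    seeds: SeedAssignment | GeneSet,
    config: PropagationConfig | None = None,
) -> InfluenceVector:
    """Unsigned random walk with restart (edge signs ignored).

    Accepts a :class:`GeneSet` directly, in which case every seed restarts
    with uniform weight.
    """
    if isinstance(seeds, GeneSet):
        seeds = SeedAssignment.from_gene_set(seeds)
    if isinstance(graph, SignedDiGraph):
        sign_blind = graph.unsigned()
    else:
        sign_blind = graph
    unsigned_seeds = SeedAssignment(
        {g: 1 for g in seeds.signs}, dict(seeds.weights) if seeds.weights else None
    )
    scores = (
        srwr(sign_blind, unsigned_seeds, config)
        if isinstance(sign_blind, SignedDiGraph)
        else _rwr_undirected(sign_blind, unsigned_seeds, config)
    )
    return InfluenceVector(scores.nodes, scores.p + scores.n, scores.n_seeds_dropped)


def _rwr_undirected(
    graph: Interactome, seeds: SeedAssignment, config: PropagationConfig | None
) -> SignedScores:
    config = config or PropagationConfig()
    nodes = _node_order(graph)
    seeds, dropped = seeds.restricted_to(set(nodes))
    w_pos, _, dangling = _transition_matrices(graph, nodes)
    q_pos, _ = _restart_vectors(seeds, nodes)
    c = config.restart_probability
    wp_t = w_pos.T.tocsr()
    s = q_pos.copy()
    for _ in range(config.max_iterations):
        d_mass = float(s[dangling].sum())
        s_new = (1 - c) * (wp_t @ s + d_mass * q_pos) + c * q_pos
        resid = float(np.abs(s_new - s).sum())
        s = s_new
        if resid < config.tolerance:
            return SignedScores(nodes, s, np.zeros_like(s), dropped)
    raise ConvergenceError(
        f"RWR did not converge in {config.max_iterations} iterations "
        f"(last L1 residual {resid:.3e})"
    )


def select_top_signed(
    scores: SignedScores,
    fraction: float,
    direction: str = "inhibited",
    set_name: str | None = None,
) -> GeneSet:
    """Top-|r| stratum filtered by activation sign.

    All nodes are ranked by ``|r|`` descending; the top
    ``ceil(fraction * n_nodes)`` rank positions are kept (boundary ties all
    included); within that stratum, nodes with ``r < 0`` are returned for
    ``direction='inhibited'`` and ``r > 0`` for ``'activated'``.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    if direction not in ("inhibited", "activated"):
        raise ValueError("direction must be 'inhibited' or 'activated'")
    name = set_name or f"top_{direction}"
    absr = np.abs(scores.r)
    if np.all(absr == 0):
        warnings.warn("all activation scores are zero; returning empty set",
                      stacklevel=2)
        return GeneSet(name, ())
    n = len(scores.nodes)
    k = math.ceil(fraction * n)
    order = np.argsort(-absr, kind="stable")
    threshold = absr[order[k - 1]]
    in_stratum = absr >= threshold
    if direction == "inhibited":
        mask = in_stratum & (scores.r < 0)
    else:
        mask = in_stratum & (scores.r > 0)
    return GeneSet(name, (scores.nodes[i] for i in np.flatnonzero(mask)))
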