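"""Drug-target / disease-gene association via influence-vector correlation.

The association between a drug's target set and a disease's gene set is
scored as the Pearson correlation (Cor) of their RWR influence vectors over
all nodes of a background network.  Significance comes from a permutation
null: the disease set is redrawn uniformly at random (same size, without
replacement) many times, and

    z = (Cor - E(Cor)) / delta(Cor)

with E and delta the mean and standard deviation of the null correlations.
No degree matching is applied to the null draws — a known limitation, since
high-degree genes carry more influence mass; see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from netpharm.graph_io import GeneSet, Interactome, SignedDiGraph
from netpharm.propagation import InfluenceVector, PropagationConfig, rwr


@dataclass
class CorrelationResult:
    """Observed correlation with its permutation-null moments and Z-score."""

    cor: float
    null_mean: float
    null_sd: float
    z_score: float
    n_null: int
    rng_seed: int
    drug_size: int = 0
    disease_size: int = 0

    @staticmethod
    def zscore_formula(cor: float, null_mean: float, null_sd: float) -> float:
        """The bare arithmetic z = (cor - E) / delta, exposed for reuse."""
        if null_sd <= 0:
            raise ValueError("null standard deviation must be positive")
        return (cor - null_mean) / null_sd


def influence_vector(
    graph: SignedDiGraph | Interactome,
    gene_set: GeneSet,
    config: PropagationConfig | None = None,
) -> InfluenceVector:
    """RWR influence vector of a gene set, uniform restart over members.

    Members absent from the graph are dropped; the count of dropped members
    is reported on the returned vector.
    """
    kept = gene_set.intersect(graph.nodes)
    if len(kept) == 0:
        raise ValueError(
            f"gene set {gene_set.name!r} has no member on the graph"
        )
    vec = rwr(graph, kept, config)
    vec.n_seeds_dropped = len(gene_set) - len(kept)
    return vec


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a, b)[0, 1])


def correlation_zscore(
    graph: SignedDiGraph | Interactome,
    drug_targets: GeneSet,
    disease_genes: GeneSet,
    config: PropagationConfig | None = None,
    n_null: int = 1000,
    rng_seed: int = 0,
) -> CorrelationResult:
    """Correlation Z-score of a drug target set against a disease gene set.

    The null redraws the *disease* side: ``n_null`` uniformly random node
    sets of the same post-intersection cardinality, each propagated and
    correlated with the fixed drug influence vector.  Deterministic given
    ``rng_seed``.
    """
    if n_null < 2:
        raise ValueError("n_null must be >= 2")
    nodes = sorted(graph.nodes)
    drug_kept = drug_targets.intersect(nodes)
    disease_kept = disease_genes.intersect(nodes)
    if len(drug_kept) == 0 or len(disease_kept) == 0:
        raise ValueError("both gene sets must intersect the graph")
    if len(disease_kept) > len(nodes):
        raise ValueError("disease set larger than the graph")

    drug_vec = influence_vector(graph, drug_kept, config).scores
    disease_vec = influence_vector(graph, disease_kept, config).scores
    cor = _pearson(drug_vec, disease_vec)

    rng = np.random.default_rng(rng_seed)
    k = len(disease_kept)
    null_cors = np.empty(n_null)
    for i in range(n_null):
        draw = rng.choice(len(nodes), size=k, replace=False)
        rand_set = GeneSet(f"null_{i}", (nodes[j] for j in draw))
        rand_vec = influence_vector(graph, rand_set, config).scores
        null_cors[i] = _pearson(drug_vec, rand_vec)

    null_mean = float(null_cors.mean())
    null_sd = float(null_cors.std(ddof=1))
    if null_sd == 0:
        raise ValueError("degenerate null: zero standard deviation")
    z = CorrelationResult.zscore_formula(cor, null_mean, null_sd)
    return CorrelationResult(
        cor=cor,
        null_mean=null_mean,
        null_sd=null_sd,
        z_score=z,
        n_null=n_null,
        rng_seed=rng_seed,
        drug_size=len(drug_kept),
        disease_size=len(disease_kept),
    )
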