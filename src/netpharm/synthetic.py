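"""Synthetic networks, gene sets and annotations with planted structure.

Everything downstream (propagation, correlation, similarity, enrichment) is
testable offline on data generated here.  The generator emulates the scale
and statistical structure of the real inputs of a signaling-network drug
study: a heavy-tailed signed signaling network of several thousand genes, a
disease gene set of order 10^3 that is *localized* in the network (a
breadth-first ball, matching the network-medicine picture of a disease
module), drug target sets of order 10^1-10^2 with a controllable fraction
planted near the disease module, and block-structured function-term
annotations under which within-block PathSim exceeds cross-block PathSim.

Defaults mirror a whole-interactome study: 7000 genes, mean out-degree 3,
a quarter of signaling edges inhibitory, 1159 disease genes, 79 drug
targets.  Tests and examples pass smaller sizes explicitly.

What it does not emulate: real interaction confidence scores, the GO DAG,
correlated noise between the network and the gene sets, or literature
ascertainment bias — recovery results on this generator show the pipeline's
statistics behave as designed, not that any particular real drug-disease
claim holds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import networkx as nx
import numpy as np

from netpharm.graph_io import (
    AnnotationMap,
    DrugProfile,
    GeneSet,
    SignedDiGraph,
    Interactome,
    write_annotations,
    write_drug_table,
    write_gmt,
    write_signed_edgelist,
)

# valid, unremarkable small-molecule SMILES used to give synthetic drugs a
# structure channel (acetylsalicylic acid, caffeine, ibuprofen, naproxen)
_DEMO_SMILES = [
    "CC(=O)Oc1ccccc1C(=O)O",
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "COc1ccc2cc(ccc2c1)C(C)C(=O)O",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the generator; identical config + seed => identical outputs."""

    n_nodes: int = 7000
    mean_out_degree: float = 3.0
    negative_edge_fraction: float = 0.25
    disease_set_size: int = 1159
    drug_target_size: int = 79
    overlap_fraction: float = 0.5
    n_function_terms: int = 50
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.negative_edge_fraction <= 1.0):
            raise ValueError("negative_edge_fraction must be in [0, 1]")
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValueError("overlap_fraction must be in [0, 1]")
        if max(self.disease_set_size, self.drug_target_size) > self.n_nodes:
            raise ValueError("set sizes cannot exceed n_nodes")
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, rng_seed=seed)


def _gene_name(i: int) -> str:
    return f"G{i:05d}"


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def gen_signed_network(config: SyntheticConfig) -> SignedDiGraph:
    """Heavy-tailed signed directed network.

    A preferential-attachment (Barabasi-Albert) skeleton gives the degree
    heavy tail; each undirected attachment edge is then assigned a uniform
    random direction, which seeds the directed cycles a signaling network's
    giant strongly connected component requires.  Each edge is independently
    inhibitory with probability ``negative_edge_fraction``.
    """
    m = _round_half_up(config.mean_out_degree)
    if m < 1 or m >= config.n_nodes:
        raise ValueError(
            f"mean_out_degree {config.mean_out_degree} infeasible for "
            f"{config.n_nodes} nodes"
        )
    rng = np.random.default_rng([config.rng_seed, 0x5E7])
    skeleton = nx.barabasi_albert_graph(
        config.n_nodes, m, seed=int(rng.integers(2**31))
    )
    edges = []
    pairs = sorted(tuple(sorted(e)) for e in skeleton.edges)
    flips = rng.random(len(pairs)) < 0.5
    negs = rng.random(len(pairs)) < config.negative_edge_fraction
    for (a, b), flip, neg in zip(pairs, flips, negs):
        u, v = (b, a) if flip else (a, b)
        edges.append((_gene_name(u), _gene_name(v), -1 if neg else 1))
    nodes = [_gene_name(i) for i in range(config.n_nodes)]
    return SignedDiGraph.from_edges(edges, nodes=nodes)


def _undirected_view(graph: SignedDiGraph | Interactome) -> nx.Graph:
    if isinstance(graph, Interactome):
        return graph.graph
    return graph.graph.to_undirected()


def plant_gene_sets(
    graph: SignedDiGraph | Interactome,
    config: SyntheticConfig,
    drug_id: str = "drug",
    smiles: str | None = None,
) -> tuple[GeneSet, DrugProfile]:
    """Disease module plus a drug profile with planted proximity to it.

    The disease set is a breadth-first ball around a random center (a
    network-localized module).  ``round(overlap_fraction *
    drug_target_size)`` drug targets are drawn from the module's closed
    1-hop neighborhood — the module itself plus, on a directed network,
    its *in*-neighbors (nodes with an edge into the module), since only an
    upstream target can propagate a perturbation into the module; on an
    undirected interactome the plain neighborhood is used.  The remainder
    come uniformly from nodes outside that neighborhood.  All target signs
    are -1 (inhibition), the direction a therapeutic perturbation study
    screens for.
    """
    rng = np.random.default_rng([config.rng_seed, 0xA17])
    und = _undirected_view(graph)
    nodes = sorted(und.nodes)
    if config.disease_set_size > len(nodes):
        raise ValueError("disease_set_size exceeds graph size")

    center = nodes[int(rng.integers(len(nodes)))]
    # BFS ball: take whole levels until the size is reached, truncating the
    # last level in randomized (seeded) order
    module: list[str] = []
    seen = {center}
    frontier = [center]
    while frontier and len(module) < config.disease_set_size:
        need = config.disease_set_size - len(module)
        if len(frontier) <= need:
            module.extend(sorted(frontier))
        else:
            take = rng.choice(sorted(frontier), size=need, replace=False)
            module.extend(take.tolist())
        nxt = set()
        for v in frontier:
            for w in und.neighbors(v):
                if w not in seen:
                    seen.add(w)
                    nxt.add(w)
        frontier = sorted(nxt)
    if len(module) < config.disease_set_size:
        raise ValueError("graph too disconnected for requested disease module")
    disease = GeneSet("disease", module)

    closed = set(module)
    if isinstance(graph, SignedDiGraph):
        for v in module:
            closed.update(graph.graph.predecessors(v))
    else:
        for v in module:
            closed.update(und.neighbors(v))
    n_prox = _round_half_up(config.overlap_fraction * config.drug_target_size)
    n_far = config.drug_target_size - n_prox
    prox_pool = sorted(closed)
    far_pool = sorted(set(nodes) - closed)
    if n_prox > len(prox_pool) or n_far > len(far_pool):
        raise ValueError(
            f"overlap request infeasible: need {n_prox} proximal of "
            f"{len(prox_pool)} and {n_far} distal of {len(far_pool)}"
        )
    targets: list[str] = []
    if n_prox:
        targets += rng.choice(prox_pool, size=n_prox, replace=False).tolist()
    if n_far:
        targets += rng.choice(far_pool, size=n_far, replace=False).tolist()
    profile = DrugProfile(drug_id, smiles, {g: -1 for g in targets})
    return disease, profile


def gen_annotations(
    targets: set[str] | list[str],
    config: SyntheticConfig,
    n_blocks: int = 2,
    terms_per_gene: int = 3,
) -> AnnotationMap:
    """Block-structured gene -> function-term annotations.

    Genes are partitioned into ``n_blocks`` blocks; the term vocabulary is
    split into disjoint per-block pools and each gene draws its terms only
    from its block's pool.  Genes of one block therefore share terms while
    cross-block pairs share none, so within-block PathSim exceeds
    cross-block PathSim.
    """
    if config.n_function_terms < 1:
        raise ValueError("n_function_terms must be >= 1")
    n_blocks = max(1, min(n_blocks, config.n_function_terms))
    rng = np.random.default_rng([config.rng_seed, 0xF17])
    genes = sorted(targets)
    terms = [f"T{i:04d}" for i in range(config.n_function_terms)]
    pools = [terms[i::n_blocks] for i in range(n_blocks)]
    ann: AnnotationMap = {}
    for idx, gene in enumerate(genes):
        pool = pools[idx % n_blocks]
        k = min(terms_per_gene, len(pool))
        ann[gene] = set(rng.choice(pool, size=k, replace=False).tolist())
    return ann


def write_fixture(config: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a complete synthetic study directory in graph_io formats.

    Produces the signaling network, an interactome view (the sign-blind
    undirected skeleton), the disease gene set (GMT), a drug table with a
    planted-overlap drug, a zero-overlap control drug and two
    structure-only comparators, and block-structured annotations covering
    all drug targets.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    graph = gen_signed_network(config)
    disease, planted = plant_gene_sets(
        graph, config, drug_id="planted_drug", smiles=_DEMO_SMILES[0]
    )
    control_cfg = replace(
        config, overlap_fraction=0.0, rng_seed=config.rng_seed + 1
    )
    _, control = plant_gene_sets(
        graph, control_cfg, drug_id="control_drug", smiles=_DEMO_SMILES[1]
    )
    extra = [
        DrugProfile("comparator_a", _DEMO_SMILES[2], {}),
        DrugProfile("comparator_b", _DEMO_SMILES[3], {}),
    ]
    all_targets = set(planted.targets) | set(control.targets)
    ann = gen_annotations(all_targets, config)

    interactome = Interactome.from_edges(
        sorted({tuple(sorted((u, v))) for u, v, _ in graph.edges}),
        nodes=graph.nodes,
    )
    paths = {
        "network": outdir / "signaling_network.tsv",
        "interactome": outdir / "interactome.tsv",
        "disease": outdir / "disease_genes.gmt",
        "drugs": outdir / "drugs.csv",
        "annotations": outdir / "annotations.tsv",
    }
    write_signed_edgelist(graph, paths["network"])
    write_signed_edgelist(interactome, paths["interactome"])
    write_gmt([disease], paths["disease"])
    write_drug_table([planted, control] + extra, paths["drugs"])
    write_annotations(ann, paths["annotations"])
    return paths
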