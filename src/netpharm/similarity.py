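"""Three drug-similarity views and hierarchical clustering of them.

* Chemical structure: Morgan (circular) fingerprints compared with the
  Tanimoto coefficient |A AND B| / |A OR B|.
* Target modules: the interactome separation S_AB = d_AB - (d_AA + d_BB)/2
  of network medicine, on closest shortest-path distances; S_AB < 0 means
  the two drugs' target modules overlap topologically.
* Cellular function: PathSim similarity 2 M_ij / (M_ii + M_jj) on the
  compound -> target -> function-term -> target -> compound metapath of a
  tripartite heterogeneous network, where M counts metapath instances.

Stereochemistry in SMILES is honored when present; two molecules whose
canonical SMILES omit stereo centers compare as identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from rdkit import Chem
from rdkit.DataStructs import TanimotoSimilarity
from rdkit.Chem import rdFingerprintGenerator

from netpharm.graph_io import AnnotationMap, DrugProfile, GeneSet, Interactome


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise similarity over an ordered list of drug ids."""

    drug_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.drug_ids), len(self.drug_ids)):
            raise ValueError("matrix shape does not match drug list")
        self.values = v

    def loc(self, a: str, b: str) -> float:
        return float(
            self.values[self.drug_ids.index(a), self.drug_ids.index(b)]
        )


@dataclass
class ProximityResult:
    """Module separation on an interactome: d_AA, d_BB, d_AB and S_AB."""

    d_aa: float
    d_bb: float
    d_ab: float
    s_ab: float
    n_dropped_a: int = 0
    n_dropped_b: int = 0


@dataclass
class ClusterAssignment:
    """Flat clustering of drugs: labels contiguous from 1."""

    labels: dict[str, int]
    linkage: str
    n_clusters: int


def _morgan_fp(smiles: str, radius: int, n_bits: int):
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return gen.GetFingerprint(mol)


def fingerprint_tanimoto(
    smiles_a: str, smiles_b: str, radius: int = 2, n_bits: int = 2048
) -> float:
    """Tanimoto coefficient between two molecules' Morgan fingerprints."""
    fa = _morgan_fp(smiles_a, radius, n_bits)
    fb = _morgan_fp(smiles_b, radius, n_bits)
    if fa.GetNumOnBits() == 0 and fb.GetNumOnBits() == 0:
        raise ValueError(
            "both fingerprints are empty; Tanimoto similarity undefined"
        )
    return float(TanimotoSimilarity(fa, fb))


def structure_similarity_matrix(
    drugs: Sequence[DrugProfile], radius: int = 2, n_bits: int = 2048
) -> SimilarityMatrix:
    """Pairwise Tanimoto matrix; drugs lacking SMILES excluded with a warning."""
    usable = [d for d in drugs if d.smiles]
    skipped = [d.drug_id for d in drugs if not d.smiles]
    if skipped:
        warnings.warn(f"drugs without SMILES excluded: {skipped}", stacklevel=2)
    if len(usable) < 2:
        raise ValueError("need at least 2 drugs with SMILES")
    fps = [_morgan_fp(d.smiles, radius, n_bits) for d in usable]
    n = len(usable)
    m = np.eye(n)
    for i, j in combinations(range(n), 2):
        if fps[i].GetNumOnBits() == 0 and fps[j].GetNumOnBits() == 0:
            raise ValueError(
                f"both fingerprints empty for {usable[i].drug_id!r} and "
                f"{usable[j].drug_id!r}"
            )
        m[i, j] = m[j, i] = TanimotoSimilarity(fps[i], fps[j])
    return SimilarityMatrix([d.drug_id for d in usable], m)


def _closest_distances(
    lengths: Mapping[str, Mapping[str, int]],
    sources: set[str],
    targets: set[str],
    exclude_self: bool,
) -> list[int]:
    """Min shortest-path hops from each source to the target set.

    ``exclude_self`` removes the source itself from its candidate targets
    (for within-module d_AA); otherwise membership in the target set counts
    as distance 0.  Unreachable sources are skipped.
    """
    out = []
    for s in sources:
        cands = targets - {s} if exclude_self else targets
        if not exclude_self and s in targets:
            out.append(0)
            continue
        dists = [lengths[s][t] for t in cands if t in lengths[s]]
        if dists:
            out.append(min(dists))
    return out


def sab_separation(
    interactome: Interactome, targets_a: GeneSet, targets_b: GeneSet
) -> ProximityResult:
    """Network-medicine separation S_AB of two target modules.

    d_AB averages, over every node of A and every node of B, its closest
    distance to the other module (0 when the node belongs to both); d_AA and
    d_BB average each member's closest distance to another member of its own
    module (singletons get 0).  Unreachable pairs are excluded from the
    means.  S_AB = d_AB - (d_AA + d_BB)/2.
    """
    nodes = interactome.nodes
    a = targets_a.members & nodes
    b = targets_b.members & nodes
    if not a or not b:
        raise ValueError("a target set is empty after interactome intersection")
    relevant = a | b
    lengths = {
        s: nx.single_source_shortest_path_length(interactome.graph, s)
        for s in relevant
    }

    ab_terms = _closest_distances(lengths, a, b, exclude_self=False)
    ba_terms = _closest_distances(lengths, b, a, exclude_self=False)
    cross = ab_terms + ba_terms
    if not cross:
        raise ValueError("modules are disconnected: no A-B pair is reachable")
    d_ab = float(np.mean(cross))

    def within(module: set[str]) -> float:
        if len(module) == 1:
            return 0.0
        terms = _closest_distances(lengths, module, module, exclude_self=True)
        return float(np.mean(terms)) if terms else 0.0

    d_aa = within(a)
    d_bb = within(b)
    return ProximityResult(
        d_aa=d_aa,
        d_bb=d_bb,
        d_ab=d_ab,
        s_ab=d_ab - (d_aa + d_bb) / 2.0,
        n_dropped_a=len(targets_a) - len(a),
        n_dropped_b=len(targets_b) - len(b),
    )


def sab_matrix(
    interactome: Interactome, drugs: Sequence[DrugProfile]
) -> tuple[list[str], np.ndarray]:
    """Pairwise S_AB over drug target sets (diagonal from self-separation).

    Returned raw (not rescaled to [0,1]): smaller S_AB means more similar.
    """
    usable = [d for d in drugs if set(d.targets) & interactome.nodes]
    if len(usable) < 2:
        raise ValueError("need at least 2 drugs with targets on the interactome")
    n = len(usable)
    m = np.zeros((n, n))
    sets = [d.target_set() for d in usable]
    for i in range(n):
        for j in range(i, n):
            m[i, j] = m[j, i] = sab_separation(interactome, sets[i], sets[j]).s_ab
    return [d.drug_id for d in usable], m


def pathsim_matrix(
    drugs: Sequence[DrugProfile],
    annotations: AnnotationMap,
) -> SimilarityMatrix:
    """PathSim on the compound-target-function-target-compound metapath.

    M_ij = sum over (t in targets_i, t' in targets_j) of the number of
    function terms shared by t and t'; similarity = 2 M_ij / (M_ii + M_jj).
    Drugs with zero self-metapaths (no annotated target) are excluded with a
    warning — mirroring compounds whose target lists are empty in real data.
    """
    def self_paths(d: DrugProfile) -> int:
        return _metapath_count(d, d, annotations)

    usable = [d for d in drugs if self_paths(d) > 0]
    skipped = [d.drug_id for d in drugs if d.drug_id not in
               {u.drug_id for u in usable}]
    if skipped:
        warnings.warn(
            f"drugs without annotated targets excluded from PathSim: {skipped}",
            stacklevel=2,
        )
    if not usable:
        raise ValueError("no drug has an annotated target")
    n = len(usable)
    counts = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            counts[i, j] = counts[j, i] = _metapath_count(
                usable[i], usable[j], annotations
            )
    m = np.eye(n)
    for i, j in combinations(range(n), 2):
        m[i, j] = m[j, i] = 2.0 * counts[i, j] / (counts[i, i] + counts[j, j])
    return SimilarityMatrix([d.drug_id for d in usable], m)


def _metapath_count(
    a: DrugProfile, b: DrugProfile, annotations: AnnotationMap
) -> int:
    total = 0
    for t in a.targets:
        terms_t = annotations.get(t, set())
        if not terms_t:
            continue
        for u in b.targets:
            total += len(terms_t & annotations.get(u, set()))
    return total


def cluster_similarity(
    matrix: SimilarityMatrix, n_clusters: int, linkage: str = "complete"
) -> ClusterAssignment:
    """Agglomerative clustering on distance 1 - similarity.

    Deterministic: among equal-distance merge candidates the pair whose
    sorted member-id lists compare lexicographically smallest is merged
    first.  Supported linkages: complete, single, average.
    """
    n = len(matrix.drug_ids)
    if not (1 <= n_clusters <= n):
        raise ValueError(f"n_clusters must be in [1, {n}]")
    if linkage not in ("complete", "single", "average"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    dist = 1.0 - matrix.values
    clusters: list[list[int]] = [[i] for i in range(n)]

    def cluster_dist(c1: list[int], c2: list[int]) -> float:
        pair = [dist[i, j] for i in c1 for j in c2]
        if linkage == "complete":
            return max(pair)
        if linkage == "single":
            return min(pair)
        return float(np.mean(pair))

    while len(clusters) > n_clusters:
        best = None
        for i, j in combinations(range(len(clusters)), 2):
            d = cluster_dist(clusters[i], clusters[j])
            key = (
                d,
                sorted(matrix.drug_ids[k] for k in clusters[i] + clusters[j]),
            )
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)

    # label clusters 1..k in order of their smallest drug id for determinism
    clusters.sort(key=lambda c: min(matrix.drug_ids[i] for i in c))
    labels = {}
    for label, members in enumerate(clusters, start=1):
        for i in members:
            labels[matrix.drug_ids[i]] = label
    return ClusterAssignment(labels=labels, linkage=linkage, n_clusters=n_clusters)
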