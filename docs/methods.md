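# Methods

This note documents the models implemented in `netpharm`, the parameter
choices that matter, the synthetic data the tests run on, and the
limitations of both.

## Random walk with restart

For a graph with out-degree-uniform transition matrix W, seed restart
distribution q and restart probability c ∈ (0, 1], the influence vector s
is the fixed point of

    s = (1 − c)·Wᵀs + c·q,

solved by power iteration from s₀ = q. Mass arriving at a dangling node
(out-degree zero) is returned to q — the walker can only jump back to its
seed — so s remains a probability vector exactly. Convergence is declared
when the L1 change of an iteration falls below the tolerance (default
1e−10; the iteration contracts with factor 1 − c, so this takes a few
dozen sweeps at c = 0.75). Exceeding `max_iterations` (default 10 000)
raises an error carrying the last residual rather than returning a
half-converged vector. Edge signs are ignored; undirected graphs are
treated as each edge running both ways.

The default restart probability is 0.75 throughout the package. A high
restart keeps influence local to the seeds, which is the regime in which
gene-set influence vectors discriminate between nearby and faraway sets.

## Signed random walk with restart (SRWR)

On a signed directed network the walker carries a sign: crossing an
inhibitory edge flips it, crossing an activating edge preserves it, and on
restart the walker regains its seed's original sign. Splitting each node's
probability into a positive channel p and negative channel n gives the
coupled fixed point

    p = (1 − c)(W₊ᵀp + W₋ᵀn + D(p,n)·q₊) + c·q₊
    n = (1 − c)(W₋ᵀp + W₊ᵀn + D(p,n)·q₋) + c·q₋

where W₊/W₋ route each node's *joint* uniform out-transition mass through
its positive/negative out-edges (one normalization over all out-edges, the
sign only selecting the channel — the alternative of normalizing each sign
class separately would not conserve mass), q₊/q₋ split the restart
distribution by seed sign, and D is the mass on dangling nodes, returned
with original seed signs. Summing the two equations recovers the unsigned
RWR equation, so p + n equals the sign-blind influence vector identically —
a property the test suite checks to 1e−8 on random graphs, alongside
agreement with an independent per-length walk-enumeration oracle on small
graphs.

The activation score is r = p − n ∈ [−1, 1]. No balance-attenuation
parameters are applied; the walker is the plain sign-flipping one
(equivalent to attenuation factors fixed at 1).

Seeds with unknown direction are treated as activating (+1) with a warning.
Seeds absent from the propagation graph are dropped and the count reported;
propagating on a giant strongly connected component (GSC) typically drops
some.

**Top-fraction selection.** Predicted inhibited genes are those whose |r|
ranks within the top ⌈fraction × n⌉ positions (default fraction 0.10) *and*
whose r < 0; ties at the rank boundary are all retained. The denominator n
is the node count of the graph actually propagated on (the GSC when the
pipeline runs on one). Published top-gene counts under nominally identical
rules are generally not reconstructible without the exact network snapshot,
which is why the denominator convention is stated rather than inferred.

## Correlation Z-score

The drug–disease association score is the Pearson correlation, over all
network nodes, of the drug-target and disease-gene influence vectors,
standardized against a permutation null: the disease set is redrawn
uniformly at random (same post-intersection size, without replacement,
n_null draws, default 1000) and z = (Cor − mean)/sd of the null
correlations. Choices worth stating:

- The *disease* side is permuted; the drug vector stays fixed. Permuting
  either side gives a valid null; one had to be chosen.
- Null draws are uniform over nodes with no degree matching. High-degree
  genes carry systematically more influence mass, so a hub-heavy real
  disease set will inflate z somewhat. This is a known limitation; degree-
  aware nulls are deliberately out of scope.
- Correlation runs over all nodes including the seeds themselves.
- Everything is deterministic given `rng_seed`.

## Drug similarity

**Structure.** Morgan (circular) fingerprints, radius 2, 2048 bits —
standard circular-fingerprint practice — compared with the Tanimoto
coefficient. Stereochemistry is honored when the SMILES carries it;
canonical SMILES that omit stereocenters make stereoisomers compare as
identical (similarity 1.0). That is a property of the input representation,
not an error, and the package does not "fix" it. Two molecules with empty
fingerprints raise an undefined-similarity error rather than returning 1.

**Target-module separation.** S_AB = d_AB − (d_AA + d_BB)/2 on an
interactome, with all distances closest-distance means in graph hops:
d_AB averages, over every node of A and of B, its minimum distance to the
other module (0 for shared members); d_AA averages each member's distance
to the nearest *other* member (singletons contribute 0). Unreachable pairs
are excluded from means; fully disconnected module pairs are an error.
Under this convention S_AB is symmetric, S_AA ≤ 0 for |A| ≥ 2, and
negative values indicate topologically overlapping target modules.

**Function (PathSim).** On the tripartite compound→target→function-term
network, M_ij counts instances of the metapath
compound−target−term−target−compound (equivalently
Σ_{t∈Tᵢ, t'∈Tⱼ} |terms(t) ∩ terms(t')|), and similarity is
2·M_ij/(M_ii + M_jj). Only the 4-step metapath is counted; directly shared
targets contribute only through shared terms. Drugs with zero self-paths
(no annotated target) are excluded with a warning — real compound sets
contain such entries, and silently giving them similarity 0 to everything
would distort clustering.

**Clustering.** Agglomerative clustering on distance 1 − similarity
(complete linkage by default; single and average available). The
implementation is a small exact agglomerator with a documented tie-break —
among equal-distance merges, the pair whose sorted member list is
lexicographically smallest merges first — making partitions independent of
input order even on tied matrices; a test cross-checks it against scipy's
hierarchy on tie-free input. Labels are contiguous from 1, ordered by each
cluster's smallest member id. The default cut of 6 clusters matches common
practice for drug panels of a few dozen compounds and is configurable.

## Enrichment and overlap bookkeeping

Validation of a selected gene set uses the upper-tail inclusive
hypergeometric probability P(X ≥ k) for drawing n genes from N with K
successes, computed via scipy's survival function (stable
log-combinatorics); k = 0 returns exactly 1. The population defaults to
the propagated graph's node set and is configurable — enrichment p-values
move substantially with the population choice, so the pipeline records it.
Raw p-values are reported; Benjamini–Hochberg adjustment is an optional
flag for multi-set runs. Overlap percentages are rounded half-up to two
decimals and trailing-zero-trimmed (48.10 prints as 48.1), matching the
mixed precision conventions of published intersection analyses.

## Potency units

pIC50 is defined on the molar scale: pIC50 = −log₁₀(IC50 [M]), so
IC50[μM] = 10^(−pIC50)·10⁶. This is the only convention under which
published pIC50/μM table pairs are mutually consistent (e.g. 3.787 ↔
163.305 μM). Conversions are exact internally; table reproduction uses
half-up rounding to 3 decimals. Published tables converted from unrounded
pIC50s can disagree with reconversion from the rounded values in the last
digit, so consistency sweeps use a 0.002 μM tolerance.

## Synthetic data: what is emulated and what is not

The generator produces study-shaped inputs with planted signal:

- **Network**: a Barabási–Albert skeleton (heavy-tailed degrees) with each
  edge given a uniform random direction — random orientation seeds the
  directed cycles a signaling network's GSC requires — and independently
  inhibitory with probability `negative_edge_fraction` (default 0.25; curated
  signaling resources typically report an inhibitory minority of roughly
  this order).
- **Disease module**: a breadth-first ball around a random center, i.e. a
  network-localized module, the assumption under which RWR proximity is
  informative at all.
- **Drug profile**: round(overlap_fraction × size) targets drawn from the
  module's closed *in*-neighborhood — the module plus nodes with a directed
  edge into it — and the rest from outside it. Upstream planting matters:
  a target adjacent to the module via an edge pointing the wrong way cannot
  propagate influence into it, and with undirected planting roughly half the
  "proximal" targets are wasted, weakening the planted signal severely.
  All target signs default to −1, the direction a therapeutic inhibition
  study screens for.
- **Annotations**: disjoint per-block term pools, so within-block PathSim
  exceeds cross-block PathSim by construction.

Defaults mirror whole-interactome scale (7000 genes, 1159 disease genes,
79 targets); tests pass smaller sizes explicitly. Two scales recur in the
test suite: correlation-recovery properties run on 200-node graphs with 50
null draws and 20 replicates (cheap, and the z-ordering signal is strong
even there), while the SRWR-enrichment property runs at study *ratios*
(1500 nodes, disease module ≈ 16% of the network, ~2% targets planted at
overlap 0.8). The latter matters because the enrichment effect in this
design is modest — on the order of 1.3× the null expectation — and a
hypergeometric test only resolves that at sufficient counts; tiny toy
networks are genuinely underpowered for it, which is a property of the
statistic, not of the implementation.

Not emulated: interaction confidence scores, the GO DAG, ascertainment
bias in curated target lists, degree-correlated disease genes, expression
data. Passing tests on this generator demonstrate that the statistics
recover planted signal under their own assumptions — they are not evidence
about any particular real drug or disease.

## Pipeline determinism

All result files of a pipeline run are byte-deterministic given the config
and seed: node orders are sorted, floats printed with fixed formats, JSON
keys sorted, and all randomness flows through one seeded generator. The one
exception is `run_log.json`, which records wall-clock per-stage timings and
is therefore diagnostic output, excluded from the determinism contract (its
seed, config hash and version fields are still deterministic).

## Numerical and degenerate-input choices

- Power iteration tolerance 1e−10 (L1, concatenated channels), far below
  any decision threshold downstream.
- Degenerate nulls (zero standard deviation) raise rather than return an
  infinite z.
- All-zero SRWR scores yield an empty top set with a warning.
- Duplicate edges in input files are errors, not merges; parsers report
  line numbers.
- Singleton modules have d_AA = 0 by convention in S_AB.
- Ranking ties at the top-fraction boundary are all retained (the
  selection can exceed ⌈fraction·n⌉).
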