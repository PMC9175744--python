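# netpharm

Signed network propagation and drug–disease association analysis for
computational systems pharmacology.

Multi-component drugs — herbal preparations especially — hit dozens of
protein targets at once, and the interesting question is not any single
binding event but what the *combined perturbation* does to a disease.
`netpharm` implements the network side of that question for researchers who
have a signaling network, an interactome, a disease gene set, and signed
drug target lists, and want to know: do the drug's targets sit close to the
disease genes, which genes does the perturbation ultimately inhibit or
activate, and does the drug resemble existing therapeutics?

## What it computes

**Influence correlation with a permutation null.** The influence of a gene
set is its random-walk-with-restart (RWR) stationary vector: a walker
follows a uniform out-edge with probability 1 − c and restarts on the seed
set with probability c (default c = 0.75). The association between drug
targets T and disease genes D is the Pearson correlation of their influence
vectors over all network nodes,

    z = (Cor(T, D) − E[Cor(T, R)]) / δ[Cor(T, R)]

where R ranges over random gene sets of |D| nodes (default 1000 draws).

**Signed propagation (SRWR).** On a signaling network whose edges carry
activation (+1) or inhibition (−1) signs, the walker also carries a sign:
it flips on inhibitory edges and regains its seed's original sign on
restart. Tracking the positive and negative channels p and n per node gives
an activation score r = p − n; genes with strongly negative r are predicted
net-inhibited by the drug. The genes whose |r| ranks in the top 10% and
whose r < 0 form the predicted inhibition set, validated against disease
gene sets with an upper-tail hypergeometric test.

**Drug similarity, three ways.** Chemical structure (Morgan fingerprints,
Tanimoto coefficient), target-module proximity on an interactome
(S_AB = d_AB − (d_AA + d_BB)/2 on closest shortest-path distances;
S_AB < 0 means overlapping modules), and cellular function (PathSim on the
compound→target→GO-term→target→compound metapath,
2·M_ij / (M_ii + M_jj) over metapath instance counts M). Each yields an
N×N matrix for hierarchical clustering.

**Potency units.** Exact pIC50 ↔ IC50 conversion on the molar scale
(pIC50 = −log₁₀ IC50[M]) with printed-table rounding.

A fully seeded synthetic-data module generates signaling networks,
localized disease modules, drug profiles with a controllable fraction of
targets planted upstream of the disease module, and block-structured GO-like
annotations, so the entire pipeline runs and is tested without any external
database.

## Worked example

A synthetic study at realistic scale ratios: a 1500-gene signaling network,
a 240-gene disease module, a 25-target all-inhibitory drug with 80% of its
targets planted upstream of the module.

```python
from netpharm import (SyntheticConfig, gen_signed_network, plant_gene_sets,
                      correlation_zscore, giant_strongly_connected, srwr,
                      select_top_signed, enrich_validate, GeneSet)
from netpharm.propagation import SeedAssignment, PropagationConfig

cfg = SyntheticConfig(n_nodes=1500, disease_set_size=240, drug_target_size=25,
                      overlap_fraction=0.8, negative_edge_fraction=0.2,
                      n_function_terms=10, rng_seed=7)
net = gen_signed_network(cfg)
disease, drug = plant_gene_sets(net, cfg)

res = correlation_zscore(net, drug.target_set(), disease, n_null=100, rng_seed=7)
print(f"Cor = {res.cor:.3f}, E(Cor) = {res.null_mean:.3f}, "
      f"delta(Cor) = {res.null_sd:.4f}, z = {res.z_score:.2f}")

gsc = giant_strongly_connected(net)
seeds, dropped = SeedAssignment(dict(drug.targets)).restricted_to(gsc.nodes)
scores = srwr(gsc, seeds, PropagationConfig(restart_probability=0.75))
top = select_top_signed(scores, 0.10, "inhibited")
enr = enrich_validate(top, disease.intersect(gsc.nodes), GeneSet("gsc", gsc.nodes))
print(f"GSC: {gsc.n_nodes()} of {net.n_nodes()} genes; "
      f"top-10% inhibited: {len(top)} genes")
print(f"overlap with disease module: {enr.overlap}/{enr.selection_size}, "
      f"hypergeometric p = {enr.p_value:.2e}")
```

prints

```
Cor = 0.057, E(Cor) = 0.010, delta(Cor) = 0.0263, z = 1.77
GSC: 1246 of 1500 genes; top-10% inhibited: 96 genes
overlap with disease module: 28/96, hypergeometric p = 4.91e-04
```

The drug's targets correlate with the disease genes above the random-set
null (z = 1.77 at this scaled-down size; real whole-interactome studies
score far higher), and the genes SRWR predicts it inhibits are enriched for
the disease module: 28 of the 96 top-inhibited genes are disease genes
versus ~15 expected by chance (p ≈ 5 × 10⁻⁴).

## Command line

```sh
netpharm simulate --n-nodes 500 --overlap-fraction 0.6 --seed 42 --out fixture/
netpharm zscore --graph fixture/signaling_network.tsv \
    --drug-set targets.txt --disease-set fixture/disease_genes.gmt --n-null 1000
netpharm srwr --graph fixture/signaling_network.tsv --seeds seeds.tsv \
    --top-fraction 0.1 --direction inhibited
netpharm similarity --mode structure --drugs fixture/drugs.csv --n-clusters 6
netpharm enrich --selected top.txt --validation disease.txt --population all.txt
netpharm convert --pic50 3.787
netpharm run --config pipeline.yaml --seed 42
```

`run` executes every stage from a YAML config and writes a deterministic
result bundle (overlap summary, correlation JSON, SRWR score table,
top-inhibited set, enrichment table, three similarity matrices, clusters,
and a run log with seed, config hash and versions).

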