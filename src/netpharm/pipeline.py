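"""End-to-end orchestration: one config in, a deterministic result bundle out.

Stages, in order: overlap bookkeeping of disease genes vs drug target sets;
correlation Z-score of each drug against the disease set on the signaling
network; SRWR propagation of the primary drug's signed targets on the giant
strongly connected component (GSC), with top-fraction inhibited-gene
selection; hypergeometric enrichment of that selection against the disease
set (population = GSC); and the three similarity matrices (structure,
S_AB target proximity, PathSim function) with hierarchical clustering.

All result files are byte-deterministic given the same config and seed.
Wall-clock stage timings are diagnostics, not results: they go only to
``run_log.json``, the one file excluded from the determinism contract.
"""

from __future__ import annotations

import hashlib
import json
import platform
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx
import numpy
import scipy

import netpharm
from netpharm.correlation import correlation_zscore
from netpharm.enrichment import enrich_validate, overlap_summary
from netpharm.graph_io import (
    GeneSet,
    giant_strongly_connected,
    read_annotations,
    read_drug_table,
    read_gmt,
    read_signed_edgelist,
)
from netpharm.propagation import (
    PropagationConfig,
    SeedAssignment,
    select_top_signed,
    srwr,
)
from netpharm.similarity import (
    SimilarityMatrix,
    cluster_similarity,
    pathsim_matrix,
    sab_matrix,
    structure_similarity_matrix,
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """Paths and parameters of one pipeline run; serialized for provenance."""

    network: str
    interactome: str
    disease_sets: str
    drugs: str
    annotations: str
    out_dir: str
    restart_probability: float = 0.75
    tolerance: float = 1e-10
    max_iterations: int = 10_000
    n_null: int = 1000
    top_fraction: float = 0.10
    n_clusters: int = 6
    linkage: str = "complete"
    rng_seed: int = 0
    extra: dict = field(default_factory=dict)

    def propagation(self) -> PropagationConfig:
        return PropagationConfig(
            self.restart_probability, self.tolerance, self.max_iterations
        )

    def validate_paths(self) -> None:
        for key in ("network", "interactome", "disease_sets", "drugs",
                    "annotations"):
            p = Path(getattr(self, key))
            if not p.exists():
                raise PipelineError(f"config: input path for {key!r} missing: {p}")


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _matrix_tsv(matrix: SimilarityMatrix, path: Path, fmt: str = "%.10g") -> None:
    lines = ["\t".join(["drug"] + matrix.drug_ids)]
    for i, d in enumerate(matrix.drug_ids):
        lines.append(
            "\t".join([d] + [fmt % v for v in matrix.values[i]])
        )
    path.write_text("\n".join(lines) + "\n")


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute every stage; returns the mapping of output name -> path."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prop_cfg = config.propagation()
    timings: dict[str, float] = {}
    outputs: dict[str, Path] = {}

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self.t0
                if exc is not None:
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return _Timer()

    with stage("load"):
        network = read_signed_edgelist(config.network, directed=True)
        interactome = read_signed_edgelist(config.interactome, directed=False)
        disease_sets = read_gmt(config.disease_sets)
        if not disease_sets:
            raise ValueError("no disease gene set in GMT")
        disease = disease_sets[0]
        drugs = read_drug_table(config.drugs)
        annotations = read_annotations(config.annotations)
        targeted = [d for d in drugs if d.targets]
        if not targeted:
            raise ValueError("no drug has any target")
        primary = targeted[0]

    with stage("overlap"):
        named = {disease.name: disease}
        for d in targeted:
            named[d.drug_id] = d.target_set()
        summary = overlap_summary(named)
        _json_dump(
            {
                "set_sizes": summary.set_sizes,
                "intersection_size": summary.intersection_size,
                "percentages": summary.percentages,
                "percentage_strings": summary.percentage_strings,
            },
            out / "overlap_summary.json",
        )
        outputs["overlap_summary"] = out / "overlap_summary.json"

    with stage("correlation"):
        results = {}
        for d in targeted:
            r = correlation_zscore(
                network,
                d.target_set(),
                disease,
                prop_cfg,
                n_null=config.n_null,
                rng_seed=config.rng_seed,
            )
            results[d.drug_id] = {
                "cor": r.cor,
                "null_mean": r.null_mean,
                "null_sd": r.null_sd,
                "z_score": r.z_score,
                "n_null": r.n_null,
                "n_targets_used": r.drug_size,
                "n_disease_used": r.disease_size,
            }
        _json_dump(results, out / "correlation.json")
        outputs["correlation"] = out / "correlation.json"

    with stage("srwr"):
        gsc = giant_strongly_connected(network)
        seeds, dropped = SeedAssignment(dict(primary.targets)).restricted_to(
            gsc.nodes
        )
        scores = srwr(gsc, seeds, prop_cfg)
        ranks = {
            node: rank + 1
            for rank, node in enumerate(
                sorted(scores.nodes, key=lambda v: -abs(scores.activation(v)))
            )
        }
        lines = ["node\tp\tn\tr\trank"]
        table = scores.as_dict()
        for node in sorted(scores.nodes):
            p, nn, r = table[node]
            lines.append(f"{node}\t{p:.10g}\t{nn:.10g}\t{r:.10g}\t{ranks[node]}")
        (out / "srwr_scores.tsv").write_text("\n".join(lines) + "\n")
        outputs["srwr_scores"] = out / "srwr_scores.tsv"

        top = select_top_signed(scores, config.top_fraction, "inhibited")
        (out / "top_inhibited.txt").write_text(
            "\n".join(sorted(top.members)) + ("\n" if top.members else "")
        )
        outputs["top_inhibited"] = out / "top_inhibited.txt"

    with stage("enrichment"):
        population = GeneSet("gsc", gsc.nodes)
        enr = enrich_validate(top, disease.intersect(gsc.nodes), population)
        lines = [
            "validation_set\tpopulation\tvalidation\tselected\toverlap\tp_value",
            f"{disease.name}\t{enr.population_size}\t{enr.validation_size}\t"
            f"{enr.selection_size}\t{enr.overlap}\t{enr.p_value:.6g}",
        ]
        (out / "enrichment.tsv").write_text("\n".join(lines) + "\n")
        outputs["enrichment"] = out / "enrichment.tsv"

    with stage("similarity"):
        struct = structure_similarity_matrix([d for d in drugs if d.smiles])
        _matrix_tsv(struct, out / "similarity_structure.tsv")
        outputs["similarity_structure"] = out / "similarity_structure.tsv"

        ids, sab = sab_matrix(interactome, targeted)
        _matrix_tsv(
            SimilarityMatrix(ids, sab), out / "similarity_sab.tsv"
        )
        outputs["similarity_sab"] = out / "similarity_sab.tsv"

        psim = pathsim_matrix(targeted, annotations)
        _matrix_tsv(psim, out / "similarity_pathsim.tsv")
        outputs["similarity_pathsim"] = out / "similarity_pathsim.tsv"

        k = min(config.n_clusters, len(struct.drug_ids))
        clusters = cluster_similarity(struct, k, config.linkage)
        lines = ["drug\tcluster"]
        for drug_id in sorted(clusters.labels):
            lines.append(f"{drug_id}\t{clusters.labels[drug_id]}")
        (out / "clusters.tsv").write_text("\n".join(lines) + "\n")
        outputs["clusters"] = out / "clusters.tsv"

    cfg_dict = asdict(config)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True).encode()
    ).hexdigest()
    _json_dump(cfg_dict, out / "pipeline_config.json")
    outputs["pipeline_config"] = out / "pipeline_config.json"
    _json_dump(
        {
            "rng_seed": config.rng_seed,
            "config_sha256": cfg_hash,
            "versions": {
                "netpharm": netpharm.__version__,
                "python": platform.python_version(),
                "numpy": numpy.__version__,
                "scipy": scipy.__version__,
                "networkx": networkx.__version__,
            },
            "stage_seconds": timings,
            "n_seeds_dropped_from_gsc": dropped,
        },
        out / "run_log.json",
    )
    outputs["run_log"] = out / "run_log.json"
    return outputs
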