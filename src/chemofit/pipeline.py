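"""End-to-end orchestration: simulate|count -> fitness -> enrich -> similarity.

A PipelineConfig fixes inputs, thresholds and the top-level seed; every
stage draws its randomness from a stream derived from that seed, so a rerun
with the same config produces bit-identical text outputs.  run_pipeline
returns (and writes) a manifest listing every artifact with its SHA-256
checksum plus per-stage row counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import counting, enrichment, fitness, similarity, synthetic

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]

logger = logging.getLogger(__name__)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the top-level seed."""
    return (int(seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Paths, thresholds and toggles for a pipeline run.

    When ``counts`` is unset the simulate stage generates a demo dataset:
    a strain catalog, a triplicate design over ``compounds``, a toy ontology,
    and counts with one planted term per screen.
    """

    out_dir: str = "chemofit_out"
    seed: int = 0
    # inputs (all optional; unset -> simulate stage provides them)
    catalog: str | None = None
    counts: str | None = None
    design: str | None = None
    gene_sets: str | None = None  # GMT path
    ontology: str | None = None  # OBO path (with GAF in gene_sets)
    # thresholds
    fd_threshold: float = 1.0
    fdr_threshold: float = 0.1
    overlap_min: float = 0.5
    jaccard_merge: float = 0.5
    # stage toggles
    run_enrichment: bool = True
    run_similarity: bool = True
    # simulate-stage parameters
    simulate: dict = field(
        default_factory=lambda: {
            "n_strains": 300,
            "n_replicates": 3,
            "n_terms": 40,
            "depth": 3,
            "planted_lfc": -2.5,
            "compounds": [
                {"name": "NDMA", "dose": "674.9uM", "diluent": "DMSO"},
                {"name": "NDEA", "dose": "489.5uM", "diluent": "DMSO"},
                {"name": "4NQO", "dose": "16.4mM", "diluent": "DMSO"},
            ],
            "date": "190801",
        }
    )

    def validate(self) -> None:
        if self.fd_threshold < 0:
            raise ValueError("fd_threshold must be >= 0")
        if not (0 < self.fdr_threshold <= 1):
            raise ValueError("fdr_threshold must be in (0, 1]")
        for name in ("overlap_min", "jaccard_merge"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if (self.counts is None) != (self.design is None):
            raise ValueError("counts and design must be provided together")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _simulate_stage(config: PipelineConfig, out: Path, manifest: dict):
    sim = config.simulate
    seed = stage_seed(config.seed, "simulate")
    catalog = synthetic.make_catalog(int(sim["n_strains"]), seed=seed)
    compounds = [(c["name"], c["dose"], c["diluent"]) for c in sim["compounds"]]
    design = synthetic.make_design(
        compounds, n_replicates=int(sim["n_replicates"]), date=str(sim["date"])
    )
    collection, dag = synthetic.make_toy_ontology(
        n_terms=int(sim["n_terms"]),
        n_genes=int(sim["n_strains"]),
        depth=int(sim["depth"]),
        seed=stage_seed(config.seed, "ontology"),
    )
    filtered = collection.filter_sizes()
    # plant one mid-sized term per screen so enrichment has signal
    candidates = sorted(
        (t for t, g in filtered.sets.items() if 10 <= len(g) <= 60),
        key=lambda t: (len(filtered.sets[t]), t),
    )
    planted: dict[str, dict[str, float]] = {}
    planted_term: dict[str, str] = {}
    for i, screen_id in enumerate(design.screen_ids):
        if not candidates:
            break
        term = candidates[i % len(candidates)]
        planted[screen_id] = {
            g: float(sim["planted_lfc"]) for g in filtered.sets[term]
        }
        planted_term[screen_id] = term
    truth = synthetic.make_truth(catalog, design, planted, planted_term=planted_term)
    params = synthetic.NBParams(seed=stage_seed(config.seed, "counts"))
    counts, _ = synthetic.simulate_counts(catalog, design, truth, params)
    paths = {
        "catalog": catalog.to_tsv(out / "catalog.tsv"),
        "design": design.to_tsv(out / "design.tsv"),
        "truth": truth.to_tsv(out / "truth.tsv"),
        "gene_sets": collection.to_gmt(out / "gene_sets.gmt"),
    }
    counts_path = out / "tag_counts.tsv"
    counts.rename_axis("tag").to_csv(counts_path, sep="\t")
    paths["tag_counts"] = counts_path
    manifest["stages"]["simulate"] = {
        "n_strains": len(catalog.frame),
        "n_samples": len(design.frame),
        "n_terms": len(collection),
    }
    return catalog, design, counts, collection, dag, paths


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in dependency order; returns the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}, "artifacts": {}}
    artifacts: dict[str, Path] = {}

    try:
        if config.counts is None:
            catalog, design, counts, collection, dag, paths = _simulate_stage(
                config, out, manifest
            )
            artifacts.update(paths)
        else:
            design = synthetic.ScreenDesign.from_tsv(config.design)
            counts = pd.read_csv(config.counts, sep="\t", index_col=0)
            catalog = (
                synthetic.StrainCatalog.from_tsv(config.catalog)
                if config.catalog
                else None
            )
            collection = dag = None
            if config.gene_sets:
                collection, dag = enrichment.load_gene_sets(
                    config.gene_sets, config.ontology
                )
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'inputs' failed: {exc}") from exc

    try:
        tag_matrix = counting.TagCountMatrix(
            counts=counts.astype(int),
            qc=pd.DataFrame(
                {
                    "total_reads": counts.sum(axis=0),
                    "assigned": counts.sum(axis=0),
                    "unmatched": 0,
                    "ambiguous": 0,
                }
            ),
        )
        if catalog is not None:
            gene_counts = fitness.collapse_tags(tag_matrix, catalog, design)
        else:
            gene_counts = fitness.GeneCountMatrix(counts=counts, design=design)
        table = fitness.fd_table(gene_counts, design, fd_threshold=config.fd_threshold)
        artifacts["fitness"] = table.to_tsv(out / "fitness.tsv")
        manifest["stages"]["fitness"] = {
            "n_genes": gene_counts.counts.shape[0],
            "n_screens": len(design.screen_ids),
            "n_sensitive": int((table.frame["call"] == "sensitive").sum()),
        }
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'fitness' failed: {exc}") from exc

    enrich_results: dict[str, list] = {}
    if config.run_enrichment and collection is not None:
        try:
            import networkx as nx

            dag = dag if dag is not None else nx.DiGraph()
            for screen_id in design.screen_ids:
                rows = enrichment.enrich_screen(
                    table,
                    screen_id,
                    collection,
                    fd_threshold=config.fd_threshold,
                    fdr_threshold=config.fdr_threshold,
                )
                rows = enrichment.prune(rows, dag, jaccard_merge=config.jaccard_merge)
                emap = enrichment.build_enrichment_map(
                    rows, collection, overlap_min=config.overlap_min
                )
                safe = screen_id.replace("/", "_")
                frame = enrichment.rows_to_frame(rows)
                path = out / f"enrichment_{safe}.tsv"
                frame.to_csv(path, sep="\t", index=False)
                artifacts[f"enrichment_{safe}"] = path
                map_path = out / f"map_{safe}.json"
                emap.to_json(map_path)
                artifacts[f"map_{safe}"] = map_path
                enrich_results[screen_id] = rows
            manifest["stages"]["enrichment"] = {
                "n_screens": len(enrich_results),
                "n_retained": sum(
                    sum(r.status == "retained" for r in rows)
                    for rows in enrich_results.values()
                ),
            }
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage 'enrichment' failed: {exc}") from exc

    if config.run_similarity:
        try:
            fd = fitness.fd_matrix(table)
            coin = similarity.coinhibition_matrix(fd)
            artifacts["coinhibition"] = coin.to_tsv(out / "coinhibition.tsv")
            if fd.shape[1] >= 2:
                dend = similarity.ward_cluster(coin)
                newick_path = out / "coinhibition_dendrogram.nwk"
                dend.to_newick(newick_path)
                artifacts["coinhibition_dendrogram"] = newick_path
                ordered = coin.values.loc[dend.leaf_order(), dend.leaf_order()]
                path = out / "coinhibition_ordered.tsv"
                ordered.to_csv(path, sep="\t")
                artifacts["coinhibition_ordered"] = path
            if fd.shape[1] >= 6:
                cofit = similarity.cofitness_matrix(fd)
                artifacts["cofitness"] = cofit.to_tsv(out / "cofitness.tsv")
            manifest["stages"]["similarity"] = {"n_screens": fd.shape[1]}
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage 'similarity' failed: {exc}") from exc

    # machine-readable bundle mirroring the interactive views
    bundle = {
        "fitness": json.loads(
            table.frame.to_json(orient="records", double_precision=10)
        ),
        "enrichment": {
            screen: json.loads(
                enrichment.rows_to_frame(rows).to_json(
                    orient="records", double_precision=10
                )
            )
            for screen, rows in enrich_results.items()
        },
    }
    bundle_path = out / "bundle.json"
    bundle_path.write_text(json.dumps(bundle, indent=1, sort_keys=True))
    artifacts["bundle"] = bundle_path

    manifest["artifacts"] = {
        name: {"path": str(path), "sha256": _sha256(Path(path))}
        for name, path in sorted(artifacts.items())
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("pipeline wrote %d artifacts to %s", len(artifacts), out)
    return manifest
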