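"""End-to-end pipeline: dictionary → index → model → query → fit → bands → network.

`run_pipeline` orchestrates every stage from a single configuration,
writes each intermediate artifact under the output directory, and emits a
JSON manifest with settings, input checksums, per-stage timings and output
paths, so a rerun with the same configuration and seed is reproducible and
any silent input change is detectable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import corpus as corpus_io
from . import disease_model as dm
from . import network as net
from .dictionary import (
    filter_vocabulary,
    build_vocabulary,
    load_mesh_headings,
    load_stopwords,
    save_dictionary,
)
from .engine import build_matrix, decompose, rank_factors, save_model
from .errors import InputError, ThresholdError

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; YAML-loadable, CLI-overridable."""

    mesh_source: str
    corpus_dir: str
    factor_table: str
    out_dir: str
    mesh_dialect: str = "flat_list"
    stoplist: str | None = None
    min_length: int = 3
    min_year: int | None = None
    max_year: int | None = None
    weighting: str = "log-entropy"
    k: int | str = "auto"
    variance_fraction: float = 0.8
    factor_mode: str = "centroid"
    bins: int = 20
    restarts: int = 20
    seed: int = 0
    thresholds: tuple[float, ...] | None = None  # manual override
    network_rule: str = "jaccard_assoc"
    min_weight: float = 0.0
    schema_version: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "thresholds" in data and data["thresholds"] is not None:
            data["thresholds"] = tuple(float(x) for x in data["thresholds"])
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, queries: list[str]) -> dict:
    """Execute all stages in order and return the run manifest.

    Stage failures abort with the failing stage named; artifacts written by
    earlier stages are retained. With fewer than two queries the network
    stage is skipped with a logged notice.
    """
    if not queries:
        raise InputError("need at least one query")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "schema_version": config.schema_version,
        "settings": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "queries": list(queries),
        "seed": config.seed,
        "inputs": {},
        "stages": [],
        "outputs": {},
    }
    stage_name = "setup"

    def stage(name):
        nonlocal stage_name
        stage_name = name
        return time.perf_counter()

    def done(t0, **outputs):
        manifest["stages"].append(
            {"name": stage_name, "seconds": round(time.perf_counter() - t0, 4)}
        )
        manifest["outputs"].update(
            {k: str(v) for k, v in outputs.items()}
        )

    try:
        # --- dictionary ------------------------------------------------
        t0 = stage("dictionary")
        manifest["inputs"]["mesh_source"] = _sha256(Path(config.mesh_source))
        headings = load_mesh_headings(config.mesh_source, config.mesh_dialect)
        stoplist = load_stopwords(config.stoplist)
        dictionary = filter_vocabulary(
            build_vocabulary(headings),
            stoplist=stoplist,
            min_length=config.min_length,
            provenance={"source": str(config.mesh_source),
                        "dialect": config.mesh_dialect},
        )
        dict_dir = out / "dictionary"
        save_dictionary(dictionary, dict_dir)
        logger.info("dictionary: %d words", len(dictionary))
        done(t0, dictionary=dict_dir)

        # --- index -----------------------------------------------------
        t0 = stage("index")
        manifest["inputs"]["factor_table"] = _sha256(Path(config.factor_table))
        factors = corpus_io.read_factor_table(config.factor_table)
        corpus_dir = Path(config.corpus_dir)
        files = {
            f.name: corpus_dir / f"{f.name.replace(' ', '_')}.medline"
            for f in factors
        }
        collection = corpus_io.assemble_collection(
            factors, files, min_year=config.min_year, max_year=config.max_year
        )
        counts = collection.counts()
        vals = list(counts.values())
        logger.info(
            "documents per factor: min %d / mean %.1f / max %d",
            min(vals), sum(vals) / len(vals), max(vals),
        )
        coll_manifest = out / "collection.json"
        coll_manifest.write_text(
            json.dumps(
                {
                    "counts": counts,
                    "files": {k: str(v) for k, v in files.items()},
                    "n_documents": collection.n_documents,
                },
                indent=2,
                sort_keys=True,
            )
            + "\n",
            encoding="utf-8",
        )
        done(t0, collection=coll_manifest)

        # --- model -----------------------------------------------------
        t0 = stage("model")
        matrix = build_matrix(collection, dictionary, config.weighting)
        k = None if config.k == "auto" else int(config.k)
        space = decompose(
            matrix,
            k=k,
            variance_fraction=config.variance_fraction,
            factor_mode=config.factor_mode,
        )
        logger.info("eigen space: k=%d", space.k)
        model_dir = out / "model"
        save_model(space, model_dir)
        done(t0, model=model_dir)

        # --- query / fit / categorize ----------------------------------
        categorized: dict[str, dm.AssociationCategories] = {}
        for query in queries:
            t0 = stage(f"query:{query}")
            result = rank_factors(query, space)
            slug = query.replace(" ", "_")
            scores_path = out / f"scores_{slug}.tsv"
            with open(scores_path, "w", encoding="utf-8") as fh:
                fh.write("# rank\tfactor\tcosine\n")
                for rank, (name, score) in enumerate(result.scores, start=1):
                    fh.write(f"{rank}\t{name}\t{score:.6f}\n")
            done(t0, **{f"scores:{query}": scores_path})

            t0 = stage(f"fit:{query}")
            hist = dm.score_histogram(
                [s for _, s in result.scores], n_bins=config.bins
            )
            fit = dm.fit_trimodal(
                hist, n_restarts=config.restarts, seed=config.seed
            )
            logger.info("fit %s: R^2=%.4f", query, fit.r_square)
            if config.thresholds is not None:
                thresholds = dm.Thresholds(
                    cutoffs=tuple(config.thresholds), source="manual"
                )
            else:
                try:
                    thresholds = dm.derive_thresholds(fit)
                except ThresholdError as exc:
                    logger.warning(
                        "query %s: %s; falling back to manual (0.1, 0.3)",
                        query, exc,
                    )
                    thresholds = dm.Thresholds((0.1, 0.3), source="manual")
            fit_path = out / f"fit_{slug}.json"
            fit_path.write_text(
                json.dumps(
                    {
                        "query": query,
                        "params": {
                            "alpha": fit.params.alpha,
                            "mu": fit.params.mu,
                            "sigma": fit.params.sigma,
                        },
                        "r_square": fit.r_square,
                        "bin_edges": fit.bins.tolist(),
                        "heights": fit.heights.tolist(),
                        "cutoffs": list(thresholds.cutoffs),
                        "threshold_source": thresholds.source,
                        "seed": config.seed,
                    },
                    indent=2,
                )
                + "\n",
                encoding="utf-8",
            )
            bands = dm.categorize(result, thresholds)
            categorized[query] = bands
            bands_path = out / f"bands_{slug}.tsv"
            with open(bands_path, "w", encoding="utf-8") as fh:
                fh.write("# factor\tcosine\tband\n")
                for name, score in result.scores:
                    fh.write(f"{name}\t{score:.6f}\t{bands.band_of(name)}\n")
            done(t0, **{f"fit:{query}": fit_path, f"bands:{query}": bands_path})

        # --- network ---------------------------------------------------
        if len(queries) >= 2:
            t0 = stage("network")
            network = net.build_network(
                categorized, rule=config.network_rule,
                min_weight=config.min_weight,
            )
            net_path = out / "network.graphml"
            net.write_graphml(network, net_path)
            edge_path = out / "network_edges.tsv"
            net.write_edgelist(network, edge_path)
            done(t0, network=net_path, network_edges=edge_path)
        else:
            logger.info("single query: network stage skipped")
            manifest["stages"].append({"name": "network", "skipped": True})
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage_name!r} failed: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(
        json.dumps(manifest, indent=2) + "\n", encoding="utf-8"
    )
    manifest["outputs"]["manifest"] = str(manifest_path)
    return manifest
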