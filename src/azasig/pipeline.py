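"""End-to-end orchestration: DEG -> ORA/network -> GSEA -> signature -> MoA.

One config object (optionally loaded from YAML) drives every stage with a
single seed; per-stage substreams are derived by name so toggling one
stage never changes another stage's draws. Each stage writes plain TSV /
GMT / Newick outputs under the output directory and the run ends with a
JSON manifest carrying the config echo, seed and per-file checksums:
deterministic outputs are byte-identical across same-seed runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io
from .containers import GeneSetCollection, intersect_samples
from .differential import (
    filter_low_expression,
    hierarchical_cluster,
    select_degs,
    t_test_per_gene,
)
from .enrichment import fisher_ora, overlap_network, pairwise_overlap_network
from .gsea import permute_and_normalize
from .moa import rank_moa
from .signature import classify_cohort, logrank_compare, score_samples

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "StageError"]

ALL_STAGES = ("deg", "ora", "gsea", "signature", "survival", "moa")

_FLOAT_FMT = "%.12g"


class StageError(RuntimeError):
    """A pipeline stage failed; earlier outputs are preserved."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths, per-stage parameters and the global seed for one run."""

    expression: str
    phenotypes: str
    out_dir: str
    gene_sets: str | None = None
    network: str | None = None
    validation_expression: str | None = None
    validation_phenotypes: str | None = None
    leading_edges: str | None = None  # precomputed GMT (alternative to gsea)
    directions: str | None = None  # TSV: set <tab> direction
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    deg_p_threshold: float = 0.01
    low_expression_max_zero_fraction: float = 0.9
    ora_alpha: float = 0.05
    edge_p_threshold: float | None = None
    gsea_n_perm: int = 1000
    gsea_min_size: int = 15
    gsea_max_size: int = 500
    gsea_weight_p: float = 1.0
    gsea_top_n: int = 10
    signature_coverage_min: float = 0.3
    moa_n_perm: int = 1000
    moa_n_bins: int = 4

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.stages = tuple(s for s in ALL_STAGES if s in self.stages)
        for name in ("deg_p_threshold", "ora_alpha"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        raw.update(overrides)
        return cls(**raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["stages"] = list(self.stages)
        return out


@dataclass
class RunManifest:
    """What a run did: config echo, seed, and output checksums."""

    config: dict
    version: str
    seed: int
    started: float
    finished: float
    outputs: dict[str, str] = field(default_factory=dict)  # relpath -> sha256

    def write(self, path: Path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str) -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format=_FLOAT_FMT)


def _check_dependencies(config: PipelineConfig) -> None:
    stages = set(config.stages)
    if {"ora", "gsea"} & stages and config.gene_sets is None:
        raise StageError("config", "ora/gsea enabled without a gene_sets GMT")
    if "ora" in stages and "deg" not in stages:
        raise StageError("config", "ora requires the deg stage")
    if "signature" in stages and "gsea" not in stages and not config.leading_edges:
        raise StageError(
            "config",
            "signature requires the gsea stage or a leading_edges GMT",
        )
    if "signature" in stages and "gsea" not in stages and not config.directions:
        raise StageError(
            "config",
            "signature with precomputed leading edges needs a directions TSV",
        )
    if "survival" in stages and "signature" not in stages:
        raise StageError("config", "survival requires the signature stage")
    if "moa" in stages and config.network is None:
        raise StageError("config", "moa enabled without a network edge list")


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run every enabled stage in order and write a manifest last."""
    _check_dependencies(config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    started = time.time()
    outputs: dict[str, str] = {}

    def record(path: Path) -> None:
        outputs[str(path.relative_to(out_dir))] = _sha256(path)

    stages = set(config.stages)
    matrix = phenotypes = None
    if stages:
        try:
            matrix = io.read_expression(config.expression)
            phenotypes = io.read_phenotypes(config.phenotypes)
            matrix, phenotypes = intersect_samples(matrix, phenotypes, logger)
            if config.low_expression_max_zero_fraction <= 1:
                matrix = filter_low_expression(
                    matrix, config.low_expression_max_zero_fraction
                )
        except Exception as exc:  # noqa: BLE001 - stage-named re-raise
            raise StageError("input", str(exc)) from exc

    gene_sets = None
    if config.gene_sets is not None:
        gene_sets = io.read_gmt(config.gene_sets)

    deg_result = degs = None
    if "deg" in stages:
        try:
            deg_result = t_test_per_gene(
                matrix, phenotypes, config.deg_p_threshold
            )
            degs = select_degs(deg_result)
            _write_tsv(deg_result.table, out_dir / "deg.tsv", "gene")
            record(out_dir / "deg.tsv")
            if len(degs) >= 2:
                clusters = hierarchical_cluster(matrix, degs)
                (out_dir / "deg_gene_dendrogram.nwk").write_text(
                    clusters.gene_newick() + "\n"
                )
                (out_dir / "deg_sample_dendrogram.nwk").write_text(
                    clusters.sample_newick() + "\n"
                )
                _write_tsv(
                    clusters.sample_partition.to_frame("cluster"),
                    out_dir / "deg_sample_partition.tsv",
                    "sample_id",
                )
                for name in (
                    "deg_gene_dendrogram.nwk",
                    "deg_sample_dendrogram.nwk",
                    "deg_sample_partition.tsv",
                ):
                    record(out_dir / name)
            else:
                logger.warning("fewer than 2 DEGs; clustering skipped")
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("deg", str(exc)) from exc

    if "ora" in stages:
        try:
            if not degs:
                logger.warning("no DEGs; ora stage skipped")
            else:
                ora = fisher_ora(
                    degs, gene_sets, matrix.gene_ids, config.ora_alpha
                )
                _write_tsv(ora.table, out_dir / "ora.tsv", "set")
                record(out_dir / "ora.tsv")
                if len(ora.significant_sets) >= 2:
                    net = pairwise_overlap_network(
                        ora, edge_p_threshold=config.edge_p_threshold
                    )
                    _write_tsv(net.edge_table(), out_dir / "ora_network_edges.tsv",
                               "index")
                    _write_tsv(net.node_table(), out_dir / "ora_network_nodes.tsv",
                               "set")
                    record(out_dir / "ora_network_edges.tsv")
                    record(out_dir / "ora_network_nodes.tsv")
        except Exception as exc:  # noqa: BLE001
            raise StageError("ora", str(exc)) from exc

    gsea_result = None
    if "gsea" in stages:
        try:
            gsea_result = permute_and_normalize(
                matrix,
                phenotypes,
                gene_sets,
                n_perm=config.gsea_n_perm,
                seed=config.seed,
                weight_p=config.gsea_weight_p,
                min_size=config.gsea_min_size,
                max_size=config.gsea_max_size,
            )
            _write_tsv(gsea_result.table, out_dir / "gsea.tsv", "set")
            record(out_dir / "gsea.tsv")
            top = gsea_result.top_sets(config.gsea_top_n, config.gsea_top_n)
            _write_tsv(top, out_dir / "gsea_top.tsv", "set")
            record(out_dir / "gsea_top.tsv")
            le = gsea_result.leading_edge_collection(list(top.index))
            io.write_gmt(le, out_dir / "leading_edges.gmt")
            record(out_dir / "leading_edges.gmt")
            dirs = pd.DataFrame(
                {"direction": {
                    n: gsea_result.directions[n]
                    for n in top.index if n in gsea_result.directions
                }}
            )
            _write_tsv(dirs, out_dir / "leading_edge_directions.tsv", "set")
            record(out_dir / "leading_edge_directions.tsv")
            universe = set().union(*(set(s.genes) for s in le)) if len(le) else set()
            if len(le) >= 2 and universe:
                le_net = overlap_network(
                    {s.name: frozenset(s.genes) for s in le},
                    universe,
                    config.edge_p_threshold,
                )
                _write_tsv(le_net.edge_table(),
                           out_dir / "gsea_network_edges.tsv", "index")
                record(out_dir / "gsea_network_edges.tsv")
        except Exception as exc:  # noqa: BLE001
            raise StageError("gsea", str(exc)) from exc

    score_matrix = partition = None
    score_phenotypes = None
    if "signature" in stages:
        try:
            if gsea_result is not None:
                top = gsea_result.top_sets(config.gsea_top_n, config.gsea_top_n)
                leading = gsea_result.leading_edge_collection(list(top.index))
                directions = {
                    n: gsea_result.directions[n]
                    for n in top.index if n in gsea_result.directions
                }
            else:
                leading = io.read_gmt(config.leading_edges)
                dir_df = pd.read_csv(config.directions, sep="\t", comment="#")
                directions = dict(
                    zip(dir_df.iloc[:, 0], dir_df.iloc[:, 1])
                )
            if config.validation_expression is not None:
                val_matrix = io.read_expression(config.validation_expression)
                score_phenotypes = (
                    io.read_phenotypes(config.validation_phenotypes)
                    if config.validation_phenotypes is not None
                    else None
                )
            else:
                val_matrix, score_phenotypes = matrix, phenotypes
            score_matrix = score_samples(
                val_matrix, leading, directions,
                low_coverage=config.signature_coverage_min,
            )
            _write_tsv(score_matrix.raw, out_dir / "signature_scores.tsv",
                       "sample_id")
            _write_tsv(score_matrix.zscores, out_dir / "signature_zscores.tsv",
                       "sample_id")
            record(out_dir / "signature_scores.tsv")
            record(out_dir / "signature_zscores.tsv")
            partition = classify_cohort(score_matrix)
            part_df = partition.labels.to_frame("label")
            part_df["orientation"] = partition.orientation
            _write_tsv(part_df, out_dir / "signature_partition.tsv", "sample_id")
            record(out_dir / "signature_partition.tsv")
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("signature", str(exc)) from exc

    if "survival" in stages:
        try:
            if score_phenotypes is None or not score_phenotypes.has_survival:
                raise ValueError(
                    "survival stage needs survival-annotated phenotypes for "
                    "the scored cohort"
                )
            comparison = logrank_compare(score_phenotypes, partition)
            summary = pd.DataFrame(
                {
                    "statistic": [comparison.statistic],
                    "p_value": [comparison.p_value],
                    **{
                        f"median_{k}": [v]
                        for k, v in comparison.median_survival.items()
                    },
                    **{
                        f"n_{k}": [v] for k, v in comparison.group_sizes.items()
                    },
                }
            )
            _write_tsv(summary, out_dir / "survival.tsv", "index")
            record(out_dir / "survival.tsv")
            for label, table in comparison.km_tables.items():
                path = out_dir / f"km_{label}.tsv"
                _write_tsv(table, path, "time")
                record(path)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("survival", str(exc)) from exc

    if "moa" in stages:
        try:
            network = io.read_network(config.network)
            moa = rank_moa(
                matrix,
                phenotypes,
                network,
                n_bins=config.moa_n_bins,
                n_perm=config.moa_n_perm,
                seed=config.seed,
            )
            _write_tsv(moa.table, out_dir / "moa.tsv", "gene")
            _write_tsv(moa.edge_table, out_dir / "moa_edges.tsv", "index")
            record(out_dir / "moa.tsv")
            record(out_dir / "moa_edges.tsv")
        except Exception as exc:  # noqa: BLE001
            raise StageError("moa", str(exc)) from exc

    manifest = RunManifest(
        config=config.to_dict(),
        version=__version__,
        seed=config.seed,
        started=started,
        finished=time.time(),
        outputs=outputs,
    )
    manifest.write(out_dir / "manifest.json")
    return manifest
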