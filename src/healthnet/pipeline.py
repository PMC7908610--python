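"""End-to-end analysis driver: inputs -> gravity network -> SNA report.

:func:`run_full_analysis` chains the stages — load or simulate a
province table and distances, assemble the gravity matrix, binarize it,
compute whole-network and per-province measures, partition with CONCOR
and build the block tables — and optionally writes the whole bundle as
CSVs plus a provenance record. The same configuration and seed always
produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .concor import (
    BlockDensityImage,
    BlockPartition,
    block_density_image,
    block_spillover_table,
    concor_partition,
)
from .errors import ConfigurationError, PipelineError
from .gravity import binarize, gravity_matrix
from .io import (
    FLOAT_FORMAT,
    read_distance_matrix,
    read_province_table,
    write_adjacency_matrix,
    write_distance_matrix,
    write_edge_list,
    write_graphml,
    write_gravity_matrix,
    write_province_table,
)
from .metrics import NetworkSummary, centrality_table, network_summary
from .simulate import generate_distances, generate_provinces
from .types import AdjacencyMatrix, DistanceMatrix, GravityMatrix, ProvinceTable

logger = logging.getLogger(__name__)

PERCENT_COLUMNS = (
    "degree_centrality",
    "closeness_centrality",
    "betweenness_centrality",
    "expected_ratio",
    "actual_ratio",
)
INDEX_COLUMNS = ("density", "connectedness", "hierarchy", "efficiency")


@dataclass
class AnalysisConfig:
    """Pipeline configuration.

    Either ``provinces_path``/``distances_path`` point at input CSVs, or
    (``n``, ``regime``, ``seed``) drive the synthetic generator.
    """

    # inputs
    provinces_path: str | None = None
    distances_path: str | None = None
    n: int = 31
    regime: str = "balanced"
    seed: int = 0
    # gravity
    economic_distance_floor: float | None = None
    # centrality
    centrality_mode: str = "symmetrized"
    # CONCOR / blockmodel
    depth: int = 2
    criterion: float = 0.2
    max_iter: int = 25
    cutoff: float | str = "auto"  # "auto" = whole-network density
    theta: float = 2.0
    rho: float = 0.3
    role_overrides: dict[int, str] = field(default_factory=dict)
    # output
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ConfigurationError(f"depth must be >= 1, got {self.depth}")
        if not (0 < self.criterion < 1):
            raise ConfigurationError(
                f"criterion must be in (0, 1), got {self.criterion}"
            )
        if self.theta <= 0 or self.rho <= 0:
            raise ConfigurationError("theta and rho must be > 0")
        if (self.provinces_path is None) != (self.distances_path is None):
            raise ConfigurationError(
                "provinces_path and distances_path must be given together"
            )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        """Load a config file; keyword overrides (e.g. CLI flags) win."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class ReportBundle:
    """All pipeline outputs for one run, in input province order."""

    table: ProvinceTable
    distances: DistanceMatrix
    gravity: GravityMatrix
    adjacency: AdjacencyMatrix
    summary: NetworkSummary
    centrality: "pd.DataFrame"  # noqa: F821 - typing only
    partition: BlockPartition
    spillover: "pd.DataFrame"  # noqa: F821
    density_image: BlockDensityImage
    config: AnalysisConfig


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    return wrap


def run_full_analysis(config: AnalysisConfig) -> ReportBundle:
    """Execute the full pipeline described by ``config``.

    Stage errors are re-raised as :class:`PipelineError` naming the
    stage; when an output directory is configured, partially written
    outputs are removed on failure.
    """
    if config.provinces_path is not None:
        table = _stage("read_inputs")(read_province_table, config.provinces_path)
        distances = _stage("read_inputs")(read_distance_matrix, config.distances_path)
    else:
        table = _stage("simulate")(
            generate_provinces, config.n, config.regime, config.seed
        )
        distances = _stage("simulate")(generate_distances, table, config.seed)
    logger.info("inputs: %d provinces", len(table))

    Y = _stage("gravity")(
        gravity_matrix,
        table,
        distances,
        economic_distance_floor=config.economic_distance_floor,
    )
    A = _stage("binarize")(binarize, Y)
    logger.info("network: %d nodes, %d arcs", A.n, A.n_arcs)

    summary = _stage("network_summary")(network_summary, A)
    centrality = _stage("centrality")(centrality_table, A, config.centrality_mode)
    partition = _stage("concor")(
        concor_partition, A, config.depth, config.criterion, config.max_iter
    )
    spillover = _stage("block_spillover")(
        block_spillover_table,
        A,
        partition,
        theta=config.theta,
        rho=config.rho,
        role_overrides=config.role_overrides or None,
    )
    cutoff = None if config.cutoff == "auto" else float(config.cutoff)
    density_image = _stage("block_density")(block_density_image, A, partition, cutoff)

    bundle = ReportBundle(
        table=table,
        distances=distances,
        gravity=Y,
        adjacency=A,
        summary=summary,
        centrality=centrality,
        partition=partition,
        spillover=spillover,
        density_image=density_image,
        config=config,
    )
    if config.out_dir is not None:
        write_bundle(bundle, config.out_dir)
    return bundle


def _rounded(frame, percents=PERCENT_COLUMNS, indices=INDEX_COLUMNS):
    frame = frame.copy()
    for col in frame.columns:
        if col in percents:
            frame[col] = frame[col].round(3)
        elif col in indices:
            frame[col] = frame[col].round(4)
    return frame


def write_bundle(bundle: ReportBundle, out_dir: str | Path) -> None:
    """Write every bundle artifact as CSV (plus edge list, GraphML and a
    JSON provenance record) into ``out_dir``; cleans up on failure."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def target(name: str) -> Path:
        p = out / name
        written.append(p)
        return p

    try:
        write_province_table(bundle.table, target("provinces.csv"))
        write_distance_matrix(bundle.distances, target("distances.csv"))
        write_gravity_matrix(bundle.gravity, target("gravity.csv"))
        write_adjacency_matrix(bundle.adjacency, target("adjacency.csv"))
        write_edge_list(bundle.adjacency, target("edge_list.csv"))
        write_graphml(bundle.adjacency, target("adjacency.graphml"))
        _rounded(bundle.summary.to_frame()).to_csv(
            target("network_summary.csv"), index=False, float_format=FLOAT_FORMAT
        )
        _rounded(bundle.centrality).to_csv(
            target("centrality.csv"), index=False, float_format=FLOAT_FORMAT
        )
        bundle.partition.to_frame().to_csv(target("partition.csv"), index=False)
        _rounded(bundle.spillover).to_csv(
            target("block_spillover.csv"), index=False, float_format=FLOAT_FORMAT
        )
        bundle.density_image.density_frame().round(4).to_csv(
            target("block_density.csv"), float_format=FLOAT_FORMAT
        )
        bundle.density_image.image_frame().to_csv(target("block_image.csv"))
        provenance = {
            "software": {"name": "healthnet", "version": __version__},
            "config": bundle.config.to_dict(),
            "n_nodes": bundle.summary.n_nodes,
            "n_arcs": bundle.summary.n_arcs,
            "fit_r2": round(bundle.density_image.fit_r2, 6),
        }
        with open(target("provenance.json"), "w") as fh:
            json.dump(provenance, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
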