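"""End-to-end pipeline: structures → ANM → tiles → weights → islands → paths.

Stage order follows the method: load the query and target structures,
compute each protein's cross-correlation matrix from its lowest normal
modes, score every query-target tile pair on the three similarity
metrics, optimize the metric weights by Bayesian optimization, build the
weighted-sum landscape over tile lengths 6..⌊N_q/2⌋, mask tiles without
a coordinating cysteine, segment islands, run the dynamic-programming
optimal path per island, pick each path's converged tile length, and map
the matches back onto the target.  The ranking thresholds (cosine ≥ 0.5,
sequence ≥ 50%, top 20% per length class) form a separate selection
track whose surviving tiles are exported alongside the island results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anm import AnmParams, CrossCorrelationMatrix, compute_cross_correlation
from .errors import ConfigError
from .islands import (
    FilterParams,
    Island,
    IslandTileMatrix,
    build_tile_matrix,
    cys_fe_filter,
    segment_islands,
)
from .paths import OptimalPath, optimal_path_for_island, path_table
from .ranking import (
    assemble_matches,
    composite_rank,
    export_dynamics_vs_structure,
    threshold_filter,
)
from .structure_io import (
    DEFAULT_FE_CLUSTER_NAMES,
    CaStructure,
    FeSite,
    MatchRecord,
    extract_fe_sites,
    load_structure,
    write_match_table,
    write_pymol_script,
)
from .tiling import ScoreTable, build_score_table, make_aligner
from .weights import OptimizationTrace, WeightVector, optimize_weights, weighted_column

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything needed for a reproducible run."""

    query_path: str
    target_path: str
    out_dir: str = "dynatile_out"
    query_chains: list[str] | None = None
    target_chains: list[str] | None = None
    gamma: float = 1.0
    cutoff: float = 15.0
    n_modes: int = 10
    r_min: float = 2.18
    r_max: float = 2.35
    l_min: int = 6
    l_max: int | None = None  # scoring range upper bound; default: query length
    landscape_l_max: int | None = None  # default: ⌊N_query/2⌋
    apply_threshold: bool = True  # compute/export the §-style top-tile track
    n_random: int = 15
    n_guided: int = 100
    seed: int = 0
    smooth_sigma: float = 2.0
    window: int = 5
    eps: float = 0.005
    gap_scores: str | None = None  # None = aligner default; or preset name
    fe_cluster_names: list[str] = field(
        default_factory=lambda: sorted(DEFAULT_FE_CLUSTER_NAMES)
    )
    fig8_length: int = 30
    use_cache: bool = True

    @property
    def anm_params(self) -> AnmParams:
        return AnmParams(gamma=self.gamma, cutoff=self.cutoff, n_modes=self.n_modes)

    @property
    def filter_params(self) -> FilterParams:
        return FilterParams(r_min=self.r_min, r_max=self.r_max)

    def params_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


@dataclass
class PipelineResult:
    query: CaStructure
    target: CaStructure
    fe_sites: list[FeSite]
    table: ScoreTable
    weights: WeightVector
    trace: OptimizationTrace
    landscape: IslandTileMatrix
    filtered: IslandTileMatrix
    islands: list[Island]
    paths: dict[str, OptimalPath]
    matches: list[MatchRecord]
    top_tiles: pd.DataFrame | None = None
    out_dir: Path | None = None


def cached_cross_correlation(
    structure: CaStructure, params: AnmParams, cache_dir: Path | None
) -> CrossCorrelationMatrix:
    """ANM cross-correlation with an optional on-disk cache.

    Cache files are .npz keyed by structure id, residue count and ANM
    parameters (format version 1: array 'values', scalar 'n_modes_used').
    """
    if cache_dir is None:
        return compute_cross_correlation(structure, params)
    cache_dir.mkdir(parents=True, exist_ok=True)
    key = f"corr_v1_{structure.source_id}_N{structure.n_residues}_{params.cache_key()}.npz"
    path = cache_dir / key
    if path.exists():
        data = np.load(path)
        return CrossCorrelationMatrix(
            values=data["values"], n_modes_used=int(data["n_modes_used"])
        )
    corr = compute_cross_correlation(structure, params)
    np.savez_compressed(path, values=corr.values, n_modes_used=corr.n_modes_used)
    return corr


def _log_stage(name: str, t0: float) -> float:
    now = time.perf_counter()
    logger.info("stage %-16s %8.2f s", name, now - t0)
    return now


def run_pipeline(config: PipelineConfig, write_outputs: bool = True) -> PipelineResult:
    """Execute the full pipeline; see the module docstring for the stages.

    Re-running with the same config and seed reproduces every numeric
    output (the weight optimizer is the only stochastic stage).
    """
    for label, p in (("query", config.query_path), ("target", config.target_path)):
        if not Path(p).exists():
            raise ConfigError(f"{label} structure file not found: {p}")
    out_dir = Path(config.out_dir)
    cache_dir = out_dir / "cache" if config.use_cache else None
    if write_outputs:
        out_dir.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    query = load_structure(config.query_path, chains=config.query_chains)
    target = load_structure(config.target_path, chains=config.target_chains)
    fe_sites = extract_fe_sites(config.target_path, config.fe_cluster_names)
    t0 = _log_stage("load", t0)

    corr_q = cached_cross_correlation(query, config.anm_params, cache_dir)
    corr_t = cached_cross_correlation(target, config.anm_params, cache_dir)
    t0 = _log_stage("anm", t0)

    l_max = config.l_max if config.l_max is not None else query.n_residues
    l_max = min(l_max, query.n_residues, target.n_residues)
    aligner = make_aligner(config.gap_scores)
    table = build_score_table(
        corr_q, corr_t, query, target, l_min=config.l_min, l_max=l_max, aligner=aligner
    )
    t0 = _log_stage("score", t0)

    weights, trace = optimize_weights(
        table, n_random=config.n_random, n_guided=config.n_guided, seed=config.seed
    )
    t0 = _log_stage("optimize-weights", t0)

    top_tiles = (
        threshold_filter(composite_rank(table), query.n_residues)
        if config.apply_threshold
        else None
    )

    land_l_max = (
        config.landscape_l_max
        if config.landscape_l_max is not None
        else query.n_residues // 2
    )
    land_df = table.df[table.df["length"] <= land_l_max]
    if len(land_df) == 0:
        raise ConfigError(f"no tile pairs at lengths <= {land_l_max}")
    landscape = build_tile_matrix(land_df, weights, target.n_residues)
    filtered = cys_fe_filter(landscape, target, fe_sites, config.filter_params)
    islands = segment_islands(filtered)
    t0 = _log_stage("islands", t0)

    paths: dict[str, OptimalPath] = {}
    for island in islands:
        paths[island.island_id] = optimal_path_for_island(filtered, island)

    lookup = land_df.copy()
    lookup["s_weighted"] = weighted_column(lookup, weights)
    matches = assemble_matches(
        paths,
        islands,
        filtered,
        target,
        smooth_sigma=config.smooth_sigma,
        window=config.window,
        eps=config.eps,
        score_lookup=lookup,
    )
    t0 = _log_stage("matches", t0)

    result = PipelineResult(
        query=query,
        target=target,
        fe_sites=fe_sites,
        table=table,
        weights=weights,
        trace=trace,
        landscape=landscape,
        filtered=filtered,
        islands=islands,
        paths=paths,
        matches=matches,
        top_tiles=top_tiles,
        out_dir=out_dir if write_outputs else None,
    )
    if write_outputs:
        write_results(result, config)
        _log_stage("write", t0)
    return result


def write_results(result: PipelineResult, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.table.to_tsv(out / "scores.tsv")
    result.trace.to_tsv(out / "weight_trace.tsv")
    if result.top_tiles is not None:
        result.top_tiles.to_csv(out / "top_tiles.tsv", sep="\t", index=False)
    result.filtered.to_long_frame(result.islands).to_csv(
        out / "landscape.tsv", sep="\t", index=False
    )
    if result.paths:
        pd.concat(
            [
                path_table(result.paths[isl.island_id], result.filtered, isl)
                for isl in result.islands
            ],
            ignore_index=True,
        ).to_csv(out / "paths.tsv", sep="\t", index=False)
    write_match_table(result.matches, out / "matches.tsv")
    if result.matches:
        write_pymol_script(result.matches, out / "matches.pml")
    fig8 = export_dynamics_vs_structure(result.table, config.fig8_length)
    fig8.to_csv(out / "dynamics_vs_structure.tsv", sep="\t", index=False)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "params_hash": config.params_hash(),
        "config": asdict(config),
        "query": {"id": result.query.source_id, "n_residues": result.query.n_residues},
        "target": {"id": result.target.source_id, "n_residues": result.target.n_residues},
        "n_fe_sites": len(result.fe_sites),
        "weights": {
            "w_cosine": result.weights.w_cosine,
            "w_frobenius": result.weights.w_frobenius,
            "w_sw": result.weights.w_sw,
        },
        "n_islands": len(result.islands),
        "islands": {
            isl.island_id: {"center_range": list(isl.center_range)} for isl in result.islands
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
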