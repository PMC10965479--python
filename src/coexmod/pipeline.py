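"""End-to-end orchestration: catalog -> per-cohort network -> enrichment ->
consensus replication ranking.

Cohorts are processed in catalog order. A cohort that fails (unreadable
matrix, no module passing the enrichment threshold, ...) is logged and
skipped rather than aborting the run; the run as a whole succeeds when at
least one cohort yields a target-module call.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import io
from .consensus import classify_known, count_unique_module_genes, tally_replication, write_report
from .enrichment import (
    TargetModuleCall,
    enrich_modules,
    select_target_module,
    write_enrichment_report,
)
from .network import ModulePartition, NetworkParams, build_network, write_partition

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs, loadable from a YAML file.

    Paths are resolved relative to the config file's directory (or the
    current directory when built in code); expression paths in the catalog
    are resolved relative to the catalog file.
    """

    catalog: str
    target_gmt: str
    target_set: str
    out_dir: str
    known_gmt: str | None = None
    network_type: str = "unsigned"
    beta: int | None = None
    r2_threshold: float = 0.8
    fallback_beta: int = 6
    min_fraction_present: float = 0.5
    max_genes: int | None = None
    min_module_size: int = 10
    cut_height: float = 0.995
    merge_height: float = 0.25
    alpha: float = 0.05
    min_replication: int = 11
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, overrides: Sequence[str] = ()) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**raw)
        cfg.apply_overrides(overrides)
        base = Path(path).parent
        for attr in ("catalog", "target_gmt", "known_gmt", "out_dir"):
            value = getattr(cfg, attr)
            if value is not None and not Path(value).is_absolute():
                setattr(cfg, attr, str(base / value))
        return cfg

    def apply_overrides(self, overrides: Sequence[str]) -> None:
        """Apply ``key=value`` overrides with field-type coercion."""
        types = {f.name: f.type for f in dataclasses.fields(self)}
        for item in overrides:
            if "=" not in item:
                raise ValueError(f"override must look like key=value, got {item!r}")
            key, value = item.split("=", 1)
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            setattr(self, key, _coerce(value, types[key]))

    def validate(self) -> None:
        for label, p in (("catalog", self.catalog), ("target_gmt", self.target_gmt)):
            if not Path(p).exists():
                raise FileNotFoundError(f"{label} file not found: {p}")
        if self.known_gmt is not None and not Path(self.known_gmt).exists():
            raise FileNotFoundError(f"known_gmt file not found: {self.known_gmt}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_replication < 1:
            raise ValueError("min_replication must be >= 1")
        if not 0 < self.cut_height <= 1:
            raise ValueError("cut_height must be in (0, 1]")
        if not 0 < self.merge_height <= 1:
            raise ValueError("merge_height must be in (0, 1]")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")

    def network_params(self) -> NetworkParams:
        return NetworkParams(
            beta=self.beta,
            network_type=self.network_type,
            r2_threshold=self.r2_threshold,
            fallback_beta=self.fallback_beta,
        )


def _coerce(value: str, typ) -> object:
    text = str(typ)
    if value.lower() in ("none", "null"):
        return None
    if "int" in text:
        return int(value)
    if "float" in text:
        return float(value)
    if "bool" in text:
        return value.lower() in ("1", "true", "yes")
    return value


@dataclass
class PipelineResult:
    calls: list[TargetModuleCall]
    table: pd.DataFrame
    partitions: dict[str, ModulePartition]
    universes: dict[str, frozenset[str]]
    candidates: list[str]
    n_unique_module_genes: int
    skipped: list[str] = field(default_factory=list)
    report_paths: dict[str, Path] = field(default_factory=dict)

    @property
    def succeeded(self) -> bool:
        return len(self.calls) > 0


def run_pipeline(config: RunConfig, keep_partitions: bool = True) -> PipelineResult:
    """Run the full discovery pipeline described by ``config``.

    Returns a :class:`PipelineResult`; ``result.succeeded`` is False when
    no cohort produced a target-module call (the CLI maps that to a
    nonzero exit status).
    """
    config.validate()
    records = io.read_catalog(config.catalog)
    summary = io.summarize_catalog(records)
    gmt = io.read_gmt(config.target_gmt)
    by_name = {s.name: s for s in gmt}
    if config.target_set not in by_name:
        raise ValueError(
            f"target set {config.target_set!r} not in {config.target_gmt} "
            f"(available: {sorted(by_name)})"
        )
    target = by_name[config.target_set]
    known_sets = io.read_gmt(config.known_gmt) if config.known_gmt else list(gmt)

    catalog_dir = Path(config.catalog).parent
    calls: list[TargetModuleCall] = []
    partitions: dict[str, ModulePartition] = {}
    universes: dict[str, frozenset[str]] = {}
    skipped: list[str] = []
    for rec in records:
        t0 = time.perf_counter()
        try:
            path = Path(rec.path)
            if not path.is_absolute():
                path = catalog_dir / path
            matrix = io.read_expression_matrix(path)
            matrix = io.preprocess_matrix(
                matrix,
                min_fraction_present=config.min_fraction_present,
                max_genes=config.max_genes,
            )
            partition = build_network(
                matrix,
                params=config.network_params(),
                min_module_size=config.min_module_size,
                cut_height=config.cut_height,
                merge_height=config.merge_height,
            )
            universe = frozenset(matrix.index)
            results = enrich_modules(partition, target, universe)
            call = select_target_module(results, partition, rec.dataset_id, alpha=config.alpha)
            per_ds = Path(config.out_dir) / "per_dataset"
            write_partition(partition, per_ds, rec.dataset_id)
            write_enrichment_report(
                results,
                call.module_label if call else None,
                per_ds / f"{rec.dataset_id}.enrichment.tsv",
            )
            universes[rec.dataset_id] = universe
            if keep_partitions:
                partitions[rec.dataset_id] = partition
            best_p = min((r.p_value for r in results), default=float("nan"))
            logger.info(
                "dataset %s: stage=complete elapsed=%.1fs beta=%s modules=%d best_p=%.3g call=%s",
                rec.dataset_id,
                time.perf_counter() - t0,
                partition.log.get("beta"),
                len(partition.module_labels),
                best_p,
                call.module_label if call else "none",
            )
            if call is None:
                skipped.append(rec.dataset_id)
            else:
                calls.append(call)
        except (OSError, ValueError) as exc:
            logger.warning("dataset %s: skipped (%s)", rec.dataset_id, exc)
            skipped.append(rec.dataset_id)

    if not calls:
        logger.error("no dataset produced a target-module call")
        return PipelineResult(
            calls=[], table=pd.DataFrame(), partitions=partitions,
            universes=universes, candidates=[], n_unique_module_genes=0,
            skipped=skipped,
        )

    table = tally_replication(calls, universes)
    table = classify_known(table, known_sets)
    candidates = [
        g for g in table.loc[
            table["replication_count"] >= config.min_replication, "gene"
        ]
    ]
    params = {
        k: v for k, v in dataclasses.asdict(config).items() if k != "log_level"
    }
    report_paths = write_report(config.out_dir, table, calls, summary, params=params)
    return PipelineResult(
        calls=calls,
        table=table,
        partitions=partitions,
        universes=universes,
        candidates=candidates,
        n_unique_module_genes=count_unique_module_genes(calls),
        skipped=skipped,
        report_paths=report_paths,
    )
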