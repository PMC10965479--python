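"""Cross-cohort replication ranking of target-module members.

After every cohort has (or has not) yielded a target-module call, each
gene is scored by its **replication count**: the number of cohorts whose
called module contains it. Genes are ranked by that count, annotated with
whether they already have a described role (membership in any known-role
gene set), and thresholded into a candidate list — the discovery output
of the framework. The number of cohorts that actually measured each gene
is reported alongside so that "absent from the module" can be told apart
from "not on that platform".
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .io import GeneSet
from .enrichment import TargetModuleCall

__all__ = [
    "OverlapStat",
    "tally_replication",
    "select_candidates",
    "classify_known",
    "count_unique_module_genes",
    "overlap_with_external_module",
    "write_report",
]

REPLICATION_COLUMNS = [
    "gene",
    "replication_count",
    "n_datasets_measured",
    "known_role",
    "known_categories",
]


@dataclass(frozen=True)
class OverlapStat:
    """Overlap of an external module's gene list with the consensus pool."""

    external_size: int
    consensus_pool_size: int
    overlap_count: int

    @property
    def fraction(self) -> float:
        return self.overlap_count / self.external_size

    @property
    def percent(self) -> int:
        """Overlap as a whole percent of the external set, as printed in reports."""
        return round(100.0 * self.fraction)

    def __str__(self) -> str:
        return f"{self.overlap_count}/{self.external_size} ({self.percent}% overlap)"


def tally_replication(
    calls: Sequence[TargetModuleCall], measured: Mapping[str, set[str] | frozenset[str]]
) -> pd.DataFrame:
    """Build the replication table from per-cohort target-module calls.

    One row per gene appearing in at least one call, sorted by descending
    replication count with alphabetical tie-break. ``measured`` maps each
    dataset id to its post-preprocessing gene universe and feeds the
    ``n_datasets_measured`` column.
    """
    if not calls:
        raise ValueError("tally_replication requires at least one call")
    for call in calls:
        if call.dataset_id not in measured:
            raise ValueError(f"no universe supplied for dataset {call.dataset_id!r}")
        stray = call.member_genes - frozenset(measured[call.dataset_id])
        if stray:
            raise ValueError(
                f"dataset {call.dataset_id!r}: call members outside its universe: "
                f"{sorted(stray)[:5]}"
            )
    counts: dict[str, int] = {}
    for call in calls:
        for gene in call.member_genes:
            counts[gene] = counts.get(gene, 0) + 1
    rows = []
    for gene in sorted(counts):
        rows.append(
            {
                "gene": gene,
                "replication_count": counts[gene],
                "n_datasets_measured": sum(gene in u for u in measured.values()),
                "known_role": False,
                "known_categories": [],
            }
        )
    table = pd.DataFrame(rows, columns=REPLICATION_COLUMNS)
    return table.sort_values(
        ["replication_count", "gene"], ascending=[False, True], ignore_index=True
    )


def select_candidates(table: pd.DataFrame, min_replication: int = 11) -> list[str]:
    """Genes replicating in at least ``min_replication`` cohorts, in table order.

    The default of 11 encodes the "replicated more than ten times"
    discovery threshold.
    """
    if min_replication < 1:
        raise ValueError(f"min_replication must be >= 1, got {min_replication}")
    keep = table["replication_count"] >= min_replication
    return table.loc[keep, "gene"].tolist()


def classify_known(table: pd.DataFrame, known_sets: Sequence[GeneSet]) -> pd.DataFrame:
    """Annotate the replication table with known-role membership."""
    if not known_sets:
        raise ValueError("classify_known requires at least one known set")
    out = table.copy()
    categories = [
        sorted(s.name for s in known_sets if gene in s.genes) for gene in out["gene"]
    ]
    out["known_categories"] = categories
    out["known_role"] = [bool(c) for c in categories]
    return out


def count_unique_module_genes(calls: Sequence[TargetModuleCall]) -> int:
    """Number of distinct genes in the union of all called target modules."""
    if not calls:
        raise ValueError("count_unique_module_genes requires at least one call")
    union: set[str] = set()
    for call in calls:
        union |= call.member_genes
    return len(union)


def overlap_with_external_module(
    consensus_pool: set[str] | frozenset[str], external: GeneSet
) -> OverlapStat:
    """Overlap of an external (e.g. human liver) module with the consensus pool.

    The fraction denominates by the external set's size, matching how
    cross-species module overlap is conventionally reported.
    """
    if not external.genes:
        raise ValueError("external gene set is empty")
    if not consensus_pool:
        raise ValueError("consensus pool is empty")
    return OverlapStat(
        external_size=len(external.genes),
        consensus_pool_size=len(consensus_pool),
        overlap_count=len(external.genes & frozenset(consensus_pool)),
    )


def write_report(
    out_dir: str | Path,
    table: pd.DataFrame,
    calls: Sequence[TargetModuleCall],
    summary,
    params: Mapping | None = None,
) -> dict[str, Path]:
    """Write the replication table, per-cohort calls, catalog summary and manifest.

    Output is deterministic: identical inputs give byte-identical files
    (UTF-8, LF line endings, fixed float formatting, no timestamps).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "replication": out / "replication.tsv",
        "calls": out / "calls.tsv",
        "summary": out / "catalog_summary.tsv",
        "manifest": out / "manifest.yaml",
    }
    rep = table.copy()
    rep["known_categories"] = [";".join(c) for c in rep["known_categories"]]
    rep.to_csv(paths["replication"], sep="\t", index=False, lineterminator="\n")

    call_rows = [
        {
            "dataset_id": c.dataset_id,
            "module_label": c.module_label,
            "n": c.enrichment.n,
            "k": c.enrichment.k,
            "K": c.enrichment.K,
            "N": c.enrichment.N,
            "p_value": f"{c.enrichment.p_value:.6g}",
        }
        for c in calls
    ]
    pd.DataFrame(
        call_rows, columns=["dataset_id", "module_label", "n", "k", "K", "N", "p_value"]
    ).to_csv(paths["calls"], sep="\t", index=False, lineterminator="\n")

    with open(paths["summary"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("statistic\tvalue\n")
        fh.write(f"n_datasets\t{summary.n_datasets}\n")
        fh.write(f"total_samples\t{summary.total_samples}\n")
        for sex in sorted(summary.per_sex):
            fh.write(f"n_datasets_{sex}\t{summary.per_sex[sex]}\n")

    from . import __version__

    manifest = {"coexmod_version": __version__, "parameters": dict(params or {})}
    with open(paths["manifest"], "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True, default_flow_style=False)
    return paths
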