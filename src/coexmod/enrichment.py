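"""Hypergeometric gene-set enrichment and target-module calling.

Each cohort's modules are scored against a target gene set (here, the
cholesterol biosynthetic process) with the one-sided hypergeometric upper
tail — the canonical GO over-representation statistic, equivalent to the
one-sided Fisher exact test. The enrichment universe is the set of genes
measured in that cohort after preprocessing, so scores are
platform-relative. The module with the smallest p-value below ``alpha``
becomes that cohort's "cholesterol module" call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from math import exp, inf, lgamma

from .io import GeneSet
from .network import ModulePartition

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "TargetModuleCall",
    "hypergeometric_p",
    "enrich_modules",
    "select_target_module",
    "write_enrichment_report",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric overlap of one module with the target gene set.

    k: overlap count; n: module size; K: target genes present in the
    universe; N: universe size; p_value: P(X >= k).
    """

    module_label: int
    k: int
    n: int
    K: int
    N: int
    p_value: float

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K) and self.n <= self.N and self.K <= self.N):
            raise ValueError(
                f"inconsistent counts: k={self.k} n={self.n} K={self.K} N={self.N}"
            )
        if not 0 < self.p_value <= 1:
            raise ValueError(f"p_value out of (0, 1]: {self.p_value}")


@dataclass(frozen=True)
class TargetModuleCall:
    """The enriched target ("cholesterol") module called for one cohort."""

    dataset_id: str
    module_label: int
    member_genes: frozenset[str]
    enrichment: EnrichmentResult

    def __post_init__(self) -> None:
        if len(self.member_genes) != self.enrichment.n:
            raise ValueError("member_genes size disagrees with enrichment.n")


def _log_comb(a: int, b: int) -> float:
    if b < 0 or b > a:
        return -inf  # C(a, b) = 0 outside the support
    return lgamma(a + 1) - lgamma(b + 1) - lgamma(a - b + 1)


def hypergeometric_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail probability P(X >= k) for X ~ Hypergeometric(N, K, n).

    Drawing ``n`` genes from a universe of ``N`` containing ``K`` target
    genes, the probability of seeing ``k`` or more target genes. Terms are
    accumulated in log space (log-sum-exp) for numerical stability.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    if k > min(n, K) or n > N or K > N:
        raise ValueError(f"inconsistent counts: k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    log_denom = _log_comb(N, n)
    log_terms = [
        _log_comb(K, x) + _log_comb(N - K, n - x) - log_denom
        for x in range(k, min(n, K) + 1)
    ]
    peak = max(log_terms)
    if peak == -inf:
        return 0.0
    return min(1.0, exp(peak) * sum(exp(t - peak) for t in log_terms))


def enrich_modules(
    partition: ModulePartition, target: GeneSet, universe: Iterable[str]
) -> list[EnrichmentResult]:
    """Score every non-zero module against the target set.

    ``universe`` must be the genes measured in the cohort after
    preprocessing; every module gene must belong to it. Results are sorted
    by ascending p-value (ties by module label).
    """
    universe = frozenset(universe)
    module_genes = set(partition.labels.index[partition.labels != 0])
    stray = module_genes - universe
    if stray:
        raise ValueError(f"module genes outside the universe: {sorted(stray)[:5]}")
    K = len(target.genes & universe)
    if K == 0:
        raise ValueError(f"target set {target.name!r} absent from universe")
    N = len(universe)
    results = []
    for label in partition.module_labels:
        members = set(partition.members(label))
        k = len(members & target.genes)
        results.append(
            EnrichmentResult(
                module_label=label,
                k=k,
                n=len(members),
                K=K,
                N=N,
                p_value=hypergeometric_p(k, K, len(members), N),
            )
        )
    return sorted(results, key=lambda r: (r.p_value, r.module_label))


def select_target_module(
    results: Sequence[EnrichmentResult],
    partition: ModulePartition,
    dataset_id: str,
    alpha: float = 0.05,
) -> TargetModuleCall | None:
    """Call the cohort's target module: minimum enrichment p below ``alpha``.

    Ties on p-value break toward larger overlap ``k``, then smaller module
    label. Returns ``None`` (with a logged warning) when no module passes
    or ``results`` is empty.
    """
    if not results:
        logger.warning("dataset %s: no modules to score", dataset_id)
        return None
    best = min(results, key=lambda r: (r.p_value, -r.k, r.module_label))
    if best.p_value >= alpha:
        logger.warning(
            "dataset %s: no module enriched below alpha=%g (best p=%.3g)",
            dataset_id, alpha, best.p_value,
        )
        return None
    return TargetModuleCall(
        dataset_id=dataset_id,
        module_label=best.module_label,
        member_genes=frozenset(partition.members(best.module_label)),
        enrichment=best,
    )


def write_enrichment_report(
    results: Sequence[EnrichmentResult],
    called_label: int | None,
    path,
) -> None:
    """Write one cohort's per-module enrichment table as TSV.

    Includes a Bonferroni-adjusted column (across that cohort's modules)
    for information; target-module calling itself uses the raw p-value.
    """
    n_tests = len(results)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("module_label\tn\tk\tK\tN\tp_value\tp_bonferroni\tcalled_flag\n")
        for r in results:
            bonf = min(1.0, r.p_value * n_tests)
            fh.write(
                f"{r.module_label}\t{r.n}\t{r.k}\t{r.K}\t{r.N}\t"
                f"{r.p_value:.6g}\t{bonf:.6g}\t{r.module_label == called_label}\n"
            )
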