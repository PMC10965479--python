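"""Weighted coexpression network construction and module detection.

One cohort's gene-by-sample matrix is turned into a module partition in
six steps:

1. pairwise-complete Pearson correlation between gene profiles;
2. soft-thresholding of the correlation into a weighted adjacency,
   ``a_ij = |r_ij|**beta`` (unsigned) or ``((1 + r_ij)/2)**beta`` (signed),
   with ``beta`` selected by the scale-free topology criterion;
3. topological overlap: similarity of two genes combines their direct
   adjacency with the adjacency they share through common neighbors,
   ``w_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)``;
4. average-linkage hierarchical clustering of the dissimilarity
   ``1 - w``, cut at a fixed fraction of the dendrogram's maximum merge
   height; clusters above a minimum size become modules;
5. per-module eigengenes (first principal component of the standardized
   member profiles, sign-oriented along the module mean);
6. merging of modules whose eigengenes are nearly collinear.

All tie-breaks (module numbering, merge order) resolve by module size and
then by the alphabetically smallest member symbol, so identical inputs
always give identical partitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkParams",
    "SoftThresholdFit",
    "ModulePartition",
    "correlation_matrix",
    "adjacency",
    "pick_soft_threshold",
    "topological_overlap",
    "cluster_modules",
    "module_eigengene",
    "merge_close_modules",
    "build_network",
    "write_partition",
]


@dataclass(frozen=True)
class NetworkParams:
    """Soft-threshold and network-type settings.

    ``beta=None`` requests automatic selection over ``power_grid`` by the
    scale-free topology criterion (smallest power whose signed model fit
    R^2 reaches ``r2_threshold``, else ``fallback_beta``).
    """

    beta: int | None = None
    network_type: str = "unsigned"
    power_grid: tuple[int, ...] = tuple(range(1, 21))
    r2_threshold: float = 0.8
    fallback_beta: int = 6

    def __post_init__(self) -> None:
        if self.network_type not in ("unsigned", "signed"):
            raise ValueError(f"unknown network_type {self.network_type!r}")
        if list(self.power_grid) != sorted(set(self.power_grid)):
            raise ValueError("power_grid must be strictly increasing")
        if not 0 < self.r2_threshold <= 1:
            raise ValueError("r2_threshold must be in (0, 1]")
        if self.fallback_beta < 1:
            raise ValueError("fallback_beta must be >= 1")


@dataclass(frozen=True)
class SoftThresholdFit:
    """Scale-free fit table over candidate powers and the selected power."""

    table: pd.DataFrame  # columns: power, signed_r2, mean_connectivity, median_connectivity
    chosen_beta: int
    used_fallback: bool


@dataclass
class ModulePartition:
    """Gene-to-module assignment for one cohort.

    ``labels`` maps each gene to a non-negative integer module label;
    label 0 means unassigned. ``eigengenes`` maps each non-zero label to a
    unit-norm vector over samples.
    """

    labels: pd.Series
    eigengenes: dict[int, pd.Series] = field(default_factory=dict)
    log: dict = field(default_factory=dict)

    @property
    def module_labels(self) -> list[int]:
        return sorted(int(l) for l in set(self.labels) if l != 0)

    @property
    def module_sizes(self) -> dict[int, int]:
        counts = self.labels[self.labels != 0].value_counts()
        return {int(k): int(v) for k, v in counts.items()}

    def members(self, label: int) -> list[str]:
        if label not in set(self.labels):
            raise KeyError(f"module label {label} not present")
        return list(self.labels.index[self.labels == label])


def correlation_matrix(m: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation between gene profiles.

    Every gene pair must share at least 3 non-missing samples. Pairs whose
    shared observations have zero variance (no estimable linear signal)
    get correlation 0.
    """
    X = m.to_numpy(dtype=float)
    if m.index.has_duplicates:
        raise ValueError("duplicate gene ids in expression matrix")
    if np.isnan(X).any():
        present = (~np.isnan(X)).astype(float)
        counts = present @ present.T
        if counts.min() < 3:
            i, j = np.unravel_index(np.argmin(counts), counts.shape)
            raise ValueError(
                f"gene pair ({m.index[i]}, {m.index[j]}) has "
                f"{int(counts[i, j])} shared observations (< 3)"
            )
        cor = m.T.corr(min_periods=3).to_numpy()
        cor = np.where(np.isnan(cor), 0.0, cor)
    else:
        sd = X.std(axis=1)
        if (sd == 0).any():
            bad = m.index[sd == 0][:5].tolist()
            raise ValueError(f"zero-variance genes (preprocess first): {bad}")
        cor = np.corrcoef(X)
    cor = np.clip((cor + cor.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(cor, 1.0)
    return pd.DataFrame(cor, index=m.index, columns=m.index)


def _check_square_symmetric(values: np.ndarray, lo: float, hi: float, what: str) -> None:
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"{what} must be square")
    if not np.allclose(values, values.T, atol=1e-10):
        raise ValueError(f"{what} must be symmetric")
    if np.nanmin(values) < lo - 1e-12 or np.nanmax(values) > hi + 1e-12:
        raise ValueError(f"{what} entries must lie in [{lo}, {hi}]")


def adjacency(cor: pd.DataFrame, params: NetworkParams) -> pd.DataFrame:
    """Soft-threshold a correlation matrix into a weighted adjacency in [0, 1]."""
    beta = params.beta if params.beta is not None else params.fallback_beta
    if beta < 1:
        raise ValueError(f"beta must be >= 1, got {beta}")
    C = cor.to_numpy(dtype=float)
    _check_square_symmetric(C, -1.0, 1.0, "correlation matrix")
    if params.network_type == "signed":
        A = ((1.0 + C) / 2.0) ** beta
    else:
        A = np.abs(C) ** beta
    np.fill_diagonal(A, 1.0)
    return pd.DataFrame(A, index=cor.index, columns=cor.columns)


def _scale_free_r2(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log10(p(k)) ~ log10(k) regression over binned connectivity.

    Connectivities are histogrammed into 10 equal-width bins. Following the
    standard scale-free fit index, empty bins stay in the regression with
    frequency 0 (represented by their midpoint and a 1e-9 offset inside the
    log), so a gappy connectivity distribution is penalized rather than
    ignored. Returns NaN when the fit is undefined (degenerate connectivity
    spread, or fewer than 3 non-empty bins).
    """
    kmin, kmax = float(k.min()), float(k.max())
    if not np.isfinite(kmax) or kmax <= 0 or np.isclose(kmax, kmin):
        return float("nan")
    edges = np.linspace(kmin, kmax, n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    mids = (edges[:-1] + edges[1:]) / 2.0
    mean_k = np.array(
        [k[which == b].mean() if (which == b).any() else mids[b] for b in range(n_bins)]
    )
    mean_k = np.where(mean_k <= 0, mids, mean_k)
    freq = np.array([(which == b).mean() for b in range(n_bins)])
    if (freq > 0).sum() < 3 or (mean_k <= 0).any():
        return float("nan")
    fit = linregress(np.log10(mean_k), np.log10(freq + 1e-9))
    return float(-np.sign(fit.slope) * fit.rvalue**2)


def pick_soft_threshold(cor: pd.DataFrame, params: NetworkParams) -> SoftThresholdFit:
    """Select the soft-threshold power by the scale-free topology criterion.

    For each candidate power the whole-network connectivities
    ``k_i = sum_{j != i} a_ij`` are binned (10 equal-width bins) and
    log-frequency is regressed on log-mean-connectivity; the signed fit is
    ``-sign(slope) * R^2``. The chosen power is the smallest one reaching
    ``r2_threshold``; if none does, ``fallback_beta`` is used and flagged.
    Powers with degenerate fits are recorded as NaN and skipped.
    """
    if len(cor) < 20:
        raise ValueError(f"scale-free fit needs >= 20 genes, got {len(cor)}")
    rows = []
    chosen: int | None = None
    for power in params.power_grid:
        A = adjacency(cor, replace(params, beta=power)).to_numpy()
        k = A.sum(axis=1) - 1.0  # exclude the unit diagonal
        signed_r2 = _scale_free_r2(k)
        rows.append(
            {
                "power": power,
                "signed_r2": signed_r2,
                "mean_connectivity": float(k.mean()),
                "median_connectivity": float(np.median(k)),
            }
        )
        if chosen is None and np.isfinite(signed_r2) and signed_r2 >= params.r2_threshold:
            chosen = power
    table = pd.DataFrame(rows, columns=["power", "signed_r2", "mean_connectivity", "median_connectivity"])
    if chosen is None:
        return SoftThresholdFit(table=table, chosen_beta=params.fallback_beta, used_fallback=True)
    return SoftThresholdFit(table=table, chosen_beta=chosen, used_fallback=False)


def topological_overlap(a: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of a weighted adjacency.

    ``w_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``l_ij = sum_{u != i,j} a_iu a_uj`` and ``k_i = sum_{u != i} a_iu``;
    the diagonal is 1. The clustering dissimilarity used downstream is
    ``1 - w``.
    """
    A = a.to_numpy(dtype=float)
    _check_square_symmetric(A, 0.0, 1.0, "adjacency matrix")
    if not np.allclose(np.diag(A), 1.0, atol=1e-12):
        raise ValueError("adjacency diagonal must be 1")
    A0 = A.copy()
    np.fill_diagonal(A0, 0.0)
    k = A0.sum(axis=1)
    L = A0 @ A0  # zero diagonal of A0 makes this exactly sum over u != i,j
    denom = np.minimum.outer(k, k) + 1.0 - A0
    tom = (L + A0) / denom
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=a.index, columns=a.columns)


def _relabel_by_size(groups: Mapping[int, Sequence[str]], index: pd.Index) -> pd.Series:
    """Number modules 1.. by decreasing size, ties by smallest member symbol."""
    ordered = sorted(groups.values(), key=lambda g: (-len(g), min(g)))
    labels = pd.Series(0, index=index, dtype=int)
    for new_label, genes in enumerate(ordered, start=1):
        labels.loc[list(genes)] = new_label
    return labels


def cluster_modules(
    diss: pd.DataFrame, min_module_size: int = 10, cut_height: float = 0.995
) -> ModulePartition:
    """Partition genes by average-linkage clustering of a TOM dissimilarity.

    The dendrogram is cut at ``cut_height`` times its maximum merge height;
    clusters of at least ``min_module_size`` genes become modules numbered
    1, 2, ... in decreasing size order (ties by alphabetically smallest
    member); all remaining genes get label 0 (unassigned).
    """
    if min_module_size < 2:
        raise ValueError(f"min_module_size must be >= 2, got {min_module_size}")
    D = diss.to_numpy(dtype=float)
    _check_square_symmetric(D, 0.0, 1.0, "dissimilarity matrix")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("dissimilarity diagonal must be 0")
    Z = linkage(squareform(D, checks=False), method="average")
    cut = cut_height * float(Z[:, 2].max())
    flat = fcluster(Z, t=cut, criterion="distance")
    groups: dict[int, list[str]] = {}
    for gene, cl in zip(diss.index, flat):
        groups.setdefault(int(cl), []).append(gene)
    modules = {cl: genes for cl, genes in groups.items() if len(genes) >= min_module_size}
    return ModulePartition(labels=_relabel_by_size(modules, diss.index))


def module_eigengene(
    m: pd.DataFrame, labels: pd.Series, module_label: int
) -> pd.Series:
    """First principal component of a module's standardized expression.

    Member genes are imputed to their own mean where missing, standardized
    to zero mean / unit variance, and decomposed by SVD. The returned
    sample-score vector has unit norm and is sign-oriented so that its
    correlation with the module's mean standardized profile is >= 0.
    """
    if module_label not in set(labels):
        raise KeyError(f"module label {module_label} not present")
    members = labels.index[labels == module_label]
    if len(members) < 2:
        raise ValueError(f"module {module_label} has {len(members)} genes (< 2)")
    X = m.loc[members].to_numpy(dtype=float)
    row_mean = np.nanmean(X, axis=1, keepdims=True)
    X = np.where(np.isnan(X), row_mean, X)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    _, _, vt = np.linalg.svd(Xs, full_matrices=False)
    eig = vt[0]
    # rows of Xs are centered, so the dot product carries the correlation sign
    if float(eig @ Xs.mean(axis=0)) < 0:
        eig = -eig
    return pd.Series(eig, index=m.columns)


def _eigengene_dissimilarity(a: pd.Series, b: pd.Series) -> float:
    return 1.0 - float(np.corrcoef(a.to_numpy(), b.to_numpy())[0, 1])


def merge_close_modules(
    m: pd.DataFrame, partition: ModulePartition, merge_height: float = 0.25
) -> ModulePartition:
    """Iteratively merge module pairs whose eigengenes nearly coincide.

    At each step the pair with the smallest eigengene dissimilarity
    ``1 - cor`` below ``merge_height`` is merged (ties resolved by smallest
    label pair), the merged eigengene recomputed, and the scan repeated.
    Surviving modules are renumbered by size.
    """
    if not 0 < merge_height <= 1:
        raise ValueError(f"merge_height must be in (0, 1], got {merge_height}")
    labels = partition.labels.copy()
    eigs = dict(partition.eigengenes)
    missing = [l for l in sorted(set(labels) - {0}) if l not in eigs]
    if missing:
        raise ValueError(f"partition lacks eigengenes for modules {missing}")
    while len(eigs) >= 2:
        best_pair, best_d = None, np.inf
        for la, lb in combinations(sorted(eigs), 2):
            d = _eigengene_dissimilarity(eigs[la], eigs[lb])
            if d < best_d:
                best_pair, best_d = (la, lb), d
        if best_pair is None or best_d >= merge_height:
            break
        la, lb = best_pair
        labels[labels == lb] = la
        del eigs[lb]
        eigs[la] = module_eigengene(m, labels, la)
    groups = {l: list(labels.index[labels == l]) for l in sorted(set(labels) - {0})}
    new_labels = _relabel_by_size(groups, labels.index)
    new_eigs: dict[int, pd.Series] = {}
    for old_label, genes in groups.items():
        new_eigs[int(new_labels[genes[0]])] = eigs[old_label]
    return ModulePartition(labels=new_labels, eigengenes=new_eigs, log=dict(partition.log))


def build_network(
    m: pd.DataFrame,
    params: NetworkParams = NetworkParams(),
    min_module_size: int = 10,
    cut_height: float = 0.995,
    merge_height: float = 0.25,
) -> ModulePartition:
    """Full per-cohort pipeline: correlation to merged module partition.

    Composes correlation -> soft-threshold selection (unless ``params.beta``
    is fixed) -> adjacency -> topological overlap -> clustering ->
    eigengenes -> module merging. The chosen power, fallback flag, fit
    table and pre-merge module count are recorded in ``partition.log``.
    """
    cor = correlation_matrix(m)
    if params.beta is None:
        fit = pick_soft_threshold(cor, params)
        beta, used_fallback, fit_table = fit.chosen_beta, fit.used_fallback, fit.table
    else:
        beta, used_fallback, fit_table = params.beta, False, None
    A = adjacency(cor, replace(params, beta=beta))
    tom = topological_overlap(A)
    diss = 1.0 - tom
    np.fill_diagonal(diss.values, 0.0)
    partition = cluster_modules(diss, min_module_size=min_module_size, cut_height=cut_height)
    n_premerge = len(partition.module_labels)
    for label in partition.module_labels:
        partition.eigengenes[label] = module_eigengene(m, partition.labels, label)
    merged = merge_close_modules(m, partition, merge_height=merge_height)
    merged.log = {
        "beta": int(beta),
        "used_fallback": bool(used_fallback),
        "network_type": params.network_type,
        "n_modules_premerge": n_premerge,
        "n_modules": len(merged.module_labels),
        "soft_threshold_table": fit_table,
    }
    logger.info(
        "network built: %d genes, beta=%d%s, %d modules (%d before merging)",
        len(m), beta, " (fallback)" if used_fallback else "", len(merged.module_labels), n_premerge,
    )
    return merged


def write_partition(partition: ModulePartition, out_dir, stem: str) -> None:
    """Write one cohort's partition, eigengenes and run log as TSV files.

    Emits ``<stem>.modules.tsv`` (gene, module_label),
    ``<stem>.eigengenes.tsv`` (samples x modules) and, when the soft
    threshold was selected automatically, ``<stem>.soft_threshold.tsv``
    (the per-power fit table with the chosen beta flagged).
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = partition.labels.rename("module_label")
    labels.index.name = "gene"
    labels.to_csv(out / f"{stem}.modules.tsv", sep="\t", lineterminator="\n")
    if partition.eigengenes:
        eig = pd.DataFrame(
            {f"ME{label}": vec for label, vec in sorted(partition.eigengenes.items())}
        )
        eig.index.name = "sample"
        eig.to_csv(
            out / f"{stem}.eigengenes.tsv", sep="\t",
            float_format="%.6g", lineterminator="\n",
        )
    fit_table = partition.log.get("soft_threshold_table")
    if fit_table is not None:
        table = fit_table.copy()
        table["chosen"] = table["power"] == partition.log.get("beta")
        table.to_csv(
            out / f"{stem}.soft_threshold.tsv", sep="\t", index=False,
            float_format="%.6g", lineterminator="\n",
        )
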