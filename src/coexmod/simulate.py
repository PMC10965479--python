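"""Synthetic multi-cohort expression collections with a planted target module.

The generator emulates the statistical skeleton of a multi-cohort liver
expression compendium: several cohorts of modest sample size, partially
overlapping gene content across platforms, a handful of coexpression
modules driven by latent factors, and a sea of unstructured noise genes.
One module is flagged as the **target** (the cholesterol-biosynthesis
stand-in): it contains a core of known-pathway genes present in every
cohort plus "novel" genes that join the module in each cohort with a
per-gene inclusion probability — the knob that controls how often a novel
gene should replicate downstream.

Model per cohort: each module m gets an i.i.d. standard-normal latent
factor ``f_m`` over samples; a member gene's profile is
``loading * f_m + eps`` with ``eps ~ N(0, noise_sd^2)``; background genes
are pure ``N(0, 1)`` noise. Under this one-factor model the expected
within-module gene-gene correlation is ``loading^2 / (loading^2 +
noise_sd^2)``.

Every collection is written to disk in exactly the formats the pipeline
consumes (catalog TSV, per-cohort expression TSVs, GMT) together with a
machine-readable truth record, and is byte-deterministic in the spec's
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .io import GeneSet, write_gmt
from .enrichment import TargetModuleCall
from .network import ModulePartition

__all__ = [
    "ModuleSpec",
    "NovelGeneSpec",
    "SyntheticSpec",
    "TruthRecord",
    "SyntheticCollection",
    "RecoveryMetrics",
    "default_recovery_spec",
    "generate_collection",
    "read_truth",
    "evaluate_recovery",
    "KNOWN_TARGET_GENES",
]

# Core cholesterol/fatty-acid metabolism symbols used as the planted module's
# "known-role" members: biosynthetic enzymes from acetyl-CoA to cholesterol,
# its transcriptional regulators, uptake/transport genes, and the fatty-acid
# arm that shares the cytosolic acetyl-CoA supply.
KNOWN_TARGET_GENES: tuple[str, ...] = (
    "ACAT2", "HMGCS1", "HMGCR", "MVK", "PMVK", "MVD", "IDI1", "FDPS", "GGPS1",
    "FDFT1", "SQLE", "LSS", "CYP51", "TM7SF2", "MSMO1", "NSDHL", "HSD17B7",
    "EBP", "SC5D", "DHCR7", "DHCR24", "LBR", "SREBF1", "SREBF2", "SCAP",
    "INSIG1", "INSIG2", "LDLR", "PCSK9", "NPC1", "ABCA1", "SOAT1", "STARD4",
    "TMEM97", "MMAB", "CYB5R3", "PDZK1IP1", "ACLY", "ACSS2", "ACSL3", "FASN",
    "ACACA", "ACACB", "ELOVL6", "SCD1",
)


@dataclass(frozen=True)
class ModuleSpec:
    name: str
    size: int
    loading: float
    is_target: bool = False


@dataclass(frozen=True)
class NovelGeneSpec:
    symbol: str
    inclusion_probability: float


def _default_modules() -> tuple[ModuleSpec, ...]:
    background = tuple(
        ModuleSpec(name=f"bg{i}", size=80, loading=0.8) for i in range(1, 6)
    )
    return background + (ModuleSpec(name="target", size=60, loading=0.9, is_target=True),)


def _default_novel() -> tuple[NovelGeneSpec, ...]:
    certain = tuple(NovelGeneSpec(f"NOVEL{i:02d}", 1.0) for i in range(1, 6))
    sometimes = tuple(NovelGeneSpec(f"NOVEL{i:02d}", 0.5) for i in range(6, 16))
    return certain + sometimes


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic multi-cohort collection."""

    n_datasets: int = 8
    samples_per_dataset: int | tuple[int, ...] = 120
    n_genes_global: int = 2000
    modules: tuple[ModuleSpec, ...] = field(default_factory=_default_modules)
    target_known_genes: int = 45
    novel_genes: tuple[NovelGeneSpec, ...] = field(default_factory=_default_novel)
    gene_measurement_probability: float = 0.9
    noise_sd: float = 0.44
    seed: int = 20240228

    def validate(self) -> None:
        targets = [m for m in self.modules if m.is_target]
        if len(targets) != 1:
            raise ValueError(f"exactly one target module required, got {len(targets)}")
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be >= 1")
        if sum(m.size for m in self.modules) > self.n_genes_global:
            raise ValueError("module sizes exceed n_genes_global")
        target = targets[0]
        if target.size != self.target_known_genes + len(self.novel_genes):
            raise ValueError(
                "target module size must equal target_known_genes + number of novel genes"
            )
        if self.target_known_genes > len(KNOWN_TARGET_GENES):
            raise ValueError(
                f"target_known_genes capped at {len(KNOWN_TARGET_GENES)}"
            )
        if not 0 <= self.gene_measurement_probability <= 1:
            raise ValueError("gene_measurement_probability must be in [0, 1]")
        for g in self.novel_genes:
            if not 0 <= g.inclusion_probability <= 1:
                raise ValueError(f"inclusion probability out of [0, 1] for {g.symbol}")
        for m in self.modules:
            if not 0 < m.loading < 1:
                raise ValueError(f"module {m.name}: loading must be in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for n in self.sample_counts():
            if n < 3:
                raise ValueError("each dataset needs >= 3 samples")

    def sample_counts(self) -> list[int]:
        if isinstance(self.samples_per_dataset, int):
            return [self.samples_per_dataset] * self.n_datasets
        counts = list(self.samples_per_dataset)
        if len(counts) != self.n_datasets:
            raise ValueError("samples_per_dataset length must equal n_datasets")
        return counts

    @property
    def target_module(self) -> ModuleSpec:
        return next(m for m in self.modules if m.is_target)


def default_recovery_spec(seed: int = 20240228, n_datasets: int = 8) -> SyntheticSpec:
    """The reference recovery benchmark: 8 cohorts x 120 samples, 2,000 genes,
    five 80-gene background modules (loading 0.8) and one 60-gene target
    module (45 known + 15 novel genes, loading 0.9, noise_sd 0.44)."""
    return SyntheticSpec(seed=seed, n_datasets=n_datasets)


@dataclass
class TruthRecord:
    """Ground truth accompanying a generated collection."""

    target_module_name: str
    known_genes: frozenset[str]
    novel_probabilities: dict[str, float]
    membership: dict[str, dict[str, str]]  # dataset -> measured gene -> module name
    factors: dict[str, pd.DataFrame]  # dataset -> samples x modules
    expected_replication: dict[str, float]

    def target_members(self, dataset_id: str) -> frozenset[str]:
        return frozenset(
            g for g, mod in self.membership[dataset_id].items()
            if mod == self.target_module_name
        )


@dataclass(frozen=True)
class SyntheticCollection:
    root: Path
    catalog_path: Path
    gmt_path: Path
    truth_path: Path
    expression_paths: dict[str, Path]
    truth: TruthRecord


def _global_gene_table(spec: SyntheticSpec) -> tuple[list[str], dict[str, str]]:
    """All global gene symbols and each structured gene's home module."""
    home: dict[str, str] = {}
    target = spec.target_module
    known = list(KNOWN_TARGET_GENES[: spec.target_known_genes])
    for g in known:
        home[g] = target.name
    for g in spec.novel_genes:
        home[g.symbol] = target.name  # conditional per dataset
    for m in spec.modules:
        if m.is_target:
            continue
        for i in range(1, m.size + 1):
            home[f"{m.name.upper()}G{i:03d}"] = m.name
    n_noise = spec.n_genes_global - len(home)
    noise = [f"NS{i:04d}" for i in range(1, n_noise + 1)]
    genes = sorted(list(home) + noise)
    return genes, home


def generate_collection(spec: SyntheticSpec, out_dir: str | Path) -> SyntheticCollection:
    """Generate a collection on disk: catalog, expression TSVs, GMT, truth.

    All randomness comes from one ``numpy.random.default_rng(spec.seed)``
    generator consumed in a fixed order, so identical specs produce
    byte-identical files. Known target genes are measured in every cohort,
    and a novel gene that joins the target module in a cohort is measured
    there too (membership implies measurement); all other genes survive
    each cohort's platform with ``gene_measurement_probability``.
    """
    spec.validate()
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    genes, home = _global_gene_table(spec)
    gene_index = {g: i for i, g in enumerate(genes)}
    target = spec.target_module
    known = [g for g in KNOWN_TARGET_GENES[: spec.target_known_genes]]
    module_order = [m.name for m in spec.modules]
    loading = {m.name: m.loading for m in spec.modules}

    membership: dict[str, dict[str, str]] = {}
    factors: dict[str, pd.DataFrame] = {}
    expression_paths: dict[str, Path] = {}
    catalog_rows = []
    sexes = ["male", "female"]
    for d, n_samples in enumerate(spec.sample_counts()):
        ds = f"sim{d + 1:02d}"
        samples = [f"{ds}_S{i + 1:03d}" for i in range(n_samples)]
        F = rng.standard_normal((len(module_order), n_samples))
        joined = rng.random(len(spec.novel_genes)) < np.array(
            [g.inclusion_probability for g in spec.novel_genes]
        )
        measured_draw = rng.random(len(genes)) < spec.gene_measurement_probability
        eps = rng.standard_normal((len(genes), n_samples))

        measured = measured_draw.copy()
        ds_module: dict[str, str] = {}
        for g in known:
            measured[gene_index[g]] = True
            ds_module[g] = target.name
        for g, in_module in zip(spec.novel_genes, joined):
            if in_module:
                measured[gene_index[g.symbol]] = True
                ds_module[g.symbol] = target.name
        for g, mod in home.items():
            if mod != target.name:
                ds_module[g] = mod

        values = eps.copy()  # background/noise genes: N(0, 1)
        for gname, mod in ds_module.items():
            gi = gene_index[gname]
            f = F[module_order.index(mod)]
            values[gi] = loading[mod] * f + spec.noise_sd * eps[gi]

        keep = np.flatnonzero(measured)
        frame = pd.DataFrame(values[keep], index=[genes[i] for i in keep], columns=samples)
        path = root / f"{ds}_expression.tsv"
        frame.index.name = "gene"
        frame.to_csv(path, sep="\t", float_format="%.6g", lineterminator="\n")
        expression_paths[ds] = path

        membership[ds] = {
            genes[i]: ds_module.get(genes[i], "noise") for i in keep
        }
        factors[ds] = pd.DataFrame(F.T, index=samples, columns=module_order)
        catalog_rows.append(
            {
                "dataset_id": ds,
                "population": "synthetic cohort",
                "sex": sexes[d % 2],
                "n_samples": n_samples,
                "data_kind": "transcriptome",
                "path": path.name,
            }
        )

    catalog_path = root / "catalog.tsv"
    pd.DataFrame(catalog_rows).to_csv(catalog_path, sep="\t", index=False, lineterminator="\n")

    gmt_path = root / "gene_sets.gmt"
    target_set = GeneSet(
        name="CHOLESTEROL_BIOSYNTHESIS",
        description="synthetic stand-in for the cholesterol biosynthetic process gene set",
        genes=frozenset(known),
    )
    known_set = GeneSet(
        name="KNOWN_LIPID_ROLE",
        description="synthetic known-role annotation (cholesterol/fatty acid metabolism)",
        genes=frozenset(known),
    )
    write_gmt([target_set, known_set], gmt_path)

    expected = {g: float(spec.n_datasets) for g in known}
    for g in spec.novel_genes:
        expected[g.symbol] = g.inclusion_probability * spec.n_datasets
    truth = TruthRecord(
        target_module_name=target.name,
        known_genes=frozenset(known),
        novel_probabilities={g.symbol: g.inclusion_probability for g in spec.novel_genes},
        membership=membership,
        factors=factors,
        expected_replication=expected,
    )
    truth_path = root / "truth.tsv"
    _write_truth(truth, truth_path)
    return SyntheticCollection(
        root=root,
        catalog_path=catalog_path,
        gmt_path=gmt_path,
        truth_path=truth_path,
        expression_paths=expression_paths,
        truth=truth,
    )


def _write_truth(truth: TruthRecord, path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"#target_module\t{truth.target_module_name}\n")
        fh.write("#known_genes\n")
        for g in sorted(truth.known_genes):
            fh.write(f"{g}\n")
        fh.write("#novel_genes\n")
        for g in sorted(truth.novel_probabilities):
            fh.write(f"{g}\t{truth.novel_probabilities[g]:g}\n")
        fh.write("#expected_replication\n")
        for g in sorted(truth.expected_replication):
            fh.write(f"{g}\t{truth.expected_replication[g]:g}\n")
        fh.write("#membership\n")
        for ds in sorted(truth.membership):
            for g in sorted(truth.membership[ds]):
                fh.write(f"{ds}\t{g}\t{truth.membership[ds][g]}\n")
        fh.write("#factors\n")
        for ds in sorted(truth.factors):
            frame = truth.factors[ds]
            for module in frame.columns:
                for sample, value in frame[module].items():
                    fh.write(f"{ds}\t{module}\t{sample}\t{value:.6g}\n")


def read_truth(path: str | Path) -> TruthRecord:
    """Parse a truth record written by :func:`generate_collection`."""
    target_name = ""
    known: set[str] = set()
    novel: dict[str, float] = {}
    expected: dict[str, float] = {}
    membership: dict[str, dict[str, str]] = {}
    factor_rows: dict[str, list[tuple[str, str, float]]] = {}
    section = ""
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                head = line[1:].split("\t")
                section = head[0]
                if section == "target_module":
                    target_name = head[1]
                continue
            fields = line.split("\t")
            if section == "known_genes":
                known.add(fields[0])
            elif section == "novel_genes":
                novel[fields[0]] = float(fields[1])
            elif section == "expected_replication":
                expected[fields[0]] = float(fields[1])
            elif section == "membership":
                ds, g, mod = fields
                membership.setdefault(ds, {})[g] = mod
            elif section == "factors":
                ds, mod, sample, value = fields
                factor_rows.setdefault(ds, []).append((mod, sample, float(value)))
    factors = {}
    for ds, rows in factor_rows.items():
        frame = pd.DataFrame(rows, columns=["module", "sample", "value"])
        factors[ds] = frame.pivot(index="sample", columns="module", values="value")
    return TruthRecord(
        target_module_name=target_name,
        known_genes=frozenset(known),
        novel_probabilities=novel,
        membership=membership,
        factors=factors,
        expected_replication=expected,
    )


@dataclass(frozen=True)
class RecoveryMetrics:
    """How well a pipeline run recovered the planted structure."""

    per_dataset_detected: dict[str, bool]
    detection_rate: float
    candidate_precision: float
    per_dataset_ari: dict[str, float] | None
    mean_ari: float | None


def _jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    union = a | b
    return len(a & b) / len(union) if union else 0.0


def evaluate_recovery(
    truth: TruthRecord,
    calls: Sequence[TargetModuleCall],
    table: pd.DataFrame,
    partitions: Mapping[str, ModulePartition] | None = None,
) -> RecoveryMetrics:
    """Score a pipeline run against the generator's truth.

    * detection: a cohort counts as detected when its call's members
      overlap the true target module with Jaccard >= 0.5;
    * candidate precision: fraction of inclusion-probability-1 novel genes
      whose replication count equals the number of cohorts measuring them;
    * ARI: adjusted Rand index of each cohort's full partition against the
      true module memberships (unassigned and background/noise each count
      as a class), when partitions are supplied.
    """
    calls_by_ds = {c.dataset_id: c for c in calls}
    unknown = set(calls_by_ds) - set(truth.membership)
    if unknown:
        raise ValueError(f"calls for datasets absent from truth: {sorted(unknown)}")
    detected: dict[str, bool] = {}
    for ds in sorted(truth.membership):
        call = calls_by_ds.get(ds)
        if call is None:
            detected[ds] = False
            continue
        stray = call.member_genes - frozenset(truth.membership[ds])
        if stray:
            raise ValueError(
                f"dataset {ds}: called genes outside the generated universe: "
                f"{sorted(stray)[:5]}"
            )
        detected[ds] = _jaccard(call.member_genes, truth.target_members(ds)) >= 0.5

    counts = dict(zip(table["gene"], table["replication_count"]))
    certain = [g for g, q in truth.novel_probabilities.items() if q == 1.0]
    hits = 0
    for g in certain:
        n_measured = sum(g in truth.membership[ds] for ds in truth.membership)
        if counts.get(g, 0) == n_measured:
            hits += 1
    precision = hits / len(certain) if certain else float("nan")

    per_ari = None
    mean_ari = None
    if partitions is not None:
        per_ari = {}
        for ds, part in partitions.items():
            if ds not in truth.membership:
                raise ValueError(f"partition for unknown dataset {ds!r}")
            genes = list(part.labels.index)
            missing = [g for g in genes if g not in truth.membership[ds]]
            if missing:
                raise ValueError(
                    f"dataset {ds}: partition genes outside the generated universe: "
                    f"{missing[:5]}"
                )
            true_labels = [truth.membership[ds][g] for g in genes]
            per_ari[ds] = float(adjusted_rand_score(true_labels, part.labels.to_numpy()))
        mean_ari = float(np.mean(list(per_ari.values()))) if per_ari else float("nan")

    return RecoveryMetrics(
        per_dataset_detected=detected,
        detection_rate=float(np.mean(list(detected.values()))),
        candidate_precision=precision,
        per_dataset_ari=per_ari,
        mean_ari=mean_ari,
    )
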