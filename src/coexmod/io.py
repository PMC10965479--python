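"""Reading and writing of dataset catalogs, expression matrices and gene sets.

The pipeline consumes three kinds of plain-text inputs:

* a **dataset catalog** (TSV/CSV): one row per cohort with id, mouse
  population, sex, number of animals, platform kind and the path of its
  expression matrix;
* **expression matrices** (TSV/CSV): genes in rows, samples in columns,
  first column gene symbols, normalized abundances with ``NA``/empty cells
  allowed as missing;
* **gene sets** in GMT format (set name, description, then member symbols,
  tab-separated), carrying the target pathway (e.g. cholesterol
  biosynthetic process) and any known-role annotation sets.

Gene identifiers are uppercase symbol strings throughout; transcript and
protein rows are matched across cohorts by symbol, so callers must map
platform-specific IDs to symbols before entry.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DatasetRecord",
    "GeneSet",
    "CatalogSummary",
    "read_catalog",
    "load_table1_catalog",
    "summarize_catalog",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gmt",
    "write_gmt",
    "preprocess_matrix",
]

MISSING_TOKENS = ("", "NA")
_SEX_TOKENS = frozenset({"male", "female", "mixed"})
_KIND_TOKENS = frozenset({"transcriptome", "proteome"})
_CATALOG_COLUMNS = ("dataset_id", "population", "sex", "n_samples", "data_kind", "path")


@dataclass(frozen=True)
class DatasetRecord:
    """One cohort in a dataset catalog."""

    dataset_id: str
    population: str
    sex: str
    n_samples: int
    data_kind: str
    path: str

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError(f"dataset {self.dataset_id!r}: n_samples must be >= 1")
        if self.sex not in _SEX_TOKENS:
            raise ValueError(f"dataset {self.dataset_id!r}: unknown sex {self.sex!r}")
        if self.data_kind not in _KIND_TOKENS:
            raise ValueError(
                f"dataset {self.dataset_id!r}: unknown data_kind {self.data_kind!r}"
            )


@dataclass(frozen=True)
class GeneSet:
    """A named flat gene set (one GMT line)."""

    name: str
    description: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        bad = [g for g in self.genes if g != g.upper()]
        if bad:
            raise ValueError(f"gene set {self.name!r}: symbols not uppercase: {bad[:5]}")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class CatalogSummary:
    n_datasets: int
    total_samples: int
    per_sex: dict[str, int]


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_catalog(path: str | Path) -> list[DatasetRecord]:
    """Read a dataset catalog table into a list of :class:`DatasetRecord`.

    The file must have a header row containing at least the columns
    ``dataset_id, population, sex, n_samples, data_kind, path``; extra
    columns are ignored. ``sex`` and ``data_kind`` are normalized to
    lowercase. Duplicate dataset ids and non-integer sample counts are
    errors.
    """
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    missing = [c for c in _CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"catalog {path}: missing columns {missing}")
    ids = df["dataset_id"].tolist()
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValueError(f"catalog {path}: duplicate dataset_id {dupes}")
    records = []
    for _, row in df.iterrows():
        raw_n = row["n_samples"].strip()
        try:
            n = int(raw_n)
        except ValueError:
            raise ValueError(
                f"catalog {path}: non-integer n_samples {raw_n!r} "
                f"for dataset {row['dataset_id']!r}"
            ) from None
        records.append(
            DatasetRecord(
                dataset_id=row["dataset_id"].strip(),
                population=row["population"].strip(),
                sex=row["sex"].strip().lower(),
                n_samples=n,
                data_kind=row["data_kind"].strip().lower(),
                path=row["path"].strip(),
            )
        )
    return records


def load_table1_catalog() -> list[DatasetRecord]:
    """Load the packaged catalog of the 35 published mouse liver cohorts.

    The fixture transcribes the study's printed dataset table (id,
    population, sex, number of mice). Expression matrices themselves are
    not bundled — they live in GEO — so the ``path`` column is empty and
    the records support catalog summaries only. The printed table does not
    state each cohort's platform, so ``data_kind`` is uniformly marked
    ``transcriptome``.
    """
    ref = importlib.resources.files("coexmod.data") / "table1_catalog.tsv"
    with importlib.resources.as_file(ref) as p:
        return read_catalog(p)


def summarize_catalog(records: Sequence[DatasetRecord]) -> CatalogSummary:
    """Summarize a catalog: dataset count, total animals, per-sex dataset counts."""
    per_sex: dict[str, int] = {}
    for r in records:
        per_sex[r.sex] = per_sex.get(r.sex, 0) + 1
    return CatalogSummary(
        n_datasets=len(records),
        total_samples=sum(r.n_samples for r in records),
        per_sex=per_sex,
    )


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a gene-by-sample expression matrix.

    First column holds gene symbols (uppercased on read), remaining columns
    are samples. Cells must be numeric, the empty string, or ``NA``
    (missing). Duplicate symbols are collapsed to the row with the highest
    variance, the standard deterministic probe-to-gene collapse. Fewer than
    3 sample columns is an error.
    """
    df = pd.read_csv(
        path,
        sep=_sep_for(path),
        index_col=0,
        na_values=list(MISSING_TOKENS),
        keep_default_na=False,
        float_precision="round_trip",
    )
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expression matrix needs >= 3 samples, got {df.shape[1]}")
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric cell in expression matrix: {exc}") from None
    df.index = df.index.astype(str).str.upper()
    df.index.name = "gene"
    if df.index.has_duplicates:
        variances = df.var(axis=1, ddof=0)
        # stable: among equal-variance duplicates the first file row wins
        order = np.arange(len(df))
        keep = (
            pd.DataFrame({"v": variances.to_numpy(), "o": order}, index=df.index)
            .reset_index()
            .sort_values(["gene", "v", "o"], ascending=[True, False, True])
            .drop_duplicates("gene", keep="first")["o"]
            .sort_values()
            .to_numpy()
        )
        df = df.iloc[keep]
    return df


def write_expression_matrix(
    m: pd.DataFrame, path: str | Path, float_format: str = "%.17g"
) -> None:
    """Write a gene-by-sample matrix as TSV/CSV (missing cells as ``NA``).

    The default float format round-trips IEEE doubles exactly.
    """
    out = m.copy()
    out.index.name = "gene"
    out.to_csv(path, sep=_sep_for(path), na_rep="NA", float_format=float_format)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file into gene sets (symbols uppercased, de-duplicated)."""
    sets = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: malformed GMT line {lineno} (< 3 fields)")
            name, desc, *genes = fields
            members = frozenset(g.strip().upper() for g in genes if g.strip())
            if not members:
                raise ValueError(f"{path}: GMT line {lineno} has no genes")
            sets.append(GeneSet(name=name, description=desc, genes=members))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.genes)]) + "\n")


def preprocess_matrix(
    m: pd.DataFrame,
    min_fraction_present: float = 0.5,
    max_genes: int | None = None,
) -> pd.DataFrame:
    """Filter an expression matrix for network construction.

    Drops genes observed in fewer than ``min_fraction_present`` of samples
    and genes with zero variance. If ``max_genes`` is set, keeps the
    ``max_genes`` genes with the highest median absolute deviation (ties
    broken alphabetically for determinism). Gene and sample order are
    preserved. The operation is idempotent.
    """
    values = m.to_numpy(dtype=float)
    frac_present = np.mean(~np.isnan(values), axis=1)
    with np.errstate(all="ignore"):
        variance = np.nanvar(values, axis=1)
    keep = (frac_present >= min_fraction_present) & (variance > 0)
    out = m.loc[keep]
    if max_genes is not None and len(out) > max_genes:
        sub = out.to_numpy(dtype=float)
        med = np.nanmedian(sub, axis=1, keepdims=True)
        mad = np.nanmedian(np.abs(sub - med), axis=1)
        ranked = sorted(zip(-mad, out.index), key=lambda t: (t[0], t[1]))
        chosen = {g for _, g in ranked[:max_genes]}
        out = out.loc[[g in chosen for g in out.index]]
    if len(out) < 2:
        raise ValueError(f"preprocessing left {len(out)} genes (< 2)")
    return out
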