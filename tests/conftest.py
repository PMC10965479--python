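import numpy as np
import pytest

from coexmod import (
    ModuleSpec,
    NovelGeneSpec,
    RunConfig,
    SyntheticSpec,
    generate_collection,
    run_pipeline,
)

TARGET_SET = "CHOLESTEROL_BIOSYNTHESIS"


def small_spec(seed: int = 777, n_datasets: int = 3) -> SyntheticSpec:
    """A scaled-down collection for fast pipeline tests: 3 cohorts x 120
    samples, 400 genes, two background modules and a 30-gene target module
    (22 known + 8 novel)."""
    modules = (
        ModuleSpec("bg1", 40, 0.8),
        ModuleSpec("bg2", 40, 0.8),
        ModuleSpec("target", 30, 0.9, is_target=True),
    )
    novel = tuple(NovelGeneSpec(f"NOVEL{i:02d}", 1.0) for i in range(1, 4)) + tuple(
        NovelGeneSpec(f"NOVEL{i:02d}", 0.5) for i in range(4, 9)
    )
    return SyntheticSpec(
        n_datasets=n_datasets,
        samples_per_dataset=120,
        n_genes_global=400,
        modules=modules,
        target_known_genes=22,
        novel_genes=novel,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_collection(tmp_path_factory):
    root = tmp_path_factory.mktemp("small_collection")
    return generate_collection(small_spec(), root)


@pytest.fixture(scope="session")
def small_run(small_collection, tmp_path_factory):
    out = tmp_path_factory.mktemp("small_run_out")
    cfg = RunConfig(
        catalog=str(small_collection.catalog_path),
        target_gmt=str(small_collection.gmt_path),
        target_set=TARGET_SET,
        known_gmt=str(small_collection.gmt_path),
        out_dir=str(out),
        min_replication=3,
    )
    return run_pipeline(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20240228)
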