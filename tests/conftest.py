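import shutil
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from allelign import Registry, generate_cohort_set, merge_reports, realign_dataset

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def trio(tmp_path_factory):
    """Three discordant cohorts realigned A → B → C against one registry.

    Session-scoped and treated as read-only by every test that uses it.
    """
    root = tmp_path_factory.mktemp("trio")
    cohorts = generate_cohort_set(
        seed=11,
        n_variants=900,
        n_shared=700,
        flip_rate=0.3,
        n_multi_indexed=8,
        n_duplicates=6,
        n_samples=120,
        n_cohorts=3,
        outdir=root / "fixtures",
    )
    registry = Registry.create(root, "trio_registry")
    outdir = root / "realigned"
    results = {
        label: realign_dataset(cohorts.specs[label], registry, outdir=outdir)
        for label in cohorts.labels
    }
    composites = {
        label: merge_reports(sorted((outdir / label).glob("chr*.identified.tsv")))
        for label in cohorts.labels
    }
    return {
        "cohorts": cohorts,
        "registry": registry,
        "outdir": outdir,
        "results": results,
        "composites": composites,
    }


@pytest.fixture()
def fresh_dir(tmp_path):
    yield tmp_path
    shutil.rmtree(tmp_path, ignore_errors=True)
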