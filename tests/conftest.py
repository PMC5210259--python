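"""Shared fixtures: one small synthetic cohort, generated once per session,
plus its annotation store and a full conversion run over it."""

from __future__ import annotations

import pytest

from tcgabed.annotations import load_store
from tcgabed.core import EXPERIMENT_TYPES
from tcgabed.fixtures import CohortSpec, annotation_paths, generate
from tcgabed.repo import Job, run_convert


@pytest.fixture(scope="session")
def cohort_spec() -> CohortSpec:
    return CohortSpec(seed=11, n_patients=3, tumor_tags=("BRCA",))


@pytest.fixture(scope="session")
def cohort_root(tmp_path_factory, cohort_spec):
    root = tmp_path_factory.mktemp("cohort")
    generate(cohort_spec, root)
    return root


@pytest.fixture(scope="session")
def store(cohort_root):
    return load_store(annotation_paths(cohort_root))


@pytest.fixture(scope="session")
def conversion_jobs(cohort_root, tmp_path_factory):
    out_root = tmp_path_factory.mktemp("repo")
    return [
        Job(
            source=cohort_root / "tcga_original",
            tumor="BRCA",
            exp_type=exp_type,
            annotations=cohort_root / "annotations",
            out_root=out_root,
            formats=("bed", "csv", "json"),
        )
        for exp_type in EXPERIMENT_TYPES
    ]


@pytest.fixture(scope="session")
def converted_repo(conversion_jobs):
    """(output root, run report) of a full six-type conversion run."""
    report = run_convert(conversion_jobs)
    assert report.ok, [j.error for j in report.jobs if not j.ok]
    return conversion_jobs[0].out_root, report
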