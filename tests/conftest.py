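"""Shared fixtures: a scaled-down synthetic study for unit tests and the
full default-scale study (computed once per session) for the acceptance
checks."""

from __future__ import annotations

import pytest

from eggprint.annmodel import AnnConfig
from eggprint.preprocess import probe_screen, vsn_normalize
from eggprint.synthetic import SimulationConfig, generate_dataset

SMALL_CONFIG = dict(
    n_probes=1200,
    n_fingerprint=40,
    n_duplicate_pairs=5,
    n_modules=6,
    seed=101,
)


@pytest.fixture(scope="session")
def small_study():
    """A 1,200-probe study with a 40-gene fingerprint in 6 modules."""
    return generate_dataset(SimulationConfig(**SMALL_CONFIG))


@pytest.fixture(scope="session")
def small_normalized(small_study):
    norm, params = vsn_normalize(small_study.expression)
    return norm, params


@pytest.fixture(scope="session")
def small_screen(small_study, small_normalized):
    norm, _ = small_normalized
    return probe_screen(norm, small_study.phenotype)


@pytest.fixture(scope="session")
def default_study():
    """The full default-scale study (15,000 probes, 233-gene fingerprint)."""
    return generate_dataset(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_normalized(default_study):
    norm, params = vsn_normalize(default_study.expression)
    return norm, params


@pytest.fixture
def ann_config():
    return AnnConfig(seed=13)


def planted_probe_ids(study) -> set[str]:
    """All probe ids measuring a planted fingerprint gene (incl. twins)."""
    gene_to_probes: dict[str, list[str]] = {}
    for _, row in study.annotation.table.iterrows():
        gene_to_probes.setdefault(row["gene_id"], []).append(row["probe_id"])
    out: set[str] = set()
    for g in study.truth.fingerprint_gene_ids:
        out.update(gene_to_probes[g])
    return out
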