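"""Shared fixtures: small synthetic studies and toy genomes."""

from __future__ import annotations

import numpy as np
import pytest

from mutascope.catalogs import build_catalog, filter_vaf, subtract_parental
from mutascope.synthdata import StudyConfig, generate_study


@pytest.fixture(scope="session")
def small_study():
    """One-genotype study on a 500 kb genome; fast but fully featured."""
    cfg = StudyConfig(
        genome_length=500_000,
        n_genes=40,
        gene_length=3000,
        g4_density=2e-4,
        genotypes=("WT",),
        n_subclones=3,
        sbs_burden={"DMSO": 500, "CX": 8000},
        dbs_burden={"DMSO": 5, "CX": 80},
        indel_burden={"DMSO": 50, "CX": 150},
        n_parental=100,
        polyclonal_samples=("WT.CX.s3",),
    )
    return generate_study(cfg, seed=20_240_101)


@pytest.fixture(scope="session")
def study_catalogs(small_study):
    """De novo, VAF-filtered catalogs per sample of the small study."""
    cats = {}
    for name, full in small_study.samples.items():
        arm = ".".join(name.split(".")[:2])
        denovo = subtract_parental(full, small_study.parental[arm])
        cats[name] = build_catalog(filter_vaf(denovo), small_study.genome, name)
    return cats


@pytest.fixture(scope="session")
def treated_denovo(small_study):
    """Pooled de novo records of the clonal treated subclones."""
    records = []
    for name in small_study.arm_samples("WT", "CX"):
        if small_study.truth[name].polyclonal:
            continue
        records += filter_vaf(
            subtract_parental(small_study.samples[name], small_study.parental["WT.CX"])
        )
    return records


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
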