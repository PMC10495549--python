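"""Shared fixtures: small genotype datasets and the synthetic study fixture."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from broompop.geno_io import GenotypeDataset, LocusDef, SampleMeta
from broompop.simulate import FixtureConfig, make_study_fixture

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


def make_dataset(calls, pops, hosts=None, motif=2, allele_range=(10, 400)):
    """Build a GenotypeDataset from a (n, L, 2) array and population labels."""
    calls = np.asarray(calls)
    if calls.ndim == 2:  # single locus given as (n, 2)
        calls = calls[:, None, :]
    n, L, _ = calls.shape
    hosts = hosts or pops
    loci = [LocusDef(f"L{j+1}", motif, allele_range) for j in range(L)]
    samples = [
        SampleMeta(individual_id=f"i{i}", population_id=p, host_crop=h)
        for i, (p, h) in enumerate(zip(pops, hosts))
    ]
    return GenotypeDataset(loci=loci, samples=samples, calls=calls)


@pytest.fixture(scope="session")
def tiny_two_pop():
    """Two fixed populations at theta = 1."""
    calls = [[100, 100]] * 8 + [[102, 102]] * 8
    return make_dataset(calls, ["A"] * 8 + ["B"] * 8)


@pytest.fixture(scope="session")
def random_small_ds():
    """Random polymorphic 3-locus, 2-population dataset for oracle checks."""
    rng = np.random.default_rng(42)
    alleles = np.array([100, 102, 104, 106])
    calls = rng.choice(alleles, size=(18, 3, 2))
    pops = ["A"] * 9 + ["B"] * 9
    return make_dataset(calls, pops)


@pytest.fixture(scope="session")
def small_fixture():
    """Reduced synthetic study fixture (3 clusters x 4 pops x 11)."""
    cfg = FixtureConfig(n_clusters=3, pops_per_cluster=4, n_per_pop=11)
    return make_study_fixture(cfg, seed=7)


@pytest.fixture(scope="session")
def study_fixture():
    """Full default synthetic study fixture with truth labels."""
    return make_study_fixture(seed=1)
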