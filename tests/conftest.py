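from __future__ import annotations

import itertools

import numpy as np
import pytest

import bridgemap as bm


@pytest.fixture
def assembly_a() -> bm.GenomeAssembly:
    return bm.GenomeAssembly("specA", {"chr1": 10_000, "chr2": 5_000})


@pytest.fixture
def assembly_b() -> bm.GenomeAssembly:
    return bm.GenomeAssembly("specB", {"chr1": 20_000})


@pytest.fixture
def params() -> bm.ScoringParams:
    return bm.ScoringParams(10_000.0)


@pytest.fixture
def two_block_set(assembly_a, assembly_b) -> bm.AnchorSet:
    """Two collinear '+' anchors with a 900 bp source gap between them."""
    blocks = [
        bm.AnchorBlock("chr1", 1000, 1100, "chr1", 2000, 2100, "+"),
        bm.AnchorBlock("chr1", 2000, 2100, "chr1", 4000, 4100, "+"),
    ]
    return bm.AnchorSet(assembly_a, assembly_b, blocks)


def make_fixture(seed: int = 11, n_species: int = 3, **overrides) -> bm.SyntenyFixture:
    """A small deterministic synteny fixture for integration tests."""
    specs = (
        bm.SpeciesSpec("zeb", 1.0),
        bm.SpeciesSpec("bri", 1.5),
        bm.SpeciesSpec("mus", 2.0),
    )[:n_species]
    config = bm.SyntenyConfig(
        seed=seed,
        species=specs,
        master_length=overrides.pop("master_length", 500_000),
        default_density=overrides.pop("default_density", 0.3),
        scale_jitter_sd=overrides.pop("scale_jitter_sd", 0.1),
        **overrides,
    )
    return bm.simulate_synteny(config)


@pytest.fixture
def bridge_fixture() -> bm.SyntenyFixture:
    """Sparse direct anchors (1/50 kb) plus a dense bridge (1/2 kb)."""
    densities = {
        frozenset(("zeb", "mus")): 0.02,
        frozenset(("zeb", "bri")): 0.5,
        frozenset(("bri", "mus")): 0.5,
    }
    return make_fixture(seed=7, anchors_per_kb=densities, master_length=1_000_000)


def random_fixture(seed: int, rng: np.random.Generator) -> bm.SyntenyFixture:
    """A random multi-species fixture with coordinate-consistent anchors."""
    k = int(rng.integers(3, 7))
    ids = [f"sp{j}" for j in range(k)]
    species = tuple(
        bm.SpeciesSpec(i, float(rng.uniform(0.5, 2.5))) for i in ids
    )
    densities = {
        frozenset(pair): float(rng.uniform(0.05, 0.5))
        for pair in itertools.combinations(ids, 2)
    }
    config = bm.SyntenyConfig(
        seed=seed,
        species=species,
        master_length=500_000,
        anchors_per_kb=densities,
        default_density=0.1,
        dropout=float(rng.uniform(0, 0.2)),
        scale_jitter_sd=float(rng.uniform(0, 0.2)),
    )
    return bm.simulate_synteny(config)
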