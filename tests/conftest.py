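import numpy as np
import pytest

from islandsweep import pipeline, simdata
from islandsweep.genotypes import NO_ALLELE, GenotypeMatrix

SESSION_SEED = 1  # one seed for every session-scoped simulation


def make_matrix(
    haplotypes,
    positions=None,
    scaffold="s1",
    is_x=True,
    length=None,
    qual=None,
    samples=None,
):
    """Small haploid GenotypeMatrix from a (n_sites, n_samples) array."""
    H = np.asarray(haplotypes, dtype=np.int8)
    n_sites, n_samples = H.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1)
    alleles = np.full((n_sites, n_samples, 2), NO_ALLELE, dtype=np.int8)
    alleles[:, :, 0] = H
    return GenotypeMatrix(
        scaffold=scaffold,
        positions=np.asarray(positions),
        alleles=alleles,
        samples=samples or [f"ind_{i}" for i in range(n_samples)],
        ploidy=np.ones(n_samples, dtype=np.int8),
        is_x=is_x,
        qual=None if qual is None else np.asarray(qual, float),
        length=length,
    )


def tiny_config(scenario="parallel"):
    """A miniature island system for fast structural tests."""
    cfg = simdata.make_scenario(scenario)
    cfg.genome_layout = [
        simdata.Scaffold("mini_A1", 60_000, is_x=False),
        simdata.Scaffold("mini_X1", 80_000, is_x=True),
    ]
    cfg.causal_scaffold = "mini_X1"
    if cfg.causal_positions:
        pos = {"parallel": {"kauai": 20_000, "oahu": 40_000, "hilo": 60_000}}
        cfg.causal_positions = pos.get(
            scenario, {d: 20_000 for d in cfg.causal_positions}
        )
    cfg.sweep_flank = 8_000
    cfg.samples = {
        "kauai": (4, 4), "oahu": (4, 4), "hilo": (4, 4),
        "australia": (0, 3), "outgroup": (0, 2),
    }
    return cfg


@pytest.fixture(scope="session")
def datasets():
    """One simulated dataset per preset, shared across the whole session."""
    cache = {}

    def get(scenario):
        if scenario not in cache:
            cfg = simdata.make_scenario(scenario)
            cache[scenario] = simdata.simulate_demography(cfg, seed=SESSION_SEED)
        return cache[scenario]

    return get


@pytest.fixture(scope="session")
def summaries(datasets, tmp_path_factory):
    """End-to-end pipeline summaries per preset (computed once)."""
    cache = {}

    def get(scenario):
        if scenario not in cache:
            out = tmp_path_factory.mktemp(f"run_{scenario}")
            cfg = pipeline.RunConfig(
                scenario=scenario, seed=SESSION_SEED, outdir=str(out)
            )
            cache[scenario] = (pipeline.run(cfg, dataset=datasets(scenario)), out)
        return cache[scenario]

    return get
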