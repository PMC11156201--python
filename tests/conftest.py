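import numpy as np
import pytest

from purgescan.simdata import (
    Epoch,
    PopulationPlan,
    SimulationConfig,
    simulate,
    write_bundle,
)
from purgescan.variant_io import GenotypeDataset


def two_pop_config(seed: int = 7, **overrides) -> SimulationConfig:
    """Cheap two-population scenario used across tests."""
    params = dict(
        seed=seed,
        n_generations=260,
        sequence_length_bp=150_000,
        populations=[
            PopulationPlan("big", [Epoch(0, 260, 60)], selfing_rate=0.0),
            PopulationPlan(
                "small",
                [Epoch(200, 260, 20)],
                selfing_rate=0.8,
                parent="big",
                split_gen=200,
            ),
        ],
        mu_neutral=3e-5,
        mu_del=1e-5,
        sel_coeff=0.3,
        dominance=0.0,
        mu_lof=2e-5,
        outgroup_divergence=0.02,
        sample_sizes={"big": 12, "small": 8},
    )
    params.update(overrides)
    return SimulationConfig(**params)


@pytest.fixture(scope="session")
def sim_pair():
    cfg = two_pop_config()
    ds, truth = simulate(cfg)
    return ds, truth


@pytest.fixture(scope="session")
def bundle(sim_pair, tmp_path_factory):
    ds, truth = sim_pair
    outdir = tmp_path_factory.mktemp("bundle")
    paths = write_bundle(ds, truth, outdir)
    return paths


def make_dataset(
    dosage,
    pos=None,
    samples=None,
    ref=None,
    alt=None,
    chrom="chr1",
    depth=None,
) -> GenotypeDataset:
    """Small literal GenotypeDataset for unit tests."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_sites, n_samples = dosage.shape
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 100
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    return GenotypeDataset(
        samples=list(samples),
        chrom=np.asarray([chrom] * n_sites, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(ref if ref is not None else ["A"] * n_sites, dtype="U1"),
        alt=np.asarray(alt if alt is not None else ["G"] * n_sites, dtype="U1"),
        dosage=dosage,
        depth=None if depth is None else np.asarray(depth),
    )
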