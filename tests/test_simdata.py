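"""Forward-simulator behaviour: determinism, closed-form calibration at small
scale, demographic validation and bundle round-trips."""

import dataclasses

import numpy as np
import pytest

from purgescan.simdata import (
    Epoch,
    ExtinctionError,
    PopulationPlan,
    SimulationConfig,
    make_highland_lowland_scenario,
    simulate,
    write_bundle,
)
from purgescan.variant_io import read_vcf

from conftest import two_pop_config


def one_pop_config(seed, N=50, gens=500, mu=2e-5, L=120_000, **kw):
    params = dict(
        seed=seed,
        n_generations=gens,
        sequence_length_bp=L,
        populations=[PopulationPlan("p", [Epoch(0, gens, N)], selfing_rate=kw.pop("selfing", 0.0))],
        mu_neutral=mu,
        mu_del=0.0,
        mu_lof=0.0,
        sample_sizes={"p": kw.pop("n_sample", N)},
    )
    params.update(kw)
    return SimulationConfig(**params)


def fourfold_pi(ds, truth):
    pool = len(truth.genome.pools["neutral-4fold"])
    n = 2 * ds.n_samples
    c = ds.dosage.clip(0).sum(axis=1)
    return float((2.0 * c * (n - c) / (n * (n - 1))).sum() / pool)


def test_same_seed_gives_identical_vcf_bytes(tmp_path):
    cfg = two_pop_config(seed=33)
    out = []
    for run in range(2):
        ds, truth = simulate(cfg)
        paths = write_bundle(ds, truth, tmp_path / f"run{run}")
        out.append(paths["vcf"].read_bytes())
    assert out[0] == out[1]


def test_different_seeds_differ(tmp_path):
    a, _ = simulate(two_pop_config(seed=1))
    b, _ = simulate(two_pop_config(seed=2))
    assert a.n_sites != b.n_sites or not np.array_equal(a.pos, b.pos)


def test_neutral_pi_matches_coalescent_expectation():
    """Mean fourfold diversity over replicates within 3 SE of theta = 4*N*mu."""
    N, mu = 40, 3e-5
    ratios = []
    for seed in range(1, 11):
        ds, truth = simulate(one_pop_config(seed, N=N, gens=8 * N, mu=mu, L=100_000))
        ratios.append(fourfold_pi(ds, truth) / (4 * N * mu))
    mean, se = np.mean(ratios), np.std(ratios, ddof=1) / np.sqrt(len(ratios))
    assert abs(mean - 1.0) < 3 * se + 0.02


def test_selfing_reduces_heterozygosity_by_fis():
    """Observed het at common neutral sites ~ (1 - F/(2-F)) * 2pq under
    selfing. Restricted to MAF >= 0.2: brand-new mutations are always
    heterozygous, so rare variants sit above the identity equilibrium."""
    F = 0.8
    fis = F / (2 - F)
    obs_het, exp_het = 0.0, 0.0
    for seed in range(1, 7):
        ds, truth = simulate(
            one_pop_config(seed, N=50, gens=400, mu=2e-5, L=100_000, selfing=F)
        )
        p = ds.dosage.clip(0).sum(axis=1) / (2 * ds.n_samples)
        common = np.minimum(p, 1 - p) >= 0.2
        obs_het += float((ds.dosage[common] == 1).mean(axis=1).sum())
        exp_het += float(((1 - fis) * 2 * p[common] * (1 - p[common])).sum())
    assert obs_het / exp_het == pytest.approx(1.0, rel=0.15)


def test_additive_mutation_selection_balance():
    """Partially dominant deleterious frequency near u/(h*s), the additive
    mutation-selection balance (2*N*h*s >> 1, so drift effects are small)."""
    s, h, u, N = 0.2, 0.5, 2e-4, 500
    cfg = SimulationConfig(
        seed=5,
        n_generations=600,
        sequence_length_bp=3_000,
        populations=[PopulationPlan("p", [Epoch(0, 600, N)])],
        mu_neutral=0.0,
        mu_del=u,
        sel_coeff=s,
        dominance=h,
        intergenic_bp=500,
        sample_sizes={"p": N},
    )
    _, truth = simulate(cfg)
    pool = len(truth.genome.pools["deleterious-missense"])
    mean_q = float(truth.pop_freqs["p"].sum() / pool)
    assert mean_q == pytest.approx(u / (h * s), rel=0.3)


def test_population_extinction_is_reported():
    cfg = one_pop_config(3, N=2, gens=50, mu=0.0)
    cfg = dataclasses.replace(cfg, mu_lof=2e-2, s_lof=1.0, h_lof=1.0, sample_sizes={"p": 2})
    with pytest.raises(ExtinctionError, match="generation"):
        simulate(cfg)


@pytest.mark.parametrize(
    "bad",
    [
        dict(mu_neutral=1.5),
        dict(dominance=-0.1),
        dict(linkage="chromosomal"),
    ],
)
def test_config_validation_rejects_bad_values(bad):
    cfg = one_pop_config(1)
    cfg = dataclasses.replace(cfg, **bad)
    with pytest.raises(ValueError):
        cfg.validate()


def test_epochs_must_tile_run():
    cfg = one_pop_config(1)
    cfg.populations[0].epochs = [Epoch(0, 100, 50), Epoch(120, 500, 50)]
    with pytest.raises(ValueError, match="tile"):
        cfg.validate()


@pytest.mark.parametrize("scale", ["small", "default"])
def test_scenario_presets_are_valid(scale):
    cfg = make_highland_lowland_scenario(scale, seed=1)
    cfg.validate()
    lowland = next(p for p in cfg.populations if p.parent is None)
    highs = [p for p in cfg.populations if p.parent is not None]
    assert len(highs) >= 2
    assert all(p.selfing_rate >= 0.5 for p in highs)
    assert all(p.size_at(cfg.n_generations - 1) < lowland.size_at(0) for p in highs)
    assert cfg.dominance == 0.0 and cfg.sel_coeff > 0


def test_small_scenario_is_desk_scale():
    cfg = make_highland_lowland_scenario("small", seed=1)
    total = sum(
        (e.end_gen - e.start_gen) * e.size for p in cfg.populations for e in p.epochs
    )
    assert total * cfg.sequence_length_bp / 1000 <= 1e8  # genotype-generations budget


def test_bundle_round_trip(sim_pair, bundle):
    ds, _ = sim_pair
    back = read_vcf(bundle["vcf"])
    assert back.samples == ds.samples
    assert np.array_equal(back.pos, ds.pos)
    assert np.array_equal(back.dosage, ds.dosage)
    assert np.array_equal(np.asarray(back.ref), np.asarray(ds.ref))


def test_empty_segregating_set_gives_header_only_vcf(tmp_path):
    cfg = one_pop_config(2, N=10, gens=20, mu=0.0, n_sample=5)
    ds, truth = simulate(cfg)
    assert ds.n_sites == 0
    paths = write_bundle(ds, truth, tmp_path)
    back = read_vcf(paths["vcf"])
    assert back.n_sites == 0 and back.samples == ds.samples


def test_truth_aligned_with_dataset(sim_pair):
    ds, truth = sim_pair
    assert len(truth.pos) == ds.n_sites
    assert np.array_equal(truth.pos, ds.pos)
    # truth ancestral allele is the reference base (mutations arise on ref)
    assert np.array_equal(truth.ancestral, np.asarray(ds.ref))
    for freqs in truth.pop_freqs.values():
        assert np.all((freqs >= 0) & (freqs <= 1))


def test_block_linkage_transmits_whole_haplotypes():
    """In block mode a selfed lineage goes fully homozygous fast."""
    cfg = one_pop_config(4, N=30, gens=300, mu=4e-5, L=150_000, selfing=0.9)
    cfg = dataclasses.replace(cfg, linkage="block")
    ds, _ = simulate(cfg)
    assert ds.n_sites >= 10
    het_rate = float((ds.dosage == 1).mean())
    assert het_rate < 0.1
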