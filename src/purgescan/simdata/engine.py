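"""Forward-time diploid Wright-Fisher engine with selection, dominance,
demography and partial selfing.

Model: non-overlapping generations; per-generation cycle is mutation ->
viability selection (per-site genotype fitness 1, 1-hs, 1-s, multiplicative
across sites) -> mating, where each offspring is produced by selfing with the
population's selfing probability and by random union of gametes otherwise.
Parents are sampled proportionally to viability. Sites are strictly biallelic
against the reference: each pool position has one bound alternate allele,
mutation acts per reference copy (ref -> alt; recurrent mutation to a third
allele never occurs), and a position fixed in every population is retired as
a substitution.

Linkage: in ``independent`` mode every site segregates independently at
gamete formation (free recombination; closed-form single-locus expectations
are exact); in ``block`` mode a gamete is one intact parental haplotype (a
single non-recombining segment).

Randomness is drawn from per-(population, generation) streams keyed from the
master seed, so identical configs reproduce bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from purgescan.simdata.config import PopulationPlan, SimulationConfig
from purgescan.simdata.genome import (
    CLASS_MISSENSE,
    CLASS_NEUTRAL,
    CLASS_STOPGAIN,
    ToyGenome,
    build_toy_genome,
)
from purgescan.variant_io import GenotypeDataset

_CLASS_ORDER = [CLASS_NEUTRAL, CLASS_MISSENSE, CLASS_STOPGAIN]
_PRUNE_INTERVAL = 16


class ExtinctionError(RuntimeError):
    """Raised when every individual of a population has zero viability."""


@dataclass
class SimTruth:
    """Ground truth aligned 1:1 with the emitted dataset's sites."""

    chrom: np.ndarray
    pos: np.ndarray  # 1-based, aligned with GenotypeDataset
    ancestral: np.ndarray  # true ancestral allele (the toy-genome ref base)
    site_class: np.ndarray  # class label per site
    s: np.ndarray
    h: np.ndarray
    pop_freqs: dict[str, np.ndarray]  # full-population final derived freq
    og1: np.ndarray  # outgroup lineage 1 allele
    og2: np.ndarray
    genome: ToyGenome
    config: SimulationConfig


class _Registry:
    """Global registry of segregating sites (columns of the pop matrices)."""

    def __init__(self) -> None:
        self.pos: list[int] = []  # 0-based genome coordinate
        self.ref: list[str] = []
        self.alt: list[str] = []
        self.cls: list[int] = []  # index into _CLASS_ORDER
        self.pool_idx: list[int] = []  # index into the class pool
        self.s = np.zeros(0)
        self.h = np.zeros(0)

    def __len__(self) -> int:
        return len(self.pos)

    def keep(self, mask: np.ndarray) -> None:
        idx = np.flatnonzero(mask)
        self.pos = [self.pos[i] for i in idx]
        self.ref = [self.ref[i] for i in idx]
        self.alt = [self.alt[i] for i in idx]
        self.cls = [self.cls[i] for i in idx]
        self.pool_idx = [self.pool_idx[i] for i in idx]
        self.s = self.s[idx]
        self.h = self.h[idx]


class _SiteBook:
    """Bookkeeping of pool positions: segregating columns and retired sites.

    Mutation is per ref copy: each event targets a uniform (site, haplotype
    copy) slot and converts ref -> the site's bound alt allele. Hitting a
    copy that already carries the alt is a no-op (exact Poisson thinning to
    the ref copies). A site fixed in every population is retired — no ref
    copies remain to mutate and the reference no longer matches the
    population consensus, matching the substitution interpretation.
    """

    def __init__(self) -> None:
        self.col_of: dict[tuple[int, int], int] = {}  # (class, pool idx) -> column
        self.retired: set[tuple[int, int]] = set()


class _Pop:
    def __init__(self, plan: PopulationPlan, A: np.ndarray, B: np.ndarray) -> None:
        self.plan = plan
        self.A = A  # haplotype 1, uint8 (N, S)
        self.B = B  # haplotype 2

    @property
    def n(self) -> int:
        return self.A.shape[0]


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed)] + [int(k) for k in key]))


def _class_params(config: SimulationConfig) -> list[tuple[str, float, float, float]]:
    return [
        (CLASS_NEUTRAL, config.mu_neutral, 0.0, 0.0),
        (CLASS_MISSENSE, config.mu_del, config.sel_coeff, config.dominance),
        (CLASS_STOPGAIN, config.mu_lof, config.s_lof, config.h_lof),
    ]


def simulate(config: SimulationConfig) -> tuple[GenotypeDataset, SimTruth]:
    """Run the scenario and return sampled genotypes plus ground truth.

    Only sites segregating among the sampled individuals are emitted. Raises
    :class:`ExtinctionError` if selection drives a population to zero mean
    viability, naming the generation.
    """
    config.validate()
    genome = build_toy_genome(
        seed=config.seed,
        sequence_length_bp=config.sequence_length_bp,
        codons_per_gene=config.codons_per_gene,
        intergenic_bp=config.intergenic_bp,
    )

    book = _SiteBook()
    registry = _Registry()
    plans = {p.name: p for p in config.populations}
    root = next(p for p in config.populations if p.parent is None)
    n0 = root.size_at(0)
    pops: dict[str, _Pop] = {
        root.name: _Pop(root, np.zeros((n0, 0), np.uint8), np.zeros((n0, 0), np.uint8))
    }
    pop_index = {p.name: i for i, p in enumerate(config.populations)}

    for gen in range(config.n_generations):
        # founding events: daughter populations sample founders from parent
        for plan in config.populations:
            if plan.split_gen == gen:
                parent = pops[plan.parent]
                rng = _rng(config.seed, 2, pop_index[plan.name], gen)
                founders = rng.integers(0, parent.n, size=plan.size_at(gen))
                pops[plan.name] = _Pop(plan, parent.A[founders].copy(), parent.B[founders].copy())

        _mutation_round(config, genome, pops, registry, book, pop_index, gen)

        # viability selection + mating
        for name, pop in pops.items():
            rng = _rng(config.seed, 4, pop_index[name], gen)
            n_next = pop.plan.size_at(min(gen + 1, config.n_generations - 1))
            w = _viability(pop, registry)
            total = w.sum()
            if total <= 0:
                raise ExtinctionError(
                    f"population {name} extinct (all viabilities zero) at generation {gen}"
                )
            prob = w / total
            mothers = rng.choice(pop.n, size=n_next, p=prob)
            selfed = rng.random(n_next) < pop.plan.selfing_rate
            fathers = np.where(selfed, mothers, rng.choice(pop.n, size=n_next, p=prob))
            A_new = _gamete(pop, mothers, rng, config.linkage)
            B_new = _gamete(pop, fathers, rng, config.linkage)
            pop.A, pop.B = A_new, B_new

        if (gen + 1) % _PRUNE_INTERVAL == 0 and len(registry):
            _prune(pops, registry, book)

    # final mutation round before observation, so sampled genomes carry the
    # current generation's mutations (matching coalescent branch-length
    # expectations for terminal branches)
    _mutation_round(config, genome, pops, registry, book, pop_index, config.n_generations)
    _prune(pops, registry, book)
    return _collect(config, genome, pops, registry)


def _mutation_round(
    config: SimulationConfig,
    genome: ToyGenome,
    pops: dict[str, _Pop],
    registry: _Registry,
    book: _SiteBook,
    pop_index: dict[str, int],
    gen: int,
) -> None:
    """Per-copy ref -> alt mutation events over each class's site pool.

    Events are drawn uniformly over site x individual x haplotype slots; hits
    on copies already carrying the alt are no-ops, so the realised rate is
    exactly mu per ref copy per generation.
    """
    events: list[tuple[str, int, int, int, int, float, float]] = []
    for name, pop in pops.items():
        rng = _rng(config.seed, 3, pop_index[name], gen)
        for ci, (cname, mu, s, h) in enumerate(_class_params(config)):
            pool = genome.pools[cname]
            if mu <= 0 or len(pool) == 0:
                continue
            n_events = int(rng.poisson(2 * pop.n * mu * len(pool)))
            if n_events == 0:
                continue
            sites = rng.integers(len(pool), size=n_events)
            inds = rng.integers(pop.n, size=n_events)
            haps = rng.integers(2, size=n_events)
            for pi, ind, hap in zip(sites, inds, haps):
                events.append((name, ci, int(pi), int(ind), int(hap), s, h))

    # register any genuinely new sites first, then apply all flips
    new_count = 0
    for name, ci, pi, ind, hap, s, h in events:
        key = (ci, pi)
        if key in book.retired or key in book.col_of:
            continue
        pool = genome.pools[_CLASS_ORDER[ci]]
        book.col_of[key] = len(registry.pos)
        registry.cls.append(ci)
        registry.pool_idx.append(pi)
        registry.pos.append(int(pool.positions[pi]))
        registry.ref.append(str(pool.ref[pi]))
        registry.alt.append(str(pool.alt[pi]))
        registry.s = np.append(registry.s, s)
        registry.h = np.append(registry.h, h)
        new_count += 1
    if new_count:
        for name, pop in pops.items():
            pad = np.zeros((pop.n, new_count), np.uint8)
            pop.A = np.hstack([pop.A, pad])
            pop.B = np.hstack([pop.B, pad.copy()])
    for name, ci, pi, ind, hap, s, h in events:
        key = (ci, pi)
        if key in book.retired:
            continue
        col = book.col_of[key]
        target = pops[name].A if hap == 0 else pops[name].B
        target[ind, col] = 1  # ref copies mutate; alt copies are no-ops


def draw_outgroup_alleles(
    ancestral: np.ndarray, divergence: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Two single-genome outgroup allele columns derived from the ancestral
    alleles: each lineage substitutes independently with probability
    1 - exp(-divergence), uniformly over the three other bases. Outgroups are
    never polymorphic."""
    p_mut = 1.0 - np.exp(-divergence)
    out = []
    for _ in range(2):
        alleles = ancestral.copy()
        mutate = rng.random(len(ancestral)) < p_mut
        for i in np.flatnonzero(mutate):
            others = [b for b in "ACGT" if b != ancestral[i]]
            alleles[i] = others[rng.integers(3)]
        out.append(alleles)
    return out[0], out[1]


def _viability(pop: _Pop, registry: _Registry) -> np.ndarray:
    sel = np.flatnonzero(registry.s > 0)
    if len(sel) == 0 or pop.A.shape[1] == 0:
        return np.ones(pop.n)
    G = pop.A[:, sel].astype(np.int8) + pop.B[:, sel]
    with np.errstate(divide="ignore"):
        log_het = np.log1p(-registry.h[sel] * registry.s[sel])
        log_hom = np.log1p(-registry.s[sel])
    logw = (G == 1) @ log_het + (G == 2) @ log_hom
    finite = np.isfinite(logw)
    if not finite.any():
        return np.zeros(pop.n)
    w = np.zeros(pop.n)
    m = logw[finite].max()
    w[finite] = np.exp(logw[finite] - m)
    return w


def _gamete(pop: _Pop, parents: np.ndarray, rng: np.random.Generator, linkage: str) -> np.ndarray:
    Ap = pop.A[parents]
    Bp = pop.B[parents]
    if linkage == "independent":
        coin = rng.random(Ap.shape, dtype=np.float32) < 0.5
    else:
        coin = rng.random((len(parents), 1), dtype=np.float32) < 0.5
    return np.where(coin, Ap, Bp)


def _prune(
    pops: dict[str, _Pop],
    registry: _Registry,
    book: _SiteBook | None = None,
) -> None:
    if len(registry) == 0:
        return
    total = np.zeros(len(registry), dtype=np.int64)
    alleles = 0
    for pop in pops.values():
        total += pop.A.sum(axis=0, dtype=np.int64) + pop.B.sum(axis=0, dtype=np.int64)
        alleles += 2 * pop.n
    keep = (total > 0) & (total < alleles)
    if keep.all():
        return
    if book is not None:
        for i in np.flatnonzero(~keep):
            key = (registry.cls[i], registry.pool_idx[i])
            book.col_of.pop(key, None)
            if total[i] >= alleles:  # globally fixed: a substitution; retire
                book.retired.add(key)
        # remap surviving columns
        new_index = np.cumsum(keep) - 1
        for key, col in list(book.col_of.items()):
            book.col_of[key] = int(new_index[col])
    registry.keep(keep)
    for pop in pops.values():
        pop.A = pop.A[:, keep]
        pop.B = pop.B[:, keep]


def _collect(
    config: SimulationConfig,
    genome: ToyGenome,
    pops: dict[str, _Pop],
    registry: _Registry,
) -> tuple[GenotypeDataset, SimTruth]:
    pop_index = {p.name: i for i, p in enumerate(config.populations)}
    samples: list[str] = []
    rows: list[np.ndarray] = []
    for name in (p.name for p in config.populations):
        if name not in config.sample_sizes:
            continue
        k = config.sample_sizes[name]
        pop = pops[name]
        if k > pop.n:
            raise ValueError(f"cannot sample {k} diploids from {name} of size {pop.n}")
        rng = _rng(config.seed, 5, pop_index[name])
        chosen = rng.choice(pop.n, size=k, replace=False)
        dosage = (pop.A[chosen].astype(np.int8) + pop.B[chosen]).astype(np.int8)
        rows.append(dosage)
        samples.extend(f"{name}_{i:03d}" for i in range(k))
    if not rows:
        raise ValueError("config.sample_sizes is empty; nothing to emit")
    dosage = np.vstack(rows)  # (n_samples, S)

    tot = dosage.sum(axis=0, dtype=np.int64)
    seg = (tot > 0) & (tot < 2 * dosage.shape[0])
    idx = np.flatnonzero(seg)
    pos0 = np.asarray([registry.pos[i] for i in idx], dtype=np.int64)
    order = np.argsort(pos0, kind="stable")
    idx = idx[order]
    pos0 = pos0[order]

    n_sites = len(idx)
    chrom = np.asarray([genome.chrom] * n_sites, dtype=object)
    ref = np.asarray([registry.ref[i] for i in idx], dtype="U1")
    alt = np.asarray([registry.alt[i] for i in idx], dtype="U1")
    ds = GenotypeDataset(
        samples=samples,
        chrom=chrom,
        pos=pos0 + 1,  # 1-based
        ref=ref,
        alt=alt,
        dosage=dosage[:, idx].T,
    )

    pop_freqs = {}
    for name, pop in pops.items():
        counts = pop.A.sum(axis=0, dtype=np.int64) + pop.B.sum(axis=0, dtype=np.int64)
        pop_freqs[name] = counts[idx] / (2 * pop.n)

    og = draw_outgroup_alleles(ref, config.outgroup_divergence, _rng(config.seed, 6))

    truth = SimTruth(
        chrom=chrom,
        pos=pos0 + 1,
        ancestral=ref.copy(),
        site_class=np.asarray([_CLASS_ORDER[registry.cls[i]] for i in idx], dtype=object),
        s=registry.s[idx],
        h=registry.h[idx],
        pop_freqs=pop_freqs,
        og1=og[0],
        og2=og[1],
        genome=genome,
        config=config,
    )
    return ds, truth
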