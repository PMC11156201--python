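"""Simulation scenarios: demographic plans, mutation/selection parameters.

Rates are per site per generation over the relevant mutable site pool of the
toy genome. Desk-scale presets use mutation rates well above the plant
nuclear point estimate (~7e-9/site/gen) so that equilibria are reached within
hundreds of generations on small genomes; diversity magnitudes scale
accordingly (theta = 4*N*mu).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class Epoch:
    start_gen: int
    end_gen: int  # exclusive
    size: int  # diploid N


@dataclass
class PopulationPlan:
    name: str
    epochs: list[Epoch]
    selfing_rate: float = 0.0
    parent: str | None = None
    split_gen: int | None = None

    def size_at(self, gen: int) -> int:
        for e in self.epochs:
            if e.start_gen <= gen < e.end_gen:
                return e.size
        if gen >= self.epochs[-1].end_gen:
            return self.epochs[-1].size
        raise ValueError(f"population {self.name} has no epoch at generation {gen}")

    @property
    def birth_gen(self) -> int:
        return self.split_gen if self.split_gen is not None else 0


@dataclass
class SimulationConfig:
    seed: int
    n_generations: int
    sequence_length_bp: int
    populations: list[PopulationPlan]
    mu_neutral: float = 7.0e-9
    mu_del: float = 7.0e-9
    sel_coeff: float = 0.0  # s for the deleterious-missense class
    dominance: float = 0.5  # h for the deleterious-missense class
    mu_lof: float = 0.0  # stopgain-like class
    s_lof: float = 0.5
    h_lof: float = 0.1
    outgroup_divergence: float = 0.02  # expected substitutions/site per lineage
    sample_sizes: dict[str, int] = field(default_factory=dict)
    linkage: str = "independent"  # or "block" (single non-recombining segment)
    codons_per_gene: int = 120
    intergenic_bp: int = 3000

    def validate(self) -> None:
        for rate in (self.mu_neutral, self.mu_del, self.mu_lof):
            if not 0 <= rate < 1:
                raise ValueError("mutation rates must be in [0, 1)")
        for s in (self.sel_coeff, self.s_lof):
            if s < 0:
                raise ValueError("selection coefficients must be >= 0")
        for h in (self.dominance, self.h_lof):
            if not 0 <= h <= 1:
                raise ValueError("dominance must be in [0, 1]")
        if self.outgroup_divergence < 0:
            raise ValueError("outgroup divergence must be >= 0")
        if self.linkage not in ("independent", "block"):
            raise ValueError("linkage must be 'independent' or 'block'")
        if not self.populations:
            raise ValueError("at least one population required")
        roots = [p for p in self.populations if p.parent is None]
        if len(roots) != 1:
            raise ValueError("exactly one root population (parent=None) required")
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("population names must be unique")
        for p in self.populations:
            if not 0 <= p.selfing_rate <= 1:
                raise ValueError(f"{p.name}: selfing rate must be in [0, 1]")
            if p.parent is not None:
                if p.parent not in names:
                    raise ValueError(f"{p.name}: unknown parent {p.parent}")
                if p.split_gen is None or not 0 < p.split_gen < self.n_generations:
                    raise ValueError(f"{p.name}: split_gen must lie inside the run")
            if not p.epochs:
                raise ValueError(f"{p.name}: needs at least one epoch")
            cursor = p.birth_gen
            for e in p.epochs:
                if e.size < 2:
                    raise ValueError(f"{p.name}: epoch size must be >= 2")
                if e.start_gen != cursor or e.end_gen <= e.start_gen:
                    raise ValueError(
                        f"{p.name}: epochs must tile [{p.birth_gen}, n_generations] without overlap"
                    )
                cursor = e.end_gen
            if cursor != self.n_generations:
                raise ValueError(f"{p.name}: epochs must end at n_generations")
        for name, n in self.sample_sizes.items():
            if name not in names:
                raise ValueError(f"sample_sizes names unknown population {name}")
            if n < 1:
                raise ValueError("sample sizes must be >= 1")


def make_highland_lowland_scenario(scale: str = "small", seed: int = 1) -> SimulationConfig:
    """Preset contrasting one large outcrossing lowland population with
    several small, bottlenecked, highly selfing highland isolates.

    The deleterious-missense class is fully recessive (h=0) by default, the
    regime in which inbreeding exposes homozygotes and purging can act; pass
    the returned config through ``dataclasses.replace`` to change ``dominance``
    for the additive contrast arm.
    """
    # Conditions are chosen to emulate the study system at desk scale:
    # highland isolates split from the lowland pool, pass through a glacial
    # bottleneck with high selfing (recessives exposed as homozygotes; the
    # per-copy purging rate ~ s * F_is stays selection-dominated), then
    # recover, which regenerates an excess of rare, still-selected
    # deleterious variants. Highland diversity ends reduced but of the same
    # order as the lowland, not erased.
    if scale == "small":
        n_gen = 880
        split = 800
        recover = 830
        lowland_n = 100
        bottleneck_ns = [15, 20, 25, 30]
        recovery_ns = [60, 75, 85, 95]
        seq_len = 400_000
        mu_neutral = 2.0e-5
        mu_del = 8.0e-6
        mu_lof = 4.0e-7
        samples = {"lowland": 15, "highland1": 15, "highland2": 15, "highland3": 15, "highland4": 15}
    elif scale == "default":
        n_gen = 5300
        split = 5000
        recover = 5120
        lowland_n = 500
        bottleneck_ns = [40, 55, 70, 90]
        recovery_ns = [250, 320, 400, 470]
        seq_len = 1_200_000
        mu_neutral = 5.0e-6
        mu_del = 2.0e-6
        mu_lof = 1.0e-7
        samples = {"lowland": 30, "highland1": 15, "highland2": 15, "highland3": 15, "highland4": 15}
    else:
        raise ValueError("scale must be 'small' or 'default'")

    pops = [
        PopulationPlan(
            name="lowland",
            epochs=[Epoch(0, n_gen, lowland_n)],
            selfing_rate=0.0,
        )
    ]
    for i, (nb, nr) in enumerate(zip(bottleneck_ns, recovery_ns), start=1):
        pops.append(
            PopulationPlan(
                name=f"highland{i}",
                epochs=[Epoch(split, recover, nb), Epoch(recover, n_gen, nr)],
                selfing_rate=0.8,
                parent="lowland",
                split_gen=split,
            )
        )
    return SimulationConfig(
        seed=seed,
        n_generations=n_gen,
        sequence_length_bp=seq_len,
        populations=pops,
        mu_neutral=mu_neutral,
        mu_del=mu_del,
        sel_coeff=0.3,
        dominance=0.0,
        mu_lof=mu_lof,
        s_lof=0.5,
        h_lof=0.1,
        outgroup_divergence=0.02,
        sample_sizes=samples,
    )
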