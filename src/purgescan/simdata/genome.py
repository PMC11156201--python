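"""Toy reference genome with protein-coding genes for the forward simulator.

The builder tiles single-exon genes (alternating strands) along one
chromosome, separated by random intergenic sequence, and enumerates the
mutable site pools the simulator draws from:

* ``neutral-4fold``   — fourfold-degenerate third codon positions; any
  substitution is synonymous.
* ``deleterious-missense`` — CDS positions with a bound alternate allele whose
  codon change is nonsynonymous (and not a stop change).
* ``stopgain``        — CDS positions with a bound alternate allele that turns
  a sense codon into a stop.

Alternate alleles are bound at build time so the mutation registry, the
emitted VCF and the functional truth labels are all consistent by
construction. Positions inside the terminal stop codon are excluded from all
pools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from purgescan._codon import (
    BASES,
    complement,
    degeneracy,
    revcomp,
    substitution_effect,
    translate_codon,
)

CLASS_NEUTRAL = "neutral-4fold"
CLASS_MISSENSE = "deleterious-missense"
CLASS_STOPGAIN = "stopgain"

# fraction of stopgain-capable CDS positions reserved for the stopgain pool
# rather than the (much larger) missense pool
_STOPGAIN_POOL_FRACTION = 0.25


@dataclass
class Gene:
    gene_id: str
    start: int  # 0-based, half-open
    end: int
    strand: str  # '+' or '-'
    n_codons: int


@dataclass
class SitePool:
    """Mutable positions of one functional class, with bound alleles."""

    positions: np.ndarray  # 0-based genome coordinates, sorted
    ref: np.ndarray  # genome-strand reference bases
    alt: np.ndarray  # genome-strand bound alternate bases

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class ToyGenome:
    chrom: str
    seq: str
    genes: list[Gene]
    pools: dict[str, SitePool] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.seq)


def _random_sense_codon(rng: np.random.Generator) -> str:
    while True:
        codon = "".join(rng.choice(list(BASES), size=3))
        if translate_codon(codon) != "*":
            return codon


def build_toy_genome(
    seed: int,
    sequence_length_bp: int,
    codons_per_gene: int = 120,
    intergenic_bp: int = 3000,
    chrom: str = "chr1",
) -> ToyGenome:
    """Build a deterministic toy genome of approximately the requested length.

    Genes alternate strand; each gene is ATG + (codons_per_gene - 2) random
    sense codons + a random stop codon, single-exon.
    """
    if codons_per_gene < 3:
        raise ValueError("codons_per_gene must be >= 3")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7919]))
    gene_bp = codons_per_gene * 3
    unit = gene_bp + intergenic_bp
    n_genes = max(1, sequence_length_bp // unit)

    parts: list[str] = []
    genes: list[Gene] = []
    cursor = 0
    for g in range(n_genes):
        inter = "".join(rng.choice(list(BASES), size=intergenic_bp))
        parts.append(inter)
        cursor += intergenic_bp
        codons = ["ATG"]
        codons += [_random_sense_codon(rng) for _ in range(codons_per_gene - 2)]
        codons.append(rng.choice(["TAA", "TAG", "TGA"]))
        cds = "".join(codons)
        strand = "+" if g % 2 == 0 else "-"
        segment = cds if strand == "+" else revcomp(cds)
        parts.append(segment)
        genes.append(
            Gene(
                gene_id=f"gene{g + 1:04d}",
                start=cursor,
                end=cursor + gene_bp,
                strand=strand,
                n_codons=codons_per_gene,
            )
        )
        cursor += gene_bp
    tail = "".join(rng.choice(list(BASES), size=intergenic_bp))
    parts.append(tail)
    seq = "".join(parts)

    genome = ToyGenome(chrom=chrom, seq=seq, genes=genes)
    genome.pools = _build_pools(genome, rng)
    return genome


def _coding_sequence(genome: ToyGenome, gene: Gene) -> str:
    segment = genome.seq[gene.start : gene.end]
    return segment if gene.strand == "+" else revcomp(segment)


def _build_pools(genome: ToyGenome, rng: np.random.Generator) -> dict[str, SitePool]:
    neutral: list[tuple[int, str, str]] = []
    missense: list[tuple[int, str, str]] = []
    stopgain: list[tuple[int, str, str]] = []

    for gene in genome.genes:
        cds = _coding_sequence(genome, gene)
        n_codons = len(cds) // 3
        for ci in range(n_codons - 1):  # skip the terminal stop codon
            codon = cds[3 * ci : 3 * ci + 3]
            for offset in range(3):
                cds_index = 3 * ci + offset
                if gene.strand == "+":
                    gpos = gene.start + cds_index
                else:
                    gpos = gene.end - 1 - cds_index
                coding_ref = codon[offset]
                genome_ref = genome.seq[gpos]
                if degeneracy(codon, offset) == 4:
                    others = [b for b in BASES if b != genome_ref]
                    neutral.append((gpos, genome_ref, rng.choice(others)))
                    continue
                stop_alts = []
                mis_alts = []
                for b in BASES:
                    if b == coding_ref:
                        continue
                    alt_codon = codon[:offset] + b + codon[offset + 1 :]
                    eff = substitution_effect(codon, alt_codon)
                    if eff == "stopgain":
                        stop_alts.append(b)
                    elif eff == "nonsynonymous":
                        mis_alts.append(b)
                if stop_alts and rng.random() < _STOPGAIN_POOL_FRACTION:
                    coding_alt = rng.choice(stop_alts)
                elif mis_alts:
                    coding_alt = rng.choice(mis_alts)
                    stop_alts = []
                else:
                    continue
                genome_alt = (
                    coding_alt if gene.strand == "+" else complement(coding_alt)
                )
                if stop_alts:
                    stopgain.append((gpos, genome_ref, genome_alt))
                else:
                    missense.append((gpos, genome_ref, genome_alt))

    def _pool(entries: list[tuple[int, str, str]]) -> SitePool:
        entries = sorted(entries)
        if entries:
            pos, ref, alt = zip(*entries)
        else:
            pos, ref, alt = (), (), ()
        return SitePool(
            positions=np.asarray(pos, dtype=np.int64),
            ref=np.asarray(ref, dtype="U1"),
            alt=np.asarray(alt, dtype="U1"),
        )

    return {
        CLASS_NEUTRAL: _pool(neutral),
        CLASS_MISSENSE: _pool(missense),
        CLASS_STOPGAIN: _pool(stopgain),
    }
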