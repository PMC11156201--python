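"""Write a simulated dataset as the standard-format bundle the pipeline reads:
VCF + reference FASTA + GFF3 gene models + outgroup/clade/dnSNP tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from purgescan.simdata.engine import SimTruth
from purgescan.simdata.genome import CLASS_MISSENSE
from purgescan.variant_io import CladeMap, GenotypeDataset, write_clade_map, write_vcf


class BundleConsistencyError(RuntimeError):
    pass


def default_clade_map(ds: GenotypeDataset, truth: SimTruth) -> CladeMap:
    """One clade per simulated population; the root population is 'low' altitude."""
    root = next(p.name for p in truth.config.populations if p.parent is None)
    s2c: dict[str, str] = {}
    for s in ds.samples:
        pop = s.rsplit("_", 1)[0]
        s2c[s] = pop
    c2a = {
        p.name: ("low" if p.name == root else "high")
        for p in truth.config.populations
        if p.name in set(s2c.values())
    }
    return CladeMap(sample_to_clade=s2c, clade_to_altitude=c2a)


def write_fasta(truth: SimTruth, path, width: int = 80) -> None:
    seq = truth.genome.seq
    with open(path, "w") as fh:
        fh.write(f">{truth.genome.chrom}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def write_gff3(truth: SimTruth, path) -> None:
    chrom = truth.genome.chrom
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {chrom} 1 {truth.genome.length}\n")
        for gene in truth.genome.genes:
            start, end = gene.start + 1, gene.end  # GFF is 1-based inclusive
            gid = gene.gene_id
            fh.write(
                f"{chrom}\tpurgescan\tgene\t{start}\t{end}\t.\t{gene.strand}\t.\t"
                f"ID={gid};Name={gid}\n"
            )
            fh.write(
                f"{chrom}\tpurgescan\tmRNA\t{start}\t{end}\t.\t{gene.strand}\t.\t"
                f"ID={gid}.t1;Parent={gid}\n"
            )
            fh.write(
                f"{chrom}\tpurgescan\tCDS\t{start}\t{end}\t.\t{gene.strand}\t0\t"
                f"ID={gid}.cds;Parent={gid}.t1\n"
            )


def write_bundle(ds: GenotypeDataset, truth: SimTruth, outdir) -> dict[str, Path]:
    """Write the full input bundle; returns a name -> path map.

    Verifies at write time that every emitted site's REF matches the toy
    reference base (the truth ancestral allele lives on the reference).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seq = truth.genome.seq
    for i in range(ds.n_sites):
        refbase = seq[int(ds.pos[i]) - 1]
        if refbase != str(ds.ref[i]):
            raise BundleConsistencyError(
                f"site {ds.chrom[i]}:{ds.pos[i]}: VCF REF {ds.ref[i]} != reference base {refbase}"
            )

    paths = {
        "vcf": outdir / "variants.vcf",
        "fasta": outdir / "reference.fa",
        "gff3": outdir / "genes.gff3",
        "outgroups": outdir / "outgroups.tsv",
        "clades": outdir / "clades.tsv",
        "dnsnp": outdir / "dnsnp_sites.tsv",
        "truth": outdir / "truth_sites.tsv",
    }
    write_vcf(ds, paths["vcf"], contig_lengths={truth.genome.chrom: truth.genome.length})
    write_fasta(truth, paths["fasta"])
    write_gff3(truth, paths["gff3"])

    pd.DataFrame(
        {"chrom": ds.chrom, "pos": ds.pos, "og1": truth.og1, "og2": truth.og2}
    ).to_csv(paths["outgroups"], sep="\t", index=False)

    write_clade_map(default_clade_map(ds, truth), paths["clades"])

    dn = truth.site_class == CLASS_MISSENSE
    pd.DataFrame({"chrom": ds.chrom[dn], "pos": ds.pos[dn]}).to_csv(
        paths["dnsnp"], sep="\t", index=False
    )

    truth_df = pd.DataFrame(
        {
            "chrom": truth.chrom,
            "pos": truth.pos,
            "ancestral": truth.ancestral,
            "site_class": truth.site_class,
            "s": truth.s,
            "h": truth.h,
        }
    )
    for name, freqs in truth.pop_freqs.items():
        truth_df[f"freq_{name}"] = freqs
    truth_df.to_csv(paths["truth"], sep="\t", index=False)
    return paths
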