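"""Codon-aware functional classification of sites and SNPs.

Classifies genomic positions against reference FASTA + GFF3 CDS models into
region classes (CDS / intron / upstream / downstream / intergenic), computes
codon degeneracy, variant effects (synonymous / nonsynonymous / stopgain /
stoploss) and the genome-wide fourfold-degenerate site table used as the
neutral reference class.

Conventions: positions are 1-based; minus-strand codons are read on the
reverse complement; the upstream/downstream flank is 1 kb by default;
multi-transcript conflicts resolve to the most severe effect, while
fourfold-degenerate status requires unanimity across transcripts. Standard
nuclear genetic code.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field

from pyfaidx import Fasta

from purgescan._codon import degeneracy, revcomp, substitution_effect

log = logging.getLogger(__name__)

SEVERITY = ["stopgain", "stoploss", "nonsynonymous", "synonymous"]
FLANK_BP = 1000


class AnnotationError(ValueError):
    pass


@dataclass
class CodonContext:
    gene_id: str
    transcript_id: str
    strand: str
    codon: str  # coding orientation
    offset: int  # 0..2 position within codon
    degeneracy: int


@dataclass
class SiteAnnotation:
    chrom: str
    pos: int  # 1-based
    region: str  # CDS | intron | upstream | downstream | intergenic
    contexts: list[CodonContext] = field(default_factory=list)
    effect: str | None = None
    dnsnp: bool = False

    @property
    def degeneracy(self) -> int | None:
        """Most constrained (minimum) degeneracy across transcripts."""
        if not self.contexts:
            return None
        return min(c.degeneracy for c in self.contexts)

    @property
    def fourfold(self) -> bool:
        return bool(self.contexts) and all(c.degeneracy == 4 for c in self.contexts)


@dataclass
class _Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int  # 0-based half-open transcript span
    end: int
    cds_pos: list[int]  # genomic 0-based positions in coding order
    cds_seq: str  # coding-orientation sequence (phase-trimmed)


class AnnotationIndex:
    """Preprocessed FASTA+GFF3 lookup for repeated site/variant queries."""

    def __init__(self, ref_fasta, gff) -> None:
        self.fasta = Fasta(str(ref_fasta), as_raw=True, sequence_always_upper=True)
        self.transcripts: list[_Transcript] = []
        self._codon_map: dict[tuple[str, int], list[CodonContext]] = {}
        self._load_gff(gff)
        self._build_codon_map()

    # -- construction ------------------------------------------------------

    def _load_gff(self, gff) -> None:
        import gffutils

        db = gffutils.create_db(
            str(gff),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
        for tx in db.features_of_type(("mRNA", "transcript")):
            cds = sorted(db.children(tx, featuretype="CDS"), key=lambda f: f.start)
            if not cds:
                continue
            gene_id = tx.attributes.get("Parent", [tx.id])[0]
            strand = tx.strand
            parts = [(f.start - 1, f.end, f.frame) for f in cds]  # 0-based half-open
            if strand == "-":
                coding_parts = parts[::-1]
            else:
                coding_parts = parts
            pos_list: list[int] = []
            seq_parts: list[str] = []
            chrom_seq = str(self.fasta[tx.seqid][:])
            for start0, end0, frame in coding_parts:
                segment = chrom_seq[start0:end0]
                positions = list(range(start0, end0))
                if strand == "-":
                    segment = revcomp(segment)
                    positions = positions[::-1]
                seq_parts.append(segment)
                pos_list.extend(positions)
            seq = "".join(seq_parts)
            phase = coding_parts[0][2]
            phase = int(phase) if phase not in (".", None) else 0
            seq = seq[phase:]
            pos_list = pos_list[phase:]
            if len(seq) % 3 != 0:
                log.warning(
                    "transcript %s: CDS length %d not divisible by 3 after phase; "
                    "excluded from codon classification",
                    tx.id,
                    len(seq),
                )
                trim = len(seq) % 3
                seq = seq[: len(seq) - trim]
                pos_list = pos_list[: len(pos_list) - trim]
            self.transcripts.append(
                _Transcript(
                    transcript_id=tx.id,
                    gene_id=gene_id,
                    chrom=tx.seqid,
                    strand=strand,
                    start=tx.start - 1,
                    end=tx.end,
                    cds_pos=pos_list,
                    cds_seq=seq,
                )
            )
        # per-chrom sorted transcript spans for region lookups
        self._spans: dict[str, tuple[list[int], list[_Transcript]]] = {}
        by_chrom: dict[str, list[_Transcript]] = {}
        for t in self.transcripts:
            by_chrom.setdefault(t.chrom, []).append(t)
        for chrom, txs in by_chrom.items():
            txs.sort(key=lambda t: t.start)
            self._spans[chrom] = ([t.start for t in txs], txs)

    def _build_codon_map(self) -> None:
        for t in self.transcripts:
            seq = t.cds_seq
            for ci in range(len(seq) // 3):
                codon = seq[3 * ci : 3 * ci + 3]
                for offset in range(3):
                    gpos = t.cds_pos[3 * ci + offset]
                    ctx = CodonContext(
                        gene_id=t.gene_id,
                        transcript_id=t.transcript_id,
                        strand=t.strand,
                        codon=codon,
                        offset=offset,
                        degeneracy=degeneracy(codon, offset),
                    )
                    self._codon_map.setdefault((t.chrom, gpos), []).append(ctx)

    # -- queries -----------------------------------------------------------

    def ref_base(self, chrom: str, pos: int) -> str:
        if chrom not in self.fasta.keys():
            raise AnnotationError(f"unknown sequence {chrom}")
        if not 1 <= pos <= len(self.fasta[chrom]):
            raise AnnotationError(f"position {chrom}:{pos} outside reference")
        return str(self.fasta[chrom][pos - 1]).upper()

    def _nearby_transcripts(self, chrom: str, pos0: int, slop: int) -> list[_Transcript]:
        if chrom not in self._spans:
            return []
        starts, txs = self._spans[chrom]
        out = []
        i = bisect_right(starts, pos0 + slop)
        for t in txs[:i]:
            if t.end + slop > pos0:
                out.append(t)
        return out

    def region_of(self, chrom: str, pos: int) -> str:
        pos0 = pos - 1
        if (chrom, pos0) in self._codon_map:
            return "CDS"
        nearby = self._nearby_transcripts(chrom, pos0, FLANK_BP)
        intron = upstream = downstream = False
        for t in nearby:
            if t.start <= pos0 < t.end:
                intron = True  # inside transcript span but not in CDS/exon
            elif t.end <= pos0 < t.end + FLANK_BP:
                if t.strand == "+":
                    downstream = True
                else:
                    upstream = True
            elif t.start - FLANK_BP <= pos0 < t.start:
                if t.strand == "+":
                    upstream = True
                else:
                    downstream = True
        if intron:
            return "intron"
        if upstream:
            return "upstream"
        if downstream:
            return "downstream"
        return "intergenic"

    def contexts_at(self, chrom: str, pos: int) -> list[CodonContext]:
        return list(self._codon_map.get((chrom, pos - 1), []))


def classify_site(index: AnnotationIndex, chrom: str, pos: int) -> SiteAnnotation:
    """Classify a genomic position (no alternate allele)."""
    index.ref_base(chrom, pos)  # validates coordinates
    contexts = index.contexts_at(chrom, pos)
    region = "CDS" if contexts else index.region_of(chrom, pos)
    return SiteAnnotation(chrom=chrom, pos=pos, region=region, contexts=contexts)


def classify_variant(
    index: AnnotationIndex, chrom: str, pos: int, ref: str, alt: str
) -> SiteAnnotation:
    """Classify a SNP; effect is the most severe across overlapping transcripts.

    For sites outside any CDS the effect is the region class itself.
    """
    actual = index.ref_base(chrom, pos)
    if actual != ref.upper():
        raise AnnotationError(
            f"REF mismatch at {chrom}:{pos}: expected {actual}, got {ref}"
        )
    ann = classify_site(index, chrom, pos)
    if not ann.contexts:
        ann.effect = ann.region
        return ann
    effects = []
    for ctx in ann.contexts:
        coding_ref = ref if ctx.strand == "+" else _complement(ref)
        coding_alt = alt if ctx.strand == "+" else _complement(alt)
        if ctx.codon[ctx.offset] != coding_ref.upper():
            raise AnnotationError(
                f"codon/reference inconsistency at {chrom}:{pos} in {ctx.transcript_id}"
            )
        alt_codon = (
            ctx.codon[: ctx.offset] + coding_alt.upper() + ctx.codon[ctx.offset + 1 :]
        )
        effects.append(substitution_effect(ctx.codon, alt_codon))
    ann.effect = min(effects, key=SEVERITY.index)
    return ann


def _complement(base: str) -> str:
    from purgescan._codon import complement

    return complement(base)


def fourfold_site_table(index: AnnotationIndex) -> list[tuple[str, int]]:
    """All and only sites where every possible substitution is synonymous in
    every transcript covering the site as CDS. Returns 1-based (chrom, pos)."""
    out = []
    for (chrom, pos0), contexts in index._codon_map.items():
        if all(c.degeneracy == 4 for c in contexts):
            out.append((chrom, pos0 + 1))
    out.sort()
    return out


def annotate_dataset(index: AnnotationIndex, ds, dnsnp_sites: set | None = None):
    """Annotate every site of a GenotypeDataset; returns a pandas DataFrame."""
    import pandas as pd

    dnsnp_sites = dnsnp_sites or set()
    rows = []
    for i in range(ds.n_sites):
        chrom, pos = str(ds.chrom[i]), int(ds.pos[i])
        ann = classify_variant(index, chrom, pos, str(ds.ref[i]), str(ds.alt[i]))
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "region": ann.region,
                "effect": ann.effect,
                "degeneracy": ann.degeneracy if ann.degeneracy is not None else 0,
                "fourfold": ann.fourfold,
                "gene_id": ann.contexts[0].gene_id if ann.contexts else ".",
                "dnsnp": (chrom, pos) in dnsnp_sites,
            }
        )
    return pd.DataFrame(rows)
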