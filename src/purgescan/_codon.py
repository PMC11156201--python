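"""Codon-level helpers shared by the annotator and the toy-genome builder.

Standard nuclear genetic code only. Stop codons translate to ``*``.
"""

from __future__ import annotations

from Bio.Data.CodonTable import unambiguous_dna_by_id

_TABLE = unambiguous_dna_by_id[1]  # the standard code

BASES = "ACGT"
STOP_CODONS = frozenset(_TABLE.stop_codons)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def translate_codon(codon: str) -> str:
    """Amino acid for a codon; ``*`` for a stop."""
    codon = codon.upper()
    if codon in STOP_CODONS:
        return "*"
    return _TABLE.forward_table[codon]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def degeneracy(codon: str, offset: int) -> int:
    """Number of bases at ``offset`` (0..2) preserving the amino acid.

    Counts the reference base itself, so the result is in {1, 2, 3, 4};
    4 means the site is fourfold degenerate.
    """
    aa = translate_codon(codon)
    n = 0
    for b in BASES:
        alt_codon = codon[:offset] + b + codon[offset + 1 :]
        if translate_codon(alt_codon) == aa:
            n += 1
    return n


def substitution_effect(ref_codon: str, alt_codon: str) -> str:
    """Classify a single-codon substitution.

    Returns one of ``synonymous``, ``nonsynonymous``, ``stopgain``,
    ``stoploss``.
    """
    ref_aa = translate_codon(ref_codon)
    alt_aa = translate_codon(alt_codon)
    if ref_aa == alt_aa:
        return "synonymous"
    if alt_aa == "*":
        return "stopgain"
    if ref_aa == "*":
        return "stoploss"
    return "nonsynonymous"
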