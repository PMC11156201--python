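"""Ancestral/derived state assignment from two outgroup alleles.

Rule order (outgroup parsimony over two single-genome outgroups):

1. both outgroups agree and the shared allele is one of the focal alleles ->
   it is ancestral; the other focal allele is derived (status ``resolved``);
2. both outgroups agree on a third allele -> both focal alleles are derived
   relative to it (status ``resolved-external``); such sites contribute to
   load-style derived counts but are excluded from the unfolded SFS, whose
   frequency axis needs a single derived allele;
3. outgroups disagree, or either is missing -> ``unresolved``; the site
   carries no derived-allele information downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from purgescan.variant_io import MISSING, GenotypeDataset

RESOLVED = "resolved"
RESOLVED_EXTERNAL = "resolved-external"
UNRESOLVED = "unresolved"

_NUCS = set("ACGT")


@dataclass
class PolarizedSite:
    chrom: str
    pos: int
    ancestral: str | None
    derived: str | None  # None for resolved-external (both alleles derived)
    status: str


def polarize_site(
    focal_alleles: tuple[str, str],
    og1: str | None,
    og2: str | None,
    chrom: str = ".",
    pos: int = 0,
) -> PolarizedSite:
    ref, alt = (a.upper() for a in focal_alleles)
    if ref == alt or ref not in _NUCS or alt not in _NUCS:
        raise ValueError(f"focal alleles must be distinct single bases, got {ref}/{alt}")
    for og in (og1, og2):
        if og is not None and og.upper() not in _NUCS:
            raise ValueError(f"non-nucleotide outgroup allele {og!r} at {chrom}:{pos}")
    if og1 is None or og2 is None or og1.upper() != og2.upper():
        return PolarizedSite(chrom, pos, None, None, UNRESOLVED)
    shared = og1.upper()
    if shared == ref:
        return PolarizedSite(chrom, pos, ref, alt, RESOLVED)
    if shared == alt:
        return PolarizedSite(chrom, pos, alt, ref, RESOLVED)
    return PolarizedSite(chrom, pos, shared, None, RESOLVED_EXTERNAL)


def polarize_dataset(
    ds: GenotypeDataset, outgroup_table: pd.DataFrame
) -> tuple[list[PolarizedSite], np.ndarray]:
    """Polarize every site of a dataset against a (chrom,pos,og1,og2) table.

    Returns per-site :class:`PolarizedSite` records plus a derived-dosage
    matrix (n_sites, n_samples): the alt dosage where alt is derived, the
    flipped dosage (2 - d) where ref is derived, 2 for every called genotype
    at resolved-external sites, and ``MISSING`` elsewhere (unresolved sites
    or missing calls).
    """
    if outgroup_table.duplicated(subset=["chrom", "pos"]).any():
        raise ValueError("duplicate outgroup rows")
    og = {
        (str(r.chrom), int(r.pos)): (r.og1, r.og2) for r in outgroup_table.itertuples()
    }
    sites: list[PolarizedSite] = []
    derived = np.full_like(ds.dosage, MISSING)
    for i in range(ds.n_sites):
        chrom, pos = str(ds.chrom[i]), int(ds.pos[i])
        pair = og.get((chrom, pos))
        if pair is None:
            sites.append(PolarizedSite(chrom, pos, None, None, UNRESOLVED))
            continue
        og1 = None if pd.isna(pair[0]) else str(pair[0])
        og2 = None if pd.isna(pair[1]) else str(pair[1])
        ps = polarize_site((str(ds.ref[i]), str(ds.alt[i])), og1, og2, chrom, pos)
        sites.append(ps)
        if ps.status == UNRESOLVED:
            continue
        called = ds.dosage[i] != MISSING
        if ps.status == RESOLVED_EXTERNAL:
            derived[i, called] = 2
        elif ps.derived == str(ds.alt[i]):
            derived[i, called] = ds.dosage[i, called]
        else:
            derived[i, called] = 2 - ds.dosage[i, called]
    return sites, derived


def polarization_table(sites: list[PolarizedSite]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos for s in sites],
            "ancestral": [s.ancestral or "." for s in sites],
            "derived": [s.derived or "." for s in sites],
            "status": [s.status for s in sites],
        }
    )
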