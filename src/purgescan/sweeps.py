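"""Outlier-window detection, two-track intersection, window-to-gene mapping
and per-clade focal-variant carrier frequencies."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from purgescan.tracks import WindowTrack
from purgescan.variant_io import MISSING, CladeMap, GenotypeDataset

log = logging.getLogger(__name__)

Window = tuple[str, int, int]


@dataclass
class CandidateSet:
    comparison: str
    outliers_a: set[Window]
    outliers_b: set[Window]
    intersected: set[Window]
    genes: set[str]
    quantile: float


def top_quantile_windows(track: WindowTrack, q: float = 0.05) -> set[Window]:
    """Windows whose value is >= the empirical (1-q) quantile of non-missing
    values; ties at the cutoff are all included."""
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    vals = track.values
    ok = ~np.isnan(vals)
    if not ok.any():
        raise ValueError("all window values missing")
    cutoff = np.quantile(vals[ok], 1 - q, method="higher")
    if np.nanmin(vals[ok]) == np.nanmax(vals[ok]):
        log.warning("constant track: every window ties at the cutoff")
    keep = ok & (vals >= cutoff)
    keys = track.keys()
    return {keys[i] for i in np.flatnonzero(keep)}


def _gene_spans(gff) -> list[tuple[str, int, int, str]]:
    """(gene_id, start0, end0) half-open gene spans from a GFF3."""
    import gffutils

    db = gffutils.create_db(
        str(gff), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    return [(g.id, g.start - 1, g.end, g.seqid) for g in db.features_of_type("gene")]


def intersect_and_map(
    outliers_a: set[Window],
    outliers_b: set[Window],
    gff,
    comparison: str = "",
    q: float = 0.05,
    gene_level: bool = False,
) -> CandidateSet:
    """Intersect two outlier-window sets and map to candidate genes.

    By default the intersection is at window level and candidates are genes
    overlapping (>= 1 bp, half-open) any intersected window. With
    ``gene_level=True`` genes are mapped to each track's outliers separately
    and the candidate set is the intersection of the two gene sets.
    """
    # grid consistency: two windows sharing a start must share an end
    # (sliding windows overlap legitimately and end-of-chromosome windows may
    # be truncated, so sizes alone cannot be compared)
    ends_a = {(c, s): e for c, s, e in outliers_a}
    for c, s, e in outliers_b:
        if (c, s) in ends_a and ends_a[(c, s)] != e:
            raise ValueError(f"window grids mismatch at {c}:{s} ({ends_a[(c, s)]} vs {e})")
    intersected = outliers_a & outliers_b
    spans = _gene_spans(gff)

    def genes_for(windows: set[Window]) -> set[str]:
        out = set()
        for gid, gstart, gend, gchrom in spans:
            for chrom, wstart, wend in windows:
                if chrom == gchrom and gstart < wend and wstart < gend:
                    out.add(gid)
                    break
        return out

    if gene_level:
        genes = genes_for(outliers_a) & genes_for(outliers_b)
    else:
        genes = genes_for(intersected)
    return CandidateSet(
        comparison=comparison,
        outliers_a=set(outliers_a),
        outliers_b=set(outliers_b),
        intersected=intersected,
        genes=genes,
        quantile=q,
    )


def parallel_candidates(set_p: CandidateSet, set_q: CandidateSet) -> set[str]:
    """Candidate genes shared between two comparisons (parallel selection)."""
    return set_p.genes & set_q.genes


def carrier_frequency(
    ds: GenotypeDataset,
    clade_map: CladeMap,
    chrom: str,
    pos: int,
    derived_allele: str,
) -> pd.DataFrame:
    """Per-clade carrier proportion and derived allele frequency at one site.

    Carrier proportion is the fraction of called individuals with derived
    dosage >= 1; DAF is derived dosage over called alleles.
    """
    i = ds.site_index(chrom, pos)  # raises KeyError when absent
    if derived_allele == str(ds.alt[i]):
        derived = ds.dosage[i].astype(float)
    elif derived_allele == str(ds.ref[i]):
        derived = np.where(ds.dosage[i] != MISSING, 2 - ds.dosage[i], MISSING).astype(float)
    else:
        raise ValueError(f"derived allele {derived_allele} not at {chrom}:{pos}")
    rows = []
    for clade in clade_map.clades():
        idx = [ds.samples.index(s) for s in clade_map.samples_of(clade) if s in ds.samples]
        vals = derived[idx]
        called = vals != MISSING
        n_called = int(called.sum())
        if n_called == 0:
            carrier = daf = float("nan")
        else:
            carrier = float((vals[called] >= 1).sum() / n_called)
            daf = float(vals[called].sum() / (2 * n_called))
        rows.append(
            {
                "clade": clade,
                "n_called": n_called,
                "carrier_proportion": carrier,
                "derived_allele_frequency": daf,
            }
        )
    return pd.DataFrame(rows)


def candidate_table(sets: list[CandidateSet]) -> pd.DataFrame:
    rows = []
    for cs in sets:
        for gene in sorted(cs.genes):
            rows.append(
                {
                    "comparison": cs.comparison,
                    "gene": gene,
                    "n_outliers_a": len(cs.outliers_a),
                    "n_outliers_b": len(cs.outliers_b),
                    "n_intersected": len(cs.intersected),
                    "quantile": cs.quantile,
                }
            )
    return pd.DataFrame(rows)
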