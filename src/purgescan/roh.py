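"""Scanning-window runs-of-homozygosity detection.

The algorithm follows the classic SNP-window heuristic used for autozygosity
scans of diploid resequencing panels:

1. slide a window of ``window_snp`` SNPs one SNP at a time (windows truncated
   at the chromosome end still count); a window is "homozygous" when it holds
   at most ``window_het`` heterozygous and at most ``window_missing`` missing
   calls;
2. each SNP's hit rate is the fraction of windows containing it that are
   homozygous; a SNP qualifies when its hit rate is at least
   ``window_threshold`` (the threshold is the minimum fraction);
3. candidate segments are maximal runs of consecutive qualifying SNPs, split
   wherever adjacent SNPs are more than ``gap_kb`` apart, then trimmed so
   both ends are homozygous non-missing calls;
4. a segment is reported when it has at least ``min_snps`` SNPs, spans at
   least ``min_kb`` kb, and averages at least one SNP per ``density_kb`` kb.

Genotypes are coded 0 hom-ref / 1 het / 2 hom-alt / -1 missing; positions
must be sorted. Exact behaviour (truncation, trimming, tie handling) is
frozen by a brute-force window-enumeration oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from purgescan.variant_io import MISSING, CladeMap, GenotypeDataset


@dataclass
class ROHParams:
    density_kb: float = 50.0
    gap_kb: float = 1000.0
    min_kb: float = 30.0
    min_snps: int = 40
    window_het: int = 2
    window_snp: int = 40
    window_missing: int = 10
    window_threshold: float = 0.05

    def __post_init__(self) -> None:
        for name in ("density_kb", "gap_kb", "min_kb", "min_snps", "window_snp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.window_het > self.window_snp:
            raise ValueError("window_het must be <= window_snp")
        if not 0 < self.window_threshold <= 1:
            raise ValueError("window_threshold must be in (0, 1]")


@dataclass
class ROHSegment:
    sample: str
    chrom: str
    start: int  # bp, 1-based inclusive
    end: int
    n_snps: int

    @property
    def length_kb(self) -> float:
        return (self.end - self.start + 1) / 1000.0


def detect_roh(
    genotypes: np.ndarray,
    positions: np.ndarray,
    params: ROHParams = ROHParams(),
    sample: str = ".",
    chrom: str = ".",
) -> list[ROHSegment]:
    """Call ROH segments for one sample on one chromosome."""
    positions = np.asarray(positions, dtype=np.int64)
    genotypes = np.asarray(genotypes)
    if len(positions) != len(genotypes):
        raise ValueError("genotypes and positions differ in length")
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted")
    m = len(positions)
    if m == 0:
        return []

    het = (genotypes == 1).astype(np.int64)
    miss = (genotypes == MISSING).astype(np.int64)
    het_c = np.concatenate([[0], np.cumsum(het)])
    miss_c = np.concatenate([[0], np.cumsum(miss)])
    W = params.window_snp

    # window starting at i covers [i, min(i+W, m))
    starts = np.arange(m)
    ends = np.minimum(starts + W, m)
    hom_window = (het_c[ends] - het_c[starts] <= params.window_het) & (
        miss_c[ends] - miss_c[starts] <= params.window_missing
    )
    homint = hom_window.astype(np.int64)
    hom_c = np.concatenate([[0], np.cumsum(homint)])

    # SNP j is covered by windows starting in [max(0, j-W+1), j]
    lo = np.maximum(0, starts - W + 1)
    n_windows = starts - lo + 1
    n_hom = hom_c[starts + 1] - hom_c[lo]
    qualifies = n_hom / n_windows >= params.window_threshold

    segments: list[ROHSegment] = []
    gap_bp = params.gap_kb * 1000.0
    i = 0
    while i < m:
        if not qualifies[i]:
            i += 1
            continue
        j = i
        while j + 1 < m and qualifies[j + 1] and positions[j + 1] - positions[j] <= gap_bp:
            j += 1
        seg = _finalize_run(genotypes, positions, i, j, params, sample, chrom)
        if seg is not None:
            segments.append(seg)
        i = j + 1
    return segments


def _finalize_run(
    genotypes, positions, i, j, params: ROHParams, sample, chrom
) -> ROHSegment | None:
    # trim ends to homozygous non-missing calls
    while i <= j and (genotypes[i] == 1 or genotypes[i] == MISSING):
        i += 1
    while j >= i and (genotypes[j] == 1 or genotypes[j] == MISSING):
        j -= 1
    if j < i:
        return None
    n_snps = j - i + 1
    length_bp = int(positions[j] - positions[i] + 1)
    if n_snps < params.min_snps:
        return None
    if length_bp < params.min_kb * 1000.0:
        return None
    if length_bp / n_snps > params.density_kb * 1000.0:
        return None
    return ROHSegment(
        sample=sample,
        chrom=chrom,
        start=int(positions[i]),
        end=int(positions[j]),
        n_snps=n_snps,
    )


def detect_roh_dataset(
    ds: GenotypeDataset, params: ROHParams = ROHParams()
) -> list[ROHSegment]:
    """Run the caller for every sample and chromosome of a dataset."""
    segments: list[ROHSegment] = []
    for chrom in pd.unique(pd.Series(ds.chrom).astype(str)):
        mask = ds.chrom == chrom
        pos = ds.pos[mask]
        dos = ds.dosage[mask]
        for si, sample in enumerate(ds.samples):
            segments.extend(
                detect_roh(dos[:, si], pos, params, sample=sample, chrom=chrom)
            )
    return segments


def roh_table(segments: list[ROHSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [s.sample for s in segments],
            "chrom": [s.chrom for s in segments],
            "start": [s.start for s in segments],
            "end": [s.end for s in segments],
            "n_snps": [s.n_snps for s in segments],
            "length_kb": [s.length_kb for s in segments],
        }
    )


def roh_summary(
    segments: list[ROHSegment],
    clade_map: CladeMap,
    genome_length_bp: int,
) -> pd.DataFrame:
    """Per-clade ROH totals plus per-sample F_ROH averaged within clades.

    F_ROH is total ROH length over assayed genome length. Samples without
    segments count as zero; clades with no samples are skipped with a warning.
    """
    import logging

    log = logging.getLogger(__name__)
    per_sample: dict[str, float] = {}
    per_sample_n: dict[str, int] = {}
    for s in segments:
        per_sample[s.sample] = per_sample.get(s.sample, 0.0) + s.length_kb
        per_sample_n[s.sample] = per_sample_n.get(s.sample, 0) + 1
    rows = []
    for clade in clade_map.clades():
        samples = clade_map.samples_of(clade)
        if not samples:
            log.warning("clade %s has no samples; skipped", clade)
            continue
        totals = np.array([per_sample.get(s, 0.0) for s in samples])
        counts = np.array([per_sample_n.get(s, 0) for s in samples])
        froh = totals * 1000.0 / genome_length_bp
        mean_len = totals.sum() / counts.sum() if counts.sum() else 0.0
        rows.append(
            {
                "clade": clade,
                "n_samples": len(samples),
                "total_length_kb": float(totals.sum()),
                "count": int(counts.sum()),
                "mean_length_kb": float(mean_len),
                "mean_froh": float(froh.mean()),
            }
        )
    return pd.DataFrame(rows)
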