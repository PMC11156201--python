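"""Readers, writers and basic filters for the formats the pipeline touches.

Coordinate conventions: genotype datasets store 1-based positions (the VCF
convention); window tracks use half-open 0-based [start, end) intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from purgescan.tracks import WindowTrack

log = logging.getLogger(__name__)

MISSING = -1  # dosage code for a missing call


class VcfParseError(ValueError):
    pass


@dataclass
class GenotypeDataset:
    """Samples x biallelic sites with alt-allele dosages.

    ``dosage`` has shape (n_sites, n_samples) with entries in {0, 1, 2} or
    ``MISSING`` (-1). ``depth`` is optional with the same shape.
    """

    samples: list[str]
    chrom: np.ndarray  # str per site
    pos: np.ndarray  # 1-based int per site
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.pos), len(self.samples)):
            raise ValueError("dosage shape does not match sites x samples")
        order = np.lexsort((self.pos, self.chrom.astype(str)))
        if not np.array_equal(order, np.arange(len(order))):
            self._reorder(order)
        key = list(zip(self.chrom, self.pos))
        if len(set(key)) != len(key):
            raise ValueError("duplicate (chrom, pos) in dataset")

    def _reorder(self, order: np.ndarray) -> None:
        self.chrom = self.chrom[order]
        self.pos = self.pos[order]
        self.ref = np.asarray(self.ref)[order]
        self.alt = np.asarray(self.alt)[order]
        self.dosage = self.dosage[order]
        if self.depth is not None:
            self.depth = self.depth[order]

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def called(self) -> np.ndarray:
        """Boolean mask of non-missing calls, shape (n_sites, n_samples)."""
        return self.dosage != MISSING

    def subset_sites(self, mask: np.ndarray) -> "GenotypeDataset":
        mask = np.asarray(mask)
        return GenotypeDataset(
            samples=list(self.samples),
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            ref=np.asarray(self.ref)[mask],
            alt=np.asarray(self.alt)[mask],
            dosage=self.dosage[mask],
            depth=None if self.depth is None else self.depth[mask],
        )

    def subset_samples(self, names: list[str]) -> "GenotypeDataset":
        idx = [self.samples.index(s) for s in names]
        return GenotypeDataset(
            samples=list(names),
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            dosage=self.dosage[:, idx],
            depth=None if self.depth is None else self.depth[:, idx],
        )

    def site_index(self, chrom: str, pos: int) -> int:
        hits = np.flatnonzero((self.chrom == chrom) & (self.pos == pos))
        if len(hits) != 1:
            raise KeyError(f"site {chrom}:{pos} not present")
        return int(hits[0])


@dataclass
class CladeMap:
    """Sample -> clade labels plus clade -> altitude class (high/low)."""

    sample_to_clade: dict[str, str]
    clade_to_altitude: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sample_to_clade:
            raise ValueError("empty clade map")
        for clade, alt in self.clade_to_altitude.items():
            if alt not in ("high", "low"):
                raise ValueError(f"altitude class for {clade} must be high/low")

    def clades(self) -> list[str]:
        return sorted(set(self.sample_to_clade.values()))

    def samples_of(self, clade: str) -> list[str]:
        return [s for s, c in self.sample_to_clade.items() if c == clade]

    def altitude_of(self, clade: str) -> str | None:
        return self.clade_to_altitude.get(clade)


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path) -> GenotypeDataset:
    """Read biallelic SNPs from a VCF with GT calls.

    Multi-allelic and non-SNP records are dropped (counts logged). Positions
    are 1-based. Missing genotypes get dosage -1. Per-call DP is kept when
    the FORMAT declares it.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    chroms, poss, refs, alts, rows, depths = [], [], [], [], [], []
    n_multi = n_nonsnp = 0
    header_has_dp = "DP" in vcf.raw_header and '##FORMAT=<ID=DP' in vcf.raw_header
    has_depth = False
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_nonsnp += 1
            continue
        gt = rec.gt_types.astype(np.int8)  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        gt[gt == 3] = MISSING
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        rows.append(gt)
        dp = rec.format("DP") if header_has_dp else None
        if dp is not None:
            has_depth = True
            depths.append(dp[:, 0].astype(np.int32))
        else:
            depths.append(np.full(len(samples), -1, dtype=np.int32))
    if n_multi or n_nonsnp:
        log.info("read_vcf: dropped %d multi-allelic, %d non-SNP records", n_multi, n_nonsnp)
    n = len(poss)
    ds = GenotypeDataset(
        samples=samples,
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(poss, dtype=np.int64),
        ref=np.asarray(refs, dtype="U1"),
        alt=np.asarray(alts, dtype="U1"),
        dosage=np.vstack(rows) if n else np.zeros((0, len(samples)), dtype=np.int8),
        depth=np.vstack(depths) if (n and has_depth) else None,
    )
    ds.excluded_multiallelic = n_multi  # type: ignore[attr-defined]
    ds.excluded_nonsnp = n_nonsnp  # type: ignore[attr-defined]
    return ds


def write_vcf(ds: GenotypeDataset, path, contig_lengths: dict[str, int] | None = None) -> None:
    """Write a minimal VCF 4.2 with GT-only genotypes."""
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=purgescan\n")
        if contig_lengths:
            for name, length in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(ds.samples)
            + "\n"
        )
        for i in range(ds.n_sites):
            calls = "\t".join(gt_strings[int(d)] for d in ds.dosage[i])
            fh.write(
                f"{ds.chrom[i]}\t{ds.pos[i]}\t.\t{ds.ref[i]}\t{ds.alt[i]}\t.\tPASS\t.\tGT\t{calls}\n"
            )


# ---------------------------------------------------------------------------
# Filtering


def filter_variants(
    ds: GenotypeDataset,
    max_missing_frac: float = 0.8,
    min_maf: float = 0.05,
    min_depth: int = 3,
) -> tuple[GenotypeDataset, dict[str, int]]:
    """Site/call filter with the common resequencing-pipeline semantics.

    ``max_missing_frac`` is the minimum fraction of samples that must be
    called at a site (0.8 means >= 80% called). Calls with depth below
    ``min_depth`` are set to missing first (skipped with a warning when the
    dataset carries no depth); MAF is computed over called alleles only.
    """
    if not 0 <= max_missing_frac <= 1:
        raise ValueError("max_missing_frac must be in [0, 1]")
    if not 0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    dosage = ds.dosage.copy()
    n_depth_masked = 0
    if min_depth > 0:
        if ds.depth is None:
            log.warning("filter_variants: no depth data; depth filter skipped")
        else:
            low = (ds.depth < min_depth) & (dosage != MISSING)
            n_depth_masked = int(low.sum())
            dosage[low] = MISSING

    called = dosage != MISSING
    n_called = called.sum(axis=1)
    called_frac = n_called / ds.n_samples
    alt_count = np.where(called, dosage, 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = alt_count / (2 * n_called)
    maf = np.minimum(p, 1 - p)
    maf = np.where(n_called > 0, maf, 0.0)

    fail_missing = called_frac < max_missing_frac
    fail_maf = (~fail_missing) & (maf < min_maf)
    keep = ~(fail_missing | fail_maf)

    out = GenotypeDataset(
        samples=list(ds.samples),
        chrom=ds.chrom[keep],
        pos=ds.pos[keep],
        ref=np.asarray(ds.ref)[keep],
        alt=np.asarray(ds.alt)[keep],
        dosage=dosage[keep],
        depth=None if ds.depth is None else ds.depth[keep],
    )
    report = {
        "calls_masked_low_depth": n_depth_masked,
        "sites_removed_missing": int(fail_missing.sum()),
        "sites_removed_maf": int(fail_maf.sum()),
        "sites_kept": int(keep.sum()),
    }
    return out, report


# ---------------------------------------------------------------------------
# Tables


def read_window_scores(path, statistic: str = "external", label: str = "") -> WindowTrack:
    """Read a (chrom, start, end, score) TSV into a sorted WindowTrack.

    Non-numeric scores become missing values. Duplicate windows are an error.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "score"}
    if not required.issubset(df.columns):
        raise ValueError(f"window score TSV needs columns {sorted(required)}")
    value = pd.to_numeric(df["score"], errors="coerce")
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].astype(str),
            "start": df["start"].astype(int),
            "end": df["end"].astype(int),
            "n_snps": df["n_snps"].astype(int) if "n_snps" in df else -1,
            "value": value,
        }
    )
    dup = out.duplicated(subset=["chrom", "start", "end"], keep=False)
    if dup.any():
        offenders = out.loc[dup, ["chrom", "start", "end"]].drop_duplicates()
        raise ValueError(
            "duplicate/overlapping windows: "
            + "; ".join(f"{r.chrom}:{r.start}-{r.end}" for r in offenders.itertuples())
        )
    return WindowTrack.from_frame(out, statistic=statistic, label=label)


def read_clade_map(path) -> CladeMap:
    """Read a sample->clade TSV with columns sample, clade[, altitude]."""
    df = pd.read_csv(path, sep="\t")
    if not {"sample", "clade"}.issubset(df.columns):
        raise ValueError("clade map TSV needs columns sample, clade")
    s2c = dict(zip(df["sample"].astype(str), df["clade"].astype(str)))
    if len(s2c) != len(df):
        raise ValueError("duplicate sample in clade map")
    c2a: dict[str, str] = {}
    if "altitude" in df.columns:
        for clade, alt in zip(df["clade"], df["altitude"]):
            c2a[str(clade)] = str(alt)
    return CladeMap(sample_to_clade=s2c, clade_to_altitude=c2a)


def write_clade_map(cm: CladeMap, path) -> None:
    rows = [
        {"sample": s, "clade": c, "altitude": cm.altitude_of(c) or "low"}
        for s, c in cm.sample_to_clade.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_outgroup_table(path) -> pd.DataFrame:
    """Read per-site outgroup alleles: chrom, pos (1-based), og1, og2."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if not {"chrom", "pos", "og1", "og2"}.issubset(df.columns):
        raise ValueError("outgroup TSV needs columns chrom, pos, og1, og2")
    if df.duplicated(subset=["chrom", "pos"]).any():
        raise ValueError("duplicate (chrom, pos) rows in outgroup table")
    return df
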