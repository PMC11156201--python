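"""Per-site and windowed nucleotide diversity, Weir-Cockerham FST and
class-stratified unfolded site frequency spectra.

Windows are half-open [start, end) in bp. Window pi divides the summed
per-site heterozygosity by the window length in bp (monomorphic positions
contribute zero), so magnitudes are per-bp diversities comparable across
datasets. Windowed FST is the ratio-of-sums ("weighted") Weir-Cockerham
estimator; negative values are retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from purgescan.tracks import WindowTrack
from purgescan.variant_io import MISSING, CladeMap, GenotypeDataset


# ---------------------------------------------------------------------------
# nucleotide diversity


def site_pi(alt_count: int, called_alleles: int) -> float:
    """Mean pairwise difference at one site: 2c(n-c) / (n(n-1)).

    Returns NaN when fewer than two called alleles.
    """
    c, n = alt_count, called_alleles
    if n < 2:
        return float("nan")
    if not 0 <= c <= n:
        raise ValueError(f"alt count {c} outside [0, {n}]")
    return 2.0 * c * (n - c) / (n * (n - 1))


def _site_pi_vector(ds: GenotypeDataset, sample_idx: np.ndarray) -> np.ndarray:
    dosage = ds.dosage[:, sample_idx]
    called = dosage != MISSING
    n = 2 * called.sum(axis=1)
    c = np.where(called, dosage, 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = 2.0 * c * (n - c) / (n * (n - 1.0))
    return np.where(n >= 2, pi, np.nan)


def _windows(chrom_length: int, window_bp: int, step_bp: int) -> list[tuple[int, int]]:
    if window_bp >= chrom_length:
        return [(0, chrom_length)]  # single truncated window
    out = []
    start = 0
    while start < chrom_length:
        out.append((start, min(start + window_bp, chrom_length)))
        start += step_bp
    return out


def windowed_pi(
    ds: GenotypeDataset,
    chrom_lengths: dict[str, int],
    window_bp: int = 50_000,
    step_bp: int = 10_000,
    mode: str = "sliding",
    samples: list[str] | None = None,
    site_list: set[tuple[str, int]] | None = None,
    label: str = "",
) -> WindowTrack:
    """Windowed nucleotide diversity per bp.

    ``mode='sliding'`` uses window_bp/step_bp windows; ``mode='nonoverlapping_10kb'``
    uses non-overlapping 10 kb windows (the fourfold-diversity convention) and,
    with ``site_list`` supplied, restricts to those (chrom, pos) sites while
    dividing by the number of listed positions per window rather than bp.
    """
    if mode == "nonoverlapping_10kb":
        window_bp = step_bp = 10_000
    elif mode != "sliding":
        raise ValueError("mode must be 'sliding' or 'nonoverlapping_10kb'")
    idx = np.arange(ds.n_samples) if samples is None else np.asarray(
        [ds.samples.index(s) for s in samples]
    )
    pivec = _site_pi_vector(ds, idx)
    keep = ~np.isnan(pivec)
    listed_by_chrom: dict[str, np.ndarray] = {}
    if site_list is not None:
        in_list = np.asarray(
            [(str(c), int(p)) in site_list for c, p in zip(ds.chrom, ds.pos)]
        )
        keep &= in_list
        tmp: dict[str, list[int]] = {}
        for c, p in site_list:
            tmp.setdefault(str(c), []).append(int(p))
        listed_by_chrom = {c: np.sort(np.asarray(v)) for c, v in tmp.items()}

    rows = []
    for chrom, length in chrom_lengths.items():
        m = keep & (ds.chrom == chrom)
        pos = ds.pos[m]
        vals = pivec[m]
        order = np.argsort(pos)
        pos, vals = pos[order], vals[order]
        cum = np.concatenate([[0.0], np.cumsum(vals)])
        for start, end in _windows(length, window_bp, step_bp):
            lo = np.searchsorted(pos, start + 1, side="left")
            hi = np.searchsorted(pos, end, side="right")
            total = cum[hi] - cum[lo]
            if site_list is not None:
                lp = listed_by_chrom.get(chrom, np.empty(0, dtype=int))
                denom = int(
                    np.searchsorted(lp, end, side="right")
                    - np.searchsorted(lp, start + 1, side="left")
                )
            else:
                denom = end - start
            value = total / denom if denom > 0 else np.nan
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "n_snps": int(hi - lo),
                    "value": value,
                }
            )
    return WindowTrack.from_frame(pd.DataFrame(rows), statistic="pi", label=label)


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) FST, two populations, random-mating diploids


def wc_fst_site(pop_allele_counts) -> tuple[float, float, float]:
    """Variance components (a, b, c) for one biallelic site.

    ``pop_allele_counts`` is a pair of (alt_count, called_alleles) tuples.
    Heterozygote frequencies use their Hardy-Weinberg expectation 2p(1-p)
    (random-mating estimator, no inbreeding correction). Returns (a, b, c);
    the per-site estimate is a / (a + b + c).
    """
    (c1, m1), (c2, m2) = pop_allele_counts
    if m1 < 2 or m2 < 2:
        raise ValueError("each population needs >= 2 called alleles")
    r = 2.0
    n1, n2 = m1 / 2.0, m2 / 2.0  # diploid sample sizes
    p1, p2 = c1 / m1, c2 / m2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    h1, h2 = 2 * p1 * (1 - p1), 2 * p2 * (1 - p2)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar)
        - ((r - 1.0) / r) * s2
        - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
    )
    c_comp = hbar / 2.0
    return a, b, c_comp


def _wc_components_vector(
    ds: GenotypeDataset, idx1: np.ndarray, idx2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (a, a+b+c) arrays; NaN where a population has < 2 alleles."""
    a_arr = np.full(ds.n_sites, np.nan)
    denom_arr = np.full(ds.n_sites, np.nan)
    d1, d2 = ds.dosage[:, idx1], ds.dosage[:, idx2]
    m1 = 2 * (d1 != MISSING).sum(axis=1)
    m2 = 2 * (d2 != MISSING).sum(axis=1)
    c1 = np.where(d1 != MISSING, d1, 0).sum(axis=1)
    c2 = np.where(d2 != MISSING, d2, 0).sum(axis=1)
    ok = (m1 >= 2) & (m2 >= 2)
    for i in np.flatnonzero(ok):
        a, b, c = wc_fst_site([(c1[i], m1[i]), (c2[i], m2[i])])
        a_arr[i] = a
        denom_arr[i] = a + b + c
    return a_arr, denom_arr


def windowed_fst(
    ds: GenotypeDataset,
    clade_map: CladeMap,
    pair: tuple,
    chrom_lengths: dict[str, int],
    window_bp: int = 50_000,
    step_bp: int = 10_000,
    min_snps: int = 10,
) -> WindowTrack:
    """Ratio-of-sums Weir-Cockerham FST in sliding windows.

    ``pair`` is two clade labels or two explicit sample lists. Windows with
    fewer than ``min_snps`` usable SNPs, or a zero denominator, are missing.
    """
    groups = []
    for g in pair:
        names = clade_map.samples_of(g) if isinstance(g, str) else list(g)
        if len(names) < 2:
            raise ValueError(f"group {g} needs >= 2 samples")
        groups.append(np.asarray([ds.samples.index(s) for s in names]))
    a_arr, d_arr = _wc_components_vector(ds, groups[0], groups[1])
    usable = ~np.isnan(a_arr)

    rows = []
    for chrom, length in chrom_lengths.items():
        m = usable & (ds.chrom == chrom)
        pos = ds.pos[m]
        order = np.argsort(pos)
        pos = pos[order]
        a_c = np.concatenate([[0.0], np.cumsum(a_arr[m][order])])
        d_c = np.concatenate([[0.0], np.cumsum(d_arr[m][order])])
        for start, end in _windows(length, window_bp, step_bp):
            lo = np.searchsorted(pos, start + 1, side="left")
            hi = np.searchsorted(pos, end, side="right")
            n_snps = int(hi - lo)
            num = a_c[hi] - a_c[lo]
            den = d_c[hi] - d_c[lo]
            value = num / den if (n_snps >= min_snps and den != 0) else np.nan
            rows.append(
                {"chrom": chrom, "start": start, "end": end, "n_snps": n_snps, "value": value}
            )
    label = "_vs_".join(str(g) for g in pair)
    return WindowTrack.from_frame(pd.DataFrame(rows), statistic="fst", label=label)


# ---------------------------------------------------------------------------
# unfolded SFS with hypergeometric projection


@dataclass
class SFS:
    n: int  # haplotypes after projection
    counts: np.ndarray  # xi_1 .. xi_{n-1} (expected counts; floats)
    site_class: str = ""
    group: str = ""
    n_sites_used: int = 0
    n_sites_skipped: int = 0

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def compute_sfs(
    derived_dosage: np.ndarray,
    sample_idx: np.ndarray,
    projection_n: int,
    site_mask: np.ndarray | None = None,
    site_class: str = "",
    group: str = "",
) -> SFS:
    """Unfolded SFS on ``projection_n`` haplotypes via hypergeometric projection.

    ``derived_dosage`` is the polarized matrix (MISSING where unresolved or
    uncalled); resolved-external sites must be excluded upstream. Each site's
    (derived, called) haplotype counts are projected down to ``projection_n``;
    the monomorphic classes (0 and n) are dropped. Fails when more than half
    of the candidate sites have fewer called haplotypes than ``projection_n``.
    """
    d = derived_dosage[:, sample_idx]
    if site_mask is not None:
        d = d[site_mask]
    called = d != MISSING
    m = 2 * called.sum(axis=1)  # called haplotypes per site
    k = np.where(called, d, 0).sum(axis=1)  # derived haplotypes per site

    informative = m > 0
    projectable = informative & (m >= projection_n)
    n_info = int(informative.sum())
    n_proj = int(projectable.sum())
    if n_info > 0 and n_proj < 0.5 * n_info:
        raise ValueError(
            f"projection_n={projection_n} exceeds called haplotypes at "
            f"{n_info - n_proj}/{n_info} sites; use a smaller projection"
        )
    counts = np.zeros(projection_n + 1)
    j = np.arange(projection_n + 1)
    for mi, ki in zip(m[projectable], k[projectable]):
        counts += hypergeom.pmf(j, mi, ki, projection_n)
    return SFS(
        n=projection_n,
        counts=counts[1:projection_n],
        site_class=site_class,
        group=group,
        n_sites_used=n_proj,
        n_sites_skipped=n_info - n_proj,
    )


def sfs_table(spectra: list[SFS]) -> pd.DataFrame:
    rows = []
    for s in spectra:
        for i, xi in enumerate(s.counts, start=1):
            rows.append(
                {
                    "group": s.group,
                    "site_class": s.site_class,
                    "n": s.n,
                    "derived_count": i,
                    "xi": xi,
                }
            )
    return pd.DataFrame(rows)
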