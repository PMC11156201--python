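"""Per-sample genetic-load proxy and clade-level comparisons.

The load proxy for a sample is the ratio of its derived deleterious-missense
(dnSNP) allele dosage to its derived fourfold-degenerate allele dosage — a
count of deleterious burden normalised by a neutral mutation-rate proxy, so
it is insensitive to callable-genome size and coverage. "Derived allele
counts" are diploid dosages (a heterozygote contributes 1, a homozygote 2);
a carrier-based variant (any-dose carriers counted once) is available via
``counting='carrier'``.

Sites polarized as resolved-external (both focal alleles derived) add a
constant dosage of 2 for every called genotype; they are excluded by default
since the offset carries no between-sample information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, ranksums, spearmanr
from statsmodels.stats.multitest import multipletests

from purgescan.variant_io import MISSING, CladeMap


@dataclass
class LoadReport:
    sample: str
    derived_dnsnp_alleles: float
    derived_fourfold_alleles: float
    n_called_dnsnp_sites: int
    n_called_fourfold_sites: int
    clade: str | None = None

    @property
    def load_proxy(self) -> float:
        if self.derived_fourfold_alleles == 0:
            return float("nan")
        return self.derived_dnsnp_alleles / self.derived_fourfold_alleles

    @property
    def defined(self) -> bool:
        return self.derived_fourfold_alleles > 0


def _dosage_sum(derived: np.ndarray, rows: np.ndarray, col: int, counting: str) -> tuple[float, int]:
    vals = derived[rows, col]
    called = vals != MISSING
    if counting == "carrier":
        total = float((vals[called] >= 1).sum())
    else:
        total = float(vals[called].sum())
    return total, int(called.sum())


def sample_load(
    derived_dosage: np.ndarray,
    dnsnp_rows: np.ndarray,
    fourfold_rows: np.ndarray,
    sample_index: int,
    sample_name: str,
    counting: str = "dosage",
) -> LoadReport:
    """Load proxy for one sample from a polarized derived-dosage matrix.

    ``dnsnp_rows`` and ``fourfold_rows`` index disjoint site sets; missing
    calls are excluded from both numerator and denominator for this sample.
    """
    if counting not in ("dosage", "carrier"):
        raise ValueError("counting must be 'dosage' or 'carrier'")
    if np.intersect1d(dnsnp_rows, fourfold_rows).size:
        raise ValueError("dnSNP and fourfold site sets must be disjoint")
    num, n_num = _dosage_sum(derived_dosage, dnsnp_rows, sample_index, counting)
    den, n_den = _dosage_sum(derived_dosage, fourfold_rows, sample_index, counting)
    return LoadReport(
        sample=sample_name,
        derived_dnsnp_alleles=num,
        derived_fourfold_alleles=den,
        n_called_dnsnp_sites=n_num,
        n_called_fourfold_sites=n_den,
    )


def load_reports(
    derived_dosage: np.ndarray,
    dnsnp_rows: np.ndarray,
    fourfold_rows: np.ndarray,
    samples: list[str],
    clade_map: CladeMap | None = None,
    counting: str = "dosage",
) -> list[LoadReport]:
    out = []
    for i, name in enumerate(samples):
        rep = sample_load(derived_dosage, dnsnp_rows, fourfold_rows, i, name, counting)
        if clade_map is not None:
            rep.clade = clade_map.sample_to_clade.get(name)
        out.append(rep)
    return out


def load_table(reports: list[LoadReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [r.sample for r in reports],
            "clade": [r.clade for r in reports],
            "derived_dnsnp_alleles": [r.derived_dnsnp_alleles for r in reports],
            "derived_fourfold_alleles": [r.derived_fourfold_alleles for r in reports],
            "load_proxy": [r.load_proxy for r in reports],
            "defined": [r.defined for r in reports],
        }
    )


def clade_load_table(
    reports: list[LoadReport], clade_map: CladeMap
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-clade median/IQR of the load proxy plus pairwise rank-sum tests.

    Undefined loads are dropped; clades of size 1 keep their median but are
    excluded from tests. Pairwise Wilcoxon rank-sum p-values are adjusted
    with Benjamini-Hochberg across pairs.
    """
    by_clade: dict[str, list[float]] = {}
    for r in reports:
        clade = r.clade or clade_map.sample_to_clade.get(r.sample)
        if clade is None or not r.defined:
            continue
        by_clade.setdefault(clade, []).append(r.load_proxy)
    if len(by_clade) < 2:
        raise ValueError("need >= 2 clades with defined loads")

    summary_rows = []
    for clade in sorted(by_clade):
        vals = np.asarray(by_clade[clade])
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        summary_rows.append(
            {
                "clade": clade,
                "n": len(vals),
                "median_load": med,
                "iqr_low": q1,
                "iqr_high": q3,
            }
        )
    summary = pd.DataFrame(summary_rows)

    testable = [c for c in sorted(by_clade) if len(by_clade[c]) > 1]
    pair_rows = []
    for i, a in enumerate(testable):
        for b in testable[i + 1 :]:
            stat, p = ranksums(by_clade[a], by_clade[b])
            pair_rows.append(
                {
                    "clade_a": a,
                    "clade_b": b,
                    "median_a": float(np.median(by_clade[a])),
                    "median_b": float(np.median(by_clade[b])),
                    "statistic": stat,
                    "p_value": p,
                }
            )
    pairs = pd.DataFrame(pair_rows)
    if len(pairs):
        pairs["p_adj_bh"] = multipletests(pairs["p_value"], method="fdr_bh")[1]
    return summary, pairs


def pis_load_relation(
    clade_pis: dict[str, float], clade_loads: dict[str, float]
) -> dict[str, float]:
    """Pearson and Spearman association between clade-level pi_s and load.

    Descriptive only; no causal claim. Returns NaN coefficients (flagged)
    for constant input.
    """
    clades = sorted(set(clade_pis) & set(clade_loads))
    if len(clades) < 3:
        raise ValueError("need >= 3 clades")
    x = np.asarray([clade_pis[c] for c in clades], dtype=float)
    y = np.asarray([clade_loads[c] for c in clades], dtype=float)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return {"pearson_r": float("nan"), "spearman_rho": float("nan"), "n_clades": len(clades)}
    pr = pearsonr(x, y)
    sr = spearmanr(x, y)
    return {
        "pearson_r": float(pr.statistic),
        "pearson_p": float(pr.pvalue),
        "spearman_rho": float(sr.statistic),
        "spearman_p": float(sr.pvalue),
        "n_clades": len(clades),
    }


def rare_fraction(sfs, daf_threshold: float = 0.1) -> float:
    """Proportion of segregating sites with derived allele frequency below
    the threshold: sum over i/n < t of xi_i, over the SFS total."""
    total = sfs.total
    if total == 0:
        return float("nan")
    i = np.arange(1, sfs.n)
    rare = sfs.counts[(i / sfs.n) < daf_threshold].sum()
    return float(rare / total)
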