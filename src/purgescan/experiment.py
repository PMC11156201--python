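"""Purging experiment: does the recessive-deleterious scenario reproduce the
highland/lowland contrasts (lower load, lower pi_s, more ROH, rarer dnSNPs in
the bottlenecked selfing isolates), and does the signal vanish with additive
(h=0.5) deleterious variants?

Each replicate simulates the highland/lowland scenario twice — once with
fully recessive deleterious mutations (h=0) and once additive (h=0.5) — runs
the full analysis pipeline on the emitted bundle, and tabulates per-clade
median load, median pi_s, per-sample ROH totals and rare-dnSNP fractions,
plus directional indicators comparing the pooled highland samples with the
lowland clade.
"""

from __future__ import annotations

import dataclasses
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from purgescan.pipeline import PipelineConfig, run_pipeline
from purgescan.simdata import make_highland_lowland_scenario, simulate, write_bundle


def plant_differentiated_gene(ds, truth, gene_index: int, group_a: list, seed: int, n_snps: int = 8):
    """Plant a strongly selected locus: add near-fixed-difference SNPs inside
    one gene (high derived frequency in ``group_a`` samples, absent
    elsewhere), emulating a recent hard sweep restricted to one population.

    Returns (new dataset, outgroup table rows for the planted sites, gene id).
    """
    import numpy as np
    import pandas as pd

    from purgescan.variant_io import GenotypeDataset

    rng = np.random.default_rng(seed)
    gene = truth.genome.genes[gene_index]
    span = gene.end - gene.start
    positions = np.sort(
        rng.choice(np.arange(gene.start + 1, gene.end + 1), size=min(n_snps, span), replace=False)
    )
    positions = np.asarray([p for p in positions if p not in set(ds.pos)], dtype=np.int64)
    a_idx = np.asarray([ds.samples.index(s) for s in group_a])
    dosage = np.zeros((len(positions), ds.n_samples), dtype=np.int8)
    for r in range(len(positions)):
        dosage[r, a_idx] = rng.choice([2, 2, 2, 1], size=len(a_idx))
    ref = np.asarray([truth.genome.seq[p - 1] for p in positions], dtype="U1")
    alt = np.asarray([("A" if r != "A" else "G") for r in ref], dtype="U1")
    new = GenotypeDataset(
        samples=list(ds.samples),
        chrom=np.concatenate([ds.chrom, [truth.genome.chrom] * len(positions)]),
        pos=np.concatenate([ds.pos, positions]),
        ref=np.concatenate([np.asarray(ds.ref), ref]),
        alt=np.concatenate([np.asarray(ds.alt), alt]),
        dosage=np.vstack([ds.dosage, dosage]),
    )
    og_rows = pd.DataFrame({"chrom": truth.genome.chrom, "pos": positions, "og1": ref, "og2": ref})
    return new, og_rows, gene.gene_id


def freq_diff_track(ds, group_a: list, group_b: list, chrom_lengths, window_bp=50_000, step_bp=10_000):
    """Windowed mean absolute allele-frequency difference between two groups —
    a simple internally computed differentiation track usable as the second
    sweep evidence line alongside FST."""
    import numpy as np
    import pandas as pd

    from purgescan.tracks import WindowTrack
    from purgescan.variant_io import MISSING

    ia = np.asarray([ds.samples.index(s) for s in group_a])
    ib = np.asarray([ds.samples.index(s) for s in group_b])

    def freqs(idx):
        d = ds.dosage[:, idx]
        called = d != MISSING
        n = 2 * called.sum(axis=1)
        c = np.where(called, d, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, c / n, np.nan)

    diff = np.abs(freqs(ia) - freqs(ib))
    rows = []
    for chrom, length in chrom_lengths.items():
        m = (ds.chrom == chrom) & ~np.isnan(diff)
        pos, vals = ds.pos[m], diff[m]
        start = 0
        while start < length:
            end = min(start + window_bp, length)
            sel = (pos > start) & (pos <= end)
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "n_snps": int(sel.sum()),
                    "value": float(vals[sel].mean()) if sel.any() else np.nan,
                }
            )
            start += step_bp
    return WindowTrack.from_frame(pd.DataFrame(rows), statistic="freq_diff")


def _clade_groups(result):
    cm = result.clade_map
    high = [c for c in cm.clades() if cm.altitude_of(c) == "high"]
    low = [c for c in cm.clades() if cm.altitude_of(c) == "low"]
    return high, low


def _replicate_metrics(result) -> dict:
    """Directional summaries from one pipeline run."""
    high_clades, low_clades = _clade_groups(result)
    ldf = result.load_table[result.load_table["defined"]]
    high_samples = ldf["clade"].isin(high_clades)
    low_samples = ldf["clade"].isin(low_clades)
    load_high = float(ldf.loc[high_samples, "load_proxy"].median())
    load_low = float(ldf.loc[low_samples, "load_proxy"].median())

    pis = {c: float(np.nanmedian(t.values)) for c, t in result.pis_windows.items()}
    pis_high = float(np.median([pis[c] for c in high_clades]))
    pis_low = float(np.median([pis[c] for c in low_clades]))

    # per-sample ROH totals (kb), averaged over samples within altitude group
    seg = result.roh_segments
    totals = seg.groupby("sample")["length_kb"].sum() if len(seg) else pd.Series(dtype=float)
    cm = result.clade_map
    def group_mean(clades):
        samples = [s for c in clades for s in cm.samples_of(c)]
        return float(np.mean([totals.get(s, 0.0) for s in samples]))
    roh_high = group_mean(high_clades)
    roh_low = group_mean(low_clades)

    from purgescan.load import rare_fraction

    def pooled_rare(clades, cls):
        fracs = []
        for c in clades:
            sfs = result.spectra.get((c, cls))
            if sfs is not None and sfs.total > 0:
                fracs.append(rare_fraction(sfs, 0.1))
        return float(np.nanmean(fracs)) if fracs else float("nan")

    rare_dn_high = pooled_rare(high_clades, "dnsnp")
    rare_dn_low = pooled_rare(low_clades, "dnsnp")
    rho = result.pis_load.get("spearman_rho", float("nan"))

    return {
        "load_high": load_high,
        "load_low": load_low,
        "pis_high": pis_high,
        "pis_low": pis_low,
        "roh_kb_high": roh_high,
        "roh_kb_low": roh_low,
        "rare_dnsnp_high": rare_dn_high,
        "rare_dnsnp_low": rare_dn_low,
        "pis_load_spearman": rho,
        "load_high_lt_low": load_high < load_low,
        "pis_high_lt_low": pis_high < pis_low,
        "roh_high_gt_low": roh_high > roh_low,
        "rare_dnsnp_high_gt_low": rare_dn_high > rare_dn_low,
        "spearman_positive": rho > 0,
    }


def run_replicate(scale: str, seed: int, dominance: float, workdir=None) -> dict:
    """Simulate one scenario arm and push the bundle through the pipeline."""
    cfg = make_highland_lowland_scenario(scale, seed=seed)
    cfg = dataclasses.replace(cfg, dominance=dominance)
    ds, truth = simulate(cfg)

    def _run(outroot: Path) -> dict:
        bundle = write_bundle(ds, truth, outroot / "bundle")
        pcfg = PipelineConfig(
            vcf=bundle["vcf"],
            fasta=bundle["fasta"],
            gff3=bundle["gff3"],
            outgroups=bundle["outgroups"],
            clades=bundle["clades"],
            dnsnp=bundle["dnsnp"],
            outdir=outroot / "pipeline",
            seed=seed,
            min_maf=0.05,
            min_depth=0,
            maf_filter_for_roh_only=True,  # SFS/load/pi need the rare variants
        )
        result = run_pipeline(pcfg)
        return _replicate_metrics(result)

    if workdir is None:
        with tempfile.TemporaryDirectory() as tmp:
            return _run(Path(tmp))
    return _run(Path(workdir))


def purging_experiment(
    scale: str = "small", n_replicates: int = 30, seed: int = 1
) -> pd.DataFrame:
    """Replicated two-arm (h=0 vs h=0.5) purging experiment.

    Returns one row per replicate per arm with the per-group medians and the
    directional indicators; downstream sign tests act on the h=0 arm.
    """
    rows = []
    for rep in range(n_replicates):
        for arm, h in (("recessive", 0.0), ("additive", 0.5)):
            rep_seed = (seed * 100_003 + rep * 211 + (0 if h == 0 else 101)) % (2**31 - 1)
            metrics = run_replicate(scale, rep_seed, h)
            metrics.update({"replicate": rep, "arm": arm, "dominance": h, "seed": rep_seed})
            rows.append(metrics)
    return pd.DataFrame(rows)


def sign_test(successes: int, n: int) -> float:
    """One-sided exact binomial p-value against P(success)=0.5."""
    return float(binomtest(successes, n, p=0.5, alternative="greater").pvalue)


def experiment_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-arm directional fractions and sign-test p-values."""
    rows = []
    for arm, sub in table.groupby("arm"):
        n = len(sub)
        row = {"arm": arm, "n_replicates": n}
        for ind in (
            "load_high_lt_low",
            "pis_high_lt_low",
            "roh_high_gt_low",
            "rare_dnsnp_high_gt_low",
            "spearman_positive",
        ):
            k = int(sub[ind].sum())
            row[f"{ind}_frac"] = k / n
            row[f"{ind}_sign_p"] = sign_test(k, n)
        rows.append(row)
    return pd.DataFrame(rows)
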