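"""End-to-end analysis pipeline: filter -> annotate -> polarize -> diversity /
differentiation -> ROH -> load -> SFS -> sweep candidates.

``run_pipeline`` is deterministic given inputs and writes every stage table
plus a JSON manifest (parameters, input checksums, stage record counts) to
the output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from purgescan import annotate as ann_mod
from purgescan import load as load_mod
from purgescan import polarize as pol_mod
from purgescan import popstats, roh, sweeps, variant_io
from purgescan.polarize import RESOLVED
from purgescan.roh import ROHParams

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    vcf: Path
    fasta: Path
    gff3: Path
    outgroups: Path
    clades: Path
    outdir: Path
    dnsnp: Path | None = None
    external_track: Path | None = None
    seed: int = 0
    # stage parameters
    max_missing_frac: float = 0.8
    min_maf: float = 0.05
    min_depth: int = 3
    maf_filter_for_roh_only: bool = False
    window_bp: int = 50_000
    step_bp: int = 10_000
    fst_min_snps: int = 10
    roh_params: ROHParams = field(default_factory=ROHParams)
    projection_n: int | None = None  # auto from smallest clade when None
    daf_threshold: float = 0.1
    sweep_q: float = 0.05
    load_counting: str = "dosage"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        roh_params = ROHParams(**raw.pop("roh_params", {}))
        raw = {k: v for k, v in raw.items()}
        for key in ("vcf", "fasta", "gff3", "outgroups", "clades", "outdir", "dnsnp", "external_track"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        return cls(roh_params=roh_params, **raw)

    def validate(self) -> None:
        for key in ("vcf", "fasta", "gff3", "outgroups", "clades"):
            p = getattr(self, key)
            if p is None or not Path(p).exists():
                raise PipelineError(f"config: missing input file for '{key}': {p}")
        for key in ("dnsnp", "external_track"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise PipelineError(f"config: optional input '{key}' not found: {p}")


@dataclass
class PipelineResult:
    """In-memory handles on the stage outputs (all also written as TSV)."""

    outdir: Path
    dataset: "variant_io.GenotypeDataset"
    clade_map: "variant_io.CladeMap"
    annotation: pd.DataFrame
    polarization: pd.DataFrame
    derived_dosage: np.ndarray
    fourfold_sites: list[tuple[str, int]]
    pi_windows: dict[str, "popstats.WindowTrack"]
    pis_windows: dict[str, "popstats.WindowTrack"]
    fst_track: "popstats.WindowTrack | None"
    roh_segments: pd.DataFrame
    roh_summary: pd.DataFrame
    load_reports: list
    load_table: pd.DataFrame
    clade_load: pd.DataFrame
    clade_load_tests: pd.DataFrame
    sfs_table: pd.DataFrame
    spectra: dict[tuple[str, str], "popstats.SFS"]
    pis_load: dict
    candidates: "sweeps.CandidateSet | None"
    manifest: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "inputs": {}, "parameters": {}}
    for key in ("vcf", "fasta", "gff3", "outgroups", "clades", "dnsnp", "external_track"):
        p = getattr(config, key)
        if p is not None:
            manifest["inputs"][key] = {"path": str(p), "sha256": _sha256(Path(p))}
    manifest["parameters"] = {
        "max_missing_frac": config.max_missing_frac,
        "min_maf": config.min_maf,
        "min_depth": config.min_depth,
        "maf_filter_for_roh_only": config.maf_filter_for_roh_only,
        "window_bp": config.window_bp,
        "step_bp": config.step_bp,
        "fst_min_snps": config.fst_min_snps,
        "roh_params": vars(config.roh_params),
        "projection_n": config.projection_n,
        "daf_threshold": config.daf_threshold,
        "sweep_q": config.sweep_q,
        "load_counting": config.load_counting,
        "seed": config.seed,
    }

    def stage(name):
        def deco(fn):
            try:
                out = fn()
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
            return out

        return deco

    # ---- ingest + filter ---------------------------------------------------
    @stage("ingest")
    def _ingest():
        ds = variant_io.read_vcf(config.vcf)
        cm = variant_io.read_clade_map(config.clades)
        missing = [s for s in cm.sample_to_clade if s not in ds.samples]
        if missing:
            raise ValueError(f"clade map samples absent from VCF: {missing[:5]}")
        return ds, cm

    raw_ds, clade_map = _ingest

    @stage("filter")
    def _filter():
        ds, report = variant_io.filter_variants(
            raw_ds, config.max_missing_frac, config.min_maf, config.min_depth
        )
        return ds, report

    filtered_ds, filter_report = _filter
    if config.maf_filter_for_roh_only:
        analysis_ds, _ = variant_io.filter_variants(
            raw_ds, config.max_missing_frac, 0.0, config.min_depth
        )
        roh_ds = filtered_ds
    else:
        analysis_ds = roh_ds = filtered_ds
    manifest["stages"]["filter"] = filter_report

    chrom_lengths = {name: len(seq) for name, seq in Fasta(str(config.fasta)).items()}
    genome_length = sum(chrom_lengths.values())

    # ---- annotate ----------------------------------------------------------
    @stage("annotate")
    def _annotate():
        index = ann_mod.AnnotationIndex(config.fasta, config.gff3)
        dnsnp_sites: set[tuple[str, int]] = set()
        if config.dnsnp is not None:
            dn = pd.read_csv(config.dnsnp, sep="\t")
            dnsnp_sites = {(str(c), int(p)) for c, p in zip(dn["chrom"], dn["pos"])}
        table = ann_mod.annotate_dataset(index, analysis_ds, dnsnp_sites)
        ff = ann_mod.fourfold_site_table(index)
        return index, table, ff, dnsnp_sites

    index, annotation, fourfold_sites, dnsnp_sites = _annotate
    annotation.to_csv(outdir / "site_annotation.tsv", sep="\t", index=False)
    manifest["stages"]["annotate"] = {
        "n_sites": len(annotation),
        "n_fourfold_reference_sites": len(fourfold_sites),
    }

    # ---- polarize ----------------------------------------------------------
    @stage("polarize")
    def _polarize():
        og = variant_io.read_outgroup_table(config.outgroups)
        sites, derived = pol_mod.polarize_dataset(analysis_ds, og)
        return sites, derived

    pol_sites, derived_dosage = _polarize
    pol_table = pol_mod.polarization_table(pol_sites)
    pol_table.to_csv(outdir / "polarization.tsv", sep="\t", index=False)
    status_counts = pol_table["status"].value_counts().to_dict()
    manifest["stages"]["polarize"] = {str(k): int(v) for k, v in status_counts.items()}

    # ---- diversity ---------------------------------------------------------
    ff_set = set(fourfold_sites)

    @stage("pi")
    def _pi():
        pi_tracks, pis_tracks = {}, {}
        for clade in clade_map.clades():
            samples = [s for s in clade_map.samples_of(clade) if s in analysis_ds.samples]
            pi_tracks[clade] = popstats.windowed_pi(
                analysis_ds, chrom_lengths, config.window_bp, config.step_bp,
                mode="sliding", samples=samples, label=clade,
            )
            pis_tracks[clade] = popstats.windowed_pi(
                analysis_ds, chrom_lengths, mode="nonoverlapping_10kb",
                samples=samples, site_list=ff_set, label=clade,
            )
        return pi_tracks, pis_tracks

    pi_windows, pis_windows = _pi
    pd.concat(
        [t.windows.assign(clade=c, statistic="pi") for c, t in pi_windows.items()]
        + [t.windows.assign(clade=c, statistic="pis_10kb") for c, t in pis_windows.items()]
    ).to_csv(outdir / "diversity_windows.tsv", sep="\t", index=False, na_rep="NA")

    # ---- FST high vs low altitude -------------------------------------------
    @stage("fst")
    def _fst():
        high = [
            s
            for c in clade_map.clades()
            if clade_map.altitude_of(c) == "high"
            for s in clade_map.samples_of(c)
            if s in analysis_ds.samples
        ]
        low = [
            s
            for c in clade_map.clades()
            if clade_map.altitude_of(c) == "low"
            for s in clade_map.samples_of(c)
            if s in analysis_ds.samples
        ]
        if len(high) < 2 or len(low) < 2:
            log.warning("fst: need >=2 samples in both altitude groups; skipped")
            return None
        return popstats.windowed_fst(
            analysis_ds, clade_map, (high, low), chrom_lengths,
            config.window_bp, config.step_bp, config.fst_min_snps,
        )

    fst_track = _fst
    if fst_track is not None:
        fst_track.to_tsv(outdir / "fst_windows.tsv")

    # ---- ROH ---------------------------------------------------------------
    @stage("roh")
    def _roh():
        segments = roh.detect_roh_dataset(roh_ds, config.roh_params)
        seg_table = roh.roh_table(segments)
        summary = roh.roh_summary(segments, clade_map, genome_length)
        return seg_table, summary

    roh_segments, roh_summary_table = _roh
    roh_segments.to_csv(outdir / "roh_segments.tsv", sep="\t", index=False)
    roh_summary_table.to_csv(outdir / "roh_summary.tsv", sep="\t", index=False)
    manifest["stages"]["roh"] = {"n_segments": int(len(roh_segments))}

    # ---- load + SFS ---------------------------------------------------------
    @stage("load")
    def _load():
        resolved = np.asarray([s.status == RESOLVED for s in pol_sites])
        keys = list(zip(map(str, analysis_ds.chrom), map(int, analysis_ds.pos)))
        is_ff = np.asarray([k in ff_set for k in keys])
        is_dn = np.asarray([k in dnsnp_sites for k in keys])
        # load uses resolved + resolved-external minus the default exclusion
        # of external sites (constant offset); SFS uses resolved only
        dn_rows = np.flatnonzero(resolved & is_dn & ~is_ff)
        ff_rows = np.flatnonzero(resolved & is_ff)
        reports = load_mod.load_reports(
            derived_dosage, dn_rows, ff_rows, analysis_ds.samples,
            clade_map, config.load_counting,
        )
        summary, tests = load_mod.clade_load_table(reports, clade_map)

        clades = clade_map.clades()
        if config.projection_n is not None:
            proj = config.projection_n
        else:
            min_clade = min(
                sum(1 for s in clade_map.samples_of(c) if s in analysis_ds.samples)
                for c in clades
            )
            proj = max(2, min(20, 2 * min_clade))
        spectra: dict[tuple[str, str], popstats.SFS] = {}
        for clade in clades:
            idx = np.asarray(
                [analysis_ds.samples.index(s) for s in clade_map.samples_of(clade)
                 if s in analysis_ds.samples]
            )
            for cls_name, rows in (("fourfold", ff_rows), ("dnsnp", dn_rows)):
                mask = np.zeros(analysis_ds.n_sites, dtype=bool)
                mask[rows] = True
                spectra[(clade, cls_name)] = popstats.compute_sfs(
                    derived_dosage, idx, proj, site_mask=mask,
                    site_class=cls_name, group=clade,
                )
        return reports, summary, tests, spectra

    load_reports, clade_load, clade_tests, spectra = _load
    load_df = load_mod.load_table(load_reports)
    load_df.to_csv(outdir / "load_per_sample.tsv", sep="\t", index=False)
    clade_load.to_csv(outdir / "load_per_clade.tsv", sep="\t", index=False)
    clade_tests.to_csv(outdir / "load_clade_tests.tsv", sep="\t", index=False)
    sfs_df = popstats.sfs_table(list(spectra.values()))
    sfs_df.to_csv(outdir / "sfs.tsv", sep="\t", index=False)

    @stage("pis_load")
    def _pis_load():
        clade_pis = {
            c: float(np.nanmedian(t.values)) for c, t in pis_windows.items()
        }
        clade_loads = {
            r["clade"]: r["median_load"] for _, r in clade_load.iterrows()
        }
        try:
            rel = load_mod.pis_load_relation(clade_pis, clade_loads)
        except ValueError:
            rel = {}
        return clade_pis, rel

    clade_pis, pis_load = _pis_load
    manifest["stages"]["load"] = {
        "clade_median_load": {
            r["clade"]: float(r["median_load"]) for _, r in clade_load.iterrows()
        },
        "clade_median_pis": clade_pis,
        "pis_load": pis_load,
    }

    # ---- sweeps ------------------------------------------------------------
    @stage("sweeps")
    def _sweeps():
        if fst_track is None or config.external_track is None:
            return None
        ext = variant_io.read_window_scores(config.external_track)
        top_fst = sweeps.top_quantile_windows(fst_track, config.sweep_q)
        top_ext = sweeps.top_quantile_windows(ext, config.sweep_q)
        return sweeps.intersect_and_map(
            top_fst, top_ext, config.gff3, comparison="high_vs_low", q=config.sweep_q
        )

    candidates = _sweeps
    if candidates is not None:
        sweeps.candidate_table([candidates]).to_csv(
            outdir / "sweep_candidates.tsv", sep="\t", index=False
        )
        manifest["stages"]["sweeps"] = {"n_candidate_genes": len(candidates.genes)}

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    summary_lines = [
        f"sites after filter: {filter_report['sites_kept']}",
        f"fourfold reference sites: {len(fourfold_sites)}",
        f"polarization: {status_counts}",
        f"ROH segments: {len(roh_segments)}",
        f"clade median load: {manifest['stages']['load']['clade_median_load']}",
    ]
    (outdir / "summary.txt").write_text("\n".join(summary_lines) + "\n")

    return PipelineResult(
        outdir=outdir,
        dataset=analysis_ds,
        clade_map=clade_map,
        annotation=annotation,
        polarization=pol_table,
        derived_dosage=derived_dosage,
        fourfold_sites=fourfold_sites,
        pi_windows=pi_windows,
        pis_windows=pis_windows,
        fst_track=fst_track,
        roh_segments=roh_segments,
        roh_summary=roh_summary_table,
        load_reports=load_reports,
        load_table=load_df,
        clade_load=clade_load,
        clade_load_tests=clade_tests,
        sfs_table=sfs_df,
        spectra=spectra,
        pis_load=pis_load,
        candidates=candidates,
        manifest=manifest,
    )
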