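"""End-to-end orchestration: simulate -> map -> mito profile -> nuclear QC.

A run directory contains a manifest (full config echo), per-library FASTQs
and alignment tables, the enrichment audit table, chrM strand bedGraphs and
localized-site calls, nuclear cross-correlation and peak reports, and a
single summary JSON. Reruns with the same manifest are byte-identical.

Presets mirror the study's scenarios:

``coating``       uniform-coating ChIP plus matched input; the expected
                  outcome is zero point-source calls anywhere.
``planted-site``  coating plus one point source at the annotated putative
                  site on chrM; expected outcome is exactly that one call.
``null-nuclear``  a signal-free "ChIP" (input model) against input, for the
                  nuclear false-positive control.
``artifact``      input background plus symmetric repeat pileups on the
                  nuclear decoy; sites are called but none classify as
                  point_source.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import (ReferenceBundle, make_chrm_reference, make_nuclear_decoy,
                     load_chrm_reference)
from .simulate import SimConfig, simulate_library, smooth_bias_field
from .mapping import ExactMatchIndex, partition, trim_reads
from .coverage import build_coverage
from .mito import (enrichment_fraction, uniformity, scan_localized_sites,
                   site_annotation_distance, replicate_correlation)
from .nuclear import cross_correlation, call_nuclear_peaks
from .peaks import ScanParams
from .io import ReadSet, read_fastq, write_bed, write_bedgraph, dump_json

log = logging.getLogger("mitochip")

PRESETS = ("coating", "planted-site", "null-nuclear", "artifact")


@dataclass
class RunConfig:
    outdir: str = "mitochip_run"
    seed: int = 0
    preset: str = "coating"
    n_fragments: int = 200_000
    n_replicates: int = 1
    chrm_length: int = 16_569
    decoy_size: int = 2_000_000
    decoy_contigs: int = 2
    n_numts: int = 3
    numt_divergence: float = 0.05
    read_length: int = 36
    fragment_mean: float = 200.0
    fragment_sd: float = 20.0
    mito_mass_fraction: float = 0.019
    chip_mito_fraction: float = 0.40
    site_enrichment: float = 10.0
    bias_amplitude: float = 0.3   # shared chrM sequencing-bias field
    window: int = 200
    step: int = 50
    q_threshold: float = 0.01
    min_fold: float = 2.0
    asym_min_gain: float = 0.2
    artifact_r_zero: float = 0.5
    stages: tuple[str, ...] = ("simulate", "map", "mito", "nuclear")
    make_plots: bool = False
    chrm_fasta: str | None = None   # optional real reference path
    chip_fastq: str | None = None   # optional real libraries
    input_fastq: str | None = None

    def scan_params(self) -> ScanParams:
        return ScanParams(window=self.window, step=self.step,
                          q_threshold=self.q_threshold,
                          min_fold=self.min_fold,
                          asym_min_gain=self.asym_min_gain,
                          artifact_r_zero=self.artifact_r_zero)


def _child_seed(seed: int, k: int) -> int:
    return (seed * 10_007 + k) % (2 ** 31)


def _chip_model(preset: str) -> str:
    return {
        "coating": "coating",
        "planted-site": "point_source_mix",
        "null-nuclear": "input",
        "artifact": "nuclear_artifact",
    }[preset]


def run_pipeline(cfg: RunConfig) -> dict:
    if cfg.preset not in PRESETS:
        raise ValueError(f"unknown preset {cfg.preset!r}; one of {PRESETS}")
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    dump_json(out / "manifest.json", asdict(cfg))
    summary: dict = {"preset": cfg.preset, "seed": cfg.seed}

    # --- references -----------------------------------------------------
    if cfg.chrm_fasta:
        chrm, annotation = load_chrm_reference(cfg.chrm_fasta)
    else:
        chrm, annotation = make_chrm_reference(
            _child_seed(cfg.seed, 1), cfg.chrm_length)
    decoy = make_nuclear_decoy(
        _child_seed(cfg.seed, 2), chrm, n_contigs=cfg.decoy_contigs,
        total_size=cfg.decoy_size, n_numts=cfg.n_numts,
        divergence=cfg.numt_divergence,
    )
    bundle = ReferenceBundle(chrm, annotation, decoy)
    refdir = out / "references"
    refdir.mkdir(exist_ok=True)
    chrm.to_fasta(refdir / "chrM.fa")
    decoy.to_fasta(refdir / "nuclear_decoy.fa")
    annotation.to_bed(refdir / "chrM_annotation.bed", chrm.length)
    decoy.registries_to_bed(refdir / "decoy_registry.bed")

    bias = {chrm.name: smooth_bias_field(_child_seed(cfg.seed, 3),
                                         chrm.length, cfg.bias_amplitude)} \
        if cfg.bias_amplitude > 0 else None
    sim = SimConfig(
        seed=0, read_length=cfg.read_length, fragment_mean=cfg.fragment_mean,
        fragment_sd=cfg.fragment_sd, mito_mass_fraction=cfg.mito_mass_fraction,
        chip_mito_fraction=cfg.chip_mito_fraction,
        site_enrichment=cfg.site_enrichment, n_fragments=cfg.n_fragments,
        bias_field=bias,
    )

    # --- simulate -------------------------------------------------------
    libdir = out / "libraries"
    libdir.mkdir(exist_ok=True)
    chip_reads: list[ReadSet] = []
    input_reads: ReadSet | None = None
    if "simulate" in cfg.stages and cfg.chip_fastq is None:
        model = _chip_model(cfg.preset)
        for rep in range(cfg.n_replicates):
            rep_sim = SimConfig(**{**asdict(sim),
                                   "seed": _child_seed(cfg.seed, 10 + rep)})
            lib = simulate_library(
                rep_sim, model, bundle,
                fastq_path=libdir / f"chip_rep{rep + 1}.fastq",
                truth_bed_path=libdir / f"chip_rep{rep + 1}.truth.bed",
            )
            chip_reads.append(lib.reads)
            log.info("simulated %s replicate %d: %d reads", model, rep + 1,
                     len(lib.reads))
        in_sim = SimConfig(**{**asdict(sim), "seed": _child_seed(cfg.seed, 99)})
        input_lib = simulate_library(in_sim, "input", bundle,
                                     fastq_path=libdir / "input.fastq")
        input_reads = input_lib.reads
    elif cfg.chip_fastq is not None:
        ids, seqs = read_fastq(cfg.chip_fastq)
        chip_reads = [trim_reads(ids, seqs, cfg.read_length)[0]]
        ids, seqs = read_fastq(cfg.input_fastq)
        input_reads = trim_reads(ids, seqs, cfg.read_length)[0]

    if "map" not in cfg.stages or input_reads is None:
        dump_json(out / "summary.json", summary)
        return summary

    # --- map ------------------------------------------------------------
    mapdir = out / "alignments"
    mapdir.mkdir(exist_ok=True)
    chrm_index = ExactMatchIndex([(chrm.name, chrm.codes)], k=cfg.read_length,
                                 circular={chrm.name})
    genome_index = ExactMatchIndex(bundle.contig_codes(), k=cfg.read_length,
                                   circular={chrm.name})
    parts = []
    enrich_rows = []
    for rep, reads in enumerate(chip_reads):
        part = partition(reads, chrm_index, genome_index,
                         seed=_child_seed(cfg.seed, 20 + rep))
        part.write(mapdir, f"chip_rep{rep + 1}")
        parts.append(part)
        rep_name = f"ChIP_rep{rep + 1}"
        enrich_rows.append(enrichment_fraction(part, rep_name).as_dict())
        log.info("%s audit: %s", rep_name, part.counts)
    input_part = partition(input_reads, chrm_index, genome_index,
                           seed=_child_seed(cfg.seed, 98))
    input_part.write(mapdir, "input")
    enrich_rows.append(enrichment_fraction(input_part, "input").as_dict())
    enrich_df = pd.DataFrame(enrich_rows)
    enrich_df.to_csv(out / "enrichment_fractions.tsv", sep="\t", index=False)
    summary["enrichment"] = enrich_rows

    params = cfg.scan_params()
    fragment_mean = int(cfg.fragment_mean)

    # --- mito -----------------------------------------------------------
    if "mito" in cfg.stages:
        mitodir = out / "mito"
        mitodir.mkdir(exist_ok=True)
        chip_covs = [
            build_coverage(p.chrm_reads, chrm.name, chrm.length,
                           read_length=cfg.read_length, circular=True)
            for p in parts
        ]
        input_cov = build_coverage(input_part.chrm_reads, chrm.name,
                                   chrm.length, read_length=cfg.read_length,
                                   circular=True)
        cov = chip_covs[0]
        rpm = cov.rpm()
        write_bedgraph(mitodir / "chip.plus.rpm.bedgraph", chrm.name, rpm.plus)
        write_bedgraph(mitodir / "chip.minus.rpm.bedgraph", chrm.name, rpm.minus)
        write_bedgraph(mitodir / "chip.combined.rpm.bedgraph", chrm.name,
                       rpm.combined())
        uni = uniformity(cov, input_cov, window=cfg.window,
                         gc_codes=chrm.codes)
        summary["uniformity"] = uni.as_dict()
        sites = scan_localized_sites(cov, input_cov, fragment_mean, params)
        write_bed(mitodir / "localized_sites.bed",
                  [s.to_bed_row() for s in sites])
        site_rows = []
        for s in sites:
            row = {
                "contig": s.contig, "start": s.start, "end": s.end,
                "summit_1based": s.summit_1based,
                "fold": round(s.fold_enrichment, 3),
                "q_value": s.q_value, "d_hat": s.d_hat,
                "r_shift": round(s.r_shift, 3), "r_zero": round(s.r_zero, 3),
                "classification": s.classification,
            }
            if s.classification == "point_source":
                row["dist_to_O_L"] = site_annotation_distance(
                    s, annotation, "O_L", chrm.length)
            site_rows.append(row)
        pd.DataFrame(site_rows).to_csv(mitodir / "localized_sites.tsv",
                                       sep="\t", index=False)
        summary["chrM_sites"] = site_rows
        summary["chrM_point_source_calls"] = sum(
            1 for s in sites if s.classification == "point_source")
        if len(chip_covs) >= 2:
            r_df, p_df, flags = replicate_correlation(chip_covs, cfg.window)
            r_df.to_csv(mitodir / "replicate_correlation_r.tsv", sep="\t")
            p_df.to_csv(mitodir / "replicate_correlation_p.tsv", sep="\t")
            summary["replicate_correlation_min_r"] = float(
                np.nanmin(r_df.to_numpy()))
        if cfg.make_plots:
            from .plotting import plot_strand_coverage
            plot_strand_coverage(cov, input_cov,
                                 mitodir / "chrM_coverage.png")

    # --- nuclear --------------------------------------------------------
    if "nuclear" in cfg.stages:
        nucdir = out / "nuclear"
        nucdir.mkdir(exist_ok=True)
        lengths = decoy.lengths
        codes = dict(decoy.contigs)
        chip_nuc = parts[0].nuclear_reads
        try:
            ccp = cross_correlation(chip_nuc, lengths,
                                    read_length=cfg.read_length)
            ccp.to_frame().to_csv(nucdir / "cross_correlation_chip.tsv",
                                  sep="\t", index=False)
            summary["cross_correlation"] = {
                "fragment_length_estimate": ccp.fragment_length_estimate,
                "read_length_peak_flag": ccp.read_length_peak_flag,
            }
            in_ccp = cross_correlation(input_part.nuclear_reads, lengths,
                                       read_length=cfg.read_length)
            in_ccp.to_frame().to_csv(nucdir / "cross_correlation_input.tsv",
                                     sep="\t", index=False)
            summary["cross_correlation"]["max_abs_delta_vs_input"] = float(
                np.max(np.abs(ccp.r - in_ccp.r)))
        except ValueError as exc:
            summary["cross_correlation"] = {"skipped": str(exc)}
        report = call_nuclear_peaks(
            chip_nuc, input_part.nuclear_reads, lengths, params,
            read_length=cfg.read_length,
            fallback_fragment=fragment_mean,
            genome_index=genome_index, contig_codes=codes,
        )
        report.to_narrowpeak(nucdir / "nuclear_peaks.narrowPeak")
        dump_json(nucdir / "nuclear_qc.json", report.as_dict())
        summary["nuclear"] = report.as_dict()
        summary["nuclear_point_source_calls"] = report.n_point_source

    dump_json(out / "summary.json", summary)
    return summary


def make_report(run_dir: str | Path) -> str:
    """Human-readable markdown report assembled from a completed run."""
    run_dir = Path(run_dir)
    summary_path = run_dir / "summary.json"
    if not summary_path.exists():
        raise FileNotFoundError(
            f"{run_dir} does not look like a completed run (no summary.json)"
        )
    import json

    summary = json.loads(summary_path.read_text())
    lines = [f"# mitochip run report ({summary.get('preset', '?')} preset)", ""]
    enrich = summary.get("enrichment")
    if enrich:
        lines += ["## chrM enrichment fractions", "",
                  "| library | mapped | chrM | % chrM |",
                  "|---|---|---|---|"]
        for row in enrich:
            lines.append(
                f"| {row['library']} | {row['total_mapped']} | "
                f"{row['chrM_mapped']} | {row['fraction_chrM_percent']:.2f} |"
            )
        lines.append("")
    uni = summary.get("uniformity")
    if uni:
        lines += ["## chrM uniformity vs input", "",
                  f"- windows: {uni['n_windows']} x {uni['window']} bp, "
                  f"flagged: {uni['n_flagged']}",
                  f"- ChIP-input window correlation r = "
                  f"{uni['chip_input_r']:.3f}",
                  f"- GC vs log-ratio r = {uni['gc_r']}", ""]
    if "chrM_sites" in summary:
        n_ps = summary.get("chrM_point_source_calls", 0)
        lines += ["## chrM localized sites", "",
                  f"- point_source calls: {n_ps}"]
        for s in summary["chrM_sites"]:
            lines.append(
                f"  - {s['contig']}:{s['start']}-{s['end']} summit "
                f"{s['summit_1based']} fold {s['fold']} -> "
                f"{s['classification']}"
            )
        lines.append("")
    else:
        lines += ["## chrM localized sites", "", "- stage skipped", ""]
    nuc = summary.get("nuclear")
    if nuc:
        lines += ["## nuclear genome", "",
                  f"- called: {nuc['n_called']} (point_source "
                  f"{nuc['n_point_source']}, artifact {nuc['n_artifact']}, "
                  f"diffuse {nuc['n_diffuse']})",
                  f"- fragment length estimate: "
                  f"{nuc['fragment_length_estimate']} bp", ""]
    else:
        lines += ["## nuclear genome", "", "- stage skipped", ""]
    text = "\n".join(lines)
    (run_dir / "report.md").write_text(text)
    return text
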