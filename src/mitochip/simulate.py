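"""Synthetic ChIP-seq / input library generator with planted ground truth.

Four generative models over a reference bundle:

``input``
    Sonicated naked-DNA control: a fragment derives from chrM with
    probability ``mito_mass_fraction`` (DNA sampled by mass; the fraction is
    an explicit parameter so desk-scale decoys reproduce full-genome
    statistics), otherwise from a nuclear contig chosen by length. Positions
    follow the shared ``bias_field`` (uniform by default).

``coating``
    ChIP library under the uniform-coating occupancy model: chrM with
    probability ``chip_mito_fraction``, positions uniform x bias_field; the
    nuclear remainder is input-like background.

``point_source_mix``
    Coating background plus localized binding: planted fragments whose
    midpoints are Normal(site_center, site_sd). The number of planted
    fragments is calibrated so the midpoint density at the site center is
    ``site_enrichment``-fold the coating background density.

``nuclear_artifact``
    Input-like background plus symmetric pileups over the decoy's repeat
    registry intervals: a read 5'-end position is drawn around the interval
    center and the strand tossed independently, so + and - strand 5'-end
    profiles are identical in expectation (the signature of a mapping
    artifact rather than true point-source binding).

Every fragment emits one single-end read of ``read_length`` bases from its
5' end: + strand reads the fragment's left end forward, - strand reads the
right end reverse-complemented. chrM fragments may wrap the circular origin.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import seq as sq
from .genome import ReferenceBundle, ConfigurationError
from .io import ReadSet, write_fastq, write_bed, dump_json

MODELS = ("input", "coating", "point_source_mix", "nuclear_artifact")


@dataclass
class SimConfig:
    """Library-generation parameters.

    Defaults are the study conditions the analysis is designed around:
    36-bp single-end reads from ~200 +/- 20 bp size-selected fragments, an
    input chrM mass fraction at the top of the 0.4-1.9% range, ChIP chrM
    fraction 40% (within the observed 30-75% band), and 10-fold point-source
    enrichment over the coating background where a site is planted.
    """

    seed: int = 0
    read_length: int = 36
    fragment_mean: float = 200.0
    fragment_sd: float = 20.0
    mito_mass_fraction: float = 0.019
    chip_mito_fraction: float = 0.40
    site_enrichment: float = 10.0
    site_sd: float = 30.0
    artifact_fraction: float = 0.05
    error_rate: float = 0.0
    n_fragments: int = 100_000
    bias_field: dict | None = None  # contig -> per-position weight array

    def __post_init__(self) -> None:
        for name in ("mito_mass_fraction", "chip_mito_fraction",
                     "artifact_fraction", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.fragment_mean <= self.read_length:
            raise ConfigurationError("fragment_mean must exceed read_length")
        if self.n_fragments <= 0:
            raise ConfigurationError("zero-length library")

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        if d["bias_field"] is not None:
            d["bias_field"] = {k: list(map(float, v))
                               for k, v in d["bias_field"].items()}
        dump_json(path, d)


@dataclass
class LibraryResult:
    reads: ReadSet
    fragments: pd.DataFrame  # contig, start, end, length, strand, origin
    truth: pd.DataFrame      # planted sites: contig, start, end, name, kind
    model: str
    config: SimConfig

    def write_truth_bed(self, path: str | Path) -> None:
        rows = [(r.contig, r.start, r.end, f"{r.kind}:{r.name}", 0, ".")
                for r in self.truth.itertuples(index=False)]
        write_bed(path, rows)


def _sample_positions(rng, weights: np.ndarray | None, length: int,
                      n: int) -> np.ndarray:
    """Sample midpoints, optionally proportional to a bias field."""
    if n == 0:
        return np.empty(0, dtype=np.int64)
    if weights is None:
        return rng.integers(0, length, size=n)
    w = np.asarray(weights, dtype=float)
    if w.size != length:
        raise ConfigurationError("bias field length != contig length")
    return rng.choice(length, size=n, p=w / w.sum())


def _fragment_lengths(rng, cfg: SimConfig, n: int, max_len: int) -> np.ndarray:
    ln = np.rint(rng.normal(cfg.fragment_mean, cfg.fragment_sd, size=n))
    return np.clip(ln, cfg.read_length, max_len).astype(np.int64)


def _extract_reads(
    codes_by_contig: dict[str, np.ndarray],
    circular: set[str],
    frames: pd.DataFrame,
    cfg: SimConfig,
    rng: np.random.Generator,
    model: str,
) -> ReadSet:
    """One read per fragment, from a uniformly chosen strand's 5' end."""
    k = cfg.read_length
    n = len(frames)
    out = np.empty((n, k), dtype=np.uint8)
    offs = np.arange(k)
    for contig, grp in frames.groupby("contig", sort=False):
        codes = codes_by_contig[contig]
        L = codes.size
        idx = grp.index.to_numpy()
        start = grp["start"].to_numpy()
        end = grp["end"].to_numpy()
        minus = grp["strand"].to_numpy() == "-"
        rstart = np.where(minus, end - k, start)
        pos = rstart[:, None] + offs[None, :]
        pos = pos % L if contig in circular else pos
        block = codes[pos]
        if minus.any():
            block[minus] = sq.revcomp(block[minus])
        out[idx] = block
    if cfg.error_rate > 0:
        err = rng.random((n, k)) < cfg.error_rate
        shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
        out[err] = (out[err] + shift) % 4
    ids = [
        f"{model}:{i}:{c}:{s}:{l}:{st}"
        for i, (c, s, l, st) in enumerate(
            zip(frames["contig"], frames["start"], frames["length"],
                frames["strand"])
        )
    ]
    return ReadSet(ids, out)


def _background_fragments(rng, cfg, bundle, n, chrm_prob) -> pd.DataFrame:
    """Fragments split chrM vs nuclear by ``chrm_prob``; nuclear contigs by
    length; midpoints bias-field weighted."""
    chrm = bundle.chrm
    names = [chrm.name]
    probs = [chrm_prob]
    if bundle.decoy is not None and chrm_prob < 1.0:
        sizes = bundle.decoy.lengths
        tot = sum(sizes.values())
        for cname, csize in sizes.items():
            names.append(cname)
            probs.append((1.0 - chrm_prob) * csize / tot)
    else:
        probs = [1.0]
    if len(names) == 1 and chrm_prob < 1.0:
        raise ConfigurationError(
            "nuclear fragments requested but bundle has no decoy genome"
        )
    which = rng.choice(len(names), size=n, p=np.asarray(probs) / sum(probs))
    codes_by = dict(bundle.contig_codes())
    bias = cfg.bias_field or {}
    rows = []
    for ci, cname in enumerate(names):
        m = int((which == ci).sum())
        if m == 0:
            continue
        L = codes_by[cname].size
        circular = cname in bundle.circular_contigs()
        lengths = _fragment_lengths(rng, cfg, m, L)
        mid = _sample_positions(rng, bias.get(cname), L, m)
        start = mid - lengths // 2
        if circular:
            start = start % L
        else:
            start = np.clip(start, 0, L - lengths)
        rows.append(pd.DataFrame({
            "contig": cname, "start": start, "end": start + lengths,
            "length": lengths, "origin": "background",
        }))
    return pd.concat(rows, ignore_index=True)


def smooth_bias_field(
    seed: int, length: int, amplitude: float = 0.3, scale_bp: int = 500,
    circular: bool = True,
) -> np.ndarray:
    """Smooth positive per-position sampling weight (sequencing-bias proxy).

    Log-normal field: exp(amplitude * smoothed white noise), correlation
    scale ``scale_bp``. Shared between ChIP and input libraries it makes the
    ChIP profile track the input, as sequencing bias does in real data.
    """
    from scipy.ndimage import gaussian_filter1d

    rng = np.random.default_rng(seed)
    noise = rng.normal(size=length)
    sm = gaussian_filter1d(noise, scale_bp, mode="wrap" if circular else "nearest")
    sd = sm.std()
    if sd > 0:
        sm = sm / sd
    return np.exp(amplitude * sm)


def simulate_library(
    config: SimConfig,
    model: str,
    bundle: ReferenceBundle,
    sites: Sequence[tuple[str, int]] | None = None,
    fastq_path: str | Path | None = None,
    truth_bed_path: str | Path | None = None,
) -> LibraryResult:
    """Generate one library under the given model.

    ``sites`` are (contig, center) point sources for point_source_mix; the
    default is the bundled annotation's putative_site feature on chrM.
    Identical config (same seed) gives byte-identical FASTQ/BED output.
    """
    if model not in MODELS:
        raise ConfigurationError(f"unknown model {model!r}; one of {MODELS}")
    rng = np.random.default_rng(config.seed)
    chrm = bundle.chrm
    L = chrm.length
    codes_by = dict(bundle.contig_codes())
    truth_rows: list[dict] = []

    if model == "input":
        frames = _background_fragments(
            rng, config, bundle, config.n_fragments, config.mito_mass_fraction
        )
    elif model == "coating":
        frames = _background_fragments(
            rng, config, bundle, config.n_fragments, config.chip_mito_fraction
        )
    elif model == "point_source_mix":
        if sites is None:
            f = bundle.annotation.get("putative_site")
            sites = [(f.contig, f.center(L))]
        # Per-fragment probability of each contig under the coating model;
        # the planted count is calibrated against the background density on
        # the site's own contig.
        contig_prob = {chrm.name: config.chip_mito_fraction}
        if bundle.decoy is not None:
            tot = bundle.decoy.total_size
            for cname, csize in bundle.decoy.lengths.items():
                contig_prob[cname] = (
                    (1.0 - config.chip_mito_fraction) * csize / tot)
        ratios = []
        for scontig, _ in sites:
            Lc = codes_by[scontig].size
            ratios.append((config.site_enrichment - 1.0)
                          * contig_prob.get(scontig, 0.0) / Lc
                          * config.site_sd * np.sqrt(2.0 * np.pi))
        if not any(r > 0 for r in ratios):
            raise ConfigurationError(
                "planted sites lie on contigs with zero background "
                "probability; cannot calibrate fold enrichment"
            )
        n_bg = int(round(config.n_fragments / (1.0 + sum(ratios))))
        frames_list = [_background_fragments(
            rng, config, bundle, n_bg, config.chip_mito_fraction)]
        n_site_total = 0
        for (scontig, scenter), ratio in zip(sites, ratios):
            m = min(int(round(ratio * n_bg)),
                    config.n_fragments - n_bg - n_site_total)
            n_site_total += m
            Lc = codes_by[scontig].size
            circ = scontig in bundle.circular_contigs()
            lengths = _fragment_lengths(rng, config, m, Lc)
            mid = np.rint(rng.normal(scenter, config.site_sd, size=m)).astype(
                np.int64)
            start = mid - lengths // 2
            if circ:
                start, mid = start % Lc, mid % Lc
            else:
                start = np.clip(start, 0, Lc - lengths)
            frames_list.append(pd.DataFrame({
                "contig": scontig, "start": start, "end": start + lengths,
                "length": lengths, "origin": "site",
            }))
            truth_rows.append({
                "contig": scontig,
                "start": int(scenter - 3 * config.site_sd),
                "end": int(scenter + 3 * config.site_sd),
                "name": f"site@{scenter + 1}",
                "kind": "point_source",
                "n_planted": m,
                "fold": config.site_enrichment,
            })
        frames = pd.concat(frames_list, ignore_index=True)
    else:  # nuclear_artifact
        if bundle.decoy is None or not bundle.decoy.repeat_registry:
            raise ConfigurationError(
                "nuclear_artifact model needs a decoy with a repeat registry"
            )
        n_art = int(round(config.artifact_fraction * config.n_fragments))
        n_bg = config.n_fragments - n_art
        frames_list = [_background_fragments(
            rng, config, bundle, n_bg, config.mito_mass_fraction)]
        registry = bundle.decoy.repeat_registry
        split = np.bincount(
            rng.integers(0, len(registry), size=n_art), minlength=len(registry)
        )
        for reg, m in zip(registry, split):
            if m == 0:
                continue
            cname = reg["contig"]
            Lc = codes_by[cname].size
            center = (reg["start"] + reg["end"]) // 2
            spread = (reg["end"] - reg["start"]) / 4.0
            # 5'-end position first, strand independent of it => the two
            # strand 5'-end profiles are identical in expectation.
            p5 = np.rint(rng.normal(center, spread, size=int(m))).astype(np.int64)
            lengths = _fragment_lengths(rng, config, int(m), Lc)
            minus = rng.random(int(m)) < 0.5
            start = np.where(minus, p5 - lengths + 1, p5)
            start = np.clip(start, 0, Lc - lengths)
            df = pd.DataFrame({
                "contig": cname, "start": start, "end": start + lengths,
                "length": lengths, "origin": "artifact",
            })
            df["strand"] = np.where(minus, "-", "+")
            frames_list.append(df)
            truth_rows.append({
                "contig": cname, "start": int(reg["start"]),
                "end": int(reg["end"]), "name": f"repeat:{reg['kind']}",
                "kind": "artifact", "n_planted": int(m), "fold": float("nan"),
            })
        frames = pd.concat(frames_list, ignore_index=True)

    if "strand" not in frames.columns:
        frames["strand"] = "."
    undecided = frames["strand"] == "."
    frames.loc[undecided, "strand"] = np.where(
        rng.random(int(undecided.sum())) < 0.5, "+", "-"
    )
    frames = frames[["contig", "start", "end", "length", "strand", "origin"]]

    reads = _extract_reads(
        codes_by, bundle.circular_contigs(), frames, config, rng, model
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["contig", "start", "end", "name", "kind", "n_planted", "fold"],
    )
    result = LibraryResult(reads, frames, truth, model, config)
    if fastq_path is not None:
        reads.to_fastq(fastq_path)
    if truth_bed_path is not None:
        result.write_truth_bed(truth_bed_path)
    return result


def summarize_fragments(fragments: pd.DataFrame, bins: int = 50) -> dict:
    """Mean/sd/histogram of fragment lengths."""
    if fragments is None or len(fragments) == 0:
        raise ValueError("empty fragment set")
    lengths = fragments["length"].to_numpy(dtype=float)
    hist, edges = np.histogram(lengths, bins=bins)
    return {
        "n": int(lengths.size),
        "mean": float(lengths.mean()),
        "sd": float(lengths.std(ddof=1)) if lengths.size > 1 else 0.0,
        "histogram": {"counts": hist.tolist(), "bin_edges": edges.tolist()},
    }
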