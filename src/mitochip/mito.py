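"""Mitochondrial occupancy analysis: enrichment fraction, uniformity against
input, localized-site scanning, annotation distances, replicate agreement.

The central biological question these operations address: does the ChIP
signal on the circular mitochondrial genome look like uniform coating
(profile tracks the input, no strand asymmetry anywhere) or like localized
point-source binding (discrete enrichment with offset strand profiles)?
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import seq as sq
from .coverage import StrandCoverage, window_sums, tile_starts
from .genome import FeatureAnnotation, Feature
from .mapping import PartitionResult
from .peaks import PeakCall, ScanParams, scan_peaks


@dataclass
class EnrichmentReport:
    """The chrM-mapped percentage — the library-level enrichment statistic."""

    name: str
    total_mapped: int
    chrm_mapped: int

    @property
    def fraction_chrm(self) -> float:
        return 100.0 * self.chrm_mapped / self.total_mapped

    def as_dict(self) -> dict:
        return {
            "library": self.name,
            "total_mapped": self.total_mapped,
            "chrM_mapped": self.chrm_mapped,
            "fraction_chrM_percent": self.fraction_chrm,
        }


def enrichment_fraction(part: PartitionResult, name: str = "library") -> EnrichmentReport:
    mapped = part.counts.get("mapped", 0)
    if mapped <= 0:
        raise ValueError("zero mapped reads")
    return EnrichmentReport(name, mapped, part.counts["chrM_mapped"])


@dataclass
class UniformityReport:
    window: int
    starts: np.ndarray
    log2_ratio: np.ndarray
    zscores: np.ndarray
    flagged: np.ndarray           # window indices with |z| above threshold
    chip_input_r: float
    chip_input_p: float
    gc_r: float | None = None
    gc_p: float | None = None

    @property
    def n_windows(self) -> int:
        return self.starts.size

    def as_dict(self) -> dict:
        return {
            "window": self.window,
            "n_windows": int(self.n_windows),
            "n_flagged": int(self.flagged.size),
            "chip_input_r": self.chip_input_r,
            "chip_input_p": self.chip_input_p,
            "gc_r": self.gc_r,
            "gc_p": self.gc_p,
        }


def uniformity(
    chip: StrandCoverage,
    input_cov: StrandCoverage,
    window: int = 200,
    gc_codes: np.ndarray | None = None,
    z_threshold: float = 3.0,
    pseudocount: float = 1.0,
) -> UniformityReport:
    """Windowed ChIP/input comparison over one contig.

    Library-size-normalised log2 ratios per tiling window, the ChIP-input
    window-count correlation (coating tracks the input, so r should be
    high), the GC vs log-ratio correlation (should be null when coverage
    irregularities are not sequence-driven), and outlier windows by a
    z-score rule on the log ratios.
    """
    if chip.length != input_cov.length or chip.contig != input_cov.contig:
        raise ValueError("chip and input tracks must share a contig")
    if not (50 <= window <= chip.length // 10):
        raise ValueError(f"window {window} outside [50, L/10]")
    in_track = input_cov.combined()
    if in_track.sum() == 0:
        raise ValueError("all-zero input track")
    chip_track = chip.combined()
    starts = tile_starts(chip.length, window)
    # tiling windows never wrap; the final partial window keeps its width
    c = window_sums(chip_track, starts, window, False)
    i = window_sums(in_track, starts, window, False)
    scale = chip_track.sum() / in_track.sum()
    ratio = np.log2((c + pseudocount) / (i * scale + pseudocount))
    sd = ratio.std()
    z = (ratio - ratio.mean()) / sd if sd > 0 else np.zeros_like(ratio)
    flagged = np.flatnonzero(np.abs(z) > z_threshold)
    r, p = stats.pearsonr(c, i) if c.size > 2 else (np.nan, np.nan)
    gc_r = gc_p = None
    if gc_codes is not None:
        gc = window_sums(sq.gc_mask(gc_codes).astype(float), starts, window,
                         False)
        widths = np.minimum(starts + window, chip.length) - starts
        gc_frac = gc / widths
        if np.ptp(gc_frac) > 0:
            gc_r, gc_p = stats.pearsonr(gc_frac, ratio)
            gc_r, gc_p = float(gc_r), float(gc_p)
    return UniformityReport(window, starts, ratio, z, flagged,
                            float(r), float(p), gc_r, gc_p)


def scan_localized_sites(
    chip: StrandCoverage,
    input_cov: StrandCoverage | None,
    fragment_mean: int = 200,
    params: ScanParams | None = None,
) -> list[PeakCall]:
    """Circular sliding-window Poisson scan + strand-asymmetry classification."""
    return scan_peaks(chip, input_cov, fragment_mean, params)


def site_annotation_distance(
    peak: PeakCall | int,
    annotation: FeatureAnnotation,
    feature_name: str,
    contig_length: int,
) -> int:
    """Minimal circular signed distance from a summit to a feature start.

    Positive values mean the summit lies that many bp *upstream* of the
    feature start in heavy-strand (coordinate-increasing) orientation;
    negative means downstream.
    """
    summit = peak.summit if isinstance(peak, PeakCall) else int(peak)
    feature = annotation.get(feature_name)
    d = (feature.start - summit) % contig_length
    if d > contig_length // 2:
        d -= contig_length
    return int(d)


def replicate_correlation(
    cov_list: Sequence[StrandCoverage],
    window: int = 200,
    names: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Pairwise Pearson r (and two-sided p) of windowed coverage counts.

    Constant tracks are flagged (r set to NaN for their pairs) rather than
    raising.
    """
    if len(cov_list) < 2:
        raise ValueError("need at least two coverage tracks")
    L = cov_list[0].length
    contig = cov_list[0].contig
    for cov in cov_list[1:]:
        if cov.length != L or cov.contig != contig:
            raise ValueError("tracks must share a contig")
    names = list(names) if names else [f"rep{i+1}" for i in range(len(cov_list))]
    starts = tile_starts(L, window)
    counts = [window_sums(c.combined(), starts, window, False)
              for c in cov_list]
    k = len(counts)
    r_mat = np.eye(k)
    p_mat = np.zeros((k, k))
    flags: list[str] = []
    for a in range(k):
        if np.ptp(counts[a]) == 0:
            flags.append(f"{names[a]}: constant track, r undefined")
    for a in range(k):
        for b in range(a + 1, k):
            if np.ptp(counts[a]) == 0 or np.ptp(counts[b]) == 0:
                r_mat[a, b] = r_mat[b, a] = np.nan
                p_mat[a, b] = p_mat[b, a] = np.nan
                continue
            r, p = stats.pearsonr(counts[a], counts[b])
            r_mat[a, b] = r_mat[b, a] = r
            p_mat[a, b] = p_mat[b, a] = p
    r_df = pd.DataFrame(r_mat, index=names, columns=names)
    p_df = pd.DataFrame(p_mat, index=names, columns=names)
    return r_df, p_df, flags
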