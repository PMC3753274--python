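"""Strand-specific read-density tracks over (possibly circular) contigs.

``end_density`` mode counts read 5'-end positions per strand: a + read's 5'
end is its leftmost alignment coordinate; a - read's 5' end is its rightmost
covered base (pos + read_length - 1). ``extended`` mode smears each read to
the expected fragment length in its 3' direction, which is the track peak
callers take summits from. Circular contigs wrap in both modes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class StrandCoverage:
    contig: str
    length: int
    plus: np.ndarray
    minus: np.ndarray
    mode: str = "end_density"
    circular: bool = False
    n_reads: int = 0

    @property
    def total(self) -> float:
        return float(self.plus.sum() + self.minus.sum())

    def combined(self) -> np.ndarray:
        return self.plus + self.minus

    def rpm(self) -> "StrandCoverage":
        """Reads-per-million normalised copy (by contributing read count)."""
        scale = 1e6 / max(self.n_reads, 1)
        return StrandCoverage(
            self.contig, self.length, self.plus * scale, self.minus * scale,
            self.mode, self.circular, self.n_reads,
        )


def five_prime_ends(
    alignments: pd.DataFrame, read_length: int, length: int, circular: bool
) -> tuple[np.ndarray, np.ndarray]:
    pos = alignments["pos"].to_numpy()
    if (pos < 0).any() or (pos >= length).any():
        raise ValueError("alignment position outside contig")
    minus = alignments["strand"].to_numpy() == "-"
    p5_plus = pos[~minus]
    p5_minus = pos[minus] + read_length - 1
    if circular:
        p5_minus = p5_minus % length
    else:
        p5_minus = np.minimum(p5_minus, length - 1)
    return p5_plus, p5_minus


def _smear(ends: np.ndarray, length: int, fragment: int, forward: bool,
           circular: bool) -> np.ndarray:
    """Extend each 5' end to ``fragment`` bases 3'-ward via a diff array."""
    delta = np.zeros(length + 1)
    if forward:
        starts, stops = ends, ends + fragment
    else:
        starts, stops = ends - fragment + 1, ends + 1
    if circular:
        starts_m = starts % length
        np.add.at(delta, starts_m, 1)
        stop_rel = starts_m + fragment
        inside = stop_rel <= length
        np.add.at(delta, stop_rel[inside], -1)
        over = stop_rel[~inside] - length
        delta[length] -= (~inside).sum()
        np.add.at(delta, np.zeros(over.size, dtype=np.int64), 1)
        np.add.at(delta, over, -1)
    else:
        starts = np.clip(starts, 0, length)
        stops = np.clip(stops, 0, length)
        np.add.at(delta, starts, 1)
        np.add.at(delta, stops, -1)
    return np.cumsum(delta[:length])


def build_coverage(
    alignments: pd.DataFrame,
    contig: str,
    length: int,
    mode: str = "end_density",
    read_length: int = 36,
    fragment_mean: int = 200,
    circular: bool = False,
) -> StrandCoverage:
    """Per-position per-strand track from one contig's alignments."""
    aln = alignments[alignments["contig"] == contig]
    p5p, p5m = five_prime_ends(aln, read_length, length, circular)
    if mode == "end_density":
        plus = np.bincount(p5p, minlength=length).astype(float)
        minus = np.bincount(p5m, minlength=length).astype(float)
    elif mode == "extended":
        fragment = int(fragment_mean)
        plus = _smear(p5p, length, fragment, True, circular)
        minus = _smear(p5m, length, fragment, False, circular)
    else:
        raise ValueError(f"unknown coverage mode {mode!r}")
    return StrandCoverage(contig, length, plus, minus, mode, circular,
                          n_reads=len(aln))


def window_sums(track: np.ndarray, starts: np.ndarray, window: int,
                circular: bool) -> np.ndarray:
    """Sum of ``track`` over [s, s+window) for each start, wrapping if circular."""
    L = track.size
    if circular:
        ext = np.concatenate([track, track[: min(window, L)]])
        cs = np.concatenate([[0.0], np.cumsum(ext)])
        starts = starts % L
        return cs[starts + window] - cs[starts]
    cs = np.concatenate([[0.0], np.cumsum(track)])
    s = np.clip(starts, 0, L)
    e = np.clip(starts + window, 0, L)
    return cs[e] - cs[s]


def tile_starts(length: int, window: int) -> np.ndarray:
    """Non-overlapping tiling starts (last window may be partial)."""
    return np.arange(0, length, window)


def grid_starts(length: int, window: int, step: int, circular: bool) -> np.ndarray:
    if circular:
        return np.arange(0, length, step)
    last = max(length - window, 0)
    return np.arange(0, last + 1, step)
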