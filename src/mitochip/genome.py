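"""Synthetic reference bundle: circular mitochondrial genome, feature
annotation, and a nuclear decoy genome carrying NUMTs and repeats.

The mitochondrial contig is a random sequence laid out with the gene
coordinates of the human reference mitochondrial genome (13 protein-coding
genes, 22 tRNAs, 2 rRNAs, the D-loop regulatory region with its promoters
and replication origins), so that coordinate-based results — in particular
the putative binding site centred at position 5175 (1-based) inside the ND2
ORF, 546 bp upstream of the light-strand replication origin O_L at 5721 —
are meaningful without shipping any real genome sequence.

The nuclear decoy is a set of linear random contigs into which diverged
partial copies of the mitochondrial sequence (NUMTs) and duplicated blocks
(repeats) are planted; both registries carry exact coordinates so tests can
interrogate every planted element.

Coordinates are 0-based half-open internally. A feature with end <= start on
the circular contig wraps through the origin (the D-loop does).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import seq as sq
from .io import write_fasta, write_bed

MT_LENGTH = 16_569
MIN_MT_LENGTH = 2_000
READ_LENGTH = 36

# (name, type, start_1based, end_1based_inclusive, strand); rCRS-like layout.
# D_loop wraps the origin; overlapping features (e.g. O_L inside the tRNA
# cluster, ATP8/ATP6 overlap) are intentional.
_MT_FEATURES_1BASED = [
    ("D_loop", "D_loop", 16024, 576, "+"),
    ("O_H", "O_H", 110, 441, "+"),
    ("LSP", "LSP", 392, 445, "-"),
    ("TFAM_site_LSP", "TFAM_site_LSP", 418, 439, "-"),
    ("TFAM_site_HSP1", "TFAM_site_HSP1", 523, 544, "+"),
    ("HSP1", "HSP1", 545, 567, "+"),
    ("tRNA-Phe", "tRNA", 577, 647, "+"),
    ("RNR1", "rRNA", 648, 1601, "+"),
    ("tRNA-Val", "tRNA", 1602, 1670, "+"),
    ("RNR2", "rRNA", 1671, 3229, "+"),
    ("tRNA-Leu1", "tRNA", 3230, 3304, "+"),
    ("ND1", "CDS", 3307, 4262, "+"),
    ("tRNA-Ile", "tRNA", 4263, 4331, "+"),
    ("tRNA-Gln", "tRNA", 4329, 4400, "-"),
    ("tRNA-Met", "tRNA", 4402, 4469, "+"),
    ("ND2", "CDS", 4470, 5511, "+"),
    ("putative_site", "putative_site", 5164, 5186, "+"),
    ("tRNA-Trp", "tRNA", 5512, 5579, "+"),
    ("tRNA-Ala", "tRNA", 5587, 5655, "-"),
    ("tRNA-Asn", "tRNA", 5657, 5729, "-"),
    ("O_L", "O_L", 5721, 5798, "-"),
    ("tRNA-Cys", "tRNA", 5761, 5826, "-"),
    ("tRNA-Tyr", "tRNA", 5826, 5891, "-"),
    ("COX1", "CDS", 5904, 7445, "+"),
    ("tRNA-Ser1", "tRNA", 7446, 7514, "-"),
    ("tRNA-Asp", "tRNA", 7518, 7585, "+"),
    ("COX2", "CDS", 7586, 8269, "+"),
    ("tRNA-Lys", "tRNA", 8295, 8364, "+"),
    ("ATP8", "CDS", 8366, 8572, "+"),
    ("ATP6", "CDS", 8527, 9207, "+"),
    ("COX3", "CDS", 9207, 9990, "+"),
    ("tRNA-Gly", "tRNA", 9991, 10058, "+"),
    ("ND3", "CDS", 10059, 10404, "+"),
    ("tRNA-Arg", "tRNA", 10405, 10469, "+"),
    ("ND4L", "CDS", 10470, 10766, "+"),
    ("ND4", "CDS", 10760, 12137, "+"),
    ("tRNA-His", "tRNA", 12138, 12206, "+"),
    ("tRNA-Ser2", "tRNA", 12207, 12265, "+"),
    ("tRNA-Leu2", "tRNA", 12266, 12336, "+"),
    ("ND5", "CDS", 12337, 14148, "+"),
    ("ND6", "CDS", 14149, 14673, "-"),
    ("tRNA-Glu", "tRNA", 14674, 14742, "-"),
    ("CYTB", "CDS", 14747, 15887, "+"),
    ("tRNA-Thr", "tRNA", 15888, 15953, "+"),
    ("tRNA-Pro", "tRNA", 15956, 16023, "-"),
    ("Ori_b", "Ori_b", 16184, 16197, "-"),
]


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class Feature:
    contig: str
    start: int  # 0-based
    end: int    # half-open; end <= start means the feature wraps the origin
    strand: str
    type: str
    name: str

    def length(self, contig_length: int) -> int:
        if self.end > self.start:
            return self.end - self.start
        return contig_length - self.start + self.end

    def center(self, contig_length: int) -> int:
        """Central position (0-based), circular-aware."""
        return (self.start + (self.length(contig_length) - 1) // 2) % contig_length


@dataclass
class FeatureAnnotation:
    features: list[Feature]

    def by_type(self, ftype: str) -> list[Feature]:
        return [f for f in self.features if f.type == ftype]

    def get(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"no feature named {name!r}")

    def type_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for f in self.features:
            counts[f.type] = counts.get(f.type, 0) + 1
        return counts

    def to_bed(self, path: str | Path, contig_length: int) -> None:
        rows = []
        for f in self.features:
            if f.end > f.start:
                rows.append((f.contig, f.start, f.end, f.name, 0, f.strand))
            else:  # split a wrapping feature into two BED lines
                rows.append((f.contig, f.start, contig_length, f.name, 0, f.strand))
                rows.append((f.contig, 0, f.end, f.name, 0, f.strand))
        write_bed(path, rows)


@dataclass
class CircularRefGenome:
    name: str
    codes: np.ndarray  # uint8 base codes
    circular: bool = True

    @property
    def length(self) -> int:
        return int(self.codes.size)

    @property
    def sequence(self) -> str:
        return sq.decode(self.codes)

    def fetch(self, start: int, end: int) -> np.ndarray:
        """Substring with circular wrap; end may exceed the length."""
        L = self.length
        idx = np.arange(start, end) % L
        return self.codes[idx]

    def to_fasta(self, path: str | Path) -> None:
        write_fasta(path, [(self.name, self.codes)])


@dataclass
class NuclearDecoyGenome:
    contigs: list[tuple[str, np.ndarray]]
    numt_registry: list[dict] = field(default_factory=list)
    repeat_registry: list[dict] = field(default_factory=list)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: int(c.size) for name, c in self.contigs}

    @property
    def total_size(self) -> int:
        return sum(c.size for _, c in self.contigs)

    def to_fasta(self, path: str | Path) -> None:
        write_fasta(path, self.contigs)

    def registries_to_bed(self, path: str | Path) -> None:
        rows = [(r["contig"], r["ins_start"], r["ins_end"],
                 f"NUMT:{r['src_start']}-{r['src_end']}:{r['n_sub']}sub", 0, "+")
                for r in self.numt_registry]
        rows += [(r["contig"], r["start"], r["end"], f"repeat:{r['kind']}", 0, "+")
                 for r in self.repeat_registry]
        write_bed(path, rows)


@dataclass
class ReferenceBundle:
    """Everything downstream stages need: chrM + annotation (+ decoy)."""

    chrm: CircularRefGenome
    annotation: FeatureAnnotation
    decoy: NuclearDecoyGenome | None = None

    def contig_codes(self) -> list[tuple[str, np.ndarray]]:
        out = [(self.chrm.name, self.chrm.codes)]
        if self.decoy is not None:
            out += self.decoy.contigs
        return out

    def contig_lengths(self) -> dict[str, int]:
        return {name: int(c.size) for name, c in self.contig_codes()}

    def circular_contigs(self) -> set[str]:
        return {self.chrm.name}


def default_annotation(contig: str = "chrM", length: int = MT_LENGTH) -> FeatureAnnotation:
    """The bundled annotation; for shorter genomes only the features that
    fit are kept (the full invariant set requires the default length)."""
    feats = []
    for name, ftype, s1, e1, strand in _MT_FEATURES_1BASED:
        start, end = s1 - 1, e1  # 1-based inclusive -> 0-based half-open
        wraps = end <= start
        if length != MT_LENGTH:
            if wraps or end > length:
                continue
        feats.append(Feature(contig, start, end, strand, ftype, name))
    return FeatureAnnotation(feats)


def make_chrm_reference(
    seed: int = 0, length: int = MT_LENGTH, name: str = "chrM"
) -> tuple[CircularRefGenome, FeatureAnnotation]:
    """Random-sequence circular mitochondrial reference plus annotation."""
    if length < MIN_MT_LENGTH:
        raise ConfigurationError(
            f"chrM length {length} below minimum {MIN_MT_LENGTH}"
        )
    rng = np.random.default_rng(seed)
    genome = CircularRefGenome(name, sq.random_codes(rng, length))
    return genome, default_annotation(name, length)


def load_chrm_reference(
    fasta_path: str | Path, name: str | None = None
) -> tuple[CircularRefGenome, FeatureAnnotation]:
    """Use a real (user-supplied) mitochondrial FASTA with the bundled
    annotation layout. The contig must match the default length for the full
    annotation to apply."""
    from .io import read_fasta

    contigs = read_fasta(fasta_path)
    if name is None:
        name, codes = contigs[0]
    else:
        codes = dict(contigs)[name]
    genome = CircularRefGenome(name, codes)
    return genome, default_annotation(name, genome.length)


def _kmer_hash_set(codes: np.ndarray, k: int) -> np.ndarray:
    from .mapping import kmer_hashes  # local import to avoid cycle

    if codes.size < k:
        return np.empty(0, dtype=np.uint64)
    fwd = kmer_hashes(codes, k)
    rev = kmer_hashes(sq.revcomp(codes), k)
    return np.union1d(fwd, rev)


def make_nuclear_decoy(
    seed: int,
    chrm: CircularRefGenome,
    n_contigs: int = 2,
    total_size: int = 5_000_000,
    n_numts: int = 3,
    numt_lengths: Sequence[int] | None = None,
    divergence: float = 0.05,
    n_repeats: int = 3,
    repeat_length: int = 500,
    repeat_flank: int = 300,
    read_length: int = READ_LENGTH,
) -> NuclearDecoyGenome:
    """Linear decoy contigs with planted NUMTs and duplicated repeat blocks.

    Each NUMT is a copy of a chrM interval carrying exactly
    ``round(divergence * length)`` substitutions at distinct positions.
    Each repeat is a block duplicated at a second locus; the registry
    records the duplicated core plus ``repeat_flank`` of unique sequence on
    either side (the interval the artifact read model piles onto).
    """
    if numt_lengths is None:
        numt_lengths = [800, 1500, 3000][:n_numts] or []
        while len(numt_lengths) < n_numts:
            numt_lengths = list(numt_lengths) + [1000]
    numt_lengths = list(numt_lengths)[:n_numts]
    for ln in numt_lengths:
        if ln < read_length:
            raise ConfigurationError(f"NUMT length {ln} shorter than a read")
        if ln > chrm.length:
            raise ConfigurationError(f"NUMT length {ln} exceeds chrM length")
    if divergence < 0:
        raise ConfigurationError("divergence must be >= 0")

    rng = np.random.default_rng(seed)
    sizes = [total_size // n_contigs] * n_contigs
    sizes[-1] += total_size - sum(sizes)

    # Background draw, redrawn in the (astronomically unlikely) event that a
    # random contig shares a k-mer with chrM.
    chrm_kmers = _kmer_hash_set(chrm.codes, read_length)
    contigs: list[tuple[str, np.ndarray]] = []
    for i, size in enumerate(sizes):
        for _attempt in range(5):
            codes = sq.random_codes(rng, size)
            if np.intersect1d(
                _kmer_hash_set(codes, read_length), chrm_kmers
            ).size == 0:
                break
        contigs.append((f"nuc{i + 1}", codes))

    occupied: dict[str, list[tuple[int, int]]] = {name: [] for name, _ in contigs}

    def _place(name_len: int, span: int) -> tuple[str, int]:
        for _ in range(1000):
            ci = int(rng.integers(0, n_contigs))
            cname, ccodes = contigs[ci]
            if ccodes.size < span + 2 * repeat_flank:
                continue
            pos = int(rng.integers(repeat_flank, ccodes.size - span - repeat_flank))
            if all(pos + span <= s or pos >= e for s, e in occupied[cname]):
                occupied[cname].append((pos, pos + span))
                return cname, pos
        raise ConfigurationError("could not place element without overlap")

    repeat_registry: list[dict] = []
    for _ in range(n_repeats):
        src_name, src_pos = _place("repeat-src", repeat_length)
        src_codes = dict(contigs)[src_name][src_pos:src_pos + repeat_length].copy()
        dst_name, dst_pos = _place("repeat-dst", repeat_length)
        dict(contigs)[dst_name][dst_pos:dst_pos + repeat_length] = src_codes
        for cname, pos, kind in ((src_name, src_pos, "source"),
                                 (dst_name, dst_pos, "copy")):
            repeat_registry.append({
                "contig": cname,
                "core_start": pos,
                "core_end": pos + repeat_length,
                "start": max(0, pos - repeat_flank),
                "end": pos + repeat_length + repeat_flank,
                "kind": kind,
            })

    numt_registry: list[dict] = []
    for ln in numt_lengths:
        src_start = int(rng.integers(0, chrm.length - ln))
        insert = chrm.codes[src_start:src_start + ln].copy()
        n_sub = int(round(divergence * ln))
        if n_sub > 0:
            pos = rng.choice(ln, size=n_sub, replace=False)
            insert[pos] = (insert[pos] + rng.integers(1, 4, size=n_sub)) % 4
        cname, ins = _place("numt", ln)
        dict(contigs)[cname][ins:ins + ln] = insert
        numt_registry.append({
            "contig": cname,
            "ins_start": ins,
            "ins_end": ins + ln,
            "src_start": src_start,
            "src_end": src_start + ln,
            "n_sub": n_sub,
        })

    return NuclearDecoyGenome(contigs, numt_registry, repeat_registry)
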