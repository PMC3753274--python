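"""Zero-mismatch short-read mapping and chrM/nuclear read partitioning.

The aligner is an exhaustive exact-match k-mer index: every read placement
with zero mismatches, on either strand of any contig, is found. Circular
contigs are indexed as sequence plus the first k-1 bases so placements that
wrap the origin are reported at their (mod L) coordinate. Reads are
classified unique / multi / unmapped by their total perfect placement count
across the whole reference set.

Implementation: a 64-bit polynomial rolling hash over all reference windows,
sorted once; queries binary-search the hash array and every candidate is
verified base-by-base against the reference, so hash collisions cannot
produce false placements.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import seq as sq
from .io import ReadSet, read_fastq, write_fastq, dump_json

_HASH_BASE = np.uint64(1_099_511_628_211)  # FNV prime, odd => invertible mod 2^64

STATUS_UNMAPPED = "unmapped"
STATUS_UNIQUE = "unique"
STATUS_MULTI = "multi"


def kmer_hashes(codes: np.ndarray, k: int) -> np.ndarray:
    """Rolling polynomial hash of every k-window (mod 2**64)."""
    codes = np.asarray(codes, dtype=np.uint64)
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    h = np.zeros(n, dtype=np.uint64)
    with np.errstate(over="ignore"):
        for j in range(k):
            h = h * _HASH_BASE + codes[j:j + n]
    return h


def _row_hashes(codes2d: np.ndarray) -> np.ndarray:
    c = np.asarray(codes2d, dtype=np.uint64)
    h = np.zeros(c.shape[0], dtype=np.uint64)
    with np.errstate(over="ignore"):
        for j in range(c.shape[1]):
            h = h * _HASH_BASE + c[:, j]
    return h


class ExactMatchIndex:
    """All perfect placements of a k-mer, both strands, over a contig set."""

    def __init__(
        self,
        contigs: Sequence[tuple[str, np.ndarray]],
        k: int = 36,
        circular: set[str] | frozenset[str] = frozenset(),
    ) -> None:
        self.k = int(k)
        self.contig_names = [name for name, _ in contigs]
        self.circular = set(circular)
        segments: list[np.ndarray] = []
        seg_offsets: list[int] = []
        self.contig_lengths: dict[str, int] = {}
        win_pos: list[np.ndarray] = []
        offset = 0
        for name, codes in contigs:
            codes = np.asarray(codes, dtype=np.uint8)
            if codes.max(initial=0) > 3:
                raise ValueError(f"ambiguity codes in contig {name}")
            L = codes.size
            self.contig_lengths[name] = int(L)
            if name in self.circular:
                ext = np.concatenate([codes, codes[: self.k - 1]])
                n_win = L  # window starts 0..L-1 cover all wrapped placements
            else:
                ext = codes
                n_win = max(L - self.k + 1, 0)
            segments.append(ext)
            seg_offsets.append(offset)
            win_pos.append(offset + np.arange(n_win, dtype=np.int64))
            offset += ext.size
        self._concat = np.concatenate(segments) if segments else np.empty(0, np.uint8)
        self._seg_offsets = np.asarray(seg_offsets, dtype=np.int64)
        positions = (np.concatenate(win_pos) if win_pos
                     else np.empty(0, dtype=np.int64))
        hashes = np.concatenate(
            [kmer_hashes(seg, self.k) for seg in segments]
        ) if segments else np.empty(0, np.uint64)
        order = np.argsort(hashes, kind="stable")
        self._sorted_h = hashes[order]
        self._sorted_pos = positions[order]

    def _global_to_contig(self, gpos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ci = np.searchsorted(self._seg_offsets, gpos, side="right") - 1
        return ci, gpos - self._seg_offsets[ci]

    def _candidates(self, hashes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        left = np.searchsorted(self._sorted_h, hashes, side="left")
        right = np.searchsorted(self._sorted_h, hashes, side="right")
        counts = right - left
        total = int(counts.sum())
        if total == 0:
            return (np.empty(0, np.int64),) * 2
        read_idx = np.repeat(np.arange(hashes.size), counts)
        cum = np.concatenate([[0], np.cumsum(counts)[:-1]])
        flat = np.repeat(left, counts) + (np.arange(total) - np.repeat(cum, counts))
        return read_idx, self._sorted_pos[flat]

    def _verify(self, read_idx, gpos, query_codes) -> np.ndarray:
        if read_idx.size == 0:
            return np.empty(0, dtype=bool)
        win = self._concat[gpos[:, None] + np.arange(self.k)]
        return (win == query_codes[read_idx]).all(axis=1)

    def lookup(self, codes2d: np.ndarray):
        """All verified placements for each query k-mer row.

        Returns (read_idx, contig_idx, local_pos, strand_is_minus) arrays,
        one entry per placement.
        """
        codes2d = np.asarray(codes2d, dtype=np.uint8)
        if codes2d.shape[1] != self.k:
            raise ValueError(
                f"query length {codes2d.shape[1]} != index k-mer size {self.k}"
            )
        parts = []
        for strand_minus, query in ((False, codes2d), (True, sq.revcomp(codes2d))):
            query = np.ascontiguousarray(query)
            ridx, gpos = self._candidates(_row_hashes(query))
            ok = self._verify(ridx, gpos, query)
            ridx, gpos = ridx[ok], gpos[ok]
            ci, lpos = self._global_to_contig(gpos)
            strand = np.full(ridx.size, strand_minus)
            parts.append((ridx, ci, lpos, strand))
        read_idx = np.concatenate([p[0] for p in parts])
        contig_idx = np.concatenate([p[1] for p in parts])
        local_pos = np.concatenate([p[2] for p in parts])
        minus = np.concatenate([p[3] for p in parts])
        return read_idx, contig_idx, local_pos, minus


def trim_reads(
    ids: Sequence[str], seqs: Sequence[str], target_length: int = 36
) -> tuple[ReadSet, int]:
    """Keep the 5' ``target_length`` bases of each read; drop shorter reads."""
    if not ids:
        raise ValueError("empty read input")
    keep_ids: list[str] = []
    rows: list[np.ndarray] = []
    dropped = 0
    for rid, s in zip(ids, seqs):
        if len(s) < target_length:
            dropped += 1
            continue
        keep_ids.append(rid)
        rows.append(sq.encode(s[:target_length]))
    codes = (np.vstack(rows) if rows
             else np.empty((0, target_length), dtype=np.uint8))
    return ReadSet(keep_ids, codes), dropped


def trim_fastq(
    fastq_in: str | Path, fastq_out: str | Path, target_length: int = 36
) -> dict:
    ids, seqs = read_fastq(fastq_in)
    reads, dropped = trim_reads(ids, seqs, target_length)
    reads.to_fastq(fastq_out)
    return {"input": len(ids), "retained": len(reads), "dropped_short": dropped}


def map_reads(
    reads: ReadSet,
    index: ExactMatchIndex,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Classify every read by exhaustive perfect-match placement.

    Returns a frame with columns read_id, contig, pos, strand, status,
    n_hits. Unique reads carry their placement; multireads carry one
    placement chosen uniformly at random when ``rng`` is given (used for
    the chrM-only pass), else no placement.
    """
    n = len(reads)
    ridx, ci, lpos, minus = index.lookup(reads.codes)
    n_hits = np.bincount(ridx, minlength=n).astype(np.int64)

    contig = np.full(n, "*", dtype=object)
    pos = np.full(n, -1, dtype=np.int64)
    strand = np.full(n, "*", dtype=object)

    order = np.argsort(ridx, kind="stable")
    ridx_s, ci_s, lpos_s, minus_s = ridx[order], ci[order], lpos[order], minus[order]
    starts = np.concatenate([[0], np.cumsum(np.bincount(ridx_s, minlength=n))])[:-1]

    hit_reads = np.flatnonzero(n_hits > 0)
    if rng is None:
        chosen_reads = np.flatnonzero(n_hits == 1)
        sel = starts[chosen_reads]
    else:
        chosen_reads = hit_reads
        sel = starts[chosen_reads] + (
            rng.random(chosen_reads.size) * n_hits[chosen_reads]
        ).astype(np.int64)
    names = np.asarray(index.contig_names, dtype=object)
    contig[chosen_reads] = names[ci_s[sel]]
    pos[chosen_reads] = lpos_s[sel]
    strand[chosen_reads] = np.where(minus_s[sel], "-", "+")

    status = np.full(n, STATUS_UNMAPPED, dtype=object)
    status[n_hits == 1] = STATUS_UNIQUE
    status[n_hits > 1] = STATUS_MULTI
    return pd.DataFrame({
        "read_id": list(reads.ids),
        "contig": contig,
        "pos": pos,
        "strand": strand,
        "status": status,
        "n_hits": n_hits,
    })


@dataclass
class PartitionResult:
    """Outcome of the two-pass mapping strategy.

    chrm_reads: placements from the chrM-only pass (any read with >=1
    perfect chrM placement; intra-chrM multireads randomly placed).
    nuclear_reads: unique whole-genome placements of reads with no chrM
    placement, excluding any that land on chrM (none can, by construction).
    """

    chrm_reads: pd.DataFrame
    nuclear_reads: pd.DataFrame
    counts: dict = field(default_factory=dict)

    def write(self, outdir: str | Path, prefix: str = "library") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.chrm_reads.to_csv(outdir / f"{prefix}.chrm.tsv", sep="\t", index=False)
        self.nuclear_reads.to_csv(
            outdir / f"{prefix}.nuclear.tsv", sep="\t", index=False
        )
        dump_json(outdir / f"{prefix}.counts.json", self.counts)


def partition(
    reads: ReadSet,
    chrm_index: ExactMatchIndex,
    genome_index: ExactMatchIndex,
    seed: int = 0,
) -> PartitionResult:
    """chrM-only pass, then whole-genome pass for the chrM-free remainder."""
    rng = np.random.default_rng(seed)
    chrm_aln = map_reads(reads, chrm_index, rng=rng)
    on_chrm = (chrm_aln["status"] != STATUS_UNMAPPED).to_numpy()
    chrm_reads = chrm_aln.loc[on_chrm].reset_index(drop=True)

    rest = reads.subset(~on_chrm)
    genome_aln = map_reads(rest, genome_index)
    status = genome_aln["status"].to_numpy()
    nuclear_reads = genome_aln.loc[status == STATUS_UNIQUE].reset_index(drop=True)
    n_multi = int((status == STATUS_MULTI).sum())
    n_unmapped = int((status == STATUS_UNMAPPED).sum())

    counts = {
        "total": len(reads),
        "chrM_mapped": int(on_chrm.sum()),
        "nuclear_unique": int(len(nuclear_reads)),
        "multi": n_multi,
        "unmapped": n_unmapped,
    }
    counts["mapped"] = counts["chrM_mapped"] + counts["nuclear_unique"] + n_multi
    return PartitionResult(chrm_reads, nuclear_reads, counts)


def write_sam(
    alignments: pd.DataFrame,
    contig_lengths: Mapping[str, int],
    path: str | Path,
    read_length: int = 36,
) -> None:
    """Optional SAM export of placed alignments (mandatory fields only)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": int(l)} for n, l in contig_lengths.items()],
    }
    tid = {n: i for i, n in enumerate(contig_lengths)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for row in alignments.itertuples(index=False):
            a = pysam.AlignedSegment(fh.header)
            a.query_name = str(row.read_id)
            if row.contig == "*" or row.pos < 0:
                a.flag = 4
                a.reference_id = -1
            else:
                a.flag = 16 if row.strand == "-" else 0
                a.reference_id = tid[row.contig]
                a.reference_start = int(row.pos)
                a.mapping_quality = 255
                a.cigarstring = f"{read_length}M"
            fh.write(a)
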