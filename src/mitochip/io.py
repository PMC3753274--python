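"""File-format glue: FASTA/FASTQ/BED/bedGraph and the in-memory read set.

FASTQ is single-end Phred+33 with a constant quality string, matching the
simulator's error-free default. FASTA reading goes through pyfaidx so that
user-supplied references (e.g. a real mitochondrial genome) work unchanged.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam
from pyfaidx import Fasta

from . import seq as sq


@dataclass
class ReadSet:
    """Fixed-length single-end reads: ids plus an (n, read_length) code matrix."""

    ids: list[str]
    codes: np.ndarray  # uint8, shape (n, read_length)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D (n_reads, read_length) array")
        if len(self.ids) != self.codes.shape[0]:
            raise ValueError("ids and codes disagree on read count")

    def __len__(self) -> int:
        return self.codes.shape[0]

    @property
    def read_length(self) -> int:
        return self.codes.shape[1]

    def sequences(self) -> list[str]:
        return [sq.decode(row) for row in self.codes]

    def subset(self, mask_or_index: np.ndarray) -> "ReadSet":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return ReadSet([self.ids[i] for i in idx], self.codes[idx])

    def to_fastq(self, path: str | Path) -> None:
        write_fastq(path, self.ids, self.codes)

    @classmethod
    def from_fastq(cls, path: str | Path) -> "ReadSet":
        ids, seqs = read_fastq(path)
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise ValueError(
                "reads of mixed length; trim first (trim_reads / trim_fastq)"
            )
        n = len(seqs)
        k = lengths.pop() if lengths else 0
        codes = np.empty((n, k), dtype=np.uint8)
        for i, s in enumerate(seqs):
            codes[i] = sq.encode(s)
        return cls(ids, codes)


def read_fastq(path: str | Path) -> tuple[list[str], list[str]]:
    ids: list[str] = []
    seqs: list[str] = []
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            ids.append(rec.name)
            seqs.append(rec.sequence)
    if not ids:
        raise ValueError(f"empty FASTQ: {path}")
    return ids, seqs


def write_fastq(path: str | Path, ids: Sequence[str], codes: np.ndarray) -> None:
    """Write reads with constant quality 'I' (Phred 40)."""
    qual = "I" * codes.shape[1]
    chunks: list[str] = []
    for rid, row in zip(ids, codes):
        chunks.append(f"@{rid}\n{sq.decode(row)}\n+\n{qual}\n")
    Path(path).write_text("".join(chunks))


def write_fasta(path: str | Path, contigs: Iterable[tuple[str, np.ndarray]],
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, codes in contigs:
            fh.write(f">{name}\n")
            s = sq.decode(codes)
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def read_fasta(path: str | Path) -> list[tuple[str, np.ndarray]]:
    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True, rebuild=True)
    return [(name, sq.encode(str(fa[name][:]))) for name in fa.keys()]


def write_bed(path: str | Path, rows: Iterable[tuple], header: str | None = None) -> None:
    """BED6-style writer; rows are (contig, start, end, name, score, strand)."""
    with open(path, "w") as fh:
        if header:
            fh.write(header.rstrip("\n") + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_bedgraph(path: str | Path, contig: str, values: np.ndarray) -> None:
    """Run-length-compressed bedGraph of a per-position track."""
    values = np.asarray(values)
    change = np.flatnonzero(np.diff(values)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [values.size]])
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            v = values[s]
            if v != 0:
                fh.write(f"{contig}\t{s}\t{e}\t{v:g}\n")


def dump_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
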