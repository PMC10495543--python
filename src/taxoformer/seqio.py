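"""Sequence I/O: FASTA/FASTQ streaming, read pairing, bounded-memory batching.

Readers normalise sequences to uppercase {A,C,G,T,N}; any other letter
(IUPAC ambiguity codes are common in metagenome-assembled genomes) is
replaced by N and counted in a logged warning.  All readers and writers are
gzip-transparent based on the filename suffix.

Parsing delegates to Bio.SeqIO; this module adds the normalisation, the
paired-end id conventions (trailing ``/1``/``/2`` or a whitespace-separated
mate field) and a bounded buffer shuffle so that training never needs the
whole read set in memory.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Union

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")


@dataclass
class ReadRecord:
    """A sequencing read, optionally with quality, mate flag and truth labels."""

    id: str
    sequence: str
    quality: Optional[str] = None
    mate: Optional[int] = None  # 1 or 2 for paired data
    truth_labels: Optional[Dict[str, str]] = None  # level -> class id

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )
        if self.mate not in (None, 1, 2):
            raise ValueError(f"record {self.id!r}: mate must be 1 or 2")


@dataclass
class GenomeRecord:
    """A labelled reference genome; ``labels`` maps taxonomic level to class id."""

    id: str
    sequence: str
    labels: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"genome {self.id!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


def _open_text(path: Union[str, Path], mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _normalize(seq: str, rid: str, counter: Dict[str, int]) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError(f"record {rid!r} has an empty sequence")
    bad = sum(1 for c in seq if c not in _VALID)
    if bad:
        counter["replaced"] = counter.get("replaced", 0) + bad
        seq = "".join(c if c in _VALID else "N" for c in seq)
    return seq


def read_fasta(path: Union[str, Path]) -> Iterator[ReadRecord]:
    """Stream records from a (possibly gzipped) FASTA file.

    Sequences are uppercased; non-ACGTN letters become N (total count logged
    once at end of stream).  An empty file is an error.
    """
    counter: Dict[str, int] = {}
    n = 0
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = _normalize(str(rec.seq), rec.id, counter)
            n += 1
            yield ReadRecord(id=rec.id, sequence=seq)
    if n == 0:
        raise ValueError(f"{path}: empty FASTA file")
    if counter.get("replaced"):
        logger.warning("%s: replaced %d non-ACGTN characters with N", path, counter["replaced"])


def read_fastq(path: Union[str, Path]) -> Iterator[ReadRecord]:
    """Stream records from a (possibly gzipped) 4-line FASTQ file.

    Quality strings are retained (the classifier itself ignores them).
    """
    counter: Dict[str, int] = {}
    n = 0
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            seq = _normalize(str(rec.seq), rec.id, counter)
            n += 1
            yield ReadRecord(id=rec.id, sequence=seq, quality=qual)
    if n == 0:
        raise ValueError(f"{path}: empty FASTQ file")
    if counter.get("replaced"):
        logger.warning("%s: replaced %d non-ACGTN characters with N", path, counter["replaced"])


def read_sequences(path: Union[str, Path]) -> Iterator[ReadRecord]:
    """Dispatch on suffix: .fa/.fasta/.fna -> FASTA, .fq/.fastq -> FASTQ."""
    name = Path(path).name
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith((".fq", ".fastq")):
        return read_fastq(path)
    return read_fasta(path)


def write_fasta(records: Iterable[ReadRecord], path: Union[str, Path]) -> int:
    """Write records as FASTA; returns the record count.

    FASTA has no portable comment syntax, so provenance headers go on the
    TSV side-car files instead.
    """
    n = 0
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")
            n += 1
    return n


def write_fastq(records: Iterable[ReadRecord], path: Union[str, Path]) -> int:
    """Write records as 4-line FASTQ; missing qualities become 'I' (Q40)."""
    n = 0
    with _open_text(path, "wt") as fh:
        for rec in records:
            qual = rec.quality if rec.quality is not None else "I" * len(rec.sequence)
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")
            n += 1
    return n


def _strip_mate(rid: str) -> str:
    if rid.endswith("/1") or rid.endswith("/2"):
        return rid[:-2]
    return rid


def interleave_pairs(
    stream_r1: Iterable[ReadRecord], stream_r2: Iterable[ReadRecord]
) -> Iterator[ReadRecord]:
    """Interleave mate streams as r1_1, r2_1, r1_2, r2_2, ... with mate flags set.

    Ids must match up to trailing ``/1``/``/2`` suffixes; a mismatch or a
    length difference raises.
    """
    it1, it2 = iter(stream_r1), iter(stream_r2)
    pos = 0
    while True:
        r1 = next(it1, None)
        r2 = next(it2, None)
        if r1 is None and r2 is None:
            return
        if r1 is None or r2 is None:
            raise ValueError(f"paired streams have different lengths (at pair {pos})")
        if _strip_mate(r1.id) != _strip_mate(r2.id):
            raise ValueError(
                f"pair id mismatch at position {pos}: {r1.id!r} vs {r2.id!r}"
            )
        r1.mate, r2.mate = 1, 2
        yield r1
        yield r2
        pos += 1


def stream_batches(
    stream: Iterable,
    batch_size: int,
    shuffle_buffer: int = 0,
    seed: int = 0,
) -> Iterator[List]:
    """Group a stream into batches with an optional bounded buffer shuffle.

    Every record is emitted exactly once; at most ``shuffle_buffer +
    batch_size`` records are held at a time.  ``shuffle_buffer=0`` preserves
    input order.  A fixed seed gives an identical batch sequence on every
    run.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    rng = np.random.default_rng(seed)
    batch: List = []

    def emit(rec):
        batch.append(rec)
        if len(batch) == batch_size:
            out = list(batch)
            batch.clear()
            return out
        return None

    if shuffle_buffer <= 0:
        for rec in stream:
            full = emit(rec)
            if full is not None:
                yield full
    else:
        buf: List = []
        for rec in stream:
            if len(buf) < shuffle_buffer:
                buf.append(rec)
                continue
            j = int(rng.integers(0, shuffle_buffer))
            out_rec, buf[j] = buf[j], rec
            full = emit(out_rec)
            if full is not None:
                yield full
        # drain the buffer in random order
        while buf:
            j = int(rng.integers(0, len(buf)))
            buf[j], buf[-1] = buf[-1], buf[j]
            full = emit(buf.pop())
            if full is not None:
                yield full
    if batch:
        yield batch
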