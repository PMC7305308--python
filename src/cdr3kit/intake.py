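"""Candidate receptor-read intake.

Produces the candidate read set for assembly, either from an indexed
coordinate-sorted SAM/BAM (reads overlapping the Ig loci -- including
soft-clipped alignments with the full original sequence restored -- merged
with all unmapped reads) or directly from FASTQ. A light preprocessing
filter drops low-quality and low-complexity reads, and optionally reads
matching an rRNA reference by exact 31-mer hit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

DEFAULT_MIN_MEAN_QUALITY = 20.0
#: Dinucleotide Shannon-entropy floor (bits); a cheap DUST-like proxy that
#: removes homopolymer/simple-repeat reads while keeping real CDR3 reads.
DEFAULT_MIN_DINUCLEOTIDE_ENTROPY = 1.0
_RRNA_K = 31


@dataclass
class CandidateRead:
    """A read admitted to assembly."""

    read_id: str
    nt_seq: str
    origin: str  # ig_mapped_clipped | unmapped | direct_fastq
    mate: Optional[int] = None
    qualities: Optional[list[int]] = None

    @property
    def key(self) -> tuple[str, Optional[int]]:
        return (self.read_id, self.mate)


def read_bed(path: str) -> list[tuple[str, int, int]]:
    """Ig locus intervals from a (at least 3-column) BED file."""
    table = pd.read_csv(
        path, sep="\t", header=None, comment="#", usecols=[0, 1, 2],
        names=["chrom", "start", "end"], dtype={0: str, 1: int, 2: int},
    )
    return list(table.itertuples(index=False, name=None))


def extract_candidates_bam(
    path: str, ig_regions: Iterable[tuple[str, int, int]]
) -> Iterator[CandidateRead]:
    """Stream candidate reads from an indexed, coordinate-sorted alignment.

    Emits (a) reads overlapping the supplied Ig intervals -- pysam's
    ``query_sequence`` already restores the full read for soft-clipped
    alignments -- and (b) every unmapped read; duplicates are removed by
    (read id, mate).
    """
    seen: set[tuple[str, Optional[int]]] = set()
    n = 0
    with pysam.AlignmentFile(path) as bam:
        for chrom, start, end in ig_regions:
            if chrom not in bam.references:
                logger.warning("reference %s absent from %s; skipped", chrom, path)
                continue
            for aln in bam.fetch(chrom, start, end):
                if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                    continue
                read = _from_alignment(aln, origin="ig_mapped_clipped")
                if read is not None and read.key not in seen:
                    seen.add(read.key)
                    n += 1
                    yield read
        for aln in bam.fetch("*"):
            if not aln.is_unmapped:
                continue
            read = _from_alignment(aln, origin="unmapped")
            if read is not None and read.key not in seen:
                seen.add(read.key)
                n += 1
                yield read
    if n == 0:
        logger.warning("%s yielded no candidate reads; repertoire will be empty", path)


def _from_alignment(aln: pysam.AlignedSegment, origin: str) -> Optional[CandidateRead]:
    seq = aln.query_sequence
    if not seq:
        return None
    if aln.is_reverse:
        # report reads in their original (sequencer) orientation
        from .germline import revcomp

        seq = revcomp(seq)
        quals = list(aln.query_qualities)[::-1] if aln.query_qualities is not None else None
    else:
        quals = list(aln.query_qualities) if aln.query_qualities is not None else None
    mate = 1 if aln.is_read1 else (2 if aln.is_read2 else None)
    return CandidateRead(
        read_id=aln.query_name, nt_seq=seq.upper(), origin=origin,
        mate=mate, qualities=quals,
    )


def read_fastq(path: str, origin: str = "direct_fastq") -> Iterator[CandidateRead]:
    """Stream a FASTQ file (plain or gzip) as candidate reads."""
    with pysam.FastxFile(path) as fh:
        for entry in fh:
            name, mate = entry.name, None
            if name.endswith("/1") or name.endswith("/2"):
                mate = int(name[-1])
                name = name[:-2]
            elif name.endswith("_1") or name.endswith("_2"):
                mate = int(name[-1])
            yield CandidateRead(
                read_id=name,
                nt_seq=entry.sequence.upper(),
                origin=origin,
                mate=mate,
                qualities=entry.get_quality_array(),
            )


def dinucleotide_entropy(seq: str) -> float:
    """Shannon entropy (bits) of the overlapping-dinucleotide composition."""
    if len(seq) < 2:
        return 0.0
    counts: dict[str, int] = {}
    for i in range(len(seq) - 1):
        pair = seq[i : i + 2]
        counts[pair] = counts.get(pair, 0) + 1
    total = len(seq) - 1
    return -sum((c / total) * math.log2(c / total) for c in counts.values())


def _kmer_set(path: str, k: int) -> set[str]:
    kmers: set[str] = set()
    with pysam.FastxFile(path) as fh:
        for entry in fh:
            seq = entry.sequence.upper()
            for i in range(len(seq) - k + 1):
                kmers.add(seq[i : i + k])
    return kmers


def quality_filter(
    reads: Iterable[CandidateRead],
    min_mean_quality: float = DEFAULT_MIN_MEAN_QUALITY,
    min_entropy: float = DEFAULT_MIN_DINUCLEOTIDE_ENTROPY,
    rrna_fasta: Optional[str] = None,
) -> Iterator[CandidateRead]:
    """Drop low-quality, low-complexity and (optionally) rRNA-matching reads.

    Reads without quality strings are kept (quality rule inapplicable); the
    rRNA filter requires an exact 31-mer shared with the supplied FASTA and
    is off unless a path is given. Survivor identity is order-independent.
    """
    rrna_kmers = _kmer_set(rrna_fasta, _RRNA_K) if rrna_fasta else None
    for read in reads:
        if read.qualities is not None and len(read.qualities) > 0:
            if sum(read.qualities) / len(read.qualities) < min_mean_quality:
                continue
        if dinucleotide_entropy(read.nt_seq) < min_entropy:
            continue
        if rrna_kmers is not None and _hits_kmers(read.nt_seq, rrna_kmers):
            continue
        yield read


def _hits_kmers(seq: str, kmers: set[str]) -> bool:
    return any(seq[i : i + _RRNA_K] in kmers for i in range(len(seq) - _RRNA_K + 1))
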