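"""Spliced-alignment input: prepare (merge/sort/index) and split-read streaming.

The prepare stage normalises any mix of SAM/BAM inputs into a single
coordinate-sorted, indexed BAM plus a faidx-indexed genome, so that the rest
of the pipeline can assume random access and sorted iteration.  Split reads
are then streamed out of reference-skip (``N``) CIGAR operations, one record
per skip, with the per-side mismatch geometry needed by MaxMMES computed
against the genome on the way through.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import pysam

from .model import SplitReadSupport

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# CIGAR op codes
_MATCH_OPS = {0, 7, 8}  # M, =, X consume both
_REF_SKIP = 3  # N


class FormatError(ValueError):
    """Input file could not be parsed in its declared format."""


class ConsistencyError(ValueError):
    """Alignments and genome disagree (unknown contig, out-of-bounds)."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PreparedInput:
    """A single sorted, indexed alignment file plus an indexed genome."""

    alignment_path: str
    genome_path: str
    read_count: int
    source_count: int


@dataclass
class SplitReadRecord:
    """One reference-skip operation of one aligned read."""

    read_id: str
    contig: str
    left_anchor: tuple[int, int]
    intron: tuple[int, int]
    right_anchor: tuple[int, int]
    uniquely_mapped: bool
    properly_paired: bool
    introns_in_read: int
    mismatches: int
    read_length: int
    left_match_run: int
    right_match_run: int

    def to_support(self) -> SplitReadSupport:
        return SplitReadSupport(
            read_id=self.read_id,
            left_anchor_start=self.left_anchor[0],
            left_anchor_end=self.left_anchor[1],
            right_anchor_start=self.right_anchor[0],
            right_anchor_end=self.right_anchor[1],
            uniquely_mapped=self.uniquely_mapped,
            properly_paired=self.properly_paired,
            introns_in_read=self.introns_in_read,
            mismatches=self.mismatches,
            read_length=self.read_length,
            left_match_run=self.left_match_run,
            right_match_run=self.right_match_run,
        )


@dataclass
class Diagnostics:
    """Tally of records seen and skipped while streaming split reads."""

    records_read: int = 0
    records_unmapped: int = 0
    records_secondary: int = 0
    skips_out_of_bounds: int = 0
    skips_no_anchor: int = 0
    split_records_emitted: int = 0
    notes: list[str] = field(default_factory=list)


def prepare(
    alignment_paths: Sequence[str],
    genome_path: str,
    workdir: Optional[str] = None,
) -> PreparedInput:
    """Merge, coordinate-sort and index alignments; index the genome.

    Returns a :class:`PreparedInput` pointing at a single BAM.  ``read_count``
    is the total number of alignment records across all inputs.  Raises
    :class:`FormatError` for unparseable input and :class:`ConsistencyError`
    when an alignment names a contig absent from the genome.
    """
    if not alignment_paths:
        raise ValueError("at least one alignment file required")
    for p in list(alignment_paths) + [genome_path]:
        if not os.path.exists(p):
            raise FormatError(f"input file not found: {p}")

    try:
        genome = pysam.FastaFile(genome_path)  # builds .fai if missing
    except Exception as exc:  # pragma: no cover - pysam raises various types
        raise FormatError(f"genome is not valid FASTA: {genome_path}: {exc}") from exc
    genome_contigs = set(genome.references)
    genome.close()

    if workdir is None:
        workdir = os.path.dirname(os.path.abspath(alignment_paths[0])) or "."
    os.makedirs(workdir, exist_ok=True)
    merged = os.path.join(workdir, "prepared.bam")
    sorted_bam = os.path.join(workdir, "prepared.sorted.bam")

    read_count = 0
    try:
        handles = [pysam.AlignmentFile(p, check_sq=False) for p in alignment_paths]
    except ValueError as exc:
        raise FormatError(f"unparseable alignment input: {exc}") from exc

    try:
        for h in handles:
            for contig in h.references:
                if contig not in genome_contigs:
                    raise ConsistencyError(
                        f"contig {contig!r} in {h.filename!r} absent from genome"
                    )
        header = handles[0].header.to_dict()
        with pysam.AlignmentFile(merged, "wb", header=header) as out:
            for h in handles:
                for rec in h:
                    out.write(rec)
                    read_count += 1
    finally:
        for h in handles:
            h.close()

    pysam.sort("-o", sorted_bam, merged)
    os.remove(merged)
    pysam.index(sorted_bam)
    log.info("prepared %d records from %d file(s)", read_count, len(alignment_paths))
    return PreparedInput(
        alignment_path=sorted_bam,
        genome_path=genome_path,
        read_count=read_count,
        source_count=len(alignment_paths),
    )


def _alignment_blocks(read: pysam.AlignedSegment) -> list[tuple[int, int, int]]:
    """(ref_start, ref_end, read_start) for each M/=/X block, in order."""
    blocks = []
    ref = read.reference_start
    qpos = 0
    for op, length in read.cigartuples:
        if op in _MATCH_OPS:
            blocks.append((ref, ref + length, qpos))
            ref += length
            qpos += length
        elif op == _REF_SKIP or op == 2:  # N, D consume ref only
            ref += length
        elif op in (1, 4):  # I, S consume query only
            qpos += length
        # H(5), P(6) consume neither
    return blocks


def _mismatch_ref_positions(
    read: pysam.AlignedSegment, ref_seq: str, ref_offset: int
) -> list[int]:
    """Reference positions where the read base differs from the genome."""
    seq = read.query_sequence
    if seq is None:
        return []
    out = []
    for rstart, rend, qstart in _alignment_blocks(read):
        for i in range(rend - rstart):
            rpos = rstart + i
            idx = rpos - ref_offset
            if 0 <= idx < len(ref_seq):
                if seq[qstart + i].upper() != ref_seq[idx].upper():
                    out.append(rpos)
    return out


def _match_runs(
    mismatches: list[int],
    left_anchor: tuple[int, int],
    right_anchor: tuple[int, int],
) -> tuple[int, int]:
    """Contiguous match lengths walking away from the junction on each side."""
    la_s, la_e = left_anchor
    ra_s, ra_e = right_anchor
    left_run = la_e - la_s
    for pos in mismatches:
        if la_s <= pos < la_e:
            left_run = min(left_run, la_e - pos - 1)
    right_run = ra_e - ra_s
    for pos in mismatches:
        if ra_s <= pos < ra_e:
            right_run = min(right_run, pos - ra_s)
    return left_run, right_run


def iterate_split_reads(
    prepared: PreparedInput,
    min_intron: int = 4,
    max_intron: int = 500_000,
    mapq_unique_cutoff: int = 30,
    include_secondary: bool = False,
    diagnostics: Optional[Diagnostics] = None,
) -> Iterator[SplitReadRecord]:
    """Stream one record per reference-skip operation within length bounds.

    Uniqueness comes from the ``NH`` tag when present, otherwise from mapping
    quality >= ``mapq_unique_cutoff``.  Mismatch counts come from ``NM`` when
    present, otherwise are recomputed against the genome.  The per-side
    mismatch-truncated match runs used by MaxMMES are always computed against
    the genome.
    """
    if not (0 < min_intron <= max_intron):
        raise ValueError("require 0 < min_intron <= max_intron")
    diag = diagnostics if diagnostics is not None else Diagnostics()
    genome = pysam.FastaFile(prepared.genome_path)
    bam = pysam.AlignmentFile(prepared.alignment_path)
    try:
        for read in bam:
            diag.records_read += 1
            if read.is_unmapped or read.cigartuples is None:
                diag.records_unmapped += 1
                continue
            if (read.is_secondary or read.is_supplementary) and not include_secondary:
                diag.records_secondary += 1
                continue
            skips = [
                (i, ln) for i, (op, ln) in enumerate(read.cigartuples) if op == _REF_SKIP
            ]
            if not skips:
                continue

            contig = read.reference_name
            span_start = read.reference_start
            span_end = read.reference_end
            ref_seq = genome.fetch(contig, span_start, span_end).upper()
            mm_positions = _mismatch_ref_positions(read, ref_seq, span_start)

            nm = read.get_tag("NM") if read.has_tag("NM") else None
            if nm is None:
                indel = sum(
                    ln for op, ln in read.cigartuples if op in (1, 2)
                )  # I, D
                nm = len(mm_positions) + indel
            nh = read.get_tag("NH") if read.has_tag("NH") else None
            unique = (nh == 1) if nh is not None else (read.mapping_quality >= mapq_unique_cutoff)

            # walk CIGAR to find each skip's ref interval and its anchors
            boundaries = []  # (intron_start, intron_end)
            ref = read.reference_start
            for op, ln in read.cigartuples:
                if op == _REF_SKIP:
                    boundaries.append((ref, ref + ln))
                    ref += ln
                elif op in _MATCH_OPS or op == 2:
                    ref += ln
            introns_in_read = len(boundaries)

            for j, (istart, iend) in enumerate(boundaries):
                if not (min_intron <= iend - istart <= max_intron):
                    diag.skips_out_of_bounds += 1
                    continue
                left_start = boundaries[j - 1][1] if j > 0 else span_start
                right_end = boundaries[j + 1][0] if j + 1 < len(boundaries) else span_end
                left_anchor = (left_start, istart)
                right_anchor = (iend, right_end)
                if left_anchor[1] <= left_anchor[0] or right_anchor[1] <= right_anchor[0]:
                    diag.skips_no_anchor += 1
                    continue
                left_run, right_run = _match_runs(mm_positions, left_anchor, right_anchor)
                diag.split_records_emitted += 1
                yield SplitReadRecord(
                    read_id=read.query_name,
                    contig=contig,
                    left_anchor=left_anchor,
                    intron=(istart, iend),
                    right_anchor=right_anchor,
                    uniquely_mapped=unique,
                    properly_paired=read.is_proper_pair,
                    introns_in_read=introns_in_read,
                    mismatches=int(nm),
                    read_length=read.query_length or read.infer_query_length() or 0,
                    left_match_run=left_run,
                    right_match_run=right_run,
                )
    finally:
        bam.close()
        genome.close()


def fetch_sequence(genome_path: str, contig: str, interval: tuple[int, int], strand: str = "+") -> str:
    """Fetch an uppercase genomic slice; reverse-complemented on the minus strand."""
    start, end = interval
    with pysam.FastaFile(genome_path) as genome:
        if contig not in genome.references:
            raise ConsistencyError(f"unknown contig {contig!r}")
        clen = genome.get_reference_length(contig)
        if start < 0 or end > clen or start >= end:
            raise IndexError(f"interval [{start},{end}) out of bounds for {contig} (len {clen})")
        seq = genome.fetch(contig, start, end).upper()
    return reverse_complement(seq) if strand == "-" else seq
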