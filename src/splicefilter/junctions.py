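"""Collapse split reads into distinct junctions and compute alignment metrics.

A junction is keyed purely on its intron interval (contig, start, end).  The
metrics quantify how the supporting split reads stack up around the junction:
raw/unique/reliable counts, Shannon entropy and positional deviations of the
read start offsets, the maximal overhang, and the mismatch-penalised MaxMMES.
Low entropy, stacked starts, short mismatch-truncated overhangs and heavy
mismatch loads are the alignment-side signatures of spurious junctions.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np

from .alignment_io import SplitReadRecord
from .model import (
    N_DEVIATIONS,
    IntronLocus,
    JunctionMetrics,
    JunctionSupportProfile,
    UndefinedMetricError,
)


def collapse_junctions(
    split_reads: Iterable[SplitReadRecord],
) -> dict[IntronLocus, JunctionSupportProfile]:
    """Group split-read records by their intron interval.

    Each record contributes exactly one support entry to exactly one locus;
    a read spanning k introns arrives as k records and therefore supports k
    loci.
    """
    profiles: dict[IntronLocus, JunctionSupportProfile] = {}
    for rec in split_reads:
        locus = IntronLocus(rec.contig, rec.intron[0], rec.intron[1])
        profile = profiles.get(locus)
        if profile is None:
            profile = profiles[locus] = JunctionSupportProfile()
        profile.add(rec.to_support())
    return profiles


def count_support_classes(
    profile: JunctionSupportProfile,
) -> tuple[int, int, int, int, float]:
    """(nb_raw, nb_unique_split, nb_unique_mapped, nb_reliable, reliable_ratio).

    "Unique split" reads contain a single intron; "reliable" reads are both
    uniquely mapped and properly paired.
    """
    if not profile.supports:
        raise UndefinedMetricError("empty support profile")
    nb_raw = len(profile.supports)
    nb_unique_split = sum(1 for s in profile.supports if s.introns_in_read == 1)
    nb_unique_mapped = sum(1 for s in profile.supports if s.uniquely_mapped)
    nb_reliable = sum(
        1 for s in profile.supports if s.uniquely_mapped and s.properly_paired
    )
    return nb_raw, nb_unique_split, nb_unique_mapped, nb_reliable, nb_reliable / nb_raw


def shannon_entropy(offset_counts: Mapping[int, int]) -> float:
    """Shannon entropy (bits) of the read-start offset distribution.

    Randomly sampled genuine junctions spread their supporting read starts
    across the upstream anchor, giving high entropy; stacked starts give 0.
    """
    counts = [c for c in offset_counts.values() if c > 0]
    if not counts:
        raise UndefinedMetricError("no positive offset counts")
    total = sum(counts)
    return -sum((c / total) * math.log2(c / total) for c in counts)


def anchor_deviations(
    offset_counts: Mapping[int, int],
    positions: int = N_DEVIATIONS,
    anchor_length: int | None = None,
) -> np.ndarray:
    """Standardised residuals |O - E|/sqrt(E) of read counts at anchor positions.

    Under uniform read sampling each of the A possible start offsets expects
    N/A reads, where A is the anchor capacity (``anchor_length``, capped at
    ``positions``).  Positions beyond the anchor are filled with 0.  When
    ``anchor_length`` is not given it defaults to the largest observed offset.
    """
    total = sum(offset_counts.values())
    if total <= 0:
        raise UndefinedMetricError("no supporting reads")
    if anchor_length is None:
        anchor_length = max(offset_counts)
    a = max(1, min(positions, anchor_length))
    expected = total / a
    out = np.zeros(positions)
    for i in range(1, a + 1):
        observed = offset_counts.get(i, 0)
        out[i - 1] = abs(observed - expected) / math.sqrt(expected)
    return out


def max_overhang(profile: JunctionSupportProfile) -> int:
    """Maximum over reads of the shorter anchor length."""
    if not profile.supports:
        raise UndefinedMetricError("empty support profile")
    return max(min(s.left_anchor_len, s.right_anchor_len) for s in profile.supports)


def maxmmes(profile: JunctionSupportProfile) -> int:
    """Maximum of the minimal mismatch-truncated match on either side (MaxMMES).

    Each side's contiguous-match length is truncated at the first mismatch
    walking away from the junction (precomputed against the genome when the
    split reads were streamed); MMES is the minimum of the two sides and the
    score is the maximum MMES over supporting reads.
    """
    if not profile.supports:
        raise UndefinedMetricError("empty support profile")
    return max(min(s.left_match_run, s.right_match_run) for s in profile.supports)


def mean_mismatches(profile: JunctionSupportProfile) -> float:
    if not profile.supports:
        raise UndefinedMetricError("empty support profile")
    return sum(s.mismatches for s in profile.supports) / len(profile.supports)


def compute_metrics(profile: JunctionSupportProfile) -> JunctionMetrics:
    """All alignment-derived metrics for one junction."""
    nb_raw, nb_us, nb_um, nb_rel, ratio = count_support_classes(profile)
    anchor_cap = max(profile.max_read_length - 1, 1)
    return JunctionMetrics(
        nb_raw=nb_raw,
        nb_unique_split=nb_us,
        nb_unique_mapped=nb_um,
        nb_reliable=nb_rel,
        reliable_ratio=ratio,
        entropy=shannon_entropy(profile.left_offset_counts),
        deviations=anchor_deviations(
            profile.left_offset_counts, anchor_length=anchor_cap
        ),
        max_overhang=max_overhang(profile),
        maxmmes=maxmmes(profile),
        mean_mismatches=mean_mismatches(profile),
    )
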