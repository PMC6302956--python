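"""Shared domain types and the canonical feature-vector schema.

Every stage of the pipeline speaks in terms of these types.  Coordinates are
0-based half-open throughout; conversion to/from 1-based formats happens only
at file-format boundaries (see :mod:`splicefilter.junction_io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: Number of anchor positions tracked by the deviation features.
N_DEVIATIONS = 20

#: Canonical ordering of the classifier feature vector.  This order is a
#: versioned contract: serialized models remain applicable only as long as it
#: is stable.
FEATURE_NAMES: tuple[str, ...] = (
    "reliable_reads",
    "reliable_ratio",
    "maxmmes",
    "mean_mismatches",
    "intron_score",
    "min_hamming",
    "pwm_score",
    "splicing_signal",
) + tuple(f"deviation_{i}" for i in range(1, N_DEVIATIONS + 1))

N_FEATURES = len(FEATURE_NAMES)  # 28


class ContractError(ValueError):
    """A caller violated an interface contract (missing metric, bad shape)."""


class UndefinedMetricError(ValueError):
    """A metric was requested on an empty support profile."""


class TrainingError(RuntimeError):
    """Self-training could not proceed (e.g., a labelled set is too small)."""


@dataclass(frozen=True, order=True)
class IntronLocus:
    """A distinct candidate intron: the junction key.

    ``start`` is the first intronic base (0-based), ``end`` is one past the
    last.  Equality and hashing deliberately ignore ``strand``: strand is
    resolved later from the genomic dinucleotides, while collapsing of split
    reads happens purely on coordinates.
    """

    contig: str
    start: int
    end: int
    strand: str = field(default="?", compare=False)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty intron interval [{self.start},{self.end})")
        if self.strand not in ("+", "-", "?"):
            raise ValueError(f"strand must be +, - or ?, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def key(self) -> tuple[str, int, int]:
        return (self.contig, self.start, self.end)


@dataclass(frozen=True)
class SplitReadSupport:
    """One supporting split read's contribution to a junction."""

    read_id: str
    left_anchor_start: int
    left_anchor_end: int
    right_anchor_start: int
    right_anchor_end: int
    uniquely_mapped: bool
    properly_paired: bool
    introns_in_read: int
    mismatches: int
    read_length: int
    #: contiguous match run walking left from the junction, truncated at the
    #: first mismatch (capped at the left anchor length)
    left_match_run: int = 0
    right_match_run: int = 0

    @property
    def left_anchor_len(self) -> int:
        return self.left_anchor_end - self.left_anchor_start

    @property
    def right_anchor_len(self) -> int:
        return self.right_anchor_end - self.right_anchor_start


@dataclass
class JunctionSupportProfile:
    """All split reads supporting a single junction, pre-aggregated."""

    supports: list[SplitReadSupport] = field(default_factory=list)
    #: anchor start offset (left anchor length) -> supporting read count
    left_offset_counts: dict[int, int] = field(default_factory=dict)
    max_read_length: int = 0

    def add(self, support: SplitReadSupport) -> None:
        self.supports.append(support)
        off = support.left_anchor_len
        self.left_offset_counts[off] = self.left_offset_counts.get(off, 0) + 1
        if support.read_length > self.max_read_length:
            self.max_read_length = support.read_length


@dataclass
class JunctionMetrics:
    """Alignment-derived junction metrics."""

    nb_raw: int
    nb_unique_split: int
    nb_unique_mapped: int
    nb_reliable: int
    reliable_ratio: float
    entropy: float
    deviations: np.ndarray  # length N_DEVIATIONS
    max_overhang: int
    maxmmes: int
    mean_mismatches: float


@dataclass(frozen=True)
class SpliceSiteCall:
    donor_dinucleotide: str
    acceptor_dinucleotide: str
    category: str  # canonical | semi_canonical | novel
    resolved_strand: str  # + | - | ?


@dataclass(frozen=True)
class HammingScores:
    left_score: int
    right_score: int
    window: int

    @property
    def min_score(self) -> int:
        return min(self.left_score, self.right_score)


@dataclass(frozen=True)
class JunctionVerdict:
    probability: float
    genuine: bool


@dataclass
class JunctionRecord:
    """A junction with everything the pipeline ever computes about it."""

    locus: IntronLocus
    metrics: Optional[JunctionMetrics] = None
    site_call: Optional[SpliceSiteCall] = None
    hamming: Optional[HammingScores] = None
    intron_score: Optional[float] = None
    pwm_score: Optional[float] = None
    splicing_signal: Optional[float] = None
    verdict: Optional[JunctionVerdict] = None
    #: maximal anchor extents over all supporting reads (for BED12 blocks)
    anchor_left_start: int = 0
    anchor_right_end: int = 0

    def with_verdict(self, verdict: JunctionVerdict) -> "JunctionRecord":
        return replace(self, verdict=verdict)


def to_feature_vector(record: JunctionRecord) -> np.ndarray:
    """Extract the canonical 28-entry feature vector from a complete record.

    Raises :class:`ContractError` naming the first missing metric if the
    record is incomplete.
    """
    for name in ("metrics", "hamming", "intron_score", "pwm_score", "splicing_signal"):
        if getattr(record, name) is None:
            raise ContractError(f"record for {record.locus} lacks {name}")
    m = record.metrics
    dev = np.asarray(m.deviations, dtype=float)
    if dev.shape != (N_DEVIATIONS,):
        padded = np.zeros(N_DEVIATIONS)
        padded[: min(len(dev), N_DEVIATIONS)] = dev[:N_DEVIATIONS]
        dev = padded
    vec = np.concatenate(
        [
            [
                float(m.nb_reliable),
                float(m.reliable_ratio),
                float(m.maxmmes),
                float(m.mean_mismatches),
                float(record.intron_score),
                float(record.hamming.min_score),
                float(record.pwm_score),
                float(record.splicing_signal),
            ],
            dev,
        ]
    )
    if not np.all(np.isfinite(vec)):
        raise ContractError(f"non-finite feature for {record.locus}")
    return vec


@dataclass
class PipelineConfig:
    """Tunable knobs for the full pipeline; all randomness flows from seed."""

    min_intron: int = 4
    max_intron: int = 500_000
    mapq_unique_cutoff: int = 30
    include_secondary: bool = False
    # rule thresholds for self-training (positive rules)
    pos_min_reliable: int = 5
    pos_min_entropy: float = 1.0
    pos_min_maxmmes: int = 12
    pos_max_mean_mismatches: float = 1.0
    pos_min_hamming: int = 5
    # negative rules
    neg_novel_max_raw: int = 2
    neg_zero_entropy_max_raw: int = 5
    neg_max_hamming: int = 2
    neg_low_mmes_cutoff: int = 6
    min_training_set: int = 20
    smote_k: int = 5
    n_trees: int = 100
    threshold: float = 0.5
    hamming_window: int = 10
    pwm_donor_window: tuple[int, int] = (-3, 8)
    pwm_acceptor_window: tuple[int, int] = (-20, 3)
    pwm_pseudocount: float = 0.5
    seed: int = 1
    threads: int = 1
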