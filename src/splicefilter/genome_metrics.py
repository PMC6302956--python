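"""Genome-derived junction features.

Four families of evidence come from the genome rather than the alignments:

* the two-base donor/acceptor dinucleotides, which resolve strand and place a
  junction in the canonical (GT-AG) / semi-canonical (GC-AG, AT-AC) / novel
  hierarchy;
* hamming distances between anchor-edge and intron-edge windows, which flag
  repeat-triggered misalignments (a repeat copy makes the windows near
  identical, so LOW scores are suspicious);
* an intron-size score, zero up to the 95th-percentile length of the
  self-trained positive set and growing logarithmically beyond it;
* position-weight-matrix scores of the splice-site neighbourhoods, both as
  log-odds against genome background and as a positive-vs-negative model
  likelihood ratio (the "splicing signal").
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pysam

from .alignment_io import reverse_complement
from .model import HammingScores, IntronLocus, SpliceSiteCall, TrainingError

CANONICAL = {("GT", "AG")}
SEMI_CANONICAL = {("GC", "AG"), ("AT", "AC")}

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


def _pair_category(donor: str, acceptor: str) -> str | None:
    if (donor, acceptor) in CANONICAL:
        return "canonical"
    if (donor, acceptor) in SEMI_CANONICAL:
        return "semi_canonical"
    return None


def classify_splice_sites(genome_path: str, locus: IntronLocus) -> SpliceSiteCall:
    """Read the terminal intronic dinucleotides and resolve category + strand.

    The pair is tested as-is (plus strand) and reverse-complemented (minus
    strand); strand resolves to whichever orientation yields a canonical or
    semi-canonical pair, preferring canonical.  Ambiguous bases give a novel
    call with unknown strand.
    """
    if locus.length < 4:
        raise ValueError("intron too short for splice-site classification")
    with pysam.FastaFile(genome_path) as genome:
        donor_fwd = genome.fetch(locus.contig, locus.start, locus.start + 2).upper()
        acceptor_fwd = genome.fetch(locus.contig, locus.end - 2, locus.end).upper()
    if set(donor_fwd + acceptor_fwd) - set(_BASES):
        return SpliceSiteCall(donor_fwd, acceptor_fwd, "novel", "?")
    # minus strand: the donor is the reverse complement of the last 2 bases
    donor_rev = reverse_complement(acceptor_fwd)
    acceptor_rev = reverse_complement(donor_fwd)
    cat_plus = _pair_category(donor_fwd, acceptor_fwd)
    cat_minus = _pair_category(donor_rev, acceptor_rev)
    rank = {"canonical": 2, "semi_canonical": 1, None: 0}
    if rank[cat_plus] >= rank[cat_minus] and cat_plus is not None:
        return SpliceSiteCall(donor_fwd, acceptor_fwd, cat_plus, "+")
    if cat_minus is not None:
        return SpliceSiteCall(donor_rev, acceptor_rev, cat_minus, "-")
    return SpliceSiteCall(donor_fwd, acceptor_fwd, "novel", "?")


def hamming_distance(a: str, b: str) -> int:
    """Position-wise mismatch count; length difference counts as mismatches."""
    n = min(len(a), len(b))
    return sum(1 for i in range(n) if a[i] != b[i]) + abs(len(a) - len(b))


def hamming_scores(
    genome_path: str, locus: IntronLocus, window: int = 10
) -> HammingScores:
    """Repeat-likeness scores at the two junction boundaries.

    left = hamming(last W bases of the left anchor, last W bases of the
    intron); right = hamming(first W bases of the intron, first W bases of
    the right anchor).  Windows are truncated where the contig ends.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    with pysam.FastaFile(genome_path) as genome:
        clen = genome.get_reference_length(locus.contig)
        w = min(window, locus.length)
        left_anchor_w = genome.fetch(
            locus.contig, max(0, locus.start - w), locus.start
        ).upper()
        intron_tail = genome.fetch(locus.contig, locus.end - w, locus.end).upper()
        intron_head = genome.fetch(locus.contig, locus.start, locus.start + w).upper()
        right_anchor_w = genome.fetch(
            locus.contig, locus.end, min(clen, locus.end + w)
        ).upper()
    # pad to common window so truncation penalises rather than rewards
    left = hamming_distance(left_anchor_w, intron_tail)
    right = hamming_distance(intron_head, right_anchor_w)
    return HammingScores(left_score=left, right_score=right, window=window)


@dataclass(frozen=True)
class IntronSizeModel:
    """95th-percentile (nearest-rank) intron length of the positive set."""

    l95: int


def fit_intron_size(positive_lengths: Sequence[int]) -> IntronSizeModel:
    if len(positive_lengths) < 20:
        raise TrainingError(
            f"only {len(positive_lengths)} positive intron lengths; "
            "need >= 20 — consider relaxing the positive rules"
        )
    ordered = sorted(positive_lengths)
    rank = math.ceil(0.95 * len(ordered))  # nearest-rank percentile
    return IntronSizeModel(l95=int(ordered[rank - 1]))


def intron_size_score(length: int, model: IntronSizeModel) -> float:
    """0 for lengths up to l95; log2(length / l95) beyond it."""
    if length < 1:
        raise ValueError("intron length must be positive")
    if length <= model.l95:
        return 0.0
    return math.log2(length / model.l95)


@dataclass
class PwmModel:
    """Donor/acceptor position-specific probability matrices.

    Windows are (upstream, downstream) extents relative to each splice site
    on the RESOLVED strand; negative positions are exonic.  The donor window
    covers positions [donor_up, donor_down) relative to the first intronic
    base, the acceptor window [acc_up, acc_down) relative to the base just
    past the intron.
    """

    donor_matrix: np.ndarray  # (donor_len, 4)
    acceptor_matrix: np.ndarray  # (acceptor_len, 4)
    donor_window: tuple[int, int]
    acceptor_window: tuple[int, int]
    pseudocount: float
    background: np.ndarray  # (4,)

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"# donor_window\t{self.donor_window[0]}\t{self.donor_window[1]}\n")
            fh.write(
                f"# acceptor_window\t{self.acceptor_window[0]}\t{self.acceptor_window[1]}\n"
            )
            fh.write(f"# pseudocount\t{self.pseudocount!r}\n")
            fh.write("# background\t" + "\t".join(repr(x) for x in self.background) + "\n")
            for name, mat in (("donor", self.donor_matrix), ("acceptor", self.acceptor_matrix)):
                for row in mat:
                    fh.write(name + "\t" + "\t".join(repr(x) for x in row) + "\n")


def _window_sequences(
    genome: pysam.FastaFile,
    locus: IntronLocus,
    strand: str,
    donor_window: tuple[int, int],
    acceptor_window: tuple[int, int],
) -> tuple[str, str]:
    """Extract donor and acceptor window sequences on the given strand.

    Out-of-contig positions are padded with N (scored as background).
    """

    def fetch_padded(contig: str, start: int, end: int) -> str:
        clen = genome.get_reference_length(contig)
        left_pad = max(0, -start)
        right_pad = max(0, end - clen)
        seq = genome.fetch(contig, max(0, start), min(clen, end)).upper()
        return "N" * left_pad + seq + "N" * right_pad

    du, dd = donor_window
    au, ad = acceptor_window
    if strand == "-":
        # donor site is at the intron end on the minus strand
        donor = reverse_complement(fetch_padded(locus.contig, locus.end - dd, locus.end - du))
        acceptor = reverse_complement(
            fetch_padded(locus.contig, locus.start - ad, locus.start - au)
        )
    else:
        donor = fetch_padded(locus.contig, locus.start + du, locus.start + dd)
        acceptor = fetch_padded(locus.contig, locus.end + au, locus.end + ad)
    return donor, acceptor


def genome_background(genome_path: str) -> np.ndarray:
    """Genome-wide mononucleotide frequencies (pseudocounted, A C G T)."""
    counts = np.ones(4)
    with pysam.FastaFile(genome_path) as genome:
        for contig in genome.references:
            seq = genome.fetch(contig).upper()
            for i, base in enumerate(_BASES):
                counts[i] += seq.count(base)
    return counts / counts.sum()


def train_pwm(
    genome_path: str,
    loci: Iterable[tuple[IntronLocus, str]],
    donor_window: tuple[int, int] = (-3, 8),
    acceptor_window: tuple[int, int] = (-20, 3),
    pseudocount: float = 0.5,
    background: np.ndarray | None = None,
) -> PwmModel:
    """Fit donor/acceptor PWMs from (locus, resolved_strand) training pairs.

    Per-position probabilities are (count + pseudocount)/(n + 4*pseudocount).
    Loci with unknown strand are skipped; if all are skipped a
    :class:`TrainingError` is raised.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    dlen = donor_window[1] - donor_window[0]
    alen = acceptor_window[1] - acceptor_window[0]
    donor_counts = np.zeros((dlen, 4))
    acceptor_counts = np.zeros((alen, 4))
    n = 0
    with pysam.FastaFile(genome_path) as genome:
        for locus, strand in loci:
            if strand not in ("+", "-"):
                continue
            donor, acceptor = _window_sequences(
                genome, locus, strand, donor_window, acceptor_window
            )
            for pos, base in enumerate(donor):
                if base in _BASE_INDEX:
                    donor_counts[pos, _BASE_INDEX[base]] += 1
            for pos, base in enumerate(acceptor):
                if base in _BASE_INDEX:
                    acceptor_counts[pos, _BASE_INDEX[base]] += 1
            n += 1
    if n == 0:
        raise TrainingError("no strand-resolved loci available for PWM training")
    if background is None:
        background = genome_background(genome_path)
    # normalise per position; N-containing positions have fewer counts
    def norm(counts: np.ndarray) -> np.ndarray:
        totals = counts.sum(axis=1, keepdims=True)
        return (counts + pseudocount) / (totals + 4 * pseudocount)

    return PwmModel(
        donor_matrix=norm(donor_counts),
        acceptor_matrix=norm(acceptor_counts),
        donor_window=donor_window,
        acceptor_window=acceptor_window,
        pseudocount=pseudocount,
        background=np.asarray(background, dtype=float),
    )


def uniform_pwm(
    donor_window: tuple[int, int] = (-3, 8),
    acceptor_window: tuple[int, int] = (-20, 3),
) -> PwmModel:
    """A flat model (every base 0.25 everywhere, uniform background)."""
    dlen = donor_window[1] - donor_window[0]
    alen = acceptor_window[1] - acceptor_window[0]
    return PwmModel(
        donor_matrix=np.full((dlen, 4), 0.25),
        acceptor_matrix=np.full((alen, 4), 0.25),
        donor_window=donor_window,
        acceptor_window=acceptor_window,
        pseudocount=1.0,
        background=np.full(4, 0.25),
    )


def _loglik(model: PwmModel, donor: str, acceptor: str, vs_background: bool) -> float:
    score = 0.0
    for mat, seq in ((model.donor_matrix, donor), (model.acceptor_matrix, acceptor)):
        for pos, base in enumerate(seq):
            idx = _BASE_INDEX.get(base)
            if idx is None:
                continue  # N: uninformative position
            p = mat[pos, idx]
            score += math.log2(p / model.background[idx]) if vs_background else math.log2(p)
    return score


def pwm_score(model: PwmModel, genome_path: str, locus: IntronLocus, strand: str = "?") -> float:
    """Log-odds (bits) of the splice-site windows against genome background.

    With unknown strand the score is computed on both strands and the
    maximum is returned.
    """
    strands = ("+", "-") if strand == "?" else (strand,)
    best = None
    with pysam.FastaFile(genome_path) as genome:
        for s in strands:
            donor, acceptor = _window_sequences(
                genome, locus, s, model.donor_window, model.acceptor_window
            )
            val = _loglik(model, donor, acceptor, vs_background=True)
            best = val if best is None else max(best, val)
    return best


def splicing_signal_score(
    pos_model: PwmModel,
    neg_model: PwmModel,
    genome_path: str,
    locus: IntronLocus,
    strand: str = "?",
) -> float:
    """Log-likelihood ratio (bits) of the windows under positive vs negative PWMs."""
    if pos_model.donor_window != neg_model.donor_window or (
        pos_model.acceptor_window != neg_model.acceptor_window
    ):
        raise ValueError("positive and negative models must share windows")
    strands = ("+", "-") if strand == "?" else (strand,)
    best = None
    with pysam.FastaFile(genome_path) as genome:
        for s in strands:
            donor, acceptor = _window_sequences(
                genome, locus, s, pos_model.donor_window, pos_model.acceptor_window
            )
            val = _loglik(pos_model, donor, acceptor, False) - _loglik(
                neg_model, donor, acceptor, False
            )
            best = val if best is None else max(best, val)
    return best
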