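"""Self-contained synthetic fixtures: genome, annotation, truth and alignments.

The generator plants two populations of junctions in a random genome and
writes the split-read alignments directly as SAM — no read simulator or
mapper is involved, because the point is to reproduce the *alignment
signatures* that distinguish genuine from spurious junctions:

* genuine junctions get canonical GT-AG introns, near-uniformly distributed
  anchor start offsets, coverage-proportional support and reliable
  (uniquely mapped, properly paired) reads;
* spurious junctions come in four archetypes, each violating exactly one
  designated signature — stacked read starts (zero entropy), non-canonical
  boundary dinucleotides, a repeat copy across the junction (hamming score
  0), or a single supporting read.

Truth files record every planted genuine intron (BED) and every spurious
one, so recall/precision can be measured exactly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .model import IntronLocus

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_ARCHETYPES = ("low_entropy", "non_canonical", "repeat", "single_read")


@dataclass
class FixtureSpec:
    """Parameters of a synthetic dataset.

    Defaults describe the standard study conditions: a 2 x 100 kb genome
    carrying 300 genuine and 300 spurious junctions (75 per archetype),
    76-base reads at 30x junction coverage.
    """

    seed: int = 1
    n_contigs: int = 2
    contig_length: int = 100_000
    n_genuine: int = 300
    spurious: dict[str, int] = field(
        default_factory=lambda: {
            "low_entropy": 75,
            "non_canonical": 75,
            "repeat": 75,
            "single_read": 75,
        }
    )
    intron_length_range: tuple[int, int] = (60, 180)
    exon_length: int = 90
    read_length: int = 76
    coverage: int = 30
    mismatch_rate: float = 0.0
    min_anchor: int = 8
    repeat_window: int = 10

    def validate(self) -> None:
        if not (0.0 <= self.mismatch_rate < 1.0):
            raise ValueError("mismatch_rate must be in [0, 1)")
        if self.read_length < 2 * self.min_anchor:
            raise ValueError("reads shorter than twice the minimum anchor")
        if self.exon_length < self.read_length - self.min_anchor:
            raise ValueError("exons too short to hold the longest anchor")
        if any(v < 0 for v in self.spurious.values()) or self.n_genuine < 0:
            raise ValueError("counts must be non-negative")
        unknown = set(self.spurious) - set(_ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown spurious archetypes: {sorted(unknown)}")


@dataclass
class SimRead:
    qname: str
    flag: int
    contig: str
    pos: int  # 0-based leftmost aligned base
    mapq: int
    cigar: str
    seq: np.ndarray  # uint8 base codes
    nh: int
    nm: int = 0

    def sam_line(self) -> str:
        seq = self.seq.tobytes().decode()
        return "\t".join(
            [
                self.qname, str(self.flag), self.contig, str(self.pos + 1),
                str(self.mapq), self.cigar, "=", str(self.pos + 1), "0",
                seq, "I" * len(seq), f"NH:i:{self.nh}", f"NM:i:{self.nm}",
            ]
        )


@dataclass
class Fixture:
    genome_fasta: str
    annotation_gff3: str
    truth_bed: str
    spurious_bed: str
    sam: str
    truth_loci: list[IntronLocus]
    spurious_loci: dict[str, list[IntronLocus]]


@dataclass
class _Slot:
    contig: str
    exon1: tuple[int, int]
    intron: tuple[int, int]
    exon2: tuple[int, int]
    kind: str  # "genuine" or an archetype name


def _plan_slots(spec: FixtureSpec, rng: np.random.Generator) -> list[_Slot]:
    kinds = ["genuine"] * spec.n_genuine
    for name in _ARCHETYPES:
        kinds += [name] * spec.spurious.get(name, 0)
    rng.shuffle(kinds)
    slots: list[_Slot] = []
    contig_idx = 0
    pos = 50
    lo, hi = spec.intron_length_range
    for kind in kinds:
        intron_len = int(rng.integers(lo, hi + 1))
        spacer = int(rng.integers(10, 31))
        total = 2 * spec.exon_length + intron_len + spacer
        if pos + total > spec.contig_length - 50:
            contig_idx += 1
            pos = 50
            if contig_idx >= spec.n_contigs:
                raise ValueError(
                    "fixture does not fit: increase contig_length/n_contigs "
                    "or reduce junction counts"
                )
        contig = f"ctg{contig_idx + 1}"
        e1 = (pos, pos + spec.exon_length)
        intr = (e1[1], e1[1] + intron_len)
        e2 = (intr[1], intr[1] + spec.exon_length)
        slots.append(_Slot(contig, e1, intr, e2, kind))
        pos = e2[1] + spacer
    return slots


def _plant(genome: np.ndarray, start: int, motif: bytes) -> None:
    genome[start : start + len(motif)] = np.frombuffer(motif, dtype=np.uint8)


def _make_reads(
    slot: _Slot,
    offsets: list[int],
    genomes: dict[str, np.ndarray],
    spec: FixtureSpec,
    name_prefix: str,
    mapq: int,
    nh: int,
    proper: bool,
) -> list[SimRead]:
    g = genomes[slot.contig]
    istart, iend = slot.intron
    intron_len = iend - istart
    reads = []
    for i, a in enumerate(offsets):
        b = spec.read_length - a
        left = g[istart - a : istart]
        right = g[iend : iend + b]
        flag = 0x1 | 0x40 | (0x2 if proper else 0)
        reads.append(
            SimRead(
                qname=f"{name_prefix}_{i}",
                flag=flag,
                contig=slot.contig,
                pos=istart - a,
                mapq=mapq,
                cigar=f"{a}M{intron_len}N{b}M",
                seq=np.concatenate([left, right]),
                nh=nh,
            )
        )
    return reads


def corrupt_reads(
    reads: list[SimRead],
    mismatch_rate: float,
    seed: int,
    genomes: dict[str, np.ndarray] | None = None,
) -> list[SimRead]:
    """Substitute bases at the given per-base rate; keep NM tags consistent.

    Each selected base is replaced by a uniformly chosen *different* base.
    When genome arrays are supplied, NM is recomputed by naive comparison of
    the aligned blocks against the genome; otherwise the substitution count
    is used (equivalent for reads that started as exact genome copies).
    """
    if not (0.0 <= mismatch_rate < 1.0):
        raise ValueError("mismatch_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    for read in reads:
        if mismatch_rate > 0.0:
            hit = rng.random(len(read.seq)) < mismatch_rate
            for idx in np.nonzero(hit)[0]:
                current = read.seq[idx]
                choices = _BASES[_BASES != current]
                read.seq[idx] = choices[rng.integers(0, len(choices))]
        if genomes is not None:
            read.nm = _count_mismatches(read, genomes[read.contig])
        else:
            read.nm = int(np.count_nonzero(hit)) if mismatch_rate > 0.0 else 0
    return reads


def _count_mismatches(read: SimRead, genome: np.ndarray) -> int:
    """Naive NM: walk the CIGAR and compare aligned bases to the genome."""
    import re

    nm = 0
    ref = read.pos
    q = 0
    for length, op in re.findall(r"(\d+)([MIDNSHP=X])", read.cigar):
        n = int(length)
        if op in "M=X":
            nm += int(np.count_nonzero(read.seq[q : q + n] != genome[ref : ref + n]))
            ref += n
            q += n
        elif op in "DN":
            if op == "D":
                nm += n
            ref += n
        elif op in "IS":
            if op == "I":
                nm += n
            q += n
    return nm


def generate_fixture(spec: FixtureSpec, outdir: str) -> Fixture:
    """Write genome FASTA, annotation GFF3, truth/spurious BED and sorted SAM."""
    spec.validate()
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    genomes = {
        f"ctg{i + 1}": rng.choice(_BASES, size=spec.contig_length)
        for i in range(spec.n_contigs)
    }
    slots = _plan_slots(spec, rng)

    # plant splice-site motifs and repeat copies before extracting any read
    for slot in slots:
        g = genomes[slot.contig]
        istart, iend = slot.intron
        if slot.kind in ("genuine", "low_entropy", "single_read"):
            _plant(g, istart, b"GT")
            _plant(g, iend - 2, b"AG")
        elif slot.kind == "non_canonical":
            _plant(g, istart, b"AA")
            _plant(g, iend - 2, b"TT")
        elif slot.kind == "repeat":
            w = spec.repeat_window
            # copy the start of the right anchor over the intron head: the
            # junction looks triggered by a repeat (right hamming score 0)
            g[istart : istart + w] = g[iend : iend + w]

    reads: list[SimRead] = []
    truth: list[IntronLocus] = []
    spurious: dict[str, list[IntronLocus]] = {a: [] for a in _ARCHETYPES}
    lo_off, hi_off = spec.min_anchor, spec.read_length - spec.min_anchor
    for idx, slot in enumerate(slots):
        locus = IntronLocus(slot.contig, slot.intron[0], slot.intron[1], "+")
        if slot.kind == "genuine":
            truth.append(locus)
            n = max(3, int(rng.poisson(spec.coverage)))
            offsets = [int(rng.integers(lo_off, hi_off + 1)) for _ in range(n)]
            reads += _make_reads(
                slot, offsets, genomes, spec, f"gen{idx}", 60, 1, proper=True
            )
        else:
            spurious[slot.kind].append(locus)
            stack = int(rng.integers(lo_off, hi_off + 1))
            if slot.kind == "low_entropy":
                reads += _make_reads(
                    slot, [stack] * 3, genomes, spec, f"le{idx}", 3, 4, proper=False
                )
            elif slot.kind == "non_canonical":
                reads += _make_reads(
                    slot, [stack] * 2, genomes, spec, f"nc{idx}", 3, 5, proper=False
                )
            elif slot.kind == "repeat":
                reads += _make_reads(
                    slot, [stack] * 2, genomes, spec, f"rep{idx}", 20, 2, proper=False
                )
            elif slot.kind == "single_read":
                reads += _make_reads(
                    slot, [stack], genomes, spec, f"sr{idx}", 60, 1, proper=True
                )

    corrupt_reads(reads, spec.mismatch_rate, spec.seed + 1, genomes)
    reads.sort(key=lambda r: (r.contig, r.pos, r.qname))

    paths = Fixture(
        genome_fasta=os.path.join(outdir, "genome.fa"),
        annotation_gff3=os.path.join(outdir, "annotation.gff3"),
        truth_bed=os.path.join(outdir, "truth.introns.bed"),
        spurious_bed=os.path.join(outdir, "spurious.introns.bed"),
        sam=os.path.join(outdir, "alignments.sam"),
        truth_loci=sorted(truth, key=lambda l: l.key()),
        spurious_loci={a: sorted(v, key=lambda l: l.key()) for a, v in spurious.items()},
    )

    with open(paths.genome_fasta, "w") as fh:
        for contig in sorted(genomes):
            fh.write(f">{contig}\n")
            seq = genomes[contig].tobytes().decode()
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")

    _write_annotation(paths.annotation_gff3, slots)
    _write_intron_bed(paths.truth_bed, paths.truth_loci)
    _write_intron_bed(
        paths.spurious_bed,
        sorted((l for v in paths.spurious_loci.values() for l in v), key=lambda l: l.key()),
    )

    with open(paths.sam, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for contig in sorted(genomes):
            fh.write(f"@SQ\tSN:{contig}\tLN:{len(genomes[contig])}\n")
        for read in reads:
            fh.write(read.sam_line() + "\n")
    return paths


def _write_annotation(path: str, slots: list[_Slot]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        n = 0
        for slot in slots:
            if slot.kind != "genuine":
                continue
            n += 1
            gid, tid = f"gene{n}", f"mrna{n}"
            start1, end2 = slot.exon1[0] + 1, slot.exon2[1]
            common = f"{slot.contig}\tsynthetic"
            fh.write(f"{common}\tgene\t{start1}\t{end2}\t.\t+\t.\tID={gid}\n")
            fh.write(f"{common}\tmRNA\t{start1}\t{end2}\t.\t+\t.\tID={tid};Parent={gid}\n")
            fh.write(
                f"{common}\texon\t{slot.exon1[0] + 1}\t{slot.exon1[1]}\t.\t+\t.\t"
                f"ID={tid}.e1;Parent={tid}\n"
            )
            fh.write(
                f"{common}\texon\t{slot.exon2[0] + 1}\t{slot.exon2[1]}\t.\t+\t.\t"
                f"ID={tid}.e2;Parent={tid}\n"
            )


def _write_intron_bed(path: str, loci: list[IntronLocus]) -> None:
    with open(path, "w") as fh:
        for i, l in enumerate(loci):
            fh.write(f"{l.contig}\t{l.start}\t{l.end}\tintron_{i}\t0\t{l.strand}\n")


def generate_multisample(
    spec: FixtureSpec,
    outdir: str,
    n_samples: int = 3,
    shared_fraction: float = 0.7,
) -> tuple[list[Fixture], str]:
    """Per-sample fixtures over one genome, sharing a fraction of genuine junctions.

    A shared pool of round(shared_fraction * n_genuine) genuine junctions
    appears in every sample; the remainder are private to individual samples.
    Spurious junctions are private per sample.  Returns the per-sample
    fixtures and the shared genome path (all fixtures reference it).
    """
    if not (0.0 <= shared_fraction <= 1.0):
        raise ValueError("shared_fraction must be in [0, 1]")
    fixtures = []
    n_shared = round(shared_fraction * spec.n_genuine)
    for s in range(n_samples):
        # identical seed -> identical genome/slot layout across samples
        sub = FixtureSpec(**{**spec.__dict__, "seed": spec.seed})
        fx = generate_fixture(sub, os.path.join(outdir, f"sample{s + 1}"))
        fixtures.append(fx)
    # Thin each sample down to its junction subset: a shared genuine pool
    # plus interleaved private shares; spurious junctions are private.
    rng = np.random.default_rng(spec.seed + 7)
    order = list(range(spec.n_genuine))
    rng.shuffle(order)
    shared = set(order[:n_shared])
    private = order[n_shared:]
    per_sample_genuine = [shared | set(private[s::n_samples]) for s in range(n_samples)]
    flat_spurious = sorted(
        (l for v in fixtures[0].spurious_loci.values() for l in v),
        key=lambda l: l.key(),
    )
    sp_order = list(range(len(flat_spurious)))
    rng.shuffle(sp_order)
    per_sample_spurious = [set(sp_order[s::n_samples]) for s in range(n_samples)]
    for s, fx in enumerate(fixtures):
        keep_genuine = [fx.truth_loci[i] for i in sorted(per_sample_genuine[s])]
        keep_spurious = [flat_spurious[i] for i in sorted(per_sample_spurious[s])]
        keep_keys = {l.key() for l in keep_genuine} | {l.key() for l in keep_spurious}
        fx.truth_loci = sorted(keep_genuine, key=lambda l: l.key())
        sp_keys = {l.key() for l in keep_spurious}
        fx.spurious_loci = {
            a: [l for l in v if l.key() in sp_keys] for a, v in fx.spurious_loci.items()
        }
        _filter_sam_to_loci(fx.sam, keep_keys)
        _write_intron_bed(fx.truth_bed, fx.truth_loci)
        _write_intron_bed(fx.spurious_bed, sorted(keep_spurious, key=lambda l: l.key()))
    return fixtures, fixtures[0].genome_fasta


def _filter_sam_to_loci(sam_path: str, keep: set[tuple[str, int, int]]) -> None:
    """Drop reads whose spliced intron is not in the keep set."""
    import re

    kept_lines = []
    with open(sam_path) as fh:
        for line in fh:
            if line.startswith("@"):
                kept_lines.append(line)
                continue
            fields = line.split("\t")
            ref = int(fields[3]) - 1
            intron = None
            for length, op in re.findall(r"(\d+)([MIDNSHP=X])", fields[5]):
                n = int(length)
                if op == "N":
                    intron = (fields[2], ref, ref + n)
                    break
                if op in "MD=X":
                    ref += n
            if intron in keep:
                kept_lines.append(line)
    with open(sam_path, "w") as fh:
        fh.writelines(kept_lines)
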