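"""Junction file formats, set algebra, reference comparison and evaluation.

Formats
-------
``tab``
    The pipeline's descriptive tabular format: one header line, one row per
    junction carrying every metric, the classifier probability and the
    verdict.  All coordinates are 0-based half-open (stated in the header
    comment).  Lossless: write -> read -> write is byte-identical.
``bed_exon``
    BED12 with two blocks (the maximal anchors), thick interval = intron,
    score = round(1000 * probability).  Locus and probability round-trip;
    metrics do not (documented one-way).
``intron_bed``
    BED6 over the intron interval.
``hint_gff``
    GFF3 ``intron`` features usable as hints by gene predictors.
``mapper_sj``
    Splice-site hint text for two-pass alignment: contig, 0-based position
    of the last exonic base before the intron, 0-based position of the first
    exonic base after it, strand.  (This is the dialect used by HISAT2's
    known-splice-site infrastructure; other mappers may differ.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model import (
    N_DEVIATIONS,
    HammingScores,
    IntronLocus,
    JunctionMetrics,
    JunctionRecord,
    JunctionVerdict,
    SpliceSiteCall,
)

TAB_VERSION = "splicefilter-tab-v1"

_FIXED_COLUMNS = [
    "contig", "start", "end", "strand", "id",
    "nb_raw", "nb_unique_split", "nb_unique_mapped", "nb_reliable",
    "reliable_ratio", "entropy", "max_overhang", "maxmmes", "mean_mismatches",
    "donor", "acceptor", "site_category",
    "hamming_left", "hamming_right", "hamming_window",
    "intron_score", "pwm_score", "splicing_signal",
    "anchor_left_start", "anchor_right_end",
]
TAB_COLUMNS = (
    _FIXED_COLUMNS
    + [f"deviation_{i}" for i in range(1, N_DEVIATIONS + 1)]
    + ["probability", "genuine"]
)


class ParseError(ValueError):
    def __init__(self, path: str, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.line_no = line_no


def _fmt(value) -> str:
    if value is None:
        return "."
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _junction_id(index: int) -> str:
    return f"junc_{index}"


def _sorted_records(records: Mapping[IntronLocus, JunctionRecord]) -> list[JunctionRecord]:
    return [records[k] for k in sorted(records, key=lambda l: l.key())]


def write_junctions(
    records: Mapping[IntronLocus, JunctionRecord],
    path: str,
    fmt: str = "tab",
) -> None:
    writers = {
        "tab": _write_tab,
        "bed_exon": _write_bed_exon,
        "intron_bed": _write_intron_bed,
        "hint_gff": _write_hint_gff,
        "mapper_sj": _write_mapper_sj,
    }
    if fmt not in writers:
        raise ValueError(f"unknown format {fmt!r}; choose from {sorted(writers)}")
    writers[fmt](_sorted_records(records), path)


def read_junctions(path: str, fmt: str = "tab") -> dict[IntronLocus, JunctionRecord]:
    readers = {"tab": _read_tab, "bed_exon": _read_bed_exon, "intron_bed": _read_intron_bed}
    if fmt not in readers:
        raise ValueError(f"format {fmt!r} is write-only or unknown")
    return readers[fmt](path)


def _write_tab(records: Sequence[JunctionRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {TAB_VERSION}; coordinates 0-based half-open\n")
        fh.write("\t".join(TAB_COLUMNS) + "\n")
        for i, rec in enumerate(records):
            m = rec.metrics
            row = [
                rec.locus.contig, rec.locus.start, rec.locus.end, rec.locus.strand,
                _junction_id(i),
            ]
            if m is None:
                row += [None] * 9
            else:
                row += [
                    m.nb_raw, m.nb_unique_split, m.nb_unique_mapped, m.nb_reliable,
                    float(m.reliable_ratio), float(m.entropy), m.max_overhang,
                    m.maxmmes, float(m.mean_mismatches),
                ]
            sc = rec.site_call
            row += (
                [sc.donor_dinucleotide, sc.acceptor_dinucleotide, sc.category]
                if sc else [None, None, None]
            )
            h = rec.hamming
            row += [h.left_score, h.right_score, h.window] if h else [None, None, None]
            row += [
                None if rec.intron_score is None else float(rec.intron_score),
                None if rec.pwm_score is None else float(rec.pwm_score),
                None if rec.splicing_signal is None else float(rec.splicing_signal),
                rec.anchor_left_start, rec.anchor_right_end,
            ]
            if m is None:
                row += [None] * N_DEVIATIONS
            else:
                dev = list(np.asarray(m.deviations, dtype=float))
                dev += [0.0] * (N_DEVIATIONS - len(dev))
                row += [float(d) for d in dev[:N_DEVIATIONS]]
            v = rec.verdict
            row += [None if v is None else float(v.probability), None if v is None else v.genuine]
            fh.write("\t".join(_fmt(x) for x in row) + "\n")


def _parse_opt(text: str, conv):
    return None if text == "." else conv(text)


def _read_tab(path: str) -> dict[IntronLocus, JunctionRecord]:
    out: dict[IntronLocus, JunctionRecord] = {}
    with open(path) as fh:
        header_seen = False
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if not header_seen:
                if line.split("\t") != TAB_COLUMNS:
                    raise ParseError(path, line_no, "unexpected tab header")
                header_seen = True
                continue
            fields = line.split("\t")
            if len(fields) != len(TAB_COLUMNS):
                raise ParseError(
                    path, line_no, f"expected {len(TAB_COLUMNS)} fields, got {len(fields)}"
                )
            row = dict(zip(TAB_COLUMNS, fields))
            try:
                locus = IntronLocus(
                    row["contig"], int(row["start"]), int(row["end"]), row["strand"]
                )
                metrics = None
                if row["nb_raw"] != ".":
                    devs = np.array(
                        [float(row[f"deviation_{i}"]) for i in range(1, N_DEVIATIONS + 1)]
                    )
                    metrics = JunctionMetrics(
                        nb_raw=int(row["nb_raw"]),
                        nb_unique_split=int(row["nb_unique_split"]),
                        nb_unique_mapped=int(row["nb_unique_mapped"]),
                        nb_reliable=int(row["nb_reliable"]),
                        reliable_ratio=float(row["reliable_ratio"]),
                        entropy=float(row["entropy"]),
                        deviations=devs,
                        max_overhang=int(row["max_overhang"]),
                        maxmmes=int(row["maxmmes"]),
                        mean_mismatches=float(row["mean_mismatches"]),
                    )
                site = None
                if row["donor"] != ".":
                    site = SpliceSiteCall(
                        row["donor"], row["acceptor"], row["site_category"], locus.strand
                    )
                hamming = None
                if row["hamming_left"] != ".":
                    hamming = HammingScores(
                        int(row["hamming_left"]), int(row["hamming_right"]),
                        int(row["hamming_window"]),
                    )
                verdict = None
                if row["probability"] != ".":
                    verdict = JunctionVerdict(
                        float(row["probability"]), row["genuine"] == "1"
                    )
                out[locus] = JunctionRecord(
                    locus=locus,
                    metrics=metrics,
                    site_call=site,
                    hamming=hamming,
                    intron_score=_parse_opt(row["intron_score"], float),
                    pwm_score=_parse_opt(row["pwm_score"], float),
                    splicing_signal=_parse_opt(row["splicing_signal"], float),
                    verdict=verdict,
                    anchor_left_start=int(row["anchor_left_start"]),
                    anchor_right_end=int(row["anchor_right_end"]),
                )
            except (ValueError, KeyError) as exc:
                if isinstance(exc, ParseError):
                    raise
                raise ParseError(path, line_no, str(exc)) from exc
    return out


def _bed_score(rec: JunctionRecord) -> int:
    return 0 if rec.verdict is None else round(1000 * rec.verdict.probability)


def _write_bed_exon(records: Sequence[JunctionRecord], path: str) -> None:
    with open(path, "w") as fh:
        for i, rec in enumerate(records):
            l = rec.locus
            chrom_start = rec.anchor_left_start if rec.anchor_left_start < l.start else max(0, l.start - 1)
            chrom_end = rec.anchor_right_end if rec.anchor_right_end > l.end else l.end + 1
            left_size = l.start - chrom_start
            right_size = chrom_end - l.end
            fh.write(
                "\t".join(
                    str(x)
                    for x in [
                        l.contig, chrom_start, chrom_end, _junction_id(i),
                        _bed_score(rec), l.strand if l.strand != "?" else ".",
                        l.start, l.end, "255,0,0", 2,
                        f"{left_size},{right_size}", f"0,{l.end - chrom_start}",
                    ]
                )
                + "\n"
            )


def _read_bed_exon(path: str) -> dict[IntronLocus, JunctionRecord]:
    out: dict[IntronLocus, JunctionRecord] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(path, line_no, f"expected 12 BED fields, got {len(fields)}")
            if int(fields[9]) != 2:
                raise ParseError(path, line_no, f"blockCount must be 2, got {fields[9]}")
            contig = fields[0]
            chrom_start = int(fields[1])
            strand = fields[5] if fields[5] in ("+", "-") else "?"
            thick_start, thick_end = int(fields[6]), int(fields[7])
            locus = IntronLocus(contig, thick_start, thick_end, strand)
            score = int(fields[4])
            verdict = JunctionVerdict(score / 1000, score / 1000 >= 0.5)
            out[locus] = JunctionRecord(
                locus=locus,
                verdict=verdict,
                anchor_left_start=chrom_start,
                anchor_right_end=int(fields[2]),
            )
    return out


def _write_intron_bed(records: Sequence[JunctionRecord], path: str) -> None:
    with open(path, "w") as fh:
        for i, rec in enumerate(records):
            l = rec.locus
            fh.write(
                "\t".join(
                    str(x)
                    for x in [
                        l.contig, l.start, l.end, _junction_id(i), _bed_score(rec),
                        l.strand if l.strand != "?" else ".",
                    ]
                )
                + "\n"
            )


def _read_intron_bed(path: str) -> dict[IntronLocus, JunctionRecord]:
    out: dict[IntronLocus, JunctionRecord] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(path, line_no, "need at least 3 BED fields")
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "?"
            try:
                locus = IntronLocus(fields[0], int(fields[1]), int(fields[2]), strand)
            except ValueError as exc:
                raise ParseError(path, line_no, str(exc)) from exc
            out[locus] = JunctionRecord(locus=locus)
    return out


def _write_hint_gff(records: Sequence[JunctionRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, rec in enumerate(records):
            l = rec.locus
            mult = rec.metrics.nb_raw if rec.metrics else 1
            score = "." if rec.verdict is None else repr(rec.verdict.probability)
            fh.write(
                "\t".join(
                    str(x)
                    for x in [
                        l.contig, "splicefilter", "intron", l.start + 1, l.end,
                        score, l.strand if l.strand != "?" else ".", ".",
                        f"ID={_junction_id(i)};mult={mult}",
                    ]
                )
                + "\n"
            )


def _write_mapper_sj(records: Sequence[JunctionRecord], path: str) -> None:
    with open(path, "w") as fh:
        for rec in records:
            l = rec.locus
            fh.write(
                f"{l.contig}\t{l.start - 1}\t{l.end}\t"
                f"{l.strand if l.strand != '?' else '.'}\n"
            )


# ---------------------------------------------------------------------------
# Marked sets, set algebra and reference comparison


@dataclass
class MarkedEntry:
    record: JunctionRecord | None = None
    sample_count: int = 1
    in_reference: bool | None = None


@dataclass
class MarkedJunctionSet:
    """A keyed junction collection with per-sample presence bookkeeping."""

    records: dict[IntronLocus, MarkedEntry] = field(default_factory=dict)

    @classmethod
    def from_records(
        cls, records: Mapping[IntronLocus, JunctionRecord]
    ) -> "MarkedJunctionSet":
        return cls({k: MarkedEntry(record=v) for k, v in records.items()})

    @classmethod
    def from_loci(cls, loci: Iterable[IntronLocus]) -> "MarkedJunctionSet":
        return cls({l: MarkedEntry(record=JunctionRecord(locus=l)) for l in loci})

    def keys(self) -> set[IntronLocus]:
        return set(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, locus: IntronLocus) -> bool:
        return locus in self.records


def set_operate(sets: Sequence[MarkedJunctionSet], op: str) -> MarkedJunctionSet:
    """union | intersection | subtract over junction keys.

    Union accumulates per-sample presence counts (each input contributes its
    own counts, so unions of unions keep honest tallies).  Intersection keeps
    keys present in every input; subtract keeps keys of the first input only.
    """
    if len(sets) < 2:
        raise ValueError("set operations need at least 2 sets")
    if op == "union":
        out: dict[IntronLocus, MarkedEntry] = {}
        for s in sets:
            for locus, entry in s.records.items():
                if locus in out:
                    got = out[locus]
                    got.sample_count += entry.sample_count
                    if got.record is None:
                        got.record = entry.record
                else:
                    out[locus] = MarkedEntry(
                        record=entry.record,
                        sample_count=entry.sample_count,
                        in_reference=entry.in_reference,
                    )
        return MarkedJunctionSet(out)
    if op == "intersection":
        keys = set(sets[0].records)
        for s in sets[1:]:
            keys &= set(s.records)
        return MarkedJunctionSet(
            {k: MarkedEntry(record=sets[0].records[k].record, sample_count=len(sets))
             for k in keys}
        )
    if op == "subtract":
        drop = set()
        for s in sets[1:]:
            drop |= set(s.records)
        return MarkedJunctionSet(
            {k: e for k, e in sets[0].records.items() if k not in drop}
        )
    raise ValueError(f"unknown set operation {op!r}")


@dataclass
class ReferenceIndex:
    """Annotated introns plus their boundary splice-site positions."""

    introns: dict[tuple[str, int, int], str]  # key -> strand
    sites: set[tuple[str, int, str]]  # (contig, boundary position, strand)

    @classmethod
    def from_loci(cls, loci: Iterable[IntronLocus]) -> "ReferenceIndex":
        introns: dict[tuple[str, int, int], str] = {}
        sites: set[tuple[str, int, str]] = set()
        for l in loci:
            introns[l.key()] = l.strand
            sites.add((l.contig, l.start, l.strand))
            sites.add((l.contig, l.end, l.strand))
        return cls(introns, sites)

    def _site_known(self, contig: str, pos: int, strand: str) -> bool:
        if strand == "?":
            return any((contig, pos, s) in self.sites for s in ("+", "-", "?"))
        return (
            (contig, pos, strand) in self.sites or (contig, pos, "?") in self.sites
        )

    def intron_known(self, locus: IntronLocus) -> bool:
        ref_strand = self.introns.get(locus.key())
        if ref_strand is None:
            return False
        return "?" in (ref_strand, locus.strand) or ref_strand == locus.strand


@dataclass
class ClassBreakdown:
    """The four-way partition of junctions by reference support."""

    counts: tuple[int, int, int, int]
    labels: dict[IntronLocus, int]

    @property
    def class1(self) -> int:
        return self.counts[0]

    @property
    def class2(self) -> int:
        return self.counts[1]

    @property
    def class3(self) -> int:
        return self.counts[2]

    @property
    def class4(self) -> int:
        return self.counts[3]


def compare_to_reference(
    junctions: Iterable[IntronLocus], reference: ReferenceIndex
) -> ClassBreakdown:
    """Partition junctions into the four reference-support classes.

    1: both sites match the same annotated intron; 2: both boundary sites
    are annotated but never as one intron; 3: exactly one site annotated;
    4: both sites novel.  Matching is strand-aware when both strands are
    known, strand-agnostic otherwise.
    """
    counts = [0, 0, 0, 0]
    labels: dict[IntronLocus, int] = {}
    for locus in junctions:
        if reference.intron_known(locus):
            cls = 1
        else:
            left = reference._site_known(locus.contig, locus.start, locus.strand)
            right = reference._site_known(locus.contig, locus.end, locus.strand)
            cls = 2 if (left and right) else 3 if (left or right) else 4
        counts[cls - 1] += 1
        labels[locus] = cls
    return ClassBreakdown(tuple(counts), labels)


def evaluate(
    predicted: set[IntronLocus] | Iterable[IntronLocus],
    truth: set[IntronLocus] | Iterable[IntronLocus],
) -> tuple[float, float, float]:
    """(recall, precision, F1) of predicted junction keys against truth keys."""
    pred = {(l.contig, l.start, l.end) for l in predicted}
    tru = {(l.contig, l.start, l.end) for l in truth}
    if not tru:
        raise ValueError("truth set is empty")
    tp = len(pred & tru)
    recall = tp / len(tru)
    precision = tp / len(pred) if pred else 0.0
    f1 = (
        2 * recall * precision / (recall + precision)
        if (recall + precision) > 0
        else 0.0
    )
    return recall, precision, f1


def load_reference(path: str, fmt: str | None = None) -> ReferenceIndex:
    """Build a ReferenceIndex from GTF/GFF3 annotation or an intron BED.

    For GTF/GFF3, introns are derived from consecutive exons of each
    transcript; single-exon transcripts contribute nothing.  The format is
    guessed from the extension when not given.
    """
    if fmt is None:
        lower = path.lower()
        if lower.endswith((".bed", ".bed6")):
            fmt = "bed"
        elif lower.endswith((".gtf",)):
            fmt = "gtf"
        else:
            fmt = "gff3"
    if fmt == "bed":
        records = _read_intron_bed(path)
        return ReferenceIndex.from_loci(records.keys())
    return ReferenceIndex.from_loci(_annotation_introns(path))


def _annotation_introns(path: str) -> list[IntronLocus]:
    import gffutils

    db = gffutils.create_db(
        path,
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_transcript: dict[str, list] = {}
    for exon in db.features_of_type("exon"):
        if "transcript_id" in exon.attributes:
            parent = exon.attributes["transcript_id"][0]
        elif "Parent" in exon.attributes:
            parent = exon.attributes["Parent"][0]
        else:
            continue
        by_transcript.setdefault(parent, []).append(exon)
    loci: dict[tuple[str, int, int], IntronLocus] = {}
    for exons in by_transcript.values():
        exons.sort(key=lambda e: e.start)
        for a, b in zip(exons, exons[1:]):
            # GFF/GTF are 1-based inclusive: the intron is (a.end, b.start-1]
            start, end = a.end, b.start - 1
            if end <= start:
                continue
            locus = IntronLocus(a.seqid, start, end, a.strand if a.strand in "+-" else "?")
            loci[locus.key()] = locus
    return list(loci.values())
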