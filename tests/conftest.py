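import numpy as np
import pysam
import pytest

from splicefilter.synthetic import FixtureSpec, generate_fixture


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """A small mixed fixture: 40 genuine + 40 spurious junctions, 0.5% errors."""
    spec = FixtureSpec(
        seed=7,
        n_contigs=2,
        contig_length=30_000,
        n_genuine=40,
        spurious={"low_entropy": 10, "non_canonical": 10, "repeat": 10, "single_read": 10},
        mismatch_rate=0.005,
    )
    outdir = tmp_path_factory.mktemp("small_fixture")
    return generate_fixture(spec, str(outdir))


@pytest.fixture(scope="session")
def clean_fixture(tmp_path_factory):
    """Error-free fixture with no spurious junctions."""
    spec = FixtureSpec(
        seed=3,
        n_contigs=1,
        contig_length=20_000,
        n_genuine=30,
        spurious={},
        mismatch_rate=0.0,
    )
    outdir = tmp_path_factory.mktemp("clean_fixture")
    return generate_fixture(spec, str(outdir))


def write_fasta(path, contigs: dict[str, str]) -> str:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n{seq}\n")
    pysam.FastaFile(str(path)).close()  # build the index
    return str(path)


def write_sam(path, contigs: dict[str, str], reads: list[tuple]) -> str:
    """reads: (qname, flag, contig, pos0, mapq, cigar, seq, tags...)"""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for name, seq in contigs.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for qname, flag, contig, pos0, mapq, cigar, seq, *tags in reads:
            fields = [
                qname, str(flag), contig, str(pos0 + 1), str(mapq), cigar,
                "*", "0", "0", seq, "I" * len(seq), *tags,
            ]
            fh.write("\t".join(fields) + "\n")
    return str(path)


@pytest.fixture()
def random_genome(tmp_path):
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=3000))
    path = write_fasta(tmp_path / "genome.fa", {"chr1": seq})
    return path, seq
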