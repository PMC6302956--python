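"""Export filtered junctions as hint files for two-pass alignment.

After filtering, the trusted junction set can be fed back to a spliced
aligner (as a splice-site text file) or to a gene predictor (as GFF3 intron
hints) to guide a second, more accurate alignment pass.
"""

import tempfile

from splicefilter import junction_io, pipeline
from splicefilter.model import PipelineConfig
from splicefilter.synthetic import FixtureSpec, generate_fixture

with tempfile.TemporaryDirectory() as work:
    spec = FixtureSpec(
        seed=11, n_contigs=1, contig_length=25_000, n_genuine=30,
        spurious={"low_entropy": 10, "single_read": 10}, mismatch_rate=0.005,
    )
    fixture = generate_fixture(spec, f"{work}/fx")
    result = pipeline.run_full(
        [fixture.sam], fixture.genome_fasta, PipelineConfig(seed=11), f"{work}/out"
    )

    junction_io.write_junctions(result.filtered, f"{work}/hints.ss", "mapper_sj")
    junction_io.write_junctions(result.filtered, f"{work}/hints.gff3", "hint_gff")

    with open(f"{work}/hints.ss") as fh:
        lines = fh.readlines()
    print(f"wrote {len(lines)} splice-site hints; first two:")
    for line in lines[:2]:
        print(" ", line.rstrip())
    with open(f"{work}/hints.gff3") as fh:
        print("GFF3 hint example:")
        print(" ", fh.readlines()[1].rstrip())

# Each splice-site hint line is: contig, 0-based position of the last exonic
# base before the intron, 0-based position of the first exonic base after it,
# and strand — the dialect spliced aligners accept as known splice sites.
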