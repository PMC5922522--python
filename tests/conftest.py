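"""Shared fixtures: small simulated datasets and hand-built alignment files."""

import numpy as np
import pysam
import pytest

from cnvlossverify import SimulationSpec, simulate_dataset
from cnvlossverify.synthetic_data import make_reference, plant_deletions, simulate_alignments


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A 100 kb contig, 5 mixed-zygosity deletions, 4x depth, 1% errors."""
    spec = SimulationSpec(ref_length=100_000, n_deletions=5, seed=11)
    out = tmp_path_factory.mktemp("smallds")
    paths = simulate_dataset(spec, out)
    return spec, paths


@pytest.fixture(scope="session")
def clean_hom_dataset(tmp_path_factory):
    """Error-free 10x data over homozygous deletions (exact-truth regime)."""
    spec = SimulationSpec(
        ref_length=120_000,
        n_deletions=6,
        hom_fraction=1.0,
        mean_depth=10.0,
        error_rate=0.0,
        seed=23,
    )
    out = tmp_path_factory.mktemp("cleands")
    ref = make_reference(spec, out / "ref.fa")
    haps, truth = plant_deletions(ref, spec)
    bam = simulate_alignments(haps, truth, out / "reads.bam")
    return {"spec": spec, "ref": ref, "fasta": out / "ref.fa", "bam": bam, "truth": truth}


def write_tiny_bam(path, reads, chrom="chrT", chrom_len=10_000):
    """Write a coordinate-sorted indexed BAM from (name, pos, seq, flags) dicts.

    Each read dict: name, pos, seq; optional cigar, flag overrides
    (is_duplicate, is_secondary, mapq).
    """
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": chrom, "LN": chrom_len}]}
    )
    recs = []
    for r in reads:
        a = pysam.AlignedSegment(header)
        a.query_name = r["name"]
        a.query_sequence = r["seq"]
        a.query_qualities = pysam.qualitystring_to_array("I" * len(r["seq"]))
        a.reference_id = 0
        a.reference_start = r["pos"]
        a.cigarstring = r.get("cigar", f"{len(r['seq'])}M")
        a.mapping_quality = r.get("mapq", 60)
        a.is_duplicate = r.get("is_duplicate", False)
        a.is_secondary = r.get("is_secondary", False)
        a.is_supplementary = r.get("is_supplementary", False)
        recs.append(a)
    recs.sort(key=lambda a: a.reference_start)
    with pysam.AlignmentFile(str(path), "wb", header=header) as out:
        for a in recs:
            out.write(a)
    pysam.index(str(path))
    return path


@pytest.fixture()
def tiny_bam(tmp_path):
    def _make(reads, **kw):
        return write_tiny_bam(tmp_path / "tiny.bam", reads, **kw)

    return _make
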