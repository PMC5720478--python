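import sys
from pathlib import Path

import numpy as np
import pysam
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from hlaloh.hla_alleles import HlaAllele
from hlaloh.synthetic_data import SimConfig, make_homolog_pair


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def homolog_pair():
    """A deterministic 1 kb pair with 20 planted substitutions."""
    cfg = SimConfig(seed=7, n_substitutions=20)
    return make_homolog_pair(cfg)


@pytest.fixture
def small_allele(rng):
    seq = "".join(rng.choice(list("ACGT"), size=400))
    return HlaAllele("hla_a_test_01", seq)


def write_tiny_bam(path, records, chrom="chr6", length=171_115_067):
    """Write a coordinate-sorted, indexed BAM from (name, mate, pos, seq,
    mate_pos) tuples; mate_pos None marks a mate-unmapped read."""
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": chrom, "LN": length}]}
    segs = []
    for name, mate, pos, seq, mate_pos in records:
        a = pysam.AlignedSegment()
        a.query_name = name
        a.query_sequence = seq
        flag = 0x1 | (0x40 if mate == 1 else 0x80)
        if mate_pos is None:
            flag |= 0x8
        a.flag = flag
        a.reference_id = 0
        a.reference_start = pos
        a.mapping_quality = 60
        a.cigarstring = f"{len(seq)}M"
        a.next_reference_id = 0 if mate_pos is not None else -1
        a.next_reference_start = mate_pos if mate_pos is not None else -1
        segs.append(a)
    segs.sort(key=lambda a: a.reference_start)
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for a in segs:
            bam.write(a)
    pysam.index(str(path))
    return path
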