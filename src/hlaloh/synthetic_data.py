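"""Synthetic patients: allele pairs, tumor/germline reads, trees, truth.

The generative model mirrors the purity/ploidy mixture the caller inverts.
A tumor sample of purity rho contains rho tumor cells carrying (n1, n2)
copies of the two homologs of a gene and 1 - rho diploid stromal cells
carrying one copy of each, so homolog i is sequenced with weight
(1 - rho) + rho * n_i while the germline weights both homologs equally.
Read counts are Poisson; read start positions are uniform; sequencing
errors are i.i.d. substitutions.  Every fixture ships a machine-readable
truth record with the planted site positions and the model-expected BAF,
logR, and verdict, so downstream estimates can be scored exactly.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pysam

from .hla_alleles import HlaAllele
from .realignment import HLA_REGIONS, ReadRecord

__all__ = [
    "SimConfig",
    "SimTruth",
    "make_homolog_pair",
    "simulate_sample_reads",
    "emit_fixture",
    "expected_baf",
    "expected_logr",
    "expected_verdict",
]

_BASES = np.array(list("ACGT"))


def expected_baf(rho: float, n1: float, n2: float) -> float:
    """Model-expected homolog-1 allele fraction in the tumor sample."""
    return (1 - rho + rho * n1) / (2 * (1 - rho) + rho * (n1 + n2))


def expected_logr(rho: float, psi: float, n1: float, n2: float) -> float:
    """Model-expected log2 coverage ratio of tumor to germline."""
    return math.log2((2 * (1 - rho) + rho * (n1 + n2)) / (2 * (1 - rho) + rho * psi))


def expected_verdict(n1: float, n2: float) -> str:
    if n1 == n2:
        return "no_imbalance"
    if min(n1, n2) < 0.5:
        return "loh_allele1_lost" if n1 < n2 else "loh_allele2_lost"
    return "allelic_imbalance_no_loh"


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated gene.

    Defaults describe a well-powered exome-like experiment: a 1 kb gene
    with 25 discriminating substitutions, 100 bp reads at 100x mean
    germline depth per homolog, and error-free bases unless asked for.
    """

    seed: int
    gene: str = "A"
    gene_length: int = 1000
    n_substitutions: int = 25
    indels: tuple[int, ...] = ()  # deletion lengths planted in allele 2
    read_length: int = 100
    germline_depth: float = 100.0
    rho: float = 1.0
    psi: float = 2.0
    cn: tuple[float, float] = (1.0, 1.0)
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.cn[0] < 0 or self.cn[1] < 0:
            raise ValueError("true copy numbers must be non-negative")
        if not 0 <= self.error_rate <= 0.05:
            raise ValueError("per-base error rate must lie in [0, 0.05]")
        if not 0 < self.rho <= 1:
            raise ValueError("purity must be in (0, 1]")
        if self.n_substitutions > self.gene_length:
            raise ValueError("more substitutions requested than positions available")

    @property
    def allele_names(self) -> tuple[str, str]:
        g = self.gene.lower()
        if self.n_substitutions == 0 and not self.indels:
            name = f"hla_{g}_sim_01"
            return (name, name)
        return (f"hla_{g}_sim_01", f"hla_{g}_sim_02")


@dataclasses.dataclass(frozen=True)
class SimTruth:
    """Ground truth emitted with every fixture."""

    config: SimConfig
    site_pos1: tuple[int, ...]  # 1-based on allele 1
    site_pos2: tuple[int, ...]  # 1-based on allele 2
    site_base1: tuple[str, ...]
    site_base2: tuple[str, ...]
    expected_baf: float
    expected_logr: float
    expected_verdict: str
    homozygous_like: bool

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["config"] = dataclasses.asdict(self.config)
        return d


def make_homolog_pair(cfg: SimConfig) -> tuple[HlaAllele, HlaAllele, SimTruth]:
    """Generate a homolog pair with planted substitutions (and deletions).

    Allele 2 equals allele 1 with ``n_substitutions`` substitutions at
    distinct random positions plus the configured deletions, placed in
    site-free stretches so every planted site survives.  Deterministic
    under the config seed.
    """
    rng = np.random.default_rng(cfg.seed)
    seq1 = rng.choice(_BASES, size=cfg.gene_length)
    # sites stay clear of the sequence ends: a terminal mismatch has no
    # flanking anchor and is clipped by local alignment
    margin = min(10, max(0, (cfg.gene_length - cfg.n_substitutions) // 2))
    eligible = np.arange(margin, cfg.gene_length - margin)
    sub_pos = np.sort(rng.choice(eligible, size=cfg.n_substitutions, replace=False))
    seq2 = seq1.copy()
    for p in sub_pos:
        choices = [b for b in "ACGT" if b != seq1[p]]
        seq2[p] = choices[rng.integers(3)]

    # deletions in allele 2, kept clear of planted sites
    deleted = np.zeros(cfg.gene_length, dtype=bool)
    occupied = set(int(p) for p in sub_pos)
    for dlen in cfg.indels:
        for _ in range(1000):
            start = int(rng.integers(0, cfg.gene_length - dlen))
            span = range(start, start + dlen)
            if all(p not in occupied and not deleted[p] for p in span):
                deleted[list(span)] = True
                break
        else:
            raise ValueError(f"could not place a {dlen}-base deletion")

    keep = ~deleted
    shift = np.cumsum(deleted)  # bases removed at or before each position
    pos2 = [int(p) + 1 - int(shift[p]) for p in sub_pos]
    name1, name2 = cfg.allele_names
    a1 = HlaAllele(name1, "".join(seq1))
    homozygous_like = cfg.n_substitutions == 0 and not cfg.indels
    a2 = a1 if homozygous_like else HlaAllele(name2, "".join(seq2[keep]))
    n1, n2 = cfg.cn
    truth = SimTruth(
        config=cfg,
        site_pos1=tuple(int(p) + 1 for p in sub_pos),
        site_pos2=tuple(pos2),
        site_base1=tuple(str(seq1[p]) for p in sub_pos),
        site_base2=tuple(str(seq2[p]) for p in sub_pos),
        expected_baf=expected_baf(cfg.rho, n1, n2) if not homozygous_like else 0.5,
        expected_logr=expected_logr(cfg.rho, cfg.psi, n1, n2),
        expected_verdict=expected_verdict(n1, n2),
        homozygous_like=homozygous_like,
    )
    return a1, a2, truth


def _allele_mean_depths(cfg: SimConfig, sample: str) -> tuple[float, float]:
    if sample == "germline":
        return cfg.germline_depth, cfg.germline_depth
    n1, n2 = cfg.cn
    denom = 2 * (1 - cfg.rho) + cfg.rho * cfg.psi
    w1 = (1 - cfg.rho) + cfg.rho * n1
    w2 = (1 - cfg.rho) + cfg.rho * n2
    return (2 * cfg.germline_depth * w1 / denom, 2 * cfg.germline_depth * w2 / denom)


def simulate_sample_reads(
    pair: tuple[HlaAllele, HlaAllele],
    cfg: SimConfig,
    sample: str,
    rng: np.random.Generator | None = None,
) -> list[ReadRecord]:
    """Draw one sample's reads from the two homologs.

    The germline sequences both homologs at ``germline_depth`` each; the
    tumor sequences homolog i at depth proportional to (1-rho) + rho*n_i,
    with the total scaled by the model coverage ratio relative to the
    germline.  Reads come in mate pairs drawn from the same homolog (one
    fragment, two mates) so the mate-consistency filter sees realistic
    input.  Deterministic under the config seed.
    """
    if sample not in ("tumor", "germline"):
        raise ValueError("sample must be 'tumor' or 'germline'")
    if rng is None:
        # offset keeps tumor/germline and pair generation streams independent
        rng = np.random.default_rng(cfg.seed + (1 if sample == "tumor" else 2))
    reads: list[ReadRecord] = []
    for idx, (allele, mean_depth) in enumerate(zip(pair, _allele_mean_depths(cfg, sample))):
        length = len(allele)
        if length < cfg.read_length:
            raise ValueError("allele shorter than read length")
        n_pairs = rng.poisson(mean_depth * length / cfg.read_length / 2.0)
        starts = rng.integers(0, length - cfg.read_length + 1, size=2 * n_pairs)
        for j in range(n_pairs):
            name = f"{sample}_{cfg.gene.lower()}_h{idx + 1}_{j:06d}"
            for mate in (1, 2):
                start = int(starts[2 * j + mate - 1])
                seq = list(allele.sequence[start : start + cfg.read_length])
                if cfg.error_rate > 0:
                    hits = np.nonzero(rng.random(cfg.read_length) < cfg.error_rate)[0]
                    for h in hits:
                        alt = [b for b in "ACGT" if b != seq[h]]
                        seq[h] = alt[rng.integers(3)]
                reads.append(ReadRecord(name, mate, "".join(seq)))
    return reads


_CHR6_LENGTH = 171_115_067

#: Total span of the three class I extraction windows (bp).
REGION_SPAN = sum(hi - lo + 1 for _, lo, hi in HLA_REGIONS)


def background_span(configs: dict[str, "SimConfig"]) -> int:
    """Copy-number-neutral portion of the extraction windows (bp).

    The extraction windows cover far more sequence than the HLA genes
    themselves; reads from that surrounding sequence are extracted too and
    enter the unique-read counts that define the multiplication factor M,
    even though they align to no allele.  Emulating them matters: without
    the neutral background, M would partially absorb the very copy-number
    signal it is meant to preserve.
    """
    return REGION_SPAN - sum(cfg.gene_length for cfg in configs.values())


def simulate_background_reads(
    span_bp: int,
    cfg: SimConfig,
    sample: str,
    rng: np.random.Generator | None = None,
) -> list[ReadRecord]:
    """Reads from the copy-number-neutral sequence around the HLA genes.

    Drawn from a random diploid reference at the configured germline depth
    per haplotype (tumor scaled by the neutral mixture factor), these
    reads are extracted like any others but align to no allele; they only
    contribute to the region-level unique-read counts behind M.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + (5 if sample == "tumor" else 6))
    ref = "".join(rng.choice(_BASES, size=span_bp))
    depth = 2 * cfg.germline_depth
    if sample == "tumor":
        # neutral diploid region: total copy number 2 in tumor cells
        depth *= 2.0 / (2 * (1 - cfg.rho) + cfg.rho * cfg.psi)
    n_pairs = rng.poisson(depth * span_bp / cfg.read_length / 2.0)
    starts = rng.integers(0, span_bp - cfg.read_length + 1, size=2 * n_pairs)
    reads = []
    for j in range(n_pairs):
        name = f"{sample}_bg_{j:06d}"
        for mate in (1, 2):
            s = int(starts[2 * j + mate - 1])
            reads.append(ReadRecord(name, mate, ref[s : s + cfg.read_length]))
    return reads


def _write_fastq(reads: list[ReadRecord], path: Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = r.qualities or "I" * len(r.sequence)
            fh.write(f"@{r.name}/{r.mate}\n{r.sequence}\n+\n{qual}\n")


def _write_bam(reads: list[ReadRecord], path: Path, seed: int) -> None:
    """Minimal sorted+indexed BAM with read pairs placed in the HLA-A window.

    Placement only needs to overlap the extraction region; the reads'
    biological origin is the allele FASTA, not chr6.
    """
    rng = np.random.default_rng(seed)
    chrom, lo, hi = HLA_REGIONS[0]
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": chrom, "LN": _CHR6_LENGTH}],
    }
    by_name: dict[str, dict[int, ReadRecord]] = {}
    for r in reads:
        by_name.setdefault(r.name, {})[r.mate] = r
    records = []
    for name in sorted(by_name):
        mates = by_name[name]
        span = hi - lo - max(len(r.sequence) for r in mates.values())
        pos = {m: int(lo - 1 + rng.integers(0, span)) for m in mates}
        for mate, r in sorted(mates.items()):
            a = pysam.AlignedSegment()
            a.query_name = name
            a.query_sequence = r.sequence
            a.flag = (0x1 | 0x2 | (0x40 if mate == 1 else 0x80)) if len(mates) == 2 else 0x40
            a.reference_id = 0
            a.reference_start = pos[mate]
            a.mapping_quality = 60
            a.cigarstring = f"{len(r.sequence)}M"
            if len(mates) == 2:
                a.next_reference_id = 0
                a.next_reference_start = pos[3 - mate]
            else:
                a.next_reference_id = -1
                a.next_reference_start = -1
            a.query_qualities = pysam.qualitystring_to_array("I" * len(r.sequence))
            records.append(a)
    records.sort(key=lambda a: a.reference_start)
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for a in records:
            bam.write(a)
    pysam.index(str(path))


def emit_fixture(
    configs: SimConfig | dict[str, SimConfig],
    out_dir: str | Path,
    with_background: bool = True,
) -> dict[str, Path]:
    """Write a complete on-disk patient fixture.

    Produces the allele FASTA, tumor/germline FASTQ and sorted+indexed
    BAM, an HLA-calls TSV, and a truth JSON.  Unless disabled, neutral
    background reads emulating the rest of the extraction windows are
    included (they set the scale of M).  FASTA/FASTQ/JSON are
    byte-identical across re-runs with the same seeds.
    """
    if isinstance(configs, SimConfig):
        configs = {configs.gene: configs}
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    alleles: dict[str, HlaAllele] = {}
    calls: list[tuple[str, str, str]] = []
    truths: dict[str, dict] = {}
    tumor_reads: list[ReadRecord] = []
    germline_reads: list[ReadRecord] = []
    for gene, cfg in sorted(configs.items()):
        a1, a2, truth = make_homolog_pair(cfg)
        alleles[a1.name] = a1
        alleles[a2.name] = a2
        calls.append((gene, a1.name, a2.name))
        truths[gene] = truth.to_dict()
        tumor_reads += simulate_sample_reads((a1, a2), cfg, "tumor")
        germline_reads += simulate_sample_reads((a1, a2), cfg, "germline")
    if with_background:
        span = background_span(configs)
        base = next(iter(sorted(configs.items())))[1]
        tumor_reads += simulate_background_reads(span, base, "tumor")
        germline_reads += simulate_background_reads(span, base, "germline")

    paths = {
        "fasta": out_dir / "alleles.fasta",
        "hla_calls": out_dir / "hla_calls.tsv",
        "truth": out_dir / "truth.json",
        "tumor_fastq": out_dir / "tumor.fastq",
        "germline_fastq": out_dir / "germline.fastq",
        "tumor_bam": out_dir / "tumor.bam",
        "germline_bam": out_dir / "germline.bam",
    }
    with open(paths["fasta"], "w") as fh:
        for allele in alleles.values():
            fh.write(f">{allele.name}\n{allele.sequence}\n")
    with open(paths["hla_calls"], "w") as fh:
        fh.write("gene\tallele1\tallele2\n")
        for gene, n1, n2 in calls:
            fh.write(f"{gene}\t{n1}\t{n2}\n")
    with open(paths["truth"], "w") as fh:
        json.dump(truths, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _write_fastq(tumor_reads, paths["tumor_fastq"])
    _write_fastq(germline_reads, paths["germline_fastq"])
    first = next(iter(configs.values()))
    _write_bam(tumor_reads, paths["tumor_bam"], seed=first.seed + 11)
    _write_bam(germline_reads, paths["germline_bam"], seed=first.seed + 12)
    return paths
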