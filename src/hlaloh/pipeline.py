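"""End-to-end orchestration: reads in, per-gene LOH verdicts out.

``run_call_pipeline`` executes the whole workflow on a pair of alignment
files; ``call_gene`` is the per-gene core shared with simulation-driven
evaluation (it accepts in-memory reads, so parameter-recovery studies can
skip the BAM round trip).
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

from . import cn_model, realignment
from .hla_alleles import (
    MIN_MISMATCH_SITES,
    HlaAllele,
    PatientHlaType,
    align_homologs,
    find_mismatch_sites,
    load_allele_sequences,
)
from .realignment import HLA_CONTIGS, HLA_REGIONS, ReadRecord

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "GeneResult", "call_gene", "run_call_pipeline", "load_hla_calls"]


@dataclasses.dataclass
class RunConfig:
    """All knobs of one caller run; defaults are the published constants."""

    tumor_path: Path
    germline_path: Path
    hla_fasta: Path
    hla_calls: Path
    rho: float
    psi: float
    out_dir: Path | None = None
    bin_width: int = cn_model.DEFAULT_BIN_WIDTH
    min_sites: int = MIN_MISMATCH_SITES
    min_germline_bin_depth: float = cn_model.MIN_GERMLINE_BIN_DEPTH
    cn_threshold: float = cn_model.LOH_CN_THRESHOLD
    alpha: float = cn_model.IMBALANCE_ALPHA
    regions: tuple[tuple[str, int, int], ...] = HLA_REGIONS
    contigs: tuple[str, ...] = HLA_CONTIGS

    def __post_init__(self) -> None:
        for name in ("bin_width", "min_sites", "min_germline_bin_depth",
                     "cn_threshold", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclasses.dataclass
class GeneResult:
    gene: str
    allele1: str
    allele2: str
    cn1: float | None
    cn2: float | None
    p_value: float | None
    n_sites: int
    n_bins: int
    verdict: str
    baf_sites: list[cn_model.BafSite] = dataclasses.field(default_factory=list)
    bins: list[cn_model.LogRBin] = dataclasses.field(default_factory=list)


def call_gene(
    gene: str,
    allele1: HlaAllele,
    allele2: HlaAllele,
    tumor_reads: list[ReadRecord],
    germline_reads: list[ReadRecord],
    pp: cn_model.PurityPloidy,
    m_factor: float | None = None,
    bin_width: int = cn_model.DEFAULT_BIN_WIDTH,
    min_sites: int = MIN_MISMATCH_SITES,
    min_germline_bin_depth: float = cn_model.MIN_GERMLINE_BIN_DEPTH,
    cn_threshold: float = cn_model.LOH_CN_THRESHOLD,
    alpha: float = cn_model.IMBALANCE_ALPHA,
) -> GeneResult:
    """Run re-alignment, filtering, coverage, and the CN model on one gene.

    ``m_factor`` is the germline/tumor unique-read ratio over the whole
    extracted HLA region; when calling a gene in isolation it defaults to
    the ratio over this gene's own aligned reads (a weaker normalization,
    since the gene's copy-number signal then partially cancels).
    """
    if allele1.name == allele2.name:
        return GeneResult(gene, allele1.name, allele2.name, None, None, None,
                          0, 0, cn_model.Verdict.HOMOZYGOUS)

    aln = align_homologs(allele1, allele2, gene=gene)
    sites = find_mismatch_sites(aln)
    if len(sites) < min_sites:
        logger.warning("gene %s: only %d mismatch sites; insufficiently polymorphic",
                       gene, len(sites))
        return GeneResult(gene, allele1.name, allele2.name, None, None, None,
                          len(sites), 0, cn_model.Verdict.INDETERMINATE)

    pos1 = [s.pos1 for s in sites]
    pos2 = [s.pos2 for s in sites]
    tracks: dict[str, realignment.CoverageTrack] = {}
    plain: dict[str, realignment.UniqueSiteCoverage] = {}
    unique: dict[str, realignment.UniqueSiteCoverage] = {}
    n_unique_reads: dict[str, int] = {}
    for sample, reads in (("tumor", tumor_reads), ("germline", germline_reads)):
        per_allele = {
            allele1.name: realignment.align_reads_to_allele(reads, allele1),
            allele2.name: realignment.align_reads_to_allele(reads, allele2),
        }
        best = realignment.best_allele_assignment(per_allele)
        sample_reads: set[tuple[str, int]] = set()
        for allele, positions in ((allele1, pos1), (allele2, pos2)):
            kept = realignment.filter_alignments(per_allele[allele.name], best)
            track = realignment.compute_coverage(kept, allele, sample)
            tracks[f"{sample}:{allele.name}"] = track
            sample_reads.update(a.read.key for a in kept)
            # only reads uniquely best on this homolog carry site evidence
            unambiguous = [a for a in kept if best.get(a.read.key) == allele.name]
            plain[f"{sample}:{allele.name}"] = realignment.site_coverage_plain(
                unambiguous, sites, positions, sample
            )
            unique[f"{sample}:{allele.name}"] = realignment.site_coverage_unique(
                unambiguous, sites, positions, sample
            )
        n_unique_reads[sample] = len(sample_reads)

    if n_unique_reads["tumor"] == 0 or n_unique_reads["germline"] == 0:
        return GeneResult(gene, allele1.name, allele2.name, None, None, None,
                          len(sites), 0, cn_model.Verdict.INDETERMINATE)
    if m_factor is None:
        m_factor = n_unique_reads["germline"] / n_unique_reads["tumor"]
    bins = cn_model.compute_logr_bins(
        (tracks[f"tumor:{allele1.name}"], tracks[f"tumor:{allele2.name}"]),
        (tracks[f"germline:{allele1.name}"], tracks[f"germline:{allele2.name}"]),
        m_factor, gene=gene, bin_width=bin_width,
        min_germline_depth=min_germline_bin_depth,
    )
    baf_sites = cn_model.compute_baf(
        (plain[f"tumor:{allele1.name}"], plain[f"tumor:{allele2.name}"]),
        (plain[f"germline:{allele1.name}"], plain[f"germline:{allele2.name}"]),
        (unique[f"tumor:{allele1.name}"], unique[f"tumor:{allele2.name}"]),
        (unique[f"germline:{allele1.name}"], unique[f"germline:{allele2.name}"]),
    )
    est = cn_model.estimate_gene_cn(baf_sites, bins, pp, bin_width=bin_width,
                                    min_sites=min_sites)
    p_value = cn_model.test_allelic_imbalance(baf_sites, min_sites=min_sites)
    verdict = cn_model.classify_loh(est, p_value, cn_threshold=cn_threshold, alpha=alpha)
    return GeneResult(
        gene, allele1.name, allele2.name,
        est.cn1 if est else None, est.cn2 if est else None,
        p_value, est.n_sites if est else len(baf_sites),
        est.n_bins if est else len(bins), verdict,
        baf_sites=baf_sites, bins=bins,
    )


def load_hla_calls(path: str | Path) -> PatientHlaType:
    """Read a gene/allele1/allele2 TSV into a patient genotype."""
    alleles: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["gene", "allele1", "allele2"]:
            raise ValueError(f"unexpected HLA-calls header in {path}: {header}")
        for line in fh:
            if not line.strip():
                continue
            gene, a1, a2 = line.rstrip("\n").split("\t")[:3]
            alleles[gene.upper()] = (a1, a2)
    return PatientHlaType(alleles)


def run_call_pipeline(cfg: RunConfig) -> list[GeneResult]:
    """Extract, re-align, filter, and call every gene of one patient."""
    genotype = load_hla_calls(cfg.hla_calls)
    registry = load_allele_sequences(cfg.hla_fasta, genotype.allele_names())
    pp = cn_model.PurityPloidy(cfg.rho, cfg.psi)
    tumor_reads = realignment.extract_candidate_reads(cfg.tumor_path, cfg.regions, cfg.contigs)
    germline_reads = realignment.extract_candidate_reads(cfg.germline_path, cfg.regions, cfg.contigs)
    logger.info("extracted %d tumor and %d germline candidate reads",
                len(tumor_reads), len(germline_reads))
    if not tumor_reads or not germline_reads:
        raise ValueError("no candidate reads extracted from one of the samples")
    # M over the whole extracted region: the germline/tumor unique-read
    # ratio that puts the samples on one coverage scale.
    m_factor = len(germline_reads) / len(tumor_reads)
    results = []
    for gene in genotype.GENES:
        name1, name2 = genotype.alleles[gene]
        results.append(call_gene(
            gene, registry[name1], registry[name2], tumor_reads, germline_reads, pp,
            m_factor=m_factor,
            bin_width=cfg.bin_width, min_sites=cfg.min_sites,
            min_germline_bin_depth=cfg.min_germline_bin_depth,
            cn_threshold=cfg.cn_threshold, alpha=cfg.alpha,
        ))
    if cfg.out_dir is not None:
        from .reports import write_report
        write_report(results, cfg.out_dir)
    return results
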