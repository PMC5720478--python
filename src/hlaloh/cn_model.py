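"""Allele-specific copy number, allelic imbalance, and the LOH verdict.

Coverage evidence is converted to binned logR (tumor/germline depth ratio,
rescaled by the unique-read multiplication factor M and log2-transformed)
and per-site BAF (homolog-1 share of the unique-read depth at each
discriminating site).  Given tumor purity rho and ploidy psi, each site's
(BAF, logR) pair inverts to the two homolog copy numbers:

    n1 = (rho - 1 + BAF * 2^logR * (2(1 - rho) + rho * psi)) / rho
    n2 = (rho - 1 - (BAF - 1) * 2^logR * (2(1 - rho) + rho * psi)) / rho

These are exact inverses of the standard purity/ploidy mixture model: a
tumor state (n1, n2) diluted by 1 - rho of diploid stroma produces
BAF = (1 - rho + rho n1) / (2(1 - rho) + rho(n1 + n2)) and a coverage
ratio (2(1 - rho) + rho(n1 + n2)) / (2(1 - rho) + rho psi).

A gene is called LOH when the smaller homolog copy number falls below 0.5
AND the paired t-test on per-site logR differences between the homologs
rejects at p < 0.01 (the extra test avoids over-calling loss from noisy
copy-number estimates alone).
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings

import numpy as np
from scipy import stats

from .hla_alleles import MIN_MISMATCH_SITES, MismatchSite
from .realignment import CoverageTrack, UniqueSiteCoverage

logger = logging.getLogger(__name__)

__all__ = [
    "PurityPloidy",
    "LogRBin",
    "BafSite",
    "AlleleCnEstimate",
    "HlaLossCall",
    "Verdict",
    "compute_logr_bins",
    "compute_baf",
    "allele_specific_cn",
    "estimate_gene_cn",
    "test_allelic_imbalance",
    "classify_loh",
    "normalized_allelic_ratio",
    "fisher_exact_2x2",
    "DEFAULT_BIN_WIDTH",
    "MIN_GERMLINE_BIN_DEPTH",
    "LOH_CN_THRESHOLD",
    "IMBALANCE_ALPHA",
]

DEFAULT_BIN_WIDTH = 150
MIN_GERMLINE_BIN_DEPTH = 10.0  # mean germline depth floor per bin
LOH_CN_THRESHOLD = 0.5
IMBALANCE_ALPHA = 0.01


class Verdict:
    LOH_ALLELE1 = "loh_allele1_lost"
    LOH_ALLELE2 = "loh_allele2_lost"
    IMBALANCE = "allelic_imbalance_no_loh"
    BALANCED = "no_imbalance"
    INDETERMINATE = "indeterminate"
    HOMOZYGOUS = "homozygous"


@dataclasses.dataclass(frozen=True)
class PurityPloidy:
    """Tumor purity rho in (0, 1] and tumor ploidy psi > 0 (supplied by an
    external allele-specific CN tool; never re-estimated here)."""

    rho: float
    psi: float

    def __post_init__(self) -> None:
        if not 0 < self.rho <= 1:
            raise ValueError(f"purity must be in (0, 1], got {self.rho}")
        if self.psi <= 0:
            raise ValueError(f"ploidy must be > 0, got {self.psi}")


@dataclasses.dataclass(frozen=True)
class LogRBin:
    """One 150-bp bin of combined-homolog coverage on allele-1 coordinates."""

    gene: str
    start: int
    end: int
    tumor_sum: int
    germline_sum: int
    m_factor: float
    logr: float


@dataclasses.dataclass(frozen=True)
class BafSite:
    """Per-site depths on the two homologs and the homolog-1 fraction.

    ``tumor1``..``germline2`` are plain pileup depths (they define BAF);
    ``utumor1``..``ugermline2`` count each sequencing template once and
    feed the paired imbalance test, where independent counts matter.
    """

    site: MismatchSite
    tumor1: int
    tumor2: int
    germline1: int
    germline2: int
    utumor1: int = 0
    utumor2: int = 0
    ugermline1: int = 0
    ugermline2: int = 0

    @property
    def baf(self) -> float:
        total = self.tumor1 + self.tumor2
        if total == 0:
            raise ZeroDivisionError("BAF undefined at zero combined depth")
        return self.tumor1 / total


@dataclasses.dataclass(frozen=True)
class AlleleCnEstimate:
    """Gene-level copy number of each homolog: the median across bins of
    per-bin medians of per-site estimates."""

    gene: str
    cn1: float
    cn2: float
    per_bin_cn1: dict[int, float]
    per_bin_cn2: dict[int, float]
    n_sites: int
    n_bins: int

    @property
    def min_cn(self) -> float:
        return min(self.cn1, self.cn2)


@dataclasses.dataclass(frozen=True)
class HlaLossCall:
    gene: str
    allele1: str
    allele2: str
    cn1: float | None
    cn2: float | None
    p_value: float | None
    n_sites: int
    n_bins: int
    verdict: str


def _bin_sum(depth: np.ndarray, start0: int, end0: int) -> tuple[int, int]:
    """Sum and covered length of depth[start0:end0], clipped to the track."""
    lo = min(start0, len(depth))
    hi = min(end0, len(depth))
    return int(depth[lo:hi].sum()), hi - lo


def compute_logr_bins(
    tumor: tuple[CoverageTrack, CoverageTrack],
    germline: tuple[CoverageTrack, CoverageTrack],
    m_factor: float,
    gene: str = "",
    bin_width: int = DEFAULT_BIN_WIDTH,
    min_germline_depth: float = MIN_GERMLINE_BIN_DEPTH,
) -> list[LogRBin]:
    """Binned logR across a gene, combining both homologs per bin.

    Per bin: ratio = M x (sum of tumor depth over both homologs) / (sum of
    germline depth over both homologs); logR = log2(ratio).  M is the
    germline-to-tumor unique-read-count ratio that puts the two samples on
    a common scale.  Bins whose mean germline depth falls below
    ``min_germline_depth`` are excluded.
    """
    t1, t2 = tumor
    g1, g2 = germline
    length = max(len(t1.depth), len(t2.depth))
    if length == 0:
        raise ValueError(f"gene {gene}: zero-length coverage tracks")
    bins: list[LogRBin] = []
    for start0 in range(0, length, bin_width):
        end0 = min(start0 + bin_width, length)
        ts = _bin_sum(t1.depth, start0, end0)[0] + _bin_sum(t2.depth, start0, end0)[0]
        gs1, w1 = _bin_sum(g1.depth, start0, end0)
        gs2, w2 = _bin_sum(g2.depth, start0, end0)
        gs = gs1 + gs2
        if w1 + w2 == 0 or gs / (w1 + w2) < min_germline_depth:
            continue
        ratio = m_factor * ts / gs
        logr = math.log2(ratio) if ratio > 0 else float("-inf")
        bins.append(LogRBin(gene, start0 + 1, end0, ts, gs, m_factor, logr))
    if not bins:
        logger.warning("gene %s: insufficient germline coverage in every bin", gene)
    return bins


def compute_baf(
    tumor: tuple[UniqueSiteCoverage, UniqueSiteCoverage],
    germline: tuple[UniqueSiteCoverage, UniqueSiteCoverage],
    tumor_unique: tuple[UniqueSiteCoverage, UniqueSiteCoverage] | None = None,
    germline_unique: tuple[UniqueSiteCoverage, UniqueSiteCoverage] | None = None,
) -> list[BafSite]:
    """Per-site BAF records from site coverage.

    ``tumor``/``germline`` carry the plain pileup depths that define BAF;
    the optional unique tracks carry the once-per-template counts for the
    imbalance test.  Sites with zero combined tumor depth are omitted.
    """
    t1, t2 = tumor
    g1, g2 = germline
    ut1, ut2 = tumor_unique if tumor_unique else (t1, t2)
    ug1, ug2 = germline_unique if germline_unique else (g1, g2)
    out: list[BafSite] = []
    for i, site in enumerate(t1.sites):
        if t1.depth[i] + t2.depth[i] == 0:
            continue
        out.append(BafSite(
            site,
            int(t1.depth[i]), int(t2.depth[i]), int(g1.depth[i]), int(g2.depth[i]),
            int(ut1.depth[i]), int(ut2.depth[i]), int(ug1.depth[i]), int(ug2.depth[i]),
        ))
    return out


def allele_specific_cn(baf: float, logr: float, pp: PurityPloidy) -> tuple[float, float]:
    """Invert one (BAF, logR) observation to the two homolog copy numbers."""
    if not 0 <= baf <= 1:
        raise ValueError(f"BAF must lie in [0, 1], got {baf}")
    rho, psi = pp.rho, pp.psi
    scale = 2.0 ** logr * (2 * (1 - rho) + rho * psi)
    cn1 = (rho - 1 + baf * scale) / rho
    cn2 = (rho - 1 - (baf - 1) * scale) / rho
    return cn1, cn2


def estimate_gene_cn(
    sites: list[BafSite],
    bins: list[LogRBin],
    pp: PurityPloidy,
    bin_width: int = DEFAULT_BIN_WIDTH,
    min_sites: int = MIN_MISMATCH_SITES,
) -> AlleleCnEstimate | None:
    """Gene-level homolog copy numbers: median over bins of per-bin medians.

    Each site uses its own BAF with the logR of the bin containing its
    allele-1 coordinate; sites in excluded bins carry no evidence.  Returns
    ``None`` (indeterminate) when fewer than ``min_sites`` sites fall in
    covered bins.
    """
    logr_by_bin = {(b.start - 1) // bin_width: b.logr for b in bins}
    per_bin: dict[int, list[tuple[float, float]]] = {}
    gene = bins[0].gene if bins else (sites[0].site.gene if sites else "")
    n_used = 0
    for s in sites:
        idx = (s.site.pos1 - 1) // bin_width
        if idx not in logr_by_bin:
            continue
        cn = allele_specific_cn(s.baf, logr_by_bin[idx], pp)
        per_bin.setdefault(idx, []).append(cn)
        n_used += 1
    if n_used < min_sites:
        return None
    bin_cn1 = {i: float(np.median([c[0] for c in v])) for i, v in per_bin.items()}
    bin_cn2 = {i: float(np.median([c[1] for c in v])) for i, v in per_bin.items()}
    return AlleleCnEstimate(
        gene=gene,
        cn1=float(np.median(list(bin_cn1.values()))),
        cn2=float(np.median(list(bin_cn2.values()))),
        per_bin_cn1=bin_cn1,
        per_bin_cn2=bin_cn2,
        n_sites=n_used,
        n_bins=len(per_bin),
    )


def test_allelic_imbalance(
    sites: list[BafSite],
    min_sites: int = MIN_MISMATCH_SITES,
) -> float | None:
    """Two-sided paired t-test on per-site homolog logR differences.

    Per site the difference log2(M t1 / n1) - log2(M t2 / n2) is formed
    from once-per-template depths (M cancels in the difference); sites
    with any zero depth are uninformative and dropped.  Returns ``None``
    (indeterminate) below ``min_sites`` usable sites; a degenerate all-zero
    difference vector gives p = 1, and zero variance around a non-zero
    mean collapses to a 1e-16 sentinel.
    """
    diffs = []
    for s in sites:
        if min(s.utumor1, s.utumor2, s.ugermline1, s.ugermline2) == 0:
            continue
        diffs.append(
            math.log2(s.utumor1 / s.ugermline1) - math.log2(s.utumor2 / s.ugermline2)
        )
    if len(diffs) < min_sites:
        return None
    d = np.asarray(diffs)
    if np.all(d == 0):
        return 1.0
    if np.ptp(d) == 0:
        warnings.warn("degenerate imbalance test: zero variance, non-zero mean")
        return 1e-16
    t_stat, p = stats.ttest_1samp(d, 0.0)
    return float(p)


def classify_loh(
    est: AlleleCnEstimate | None,
    p_value: float | None,
    cn_threshold: float = LOH_CN_THRESHOLD,
    alpha: float = IMBALANCE_ALPHA,
) -> str:
    """Apply the verdict rule: LOH iff min(cn1, cn2) < 0.5 and p < 0.01."""
    if est is None or p_value is None:
        return Verdict.INDETERMINATE
    significant = p_value < alpha
    if est.min_cn < cn_threshold and significant:
        return Verdict.LOH_ALLELE1 if est.cn1 <= est.cn2 else Verdict.LOH_ALLELE2
    if significant:
        return Verdict.IMBALANCE
    return Verdict.BALANCED


def normalized_allelic_ratio(
    a_tumor: float, b_tumor: float, a_normal: float, b_normal: float
) -> float:
    """Fragment-analysis imbalance readout (A_t / B_t) / (A_n / B_n)."""
    if min(a_tumor, b_tumor, a_normal, b_normal) <= 0:
        raise ValueError("all peak areas must be positive")
    return (a_tumor / b_tumor) / (a_normal / b_normal)


def fisher_exact_2x2(table: list[list[int]] | np.ndarray) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 contingency table.

    Returns (odds ratio, p-value); the cohort-level enrichment statistics
    are computed with this utility.
    """
    arr = np.asarray(table, dtype=np.int64)
    if arr.shape != (2, 2) or np.any(arr < 0):
        raise ValueError("table must be 2x2 with non-negative counts")
    res = stats.fisher_exact(arr, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
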