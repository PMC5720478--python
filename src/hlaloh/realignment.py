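"""Candidate-read extraction, re-alignment to patient alleles, and coverage.

The caller works on the reads overlapping the class I region of chr6 (plus
the alternate MHC haplotype contigs).  Those reads are re-aligned against
the patient's own allele sequences, the post-alignment filters are applied
(mate on the other homolog; more than one mismatch/insertion/deletion
event), and per-position depth plus unique-read depth at discriminating
sites are computed.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import edlib
import numpy as np
import pysam
from Bio import Align

from .hla_alleles import HlaAllele, MismatchSite

logger = logging.getLogger(__name__)

__all__ = [
    "HLA_REGIONS",
    "HLA_CONTIGS",
    "ReadRecord",
    "AlleleAlignment",
    "CoverageTrack",
    "UniqueSiteCoverage",
    "extract_candidate_reads",
    "align_reads_to_allele",
    "best_allele_assignment",
    "filter_alignments",
    "compute_coverage",
    "site_coverage_unique",
    "site_coverage_plain",
]

#: Default extraction windows (1-based inclusive): the HLA-A, HLA-C and
#: HLA-B intervals of GRCh37 chr6.
HLA_REGIONS: tuple[tuple[str, int, int], ...] = (
    ("chr6", 29909037, 29913661),
    ("chr6", 31321649, 31324964),
    ("chr6", 31236526, 31239869),
)

#: Alternate MHC haplotype contigs whose reads are extracted wholesale.
HLA_CONTIGS: tuple[str, ...] = (
    "chr6_cox_hap2",
    "chr6_dbb_hap3",
    "chr6_mann_hap4",
    "chr6_mcf_hap5",
    "chr6_qbl_hap6",
    "chr6_ssto_hap7",
)

#: Minimum re-alignment score as a fraction of read length (match +1 scheme).
MIN_SCORE_FRACTION = 0.8

#: Maximum total event count (substitutions + insertion events + deletion
#: events) a kept read may carry relative to its allele reference.
MAX_EVENTS = 1


@dataclasses.dataclass(frozen=True)
class ReadRecord:
    """A candidate read: name, mate index (1/2), sequence, qualities."""

    name: str
    mate: int
    sequence: str
    qualities: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.name}/{self.mate}: empty sequence")
        if self.mate not in (1, 2):
            raise ValueError(f"read {self.name}: mate index must be 1 or 2")

    @property
    def key(self) -> tuple[str, int]:
        return (self.name, self.mate)

    @property
    def mate_key(self) -> tuple[str, int]:
        return (self.name, 3 - self.mate)


@dataclasses.dataclass(frozen=True)
class AlleleAlignment:
    """One read aligned to one allele reference.

    ``start`` is 1-based on the allele; ``ref_bases`` holds the read's base
    call per covered allele position ('-' where the read has a deletion).
    Contiguous gaps count as single events.
    """

    read: ReadRecord
    allele: str
    start: int
    subs: int
    ins_events: int
    del_events: int
    ref_bases: str
    score: float

    @property
    def end(self) -> int:
        """Last covered allele position, 1-based inclusive."""
        return self.start + len(self.ref_bases) - 1

    @property
    def n_events(self) -> int:
        return self.subs + self.ins_events + self.del_events

    def covers(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def base_at(self, pos: int) -> str:
        if not self.covers(pos):
            raise IndexError(f"position {pos} outside [{self.start}, {self.end}]")
        return self.ref_bases[pos - self.start]


@dataclasses.dataclass
class CoverageTrack:
    """Per-position depth of one sample on one allele reference."""

    allele: str
    sample: str
    depth: np.ndarray
    n_unique_reads: int

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if np.any(self.depth < 0):
            raise ValueError("depths must be non-negative")


@dataclasses.dataclass
class UniqueSiteCoverage:
    """Depth at each mismatch site counting each read at most once.

    A read spanning several discriminating sites contributes only at its
    leftmost covered site, so site depths never over-count the evidence.
    """

    allele: str
    sample: str
    sites: list[MismatchSite]
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if len(self.depth) != len(self.sites):
            raise ValueError("one depth per site required")


def _region_reads(
    af: pysam.AlignmentFile,
    regions: tuple[tuple[str, int, int], ...],
    contigs: tuple[str, ...],
) -> dict[tuple[str, int], ReadRecord]:
    collected: dict[tuple[str, int], ReadRecord] = {}
    present = set(af.references)
    for chrom, start, end in regions:
        if chrom not in present:
            continue
        for seg in af.fetch(chrom, start - 1, end):  # 1-based incl -> 0-based half-open
            _collect(seg, collected)
    for contig in contigs:
        if contig not in present:
            continue
        for seg in af.fetch(contig):
            _collect(seg, collected)
    return collected


def _collect(seg: pysam.AlignedSegment, out: dict[tuple[str, int], ReadRecord]) -> None:
    if seg.is_secondary or seg.is_supplementary or seg.is_unmapped:
        return
    seq = seg.get_forward_sequence() or seg.query_sequence
    if not seq:
        return
    mate = 2 if seg.is_read2 else 1
    qual = seg.qual
    out.setdefault((seg.query_name, mate), ReadRecord(seg.query_name, mate, seq.upper(), qual))


def extract_candidate_reads(
    alignment_path: str | Path,
    regions: tuple[tuple[str, int, int], ...] = HLA_REGIONS,
    contigs: tuple[str, ...] = HLA_CONTIGS,
) -> list[ReadRecord]:
    """Extract reads overlapping the HLA regions or mapped to MHC contigs.

    Regions are 1-based inclusive genome intervals.  Reads whose mate was
    not itself extracted (unpaired survivors) are removed.  The alignment
    file must be coordinate-sorted and indexed.
    """
    alignment_path = Path(alignment_path)
    if not alignment_path.exists():
        raise FileNotFoundError(alignment_path)
    with pysam.AlignmentFile(str(alignment_path)) as af:
        if not af.has_index():
            raise ValueError(f"{alignment_path} has no index; run samtools index")
        collected = _region_reads(af, regions, contigs)
    paired = [r for key, r in collected.items() if r.mate_key in collected]
    n_dropped = len(collected) - len(paired)
    if n_dropped:
        logger.info("extract: removed %d unpaired mates", n_dropped)
    paired.sort(key=lambda r: r.key)
    return paired


def _parse_extended_cigar(cigar: str) -> list[tuple[int, str]]:
    ops: list[tuple[int, str]] = []
    n = 0
    for ch in cigar:
        if ch.isdigit():
            n = n * 10 + int(ch)
        else:
            ops.append((n, ch))
            n = 0
    return ops


def _score_and_events(ops: list[tuple[int, str]]) -> tuple[float, int, int, int]:
    """Affine score (match +1, mismatch -1, open -5, extend -1) and event counts."""
    score = 0.0
    subs = ins_events = del_events = 0
    for length, op in ops:
        if op == "=":
            score += length
        elif op == "X":
            score -= length
            subs += length
        elif op == "I":
            score -= 5 + (length - 1)
            ins_events += 1
        elif op == "D":
            score -= 5 + (length - 1)
            del_events += 1
        else:  # pragma: no cover - edlib emits only =XID in path mode
            raise ValueError(f"unexpected cigar op {op}")
    return score, subs, ins_events, del_events


def _make_infix_aligner() -> Align.PairwiseAligner:
    # affine scheme of the homolog aligner, target flanks free (infix):
    # end gaps in the query row (unaligned target flanks) cost nothing
    aligner = Align.PairwiseAligner(
        mode="global", match_score=1, mismatch_score=-1,
        open_gap_score=-5, extend_gap_score=-1,
    )
    try:
        aligner.open_end_deletion_score = 0
        aligner.extend_end_deletion_score = 0
    except AttributeError:  # older attribute names
        aligner.query_end_open_gap_score = 0
        aligner.query_end_extend_gap_score = 0
    return aligner


_INFIX_ALIGNER = _make_infix_aligner()


def _affine_refine(read_seq: str, target: str) -> tuple[int, list[tuple[int, str]], float]:
    """Affine-score infix alignment (start0, extended-cigar ops, score).

    Used when an edit-distance path contains gaps: edlib breaks ties
    arbitrarily and may split a contiguous gap, which misstates event
    counts under the affine scheme.
    """
    aln = _INFIX_ALIGNER.align(target, read_seq)[0]
    ti, qi = aln.indices
    qcols = np.flatnonzero(qi >= 0)
    lo, hi = int(qcols[0]), int(qcols[-1])
    ops: list[tuple[int, str]] = []
    for col in range(lo, hi + 1):
        if qi[col] < 0:
            op = "D"
        elif ti[col] < 0:
            op = "I"
        else:
            op = "=" if target[ti[col]] == read_seq[qi[col]] else "X"
        if ops and ops[-1][1] == op:
            ops[-1] = (ops[-1][0] + 1, op)
        else:
            ops.append((1, op))
    start_cols = ti[lo:hi + 1]
    start0 = int(start_cols[start_cols >= 0][0])
    return start0, ops, float(aln.score)


def align_reads_to_allele(
    reads: list[ReadRecord],
    allele: HlaAllele,
    min_score_fraction: float = MIN_SCORE_FRACTION,
) -> list[AlleleAlignment]:
    """Glocal alignment of each read against one allele sequence.

    Reads are placed within the allele by edit distance (fast bit-parallel
    search); paths containing gaps are re-aligned under the affine scheme
    so contiguous gaps count as single events.  Alignments scoring below
    ``min_score_fraction`` x read length are dropped.  A read may align to
    several alleles; mate and event filtering happen later.
    """
    out: list[AlleleAlignment] = []
    n_unaligned = 0
    target = allele.sequence
    for read in reads:
        res = edlib.align(read.sequence, target, mode="HW", task="path")
        if res["editDistance"] < 0 or not res.get("cigar"):
            n_unaligned += 1
            continue
        ops = _parse_extended_cigar(res["cigar"])
        start0 = res["locations"][0][0]
        n_ins = sum(1 for _, op in ops if op == "I")
        n_del = sum(1 for _, op in ops if op == "D")
        n_x = sum(n for n, op in ops if op == "X")
        # edlib breaks edit-distance ties arbitrarily and may split one
        # contiguous gap; re-align under the affine scheme, but only when
        # the path could collapse to a single gap event — otherwise the
        # read fails the one-event filter regardless of decomposition
        if n_x == 0 and n_ins + n_del > 1 and (n_ins == 0 or n_del == 0):
            start0, ops, _ = _affine_refine(read.sequence, target)
        score, subs, ins_events, del_events = _score_and_events(ops)
        if score < min_score_fraction * len(read.sequence):
            n_unaligned += 1
            continue
        ref_bases = _reference_space_bases(read.sequence, ops)
        out.append(
            AlleleAlignment(
                read=read,
                allele=allele.name,
                start=start0 + 1,
                subs=subs,
                ins_events=ins_events,
                del_events=del_events,
                ref_bases=ref_bases,
                score=score,
            )
        )
    if n_unaligned:
        logger.debug("align: %d reads below score floor on %s", n_unaligned, allele.name)
    return out


def _reference_space_bases(seq: str, ops: list[tuple[int, str]]) -> str:
    parts: list[str] = []
    qi = 0
    for length, op in ops:
        if op in ("=", "X"):
            parts.append(seq[qi : qi + length])
            qi += length
        elif op == "I":
            qi += length
        elif op == "D":
            parts.append("-" * length)
    return "".join(parts)


def best_allele_assignment(
    per_allele: dict[str, list[AlleleAlignment]],
) -> dict[tuple[str, int], str | None]:
    """Best-scoring allele per (read name, mate); ``None`` marks a tie.

    Ties are treated conservatively: the read stays on both homologs for
    coverage but carries no site-level allele evidence.
    """
    best: dict[tuple[str, int], tuple[float, str | None]] = {}
    for allele, alns in per_allele.items():
        for aln in alns:
            key = aln.read.key
            if key not in best or aln.score > best[key][0]:
                best[key] = (aln.score, allele)
            elif aln.score == best[key][0] and best[key][1] != allele:
                best[key] = (aln.score, None)
    return {key: allele for key, (_, allele) in best.items()}


def filter_alignments(
    alignments: list[AlleleAlignment],
    best_map: dict[tuple[str, int], str | None],
) -> list[AlleleAlignment]:
    """Apply the post-alignment filters to one allele's alignments.

    Removes reads whose total event count exceeds one, reads whose best
    alignment is on the other homolog, and reads whose mate's best
    alignment is on the other homolog (mate ties do not discard).
    """
    kept: list[AlleleAlignment] = []
    n_events = n_other = n_mate = 0
    for aln in alignments:
        if aln.n_events > MAX_EVENTS:
            n_events += 1
            continue
        own_best = best_map.get(aln.read.key)
        if own_best is not None and own_best != aln.allele:
            n_other += 1
            continue
        mate_best = best_map.get(aln.read.mate_key)
        if mate_best is not None and mate_best != aln.allele:
            n_mate += 1
            continue
        kept.append(aln)
    logger.debug(
        "filter %s: kept %d, dropped %d (>1 event) %d (better elsewhere) %d (mate on other allele)",
        alignments[0].allele if alignments else "?",
        len(kept), n_events, n_other, n_mate,
    )
    return kept


def compute_coverage(
    alignments: list[AlleleAlignment],
    allele: HlaAllele,
    sample: str,
) -> CoverageTrack:
    """Per-position depth on one allele from filtered alignments."""
    diff = np.zeros(len(allele) + 1, dtype=np.int64)
    reads: set[tuple[str, int]] = set()
    for aln in alignments:
        lo = max(aln.start, 1)
        hi = min(aln.end, len(allele))
        if hi < lo:
            continue
        diff[lo - 1] += 1
        diff[hi] -= 1
        reads.add(aln.read.key)
    depth = np.cumsum(diff[:-1])
    return CoverageTrack(allele.name, sample, depth, len(reads))


def _partition_cuts(pos_sorted: np.ndarray, read_len: int,
                    start_min: int, start_max: int) -> np.ndarray:
    """Cut the read-start axis into one catchment per site.

    ``cuts[i]``/``cuts[i+1]`` bound sorted site i's catchment: a read
    starting in ``(cuts[i], cuts[i+1]]`` is assigned to that site.  A read
    assigned to site i must still cover it, so cut i is confined to
    ``[pos_i - read_len, pos_(i-1)]``.  Within those bands the cuts are
    relaxed toward equal catchment widths (each cut pulled to the midpoint
    of its neighbours), so clustered sites borrow start-space from their
    sparser flanks instead of being starved.
    """
    k = len(pos_sorted)
    # the catchment axis only spans starts that exist in the read set
    lo = np.maximum(pos_sorted - read_len, start_min - 1).astype(float)
    hi = np.minimum(pos_sorted, start_max).astype(float)
    cuts = np.empty(k + 1)
    cuts[0] = lo[0]
    cuts[k] = min(int(pos_sorted[-1]), start_max)
    span = cuts[k] - cuts[0]
    for i in range(1, k):
        cuts[i] = min(hi[i - 1], max(lo[i], cuts[0] + i * span / k))
    for _ in range(60):
        for i in range(1, k):
            target = 0.5 * (cuts[i - 1] + cuts[i + 1])
            cuts[i] = min(hi[i - 1], cuts[i + 1], max(lo[i], cuts[i - 1], target))
    return np.floor(cuts).astype(np.int64)


def site_coverage_unique(
    alignments: list[AlleleAlignment],
    sites: list[MismatchSite],
    positions: list[int],
    sample: str = "",
) -> UniqueSiteCoverage:
    """Unique-read depth at mismatch sites on one allele.

    ``positions`` gives each site's 1-based coordinate on this allele (the
    allele-1 or allele-2 column of the site catalog).  Each read counts at
    exactly one covered site, chosen by where the read starts: the start
    axis is cut into one contiguous catchment per site, with cuts placed
    as evenly as read length allows.  A positional partition keeps the
    per-site counts statistically independent (disjoint windows of the
    same read process), and even catchments avoid sites with only a
    handful of reads, whose noisy allele fractions would otherwise bias
    the downstream medians and destabilize the paired imbalance test.
    Reads missing their catchment's site (boundary effects, short reads)
    fall back to their leftmost covered site.

    The counting unit is the sequencing template: a fragment's two mates
    carry the same molecule's evidence, so each template is represented by
    its lowest-numbered mate present (a deterministic choice whose start
    stays uniformly distributed, unlike the min of the two mate starts).
    Mate pairs are the reason read-level counts are overdispersed relative
    to Poisson; counting templates keeps the per-site counts independent,
    which the paired imbalance test relies on.
    """
    if len(positions) != len(sites):
        raise ValueError("positions must parallel sites")
    order = np.argsort(positions, kind="stable")
    pos_sorted = np.asarray([positions[i] for i in order])
    k = len(pos_sorted)
    depth = np.zeros(len(sites), dtype=np.int64)
    counted: set[tuple[str, int]] = set()
    allele = alignments[0].allele if alignments else ""
    if k == 0 or not alignments:
        return UniqueSiteCoverage(allele, sample, list(sites), depth)

    # one representative alignment per template: the lowest mate index,
    # breaking duplicates by position
    by_name: dict[str, AlleleAlignment] = {}
    for aln in alignments:
        cur = by_name.get(aln.read.name)
        if cur is None or (aln.read.mate, aln.start) < (cur.read.mate, cur.start):
            by_name[aln.read.name] = aln
    reps = list(by_name.values())

    read_len = int(np.median([a.end - a.start + 1 for a in reps]))
    starts = [a.start for a in reps]
    cuts = _partition_cuts(pos_sorted, read_len,
                           start_min=min(starts), start_max=max(starts))

    for aln in sorted(reps, key=lambda a: (a.start, a.read.key)):
        if aln.read.name in counted:
            continue
        idx = int(np.searchsorted(cuts[1:], aln.start, side="left"))
        site_rank = -1
        if idx < k:
            pos = int(pos_sorted[idx])
            if aln.covers(pos) and aln.base_at(pos) != "-":
                site_rank = idx
        if site_rank < 0:  # fallback: leftmost covered site
            for j, pos in enumerate(pos_sorted):
                if aln.covers(int(pos)) and aln.base_at(int(pos)) != "-":
                    site_rank = j
                    break
        if site_rank >= 0:
            depth[order[site_rank]] += 1
            counted.add(aln.read.name)
    return UniqueSiteCoverage(allele, sample, list(sites), depth)


def site_coverage_plain(
    alignments: list[AlleleAlignment],
    sites: list[MismatchSite],
    positions: list[int],
    sample: str = "",
) -> UniqueSiteCoverage:
    """Plain pileup depth at each mismatch site (every covering read counts).

    This is the coverage that enters the per-site allele fraction; the
    once-per-template counts of :func:`site_coverage_unique` are used only
    by the paired imbalance test.
    """
    if len(positions) != len(sites):
        raise ValueError("positions must parallel sites")
    depth = np.zeros(len(sites), dtype=np.int64)
    allele = alignments[0].allele if alignments else ""
    for aln in alignments:
        for i, pos in enumerate(positions):
            if aln.covers(pos) and aln.base_at(pos) != "-":
                depth[i] += 1
    return UniqueSiteCoverage(allele, sample, list(sites), depth)
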