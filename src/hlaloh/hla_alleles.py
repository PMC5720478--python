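"""Patient HLA genotypes, allele sequences, and homolog mismatch catalogs.

A patient carries up to six distinct class I alleles (two per gene over
HLA-A/B/C).  LOH calling needs the positions at which the two homologous
alleles of one gene differ: reads covering such a site can be assigned to
one homolog, and the site-level depth ratio between homologs carries the
allelic-imbalance signal.  This module aligns the two homologs of each
heterozygous gene and extracts the catalog of discriminating substitution
sites.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from Bio import Align, SeqIO

__all__ = [
    "HlaAllele",
    "PatientHlaType",
    "HomologAlignment",
    "MismatchSite",
    "load_allele_sequences",
    "align_homologs",
    "find_mismatch_sites",
    "MIN_MISMATCH_SITES",
]

#: Genes with fewer discriminating sites than this are reported as
#: "insufficiently polymorphic" and excluded from imbalance testing.
MIN_MISMATCH_SITES = 5

_VALID_BASES = set("ACGTN")


@dataclasses.dataclass(frozen=True)
class HlaAllele:
    """One HLA allele: a lowercase underscore-delimited name (e.g.
    ``hla_a_01_01``) and its uppercase nucleotide sequence."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("allele name must be non-empty")
        if not self.sequence:
            raise ValueError(f"allele {self.name}: sequence must be non-empty")
        extra = set(self.sequence) - _VALID_BASES
        if extra:
            raise ValueError(
                f"allele {self.name}: invalid bases {sorted(extra)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass(frozen=True)
class PatientHlaType:
    """Patient class I genotype: one allele-name pair per gene.

    Genes where both calls name the same allele are homozygous; HLA LOH is
    undetectable there and such genes are flagged and skipped downstream.
    """

    alleles: dict[str, tuple[str, str]]

    GENES = ("A", "B", "C")

    def __post_init__(self) -> None:
        if set(self.alleles) != set(self.GENES):
            raise ValueError(
                f"genotype must cover genes {self.GENES}, got {sorted(self.alleles)}"
            )

    def is_homozygous(self, gene: str) -> bool:
        a1, a2 = self.alleles[gene]
        return a1 == a2

    def allele_names(self) -> list[str]:
        """Distinct allele names over all genes, order preserved."""
        seen: dict[str, None] = {}
        for gene in self.GENES:
            for name in self.alleles[gene]:
                seen.setdefault(name)
        return list(seen)


@dataclasses.dataclass(frozen=True)
class HomologAlignment:
    """Local pairwise alignment of a gene's two homologous alleles.

    ``pos1``/``pos2`` give, per alignment column, the 0-based position on
    each allele, or -1 in gap columns.  The public contract for reported
    coordinates is 1-based inclusive.
    """

    gene: str
    allele1: str
    allele2: str
    seq1: str
    seq2: str
    pos1: np.ndarray
    pos2: np.ndarray
    score: float

    def __post_init__(self) -> None:
        for arr in (self.pos1, self.pos2):
            covered = arr[arr >= 0]
            if covered.size and np.any(np.diff(covered) <= 0):
                raise ValueError("coordinate map must be strictly monotone")

    @property
    def n_columns(self) -> int:
        return len(self.pos1)


@dataclasses.dataclass(frozen=True)
class MismatchSite:
    """One substitution column between the two homologs (1-based positions)."""

    gene: str
    pos1: int
    pos2: int
    base1: str
    base2: str

    def __post_init__(self) -> None:
        if self.base1 == self.base2:
            raise ValueError("mismatch site requires differing bases")

    def swapped(self) -> "MismatchSite":
        return MismatchSite(self.gene, self.pos2, self.pos1, self.base2, self.base1)


def _normalize_name(name: str) -> str:
    return name.strip().lower().replace("-", "_").replace("*", "_").replace(":", "_")


def load_allele_sequences(fasta_path: str | Path, wanted: list[str]) -> dict[str, HlaAllele]:
    """Read the wanted alleles from a FASTA of HLA allele sequences.

    Record identifiers and wanted names are normalized to lowercase
    underscore-delimited form; sequences are uppercased.  Raises
    ``FileNotFoundError`` for a missing file, ``ValueError`` for duplicate
    FASTA identifiers, and ``KeyError`` naming the first wanted allele that
    is absent.
    """
    fasta_path = Path(fasta_path)
    if not fasta_path.exists():
        raise FileNotFoundError(fasta_path)
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        key = _normalize_name(rec.id)
        if key in records:
            raise ValueError(f"duplicate FASTA identifier: {key}")
        records[key] = str(rec.seq).upper()
    registry: dict[str, HlaAllele] = {}
    for raw in wanted:
        key = _normalize_name(raw)
        if key not in records:
            raise KeyError(f"allele {key} not found in {fasta_path}")
        registry[key] = HlaAllele(key, records[key])
    return registry


def _make_aligner() -> Align.PairwiseAligner:
    # Conservative gap costs keep dense SNP stretches as substitutions
    # rather than gaps, so they stay in the mismatch-site catalog.
    return Align.PairwiseAligner(
        mode="local",
        match_score=1,
        mismatch_score=-1,
        open_gap_score=-5,
        extend_gap_score=-1,
    )


def align_homologs(a1: HlaAllele, a2: HlaAllele, gene: str = "") -> HomologAlignment:
    """Optimal local alignment of the two homologs of one gene.

    Scoring: match +1, mismatch -1, gap open -5, gap extend -1 (the opening
    base of a gap costs -5, each further base -1).  The coordinate map
    covers the locally aligned region only.
    """
    aligner = _make_aligner()
    aln = aligner.align(a1.sequence, a2.sequence)[0]
    indices = aln.indices  # 2 x ncol, -1 in gap columns
    return HomologAlignment(
        gene=gene,
        allele1=a1.name,
        allele2=a2.name,
        seq1=a1.sequence,
        seq2=a2.sequence,
        pos1=indices[0].copy(),
        pos2=indices[1].copy(),
        score=float(aln.score),
    )


def find_mismatch_sites(aln: HomologAlignment) -> list[MismatchSite]:
    """Extract the substitution columns of a homolog alignment.

    Gap columns are not mismatch sites.  Results are 1-based and sorted by
    position on allele 1.
    """
    sites: list[MismatchSite] = []
    for p1, p2 in zip(aln.pos1, aln.pos2):
        if p1 < 0 or p2 < 0:
            continue
        b1 = aln.seq1[p1]
        b2 = aln.seq2[p2]
        if b1 != b2:
            sites.append(MismatchSite(aln.gene, int(p1) + 1, int(p2) + 1, b1, b2))
    sites.sort(key=lambda s: s.pos1)
    return sites
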