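"""Placing LOH events on clone trees and testing LOH enrichment.

An LOH event observed at different intensities across tumor regions is
assigned to a branch of the patient's clone tree by least squares: for
each candidate branch the tree splits into the subtree at/below the event
and the remainder, each summarized by its per-region cancer-cell-fraction
(CCF) sums, and the two-component copy-number mixture that best explains
the observed regional lost-allele copy number is found under the
constraints that both components are non-negative and the remainder keeps
at least 0.5 copies.  The branch with the least squared error wins.

Segment-scale classification (focal vs arm-level at the 75%-of-arm rule)
and the permutation test for whether locus-level LOH exceeds the
genome-wide expectation live here too.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.optimize import lsq_linear

logger = logging.getLogger(__name__)

__all__ = [
    "CloneTree",
    "QpPlacement",
    "LohEvent",
    "GenomeSegment",
    "map_loss_to_clone",
    "classify_event_clonality",
    "merge_adjacent_segments",
    "classify_segment_scale",
    "simulate_loh_expectation",
    "ARM_LEVEL_FRACTION",
    "UNPLACED_RELATIVE_ERROR",
    "REMAINDER_CN_FLOOR",
]

ARM_LEVEL_FRACTION = 0.75
REMAINDER_CN_FLOOR = 0.5
#: Relative squared error above which no branch is considered to fit
#: (mirrors manual gray-node adjustment: we flag instead of adding nodes).
UNPLACED_RELATIVE_ERROR = 0.25
CCF_PIGEONHOLE_TOL = 0.05


@dataclasses.dataclass
class CloneTree:
    """Clone phylogeny with per-region CCFs.

    ``parents`` maps each clone to its parent (the single root maps to
    ``None``); ``ccf`` maps clone -> region -> cancer cell fraction.
    """

    parents: dict[str, str | None]
    ccf: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        roots = [n for n, p in self.parents.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {roots}")
        for node, parent in self.parents.items():
            if parent is not None and parent not in self.parents:
                raise ValueError(f"unknown parent {parent} of {node}")
        # reject cycles by requiring every node to reach the root
        for node in self.parents:
            seen = set()
            while node is not None:
                if node in seen:
                    raise ValueError("tree contains a cycle")
                seen.add(node)
                node = self.parents[node]
        if set(self.ccf) != set(self.parents):
            raise ValueError("ccf must cover exactly the tree's clones")
        regions = self.regions
        for node, per_region in self.ccf.items():
            if set(per_region) != set(regions):
                raise ValueError(f"clone {node}: CCFs must cover all regions")
            for region, value in per_region.items():
                if not 0 <= value <= 1 + 1e-9:
                    raise ValueError(f"CCF out of [0,1]: {node}/{region} = {value}")
        self._warn_pigeonhole()

    def _warn_pigeonhole(self) -> None:
        for node, parent in self.parents.items():
            if parent is None:
                continue
            for region in self.regions:
                if self.ccf[node][region] > self.ccf[parent][region] + CCF_PIGEONHOLE_TOL:
                    logger.warning(
                        "clone %s CCF exceeds parent %s in %s (%.3f > %.3f)",
                        node, parent, region,
                        self.ccf[node][region], self.ccf[parent][region],
                    )

    @property
    def root(self) -> str:
        return next(n for n, p in self.parents.items() if p is None)

    @property
    def regions(self) -> list[str]:
        return sorted(self.ccf[self.root])

    def children(self, node: str) -> list[str]:
        return sorted(n for n, p in self.parents.items() if p == node)

    def subtree(self, node: str) -> set[str]:
        out = {node}
        stack = [node]
        while stack:
            for child in self.children(stack.pop()):
                out.add(child)
                stack.append(child)
        return out

    def preorder(self) -> list[str]:
        """Root-first traversal; earlier nodes are more ancestral."""
        order: list[str] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(reversed(self.children(node)))
        return order

    def ccf_sum(self, nodes: set[str]) -> np.ndarray:
        return np.array(
            [sum(self.ccf[n][r] for n in nodes) for r in self.regions]
        )


@dataclasses.dataclass(frozen=True)
class QpPlacement:
    """The least-squares fit of an event at one candidate branch."""

    branch: str
    f_matrix: np.ndarray  # 2 x n_regions: subtree row, remainder row
    b: np.ndarray  # (subtree copy number, remainder copy number)
    error: float  # squared residual ||c - b^T F||^2


@dataclasses.dataclass(frozen=True)
class LohEvent:
    gene: str
    lost_allele: str
    regional_cn: dict[str, float]
    branch: str | None
    b: np.ndarray | None
    error: float
    clonality: str
    unplaced: bool = False


def _fit_branch(tree: CloneTree, branch: str, c: np.ndarray) -> QpPlacement:
    inside = tree.subtree(branch)
    outside = set(tree.parents) - inside
    f = np.vstack([tree.ccf_sum(inside), tree.ccf_sum(outside)])
    # min ||c - F^T b||^2 s.t. b >= 0 and remainder copy number >= 0.5;
    # equivalently the QP min(-d^T b + 1/2 b^T D b) with D = F F^T, d = F c.
    res = lsq_linear(f.T, c, bounds=([0.0, REMAINDER_CN_FLOOR], [np.inf, np.inf]))
    err = float(np.sum((c - f.T @ res.x) ** 2))
    return QpPlacement(branch, f, res.x, err)


def map_loss_to_clone(
    tree: CloneTree,
    regional_cn: dict[str, float],
    unplaced_threshold: float = UNPLACED_RELATIVE_ERROR,
) -> tuple[QpPlacement, bool]:
    """Assign a lost-allele copy-number profile to the best tree branch.

    Every branch is tried; the least-error fit wins, with ties broken
    toward the most ancestral branch.  When even the best fit leaves more
    than ``unplaced_threshold`` of ``||c||^2`` unexplained the event is
    flagged as not fitting the tree (returned second value True).
    """
    missing = set(tree.regions) - set(regional_cn)
    if missing:
        raise ValueError(f"regional copy number missing for regions {sorted(missing)}")
    c = np.array([regional_cn[r] for r in tree.regions], dtype=float)
    best: QpPlacement | None = None
    for branch in tree.preorder():  # ancestral first => '<' keeps ancestral ties
        fit = _fit_branch(tree, branch, c)
        if best is None or fit.error < best.error - 1e-12:
            best = fit
    assert best is not None
    c_norm = float(np.sum(c**2))
    unplaced = c_norm > 0 and best.error > unplaced_threshold * c_norm
    if unplaced:
        logger.warning(
            "event does not fit tree: best branch %s, relative error %.3f",
            best.branch, best.error / c_norm,
        )
    return best, unplaced


def classify_event_clonality(detected: set[str], analyzable: set[str]) -> str:
    """Clonal iff the event was detected in every analyzable region."""
    if not analyzable:
        raise ValueError("no analyzable regions")
    if not detected:
        raise ValueError("no event: empty detected set")
    if not detected <= analyzable:
        raise ValueError(f"detected regions {detected - analyzable} not analyzable")
    return "clonal" if detected == analyzable else "subclonal"


@dataclasses.dataclass(frozen=True)
class GenomeSegment:
    """A minor-allele copy-number segment, half-open [start, end) on an arm."""

    arm: str
    start: float
    end: float
    minor_cn: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")

    @property
    def length(self) -> float:
        return self.end - self.start


def merge_adjacent_segments(segments: list[GenomeSegment]) -> list[GenomeSegment]:
    """Merge touching same-arm segments with identical minor copy number."""
    merged: list[GenomeSegment] = []
    for seg in sorted(segments, key=lambda s: (s.arm, s.start)):
        if (
            merged
            and merged[-1].arm == seg.arm
            and merged[-1].minor_cn == seg.minor_cn
            and merged[-1].end >= seg.start
        ):
            merged[-1] = GenomeSegment(
                seg.arm, merged[-1].start, max(merged[-1].end, seg.end), seg.minor_cn
            )
        else:
            merged.append(seg)
    return merged


def classify_segment_scale(
    segment: GenomeSegment,
    arm_length: float,
    context: list[GenomeSegment] | None = None,
) -> str:
    """'arm-level' iff the (merged) segment spans >= 75% of its arm.

    When ``context`` is given, same-arm neighbours with identical minor
    copy number are merged with the segment before measuring.
    """
    if arm_length <= 0:
        raise ValueError("arm length must be positive")
    if segment.length > arm_length:
        raise ValueError("segment exceeds arm length")
    if context:
        pool = [s for s in context if s.arm == segment.arm] + [segment]
        merged = merge_adjacent_segments(pool)
        segment = next(s for s in merged if s.start <= segment.start < s.end)
    fraction = segment.length / arm_length
    return "arm-level" if fraction >= ARM_LEVEL_FRACTION else "focal"


def simulate_loh_expectation(
    per_tumor_probability: list[float],
    observed_fraction: float,
    n_reps: int = 10_000,
    seed: int = 0,
) -> float:
    """Permutation p-value for cohort LOH enrichment at one locus.

    Each tumor's genome-wide probability of (focal or arm-level) minor
    allele loss drives an independent Bernoulli draw; the p-value is the
    fraction of ``n_reps`` replicate cohorts whose loss proportion is at
    least the observed one, floored at 1/n_reps.
    """
    probs = np.asarray(per_tumor_probability, dtype=float)
    if probs.size == 0:
        raise ValueError("empty cohort")
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    draws = rng.random((n_reps, probs.size)) < probs
    proportions = draws.mean(axis=1)
    p = float(np.mean(proportions >= observed_fraction - 1e-12))
    return max(p, 1.0 / n_reps)
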