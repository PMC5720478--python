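"""Simulation studies of caller performance.

These helpers run the full per-gene caller on freshly simulated reads and
score the verdicts against the generator's truth.  They back both the
test suite and the reproducibility script; problem sizes are the package's
study conditions (25 discriminating sites, 100x germline depth, 100 bp
reads, 1 kb genes).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .cn_model import PurityPloidy, Verdict
from .pipeline import call_gene
from .synthetic_data import (
    REGION_SPAN,
    SimConfig,
    make_homolog_pair,
    simulate_sample_reads,
)

__all__ = ["RecoveryResult", "run_one_replicate", "recovery_grid", "imbalance_calibration"]

#: The parameter-recovery grid: purities crossed with true homolog states.
GRID_RHOS = (0.3, 0.6, 0.9)
GRID_STATES = ((1.0, 1.0), (0.0, 1.0), (0.0, 2.0), (1.0, 2.0))


@dataclasses.dataclass
class RecoveryResult:
    """Scored verdicts of one recovery-grid run."""

    n_loss_runs: int
    n_loss_correct: int
    n_balanced_runs: int
    n_false_loh: int
    per_cell: dict[tuple[float, tuple[float, float]], float]

    @property
    def loss_accuracy(self) -> float:
        return self.n_loss_correct / self.n_loss_runs

    @property
    def false_loh_rate(self) -> float:
        return self.n_false_loh / self.n_balanced_runs


def _region_read_counts(cfg: SimConfig, rng: np.random.Generator) -> tuple[int, int]:
    """Extracted-read counts of everything in the region except the tested gene.

    The multiplication factor M is the germline/tumor unique-read ratio
    over the whole extracted region: the two companion genes (balanced
    diploid) and the copy-number-neutral sequence of the extraction
    windows both contribute.  Only counts are needed, drawn from the same
    Poisson model the materialized reads follow.
    """
    neutral_bp = 2 * cfg.gene_length + (REGION_SPAN - 3 * cfg.gene_length)
    pairs = cfg.germline_depth * neutral_bp / cfg.read_length / 2.0
    denom = 2 * (1 - cfg.rho) + cfg.rho * cfg.psi
    tumor_scale = 2.0 / denom  # neutral: total copy number 2 in tumor cells
    n_tumor = int(2 * rng.poisson(2 * pairs * tumor_scale))
    n_germline = int(2 * rng.poisson(2 * pairs))
    return n_tumor, n_germline


def run_one_replicate(cfg: SimConfig) -> str:
    """Simulate one patient and return the verdict for the gene under test.

    The tested gene's reads are materialized and called; the rest of the
    extraction region (companion genes and neutral background) enters
    through the region-level read counts that set M.
    """
    a1, a2, _ = make_homolog_pair(cfg)
    tumor = simulate_sample_reads((a1, a2), cfg, "tumor")
    germline = simulate_sample_reads((a1, a2), cfg, "germline")
    rng = np.random.default_rng(cfg.seed + 3)
    extra_t, extra_g = _region_read_counts(cfg, rng)
    m_factor = (len(germline) + extra_g) / (len(tumor) + extra_t)
    res = call_gene(cfg.gene, a1, a2, tumor, germline,
                    PurityPloidy(cfg.rho, cfg.psi), m_factor=m_factor)
    return res.verdict


def recovery_grid(
    seed: int,
    n_replicates: int = 20,
    rhos: tuple[float, ...] = GRID_RHOS,
    states: tuple[tuple[float, float], ...] = GRID_STATES,
) -> RecoveryResult:
    """Score LOH-verdict recovery across the purity x state grid.

    A run on a true-loss state counts as correct when the verdict is LOH
    with the right allele lost; a false LOH is any LOH verdict on a
    balanced or loss-free state ((1,1) or (1,2)).  Ploidy is matched to
    truth (psi = 2).
    """
    rng = np.random.default_rng(seed)
    loss_runs = loss_correct = balanced_runs = false_loh = 0
    per_cell: dict[tuple[float, tuple[float, float]], float] = {}
    for rho in rhos:
        for state in states:
            truth_is_loss = min(state) < 0.5
            expected = (Verdict.LOH_ALLELE1 if state[0] < state[1]
                        else Verdict.LOH_ALLELE2)
            n_ok = 0
            for _ in range(n_replicates):
                cfg = SimConfig(seed=int(rng.integers(2**31)), rho=rho, cn=state)
                verdict = run_one_replicate(cfg)
                if truth_is_loss:
                    loss_runs += 1
                    if verdict == expected:
                        loss_correct += 1
                        n_ok += 1
                else:
                    balanced_runs += 1
                    if verdict in (Verdict.LOH_ALLELE1, Verdict.LOH_ALLELE2):
                        false_loh += 1
                    else:
                        n_ok += 1
            per_cell[(rho, state)] = n_ok / n_replicates
    return RecoveryResult(loss_runs, loss_correct, balanced_runs, false_loh, per_cell)


def imbalance_calibration(
    seed: int,
    n_replicates: int = 200,
    alpha: float = 0.01,
    rho: float = 1.0,
) -> float:
    """Type-I error of the imbalance t-test on balanced (1,1) replicates.

    Returns the fraction of replicates rejecting at ``alpha``; under a
    calibrated test it should match ``alpha`` up to binomial noise.
    """
    rng = np.random.default_rng(seed)
    n_reject = 0
    for _ in range(n_replicates):
        cfg = SimConfig(seed=int(rng.integers(2**31)), rho=rho, cn=(1.0, 1.0))
        a1, a2, _ = make_homolog_pair(cfg)
        tumor = simulate_sample_reads((a1, a2), cfg, "tumor")
        germline = simulate_sample_reads((a1, a2), cfg, "germline")
        res = call_gene(cfg.gene, a1, a2, tumor, germline,
                        PurityPloidy(cfg.rho, cfg.psi))
        if res.p_value is not None and res.p_value < alpha:
            n_reject += 1
    return n_reject / n_replicates
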