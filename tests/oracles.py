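"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations

import numpy as np


def affine_local_score(seq1: str, seq2: str,
                       match: int = 1, mismatch: int = -1,
                       gap_open: int = -5, gap_extend: int = -1) -> float:
    """Optimal local alignment score by Gotoh dynamic programming.

    The opening base of a gap scores ``gap_open``; each further base
    ``gap_extend``.  Exhaustive over all local alignments; quadratic, so
    only for short test sequences.
    """
    n, m = len(seq1), len(seq2)
    neg = float("-inf")
    h = np.zeros((n + 1, m + 1))
    e = np.full((n + 1, m + 1), neg)  # gap in seq1 (consumes seq2)
    f = np.full((n + 1, m + 1), neg)  # gap in seq2 (consumes seq1)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e[i][j] = max(h[i][j - 1] + gap_open, e[i][j - 1] + gap_extend)
            f[i][j] = max(h[i - 1][j] + gap_open, f[i - 1][j] + gap_extend)
            sub = match if seq1[i - 1] == seq2[j - 1] else mismatch
            h[i][j] = max(0.0, h[i - 1][j - 1] + sub, e[i][j], f[i][j])
            best = max(best, h[i][j])
    return best


def edit_distance_events(read: str, target: str) -> tuple[int, int, int]:
    """Minimum-edit glocal alignment event counts (subs, ins runs, del runs).

    Full dynamic programming over all placements of ``read`` within
    ``target`` with free target flanks, followed by traceback; gap runs
    collapse to single events.
    """
    n, m = len(read), len(target)
    dp = np.zeros((n + 1, m + 1), dtype=int)
    dp[1:, 0] = np.arange(1, n + 1)  # free leading target flank: dp[0,:] = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cost = 0 if read[i - 1] == target[j - 1] else 1
            dp[i][j] = min(dp[i - 1][j - 1] + cost, dp[i - 1][j] + 1, dp[i][j - 1] + 1)
    j = int(np.argmin(dp[n]))
    i = n
    ops: list[str] = []
    while i > 0 and j > 0:
        cost = 0 if read[i - 1] == target[j - 1] else 1
        choices = []
        if dp[i][j] == dp[i - 1][j - 1] + cost:
            choices.append("X" if cost else "=")
        if dp[i][j] == dp[i - 1][j] + 1:
            choices.append("I")
        if dp[i][j] == dp[i][j - 1] + 1:
            choices.append("D")
        # among optimal steps, continue the current gap run if possible
        op = next((c for c in choices if ops and c == ops[-1] and c in "ID"),
                  choices[0])
        ops.append(op)
        if op in ("=", "X"):
            i, j = i - 1, j - 1
        elif op == "I":
            i -= 1
        else:
            j -= 1
    while i > 0:
        ops.append("I")
        i -= 1
    ops.reverse()
    subs = sum(1 for o in ops if o == "X")
    ins = sum(1 for k, o in enumerate(ops) if o == "I" and (k == 0 or ops[k - 1] != "I"))
    dels = sum(1 for k, o in enumerate(ops) if o == "D" and (k == 0 or ops[k - 1] != "D"))
    return subs, ins, dels


def stab_coverage(intervals: list[tuple[int, int]], length: int) -> np.ndarray:
    """Per-position depth by brute-force interval stabbing (1-based incl.)."""
    depth = np.zeros(length, dtype=int)
    for lo, hi in intervals:
        for pos in range(max(lo, 1), min(hi, length) + 1):
            depth[pos - 1] += 1
    return depth


def forward_mixture(rho: float, psi: float, n1: float, n2: float) -> tuple[float, float]:
    """Model-expected (BAF, logR) for a tumor state diluted by stroma."""
    baf = (1 - rho + rho * n1) / (2 * (1 - rho) + rho * (n1 + n2))
    logr = np.log2((2 * (1 - rho) + rho * (n1 + n2)) / (2 * (1 - rho) + rho * psi))
    return baf, float(logr)


def qp_grid_oracle(f_matrix: np.ndarray, c: np.ndarray,
                   step: float = 0.01, b_max: float = 4.0) -> tuple[np.ndarray, float]:
    """Exhaustive grid search for the branch-placement least-squares fit.

    Scans b on a ``step`` grid with b >= 0 and the remainder component
    >= 0.5; returns the best (b, squared error).
    """
    b1 = np.arange(0.0, b_max + step / 2, step)
    b2 = np.arange(0.5, b_max + step / 2, step)
    pred = (b1[:, None, None] * f_matrix[0][None, None, :]
            + b2[None, :, None] * f_matrix[1][None, None, :])
    err = ((c[None, None, :] - pred) ** 2).sum(axis=2)
    i, j = np.unravel_index(np.argmin(err), err.shape)
    return np.array([b1[i], b2[j]]), float(err[i, j])
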