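"""Independent brute-force oracles used to validate the implementation.

Everything here is written from first principles (enumeration, direct
counting, textbook constant definitions) and deliberately shares no code
with the package internals it checks.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


def brute_pi(matrix: np.ndarray, columns: np.ndarray | None = None) -> float:
    """Average proportion of differing sites over all haplotype pairs."""
    if columns is not None:
        matrix = matrix[:, columns]
    n, L = matrix.shape
    diffs = []
    for a, b in itertools.combinations(range(n), 2):
        diffs.append(np.sum(matrix[a] != matrix[b]) / L)
    return float(np.mean(diffs))


def brute_pairwise_differences(matrix: np.ndarray) -> float:
    """Mean number of differing sites over all pairs (counts, not per site)."""
    n = matrix.shape[0]
    total = 0
    for a, b in itertools.combinations(range(n), 2):
        total += int(np.sum(matrix[a] != matrix[b]))
    return total / math.comb(n, 2)


def tajimas_d_independent(pi_hat: float, S: int, n: int) -> float:
    """Second implementation of Tajima's D from the constant definitions."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi_hat - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def fold_spectrum(xi: np.ndarray, n: int) -> np.ndarray:
    """Fold an unfolded spectrum by definition."""
    eta = np.zeros(n // 2 + 1, dtype=np.int64)
    for i in range(1, n):
        eta[min(i, n - i)] += xi[i]
    return eta


def fisher_two_sided_enum(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact P by exact-rational enumeration of the full
    hypergeometric support, summing tables no more probable than observed."""
    r1, r2 = a + b, c + d
    c1 = a + c
    N = r1 + r2

    def table_prob(x: int) -> Fraction:
        # P(X = x) for X = top-left cell, margins fixed
        return Fraction(math.comb(r1, x) * math.comb(r2, c1 - x),
                        math.comb(N, c1))

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = table_prob(a)
    total = Fraction(0)
    for x in range(lo, hi + 1):
        p = table_prob(x)
        if p <= p_obs:
            total += p
    return float(total)


def r2_direct(col_a: np.ndarray, col_b: np.ndarray) -> float:
    """r^2 from direct haplotype-frequency counting."""
    n = len(col_a)
    pa = np.mean(col_a)
    pb = np.mean(col_b)
    pab = np.mean(col_a * col_b)
    return (pab - pa * pb) ** 2 / (pa * (1 - pa) * pb * (1 - pb))


def omega_enum(positions: np.ndarray, matrix: np.ndarray, center: float,
               minwin: float, maxwin: float) -> float:
    """omega by exhaustive evaluation over every admissible window pair,
    with r^2 sums done by direct double loops."""
    best = -np.inf
    dist = positions - center
    left_all = [i for i in range(len(positions))
                if -maxwin <= dist[i] < 0]
    right_all = [i for i in range(len(positions))
                 if 0 < dist[i] <= maxwin]
    if len(left_all) < 2 or len(right_all) < 2:
        return float("nan")
    widths_l = sorted({minwin} | {-dist[i] for i in left_all if -dist[i] >= minwin})
    widths_r = sorted({minwin} | {dist[i] for i in right_all if dist[i] >= minwin})
    for wl in widths_l:
        L = [i for i in left_all if -dist[i] <= wl]
        if len(L) < 2:
            continue
        for wr in widths_r:
            R = [i for i in right_all if dist[i] <= wr]
            if len(R) < 2:
                continue
            within = 0.0
            for i, j in itertools.combinations(L, 2):
                within += r2_direct(matrix[:, i], matrix[:, j])
            for i, j in itertools.combinations(R, 2):
                within += r2_direct(matrix[:, i], matrix[:, j])
            cross = 0.0
            for i in L:
                for j in R:
                    cross += r2_direct(matrix[:, i], matrix[:, j])
            n_within = math.comb(len(L), 2) + math.comb(len(R), 2)
            num = within / n_within
            den = cross / (len(L) * len(R))
            om = np.inf if den == 0 else num / den
            if om > best:
                best = om
    return best


def sweep_transform_enum(phi: np.ndarray, n: int, p_e: float) -> np.ndarray:
    """Sweep-transformed spectrum by enumeration of the full outcome space
    (escape count B, downsampled subset, collapsed-lineage choice) at small n.

    phi is the background over derived counts 1..n-1 (length n+1 vector).
    """
    full = np.zeros(n + 1)
    lineages = list(range(n))
    for j in range(1, n):
        pj = phi[j]
        if pj == 0:
            continue
        for B in range(n + 1):
            wB = math.comb(n, B) * p_e**B * (1 - p_e) ** (n - B)
            if B == n:
                full[j] += pj * wB  # nothing swept: background class kept
                continue
            nsub = B + 1
            subsets = list(itertools.combinations(lineages, nsub))
            for T in subsets:
                # background assigns the j derived alleles to a uniform
                # subset; by symmetry fix derived = first j lineages
                m = sum(1 for x in T if x < j)
                for coll in T:
                    final = (m - 1 + n - B) if coll < j else m
                    full[final] += pj * wB / (len(subsets) * nsub)
    poly = full.copy()
    poly[0] = 0.0
    poly[n] = 0.0
    return poly / poly.sum()
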