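"""Neutral coalescent simulation: the engine behind every empirical null.

Time is scaled in units of 2N generations and theta = 4*N*mu per locus, the
conventions of Hudson's ms, so published neutral expectations (E[S] =
theta*a_n, E[pi] = theta) apply directly. Three modes are provided:

* theta mode without recombination (fast Kingman trees, Poisson mutations);
* fixed-S mode (exactly S mutations placed multinomially on branches,
  the conservative null used for Tajima's D / Fay-Wu H significance);
* theta mode with recombination (a Hudson-style ancestral recombination
  graph over a continuous sequence), used for LD-based nulls and the
  synthetic region generator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


def harmonic(n: int) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i."""
    return float(np.sum(1.0 / np.arange(1, n)))


def harmonic2(n: int) -> float:
    """b_n = sum_{i=1}^{n-1} 1/i^2."""
    return float(np.sum(1.0 / np.arange(1, n) ** 2))


@dataclass
class SimConfig:
    """Parameters of one batch of neutral replicates."""

    n: int
    theta: float | None = None   # per locus
    S: int | None = None         # fixed segregating sites (overrides theta)
    rho: float = 0.0             # population recombination rate for the region
    L: float = 1.0               # region length (positions drawn on (0, L])
    replicates: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.theta is None and self.S is None:
            raise ValueError("one of theta or S is required")
        if self.S is not None and self.rho:
            raise ValueError("fixed-S mode assumes no recombination")


@dataclass
class Haplotypes:
    """One replicate: binary ancestral(0)/derived(1) matrix with positions."""

    positions: np.ndarray  # float, strictly increasing, in (0, L]
    matrix: np.ndarray     # uint8, shape (n, S)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def S(self) -> int:
        return self.matrix.shape[1]

    def derived_counts(self) -> np.ndarray:
        return self.matrix.sum(axis=0)


# ---------------------------------------------------------------------------
# Kingman trees (no recombination)
# ---------------------------------------------------------------------------

def _kingman_edges_sizes(n: int, rng: np.random.Generator):
    """Sizes-only Kingman tree: per-branch (subtree size, branch length)."""
    sizes = np.ones(n, dtype=np.int64)
    birth = np.zeros(n)
    out_sizes = np.empty(2 * (n - 1), dtype=np.int64)
    out_len = np.empty(2 * (n - 1))
    t = 0.0
    k = n
    m = 0
    while k > 1:
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        for idx in (i, j):
            out_sizes[m] = sizes[idx]
            out_len[m] = t - birth[idx]
            m += 1
        sizes[min(i, j)] = sizes[i] + sizes[j]
        birth[min(i, j)] = t
        sizes[max(i, j)] = sizes[k - 1]
        birth[max(i, j)] = birth[k - 1]
        k -= 1
    return out_sizes, out_len


def _kingman_edges_leaves(n: int, rng: np.random.Generator):
    """Full Kingman tree: per-branch (leaf list, branch length)."""
    leaves: list[list[int]] = [[i] for i in range(n)]
    birth = [0.0] * n
    out_leaves: list[list[int]] = []
    out_len: list[float] = []
    t = 0.0
    k = n
    while k > 1:
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        for idx in (i, j):
            out_leaves.append(leaves[idx])
            out_len.append(t - birth[idx])
        merged = leaves[i] + leaves[j]
        lo, hi = min(i, j), max(i, j)
        leaves[lo] = merged
        birth[lo] = t
        leaves[hi] = leaves[k - 1]
        birth[hi] = birth[k - 1]
        del leaves[k - 1], birth[k - 1]
        k -= 1
    return out_leaves, np.asarray(out_len)


def fixed_s_counts(n: int, S: int, replicates: int,
                   rng: np.random.Generator) -> list[np.ndarray]:
    """Derived-allele counts per mutation for fixed-S replicates.

    Sufficient for SFS-based statistics (D, H, pi in counts) and much
    cheaper than materializing haplotype matrices.
    """
    out = []
    for _ in range(replicates):
        sizes, lens = _kingman_edges_sizes(n, rng)
        if S == 0:
            out.append(np.empty(0, dtype=np.int64))
            continue
        probs = lens / lens.sum()
        chosen = rng.choice(lens.size, size=S, p=probs)
        out.append(sizes[chosen])
    return out


def _matrix_from_tree(n: int, nmut: int, leaves, lens, L: float,
                      rng: np.random.Generator) -> Haplotypes:
    if nmut == 0:
        return Haplotypes(np.empty(0), np.zeros((n, 0), dtype=np.uint8))
    probs = lens / lens.sum()
    chosen = rng.choice(lens.size, size=nmut, p=probs)
    pos = np.sort(rng.uniform(0.0, L, size=nmut))
    mat = np.zeros((n, nmut), dtype=np.uint8)
    for col, e in enumerate(chosen):
        mat[leaves[e], col] = 1
    return Haplotypes(pos, mat)


def simulate_fixed_s(n: int, S: int, replicates: int = 1,
                     seed: int | None = None,
                     L: float = 1.0) -> list[Haplotypes]:
    """Neutral replicates conditioned on exactly S segregating sites."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(replicates):
        leaves, lens = _kingman_edges_leaves(n, rng)
        out.append(_matrix_from_tree(n, S, leaves, lens, L, rng))
    return out


def simulate_neutral(config: SimConfig) -> list[Haplotypes]:
    """Neutral replicates under the standard equilibrium model.

    theta mode places Poisson(theta/2 * total tree length) mutations; with
    rho > 0 genealogies come from the ancestral recombination graph.
    """
    rng = np.random.default_rng(config.seed)
    out = []
    for _ in range(config.replicates):
        if config.S is not None:
            leaves, lens = _kingman_edges_leaves(config.n, rng)
            out.append(_matrix_from_tree(config.n, config.S, leaves, lens,
                                         config.L, rng))
        elif config.rho == 0.0:
            leaves, lens = _kingman_edges_leaves(config.n, rng)
            nmut = rng.poisson(config.theta / 2.0 * lens.sum())
            out.append(_matrix_from_tree(config.n, nmut, leaves, lens,
                                         config.L, rng))
        else:
            out.append(_simulate_arg(config.n, config.theta, config.rho,
                                     config.L, rng))
    return out


# ---------------------------------------------------------------------------
# Ancestral recombination graph (Hudson's algorithm)
# ---------------------------------------------------------------------------

def _interval_subtract(l: float, r: float, cover: list[tuple[float, float]]):
    """Parts of (l, r) not covered by the sorted disjoint intervals."""
    out = []
    cur = l
    for cl, cr in cover:
        if cr <= cur or cl >= r:
            continue
        if cl > cur:
            out.append((cur, min(cl, r)))
        cur = max(cur, cr)
        if cur >= r:
            break
    if cur < r:
        out.append((cur, r))
    return out


def _union(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [list(intervals[0])]
    for l, r in intervals[1:]:
        if l <= out[-1][1]:
            out[-1][1] = max(out[-1][1], r)
        else:
            out.append([l, r])
    return [(l, r) for l, r in out]


def _simulate_arg(n: int, theta: float, rho: float, L: float,
                  rng: np.random.Generator) -> Haplotypes:
    """Coalescent with recombination over a continuous sequence [0, L)."""
    # each lineage: sorted list of (left, right, node); nodes 0..n-1 samples
    lineages: list[list[tuple[float, float, int]]] = [
        [(0.0, L, i)] for i in range(n)
    ]
    node_time = [0.0] * n
    edges: list[tuple[float, float, int, int]] = []  # (l, r, child, parent)
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        spans = np.array([lin[-1][1] - lin[0][0] for lin in lineages])
        recomb_rates = (rho / 2.0) * spans / L
        total_recomb = recomb_rates.sum()
        coal_rate = k * (k - 1) / 2.0
        total = coal_rate + total_recomb
        t += rng.exponential(1.0 / total)
        if rng.uniform() < coal_rate / total:
            i, j = rng.choice(k, size=2, replace=False)
            a, b = lineages[i], lineages[j]
            others = [lineages[m] for m in range(k) if m not in (i, j)]
            other_cover = _union([(l, r) for lin in others for l, r, _ in lin])
            p = len(node_time)
            node_time.append(t)
            merged: list[tuple[float, float, int]] = []
            bounds = sorted({x for l, r, _ in a + b for x in (l, r)})
            for l, r in zip(bounds, bounds[1:]):
                mid = (l + r) / 2.0
                na = next((nd for sl, sr, nd in a if sl <= mid < sr), None)
                nb = next((nd for sl, sr, nd in b if sl <= mid < sr), None)
                if na is not None and nb is not None:
                    edges.append((l, r, na, p))
                    edges.append((l, r, nb, p))
                    # spans nobody else carries have reached their MRCA
                    for cl, cr in _union(
                        [(max(l, ol), min(r, orr))
                         for ol, orr in other_cover if ol < r and orr > l]
                    ):
                        merged.append((cl, cr, p))
                elif na is not None:
                    merged.append((l, r, na))
                elif nb is not None:
                    merged.append((l, r, nb))
            merged.sort()
            # coalesce adjacent pieces mapping to the same node
            compact: list[tuple[float, float, int]] = []
            for seg in merged:
                if compact and compact[-1][2] == seg[2] and compact[-1][1] == seg[0]:
                    compact[-1] = (compact[-1][0], seg[1], seg[2])
                else:
                    compact.append(seg)
            new_lineages = [lineages[m] for m in range(k) if m not in (i, j)]
            if compact:
                new_lineages.append(compact)
            lineages = new_lineages
        else:
            i = rng.choice(k, p=recomb_rates / total_recomb)
            segs = lineages[i]
            lo, hi = segs[0][0], segs[-1][1]
            bp = rng.uniform(lo, hi)
            left = [(l, min(r, bp), nd) for l, r, nd in segs if l < bp]
            right = [(max(l, bp), r, nd) for l, r, nd in segs if r > bp]
            if left and right:
                lineages[i] = left
                lineages.append(right)

    # mutations: Poisson with rate theta/2 per unit time over the full region
    node_time = np.asarray(node_time)
    if not edges:
        return Haplotypes(np.empty(0), np.zeros((n, 0), dtype=np.uint8))
    el = np.array([e[0] for e in edges])
    er = np.array([e[1] for e in edges])
    child = np.array([e[2] for e in edges])
    parent = np.array([e[3] for e in edges])
    weight = (node_time[parent] - node_time[child]) * (er - el) / L
    total_weight = weight.sum()
    nmut = rng.poisson(theta / 2.0 * total_weight)
    if nmut == 0:
        return Haplotypes(np.empty(0), np.zeros((n, 0), dtype=np.uint8))
    children_index: dict[int, list[int]] = {}
    for idx, pnode in enumerate(parent):
        children_index.setdefault(int(pnode), []).append(idx)
    chosen = rng.choice(len(edges), size=nmut, p=weight / total_weight)
    pos = rng.uniform(el[chosen], er[chosen])
    order = np.argsort(pos)
    pos = pos[order]
    chosen = chosen[order]
    mat = np.zeros((n, nmut), dtype=np.uint8)
    for col, e in enumerate(chosen):
        stack = [int(child[e])]
        x = pos[col]
        while stack:
            v = stack.pop()
            if v < n:
                mat[v, col] = 1
                continue
            for idx in children_index.get(v, ()):
                if el[idx] <= x < er[idx]:
                    stack.append(int(child[idx]))
    return Haplotypes(pos, mat)


# ---------------------------------------------------------------------------
# Null distributions and cutoffs
# ---------------------------------------------------------------------------

@dataclass
class CutoffResult:
    cutoff: float
    quantile: float
    replicates: int
    seed: int | None
    values: np.ndarray = field(repr=False)


def null_cutoff(stat_fn, config: SimConfig, quantile: float = 0.99) -> CutoffResult:
    """Empirical quantile of a statistic over neutral replicates.

    ``stat_fn`` maps one Haplotypes replicate to a scalar; NaN results
    (statistic undefined on that replicate) are dropped.
    """
    if config.replicates < 100 and quantile not in (0.0, 1.0):
        warnings.warn(
            f"{config.replicates} replicates is few for a "
            f"{100 * min(quantile, 1 - quantile):g}% cutoff"
        )
    reps = simulate_neutral(config)
    values = np.array([stat_fn(rep) for rep in reps], dtype=float)
    usable = values[~np.isnan(values)]
    if usable.size == 0:
        raise ValueError("statistic undefined on every replicate")
    return CutoffResult(float(np.quantile(usable, quantile)), quantile,
                        config.replicates, config.seed, values)


def empirical_p(r: int, replicates: int) -> float:
    """P = (r+1)/(reps+1): never exactly zero."""
    return (r + 1) / (replicates + 1)


def segregating_sites_distribution(n: int, theta: float, replicates: int,
                                   rng: np.random.Generator) -> np.ndarray:
    """Vectorized draw of S under the neutral coalescent (no recombination):
    total tree length summed over intervals, then Poisson thinning."""
    k = np.arange(n, 1, -1)
    rates = k * (k - 1) / 2.0
    waits = rng.exponential(1.0 / rates, size=(replicates, n - 1))
    total_len = (waits * k).sum(axis=1)
    return rng.poisson(theta / 2.0 * total_len)


def to_ms_text(replicates: list[Haplotypes], L: float = 1.0) -> str:
    """ms-compatible text blocks for interoperability and cross-checks."""
    out = []
    for rep in replicates:
        out.append("//")
        out.append(f"segsites: {rep.S}")
        if rep.S:
            pos = " ".join(f"{p / L:.5f}" for p in rep.positions)
            out.append(f"positions: {pos}")
            for row in rep.matrix:
                out.append("".join(str(int(x)) for x in row))
        out.append("")
    return "\n".join(out)
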