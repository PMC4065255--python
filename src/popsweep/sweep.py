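"""Genome scans for selective sweeps: composite likelihood ratio and omega.

The CLR scan contrasts, at each grid position, a sweep model against the
background site-frequency spectrum estimated from all scanned SNPs. The
sweep model distorts the background spectrum through the escape probability
p_e = 1 - exp(-alpha*d) at distance d from the proposed sweep site: B ~
Binomial(n, p_e) lineages escape the sweep, the remaining n-B collapse onto
a single lineage drawn from the pre-sweep population (a hypergeometric
downsampling of the background from n to B+1, with the collapsed lineage's
allele replicated n-B times), and the resulting spectrum is renormalized
over the observable polymorphic classes.

The omega statistic detects the complementary LD signature: elevated
linkage within each flank of a swept site but decoupled LD across it. For a
candidate position, the window SNPs are split into a left and right set and
omega is the ratio of mean within-flank r^2 to mean cross-flank r^2,
maximized over admissible window extents between minwin and maxwin.

Both scans use a 125-point grid by default and take their 1% significance
cutoffs from neutral coalescent simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import coalescent
from .alignio import BASES, HaplotypeAlignment
from .coalescent import Haplotypes, SimConfig

DEFAULT_GRID = 125
DEFAULT_MINWIN = 1000
DEFAULT_MAXWIN = 2000


# ---------------------------------------------------------------------------
# SNP matrix
# ---------------------------------------------------------------------------

@dataclass
class SnpMatrix:
    """Biallelic SNPs: positions (bp), n x S binary matrix, polarization.

    For polarized SNPs the coded allele 1 is the derived allele; for
    unpolarized SNPs the coding is arbitrary (folded statistics only).
    """

    positions: np.ndarray      # float, strictly increasing
    matrix: np.ndarray         # uint8 (n, S)
    polarized: np.ndarray      # bool per SNP

    def __post_init__(self) -> None:
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("SNP positions must be strictly increasing")
        counts = self.matrix.sum(axis=0)
        if np.any(counts == 0) or np.any(counts == self.n):
            raise ValueError("monomorphic column in SNP matrix")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def S(self) -> int:
        return self.matrix.shape[1]

    def counts(self) -> np.ndarray:
        """Derived counts (polarized) / coded-allele counts (unpolarized)."""
        return self.matrix.sum(axis=0).astype(np.int64)

    @classmethod
    def from_alignment(cls, aln: HaplotypeAlignment,
                       columns: np.ndarray | None = None) -> "SnpMatrix":
        """Extract biallelic SNPs; polarization follows the outgroup rule
        (outgroup base must match exactly one ingroup allele)."""
        m = aln.ingroup_matrix
        out_row = aln.outgroup_row
        if columns is None:
            columns = aln.good_columns()
        pos, cols, polar = [], [], []
        for col in np.nonzero(columns)[0]:
            counts = {b: int(np.sum(m[:, col] == b)) for b in BASES}
            alleles = [b for b, c in counts.items() if c > 0]
            if len(alleles) != 2:
                continue
            a1, a2 = alleles
            out_base = out_row[col] if out_row is not None else "N"
            if out_base == a1:
                cols.append((m[:, col] == a2).astype(np.uint8))
                polar.append(True)
            elif out_base == a2:
                cols.append((m[:, col] == a1).astype(np.uint8))
                polar.append(True)
            else:
                cols.append((m[:, col] == a2).astype(np.uint8))
                polar.append(False)
            pos.append(col + aln.region_offset)
        if not cols:
            return cls(np.empty(0), np.zeros((m.shape[0], 0), dtype=np.uint8),
                       np.empty(0, dtype=bool))
        return cls(np.asarray(pos, dtype=float), np.column_stack(cols),
                   np.asarray(polar, dtype=bool))

    @classmethod
    def from_haplotypes(cls, rep: Haplotypes) -> "SnpMatrix":
        """Simulated replicates carry known ancestral states: all polarized.
        Monomorphic columns (possible after transformations) are dropped."""
        counts = rep.matrix.sum(axis=0)
        keep = (counts > 0) & (counts < rep.n)
        pos = rep.positions[keep]
        # enforce strictly increasing positions (continuous positions are
        # almost surely distinct; guard against ties anyway)
        pos = pos + np.arange(pos.size) * 0.0
        dedup = np.concatenate([[True], np.diff(pos) > 0])
        return cls(pos[dedup], rep.matrix[:, keep][:, dedup],
                   np.ones(int(dedup.sum()), dtype=bool))


@dataclass
class ScanTrack:
    """Per-grid-position scan statistic with its simulated cutoff."""

    track: pd.DataFrame          # position, stat [, alpha_hat]
    statistic: str               # 'CLR' | 'omega'
    argmax_position: float
    max_value: float
    cutoff: float | None = None
    cutoff_quantile: float | None = None
    replicates: int | None = None
    seed: int | None = None

    def to_tsv(self, path) -> None:
        self.track.to_csv(path, sep="\t", index=False)

    def summary(self) -> dict:
        return {
            "statistic": self.statistic,
            "argmax_position": self.argmax_position,
            "max_value": self.max_value,
            "cutoff": self.cutoff,
            "cutoff_quantile": self.cutoff_quantile,
            "replicates": self.replicates,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# Background and sweep-transformed spectra
# ---------------------------------------------------------------------------

@dataclass
class BackgroundSFS:
    """Probability vector over derived counts 1..n-1 (index 0 unused)."""

    n: int
    probs: np.ndarray  # length n+1; mass on 1..n-1 (and optionally n)
    include_fixed: bool = False

    def __post_init__(self) -> None:
        total = self.probs.sum()
        if not np.isclose(total, 1.0):
            raise ValueError("background spectrum must sum to 1")


def background_sfs(snps: SnpMatrix, include_fixed: bool = False) -> BackgroundSFS:
    """Estimate the background spectrum from all scanned SNPs (the sweep
    scan's composite null). Unpolarized SNPs split half-and-half between
    the two complementary derived-count classes."""
    n = snps.n
    mass = np.zeros(n + 1)
    counts = snps.counts()
    for c, pol in zip(counts, snps.polarized):
        if pol:
            mass[c] += 1.0
        else:
            mass[c] += 0.5
            mass[n - c] += 0.5
    if not include_fixed:
        mass[n] = 0.0
    mass[0] = 0.0
    if mass.sum() == 0:
        raise ValueError("no SNPs to estimate a background spectrum from")
    return BackgroundSFS(n, mass / mass.sum(), include_fixed)


def _transform_matrix(background: BackgroundSFS) -> np.ndarray:
    """C[B, j]: distribution of the post-sweep derived count j (0..n) given
    that exactly B of the n lineages escaped the sweep."""
    n = background.n
    phi = background.probs[1:n]  # over j = 1..n-1
    j = np.arange(1, n)
    C = np.zeros((n + 1, n + 1))
    C[n, 1:n] = phi  # every lineage escaped: background unchanged
    for B in range(n):
        nsub = B + 1
        m = np.arange(nsub + 1)
        # hypergeometric downsampling of the background from n to B+1
        H = stats.hypergeom.pmf(m[None, :], n, j[:, None], nsub)
        pm = phi @ H  # distribution of derived count among the B+1
        p_coll = m / nsub  # collapsed lineage carries the derived allele
        for mm in range(nsub + 1):
            if pm[mm] == 0:
                continue
            C[B, mm - 1 + n - B] += pm[mm] * p_coll[mm]
            C[B, mm] += pm[mm] * (1.0 - p_coll[mm])
    return C


def sweep_transformed_sfs(background: BackgroundSFS, p_e: float,
                          _C: np.ndarray | None = None) -> np.ndarray:
    """Spectrum over derived counts 1..n-1 after a sweep with escape
    probability p_e, renormalized over the observable polymorphic classes.

    Returns a length-(n+1) vector with mass on 1..n-1.
    """
    if not 0.0 <= p_e <= 1.0:
        raise ValueError("p_e must be in [0, 1]")
    n = background.n
    C = _transform_matrix(background) if _C is None else _C
    w = stats.binom.pmf(np.arange(n + 1), n, p_e)
    full = w @ C
    poly = full.copy()
    poly[0] = 0.0
    poly[n] = 0.0
    total = poly.sum()
    if total <= 0:
        # complete hitchhiking: no polymorphism observable; limit spectrum
        # concentrates on singleton/(n-1) classes, approximated at tiny p_e
        return sweep_transformed_sfs(background, max(p_e, 1e-12), _C=C)
    return poly / total


# ---------------------------------------------------------------------------
# CLR scan
# ---------------------------------------------------------------------------

def _default_alpha_grid(half_width: float, size: int = 40) -> np.ndarray:
    """Log-spaced sweep strengths spanning effectively-complete hitchhiking
    to effectively-neutral at the region's half width, plus the exactly
    neutral member (alpha = inf <=> p_e = 1) so the model nests the null."""
    lo = 1e-4 / half_width
    hi = 30.0 / half_width
    return np.concatenate([np.geomspace(lo, hi, size - 1), [np.inf]])


def _pe_log_table(background: BackgroundSFS, n_bins: int = 64):
    """Spectra precomputed on a log grid of alpha*d values.

    Row i holds the transformed polymorphic spectrum at
    x = x_grid[i] (p_e = 1 - exp(-x)); the last row is p_e = 1 (background).
    """
    x_grid = np.geomspace(1e-6, 30.0, n_bins - 1)
    C = _transform_matrix(background)
    rows = [sweep_transformed_sfs(background, 1.0 - np.exp(-x), _C=C)
            for x in x_grid]
    bg = background.probs.copy()
    bg[0] = 0.0
    bg[background.n] = 0.0
    rows.append(bg / bg.sum())
    return np.log(x_grid), np.vstack(rows)


def _snp_log_probs(table: np.ndarray, bin_idx: np.ndarray,
                   counts: np.ndarray, polarized: np.ndarray,
                   n: int) -> np.ndarray:
    """Per-SNP log model probability; folded SNPs sum complementary classes."""
    p = table[bin_idx, counts]
    comp = n - counts
    fold_extra = np.where(polarized | (comp == counts), 0.0,
                          table[bin_idx, comp])
    return np.log(np.maximum(p + fold_extra, 1e-300))


def clr_scan(snps: SnpMatrix, grid: int = DEFAULT_GRID,
             alpha_grid: np.ndarray | None = None,
             background: BackgroundSFS | None = None,
             pe_bins: int = 64) -> ScanTrack:
    """Composite likelihood ratio scan over an evenly spaced position grid.

    CLR(x) = 2 [ max_alpha sum_SNPs log p_sweep(count; alpha, |pos-x|)
                 - sum_SNPs log p_background(count) ].
    """
    if snps.S < 2:
        raise ValueError("CLR scan needs at least 2 SNPs")
    if background is None:
        background = background_sfs(snps)
    n = snps.n
    first, last = snps.positions[0], snps.positions[-1]
    grid_pos = np.linspace(first, last, grid)
    if alpha_grid is None:
        alpha_grid = _default_alpha_grid((last - first) / 2.0)
    log_x_grid, table = _pe_log_table(background, pe_bins)
    counts = snps.counts()
    bg_row = np.full(snps.S, table.shape[0] - 1)
    bg_loglik = _snp_log_probs(table, bg_row, counts, snps.polarized, n).sum()

    finite_alpha = alpha_grid[np.isfinite(alpha_grid)]
    log_alpha = np.log(finite_alpha)
    clr = np.empty(grid)
    alpha_hat = np.empty(grid)
    if finite_alpha.size == 0:
        # only the effectively-neutral member: model == background
        track = pd.DataFrame({"position": grid_pos,
                              "stat": np.zeros(grid),
                              "alpha_hat": np.full(grid, np.inf)})
        return ScanTrack(track, "CLR", float(grid_pos[0]), 0.0)
    for gi, x in enumerate(grid_pos):
        d = np.abs(snps.positions - x)
        log_d = np.log(np.maximum(d, 1e-9))
        # bin log(alpha*d) for every (alpha, SNP) pair at once
        log_ad = log_alpha[:, None] + log_d[None, :]
        idx = np.clip(
            np.searchsorted(log_x_grid, log_ad), 0, log_x_grid.size - 1
        )
        # snap to nearest grid neighbor in log space
        left = np.maximum(idx - 1, 0)
        nearer_left = (np.abs(log_ad - log_x_grid[left])
                       < np.abs(log_x_grid[idx] - log_ad))
        idx = np.where(nearer_left, left, idx)
        idx[log_ad > log_x_grid[-1]] = table.shape[0] - 1  # p_e ~ 1
        logliks = np.array([
            _snp_log_probs(table, idx[a], counts, snps.polarized, n).sum()
            for a in range(finite_alpha.size)
        ])
        best = int(np.argmax(logliks))
        best_ll = logliks[best]
        if np.isinf(alpha_grid).any() and bg_loglik >= best_ll:
            clr[gi] = 0.0
            alpha_hat[gi] = np.inf
        else:
            clr[gi] = 2.0 * (best_ll - bg_loglik)
            alpha_hat[gi] = finite_alpha[best]
    track = pd.DataFrame({"position": grid_pos, "stat": clr,
                          "alpha_hat": alpha_hat})
    amax = int(np.argmax(clr))
    return ScanTrack(track, "CLR", float(grid_pos[amax]), float(clr[amax]))


# ---------------------------------------------------------------------------
# LD: r^2 and omega
# ---------------------------------------------------------------------------

def r_squared(snp_a: np.ndarray, snp_b: np.ndarray) -> float:
    """r^2 between two biallelic SNP columns on the same haplotype set:
    (p_AB - p_A p_B)^2 / (p_A(1-p_A) p_B(1-p_B))."""
    a = np.asarray(snp_a, dtype=float)
    b = np.asarray(snp_b, dtype=float)
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValueError("r^2 undefined for monomorphic input")
    pab = np.mean(a * b)
    return float((pab - pa * pb) ** 2 / (pa * (1 - pa) * pb * (1 - pb)))


def r2_matrix(snps: SnpMatrix) -> np.ndarray:
    m = snps.matrix.astype(float)
    c = np.corrcoef(m, rowvar=False)
    return c**2


def _prefix2d(a: np.ndarray) -> np.ndarray:
    p = np.zeros((a.shape[0] + 1, a.shape[1] + 1))
    p[1:, 1:] = np.cumsum(np.cumsum(a, axis=0), axis=1)
    return p


def _block_sum(p: np.ndarray, r0: int, r1: int, c0: int, c1: int) -> float:
    """Sum of a[r0..r1, c0..c1] inclusive from the 2D prefix array."""
    return float(p[r1 + 1, c1 + 1] - p[r0, c1 + 1] - p[r1 + 1, c0] + p[r0, c0])


def omega_at(position: float, snps: SnpMatrix,
             minwin: float = DEFAULT_MINWIN, maxwin: float = DEFAULT_MAXWIN,
             r2: np.ndarray | None = None,
             _prefix: np.ndarray | None = None) -> tuple[float, int, int]:
    """omega at a candidate position, maximized over admissible window
    extents between minwin and maxwin on each side.

    Returns (omega, n_left, n_right); omega is NaN when fewer than 2 SNPs
    are available on either side within maxwin, and +inf when the best
    split has zero cross-flank r^2 (two perfect flanking LD blocks).
    Ties in omega resolve to the leftmost (smallest) window pair.
    """
    pos = snps.positions
    if r2 is None:
        r2 = r2_matrix(snps)
    p2 = _prefix2d(r2) if _prefix is None else _prefix

    left_all = np.nonzero((pos < position) & (pos >= position - maxwin))[0]
    right_all = np.nonzero((pos > position) & (pos <= position + maxwin))[0]
    if left_all.size < 2 or right_all.size < 2:
        return (float("nan"), int(left_all.size), int(right_all.size))
    iL = left_all[-1]   # nearest left SNP
    iR = right_all[0]   # nearest right SNP
    # candidate left boundaries: the window [position-w, position) for
    # w in [minwin, maxwin] selects a suffix of left_all; distinct suffixes
    # are the mandatory minwin set plus one per SNP beyond minwin
    dist_l = position - pos[left_all]
    cand_l = list(left_all[dist_l >= minwin])
    near_l = left_all[dist_l < minwin]
    if near_l.size:
        cand_l.append(near_l[0])
    left_starts = [a for a in cand_l if iL - a + 1 >= 2]
    dist_r = pos[right_all] - position
    cand_r = list(right_all[dist_r >= minwin])
    near_r = right_all[dist_r < minwin]
    if near_r.size:
        cand_r.append(near_r[-1])
    right_ends = [b for b in cand_r if b - iR + 1 >= 2]
    if not left_starts or not right_ends:
        return (float("nan"), int(left_all.size), int(right_all.size))

    best = (-np.inf, 0, 0)
    for a in left_starts:
        el = iL - a + 1
        within_l = (_block_sum(p2, a, iL, a, iL) - el) / 2.0
        for b in right_ends:
            r = b - iR + 1
            within_r = (_block_sum(p2, iR, b, iR, b) - r) / 2.0
            cross = _block_sum(p2, a, iL, iR, b)
            n_within = el * (el - 1) // 2 + r * (r - 1) // 2
            num = (within_l + within_r) / n_within
            if cross <= 0:
                om = np.inf
            else:
                om = num / (cross / (el * r))
            if om > best[0]:
                best = (om, el, r)
    return best


def omega_scan(snps: SnpMatrix, grid: int = DEFAULT_GRID,
               minwin: float = DEFAULT_MINWIN,
               maxwin: float = DEFAULT_MAXWIN) -> ScanTrack:
    """omega over an evenly spaced grid spanning [first SNP, last SNP]."""
    if snps.S < 4:
        raise ValueError("omega scan needs at least 4 SNPs")
    r2 = r2_matrix(snps)
    p2 = _prefix2d(r2)
    grid_pos = np.linspace(snps.positions[0], snps.positions[-1], grid)
    om = np.empty(grid)
    for gi, x in enumerate(grid_pos):
        om[gi], _, _ = omega_at(x, snps, minwin, maxwin, r2=r2, _prefix=p2)
    track = pd.DataFrame({"position": grid_pos, "stat": om})
    finite = np.where(np.isnan(om), -np.inf, om)
    amax = int(np.argmax(finite))
    return ScanTrack(track, "omega", float(grid_pos[amax]), float(om[amax]))


# ---------------------------------------------------------------------------
# Neutral cutoffs
# ---------------------------------------------------------------------------

def clr_max_statistic(rep: Haplotypes) -> float:
    """Max CLR over the grid for one neutral replicate (its own background)."""
    snps = SnpMatrix.from_haplotypes(rep)
    if snps.S < 5:
        return float("nan")
    return clr_scan(snps).max_value


def omega_max_statistic(rep: Haplotypes, minwin: float = DEFAULT_MINWIN,
                        maxwin: float = DEFAULT_MAXWIN) -> float:
    snps = SnpMatrix.from_haplotypes(rep)
    if snps.S < 8:
        return float("nan")
    track = omega_scan(snps, minwin=minwin, maxwin=maxwin)
    vals = track.track["stat"].to_numpy()
    vals = vals[np.isfinite(vals)]
    return float(np.max(vals)) if vals.size else float("nan")


def clr_cutoff(config: SimConfig, quantile: float = 0.99):
    return coalescent.null_cutoff(clr_max_statistic, config, quantile)


def omega_cutoff(config: SimConfig, quantile: float = 0.99,
                 minwin: float = DEFAULT_MINWIN, maxwin: float = DEFAULT_MAXWIN):
    return coalescent.null_cutoff(
        lambda rep: omega_max_statistic(rep, minwin, maxwin), config, quantile
    )
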