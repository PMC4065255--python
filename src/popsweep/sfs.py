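"""Site-frequency-spectrum construction and SFS-based neutrality tests.

Derived alleles are polarized against a single outgroup haplotype; sites
where the outgroup is missing, gapped, or carries a third allele enter the
folded spectrum only (a per-site mixed folded/unfolded scheme). Tajima's D
contrasts pi-based and S-based theta estimators; the normalized Fay-Wu H
contrasts pi against the high-frequency-weighted theta_L and is the classic
hitchhiking signature. Significance for both comes from fixed-S coalescent
nulls (conservatively assuming no intragenic recombination).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import coalescent
from .alignio import BASES, HaplotypeAlignment, SiteClassMap
from .coalescent import harmonic, harmonic2

POLARIZED, UNPOLARIZABLE = "polarized", "unpolarizable"


@dataclass
class SiteFrequencySpectrum:
    """Unfolded counts xi_i (derived count i) and folded counts eta_i.

    ``xi`` is indexed 0..n (entries 0 and n unused for polymorphic spectra);
    ``eta`` indexed 0..floor(n/2). Sites that cannot be polarized contribute
    to ``eta`` only; polarized sites contribute to both.
    """

    n: int
    xi: np.ndarray
    eta: np.ndarray
    status: list[str]

    @property
    def S(self) -> int:
        """All biallelic segregating sites (polarized + unpolarizable)."""
        return len(self.status)

    @property
    def S_polarized(self) -> int:
        return int(self.xi[1:self.n].sum())

    def folded_from_unfolded(self) -> np.ndarray:
        """eta_i = xi_i + xi_{n-i} (i < n/2), eta_{n/2} = xi_{n/2}."""
        n = self.n
        eta = np.zeros(n // 2 + 1, dtype=self.xi.dtype)
        for i in range(1, n // 2 + 1):
            if i == n - i:
                eta[i] = self.xi[i]
            else:
                eta[i] = self.xi[i] + self.xi[n - i]
        return eta


def build_sfs(aln: HaplotypeAlignment,
              columns: np.ndarray | None = None,
              require_outgroup: bool = True) -> SiteFrequencySpectrum:
    """Build the mixed unfolded/folded spectrum over the selected columns.

    Only biallelic ingroup sites are used (sites with >2 ingroup alleles are
    excluded: every downstream statistic assumes the infinite-sites model).
    A site is polarized iff the outgroup base matches exactly one ingroup
    allele; the other allele is then derived.
    """
    if require_outgroup and aln.outgroup_id is None:
        raise ValueError("unfolded spectrum requested but no outgroup present")
    m = aln.ingroup_matrix
    n = m.shape[0]
    out_row = aln.outgroup_row
    if columns is None:
        columns = aln.good_columns()
    xi = np.zeros(n + 1, dtype=np.int64)
    eta = np.zeros(n // 2 + 1, dtype=np.int64)
    status: list[str] = []
    for col in np.nonzero(columns)[0]:
        counts = {b: int(np.sum(m[:, col] == b)) for b in BASES}
        alleles = [b for b, c in counts.items() if c > 0]
        if len(alleles) != 2:
            continue
        a1, a2 = alleles
        out_base = out_row[col] if out_row is not None else "N"
        if out_base == a1:
            xi[counts[a2]] += 1
            eta[min(counts[a2], n - counts[a2])] += 1
            status.append(POLARIZED)
        elif out_base == a2:
            xi[counts[a1]] += 1
            eta[min(counts[a1], n - counts[a1])] += 1
            status.append(POLARIZED)
        else:
            eta[min(counts[a1], counts[a2])] += 1
            status.append(UNPOLARIZABLE)
    return SiteFrequencySpectrum(n, xi, eta, status)


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajima_constants(n: int) -> dict[str, float]:
    a1 = harmonic(n)
    a2 = harmonic2(n)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(pi_hat: float, S: int, n: int) -> float | None:
    """D = (pi_hat - S/a1) / sqrt(e1*S + e2*S*(S-1)).

    ``pi_hat`` is the mean number of pairwise differences (in counts, not
    per site) over the same sites that contribute to S. Undefined at S = 0.
    """
    if S == 0:
        return None
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    if var <= 0:  # degenerate (n = 2 with S = 1): D undefined
        return None
    return float((pi_hat - S / c["a1"]) / math.sqrt(var))


def pi_from_counts(counts: np.ndarray, n: int) -> float:
    """Mean pairwise differences from per-site derived (or minor) counts."""
    counts = np.asarray(counts)
    return float(np.sum(2.0 * counts * (n - counts)) / (n * (n - 1)))


def tajimas_d_from_counts(counts: np.ndarray, n: int) -> float | None:
    return tajimas_d(pi_from_counts(counts, n), len(counts), n)


# ---------------------------------------------------------------------------
# Normalized Fay-Wu H
# ---------------------------------------------------------------------------

def fay_wu_h_norm(sfs: SiteFrequencySpectrum) -> float | None:
    """Normalized H = (theta_pi - theta_L)/sqrt(Var), computed on the
    polarized unfolded spectrum. Undefined without polarized sites."""
    xi = sfs.xi[1:sfs.n]
    if xi.sum() == 0:
        return None
    return _h_from_xi(xi, sfs.n)


def _h_from_xi(xi: np.ndarray, n: int) -> float:
    i = np.arange(1, n)
    S = float(xi.sum())
    theta_pi = float(np.sum(i * (n - i) * xi) * 2.0 / (n * (n - 1)))
    theta_l = float(np.sum(i * xi) / (n - 1))
    a_n = harmonic(n)
    b_n = harmonic2(n)
    b_n1 = harmonic2(n + 1)  # sum_{i<=n} 1/i^2
    theta_w = S / a_n
    theta_sq = S * (S - 1) / (a_n**2 + b_n)
    var = (theta_w * (n - 2) / (6.0 * (n - 1))
           + theta_sq * (18.0 * n**2 * (3 * n + 2) * b_n1
                         - (88.0 * n**3 + 9 * n**2 - 13 * n + 6))
           / (9.0 * n * (n - 1) ** 2))
    return float((theta_pi - theta_l) / math.sqrt(var))


def fay_wu_h_from_counts(counts: np.ndarray, n: int) -> float | None:
    """H from a vector of per-site derived counts (all treated as polarized)."""
    counts = np.asarray(counts)
    counts = counts[(counts > 0) & (counts < n)]
    if counts.size == 0:
        return None
    xi = np.bincount(counts, minlength=n + 1)[1:n]
    return _h_from_xi(xi, n)


# ---------------------------------------------------------------------------
# Misorientation probability (outgroup homoplasy)
# ---------------------------------------------------------------------------

def misorientation_probability(d: float) -> float:
    """Probability that the outgroup base at a polymorphic site has itself
    mutated to coincide with the derived ingroup allele.

    Under a Jukes-Cantor-style argument with per-site silent divergence d,
    p_mis = (d/3) / (1 - 2d/3). Saturated divergence (d >= 3/4) is an error.
    """
    if d < 0:
        raise ValueError("divergence must be >= 0")
    if d >= 0.75:
        raise ValueError(f"silent divergence d={d} is saturated (>= 3/4)")
    return (d / 3.0) / (1.0 - 2.0 * d / 3.0)


def silent_divergence(aln: HaplotypeAlignment, classmap: SiteClassMap) -> float:
    """Per-site silent divergence between the ingroup consensus and the
    outgroup, over unmasked silent (synonymous-weighted + intronic) columns."""
    if aln.outgroup_id is None:
        raise ValueError("outgroup required for divergence")
    out_row = aln.outgroup_row
    cons = classmap.consensus
    from .alignio import CODING, INTRONIC
    coding = classmap.class_mask(CODING)
    intronic = classmap.class_mask(INTRONIC)
    ok = (out_row != "N") & (out_row != "-")
    diff = cons != out_row
    # each differing coding column contributes its synonymous site weight
    num = float(np.sum(diff & intronic & ok)) \
        + float(np.sum(classmap.syn_weight[diff & coding & ok]))
    denom = float(np.sum(intronic & ok)) \
        + float(np.sum(classmap.syn_weight[coding & ok]))
    if denom <= 0:
        raise ValueError("no usable silent sites for divergence")
    return num / denom


# ---------------------------------------------------------------------------
# Empirical rank against a background gene set
# ---------------------------------------------------------------------------

@dataclass
class RankResult:
    rank: int          # 1 = smallest (most negative) among background + focal
    n_tied: int
    percentile: float  # midrank percentile of focal within background
    n_background: int


def empirical_rank(focal: float, background) -> RankResult:
    """Rank of a focal statistic within an empirical background distribution."""
    bg = np.asarray(list(background), dtype=float)
    if bg.size == 0:
        raise ValueError("background must be non-empty")
    below = int(np.sum(bg < focal))
    tied = int(np.sum(bg == focal))
    percentile = 100.0 * (below + 0.5 * tied) / bg.size
    return RankResult(rank=below + 1, n_tied=tied, percentile=percentile,
                      n_background=bg.size)


# ---------------------------------------------------------------------------
# Coalescent significance
# ---------------------------------------------------------------------------

@dataclass
class NeutralityResult:
    statistic: str
    value: float
    p_value: float
    replicates: int
    seed: int | None


def neutrality_test(statistic: str, observed: float, n: int, S: int,
                    replicates: int = 10_000,
                    seed: int | None = None) -> NeutralityResult:
    """Two-tailed empirical P for Tajima's D or normalized Fay-Wu H.

    The null is the fixed-S coalescent without recombination (conservative).
    P doubles the smaller one-sided empirical tail, with the +1 correction
    so P is never exactly zero. Replicate H values are polarized by
    construction (the simulator knows ancestral states).
    """
    if statistic not in ("D", "H"):
        raise ValueError("statistic must be 'D' or 'H'")
    rng = np.random.default_rng(seed)
    counts = coalescent.fixed_s_counts(n, S, replicates, rng)
    fn = tajimas_d_from_counts if statistic == "D" else fay_wu_h_from_counts
    values = np.array([v for v in (fn(c, n) for c in counts) if v is not None])
    r_low = int(np.sum(values <= observed))
    r_high = int(np.sum(values >= observed))
    p = min(1.0, 2.0 * min(coalescent.empirical_p(r_low, values.size),
                           coalescent.empirical_p(r_high, values.size)))
    return NeutralityResult(statistic, observed, p, replicates, seed)
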