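"""Hudson-Kreitman-Aguade tests of polymorphism/divergence proportionality.

Under neutrality, within-species polymorphism and between-species divergence
are both proportional to the mutation rate, so their ratio should be shared
across loci. The pairwise test fits per-locus theta and a shared divergence
time T by moments and measures departure with a chi-square-style X^2 whose
significance comes from coalescent simulation under the fitted null. The
maximum-likelihood variant models S_i and D_i as Poisson with means
k_i*theta_i*L_i*a_{n_i} and theta_i*L_i*(T+1); freeing the selection
parameter k at a focal locus and comparing likelihoods gives an LRT against
chi-square with one degree of freedom per freed k. k < 1 means a diversity
deficit at the focal locus relative to the multilocus fit, the sweep
signature.

MLEs come from deterministic multi-start bounded optimization (the
per-locus theta profile out in closed form, leaving a small search over T
and the k's); restarts must agree within tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from . import coalescent
from .coalescent import harmonic, harmonic2

K_BOUNDS = (1e-4, 1e2)
T_BOUNDS = (1e-3, 1e3)


@dataclass
class HkaLocusData:
    """Silent-site polymorphism and divergence summary for one locus."""

    locus: str
    n: int        # chromosomes sampled
    L: float      # silent sites
    S: int        # silent segregating sites
    D: float      # mean pairwise silent divergence to outgroup, in counts

    def __post_init__(self) -> None:
        if self.n < 2 or self.L <= 0 or self.S < 0 or self.D < 0:
            raise ValueError(f"invalid HKA locus data for {self.locus}")


def region_hka_data(aln, classmap, annotations) -> list[HkaLocusData]:
    """Per-gene silent-site HKA input from a classified region alignment.

    S_i counts silent segregating sites within the gene; D_i is the mean
    over ingroup haplotypes of silent differences to the outgroup (in
    counts, coding columns weighted by their synonymous fraction);
    L_i is the gene's silent site count.
    """
    import numpy as np

    from .alignio import CODING, INTRONIC
    from .diversity import per_gene_summaries

    if aln.outgroup_id is None:
        raise ValueError("outgroup required for HKA divergence")
    summaries = per_gene_summaries(aln, classmap, annotations)
    m = aln.ingroup_matrix
    out_row = aln.outgroup_row
    ok = (out_row != "N") & (out_row != "-") & ~classmap.masked
    out = []
    for ann in annotations:
        span = np.zeros(classmap.L, dtype=bool)
        span[ann.start - aln.region_offset: ann.end - aln.region_offset + 1] = True
        coding = classmap.class_mask(CODING) & span & ok
        intronic = classmap.class_mask(INTRONIC) & span & ok
        w = np.zeros(classmap.L)
        w[intronic] = 1.0
        w[coding] = classmap.syn_weight[coding]
        diffs = (m != out_row[None, :]).astype(float) @ w
        L_i = float(w.sum())
        s = summaries[ann.gene_id]
        out.append(HkaLocusData(ann.gene_id, aln.n, L_i, s.S_silent,
                                float(diffs.mean())))
    return out


def read_hka_table(path) -> list[HkaLocusData]:
    df = pd.read_csv(path, sep="\t")
    return [HkaLocusData(str(r.locus), int(r.n), float(r.L), int(r.S), float(r.D))
            for r in df.itertuples()]


# ---------------------------------------------------------------------------
# Pairwise HKA
# ---------------------------------------------------------------------------

def _moment_fit(loci: list[HkaLocusData]):
    """theta_i and T from: sum S_i = sum theta_i L_i a_ni; D_i = theta_i L_i (T+1)."""
    sum_s = sum(l.S for l in loci)
    sum_da = sum(l.D * harmonic(l.n) for l in loci)
    if sum_s == 0 or sum_da == 0:
        raise ValueError("degenerate system: no polymorphism or no divergence")
    t_plus_1 = sum_da / sum_s
    thetas = [l.D / (l.L * t_plus_1) for l in loci]
    return thetas, t_plus_1 - 1.0


def _hka_x2(loci: list[HkaLocusData], thetas, T) -> float:
    x2 = 0.0
    for l, th in zip(loci, thetas):
        tl = th * l.L
        a_n, b_n = harmonic(l.n), harmonic2(l.n)
        exp_s = tl * a_n
        var_s = tl * a_n + tl**2 * b_n
        exp_d = tl * (T + 1.0)
        var_d = tl * (T + 1.0) + tl**2
        x2 += (l.S - exp_s) ** 2 / var_s + (l.D - exp_d) ** 2 / var_d
    return x2


@dataclass
class PairwiseHkaResult:
    x2: float
    p_value: float
    thetas: dict[str, float]
    T: float
    replicates: int
    seed: int | None


def pairwise_hka(locus_a: HkaLocusData, locus_b: HkaLocusData,
                 replicates: int = 10_000,
                 seed: int | None = None) -> PairwiseHkaResult:
    """Two-locus HKA test with significance by simulation under the
    fitted neutral model (S_i from the coalescent; D_i compounded over the
    exponential ancestral coalescence time)."""
    loci = [locus_a, locus_b]
    thetas, T = _moment_fit(loci)
    x2_obs = _hka_x2(loci, thetas, T)

    rng = np.random.default_rng(seed)
    sims = []
    for l, th in zip(loci, thetas):
        tl = th * l.L
        s_rep = coalescent.segregating_sites_distribution(
            l.n, tl, replicates, rng)
        t_anc = rng.exponential(1.0, size=replicates)
        d_rep = rng.poisson(tl * (T + t_anc))
        sims.append((s_rep, d_rep))

    exceed = 0
    usable = 0
    for r in range(replicates):
        rep = [HkaLocusData(l.locus, l.n, l.L, int(sims[i][0][r]),
                            float(sims[i][1][r]))
               for i, l in enumerate(loci)]
        try:
            th_r, t_r = _moment_fit(rep)
        except ValueError:
            continue
        usable += 1
        if _hka_x2(rep, th_r, t_r) >= x2_obs:
            exceed += 1
    p = coalescent.empirical_p(exceed, usable)
    return PairwiseHkaResult(x2_obs, p, {l.locus: th for l, th in zip(loci, thetas)},
                             T, replicates, seed)


# ---------------------------------------------------------------------------
# Maximum-likelihood HKA
# ---------------------------------------------------------------------------

@dataclass
class MlHkaResult:
    model: str                   # 'no-selection' | 'selection'
    loglik: float
    thetas: dict[str, float]
    T: float
    k: dict[str, float]          # focal-locus selection parameters (k = 1 elsewhere)
    converged: bool
    restart_spread: float


def _poisson_loglik(x: float, mu: float) -> float:
    return float(special.xlogy(x, mu) - mu - special.gammaln(x + 1.0))


def _profile_loglik(loci, a_n, T, ks) -> tuple[float, np.ndarray]:
    """Per-locus theta has a closed-form MLE given T and k; return the
    profiled log-likelihood and those theta-hats."""
    B = T + 1.0
    logl = 0.0
    thetas = np.empty(len(loci))
    for i, l in enumerate(loci):
        denom = ks[i] * l.L * a_n[i] + l.L * B
        total = l.S + l.D
        theta = total / denom if total > 0 else K_BOUNDS[0] / denom
        thetas[i] = theta
        logl += _poisson_loglik(l.S, ks[i] * theta * l.L * a_n[i])
        logl += _poisson_loglik(l.D, theta * l.L * B)
    return logl, thetas


def mlhka_fit(loci: list[HkaLocusData], focal_ids: list[str] | None = None,
              selection: bool = False, restarts: int = 3,
              seed: int | None = None, tol: float = 1e-4) -> MlHkaResult:
    """Fit the multilocus ML-HKA model, optionally freeing k at focal loci.

    Optimization is over (log T, log k_focal...) with L-BFGS-B from
    ``restarts`` deterministic seeded starting points; the restarts must
    agree in log-likelihood within ``tol`` or an error is raised.
    """
    if len(loci) < 2:
        raise ValueError("ML-HKA needs at least two loci")
    focal_ids = focal_ids or []
    if selection and not focal_ids:
        raise ValueError("selection model requires a non-empty focal set")
    focal_idx = [i for i, l in enumerate(loci) if l.locus in focal_ids]
    if selection and len(focal_idx) != len(focal_ids):
        missing = set(focal_ids) - {l.locus for l in loci}
        raise ValueError(f"focal loci not in data: {sorted(missing)}")
    a_n = np.array([harmonic(l.n) for l in loci])
    n_k = len(focal_idx) if selection else 0

    def negloglik(x):
        T = np.exp(x[0])
        ks = np.ones(len(loci))
        for j, i in enumerate(focal_idx[:n_k]):
            ks[i] = np.exp(x[1 + j])
        logl, _ = _profile_loglik(loci, a_n, T, ks)
        return -logl

    bounds = [(np.log(T_BOUNDS[0]), np.log(T_BOUNDS[1]))]
    bounds += [(np.log(K_BOUNDS[0]), np.log(K_BOUNDS[1]))] * n_k
    rng = np.random.default_rng(seed)
    best = None
    logliks = []
    # moment-style start for T plus randomized restarts
    try:
        _, t0 = _moment_fit(loci)
        t0 = min(max(t0, T_BOUNDS[0] * 2), T_BOUNDS[1] / 2)
    except ValueError:
        t0 = 1.0
    for r in range(restarts):
        x0 = np.empty(1 + n_k)
        if r == 0:
            x0[0] = np.log(t0)
            x0[1:] = 0.0
        else:
            x0[0] = np.log(t0) + rng.normal(0, 1.0)
            x0[1:] = rng.normal(0, 1.0, size=n_k)
        res = optimize.minimize(negloglik, x0, method="L-BFGS-B", bounds=bounds)
        logliks.append(-res.fun)
        if best is None or -res.fun > -best.fun:
            best = res
    spread = float(np.max(logliks) - np.min(logliks))
    if spread > max(tol, 1e-6 * abs(logliks[0])) * 100:
        raise RuntimeError(
            f"ML-HKA restarts disagree (log-likelihoods {logliks}); "
            "check data scale or increase restarts"
        )
    T = float(np.exp(best.x[0]))
    ks = np.ones(len(loci))
    for j, i in enumerate(focal_idx[:n_k]):
        ks[i] = float(np.exp(best.x[1 + j]))
    logl, thetas = _profile_loglik(loci, a_n, T, ks)
    return MlHkaResult(
        model="selection" if selection else "no-selection",
        loglik=float(logl),
        thetas={l.locus: float(t) for l, t in zip(loci, thetas)},
        T=T,
        k={loci[i].locus: float(ks[i]) for i in focal_idx} if selection else {},
        converged=bool(best.success),
        restart_spread=spread,
    )


@dataclass
class LrtResult:
    two_delta_l: float
    df: int
    p_value: float


def mlhka_lrt(fit_null: MlHkaResult, fit_alt: MlHkaResult,
              tol: float = 1e-6) -> LrtResult:
    """2*deltaL against chi-square with df = number of freed k parameters."""
    df = len(fit_alt.k) - len(fit_null.k)
    if df < 1:
        raise ValueError("models are not nested with freed k parameters")
    two_dl = 2.0 * (fit_alt.loglik - fit_null.loglik)
    if two_dl < -tol:
        raise RuntimeError(
            f"alternative log-likelihood below null ({two_dl/2:.6g}): "
            "optimization failure"
        )
    two_dl = max(two_dl, 0.0)
    return LrtResult(two_dl, df, lrt_p_value(two_dl, df))


def lrt_p_value(two_delta_l: float, df: int = 1) -> float:
    """Upper tail of chi-square(df) at the observed 2*deltaL."""
    if two_delta_l < 0:
        raise ValueError("2*deltaL must be >= 0")
    return float(stats.chi2.sf(two_delta_l, df))
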