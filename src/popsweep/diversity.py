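"""Nucleotide diversity by site class and sliding-window diversity tracks.

Diversity is Nei's per-site pi: the average proportion of pairwise
differences among ingroup haplotypes, uncorrected for multiple hits.
Class-specific estimators (pi_a, pi_s, pi_si) divide class-specific pairwise
difference counts by fractional Nei–Gojobori site counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignio import (
    CODING,
    INTRONIC,
    BASES,
    HaplotypeAlignment,
    SiteClassMap,
    polymorphism_classes,
)


def _per_column_mpd(aln: HaplotypeAlignment) -> np.ndarray:
    """Mean pairwise difference per column: 1 - sum_b c_b(c_b-1)/(n(n-1))."""
    m = aln.ingroup_matrix
    n = m.shape[0]
    if n < 2:
        raise ValueError("need >= 2 ingroup haplotypes")
    same = np.zeros(m.shape[1], dtype=np.int64)
    for b in BASES:
        c = np.sum(m == b, axis=0)
        same += c * (c - 1)
    return 1.0 - same / (n * (n - 1))


def pairwise_pi(aln: HaplotypeAlignment,
                columns: np.ndarray | None = None,
                site_count: float | None = None) -> float | None:
    """Per-site pi over the selected columns.

    ``columns`` is a boolean mask (default: columns without gap/N);
    ``site_count`` overrides the denominator with a fractional site count
    (used for synonymous / nonsynonymous / silent classes). Returns None when
    no usable sites remain (pi undefined, not 0).
    """
    if columns is None:
        columns = aln.good_columns()
    mpd = _per_column_mpd(aln)
    denom = float(np.sum(columns)) if site_count is None else float(site_count)
    if denom <= 0:
        return None
    return float(mpd[columns].sum() / denom)


def mean_pairwise_differences(aln: HaplotypeAlignment,
                              columns: np.ndarray | None = None) -> float:
    """Pi in counts (mean number of pairwise differences), not per site."""
    if columns is None:
        columns = aln.good_columns()
    return float(_per_column_mpd(aln)[columns].sum())


def watterson_theta(S: int, n: int, L: float) -> float:
    """Watterson's per-site theta_W = S / (a_n * L), a_n = sum_{i<n} 1/i."""
    if n < 2:
        raise ValueError("watterson_theta requires n >= 2")
    if L <= 0:
        raise ValueError("watterson_theta requires L > 0")
    a_n = np.sum(1.0 / np.arange(1, n))
    return float(S / (a_n * L))


@dataclass
class LocusSummary:
    """One table row of polymorphism summaries for a locus."""

    locus: str
    n: int
    n_sites: int
    P: int                 # polymorphic (segregating) sites
    A: int                 # amino-acid replacement polymorphisms
    Syn: int               # synonymous polymorphisms
    S_silent: int          # silent segregating sites
    pi: float | None
    pi_a: float | None
    pi_s: float | None
    pi_si: float | None

    def as_row(self, scale: float = 1e3) -> dict:
        """Table-shaped row with pi values scaled (x10^3 mirrors reports)."""
        f = lambda v: None if v is None else round(v * scale, 4)
        return {
            "locus": self.locus, "n": self.n, "NS": self.n_sites, "P": self.P,
            "A": self.A, "S": self.Syn,
            "pi": f(self.pi), "pi_a": f(self.pi_a),
            "pi_s": f(self.pi_s), "pi_si": f(self.pi_si),
        }


def locus_summary(aln: HaplotypeAlignment, classmap: SiteClassMap,
                  locus: str = "locus",
                  columns: np.ndarray | None = None,
                  _poly: pd.DataFrame | None = None) -> LocusSummary:
    """Compute the per-locus summary (counts and pi by site class).

    ``columns`` optionally restricts to a span (e.g. one gene) of a region
    classified as a whole; ``_poly`` lets callers reuse one
    polymorphism_classes pass across genes.
    """
    poly = polymorphism_classes(aln, classmap) if _poly is None else _poly
    span = np.ones(classmap.L, dtype=bool) if columns is None else columns
    unmasked = ~classmap.masked & span
    mpd = _per_column_mpd(aln)

    coding = classmap.class_mask(CODING) & span
    intronic = classmap.class_mask(INTRONIC) & span
    if len(poly):
        in_span = span[poly["column"].to_numpy()]
        poly = poly.loc[in_span]
    if len(poly):
        seg_cols = poly["column"].to_numpy()
        syn_cols = poly.loc[(poly["label"] == CODING) & (poly["synonymous"] == True),
                            "column"].to_numpy()
        rep_cols = poly.loc[(poly["label"] == CODING) & (poly["synonymous"] == False),
                            "column"].to_numpy()
        intron_seg = poly.loc[poly["label"] == INTRONIC, "column"].to_numpy()
    else:
        seg_cols = syn_cols = rep_cols = intron_seg = np.array([], dtype=int)

    syn_sites = float(classmap.syn_weight[coding].sum())
    nonsyn_sites = float(np.sum(1.0 - classmap.syn_weight[coding]))
    silent_sites = syn_sites + float(intronic.sum())

    def _pi(num_cols, denom):
        if denom <= 0:
            return None
        return float(mpd[num_cols].sum() / denom)

    return LocusSummary(
        locus=locus,
        n=aln.n,
        n_sites=int(unmasked.sum()),
        P=int(len(seg_cols)),
        A=int(len(rep_cols)),
        Syn=int(len(syn_cols)),
        S_silent=int(len(syn_cols) + len(intron_seg)),
        pi=_pi(np.nonzero(unmasked)[0], int(unmasked.sum())),
        pi_a=_pi(rep_cols, nonsyn_sites),
        pi_s=_pi(syn_cols, syn_sites),
        pi_si=_pi(np.concatenate([syn_cols, intron_seg]).astype(int), silent_sites),
    )


def per_gene_summaries(aln: HaplotypeAlignment, classmap: SiteClassMap,
                       annotations) -> dict[str, LocusSummary]:
    """Locus summaries for each annotated gene from one region-wide
    classification (columns outside the gene span are excluded)."""
    poly = polymorphism_classes(aln, classmap)
    out = {}
    for ann in annotations:
        span = np.zeros(classmap.L, dtype=bool)
        span[ann.start - aln.region_offset: ann.end - aln.region_offset + 1] = True
        out[ann.gene_id] = locus_summary(aln, classmap, ann.gene_id,
                                         columns=span, _poly=poly)
    return out


@dataclass
class WindowTrack:
    """Sliding-window diversity: (start, end) are 0-based half-open."""

    windows: pd.DataFrame  # columns: start, end, midpoint, pi
    window: int
    step: int

    def to_bed(self, path, chrom: str = "region") -> None:
        df = self.windows[["start", "end", "pi"]].copy()
        df.insert(0, "chrom", chrom)
        df.to_csv(path, sep="\t", header=False, index=False)


def sliding_window_pi(aln: HaplotypeAlignment, window: int = 150,
                      step: int = 25) -> WindowTrack:
    """Pi in 150-bp windows with 25-bp steps by default.

    Windows are placed on alignment coordinates (masked columns included in
    the tiling but excluded from numerator and denominator), so tracks stay
    positionally stable; window count = floor((L - window)/step) + 1.
    """
    L = aln.L
    if L < window:
        raise ValueError(f"region length {L} shorter than window {window}")
    good = aln.good_columns()
    mpd = _per_column_mpd(aln)
    mpd_good = np.where(good, mpd, 0.0)
    cum_mpd = np.concatenate([[0.0], np.cumsum(mpd_good)])
    cum_good = np.concatenate([[0], np.cumsum(good.astype(np.int64))])
    starts = np.arange(0, L - window + 1, step)
    rows = []
    for s in starts:
        e = s + window
        usable = cum_good[e] - cum_good[s]
        pi = (cum_mpd[e] - cum_mpd[s]) / usable if usable else np.nan
        rows.append((int(s), int(e), (s + e) / 2.0, pi))
    df = pd.DataFrame(rows, columns=["start", "end", "midpoint", "pi"])
    return WindowTrack(df, window, step)
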