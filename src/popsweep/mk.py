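"""McDonald-Kreitman tests and a counting-method dN/dS estimator.

The MK test contrasts replacement vs. synonymous counts among fixed
interspecific differences (Da, Ds) and within-species polymorphisms
(Pa, Ps) in a 2x2 Fisher exact test; an excess of replacement divergence
indicates repeated adaptive protein evolution, a deficit long-term
purifying selection. dN/dS uses Nei-Gojobori counting with fractional
site weights, mutational-pathway averaging for multi-hit codons, and a
Jukes-Cantor correction per class.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .alignio import (
    CODING,
    GENETIC_CODE,
    HaplotypeAlignment,
    SiteClassMap,
    _COMPLEMENT,
    synonymous_weights,
)


@dataclass
class MkTable:
    """Fixed (Da, Ds) and polymorphic (Pa, Ps) replacement/synonymous counts."""

    Da: float
    Ds: float
    Pa: float
    Ps: float

    def __post_init__(self) -> None:
        if min(self.Da, self.Ds, self.Pa, self.Ps) < 0:
            raise ValueError("MK counts must be non-negative")


@dataclass
class MkResult:
    table: MkTable
    p_value: float
    da_ds: float | None
    pa_ps: float | None
    degenerate: bool = False


def fisher_exact_two_sided(a: float, b: float, c: float, d: float) -> float:
    """Two-sided Fisher exact P by the sum-of-tables-no-more-probable rule.

    A zero margin makes the table degenerate: P = 1 by convention.
    Fractional counts (from pathway averaging) are rounded with a warning.
    """
    cells = [a, b, c, d]
    if any(x < 0 for x in cells):
        raise ValueError("negative cell count")
    rounded = [int(round(x)) for x in cells]
    if any(abs(x - r) > 1e-9 for x, r in zip(cells, rounded)):
        warnings.warn("fractional MK counts rounded for the exact test")
    a, b, c, d = rounded
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def mk_test(table: MkTable) -> MkResult:
    """Fisher exact test on the [fixed vs polymorphic] x [replacement vs
    synonymous] contingency table, with Da/Ds and Pa/Ps ratios."""
    if table.Da + table.Ds + table.Pa + table.Ps == 0:
        raise ValueError("all MK cells are zero")
    degenerate = (table.Da + table.Ds == 0) or (table.Pa + table.Ps == 0) or \
                 (table.Da + table.Pa == 0) or (table.Ds + table.Ps == 0)
    p = fisher_exact_two_sided(table.Da, table.Pa, table.Ds, table.Ps)
    return MkResult(
        table=table,
        p_value=p,
        da_ds=(table.Da / table.Ds) if table.Ds > 0 else None,
        pa_ps=(table.Pa / table.Ps) if table.Ps > 0 else None,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Nei-Gojobori dN/dS
# ---------------------------------------------------------------------------

@dataclass
class DnDsResult:
    dN: float
    dS: float
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float

    @property
    def ratio(self) -> float | None:
        """dN/dS; undefined when dS = 0."""
        if self.dS == 0:
            return None
        return self.dN / self.dS


def dn_ds_ratio(dn: float, ds: float) -> float | None:
    if ds == 0:
        return None
    return round(dn / ds, 4)


def _codon_path_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous differences between two codons, averaged
    over minimal mutational pathways; pathways through stop codons are
    excluded when an alternative exists."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    k = len(diff_pos)
    if k == 0:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        syn = nsy = 0
        valid = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if GENETIC_CODE[nxt] == "*" and nxt != c2:
                valid = False
                break
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                syn += 1
            else:
                nsy += 1
            cur = nxt
        if valid:
            paths.append((syn, nsy))
    if not paths:  # every pathway crosses a stop; fall back to all pathways
        for order in itertools.permutations(diff_pos):
            cur = c1
            syn = nsy = 0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                    syn += 1
                else:
                    nsy += 1
                cur = nxt
            paths.append((syn, nsy))
    syn = float(np.mean([p[0] for p in paths]))
    nsy = float(np.mean([p[1] for p in paths]))
    return syn, nsy


def _jukes_cantor(p: float) -> float:
    """d = -(3/4) ln(1 - 4p/3); saturates at p >= 3/4."""
    if p >= 0.75:
        raise ValueError(f"proportion {p:.4f} is saturated (>= 3/4)")
    return float(-0.75 * np.log(1.0 - 4.0 * p / 3.0))


def nei_gojobori_dnds(seq_a: str, seq_b: str) -> DnDsResult:
    """Counting dN/dS between two aligned in-frame coding sequences.

    Site counts are Nei-Gojobori fractional weights averaged over both
    sequences; differences use pathway averaging; the Jukes-Cantor
    correction is applied per class. Codons containing gap/N in either
    sequence are skipped.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned (equal length)")
    if len(seq_a) % 3:
        raise ValueError("sequence length must be a multiple of 3")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    syn_sites = nonsyn_sites = 0.0
    syn_d = nonsyn_d = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3], seq_b[i:i + 3]
        if any(x not in "ACGT" for x in ca + cb):
            continue
        if GENETIC_CODE[ca] == "*" or GENETIC_CODE[cb] == "*":
            continue
        wa = sum(synonymous_weights(ca))
        wb = sum(synonymous_weights(cb))
        syn_sites += (wa + wb) / 2.0
        nonsyn_sites += 3.0 - (wa + wb) / 2.0
        sd, nd = _codon_path_diffs(ca, cb)
        syn_d += sd
        nonsyn_d += nd
    if syn_sites == 0 or nonsyn_sites == 0:
        raise ValueError("no usable codons")
    ps = syn_d / syn_sites
    pn = nonsyn_d / nonsyn_sites
    return DnDsResult(
        dN=_jukes_cantor(pn), dS=_jukes_cantor(ps),
        syn_sites=syn_sites, nonsyn_sites=nonsyn_sites,
        syn_diffs=syn_d, nonsyn_diffs=nonsyn_d,
    )


def gene_dnds(aln: HaplotypeAlignment, classmap: SiteClassMap,
              annotation) -> DnDsResult:
    """dN/dS between the ingroup consensus and the outgroup for one gene,
    on the mRNA-sense coding sequence."""
    if aln.outgroup_id is None:
        raise ValueError("outgroup required for dN/dS")
    cols = annotation.coding_columns(aln.region_offset)
    cols = cols[: len(cols) - len(cols) % 3]
    cons = "".join(classmap.consensus[cols])
    out = "".join(aln.outgroup_row[cols])
    if annotation.strand == "-":
        cons = cons.translate(_COMPLEMENT)
        out = out.translate(_COMPLEMENT)
    return nei_gojobori_dnds(cons, out)


# ---------------------------------------------------------------------------
# MK table construction from an alignment
# ---------------------------------------------------------------------------

def polarized_substitution_counts(aln: HaplotypeAlignment,
                                  classmap: SiteClassMap) -> MkTable:
    """Build the MK table from coding codons of an ingroup alignment plus
    one outgroup haplotype.

    A site is fixed iff the ingroup is monomorphic and differs from the
    outgroup; polymorphic iff the ingroup segregates (a site both
    polymorphic and divergent counts as polymorphic only, the standard MK
    convention). Changes classify as replacement or synonymous in the codon
    context; codons carrying several changes average over minimal
    mutational pathways.
    """
    if aln.outgroup_id is None:
        raise ValueError("outgroup required for the MK table")
    m = aln.ingroup_matrix
    out_row = aln.outgroup_row
    Da = Ds = Pa = Ps = 0.0
    for cid, ((c0, c1, c2), strand) in classmap.codon_cols.items():
        cols = (c0, c1, c2)
        if classmap.masked[list(cols)].any():
            continue
        ing_codons = {"".join(row) for row in m[:, list(cols)]}
        out_codon = "".join(out_row[list(cols)])
        if strand == "-":
            ing_codons = {c.translate(_COMPLEMENT) for c in ing_codons}
            out_codon = out_codon.translate(_COMPLEMENT)
        if any(set(c) - set("ACGT") for c in ing_codons) or \
                set(out_codon) - set("ACGT"):
            continue
        # polymorphic positions: classify changes among observed ingroup codons
        poly_pos = {p for p in range(3)
                    if len({c[p] for c in ing_codons}) > 1}
        if poly_pos:
            # average the pathway classification over all pairs of observed
            # codons, then normalize so each polymorphic position counts once
            pairs = list(itertools.combinations(sorted(ing_codons), 2))
            per_pair = [_codon_path_diffs(ca, cb) for ca, cb in pairs]
            mean_s = float(np.mean([p[0] for p in per_pair]))
            mean_n = float(np.mean([p[1] for p in per_pair]))
            tot = mean_s + mean_n
            if tot > 0:
                Ps += len(poly_pos) * mean_s / tot
                Pa += len(poly_pos) * mean_n / tot
        # fixed positions: ingroup monomorphic, differs from outgroup,
        # and the position is not polymorphic
        consensus = next(iter(ing_codons)) if len(ing_codons) == 1 else None
        if consensus is None:
            # use per-position monomorphy even when other positions segregate
            bases = [{c[p] for c in ing_codons} for p in range(3)]
            consensus = "".join(sorted(b)[0] if len(b) == 1 else "?"
                                for b in bases)
        fixed_pos = [p for p in range(3)
                     if p not in poly_pos and consensus[p] != "?"
                     and consensus[p] != out_codon[p]]
        if fixed_pos:
            ing_ctx = consensus.replace("?", "N")
            if "N" in ing_ctx:
                # mixed codon: classify each fixed change one at a time in
                # the majority ingroup context
                base_codon = classmap.reference_codon(cid)
                for p in fixed_pos:
                    alt = base_codon[:p] + out_codon[p] + base_codon[p + 1:]
                    if GENETIC_CODE[alt] == GENETIC_CODE[base_codon]:
                        Ds += 1
                    else:
                        Da += 1
            else:
                sd, nd = _codon_path_diffs(
                    ing_ctx,
                    "".join(out_codon[p] if p in fixed_pos else ing_ctx[p]
                            for p in range(3)),
                )
                Ds += sd
                Da += nd
    return MkTable(Da=Da, Ds=Ds, Pa=Pa, Ps=Ps)
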