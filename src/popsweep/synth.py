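"""Synthetic region generator: fully specified inputs for the pipeline.

Emulates the study design the analysis assumes: a compact ~17-kb genomic
region holding seven genes, resequenced as phased haplotypes in three
population samples plus a single outgroup sequence, with silent-site
diversity in the low-percent range, outgroup silent divergence around
0.1 per site, strong purifying constraint on replacement sites, and an
optional hard selective sweep centered on one focal gene.

The sweep is emulated at the haplotype level: a template haplotype is the
sweeping lineage; every other haplotype copies the template's alleles over
a tract around the sweep position whose one-sided extents are exponential
with rate alpha per bp, so a site at distance d escapes the sweep with
probability 1 - exp(-alpha*d) per lineage, matching the escape-probability
model the CLR scan fits. This collapses diversity at the focal gene,
skews the SFS toward rare and high-frequency-derived variants, and leaves
the flanking-LD-block signature the omega statistic targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .alignio import (
    BASES,
    GENETIC_CODE,
    GeneAnnotation,
    HaplotypeAlignment,
    PopulationMap,
    classify_sites,
    write_annotation,
    write_fasta_alignment,
    write_population_map,
)
from .coalescent import SimConfig, simulate_neutral

_NONSTOP = sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")

OUTGROUP_ID = "outgroup"


@dataclass
class GeneSpec:
    gene_id: str
    cds_exons: list[int]          # exon CDS lengths, genome order
    intron_length: int = 60
    strand: str = "+"
    theta_site: float | None = None  # silent per-site theta; None = global

    @property
    def cds_total(self) -> int:
        return sum(self.cds_exons)

    @property
    def span(self) -> int:
        return self.cds_total + self.intron_length * (len(self.cds_exons) - 1)


@dataclass
class SweepSpec:
    present: bool = True
    position: int | None = None   # bp (1-based); None = focal gene midpoint
    alpha: float = 7e-5           # per-bp escape rate
    focal_gene: str = "geneD"


def default_genes() -> list[GeneSpec]:
    """Seven compact genes; the fourth (focal) has the longest CDS."""
    return [
        GeneSpec("geneA", [930, 930]),
        GeneSpec("geneB", [635, 635, 635], strand="-"),
        GeneSpec("geneC", [480, 480]),
        GeneSpec("geneD", [510, 510, 510, 510, 510, 510, 504]),
        GeneSpec("geneE", [816, 816, 816]),
        GeneSpec("geneF", [510]),
        GeneSpec("geneG", [843, 843, 843, 843]),
    ]


@dataclass
class RegionSpec:
    """Parameters of one synthetic region sample."""

    length: int = 16_950
    genes: list[GeneSpec] = field(default_factory=default_genes)
    theta_site: float = 0.01        # silent per-site theta = 4*N*mu
    rho: float = 50.0               # region-wide population recombination rate
    T: float = 11.0                 # outgroup divergence, 2N units
    nonsyn_constraint: float = 0.85  # fraction of replacement mutations removed
    sweep: SweepSpec = field(default_factory=SweepSpec)
    populations: dict[str, int] = field(
        default_factory=lambda: {"pop1": 48, "pop2": 46, "pop3": 38})
    seed: int | None = None

    @property
    def n_total(self) -> int:
        return sum(self.populations.values())

    def validate(self) -> None:
        if any(g.cds_total % 3 for g in self.genes):
            raise ValueError("every gene's CDS length must be divisible by 3")
        if sum(g.span for g in self.genes) >= self.length:
            raise ValueError("gene layout does not fit in the region")
        if self.sweep.present and self.sweep.focal_gene not in {
            g.gene_id for g in self.genes
        }:
            raise ValueError(f"unknown focal gene {self.sweep.focal_gene!r}")
        for r in (self.theta_site, self.rho, self.T, self.nonsyn_constraint):
            if r < 0:
                raise ValueError("rates must be >= 0")


# ---------------------------------------------------------------------------
# Region layout and ancestral sequence
# ---------------------------------------------------------------------------

def _layout(spec: RegionSpec) -> list[GeneAnnotation]:
    """Place genes left to right with equal intergenic gaps."""
    genic = sum(g.span for g in spec.genes)
    n_gaps = len(spec.genes) + 1
    gap = (spec.length - genic) // n_gaps
    annotations = []
    cursor = gap + 1  # 1-based
    for g in spec.genes:
        cds = []
        pos = cursor
        for ex in g.cds_exons:
            cds.append([pos, pos + ex - 1, 0])
            pos += ex + g.intron_length
        # GFF3 phase: bases to skip at the 5' end of each exon, strand-aware
        reading = cds if g.strand == "+" else cds[::-1]
        cum = 0
        for exon in reading:
            exon[2] = (3 - cum % 3) % 3
            cum += exon[1] - exon[0] + 1
        annotations.append(
            GeneAnnotation(g.gene_id, g.strand, [tuple(e) for e in cds])
        )
        cursor += g.span + gap
    if annotations[-1].end > spec.length:
        raise ValueError("infeasible layout: genes overflow the region")
    return annotations


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def generate_region(spec: RegionSpec,
                    rng: np.random.Generator | None = None
                    ) -> tuple[list[GeneAnnotation], str]:
    """Ancestral sequence plus annotations; every CDS is a valid ORF
    (ATG start, no internal stop). Deterministic under the spec seed."""
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    annotations = _layout(spec)
    seq = list(rng.choice(list("ACGT"), size=spec.length))
    for gene in annotations:
        cols = gene.coding_columns(region_offset=1)
        n_codons = len(cols) // 3
        codons = ["ATG"] + [
            _NONSTOP[i] for i in rng.integers(0, len(_NONSTOP), size=n_codons - 1)
        ]
        mrna = "".join(codons)
        for i, col in enumerate(cols):
            base = mrna[i]
            seq[col] = base if gene.strand == "+" else _COMP[base]
    return annotations, "".join(seq)


# ---------------------------------------------------------------------------
# Sample simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedRegion:
    alignment: HaplotypeAlignment
    annotations: list[GeneAnnotation]
    population_map: PopulationMap
    truth: dict

    def write(self, outdir) -> dict:
        import os
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "fasta": os.path.join(outdir, "region.fasta"),
            "gff": os.path.join(outdir, "region.gff3"),
            "populations": os.path.join(outdir, "populations.tsv"),
            "truth": os.path.join(outdir, "truth.json"),
        }
        write_fasta_alignment(self.alignment, paths["fasta"])
        write_annotation(self.annotations, paths["gff"])
        write_population_map(self.population_map, paths["populations"])
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=2, default=float)
        return paths


def _mutation_is_stop(codon: str, pos: int, new_base: str) -> bool:
    mut = codon[:pos] + new_base + codon[pos + 1:]
    return GENETIC_CODE[mut] == "*"


def simulate_region_sample(spec: RegionSpec) -> SimulatedRegion:
    """Simulate phased haplotypes for three populations plus an outgroup.

    Neutral genealogies come from the coalescent with recombination; each
    mutation maps onto the ancestral sequence respecting site classes
    (replacement changes thinned by the constraint factor, nonsense changes
    suppressed); an optional sweep is applied by template-tract copying;
    the outgroup accumulates divergence theta*(T+1) per silent site.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    annotations, ancestral = generate_region(spec, rng)
    anc = np.array(list(ancestral), dtype="<U1")

    anc_aln = HaplotypeAlignment(["ancestral"], anc[None, :])
    classmap = classify_sites(anc_aln, annotations)

    # per-column silent theta (gene-specific values override the global one)
    theta_col = np.full(spec.length, spec.theta_site)
    for g, ann in zip(spec.genes, annotations):
        if g.theta_site is not None:
            theta_col[ann.start - 1: ann.end] = g.theta_site
    theta_max = float(theta_col.max())

    n = spec.n_total
    config = SimConfig(n=n, theta=theta_max * spec.length, rho=spec.rho,
                       L=float(spec.length), replicates=1,
                       seed=int(rng.integers(2**31 - 1)))
    rep = simulate_neutral(config)[0]

    # map mutations to columns; thin by site class; draw derived bases
    cols, derived_bases, carrier_cols = [], [], []
    used = set()
    order = rng.permutation(rep.S)
    for k in order:
        col = int(rep.positions[k])
        if col >= spec.length or col in used:
            continue
        anc_base = anc[col]
        retain_p = theta_col[col] / theta_max
        new_base = str(rng.choice([b for b in BASES if b != anc_base]))
        if classmap.labels[col] == "coding":
            cid = classmap.codon_id[col]
            (c0, c1, c2), strand = classmap.codon_cols[cid]
            pos_in_codon = [c0, c1, c2].index(col)
            codon = classmap.reference_codon(cid)
            b = _COMP[new_base] if strand == "-" else new_base
            mut = codon[:pos_in_codon] + b + codon[pos_in_codon + 1:]
            if GENETIC_CODE[mut] == "*":
                continue  # nonsense changes are removed outright
            if GENETIC_CODE[mut] != GENETIC_CODE[codon]:
                retain_p *= 1.0 - spec.nonsyn_constraint
        if rng.uniform() >= retain_p:
            continue
        used.add(col)
        cols.append(col)
        derived_bases.append(new_base)
        carrier_cols.append(rep.matrix[:, k].copy())

    order2 = np.argsort(cols)
    cols = [cols[i] for i in order2]
    derived_bases = [derived_bases[i] for i in order2]
    carriers = np.column_stack([carrier_cols[i] for i in order2]) \
        if cols else np.zeros((n, 0), dtype=np.uint8)

    # sweep: template-tract copying around the sweep position
    sweep_truth: dict = {"present": bool(spec.sweep.present)}
    if spec.sweep.present:
        focal = next(a for a in annotations
                     if a.gene_id == spec.sweep.focal_gene)
        sp = spec.sweep.position or (focal.start + focal.end) // 2
        alpha = spec.sweep.alpha
        template = int(rng.integers(n))
        ext_left = rng.exponential(1.0 / alpha, size=n)
        ext_right = rng.exponential(1.0 / alpha, size=n)
        pos_arr = np.asarray(cols, dtype=float) + 1.0  # 1-based bp
        for i in range(n):
            if i == template:
                continue
            inside = (pos_arr > sp - ext_left[i]) & (pos_arr < sp + ext_right[i])
            carriers[i, inside] = carriers[template, inside]
        sweep_truth.update(position=sp, alpha=alpha, template=template,
                           focal_gene=spec.sweep.focal_gene)

    # haplotype sequences
    sample_ids = []
    for pop, size in spec.populations.items():
        sample_ids += [f"{pop}_h{j:03d}" for j in range(size)]
    matrix = np.tile(anc, (n, 1))
    for j, col in enumerate(cols):
        has = carriers[:, j].astype(bool)
        matrix[has, col] = derived_bases[j]

    # outgroup: independent divergence from the ancestral sequence
    out_seq = anc.copy()
    div_p = theta_col * (spec.T + 1.0)
    u = rng.uniform(size=spec.length)
    n_out = 0
    for col in np.nonzero(u < div_p)[0]:
        anc_base = anc[col]
        new_base = str(rng.choice([b for b in BASES if b != anc_base]))
        if classmap.labels[col] == "coding":
            cid = classmap.codon_id[col]
            (c0, c1, c2), strand = classmap.codon_cols[cid]
            pos_in_codon = [c0, c1, c2].index(col)
            codon = classmap.reference_codon(cid)
            b = _COMP[new_base] if strand == "-" else new_base
            mut = codon[:pos_in_codon] + b + codon[pos_in_codon + 1:]
            if GENETIC_CODE[mut] == "*":
                continue
            if GENETIC_CODE[mut] != GENETIC_CODE[codon]:
                if rng.uniform() < spec.nonsyn_constraint:
                    continue
        out_seq[col] = new_base
        n_out += 1

    full_ids = sample_ids + [OUTGROUP_ID]
    full_matrix = np.vstack([matrix, out_seq[None, :]])
    aln = HaplotypeAlignment(full_ids, full_matrix, region_offset=1,
                             outgroup_id=OUTGROUP_ID)
    pmap = PopulationMap({s: p for p, size in spec.populations.items()
                          for s in sample_ids if s.startswith(p + "_")})
    truth = {
        "seed": spec.seed,
        "length": spec.length,
        "theta_site": spec.theta_site,
        "rho": spec.rho,
        "T": spec.T,
        "nonsyn_constraint": spec.nonsyn_constraint,
        "populations": spec.populations,
        "sweep": sweep_truth,
        "n_mutations": len(cols),
        "n_outgroup_changes": n_out,
        "genes": {a.gene_id: [a.start, a.end] for a in annotations},
    }
    return SimulatedRegion(aln, annotations, pmap, truth)


# ---------------------------------------------------------------------------
# Planted MK tables
# ---------------------------------------------------------------------------

def plant_mk_table(Da: int, Ds: int, Pa: int, Ps: int,
                   gene_length: int = 3564, n_haplotypes: int = 8,
                   seed: int | None = None
                   ) -> tuple[HaplotypeAlignment, GeneAnnotation]:
    """Construct a coding alignment + outgroup realizing exactly the given
    MK counts (round-trip fixture: polarized_substitution_counts recovers
    them). One codon per planted event; remaining codons are invariant.
    """
    if gene_length % 3:
        raise ValueError("gene_length must be a multiple of 3")
    n_codons = gene_length // 3
    events = Da + Ds + Pa + Ps
    if events > n_codons - 1:
        raise ValueError(
            f"counts ({events}) exceed available codons ({n_codons - 1})"
        )
    if min(Da, Ds, Pa, Ps) < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    ing = ["CTT"] * n_codons
    out = ["CTT"] * n_codons
    ing[0] = out[0] = "ATG"
    half = max(1, n_haplotypes // 2)
    per_hap: list[list[str]] = [list(ing) for _ in range(n_haplotypes)]
    slots = list(rng.permutation(np.arange(1, n_codons))[:events])
    it = iter(slots)
    for _ in range(Ds):         # fixed synonymous: GGT (all) vs GGC
        c = next(it)
        for h in per_hap:
            h[c] = "GGT"
        out[c] = "GGC"
    for _ in range(Da):         # fixed replacement: AAA (Lys) vs GAA (Glu)
        c = next(it)
        for h in per_hap:
            h[c] = "AAA"
        out[c] = "GAA"
    for _ in range(Ps):         # synonymous polymorphism, outgroup matches
        c = next(it)
        for i, h in enumerate(per_hap):
            h[c] = "GGT" if i < half else "GGC"
        out[c] = "GGT"
    for _ in range(Pa):         # replacement polymorphism, outgroup matches
        c = next(it)
        for i, h in enumerate(per_hap):
            h[c] = "AAA" if i < half else "GAA"
        out[c] = "AAA"
    ids = [f"hap{i:02d}" for i in range(n_haplotypes)] + [OUTGROUP_ID]
    rows = ["".join(h) for h in per_hap] + ["".join(out)]
    matrix = np.array([list(r) for r in rows], dtype="<U1")
    aln = HaplotypeAlignment(ids, matrix, outgroup_id=OUTGROUP_ID)
    gene = GeneAnnotation("planted", "+", [(1, gene_length, 0)])
    return aln, gene
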