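"""Alignment, annotation and population-map input with site classification.

The analyses downstream all operate on a single resequenced genomic region:
an aligned set of phased haplotypes (optionally including one outgroup
sequence) together with gene annotations that let every alignment column be
assigned to a mutually exclusive site class (coding / intronic / intergenic)
and, for coding columns, a fractional synonymous site weight following the
Nei–Gojobori counting scheme.

Coordinates are 1-based inclusive in files and reports and half-open 0-based
internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

VALID_BASES = frozenset("ACGTN-")
BASES = "ACGT"

GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")

_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised for malformed input files."""


# ---------------------------------------------------------------------------
# Haplotype alignment
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeAlignment:
    """n_samples x L nucleotide matrix of phased haplotypes.

    The optional outgroup row is excluded from every ingroup statistic;
    ``region_offset`` is the 1-based genomic coordinate of column 0.
    """

    sample_ids: list[str]
    matrix: np.ndarray  # dtype '<U1', shape (n_samples, L)
    region_offset: int = 1
    outgroup_id: str | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        if self.matrix.ndim != 2:
            raise FormatError("alignment matrix must be 2-dimensional")
        if len(self.sample_ids) != self.matrix.shape[0]:
            raise FormatError("sample_ids / matrix row mismatch")
        if self.outgroup_id is not None and self.outgroup_id not in self.sample_ids:
            raise FormatError(f"outgroup id {self.outgroup_id!r} not among records")

    @property
    def L(self) -> int:
        return self.matrix.shape[1]

    @property
    def ingroup_ids(self) -> list[str]:
        return [s for s in self.sample_ids if s != self.outgroup_id]

    @property
    def n(self) -> int:
        """Number of ingroup haplotypes."""
        return len(self.ingroup_ids)

    @property
    def ingroup_matrix(self) -> np.ndarray:
        rows = [i for i, s in enumerate(self.sample_ids) if s != self.outgroup_id]
        return self.matrix[rows]

    @property
    def outgroup_row(self) -> np.ndarray | None:
        if self.outgroup_id is None:
            return None
        return self.matrix[self.sample_ids.index(self.outgroup_id)]

    def good_columns(self) -> np.ndarray:
        """Boolean mask of columns without gap/N in any ingroup row."""
        m = self.ingroup_matrix
        return ~np.any((m == "-") | (m == "N"), axis=0)

    def subset(self, sample_ids: list[str], keep_outgroup: bool = True) -> "HaplotypeAlignment":
        """Restrict to the given ingroup samples (outgroup retained by default)."""
        keep = list(sample_ids)
        if keep_outgroup and self.outgroup_id is not None and self.outgroup_id not in keep:
            keep.append(self.outgroup_id)
        idx = [self.sample_ids.index(s) for s in keep]
        return HaplotypeAlignment(keep, self.matrix[idx], self.region_offset,
                                  self.outgroup_id if keep_outgroup else None)


def read_fasta_alignment(path, outgroup_id: str | None = None) -> HaplotypeAlignment:
    """Read an aligned multi-FASTA of phased haplotypes.

    IUPAC ambiguity codes other than ACGTN are rejected: heterozygous
    genotype calls must be phased upstream before analysis.
    """
    ids: list[str] = []
    rows: list[str] = []
    with open(path) as handle:
        records = list(SeqIO.parse(handle, "fasta"))
    for rec in records:
        if rec.id in ids:
            raise FormatError(f"duplicate record id {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = [c for c in set(seq) if c not in VALID_BASES]
        if bad:
            col = next(i for i, c in enumerate(seq) if c in bad)
            raise FormatError(
                f"record {rec.id!r} contains ambiguity code {seq[col]!r} at column "
                f"{col + 1}; phase heterozygous sites before analysis"
            )
        ids.append(rec.id)
        rows.append(seq)
    if not ids:
        raise FormatError(f"no FASTA records in {path}")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise FormatError(f"unequal sequence lengths {sorted(lengths)} in {path}")
    matrix = np.array([list(r) for r in rows], dtype="<U1")
    return HaplotypeAlignment(ids, matrix, outgroup_id=outgroup_id)


def write_fasta_alignment(aln: HaplotypeAlignment, path) -> None:
    with open(path, "w") as fh:
        for i, sid in enumerate(aln.sample_ids):
            fh.write(f">{sid}\n")
            fh.write("".join(aln.matrix[i]) + "\n")


# ---------------------------------------------------------------------------
# Gene annotation (GFF3 subset)
# ---------------------------------------------------------------------------

@dataclass
class GeneAnnotation:
    """One gene: ordered CDS intervals (1-based inclusive) with frame."""

    gene_id: str
    strand: str  # '+' or '-'
    cds: list[tuple[int, int, int]]  # (start, end, frame), 1-based inclusive
    introns: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"{self.gene_id}: strand must be + or -")
        self.cds = sorted(self.cds)
        for (s1, e1), (s2, e2) in zip(
            [(s, e) for s, e, _ in self.cds], [(s, e) for s, e, _ in self.cds[1:]]
        ):
            if s2 <= e1:
                raise FormatError(f"{self.gene_id}: overlapping CDS intervals")
        total = self.total_cds_length()
        if total % 3 != 0:
            raise FormatError(
                f"{self.gene_id}: CDS length {total} after frame adjustment "
                "not divisible by 3"
            )
        if not self.introns:
            self.introns = self._infer_introns()

    def total_cds_length(self) -> int:
        """CDS length after trimming the leading frame of the first-read exon."""
        frame = self._first_frame()
        return sum(e - s + 1 for s, e, _ in self.cds) - frame

    def _first_frame(self) -> int:
        # frame of the exon read first on this strand
        return self.cds[0][2] if self.strand == "+" else self.cds[-1][2]

    def _infer_introns(self) -> list[tuple[int, int]]:
        out = []
        for (s1, e1, _), (s2, e2, _) in zip(self.cds, self.cds[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out

    @property
    def start(self) -> int:
        return self.cds[0][0]

    @property
    def end(self) -> int:
        return self.cds[-1][1]

    def coding_columns(self, region_offset: int = 1) -> np.ndarray:
        """0-based alignment columns of the CDS, in reading order.

        The leading ``frame`` bases of the first-read exon are dropped so the
        result starts at codon position 0 and has length divisible by 3.
        """
        cols: list[int] = []
        for s, e, _ in self.cds:
            cols.extend(range(s - region_offset, e - region_offset + 1))
        if self.strand == "-":
            cols = cols[::-1]
        frame = self._first_frame()
        return np.asarray(cols[frame:], dtype=np.int64)


def read_annotation(path) -> list[GeneAnnotation]:
    """Read a GFF3 subset (gene + CDS with phase); introns are inferred
    as intra-gene gaps between CDS intervals. Returns genes sorted by start.
    """
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"malformed GFF3 line: {line!r}")
            _, _, ftype, start, end, _, strand, phase, attrs = parts
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = attr.get("ID", attr.get("Name"))
                if gid is None:
                    raise FormatError(f"gene feature without ID: {line!r}")
                genes.setdefault(gid, {"strand": strand, "cds": []})
                if gid not in order:
                    order.append(gid)
            elif ftype == "CDS":
                gid = attr.get("Parent", attr.get("ID"))
                if gid is None:
                    raise FormatError(f"CDS feature without Parent: {line!r}")
                rec = genes.setdefault(gid, {"strand": strand, "cds": []})
                if gid not in order:
                    order.append(gid)
                frame = 0 if phase in (".", "") else int(phase)
                rec["cds"].append((int(start), int(end), frame))
    out = []
    for gid in order:
        rec = genes[gid]
        if not rec["cds"]:
            continue
        out.append(GeneAnnotation(gid, rec["strand"], rec["cds"]))
    out.sort(key=lambda g: g.start)
    return out


def write_annotation(genes: list[GeneAnnotation], path, seqid: str = "region") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{seqid}\tpopsweep\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for s, e, frame in g.cds:
                fh.write(
                    f"{seqid}\tpopsweep\tCDS\t{s}\t{e}\t.\t{g.strand}\t{frame}\t"
                    f"Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# Population map
# ---------------------------------------------------------------------------

POOLED = "pooled"


@dataclass
class PopulationMap:
    """sample_id -> population label, plus the pooled virtual grouping."""

    assignments: dict[str, str]

    @property
    def populations(self) -> list[str]:
        seen: list[str] = []
        for p in self.assignments.values():
            if p not in seen:
                seen.append(p)
        return seen

    def samples(self, population: str) -> list[str]:
        if population == POOLED:
            return list(self.assignments)
        return [s for s, p in self.assignments.items() if p == population]

    def groupings(self) -> dict[str, list[str]]:
        """Each population separately plus all strains pooled."""
        out = {p: self.samples(p) for p in self.populations}
        out[POOLED] = list(self.assignments)
        return out

    def validate_against(self, aln: HaplotypeAlignment) -> None:
        missing = [s for s in aln.ingroup_ids if s not in self.assignments]
        if missing:
            raise FormatError(f"samples without population assignment: {missing}")


def read_population_map(path) -> PopulationMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "population"]:
        raise FormatError(
            "population map must have header 'sample_id<TAB>population'"
        )
    if df["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in population map")
    return PopulationMap(dict(zip(df["sample_id"], df["population"])))


def write_population_map(pmap: PopulationMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tpopulation\n")
        for s, p in pmap.assignments.items():
            fh.write(f"{s}\t{p}\n")


# ---------------------------------------------------------------------------
# Site classification
# ---------------------------------------------------------------------------

def _compute_synonymous_weights(codon: str) -> tuple[float, float, float]:
    aa = GENETIC_CODE[codon]
    out = []
    for pos in range(3):
        syn = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if GENETIC_CODE[mut] == aa:
                syn += 1
        out.append(syn / 3.0)
    return tuple(out)


_SYN_WEIGHTS = {c: _compute_synonymous_weights(c) for c in GENETIC_CODE}


def synonymous_weights(codon: str) -> tuple[float, float, float]:
    """Fraction of the 3 possible single-base changes at each codon position
    that are synonymous (Nei–Gojobori site counting)."""
    return _SYN_WEIGHTS[codon]


CODING, INTRONIC, INTERGENIC = "coding", "intronic", "intergenic"


@dataclass
class SiteClassMap:
    """Per-column site classes, masks and fractional synonymous weights.

    ``codon_id[col] >= 0`` groups coding columns into codons; ``codon_cols``
    gives, per codon, its three alignment columns in reading order (so a
    minus-strand codon lists decreasing columns) and its strand.
    """

    labels: np.ndarray          # '<U10' per column
    syn_weight: np.ndarray      # float per column (0 outside coding)
    masked: np.ndarray          # bool per column (gap/N or stop-codon columns)
    codon_id: np.ndarray        # int per column, -1 outside coding
    codon_cols: dict[int, tuple[tuple[int, int, int], str]]
    consensus: np.ndarray       # majority ingroup base per column

    @property
    def L(self) -> int:
        return self.labels.size

    def class_mask(self, label: str, unmasked_only: bool = True) -> np.ndarray:
        m = self.labels == label
        if unmasked_only:
            m &= ~self.masked
        return m

    # aggregate site counts (unmasked columns only)
    @property
    def n_sites(self) -> int:
        """Sites analyzed, excluding gap/N and stop-masked columns."""
        return int(np.sum(~self.masked))

    @property
    def synonymous_sites(self) -> float:
        return float(self.syn_weight[self.class_mask(CODING)].sum())

    @property
    def nonsynonymous_sites(self) -> float:
        m = self.class_mask(CODING)
        return float(np.sum(1.0 - self.syn_weight[m]))

    @property
    def intronic_sites(self) -> int:
        return int(self.class_mask(INTRONIC).sum())

    @property
    def silent_sites(self) -> float:
        """Silent = synonymous + intronic."""
        return self.synonymous_sites + self.intronic_sites

    def reference_codon(self, cid: int) -> str:
        (c0, c1, c2), strand = self.codon_cols[cid]
        codon = self.consensus[c0] + self.consensus[c1] + self.consensus[c2]
        if strand == "-":
            codon = codon.translate(_COMPLEMENT)
        return codon


def majority_consensus(aln: HaplotypeAlignment) -> np.ndarray:
    """Majority ingroup allele per column; ties broken alphabetically;
    gap/N ignored unless a column is all gap/N."""
    m = aln.ingroup_matrix
    L = aln.L
    out = np.empty(L, dtype="<U1")
    counts = np.zeros((4, L), dtype=np.int64)
    for bi, b in enumerate(BASES):
        counts[bi] = np.sum(m == b, axis=0)
    best = np.argmax(counts, axis=0)  # argmax takes first max -> alphabetical tie-break
    out[:] = np.array(list(BASES))[best]
    out[counts.sum(axis=0) == 0] = "N"
    return out


def classify_sites(aln: HaplotypeAlignment,
                   annotations: list[GeneAnnotation]) -> SiteClassMap:
    """Assign every column a site class and a Nei–Gojobori synonymous weight.

    The reference codon is read from the majority ingroup consensus. Codons
    spanning gap/N-masked columns are wholly masked; a codon translating to
    an internal stop raises a warning and is masked.
    """
    L = aln.L
    labels = np.full(L, INTERGENIC, dtype="<U10")
    syn_w = np.zeros(L, dtype=float)
    masked = ~aln.good_columns()
    codon_id = np.full(L, -1, dtype=np.int64)
    codon_cols: dict[int, tuple[tuple[int, int, int], str]] = {}
    consensus = majority_consensus(aln)

    for gene in annotations:
        if gene.start < aln.region_offset or gene.end > aln.region_offset + L - 1:
            raise FormatError(f"{gene.gene_id}: annotation outside alignment bounds")
        for s, e in gene.introns:
            labels[s - aln.region_offset: e - aln.region_offset + 1] = INTRONIC
        for s, e, _ in gene.cds:
            labels[s - aln.region_offset: e - aln.region_offset + 1] = CODING
        cols = gene.coding_columns(aln.region_offset)
        # CDS columns outside complete codons (frame-trimmed lead, tail
        # remainder) lack degeneracy context and stay masked
        in_codon = np.zeros(L, dtype=bool)
        in_codon[cols[: len(cols) - len(cols) % 3]] = True
        for s, e, _ in gene.cds:
            sl = slice(s - aln.region_offset, e - aln.region_offset + 1)
            masked[sl] |= ~in_codon[sl]
        next_cid = max(codon_cols) + 1 if codon_cols else 0
        for k in range(0, len(cols) - len(cols) % 3, 3):
            c = cols[k:k + 3]
            cid = next_cid
            next_cid += 1
            codon_id[c] = cid
            codon_cols[cid] = ((int(c[0]), int(c[1]), int(c[2])), gene.strand)
            if masked[c].any():
                masked[c] = True  # whole codon masked
                continue
            # c is in reading order; on the minus strand genome bases must be
            # complemented (order already reversed by coding_columns)
            codon = "".join(consensus[c])
            if "N" in codon:
                masked[c] = True
                continue
            if gene.strand == "-":
                codon = codon.translate(_COMPLEMENT)
            if GENETIC_CODE[codon] == "*":
                warnings.warn(
                    f"internal stop codon in reference frame at columns {c.tolist()}; "
                    "codon masked"
                )
                masked[c] = True
                continue
            w = synonymous_weights(codon)
            for pos in range(3):
                syn_w[c[pos]] = w[pos]
    return SiteClassMap(labels, syn_w, masked, codon_id, codon_cols, consensus)


def polymorphism_classes(aln: HaplotypeAlignment,
                         classmap: SiteClassMap) -> pd.DataFrame:
    """Per segregating (unmasked) column: its site class and, for coding
    columns, whether the observed change is synonymous.

    A coding polymorphism is synonymous iff every observed allele yields the
    same amino acid in the consensus codon context; columns where some pairs
    differ in amino acid and some do not are labelled mixed (counted as
    nonsynonymous for the replacement tally, matching the conservative
    convention).
    """
    m = aln.ingroup_matrix
    rows = []
    for col in np.nonzero(~classmap.masked)[0]:
        alleles = sorted(set(m[:, col]))
        if len(alleles) < 2:
            continue
        label = classmap.labels[col]
        syn = None
        if label == CODING:
            cid = classmap.codon_id[col]
            (c0, c1, c2), strand = classmap.codon_cols[cid]
            pos = [c0, c1, c2].index(col)
            base_codon = list(classmap.reference_codon(cid))
            aas = set()
            for a in alleles:
                b = a.translate(_COMPLEMENT) if strand == "-" else a
                cod = base_codon.copy()
                cod[pos] = b
                aas.add(GENETIC_CODE["".join(cod)])
            syn = len(aas) == 1
        rows.append({"column": int(col), "label": label, "synonymous": syn,
                     "n_alleles": len(alleles)})
    return pd.DataFrame(rows, columns=["column", "label", "synonymous", "n_alleles"])
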