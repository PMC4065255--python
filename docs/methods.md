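# Methods

This note records the models implemented in `popsweep`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions that were genuinely open.

## Data model and site classification

All analyses operate on one aligned region: an n × L matrix of phased
haplotypes, optionally with one outgroup row, plus gene annotations (GFF3
subset: gene and CDS with phase). Coordinates are 1-based inclusive in files
and half-open 0-based internally. Columns carrying a gap or N in any ingroup
row are excluded from site counts ("sites analyzed" excludes gap positions),
and a codon spanning any masked column is masked whole — fractional codons
have no well-defined degeneracy. IUPAC ambiguity codes are rejected at
input: the estimators assume resolved haplotypes, so heterozygous genotype
calls must be phased upstream.

Every column gets exactly one class: coding, intronic, or intergenic. Coding
columns carry a fractional synonymous weight by Nei–Gojobori counting — the
share of the three possible single-base changes that leave the amino acid
unchanged — read off the majority ingroup consensus codon (ties broken
alphabetically; consensus classification is reproducible, unlike picking an
arbitrary reference haplotype). Silent sites are synonymous plus intronic.
A consensus codon translating to a stop is masked with a warning. Segregating
coding columns are classified synonymous when every observed allele yields
the same amino acid in the consensus codon context; codons observed with
multiple segregating or divergent positions are resolved by averaging over
minimal mutational pathways. DnaSP-style tools may treat doubly polymorphic
codons slightly differently; discrepancies are at most a site or two per
locus.

## Diversity

π is Nei's per-site mean pairwise difference, uncorrected for multiple hits
(the estimator class standard desktop tools report). Class-specific π
divides class-specific difference counts by fractional site counts. Zero
usable sites yields an explicit null, never 0. Sliding windows (150 bp,
25-bp step; floor((L − window)/step) + 1 windows, 673 for the default
16,950-bp region) are laid on alignment coordinates with masked columns
dropping out of numerator and denominator both, keeping tracks positionally
stable.

## Coalescent engine

All nulls come from a self-contained neutral coalescent in ms scaling (time
in 2N generations, θ = 4Nμ per locus), so E[S] = θa_n and E[π̂] = θ hold
directly and are verified as moment checks. Three modes:

* θ mode, no recombination: Kingman trees, Poisson mutations on branches.
* fixed-S: exactly S mutations placed multinomially by branch length. This
  is the conservative null for Tajima's D and Fay–Wu H (no intragenic
  recombination inflates the variance of both statistics).
* θ mode with recombination: a Hudson-style ancestral recombination graph
  over a continuous sequence, with ancestral-material tracking and removal
  of fully coalesced segments. Used for LD-based nulls and the synthetic
  region generator. The engine agrees with msprime on the distribution of S
  (KS test in the suite).

Empirical P-values use (r+1)/(reps+1) so no P is exactly zero. A note on
fixed-S conditioning: because mutations are placed on the *realized* tree,
the conditional expectation of the normalized Fay–Wu H is slightly positive
(≈ +0.098 at n=20, S=30, reproduced independently by placing fixed numbers
of mutations on msprime trees). The normalization targets the unconditional
neutral model; the offset is a property of the conditioning, not a defect,
and is within the ±0.1 band the calibration checks.

## SFS tests

The unfolded spectrum is polarized per site: the outgroup base must match
exactly one ingroup allele, otherwise (missing, gapped, or third-allele
outgroup) the site enters the folded spectrum only — a mixed per-site
folded/unfolded scheme. Sites with more than two ingroup alleles are
excluded from SFS statistics (infinite-sites assumption) though still
reported in polymorphic-site counts.

Tajima's D follows the standard constants (a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂);
π̂ enters in counts over the same sites as S. D is undefined at S = 0 and in
the degenerate zero-variance cases (n = 2; n = 3 with S = 1). The normalized
H uses θ_π, θ_L = Σ i·ξ_i/(n−1), θ_W, and θ̂² = S(S−1)/(a_n²+b_n) with the
variance expression involving b_{n+1} = Σ_{i≤n} 1/i². Default significance
settings: 50,000 fixed-S replicates for D and 10,000 for H, two-tailed
(double the smaller one-sided tail, capped at 1).

Because H is sensitive to ancestral-state misidentification, the package
reports a misorientation probability from per-site silent divergence d to
the outgroup: p_mis = (d/3)/(1 − 2d/3), the probability under a
Jukes–Cantor-style argument that the outgroup base at a polymorphic site has
itself mutated so as to coincide with the derived allele. This is a
first-principles approximation (saturating divergence is an error), intended
as an order-of-magnitude guard, not a calibrated estimator.

An empirical-rank utility places a focal statistic within a background gene
set (rank, tie count, midrank percentile) — the standard argument that a
genome-wide demographic process cannot explain an extreme single-locus value.

## HKA

The pairwise test fits per-locus θ and a shared divergence time T by
moments (ΣS_i = Σθ̂_iL_ia_{n_i}; D_i = θ̂_iL_i(T̂+1)) and forms the usual X²
with Var(S_i) = θ̂L a_n + (θ̂L)²b_n and Var(D_i) = θ̂L(T̂+1) + (θ̂L)².
Significance is by parametric bootstrap under the fitted null: S_i from the
coalescent, D_i ~ Poisson(θ̂L(T̂+t)) with t ~ Exp(1) (reproducing the
divergence variance), estimators refitted per replicate.

The ML variant writes the likelihood as independent Poissons for S_i and
D_i, with a selection parameter k multiplying the focal locus's polymorphism
mean. θ_i profiles out in closed form given (T, k), leaving a 1–2 parameter
bounded search (log scale; k ∈ [10⁻⁴, 10²], T ∈ [10⁻³, 10³]) run from three
seeded starts that must agree — a deterministic replacement for MCMC with
identical model content, justified because only the MLEs and the
likelihood-ratio test are consumed. 2ΔL is referred to χ²(1) per freed k.
Sample-size corrections to the divergence expectation are omitted (the
standard Poisson-HKA simplification); calibration under the null is checked
by simulation (rejection at the χ² 5% point within [0.02, 0.08]).

## Sweep scans

**CLR.** The background spectrum is estimated from all scanned SNPs
(including the focal region — the composite approach), unpolarized SNPs
contributing half to each complementary class; fixed derived sites are
excluded by default (flag available). The sweep model at escape probability
p_e: B ~ Binomial(n, p_e) lineages escape; the background is downsampled
hypergeometrically from n to B+1; one of the B+1 is the swept ancestor whose
allele is replicated n−B times; the result is renormalized over polymorphic
classes. B = n leaves the background untouched. Spectra are precomputed on a
64-point log grid of α·d (the transform depends on p_e only), making the
125-grid × 40-α scan a table lookup; the α grid spans effectively complete
hitchhiking to effectively neutral at the region half-width and includes the
exactly neutral member (p_e = 1), so CLR ≥ 0 by nesting. Folded SNPs sum the
two complementary class probabilities. Distances are in bp with the
recombination-rate scale absorbed into α.

**ω.** r² comes from haplotype frequencies (equivalently the squared
Pearson correlation of allele indicators, so allele relabeling is
irrelevant). At a candidate position, window extents between minwin
(1000 bp) and maxwin (2000 bp) on each side define candidate left/right SNP
sets (each needing ≥2 SNPs); ω = mean within-flank r² / mean cross-flank
r², maximized over extents, evaluated with 2-D prefix sums over the r²
matrix. Zero cross-flank r² reports +inf; ties resolve to the smallest
windows; grid points without sufficient flanking SNPs record NaN rather than
failing. Both scans use 125 evenly spaced grid points spanning the SNP range
(the SweepFinder-style grid convention) and take 1% cutoffs from neutral
simulation — with recombination for ω, whose null depends on LD.

## MK and dN/dS

The MK table classifies each coding site as fixed (ingroup monomorphic,
different from outgroup) or polymorphic (site both polymorphic and divergent
counts as polymorphic only, the standard convention), replacement vs.
synonymous from codon context with pathway averaging for multi-hit codons;
fixed differences are unpolarized (interspecific) by default. The two-sided
Fisher exact P sums hypergeometric probabilities of tables no more probable
than the observed one (scipy's rule; verified in the suite against exact
rational enumeration of the full support). dN/dS uses Nei–Gojobori counting:
sites averaged over both sequences, differences pathway-averaged excluding
stop-crossing paths when avoidable, Jukes–Cantor correction per class with a
saturation error at p ≥ 3/4. A counting estimator was chosen over ML codon
models to keep the pipeline self-contained and deterministic; for the
divergence levels the package targets (dS ≈ 0.1) the two agree closely (the
suite cross-checks against Biopython's NG86).

## Synthetic regions

The generator emulates the study design end to end: 16,950 bp, seven genes
(CDS/intron layouts echoing a compact gene-dense region, one on the minus
strand; ~8% intergenic), ancestral sequence with valid ORFs, three
population samples (48 + 46 + 38 haplotypes by default) drawn from one
panmictic coalescent with recombination (ρ = 50 for the region), and a
single outgroup. Defaults: silent per-site θ = 0.01 (silent diversity
~1%, inside the 0.2–2% range such data show), outgroup divergence time
T = 11 so silent divergence ≈ θ(T+1) = 0.12 per site, and 85% of
replacement mutations removed by purifying constraint (nonsense changes
removed outright), giving π_a ≪ π_s.

The sweep is emulated at the haplotype level: one template haplotype is the
sweeping lineage, and every other haplotype copies the template's alleles
over a tract around the sweep position with one-sided exponential extents of
rate α per bp — so each lineage escapes at distance d with probability
1 − e^{−αd}, exactly the escape model the CLR fits, while also creating the
flanking-LD-block pattern ω targets. The default α = 7×10⁻⁵/bp was set so
the focal gene's silent diversity drops ≥5-fold against the outermost genes
(median over replicates), the magnitude of valley the analysis is designed
to detect; the neutral control stays within a factor of two of flat.

What the generator does *not* emulate: real demographic history (growth,
structure, migration — the analysis assumes demographic equilibrium, and so
does the generator), gene conversion, mutation-rate heterogeneity beyond the
per-gene θ knob, sequencing or phasing error, and alignment gaps. Passing
tests therefore show the estimators and scans are correct and calibrated
under the stated model, not that real data meet that model.

## Problem sizes and defaults in the suite

Unit tests run reduced samples (28 haplotypes) of the same region; the
calibration and recovery experiments use n = 20, S = 30 with 10,000 fixed-S
replicates for D/H calibration, 50 replicates for CLR localization (200
SNPs over 17 kb, α* = 5×10⁻⁴), 300 + 200 neutral replicates for CLR cutoff
calibration, and 50 strong-sweep regions (single 30-chromosome sample)
against a 200-replicate ω null — sizes chosen so the whole suite completes
in a few minutes while leaving Monte-Carlo error well inside the asserted
margins. Pipeline defaults keep the field-standard replicate counts (50,000
for D; 10,000 for H and cutoffs).

## Known limitations

* The misorientation probability is an approximation; it is reported, not
  used to correct H.
* Pairwise HKA simulates divergence as exponentially compounded Poisson
  rather than running two-species coalescents; the variance matches the
  classical formula but higher moments differ slightly.
* ML-HKA's Poisson likelihood ignores the coalescent overdispersion of S
  (Var = θLa_n + (θL)²b_n), making the LRT mildly anticonservative at very
  high per-locus θL; calibration at the package's default data scale is
  verified in the suite.
* π on multi-allelic silent columns in the pipeline's D computation counts
  only the two most frequent alleles.
* The ω implementation maximizes over contiguous window extents, not
  arbitrary SNP subsets (the standard definition).
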