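# Methods

This note records the models, conventions and numerical choices behind
`kmlst`, and what the synthetic-data calibrations do and do not establish.

## Typing model

A strain is typed at five housekeeping loci. Each locus's sequenced
fragment is compared as a literal string over the IUPAC nucleotide
alphabet; every unique string is a genotype, numbered from 1. Two
consequences follow from the diploid biology:

- **Heterozygotes are variants.** A position with two coincident peaks on
  both strands is recorded as the ambiguity code of the two bases, and a
  sequence differing only as A vs R is a distinct genotype. Phasing the two
  haplotypes is impossible from Sanger traces of a diploid, so no attempt
  is made; the ambiguity-coded sequence *is* the typed object.
- **No alignment.** The typed fragments carry no indels, so allele calling
  is exact string matching and length mismatches are rejected rather than
  aligned.

Genotype 1 of a catalog is the *reference*: the majority consensus over
the typed population (most common nucleotide per site, weighted by strain
multiplicity). Majority ties break alphabetically (A < C < G < T); the
tie rule is a package convention, chosen once for determinism. Novel
alleles are numbered append-only in discovery order, so replaying the same
input order reproduces the same numbering; discovery order over the
packaged table reproduces its published DST numbering 1..66 exactly.

Strand merging takes the per-position intersection of the two reads' base
sets; an empty intersection becomes N and is reported as a conflict, never
silently resolved toward one strand. Merges with more than 5 % conflicting
positions (configurable) are rejected as failed sequencing.

## Scheme geometry

Fragment coordinates are 1-based inclusive within the gene CDS;
`frame_offset = (fragment_start − 1) mod 3` places fragment positions into
codons for the synonymous/non-synonymous classification. In the published
locus table the parenthetical end coordinate consistently equals
start + fragment size, i.e. it is end-exclusive; the packaged scheme
stores the inclusive end (start + size − 1) so that
`size = end − start + 1` holds.

Two packaged rows (GSY2 and SGA1) report a fragment size equal to
amplicon − one primer length rather than amplicon − both primers; the
packaged values are kept as printed and the validator emits a warning for
these rows. For user-supplied scheme files the same inconsistency is an
error by default (`on_conflict="error"`), since there is no printed
authority to defer to. Primer matching during trimming is exact by default
(primers target non-variable regions by design) with an optional
mismatch budget.

Site classification expands any ambiguity codes in the codon into all
compatible concrete codons: a site is synonymous only if *every* expansion
translates identically, and a replacement is "substantive" if any two
encoded residues fall in different side-chain categories
(nonpolar-aliphatic, polar-aliphatic, aromatic, basic, acidic). Codons
truncated at a fragment edge are classified as indeterminate, not errors.

## Index of association

For strains a, b let K_ab be the number of loci at which their genotypes
differ. With V_D the variance of {K_ab} over all n(n−1)/2 pairs and
V_e = Σ_j h_j(1−h_j) its expectation under linkage equilibrium
(h_j = unbiased heterozygosity n/(n−1)(1 − Σ p²)),

    I_A = V_D/V_e − 1,      I_A^S = I_A / (l − 1).

Zero is expected under free recombination; clonal structure inflates V_D.
V_D divides by the pair count (population variance) by default;
`variance="sample"` divides by pairs − 1. The sample-variance convention
reproduces the published per-subpopulation values for this dataset at
printed precision (0.208 and 0.269), so that flag is the one to use when
comparing against legacy outputs; the two differ only in O(1/pairs).
Degenerate designs make V_e vanish — all loci monomorphic, or every strain
unique at every locus (unbiased h = 1) — and are rejected as undefined
rather than returned as infinities.

Significance comes from shuffling each locus's genotype column
independently (preserving allele frequencies, destroying between-locus
association), with the positively biased estimator
p = (#{V_D,perm ≥ V_D} + 1)/(B + 1).

## PHI test

Parsimony-informative sites (≥2 states each carried by ≥2 sequences) are
extracted from the alignment; heterozygous IUPAC calls are treated as
missing at that site — a diploid ambiguity is not a third allele, and
counting it as one would manufacture homoplasy. For two sites, the refined
incompatibility is E − V + C of the bipartite graph whose vertices are the
observed states at each site and whose edges are the observed joint states
(over sequences resolved at both sites); it is 0 exactly when the pair is
compatible with a single tree and equals the four-gamete test on binary
sites. The statistic is the mean score over informative pairs closer than
w = 100 alignment positions (original coordinates).

The null permutes the informative sites over their positions. The test is
one-sided with p = (#{phi_perm ≤ phi_obs} + 1)/(B + 1): recombination
makes nearby sites *more* compatible than distant ones, lowering the
observed mean below the permuted ones. Ties count toward the null, making
the test mildly conservative. Only the permutation p-value is
implemented; no normal approximation is provided.

## dN/dS

Nei–Gojobori counting: per-codon synonymous site fractions from the
standard genetic code (changes to stop codons disregarded), pairwise
substitution counts averaged over all orderings of the differing
positions, excluding pathways that pass through a stop codon (all
pathways are kept if every one is blocked). dN = Nd/N and dS = Sd/S are
proportion distances by default; a Jukes–Cantor correction is optional.
Codons containing ambiguity codes are skipped by default or expanded and
averaged under `ambiguity_policy="expand"`. The standard error of dN/dS
is the standard deviation over codon-bootstrap replicates (replicates with
dS = 0 are dropped). dS = dN = 0 reports an undefined ratio; dS = 0 < dN
reports infinity.

## Trees

UPGMA uses size-weighted average linkage; neighbor joining the standard
Q-criterion with closed-form terminal branch lengths and negative lengths
clamped to zero with a warning. All tie-breaks are lowest-index-first, so
outputs are run-to-run deterministic. Bootstrap resamples alignment
columns with replacement (or whole loci via `locus_spans`) and labels each
internal bipartition of the original tree with its replicate percentage.
Maximum-likelihood tree inference is deliberately out of scope: distance
trees are a transparent substitute, and alignments/trees are exported so
external ML tools can be applied.

## Split decomposition

The isolation index of a bipartition {A, B} is

    α = ½ · min_{i,j∈A; k,l∈B} [ max{d(ik)+d(jl), d(il)+d(jk), d(ij)+d(kl)} − d(ij) − d(kl) ]

with repeats allowed. The d-splits (α > ε, ε = 1e−9 as a floating-point
guard) are computed incrementally by inserting taxa one at a time and
extending/filtering candidates — valid because every d-split restricts to
a d-split of any taxon subset. An exhaustive-bipartition implementation is
kept as the testing oracle (n ≤ 12). On a tree metric the output is
exactly the tree's edges with branch-length weights and the fit (percent
of total pairwise distance represented by the split metric) is 100;
conflicting splits (boxes) signal recombinant structure. Networks are
exported as NEXUS SPLITS blocks; drawing is delegated to external viewers.

## Synthetic data

The population generator emulates the study system: diploid strains at
five loci with the study's fragment lengths (763/791/862/871/906), allele
counts (26–37 per locus) and polymorphic-site counts, heterozygosity as
the probability (default 0.3 — heterozygosity was "quite common" in the
study population) that a strain carries two distinct alleles at a locus,
and no indels. `clonal` populations copy a few founder genotype vectors
(maximal linkage), `panmictic` ones draw every locus independently
(linkage equilibrium); `mixture` interpolates. Reads are emitted on both
strands with the IUPAC code at heterozygous sites, optionally with primer
flanks so the trimmer is exercised.

Alignment-level generators serve the recombination tests: clonal
alignments evolve sequences down a random coalescent-style tree with
recurrent mutation (homoplasy without spatial pattern — the PHI null holds
exactly), and recombinant alignments splice two divergent haplotypes at a
midpoint breakpoint in half the sequences (four gametes across the
breakpoint, two within blocks).

What the calibrations show: PHI type-I error within the binomial 95 %
interval of 0.05 over 200 clonal simulations, power ≥ 80 % on two-block
recombinants, I_A permutation p uniform under its null, and exact
end-to-end recovery of the simulated DST partition from mutation-free
reads. What they do not show: performance on real chromatograms (no peak
calling or base-call error model beyond optional uniform miscalls), on
populations with indels, or on recombination histories more complex than
the two-block construction.

## Reference data notes

The packaged profile table stores the published table as printed. Its
TFC1 column contains 36 distinct genotype numbers (genotype 2 never
appears) although the locus-level table reports 37; the discrepancy is in
the source material and TFC1 is therefore excluded from the
distinct-count checks. The combined-population I_A^S of these profiles is
≈ 0.25 (52 cheese strains or all 83, either variance convention); the
per-subpopulation values 0.208/0.269 are reproduced exactly under the
sample-variance convention.

## Problem sizes

The default test and acceptance runs use 200 simulations × 199
permutations for the PHI and I_A calibrations, 100 power simulations,
trees of 4–12 taxa for exact-recovery checks, exhaustive split
enumeration up to n = 9, and 3 × 20-strain end-to-end pipelines — sizes at
which every check is exact or tightly calibrated while the whole suite
runs in seconds.
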