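# kmlst

A multilocus sequence typing (MLST) toolkit for the dairy yeast
*Kluyveromyces marxianus*.

*K. marxianus* strains — many of them diploid — are typed by Sanger
sequencing five housekeeping loci (*IPP1*, *TFC1*, *GPH1*, *GSY2*, *SGA1*),
calling a genotype (allele) number for each unique fragment sequence, and
summarising the five numbers as a **diploid sequence type (DST)**.
Heterozygous positions appear as coincident double peaks on both sequencing
strands and are recorded with IUPAC ambiguity codes (R = A/G, ...), so a
heterozygote is a sequence variant in its own right: any single-nucleotide
difference, including A vs R, defines a new genotype. The package covers the
whole workflow and the population-genetic analyses built on it:

- **scheme** — locus definitions (primers, amplicon/fragment geometry,
  reading-frame offsets), primer trimming, FASTA/TSV I/O. The packaged
  `kmarxianus` scheme ships the five loci with their published bookkeeping
  (196 variable sites, 133 synonymous / 63 non-synonymous changes).
- **typing** — forward/reverse strand-read merging into IUPAC consensus
  sequences, allele catalogs (genotype 1 = majority-consensus reference),
  exact-match allele calling with append-only novel-allele numbering, and
  synonymous/non-synonymous site classification.
- **profiles** — DST assignment in discovery order and profile-table
  summaries; the published 83-strain / 66-DST table is packaged as the
  reference database.
- **trees** — allelic-profile mismatch and p-distances, UPGMA and
  neighbor-joining trees with deterministic tie-breaking, column (or
  whole-locus) bootstrap supports, Newick and PHYLIP I/O.
- **popgen** — the standardized index of association
  `I_A^S = (V_D/V_e − 1)/(l − 1)` with a within-locus permutation null,
  the PHI (pairwise homoplasy) recombination test, and Nei–Gojobori dN/dS
  with pathway averaging and codon bootstrap.
- **splits** — Bandelt–Dress split decomposition of a distance matrix into
  weighted weakly compatible splits (isolation indices), with a
  SplitsTree-compatible NEXUS writer.
- **simulate** — seeded synthetic diploid populations (clonal, panmictic or
  mixed), strand-read emission with heterozygous IUPAC codes, and
  clonal/recombinant alignment generators for calibrating the tests.

## Worked example

Summarise the packaged strain database:

```
$ kmlst profile summarize
n_strains       83
n_dsts  66
n_singleton_strains     58
n_multi_dsts    8
max_dst_size    7
genotypes_per_locus     {'IPP1': 28, 'TFC1': 36, 'GPH1': 30, 'GSY2': 34, 'SGA1': 26}
```

83 strains fall into 66 DSTs; 58 strains are the sole representative of
their DST and 8 DSTs hold 2–7 strains each — the high resolution that makes
five-locus MLST useful for strain identification.

Assign a DST to a known profile (the species type strain):

```
$ kmlst profile assign --genotypes 1,1,11,1,4
DST 10
```

Measure multilocus linkage disequilibrium over the 52 strains isolated from
the two Italian cheeses (Parmigiano Reggiano + Pecorino di Farindola):

```
$ kmlst popgen ia --source "Parmigiano Reggiano" \
                  --source "Pecorino di Farindola" --perms 999 --seed 1
n       52
l       5
h       (0.7111613876319758, 0.7518853695324282, 0.8092006033182504, 0.8288084464555053, 0.8597285067873303)
mean_k  3.9607843137254903
v_d     1.6289297015940616
v_e     0.8088400228405553
i_a     1.0139083818743826
i_sa    0.25347709546859565
p_value 0.001
n_permutations  999
seed    1
```

`v_d` is the variance of the pairwise locus-mismatch counts over all
52·51/2 strain pairs and `v_e` its expectation under linkage equilibrium
(Σ h_j(1−h_j) from the per-locus unbiased heterozygosities `h`). The
observed variance is twice the equilibrium expectation (`i_a` ≈ 1.01,
`i_sa` ≈ 0.25, permutation p ≈ 0.001): strong multilocus structure, i.e.
the combined population is far from freely recombining. Running the two
cheese subpopulations separately (`--variance sample`) gives
`i_sa` = 0.208 (Parmigiano Reggiano, n=39) and 0.269 (Pecorino di
Farindola, n=13) — much weaker association, consistent with recombination
*within* each subpopulation.

Typing new strains from sequence reads end to end:

```sh
kmlst simulate --mode mixture --rate 0.4 --n 10 --seed 7 --out sim/ --with-primers
kmlst type call --fasta sim/reads_fwd.fasta --trim --out typed/
```

writes a typing report TSV, per-locus allele catalogs and Newick trees
(neighbor joining on concatenated p-distances over the queries, UPGMA over
allelic profiles of queries plus the 83 database strains).

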