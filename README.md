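# clonalmlst

Multilocus sequence analysis for clonally diversifying bacterial
endosymbionts (*Wolbachia*, *Cardinium*, and similar maternally inherited
symbionts of arthropods): MLST allele/ST typing, per-locus diversity
statistics, eBURST-style clonal complexes, classification of within-complex
variant alleles into point mutation versus recombinational import, and a
MaxChi scan for intragenic mosaic structure.

## The problem

Endosymbionts spread clonally through host populations, but their genomes
also exchange DNA by homologous recombination. The relative frequency of
the two processes — how often a new allele arises by recombinational import
versus by de novo point mutation — shapes how strain diversity should be
interpreted. `clonalmlst` implements the classical multilocus counting
approach to that question:

1. **Typing.** Each unique sequence at a locus gets an allele identifier;
   each unique tuple of allele identifiers across *L* loci is a sequence
   type (ST).
2. **Clonal complexes.** STs whose profiles differ at exactly one locus
   (single-locus variants, SLVs) are linked; connected groups of ≥2 STs in
   which every member shares *L*−1 alleles with at least one other member
   form clonal complexes, each with a founder genotype (most SLV links,
   ties by frequency).
3. **Attribution.** Each member allele deviating from the founder's allele
   is compared with it base by base. One unique change → point mutation;
   one change that recurs elsewhere at the locus, or many changes (≥3 by
   default), → recombination; two changes are ambiguous. Counting these
   events gives the recombination:mutation (r:m) ratio under a strict rule
   (imports : unique singles, ambiguous classes dropped) and an inclusive
   rule (non-unique singles and elsewhere-seen doubles count as
   recombination, the rest as mutation).
4. **Diversity and mosaics.** Per-locus variable sites, nucleotide
   diversity π (mean pairwise p-distance, pairwise deletion), maximum
   p-distance, Nei–Gojobori dN/dS with Jukes–Cantor correction; and a
   MaxChi permutation scan that locates intragenic recombination
   breakpoints in parent/parent/child triplets.

The package ships a published 22-ST clonal-complex reference table (five
complexes, 44 isolates, loci *wsp*, *ftsZ*, *groEL*, *trmD*) as its
built-in acceptance dataset, a deterministic synthetic sequence realization
of it, and a forward simulator of clonal diversification with a truth log,
so the whole pipeline is testable without downloading anything.

## Worked example

Write the reference dataset (including one background isolate that carries
the sharing evidence for the ambiguous two-change variant) and run the full
pipeline:

```sh
clonalmlst fixture --out fixture_data --include-background
clonalmlst run --loci fixture_data/wsp.fasta --loci fixture_data/ftsZ.fasta \
    --loci fixture_data/groEL.fasta --loci fixture_data/trmD.fasta \
    --locus-order wsp,ftsZ,groEL,trmD --out results
```

which prints

```
45 isolates, 23 STs, 5 complexes (44 isolates); 17 variants, r:m strict 11:1, inclusive 15:2
summary: results/summary.txt
```

Read: of 45 isolates (44 reference + 1 background), 44 fall into five
clonal complexes. Within those complexes 17 alleles deviate from their
founder's allele: 1 unique single change (point mutation), 3 non-unique
single changes, 2 two-change alleles, and 11 multi-change recombinational
imports. Under the strict counting rule new alleles arose 11 times by
recombination for every mutation; under the inclusive rule 15:2 = 7.5 —
i.e. recombination outpaces mutation by roughly an order of magnitude
during clonal diversification. `results/summary.txt` also reports the
per-locus variant counts (*trmD* 10, *wsp* 3, *groEL* 3, *ftsZ* 1) and the
chi-square test of their uniformity (χ² = 11.0, df 3, p ≈ 0.012): variant
alleles concentrate at *trmD*.

The same numbers come straight from the annotation table without
sequences:

```sh
clonalmlst attribute --fixture --out attr
# 17 variant alleles (unique_single=1, nonunique_single=3, double=2, import=11); r:m strict 11:1, inclusive 15:2
# locus bias chi2=11.0 (df=3, p=0.0117)
```

Other subcommands: `type`, `diversity`, `complexes`, `scan` (MaxChi
triplet scan), `simulate` (forward simulator with truth log), and `run2`
(two-locus mode, e.g. 16S rDNA + *gyrB*, with a low-resolution caveat in
the report).

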