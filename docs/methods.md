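# Methods

## Typing

Allele calling is exact string identity on normalized sequences
(uppercase, U→T). Gaps are ordinary characters, so alleles differing only
by an indel are distinct — within-gene indels occur in surface genes such
as *wsp* and carry typing information. IUPAC ambiguity codes are accepted
and flagged but never wildcard-matched: a sequence with an ambiguity code
joins an existing allele only on exact equality. Allele identifiers and ST
numbers are assigned consecutively from 1 in input order; they are
reproducible for a fixed input but are labels only (published allele
numbering schemes will not coincide). Isolates missing any locus are
excluded from ST assignment — and reported — but remain available to the
per-locus diversity statistics; deliberate exclusions (e.g. a known highly
divergent lineage) are a configuration list, not an automatic outlier
rule.

## Diversity statistics

A site is variable when ≥2 distinct determinate bases occur in its column
(gaps and N ignored). π is the mean, over all unordered sequence pairs, of
the pairwise p-distance; the maximum of the same set is reported as a
percentage. All pairwise comparisons use **pairwise deletion**: a column
is dropped for a pair only when either member carries a gap or N there,
keeping per-pair denominators maximal. π is computed over all isolate
sequences, not one per allele, so common genotypes weigh more — the
convention matches per-strain survey tables.

dN/dS uses the Nei–Gojobori (1986) counting method. Potential synonymous
sites per codon position are the fraction of the three single-base changes
preserving the amino acid (denominator 3, changes to stop codons counted
as nonsynonymous); e.g. TTT has s = 1/3. For codon pairs differing at
several positions, all orderings of the changes are weighted equally,
including paths through stop intermediates — the simplest published
convention, and the one an enumeration oracle can reproduce path by path.
Codons containing a gap, N, ambiguity code, or a stop in either member of
a pair are skipped (stops with a warning). pS = Sd/S and pN = Nd/N are
averaged over pairs and Jukes–Cantor corrected
(d = −(3/4)·ln(1 − 4p/3)) before forming the ratio; dS = 0 yields an
undefined (not infinite) ratio, and a proportion ≥ 3/4 — possible only on
degenerate, few-codon inputs — saturates to an infinite distance rather
than raising.

## Clonal complexes

The SLV graph links STs whose allele tuples have Hamming distance exactly
1. Clonal complexes are connected components with ≥2 STs: the stringent
grouping in which every member shares L−1 of L alleles with at least one
other member (no relaxed L−2 grouping). Complexes are labelled with Roman
numerals in decreasing order of isolate count (ties: more STs, then lowest
member ST); labels are deterministic and are not meant to match any
published labelling — tests map complexes by membership. The founder is
the member with the most SLV links inside the complex, ties broken by
isolate frequency and then lowest ST id, with the ranking logged. No
bootstrap founder support is computed. A complex that is a complete SLV
graph with equal frequencies (every member differs from every other at the
same single locus) has no information to rank founders beyond the id
tie-break; the shipped reference table therefore carries an explicit
founder designation column, which takes precedence when present.

## Variant attribution and the r:m ratio

Within each complex, every (locus, allele) deviating from the founder's
allele is one variant — counted once per complex even when several member
STs carry it, and counted again if the same allele deviates in a different
complex (the event happened independently in each clonal background).
Nucleotide differences are counted column-wise with gap-containing columns
excluded.

Classification: 1 difference whose derived state recurs in another allele
at that locus → `nonunique_single`; 1 unique difference →
`unique_single`; 2 differences → `double`; ≥3 differences → `import`. The
threshold 3 generalizes the empirical gap observed in the reference data
(imports there differ at ≥4 sites) while keeping "multiple changes minus
the explicitly ambiguous 2-change class"; it is configurable
(`--import-threshold`). "Recurs elsewhere" for a single change means the
same column carries the same derived base in any other allele at the
locus; for a double it means the identical allele occurs in an isolate
outside the complex.

The strict r:m ratio is imports : unique singles, dropping non-unique
singles and doubles entirely. The inclusive ratio moves non-unique singles
and elsewhere-seen doubles to recombination and the remaining doubles to
mutation. A zero mutation denominator flags the ratio infinite rather than
failing. The per-locus variant counts are tested against a uniform
expectation with a df = L−1 goodness-of-fit chi-square, no continuity
correction, as is standard for a 4-cell table. The p-value is reported but
deliberately not pinned in the acceptance checks: on the reference counts
(10, 3, 3, 1) this statistic is exactly 11.0 (p ≈ 0.012), while the
originally reported p = 0.003 evidently came from a differently specified
test that was not documented; the statistic, not the p, is the anchored
quantity.

## MaxChi breakpoint scan

For a (parent A, parent B, child) triplet, informative sites are columns
where the parents carry distinct determinate bases and the child matches
exactly one of them. For every cut with at least `min_sites_per_side`
(default 3) informative sites on each side, the 2×2 chi-square of
(matches A / matches B) × (left / right) is computed; the maximizing cut —
leftmost on ties — is the candidate breakpoint, reported as the midpoint
of its flanking informative sites. Significance comes from permuting the
site labels (default 1000 permutations, seeded), with the add-one
estimator (b+1)/(n+1). Fewer than 2×`min_sites_per_side` informative
sites yields an explicit no-call. Only the single best breakpoint per
triplet is called; serial scanning for multiple breakpoints and
multi-program consensus detection are out of scope. Note the permutation
p-value is uniform under an exchangeable null (child drawing from either
parent independently per site); on a clonal child that simply copies one
parent, informative sites are scarce and one-sided and the test is
conservative, which is the desired direction for a false-positive
control.

## Synthetic data

The forward simulator emulates exactly the diversification process the
counting estimator assumes: founder genotypes (default 2) with random
~500 bp alleles at 4 loci; 60 isolates, each a clonal copy of a uniformly
chosen founder; Poisson(0.05) point mutations per lineage (uniform locus,
site, and non-identical base) and Poisson(0.5) recombinational imports
(wholesale replacement of one locus's allele with one of 8 donor alleles
held at exactly 6 nt from the founder allele). These defaults describe a
regime of rare mutation and order-of-magnitude-more-frequent import at
import divergences comfortably above the 3-difference classification
threshold. Bookkeeping is exact by construction: one import at most per
locus per isolate, mutation sites resampled if the isolate already
differs from its founder there, so differences-from-founder equal logged
edits and the truth log is authoritative.

What the simulator does **not** emulate: coalescent genealogy within
complexes (isolates attach directly to founders), selection, intragenic
recombination (imports are whole-fragment), sequencing error, indels, or
multiple infection. Recovery tests on this data therefore show that the
counting estimator is consistent when its own assumptions hold — they say
nothing about mis-specification on real data, where deeper genealogies
spread variants over several linked STs. The parameter-recovery check
(ratios 1:1, 5:1, 10:1; 20 seeds; median strict estimate within a factor
of 2 of the realized truth) uses these problem sizes to keep the full
grid under a minute.

The reference-table sequence realization (`fixture` subcommand) is
synthetic: deterministic sequences constructed so that every annotated
difference count, and every sharing flag that is decidable within the
table, recomputes exactly from sequence (non-unique single changes are
planted in the divergence sets of existing alleles). The elsewhere-seen
flag of the 2-difference groEL variant refers to an isolate outside the
table; `--include-background` adds one synthetic singleton isolate
carrying that allele (and novel alleles elsewhere, so it joins no
complex), making that flag sequence-decidable too. Without it, the flag
is taken from the annotation table.

## Numerical and design notes

- All randomness flows through `numpy.random.default_rng(seed)`; equal
  seeds give byte-identical outputs (FASTA, TSV, reports).
- Ratios are formed with exact integer arithmetic (`fractions.Fraction`)
  before conversion to float.
- Reports are plain text and TSV only, and every number in the summary is
  echoed from an upstream table rather than recomputed.
- Two-locus mode (`run2`) runs the identical pipeline with L = 2, where
  the SLV rule degenerates to sharing 1 of 2 alleles; the report carries
  an explicit caveat that attribution at L = 2 has little resolution.
  Single-locus input is refused.
- Known limitations: no likelihood-based r/m estimation, no per-site
  selection scan, no phylogenetic tree inference, no bootstrap founder
  confidence; allele ids are not stable across datasets.
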