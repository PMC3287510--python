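"""Mutation-versus-recombination attribution of within-complex variants.

Each clonal-complex member whose profile deviates from the founder does so
at one or more loci; comparing the deviating allele's sequence with the
founder's allele at that locus gives a nucleotide difference count, and the
pattern of differences classifies the variant:

- 1 difference, not seen in any other allele at that locus → putative de
  novo point mutation (``unique_single``);
- 1 difference that recurs elsewhere at the locus → ``nonunique_single``,
  suggestive of recombination between similar alleles;
- 2 differences → ``double``, ambiguous (a pair of mutations or a short
  import); an identical allele elsewhere in the dataset tips it toward
  recombination;
- ≥3 differences (configurable) → ``import``, a recombinational allele
  replacement.

The recombination:mutation (r:m) ratio is reported under two counting
rules: a strict rule that drops the ambiguous classes entirely
(imports : unique singles) and an inclusive rule that assigns non-unique
singles and elsewhere-seen doubles to recombination and the remaining
doubles to mutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

from scipy import stats

from .complexes import ClonalComplex
from .mlst import AlleleTable, STProfile

CLASSIFICATIONS = ("unique_single", "nonunique_single", "double", "import")


@dataclass
class VariantAllele:
    """A within-complex allele deviating from the founder's allele."""

    complex_id: str
    st_ids: list[int]  # complex members carrying this variant
    locus: str
    founder_allele_id: int
    variant_allele_id: int
    n_diffs: int
    single_change_seen_elsewhere: bool = False
    allele_seen_elsewhere: bool = False
    classification: str | None = None


@dataclass
class RMEstimate:
    """Recombination:mutation ratio under strict and inclusive rules."""

    n_variants: int
    counts: dict[str, int]
    strict_recomb: int
    strict_mut: int
    inclusive_recomb: int
    inclusive_mut: int
    strict_ratio: float  # inf when the mutation denominator is 0
    inclusive_ratio: float
    ratio_range: tuple[float, float] = field(default=(0.0, 0.0))

    def describe(self) -> str:
        s = f"{self.strict_recomb}:{self.strict_mut}"
        i = f"{self.inclusive_recomb}:{self.inclusive_mut}"
        return (
            f"{self.n_variants} variant alleles "
            f"({', '.join(f'{k}={v}' for k, v in self.counts.items())}); "
            f"r:m strict {s}, inclusive {i}"
        )


def count_sequence_diffs(seq_a: str, seq_b: str) -> int:
    """Column-wise differences, excluding columns with a gap in either."""
    return sum(
        1 for a, b in zip(seq_a, seq_b) if a != "-" and b != "-" and a != b
    )


def _single_change_elsewhere(
    table: AlleleTable, variant_id: int, founder_id: int
) -> bool:
    """True when the variant's single polymorphism (column + derived base)
    recurs in any other allele at this locus."""
    var_seq = table.allele_seqs[variant_id]
    founder_seq = table.allele_seqs[founder_id]
    change = [
        (col, v)
        for col, (f, v) in enumerate(zip(founder_seq, var_seq))
        if f != "-" and v != "-" and f != v
    ]
    if len(change) != 1:
        raise ValueError("variant does not differ by exactly one base")
    col, derived = change[0]
    return any(
        seq[col] == derived
        for allele_id, seq in table.allele_seqs.items()
        if allele_id != variant_id
    )


def _allele_elsewhere(
    table: AlleleTable,
    variant_id: int,
    complex_isolates: set[str],
) -> bool:
    """True when an isolate outside this complex carries the same allele."""
    return any(
        allele_id == variant_id and iso not in complex_isolates
        for iso, allele_id in table.isolate_alleles.items()
    )


def extract_variants(
    complexes: list[ClonalComplex],
    sts: list[STProfile],
    tables: dict[str, AlleleTable],
    locus_order: list[str],
    import_threshold: int = 3,
) -> list[VariantAllele]:
    """Collect and classify deviating alleles within each clonal complex.

    A variant is one distinct (complex, locus, variant allele) triple: an
    allele shared by several member STs of one complex counts once there,
    but is counted again if it also deviates in another complex. Difference
    counts and sharing flags are computed from the allele sequences over
    the full dataset.
    """
    st_by_id = {st.st_id: st for st in sts}
    variants: list[VariantAllele] = []
    for cc in complexes:
        founder = st_by_id[cc.founder_st_id]
        complex_isolates = {
            iso for st_id in cc.member_st_ids for iso in st_by_id[st_id].isolate_ids
        }
        seen: dict[tuple[str, int], VariantAllele] = {}
        for st_id in cc.member_st_ids:
            if st_id == cc.founder_st_id:
                continue
            st = st_by_id[st_id]
            for locus, allele, founder_allele in zip(
                locus_order, st.alleles, founder.alleles
            ):
                if allele == founder_allele:
                    continue
                key = (locus, allele)
                if key in seen:
                    seen[key].st_ids.append(st_id)
                    continue
                table = tables[locus]
                if founder_allele not in table.allele_seqs:
                    raise ValueError(
                        f"founder ST{founder.st_id} allele {founder_allele} "
                        f"missing from {locus} table"
                    )
                n_diffs = count_sequence_diffs(
                    table.allele_seqs[allele], table.allele_seqs[founder_allele]
                )
                v = VariantAllele(
                    complex_id=cc.complex_id,
                    st_ids=[st_id],
                    locus=locus,
                    founder_allele_id=founder_allele,
                    variant_allele_id=allele,
                    n_diffs=n_diffs,
                )
                if n_diffs == 1:
                    v.single_change_seen_elsewhere = _single_change_elsewhere(
                        table, allele, founder_allele
                    )
                v.allele_seen_elsewhere = _allele_elsewhere(
                    table, allele, complex_isolates
                )
                classify_variant(v, import_threshold)
                seen[key] = v
        variants.extend(seen.values())
    return variants


def classify_variant(v: VariantAllele, import_threshold: int = 3) -> str:
    """Apply the diff-count/sharing rules; stores and returns the class."""
    if v.n_diffs < 1:
        raise ValueError("variant allele with zero differences from founder")
    if v.n_diffs == 1:
        cls = "nonunique_single" if v.single_change_seen_elsewhere else "unique_single"
    elif v.n_diffs < import_threshold:
        cls = "double"
    else:
        cls = "import"
    v.classification = cls
    return cls


def estimate_rm(variants: list[VariantAllele]) -> RMEstimate:
    """r:m under the strict and inclusive counting rules.

    Strict: imports : unique singles, ignoring non-unique singles and
    doubles. Inclusive: non-unique singles and elsewhere-seen doubles join
    recombination; unseen doubles join mutation. A zero mutation count
    yields an infinite (flagged) ratio rather than an error.
    """
    if not variants:
        raise ValueError("no variants to estimate from")
    counts = {c: 0 for c in CLASSIFICATIONS}
    doubles_seen = 0
    for v in variants:
        if v.classification is None:
            classify_variant(v)
        counts[v.classification] += 1
        if v.classification == "double" and v.allele_seen_elsewhere:
            doubles_seen += 1
    strict_recomb = counts["import"]
    strict_mut = counts["unique_single"]
    inclusive_recomb = counts["import"] + counts["nonunique_single"] + doubles_seen
    inclusive_mut = counts["unique_single"] + (counts["double"] - doubles_seen)

    def ratio(r: int, m: int) -> float:
        if m == 0:
            return float("inf") if r > 0 else 0.0
        return float(Fraction(r, m))

    strict = ratio(strict_recomb, strict_mut)
    inclusive = ratio(inclusive_recomb, inclusive_mut)
    return RMEstimate(
        n_variants=len(variants),
        counts=counts,
        strict_recomb=strict_recomb,
        strict_mut=strict_mut,
        inclusive_recomb=inclusive_recomb,
        inclusive_mut=inclusive_mut,
        strict_ratio=strict,
        inclusive_ratio=inclusive,
        ratio_range=tuple(sorted((inclusive, strict))),
    )


def locus_bias_test(
    variants: list[VariantAllele], loci: list[str]
) -> tuple[float, int, float]:
    """Goodness-of-fit chi-square of per-locus variant counts vs uniform.

    Returns (statistic, df, p). No continuity correction.
    """
    if len(loci) < 2:
        raise ValueError("need at least 2 loci")
    observed = [sum(1 for v in variants if v.locus == l) for l in loci]
    if sum(observed) == 0:
        raise ValueError("no variants at any locus")
    stat, p = stats.chisquare(observed)
    return float(stat), len(loci) - 1, float(p)


def per_locus_counts(variants: list[VariantAllele], loci: list[str]) -> dict[str, int]:
    return {l: sum(1 for v in variants if v.locus == l) for l in loci}


def write_variants_tsv(variants: list[VariantAllele], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "complex_id\tmember_sts\tlocus\tfounder_allele\tvariant_allele\t"
            "n_diffs\tsingle_change_seen_elsewhere\tallele_seen_elsewhere\t"
            "classification\n"
        )
        for v in variants:
            fh.write(
                f"{v.complex_id}\t{','.join(map(str, v.st_ids))}\t{v.locus}\t"
                f"{v.founder_allele_id}\t{v.variant_allele_id}\t{v.n_diffs}\t"
                f"{int(v.single_change_seen_elsewhere)}\t"
                f"{int(v.allele_seen_elsewhere)}\t{v.classification}\n"
            )
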