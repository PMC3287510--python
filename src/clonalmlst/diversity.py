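"""Per-locus diversity statistics.

Implements the summary statistics reported per gene fragment: variable-site
counts, nucleotide diversity π (mean pairwise p-distance with pairwise
deletion), maximum pairwise p-distance, and the Nei–Gojobori estimate of
dN/dS with Jukes–Cantor correction.

Gap (``-``) and ``N`` columns are handled by pairwise deletion: for each
sequence pair, only columns where both members carry a determinate base are
compared. This keeps per-pair denominators maximal and matches the default
behaviour of the common distance calculators for this kind of data.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .alignio import LocusAlignment

MISSING = {"-", "N"}


@dataclass
class DiversitySummary:
    """One row of a per-locus diversity table."""

    locus_name: str
    size_bp: int
    n_sequences: int
    n_alleles: int
    variable_sites: int
    variable_sites_pct: float
    pi: float
    max_p_distance_pct: float
    dnds: float | None = None
    dn: float | None = None
    ds: float | None = None


def _matrix(aln: LocusAlignment) -> np.ndarray:
    return np.array([list(s) for s in aln.sequences], dtype="U1")


def count_variable_sites(aln: LocusAlignment) -> tuple[int, float]:
    """Number and percentage of columns with ≥2 distinct determinate bases.

    Gaps and N are ignored when deciding whether a column varies.
    """
    mat = _matrix(aln)
    count = 0
    for col in mat.T:
        bases = set(col.tolist()) - MISSING
        if len(bases) >= 2:
            count += 1
    return count, 100.0 * count / aln.length


def _pairwise_p(seq_a: str, seq_b: str) -> tuple[int, int]:
    """(differences, compared sites) under pairwise deletion."""
    diffs = 0
    compared = 0
    for a, b in zip(seq_a, seq_b):
        if a in MISSING or b in MISSING:
            continue
        compared += 1
        if a != b:
            diffs += 1
    return diffs, compared


def p_distance_matrix(aln: LocusAlignment) -> np.ndarray:
    """Symmetric matrix of pairwise p-distances (proportions)."""
    n = aln.n_sequences
    mat = _matrix(aln)
    valid = ~np.isin(mat, list(MISSING))
    dist = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        diff = (mat[i] != mat[i + 1 :]) & both
        compared = both.sum(axis=1)
        with np.errstate(invalid="ignore"):
            d = np.where(compared > 0, diff.sum(axis=1) / compared, np.nan)
        dist[i, i + 1 :] = d
        dist[i + 1 :, i] = d
    return dist


def nucleotide_diversity(aln: LocusAlignment) -> float:
    """π: mean p-distance over all unordered sequence pairs."""
    if aln.n_sequences < 2:
        raise ValueError("nucleotide diversity needs at least 2 sequences")
    dist = p_distance_matrix(aln)
    iu = np.triu_indices(aln.n_sequences, k=1)
    return float(np.nanmean(dist[iu]))


def max_p_distance(aln: LocusAlignment) -> float:
    """Maximum pairwise p-distance, as a percentage."""
    if aln.n_sequences < 2:
        raise ValueError("max p-distance needs at least 2 sequences")
    dist = p_distance_matrix(aln)
    iu = np.triu_indices(aln.n_sequences, k=1)
    return float(np.nanmax(dist[iu])) * 100.0


# ---------------------------------------------------------------------------
# Nei–Gojobori dN/dS

_CODE = standard_dna_table.forward_table
_STOPS = set(standard_dna_table.stop_codons)
_BASES = "ACGT"


def _translate(codon: str) -> str | None:
    """Amino acid, '*' for stop, None if codon contains gap/N/ambiguity."""
    if codon in _STOPS:
        return "*"
    return _CODE.get(codon)


@lru_cache(maxsize=None)
def synonymous_sites(codon: str) -> float:
    """Potential synonymous sites of a codon.

    Per position, the fraction of the three single-base changes that
    preserve the amino acid; summed over positions. Changes to stop codons
    count as nonsynonymous. E.g. TTT → 1/3 (only TTT→TTC is silent).
    """
    aa = _translate(codon)
    if aa is None or aa == "*":
        raise ValueError(f"cannot count sites for codon {codon!r}")
    s = 0.0
    for pos in range(3):
        syn = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if _translate(mutant) == aa:
                syn += 1
        s += syn / 3.0
    return s


@lru_cache(maxsize=None)
def codon_path_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    All mutational pathways (orderings of the differing positions) are
    weighted equally, including those passing through stop intermediates;
    each single-base step is synonymous iff it preserves the amino acid.
    """
    positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not positions:
        return 0.0, 0.0
    syn_total = 0.0
    nonsyn_total = 0.0
    paths = list(itertools.permutations(positions))
    for order in paths:
        current = codon_a
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            aa_from, aa_to = _translate(current), _translate(nxt)
            if aa_from == aa_to and aa_from != "*":
                syn_total += 1.0
            else:
                nonsyn_total += 1.0
            current = nxt
    k = len(paths)
    return syn_total / k, nonsyn_total / k


def jukes_cantor(p: float) -> float:
    """JC69 correction d = -(3/4)·ln(1 − 4p/3); raises for p ≥ 3/4."""
    if p >= 0.75:
        raise ValueError(f"proportion {p} too large for Jukes-Cantor correction")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class DnDsResult:
    dn: float
    ds: float
    pn: float
    ps: float
    dnds: float | None  # None when dS = 0 (undefined, not infinity)
    n_codons: int
    skipped_codons: int


def nei_gojobori_dnds(aln: LocusAlignment, frame_offset: int = 0) -> DnDsResult:
    """Nei–Gojobori dN/dS over all sequence pairs of a coding alignment.

    Codons containing gaps, N, ambiguity codes, or a stop in either member
    of a pair are skipped (stops with a warning). pS and pN are averaged
    over pairs, then Jukes–Cantor corrected; the ratio is None when dS = 0.
    """
    if aln.n_sequences < 2:
        raise ValueError("dN/dS needs at least 2 sequences")
    usable = aln.length - frame_offset
    if usable < 3:
        raise ValueError("fewer than one codon after frame offset")
    n_codons = usable // 3
    starts = [frame_offset + 3 * k for k in range(n_codons)]

    ps_vals: list[float] = []
    pn_vals: list[float] = []
    skipped = 0
    stop_seen = False
    for a, b in itertools.combinations(range(aln.n_sequences), 2):
        seq_a, seq_b = aln.sequences[a], aln.sequences[b]
        S = N = Sd = Nd = 0.0
        for start in starts:
            ca, cb = seq_a[start : start + 3], seq_b[start : start + 3]
            ta, tb = _translate(ca), _translate(cb)
            if ta is None or tb is None:
                skipped += 1
                continue
            if ta == "*" or tb == "*":
                skipped += 1
                stop_seen = True
                continue
            sa, sb = synonymous_sites(ca), synonymous_sites(cb)
            S += (sa + sb) / 2.0
            N += 3.0 - (sa + sb) / 2.0
            sd, nd = codon_path_differences(ca, cb)
            Sd += sd
            Nd += nd
        if S > 0 and N > 0:
            ps_vals.append(Sd / S)
            pn_vals.append(Nd / N)
    if stop_seen:
        warnings.warn("internal stop codon(s) encountered; codons skipped")
    if not ps_vals:
        raise ValueError("no comparable codons in any pair")
    ps = float(np.mean(ps_vals))
    pn = float(np.mean(pn_vals))
    # p ≥ 3/4 means saturation: the corrected distance diverges. This only
    # occurs on degenerate inputs (very few codons); report d = inf there.
    ds = jukes_cantor(ps) if ps < 0.75 else math.inf
    dn = jukes_cantor(pn) if pn < 0.75 else math.inf
    if ds == 0:
        dnds = None
    elif math.isinf(dn) and math.isinf(ds):
        dnds = None
    else:
        dnds = dn / ds
    return DnDsResult(dn, ds, pn, ps, dnds, n_codons, skipped)


def summarize_locus(
    aln: LocusAlignment,
    n_alleles: int,
    coding: bool = True,
    frame_offset: int = 0,
) -> DiversitySummary:
    """Assemble one diversity-table row for a locus."""
    var_n, var_pct = count_variable_sites(aln)
    pi = nucleotide_diversity(aln) if aln.n_sequences >= 2 else float("nan")
    maxp = max_p_distance(aln) if aln.n_sequences >= 2 else float("nan")
    dnds = dn = ds = None
    if coding and aln.n_sequences >= 2:
        try:
            res = nei_gojobori_dnds(aln, frame_offset)
            dnds, dn, ds = res.dnds, res.dn, res.ds
        except ValueError:
            pass
    return DiversitySummary(
        locus_name=aln.locus_name,
        size_bp=aln.length,
        n_sequences=aln.n_sequences,
        n_alleles=n_alleles,
        variable_sites=var_n,
        variable_sites_pct=var_pct,
        pi=pi,
        max_p_distance_pct=maxp,
        dnds=dnds,
        dn=dn,
        ds=ds,
    )
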