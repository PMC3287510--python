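import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonalmlst.diversity import (
    codon_path_differences,
    count_variable_sites,
    jukes_cantor,
    max_p_distance,
    nei_gojobori_dnds,
    nucleotide_diversity,
    synonymous_sites,
)
from conftest import make_alignment

# ---------------------------------------------------------------------------
# independent brute-force oracles (plain loops, no shared code paths)

GENETIC_CODE = {}


def _build_code():
    from Bio.Seq import Seq

    for b1 in "ACGT":
        for b2 in "ACGT":
            for b3 in "ACGT":
                codon = b1 + b2 + b3
                GENETIC_CODE[codon] = str(Seq(codon).translate())


_build_code()


def oracle_pairwise_p(a, b):
    diffs = compared = 0
    for x, y in zip(a, b):
        if x in "-N" or y in "-N":
            continue
        compared += 1
        diffs += x != y
    return diffs / compared if compared else float("nan")


def oracle_pi(seqs):
    pairs = list(itertools.combinations(seqs, 2))
    vals = [oracle_pairwise_p(a, b) for a, b in pairs]
    vals = [v for v in vals if not math.isnan(v)]
    return sum(vals) / len(vals)


def oracle_max_p(seqs):
    vals = [
        oracle_pairwise_p(a, b) for a, b in itertools.combinations(seqs, 2)
    ]
    vals = [v for v in vals if not math.isnan(v)]
    return max(vals) * 100.0


def oracle_syn_sites(codon):
    """Fraction of the nine single-base changes preserving the amino acid."""
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if GENETIC_CODE[mutant] == aa:
                s += 1 / 3
    return s


aln_strategy = st.integers(2, 10).flatmap(
    lambda n: st.integers(4, 50).flatmap(
        lambda L: st.lists(
            st.text(alphabet="ACGT", min_size=L, max_size=L),
            min_size=n,
            max_size=n,
        )
    )
)


class TestVariableSites:
    def test_one_variable_site(self):
        assert count_variable_sites(make_alignment(["ACGT", "ACGA"])) == (1, 25.0)

    def test_all_identical(self):
        assert count_variable_sites(make_alignment(["ACGT"] * 4)) == (0, 0.0)

    def test_gap_and_n_do_not_create_variability(self):
        n, _ = count_variable_sites(make_alignment(["ACG-", "ACGN", "ACGT"]))
        assert n == 0


class TestPiAndMaxP:
    def test_pair_one_diff_in_ten(self):
        aln = make_alignment(["ACGTACGTAC", "ACGTACGTAA"])
        assert nucleotide_diversity(aln) == pytest.approx(0.1)
        assert max_p_distance(aln) == pytest.approx(10.0)

    def test_identical_sequences(self):
        aln = make_alignment(["ACGTACGTAC"] * 4)
        assert nucleotide_diversity(aln) == 0.0
        assert max_p_distance(aln) == 0.0

    def test_four_seq_hand_built(self):
        """π over four 12-bp sequences equals the brute-force average of
        the 6 pairwise p-distances."""
        seqs = ["ACGTACGTACGT", "ACGTACGTACGA", "ACGAACGTACGA", "TCGAACGTACGA"]
        aln = make_alignment(seqs)
        assert nucleotide_diversity(aln) == pytest.approx(oracle_pi(seqs), abs=1e-12)

    def test_pairwise_deletion(self):
        # the gapped column is dropped only for pairs involving seq 1
        seqs = ["AC-TACGTAC", "ACGTACGTAA", "ACGTACGTAC"]
        aln = make_alignment(seqs)
        assert nucleotide_diversity(aln) == pytest.approx(oracle_pi(seqs), abs=1e-12)

    def test_fewer_than_two_sequences_rejected(self):
        with pytest.raises(ValueError):
            nucleotide_diversity(make_alignment(["ACGT"]))

    @settings(max_examples=80, deadline=None)
    @given(seqs=aln_strategy)
    def test_matches_bruteforce_oracle(self, seqs):
        aln = make_alignment(seqs)
        assert nucleotide_diversity(aln) == pytest.approx(
            oracle_pi(seqs), abs=1e-12
        )
        assert max_p_distance(aln) == pytest.approx(oracle_max_p(seqs), abs=1e-12)

    @settings(max_examples=40, deadline=None)
    @given(seqs=aln_strategy)
    def test_pi_bounded_by_max_p(self, seqs):
        aln = make_alignment(seqs)
        assert nucleotide_diversity(aln) <= max_p_distance(aln) / 100.0 + 1e-12


class TestNeiGojobori:
    def test_ttt_synonymous_sites(self):
        # only TTT→TTC among the nine single-base changes is silent
        assert synonymous_sites("TTT") == pytest.approx(1 / 3)

    @pytest.mark.parametrize(
        "codon",
        [
            c
            for c in (a + b + c for a in "AT" for b in "CG" for c in "ACGT")
            if GENETIC_CODE[c] != "*"
        ],
    )
    def test_site_counts_match_enumeration(self, codon):
        assert synonymous_sites(codon) == pytest.approx(oracle_syn_sites(codon))

    def test_pathway_counting_two_diff_codon(self):
        # TTT→GTA: path TTT→GTT(F→V)→GTA(V→V syn) and TTT→TTA(F→L)→GTA(L→V)
        sd, nd = codon_path_differences("TTT", "GTA")
        assert (sd, nd) == (0.5, 1.5)

    def test_pathway_counting_mixed(self):
        # CCT→CCC silent; enumerate CCT→CAC (2 diffs): paths via CAT and CCC
        sd, nd = codon_path_differences("CCT", "CAC")
        # path1 CCT→CAT(P→H nonsyn)→CAC(H→H syn); path2 CCT→CCC(syn)→CAC(nonsyn)
        assert (sd, nd) == (1.0, 1.0)

    def test_purely_synonymous_pair(self):
        aln = make_alignment(["TTT", "TTC"])
        res = nei_gojobori_dnds(aln)
        assert res.dn == 0.0
        assert res.ds > 0
        assert res.dnds == 0.0

    def test_identical_sequences_undefined_ratio(self):
        aln = make_alignment(["TTTACG", "TTTACG"])
        res = nei_gojobori_dnds(aln)
        assert res.dn == res.ds == 0.0
        assert res.dnds is None

    def test_site_totals_sum_to_three_per_codon(self):
        # S + N = 3 × codons whenever no codon is skipped
        import numpy as np

        rng = np.random.default_rng(7)
        while True:
            seqs = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(3)]
            try:
                res = nei_gojobori_dnds(make_alignment(seqs))
            except ValueError:
                continue
            if res.skipped_codons == 0:
                break
        for a, b in itertools.combinations(seqs, 2):
            S = N = 0.0
            for k in range(0, 30, 3):
                sa = oracle_syn_sites(a[k : k + 3])
                sb = oracle_syn_sites(b[k : k + 3])
                S += (sa + sb) / 2
                N += 3 - (sa + sb) / 2
            assert S + N == pytest.approx(30.0, abs=1e-9)

    def test_internal_stop_skipped_with_warning(self):
        aln = make_alignment(["TAATTT", "TACTTC"])
        with pytest.warns(UserWarning, match="stop"):
            res = nei_gojobori_dnds(aln)
        assert res.skipped_codons > 0

    def test_frame_offset_too_short(self):
        with pytest.raises(ValueError):
            nei_gojobori_dnds(make_alignment(["ACGT", "ACGA"]), frame_offset=2)


def test_jukes_cantor_inverts_small_p():
    assert jukes_cantor(0.0) == 0.0
    assert jukes_cantor(0.1) == pytest.approx(
        -0.75 * math.log(1 - 4 * 0.1 / 3)
    )
    with pytest.raises(ValueError):
        jukes_cantor(0.8)
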