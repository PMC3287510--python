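"""The published clonal-complex reference dataset and its sequence realization.

The package ships, as plain TSV, the 22-ST / 44-isolate clonal-complex
table from the source survey of *Wolbachia* in spider-mite hosts: five
complexes (designated founders ST4, ST30, ST16, ST24, ST33) over the loci
wsp, ftsZ, groEL, trmD, with each member's deviating allele annotated with
its nucleotide-difference count from the founder allele and, for the short
variants, whether the change or allele recurs elsewhere in the full survey.

``load_reference_profiles`` / ``load_reference_variants`` expose those tables as
pipeline objects. ``fabricate_sequences`` builds a synthetic per-locus
sequence realization that reproduces every annotated difference count and
every recomputable sharing flag, so the whole pipeline can be exercised at
the sequence level without downloading the deposited data. The one flag
that refers to isolates outside the shipped table (the elsewhere-seen
2-difference groEL allele) becomes recomputable only when the optional
background isolate carrying that allele is included.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .alignio import LocusAlignment, write_locus_alignment
from .attribution import VariantAllele, classify_variant
from .complexes import ClonalComplex, find_clonal_complexes, build_slv_graph
from .mlst import AlleleTable, STProfile

LOCUS_ORDER = ["wsp", "ftsZ", "groEL", "trmD"]
LOCUS_LENGTHS = {"wsp": 525, "ftsZ": 507, "groEL": 491, "trmD": 453}
_BASE_CYCLE = {"A": "C", "C": "G", "G": "T", "T": "A"}
_FABRICATION_SEED = 2011  # fixed: the realization is part of the fixture


def _data_path(name: str):
    return resources.files("clonalmlst.data").joinpath(name)


def load_reference_profiles() -> tuple[list[STProfile], dict[str, list[int]], dict[str, int]]:
    """Shipped ST table.

    Returns (profiles, complex membership {label: [st ids]}, designated
    founders {label: st id}). Isolate ids are synthesized as ``ST<x>_<k>``
    to carry the published frequencies.
    """
    profiles: list[STProfile] = []
    membership: dict[str, list[int]] = {}
    founders: dict[str, int] = {}
    with _data_path("reference_profiles.tsv").open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            st_id = int(row["st"])
            freq = int(row["freq"])
            profiles.append(
                STProfile(
                    st_id=st_id,
                    alleles=tuple(int(row[l]) for l in LOCUS_ORDER),
                    isolate_ids=[f"ST{st_id}_{k + 1}" for k in range(freq)],
                )
            )
            membership.setdefault(row["complex"], []).append(st_id)
            if row["is_founder"] == "1":
                founders[row["complex"]] = st_id
    return profiles, membership, founders


@dataclass
class FixtureVariantRow:
    complex_label: str  # published label (I..V)
    locus: str
    founder_allele: int
    variant_allele: int
    n_diffs: int
    seen_elsewhere: bool
    member_sts: list[int]


def load_reference_variant_rows() -> list[FixtureVariantRow]:
    rows: list[FixtureVariantRow] = []
    with _data_path("reference_variants.tsv").open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rows.append(
                FixtureVariantRow(
                    complex_label=row["complex"],
                    locus=row["locus"],
                    founder_allele=int(row["founder_allele"]),
                    variant_allele=int(row["variant_allele"]),
                    n_diffs=int(row["n_diffs"]),
                    seen_elsewhere=row["seen_elsewhere"] == "1",
                    member_sts=[int(s) for s in row["member_sts"].split(",")],
                )
            )
    return rows


def load_reference_variants(import_threshold: int = 3) -> list[VariantAllele]:
    """Fixture variants as classified :class:`VariantAllele` objects."""
    variants: list[VariantAllele] = []
    for row in load_reference_variant_rows():
        v = VariantAllele(
            complex_id=row.complex_label,
            st_ids=list(row.member_sts),
            locus=row.locus,
            founder_allele_id=row.founder_allele,
            variant_allele_id=row.variant_allele,
            n_diffs=row.n_diffs,
            single_change_seen_elsewhere=row.n_diffs == 1 and row.seen_elsewhere,
            allele_seen_elsewhere=row.n_diffs >= 2 and row.seen_elsewhere,
        )
        classify_variant(v, import_threshold)
        variants.append(v)
    return variants


def fixture_complexes() -> tuple[list[ClonalComplex], list[int], list[STProfile]]:
    """SLV graph + clonal complexes of the fixture, founders designated."""
    profiles, membership, founders = load_reference_profiles()
    graph = build_slv_graph(profiles)
    designated = {
        frozenset(members): founders[label] for label, members in membership.items()
    }
    complexes, singletons = find_clonal_complexes(graph, designated)
    return complexes, singletons, profiles


# ---------------------------------------------------------------------------
# Sequence fabrication


def _mutate(seq: list[str], cols: list[int]) -> list[str]:
    out = list(seq)
    for c in cols:
        out[c] = _BASE_CYCLE[out[c]]
    return out


def _fabricate_locus_alleles() -> dict[str, dict[int, str]]:
    """Deterministic allele sequences reproducing every fixture diff count.

    Each allele is the locus's base allele with substitutions at disjoint
    column blocks; substituted bases follow a fixed A→C→G→T cycle, so a
    polymorphism planted at the same column in two alleles is identical —
    which is how the non-unique single changes (and only those) are made
    to recur. Synthetic data: the realization is not the deposited
    sequence set, only difference-structure-faithful to it.
    """
    rng = np.random.default_rng(_FABRICATION_SEED)
    base = {
        locus: [str(b) for b in np.array(list("ACGT"))[rng.integers(0, 4, n)]]
        for locus, n in LOCUS_LENGTHS.items()
    }
    w1 = base["wsp"]
    w12 = _mutate(w1, list(range(400, 425)))
    w6 = _mutate(w1, list(range(370, 395)))
    w5 = _mutate(w1, list(range(10, 28)))       # 18 diffs from w1
    w3 = _mutate(w5, list(range(30, 38)))       # 8 diffs from w5
    w4 = _mutate(w12, list(range(50, 66)))      # 16 diffs from w12

    f2 = base["ftsZ"]
    f10 = _mutate(f2, list(range(400, 420)))
    f14 = _mutate(f2, list(range(370, 390)))
    f1 = _mutate(f2, [10])                      # the unique single change
    f3 = _mutate(f2, list(range(340, 360)))

    g8 = base["groEL"]
    g12 = _mutate(g8, list(range(400, 420)))
    g3 = _mutate(g8, list(range(370, 390)))
    g4 = _mutate(g8, list(range(10, 14)))       # 4 diffs from g8
    g11 = _mutate(g12, [20, 21])                # 2 diffs from g12

    t1 = base["trmD"]
    t8 = _mutate(t1, list(range(400, 422)))
    t9 = _mutate(t1, list(range(370, 390)))
    t3 = _mutate(t1, [10])                      # shared with t10 → non-unique
    t2 = _mutate(t1, [20])                      # shared with t14 → non-unique
    t10 = _mutate(t1, [10] + list(range(40, 54)))   # 15 diffs
    t14 = _mutate(t1, [20] + list(range(70, 78)))   # 9 diffs
    t6 = _mutate(t1, [110] + list(range(60, 66)))   # 7 diffs
    t5 = _mutate(t1, [30, 31])                      # 2 diffs
    t17 = _mutate(t8, list(range(90, 99)))          # 9 diffs from t8
    t15 = _mutate(t8, list(range(100, 108)))        # 8 diffs from t8
    t11 = _mutate(t9, [110])                        # shared with t6 → non-unique

    join = lambda s: "".join(s)
    return {
        "wsp": {1: join(w1), 3: join(w3), 4: join(w4), 5: join(w5), 6: join(w6), 12: join(w12)},
        "ftsZ": {1: join(f1), 2: join(f2), 3: join(f3), 10: join(f10), 14: join(f14)},
        "groEL": {3: join(g3), 4: join(g4), 8: join(g8), 11: join(g11), 12: join(g12)},
        "trmD": {
            1: join(t1), 2: join(t2), 3: join(t3), 5: join(t5), 6: join(t6),
            8: join(t8), 9: join(t9), 10: join(t10), 11: join(t11),
            14: join(t14), 15: join(t15), 17: join(t17),
        },
    }


def _background_alleles(allele_seqs: dict[str, dict[int, str]]) -> dict[str, int]:
    """Add one background singleton's alleles: novel at wsp/ftsZ/trmD
    (far from every fixture allele) and the elsewhere-seen groEL allele."""
    profile = {}
    # derive the novel alleles from ancestral (founder) alleles, away from
    # every annotated polymorphism column, so no sharing flag is disturbed
    for locus, source_id, novel_id in (("wsp", 1, 90), ("ftsZ", 2, 90), ("trmD", 1, 90)):
        founder_seq = list(allele_seqs[locus][source_id])
        allele_seqs[locus][novel_id] = "".join(
            _mutate(founder_seq, list(range(200, 230)))
        )
        profile[locus] = novel_id
    profile["groEL"] = 11
    return profile


@dataclass
class FixtureDataset:
    alignments: dict[str, LocusAlignment]
    allele_tables: dict[str, AlleleTable]
    profiles: list[STProfile]
    locus_order: list[str]
    metadata: list[dict]


def fabricate_sequences(include_background: bool = False) -> FixtureDataset:
    """Per-locus alignments realizing the fixture's difference structure.

    With ``include_background=True`` one extra singleton isolate is added
    (novel alleles at three loci, the elsewhere-seen groEL allele at the
    fourth) so that the 2-difference sharing flag also recomputes from
    sequence; it joins no clonal complex.
    """
    allele_seqs = _fabricate_locus_alleles()
    profiles, membership, _ = load_reference_profiles()
    complex_of = {
        st: label for label, members in membership.items() for st in members
    }
    isolate_rows: list[tuple[str, dict[str, int], str, int]] = []
    for st in profiles:
        alleles = dict(zip(LOCUS_ORDER, st.alleles))
        for iso in st.isolate_ids:
            isolate_rows.append((iso, alleles, complex_of[st.st_id], st.st_id))
    if include_background:
        bg_profile = _background_alleles(allele_seqs)
        isolate_rows.append(("BG1_1", bg_profile, "-", 0))

    alignments: dict[str, LocusAlignment] = {}
    tables: dict[str, AlleleTable] = {}
    for locus in LOCUS_ORDER:
        ids = [iso for iso, _, _, _ in isolate_rows]
        seqs = [allele_seqs[locus][alleles[locus]] for _, alleles, _, _ in isolate_rows]
        alignments[locus] = LocusAlignment(locus, ids, seqs)
        tables[locus] = AlleleTable(
            locus_name=locus,
            allele_seqs=dict(allele_seqs[locus]),
            isolate_alleles={
                iso: alleles[locus] for iso, alleles, _, _ in isolate_rows
            },
        )
    metadata = [
        {"isolate_id": iso, "complex": label, "st": st_id}
        for iso, _, label, st_id in isolate_rows
    ]
    return FixtureDataset(alignments, tables, profiles, list(LOCUS_ORDER), metadata)


def emit_fixture_dataset(
    outdir: str | Path, include_background: bool = False
) -> dict[str, Path]:
    """Write the fixture in pipeline-native form: per-locus FASTA, the ST
    and variant TSVs, and isolate metadata. Returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = fabricate_sequences(include_background)
    paths: dict[str, Path] = {}
    for locus, aln in ds.alignments.items():
        p = outdir / f"{locus}.fasta"
        write_locus_alignment(aln, p)
        paths[locus] = p
    for name in ("reference_profiles.tsv", "reference_variants.tsv"):
        dest = outdir / name
        dest.write_text(_data_path(name).read_text())
        paths[name] = dest
    meta = outdir / "metadata.tsv"
    with open(meta, "w") as fh:
        fh.write("isolate_id\tcomplex\tst\n")
        for row in ds.metadata:
            fh.write(f"{row['isolate_id']}\t{row['complex']}\t{row['st']}\n")
    paths["metadata"] = meta
    return paths
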