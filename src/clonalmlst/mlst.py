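"""MLST allele calling and sequence-type (ST) assignment.

Following standard MLST practice, each unique sequence at a locus receives
an integer allele identifier, and each unique tuple of allele identifiers
across the loci (in a fixed locus order) receives an ST number. Identifiers
are assigned consecutively from 1 in order of first appearance, so they are
reproducible for a given input order but carry no meaning beyond identity.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .alignio import LocusAlignment


class PipelineError(RuntimeError):
    """Raised when a pipeline stage cannot produce a usable result."""


@dataclass
class AlleleTable:
    """Alleles called at one locus.

    ``allele_seqs`` maps allele id (1-based, consecutive) to the aligned
    sequence; ``isolate_alleles`` maps each isolate to its allele id.
    """

    locus_name: str
    allele_seqs: dict[int, str]
    isolate_alleles: dict[str, int]

    @property
    def n_alleles(self) -> int:
        return len(self.allele_seqs)


@dataclass
class STProfile:
    """One sequence type: a unique allelic profile across all loci."""

    st_id: int
    alleles: tuple[int, ...]
    isolate_ids: list[str] = field(default_factory=list)

    @property
    def frequency(self) -> int:
        return len(self.isolate_ids)


def call_alleles(aln: LocusAlignment) -> AlleleTable:
    """Assign allele identifiers to the unique sequences of one locus.

    Exact string identity (sequences are already uppercased with U→T)
    defines an allele; gaps are ordinary characters, so sequences differing
    only by indels are distinct alleles. Ids run from 1 in order of first
    appearance.
    """
    allele_of_seq: dict[str, int] = {}
    allele_seqs: dict[int, str] = {}
    isolate_alleles: dict[str, int] = {}
    for isolate_id, seq in zip(aln.isolate_ids, aln.sequences):
        allele_id = allele_of_seq.get(seq)
        if allele_id is None:
            allele_id = len(allele_of_seq) + 1
            allele_of_seq[seq] = allele_id
            allele_seqs[allele_id] = seq
        isolate_alleles[isolate_id] = allele_id
    return AlleleTable(aln.locus_name, allele_seqs, isolate_alleles)


def assign_sts(
    tables: dict[str, AlleleTable], locus_order: list[str]
) -> tuple[list[STProfile], list[str]]:
    """Build ST profiles from per-locus allele tables.

    Isolates missing any locus are excluded from ST assignment and returned
    as the second element (they remain usable for per-locus diversity).
    ST ids are consecutive from 1 in order of first appearance.
    """
    missing_loci = [l for l in locus_order if l not in tables]
    if missing_loci:
        raise PipelineError(f"no allele table for loci: {missing_loci}")
    first = tables[locus_order[0]]
    candidate_isolates = list(first.isolate_alleles)
    excluded = [
        iso
        for iso in candidate_isolates
        if any(iso not in tables[l].isolate_alleles for l in locus_order)
    ]
    # isolates present at other loci but absent from the first are also excluded
    for locus in locus_order[1:]:
        for iso in tables[locus].isolate_alleles:
            if iso not in first.isolate_alleles and iso not in excluded:
                excluded.append(iso)
    typed = [i for i in candidate_isolates if i not in excluded]
    if not typed:
        raise PipelineError("no isolate is typed at every locus")

    profiles: dict[tuple[int, ...], STProfile] = {}
    for iso in typed:
        profile = tuple(tables[l].isolate_alleles[iso] for l in locus_order)
        st = profiles.get(profile)
        if st is None:
            st = STProfile(st_id=len(profiles) + 1, alleles=profile)
            profiles[profile] = st
        st.isolate_ids.append(iso)
    return list(profiles.values()), excluded


# ---------------------------------------------------------------------------
# TSV round-trip

def write_allele_table(table: AlleleTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["locus", "allele_id", "sequence"])
        for allele_id, seq in sorted(table.allele_seqs.items()):
            w.writerow([table.locus_name, allele_id, seq])


def write_isolate_alleles(table: AlleleTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["locus", "isolate_id", "allele_id"])
        for iso, allele_id in table.isolate_alleles.items():
            w.writerow([table.locus_name, iso, allele_id])


def read_allele_table(
    seq_path: str | Path, isolates_path: str | Path
) -> AlleleTable:
    allele_seqs: dict[int, str] = {}
    locus = None
    with open(seq_path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            locus = row["locus"]
            allele_seqs[int(row["allele_id"])] = row["sequence"]
    isolate_alleles: dict[str, int] = {}
    with open(isolates_path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            isolate_alleles[row["isolate_id"]] = int(row["allele_id"])
    if locus is None:
        raise ValueError(f"empty allele table {seq_path}")
    return AlleleTable(locus, allele_seqs, isolate_alleles)


def write_st_table(
    sts: list[STProfile], locus_order: list[str], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["st_id", *locus_order, "frequency", "isolates"])
        for st in sts:
            w.writerow([st.st_id, *st.alleles, st.frequency, ",".join(st.isolate_ids)])


def read_st_table(path: str | Path) -> tuple[list[STProfile], list[str]]:
    """Read an ST table; returns (profiles, locus_order)."""
    sts: list[STProfile] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        locus_order = header[1:-2]
        for row in reader:
            st_id = int(row[0])
            alleles = tuple(int(a) for a in row[1 : 1 + len(locus_order)])
            isolates = row[-1].split(",") if row[-1] else []
            sts.append(STProfile(st_id, alleles, isolates))
    return sts, locus_order
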