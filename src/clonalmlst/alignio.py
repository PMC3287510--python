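"""Per-locus alignment container and FASTA input.

Inputs are pre-aligned gene fragments, one FASTA per locus, with the record
id naming the host isolate the endosymbiont sequence came from. Sequences
are normalized to uppercase with U mapped to T; gaps (``-``) and ``N`` are
retained as alignment characters. IUPAC ambiguity codes are accepted but
flagged, since downstream allele calling treats them literally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

#: Unambiguous characters after normalization.
CANONICAL = set("ACGTN-")
#: IUPAC nucleotide ambiguity codes (degenerate bases other than N).
IUPAC_AMBIGUOUS = set("RYSWKMBDHV")
ALLOWED = CANONICAL | IUPAC_AMBIGUOUS


class AlignmentError(ValueError):
    """Raised for malformed alignments (ragged lengths, bad characters)."""


def normalize_sequence(seq: str) -> str:
    """Uppercase and map U (RNA convention) to T."""
    return seq.upper().replace("U", "T")


@dataclass
class LocusAlignment:
    """Aligned sequences for one locus across isolates.

    Attributes
    ----------
    locus_name : str
        Short locus label, e.g. ``"wsp"``.
    isolate_ids : list of str
        One id per row, unique within the locus.
    sequences : list of str
        Normalized sequences, all of identical length.
    ambiguous_isolates : set of str
        Isolates whose sequence contains IUPAC ambiguity codes.
    """

    locus_name: str
    isolate_ids: list[str]
    sequences: list[str]
    ambiguous_isolates: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AlignmentError(f"{self.locus_name}: alignment has no sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError(
                f"{self.locus_name}: unequal sequence lengths {sorted(lengths)}"
            )
        if self.length == 0:
            raise AlignmentError(f"{self.locus_name}: zero-length alignment")
        if len(set(self.isolate_ids)) != len(self.isolate_ids):
            dupes = {i for i in self.isolate_ids if self.isolate_ids.count(i) > 1}
            raise AlignmentError(
                f"{self.locus_name}: duplicate isolate ids {sorted(dupes)}"
            )
        if len(self.isolate_ids) != len(self.sequences):
            raise AlignmentError(f"{self.locus_name}: ids/sequences length mismatch")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    def sequence_of(self, isolate_id: str) -> str:
        return self.sequences[self.isolate_ids.index(isolate_id)]

    def subset(self, isolate_ids: Iterable[str]) -> "LocusAlignment":
        """Restrict to the given isolates, preserving their given order."""
        wanted = list(isolate_ids)
        missing = [i for i in wanted if i not in self.isolate_ids]
        if missing:
            raise KeyError(f"{self.locus_name}: isolates not in alignment: {missing}")
        return LocusAlignment(
            locus_name=self.locus_name,
            isolate_ids=wanted,
            sequences=[self.sequence_of(i) for i in wanted],
            ambiguous_isolates=self.ambiguous_isolates & set(wanted),
        )

    def drop(self, isolate_ids: Iterable[str]) -> "LocusAlignment":
        """Remove the given isolates (used for config-listed exclusions)."""
        dropped = set(isolate_ids)
        keep = [i for i in self.isolate_ids if i not in dropped]
        return self.subset(keep)


def read_locus_alignment(path: str | Path, locus_name: str | None = None) -> LocusAlignment:
    """Read one locus alignment from FASTA.

    Record ids are isolate ids. Raises :class:`AlignmentError` on ragged
    lengths (naming the offending record) and ``ValueError`` on empty files
    or characters outside the IUPAC alphabet.
    """
    path = Path(path)
    if locus_name is None:
        locus_name = path.stem
    ids: list[str] = []
    seqs: list[str] = []
    ambiguous: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        seq = normalize_sequence(str(record.seq))
        bad = set(seq) - ALLOWED
        if bad:
            raise ValueError(
                f"{locus_name}: record {record.id!r} contains characters "
                f"outside the IUPAC nucleotide alphabet: {sorted(bad)}"
            )
        if set(seq) & IUPAC_AMBIGUOUS:
            ambiguous.add(record.id)
        if seqs and len(seq) != len(seqs[0]):
            raise AlignmentError(
                f"{locus_name}: record {record.id!r} has length {len(seq)}, "
                f"expected {len(seqs[0])} (alignment is ragged)"
            )
        ids.append(record.id)
        seqs.append(seq)
    if not seqs:
        raise ValueError(f"{locus_name}: no FASTA records in {path}")
    return LocusAlignment(locus_name, ids, seqs, ambiguous)


def write_locus_alignment(aln: LocusAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for isolate_id, seq in zip(aln.isolate_ids, aln.sequences):
            fh.write(f">{isolate_id}\n{seq}\n")
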