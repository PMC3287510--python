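from pathlib import Path

import pytest

from clonalmlst.alignio import LocusAlignment

LOCI = ["wsp", "ftsZ", "groEL", "trmD"]


def make_alignment(seqs, locus="test", ids=None):
    if ids is None:
        ids = [f"iso{i + 1}" for i in range(len(seqs))]
    return LocusAlignment(locus, ids, [s.upper() for s in seqs])


@pytest.fixture
def write_fasta(tmp_path):
    def _write(records, name="locus.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records:
                fh.write(f">{rid}\n{seq}\n")
        return path

    return _write


@pytest.fixture(scope="session")
def fixture_dataset():
    from clonalmlst.fixture import fabricate_sequences

    return fabricate_sequences(include_background=False)


@pytest.fixture(scope="session")
def fixture_dataset_bg():
    from clonalmlst.fixture import fabricate_sequences

    return fabricate_sequences(include_background=True)
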