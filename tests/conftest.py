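import random

import pytest

from sdscan import synthetic_data as synth


@pytest.fixture(scope="session")
def locus_set():
    """One default five-isoform locus, shared across tests."""
    return synth.generate_locus_with_isoforms(seed=11)


@pytest.fixture()
def rng():
    return random.Random(20240917)


def make_fasta(tmp_path, records, name="seqs.fasta"):
    path = tmp_path / name
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")
    return path
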