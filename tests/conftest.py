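import numpy as np
import pytest

from ripscan import GenomeAssembly, IntervalSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_sequence(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


@pytest.fixture
def toy_assembly():
    """100 kb single-scaffold assembly with deterministic content."""
    rng = np.random.default_rng(7)
    return GenomeAssembly({"s1": random_sequence(rng, 100_000)})


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{seq}\n")
    return path


def write_gff3(path, rows):
    """rows: (scaffold, feature, start_1based, end_1based)"""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, (scaf, feat, s, e) in enumerate(rows):
            fh.write(f"{scaf}\t.\t{feat}\t{s}\t{e}\t.\t+\t.\tID=f{i}\n")
    return path


def write_bed(path, rows):
    with open(path, "w") as fh:
        for scaf, s, e in rows:
            fh.write(f"{scaf}\t{s}\t{e}\n")
    return path
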