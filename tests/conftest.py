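import numpy as np
import pytest

from taphage.genome_io import GenomeRecord


@pytest.fixture
def write_fasta_file(tmp_path):
    """Factory writing a FASTA file from (header, sequence) pairs."""

    def _write(entries, name="genomes.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for header, seq in entries:
                fh.write(f">{header}\n{seq}\n")
        return path

    return _write


@pytest.fixture
def random_rna():
    """Seeded generator of random ambiguity-free RNA strings."""
    rng = np.random.default_rng(20_240_001)

    def _draw(length, p=(0.25, 0.25, 0.25, 0.25)):
        return "".join(rng.choice(list("ACGU"), size=length, p=p))

    return _draw


@pytest.fixture
def make_record():
    def _make(seq, id="g1", **kwargs):
        return GenomeRecord(id=id, sequence=seq, **kwargs)

    return _make
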