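import numpy as np
import pytest

from barcodekit.seqio import Alignment, SampleMetadata, SequenceRecord


def make_alignment(seqs: dict[str, str], species: dict[str, str] | None = None):
    species = species or {}
    return Alignment(
        [
            SequenceRecord(id=k, seq=v, species=species.get(k, ""))
            for k, v in seqs.items()
        ]
    )


def make_metadata(species: dict[str, str], outgroup: str | None = None):
    return [
        SampleMetadata(
            sample_id=k, species=sp, is_outgroup=(sp == outgroup)
        )
        for k, sp in species.items()
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240925)


@pytest.fixture
def two_species_alignment():
    """Two species fixed A vs G at column 3, shared elsewhere."""
    seqs = {
        "x1": "ACATG",
        "x2": "ACATG",
        "y1": "ACGTG",
        "y2": "ACGTG",
    }
    species = {"x1": "spx", "x2": "spx", "y1": "spy", "y2": "spy"}
    return make_alignment(seqs, species), make_metadata(species)
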