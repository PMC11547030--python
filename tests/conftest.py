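import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # makes _oracles importable

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_genome():
    """The bundled aphid mitogenome annotation (no sequence)."""
    from mitocodon import load_reference_annotation

    return load_reference_annotation()


@pytest.fixture(scope="session")
def code5():
    from mitocodon import INVERTEBRATE_MITO

    return INVERTEBRATE_MITO


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def random_dna(rng):
    def make(length: int, at: float = 0.5) -> str:
        p = np.array([at / 2, at / 2, (1 - at) / 2, (1 - at) / 2])
        return "".join(rng.choice(list("ATGC"), size=length, p=p))

    return make


@pytest.fixture()
def genbank_file(tmp_path):
    """Write a small synthetic GenBank record and return its path."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
    from Bio.SeqRecord import SeqRecord

    def make(features, sequence="ATGC" * 25, name="SYNTH"):
        rec = SeqRecord(
            Seq(sequence),
            id=name,
            name=name,
            description="synthetic fixture",
            annotations={"molecule_type": "DNA", "topology": "circular"},
        )
        built = []
        for ftype, start, end, strand, quals in features:
            if end < start:  # wrap the origin via a join()
                loc = CompoundLocation(
                    [
                        SimpleLocation(start - 1, len(sequence), strand),
                        SimpleLocation(0, end, strand),
                    ]
                )
            else:
                loc = SimpleLocation(start - 1, end, strand)
            built.append(SeqFeature(loc, type=ftype, qualifiers=quals))
        rec.features = built
        path = tmp_path / f"{name}.gb"
        with open(path, "w") as fh:
            SeqIO.write(rec, fh, "genbank")
        return path

    return make
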