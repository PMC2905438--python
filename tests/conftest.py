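import numpy as np
import pytest

from wgdtiming.alignment_qc import CodonAlignment
from wgdtiming.io import DEFAULT_SPECIES_MAP, SequenceRecord


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def make_alignment():
    """Build a CodonAlignment from (id, gapped-sequence) pairs; species come
    from the default prefix rule (Cf_/Glyma/Mt/Vitis...)."""

    def build(*rows, family_id="fam0001"):
        records = [
            SequenceRecord(seq_id, DEFAULT_SPECIES_MAP.species(seq_id), seq)
            for seq_id, seq in rows
        ]
        return CodonAlignment(family_id, records)

    return build
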