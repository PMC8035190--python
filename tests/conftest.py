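import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from pequant.core_model import AmpliconSpec, EditSpec, PamMod, build_edited_allele
from pequant.read_processing import SequencedRead


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def point_edit_locus():
    """A 240-bp locus with a 1-bp A->G edit plus AGG->AAG PAM change."""
    gen = np.random.default_rng(42)
    seq = "".join(gen.choice(list("ACGT"), size=240))
    seq = seq[:120] + "A" + seq[121:]
    seq = seq[:122] + "AGG" + seq[125:]
    amplicon = AmpliconSpec(
        name="point_locus", sequence=seq, peg_nick=119, nick_sgrna_nick=179,
        pam_interval=(122, 125), uditas_primer_interval=(60, 80),
    )
    edit = EditSpec(
        edit_type="substitution", ref_interval=(120, 121), alt_segment="G",
        pam_mod=PamMod(position=123, ref="G", alt="A"), quant_window=(117, 126),
    )
    return amplicon, edit, build_edited_allele(amplicon, edit)


def make_read(bases: str, q: int = 35, read_id: str = "r", **kw) -> SequencedRead:
    return SequencedRead(
        read_id=read_id, bases=bases, quals=np.full(len(bases), q, dtype=np.int16), **kw
    )


@pytest.fixture
def read_factory():
    return make_read
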