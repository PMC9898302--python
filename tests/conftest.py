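import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from miredit.annotation import MatureMirna, MirnaAnnotation, Premirna
from miredit.synthetic_data import SimCohortDesign, make_reference


@pytest.fixture(scope="session")
def bundle8():
    """Shared 8-miRNA reference (mito + minus-strand + VCF-flagged hairpins)."""
    return make_reference(8, rng_seed=1)


@pytest.fixture
def four_stage_design():
    return SimCohortDesign(
        stages=("NORMAL", "CH", "CIRRHOSIS", "HCC"),
        samples_per_stage=2,
        depth_per_mirna=300,
        error_rate=0.01,
        rng_seed=11,
    )


@pytest.fixture
def toy_annotation():
    """Two hand-built hairpins: plus-strand and minus-strand."""
    plus = Premirna(
        id="pre-plus", contig="c1", start=10, end=70, strand="+", mito=False,
        matures=(MatureMirna("plus-3p", 20, 42),),
    )
    minus = Premirna(
        id="pre-minus", contig="c1", start=100, end=160, strand="-", mito=False,
        matures=(MatureMirna("minus-3p", 110, 132),),
    )
    return MirnaAnnotation([plus, minus])
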