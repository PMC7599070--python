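import numpy as np
import pandas as pd
import pytest

import holophos as hp

IDENTITY_DESIGN = hp.SilacDesign(
    columns={s: s for s in ("r2H1L", "r3H1L", "r2L1H", "r3L1H")})


@pytest.fixture
def identity_design():
    return IDENTITY_DESIGN


@pytest.fixture
def small_fasta(tmp_path):
    path = tmp_path / "seqs.fa"
    path.write_text(">p1 some description\nqqgkSSSTGNLLDKDDL\n"
                    ">p2\nDPAQSASRENLLEEQ\n")
    return path


@pytest.fixture
def planted_truth():
    """Small seeded proteome with 20 planted substrate sites."""
    _, truth = hp.gen_proteome(n_proteins=100, length=60,
                               n_substrates=20, seed=11)
    return truth
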