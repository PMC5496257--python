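import pytest

import equilnc as eq


@pytest.fixture(scope="session")
def default_dataset():
    """The standard synthetic transcriptome: ~2000 transcripts, seed 42."""
    return eq.generate(eq.SimConfig(seed=42))


@pytest.fixture(scope="session")
def default_result(default_dataset):
    ds = default_dataset
    return eq.run_pipeline(ds.records, ds.expr, ds.genes, ds.protein_db,
                           ds.motifs, ds.lnc_db)


@pytest.fixture(scope="session")
def small_dataset():
    """A ten-fold smaller transcriptome for cheaper structural tests."""
    cfg = eq.SimConfig(seed=7, n_coding=40, n_true_lncrna=80, n_utr_fragment=30,
                       n_short=25, n_low_expression=25, n_proteins=20)
    return eq.generate(cfg)
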