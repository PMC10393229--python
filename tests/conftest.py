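import numpy as np
import pandas as pd
import pytest

from npxtools import synth
from npxtools.qc import NPXMatrix


@pytest.fixture
def small_config():
    """A fast, fully featured synthetic study configuration."""
    return synth.SynthConfig(
        n_plhiv_disc=60,
        n_hc_disc=40,
        n_plhiv_repl=80,
        n_hc_repl=40,
        n_proteins=200,
        n_true_dep=40,
        n_low_detect=20,
        n_species=40,
        n_linked_pairs=10,
        n_outlier_plhiv_disc=2,
        n_outlier_hc_disc=1,
        n_outlier_plhiv_repl=1,
        n_outlier_hc_repl=1,
        n_random_gene_sets=8,
        n_planted_gene_sets=4,
        n_cvd_drivers=4,
        seed=7,
    )


def toy_matrix(values, lods=None, panels=None, proteins=None, sample_qc=None):
    """Build a small NPXMatrix from a samples x assays array."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    assays = [f"A{j}" for j in range(p)]
    samples = [f"S{i}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "protein": proteins if proteins is not None else assays,
            "panel": panels if panels is not None else ["p1"] * p,
            "lod": lods if lods is not None else [-np.inf] * p,
        },
        index=pd.Index(assays, name="assay_id"),
    )
    vdf = pd.DataFrame(values, index=pd.Index(samples, name="sample_id"), columns=assays)
    sq = None
    if sample_qc is not None:
        sq = pd.DataFrame(sample_qc, index=vdf.index)
    return NPXMatrix(vdf, meta, sq)
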