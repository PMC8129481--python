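import numpy as np
import pandas as pd
import pytest

from lipoproteome import IntensityMatrix


def make_matrix(values, peptide_counts=None, n_pairs=None):
    """Build an IntensityMatrix from a proteins x samples array.

    Columns are laid out LPA_1..LPA_k, LDL_1..LDL_k with pairing S1..Sk.
    ``values`` may contain NaN for missing cells.
    """
    values = np.asarray(values, dtype=float)
    n_prot, n_samp = values.shape
    if n_pairs is None:
        n_pairs = n_samp // 2
    assert n_samp == 2 * n_pairs
    sample_ids = pd.Index(
        [f"LPA_{j + 1}" for j in range(n_pairs)] + [f"LDL_{j + 1}" for j in range(n_pairs)],
        name="sample_id",
    )
    protein_ids = pd.Index([f"P{i}" for i in range(n_prot)], name="protein_id")
    if peptide_counts is None:
        peptide_counts = np.full(n_prot, 3)
    return IntensityMatrix(
        intensities=pd.DataFrame(values, index=protein_ids, columns=sample_ids),
        condition=pd.Series(["LPA"] * n_pairs + ["LDL"] * n_pairs, index=sample_ids),
        pair_id=pd.Series([f"S{j + 1}" for j in range(n_pairs)] * 2, index=sample_ids),
        peptide_counts=pd.Series(peptide_counts, index=protein_ids),
    )


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(0)
    vals = 2.0 ** rng.normal(25, 2, size=(30, 12))
    return make_matrix(vals)
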