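import numpy as np
import pandas as pd
import pytest

from macsig.io import FeatureTable


def make_table(
    values,
    condition_of_sample=None,
    feature_id=None,
    protein_id=None,
    phospho=False,
    **meta_overrides,
):
    """Build a FeatureTable from a raw matrix with sensible metadata defaults.

    ``condition_of_sample`` defaults to two conditions A/B split evenly over
    the columns.  Metadata columns can be overridden with arrays via
    keyword arguments (e.g. ``multiplicity=[1, 2]``).
    """
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    if condition_of_sample is None:
        samples = [f"A_{j + 1}" for j in range(m // 2)] + [
            f"B_{j + 1}" for j in range(m - m // 2)
        ]
        condition_of_sample = {s: s.split("_")[0] for s in samples}
    else:
        samples = list(condition_of_sample)
    feature_id = feature_id or [f"f{i + 1}" for i in range(n)]
    protein_id = protein_id or list(feature_id)
    meta = pd.DataFrame(
        {
            "peptide_count": 2,
            "multiplicity": 1.0 if phospho else np.nan,
            "localization_prob": 0.9 if phospho else np.nan,
            "residue": "S1" if phospho else "",
            "is_contaminant": False,
            "is_decoy": False,
            "is_phosphopeptide": phospho,
        },
        index=range(n),
    )
    for key, val in meta_overrides.items():
        meta[key] = val
    return FeatureTable(values, feature_id, protein_id, samples, condition_of_sample, meta)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
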