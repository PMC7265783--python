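import numpy as np
import pandas as pd
import pytest

from proteopath.io import ExpressionStudy


def study_from_matrix(X, proteins=None, lineage="lin", system="patient", start=0):
    """Wrap a raw matrix into a validated single-lineage ExpressionStudy."""
    X = np.asarray(X, dtype=float)
    if proteins is None:
        proteins = [f"P{i}" for i in range(X.shape[1])]
    vals = pd.DataFrame(X, index=[f"S{i + start}" for i in range(len(X))], columns=proteins)
    ann = pd.DataFrame({"system": system, "lineage": lineage}, index=vals.index)
    return ExpressionStudy(vals, ann)


@pytest.fixture
def small_study():
    rng = np.random.default_rng(0)
    return study_from_matrix(rng.standard_normal((30, 4)))


@pytest.fixture
def tmp_tsv_factory(tmp_path):
    def write(name, text):
        p = tmp_path / name
        p.write_text(text)
        return p

    return write
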