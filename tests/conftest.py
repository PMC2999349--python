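import numpy as np
import pandas as pd
import pytest

from pcnkit.matrix import ExpressionMatrix


def make_matrix(values, sample_groups, probe_ids=None, flags=None, scale_state="raw"):
    """Small ExpressionMatrix from a 2-D list/array and a sample->group dict."""
    values = np.asarray(values, dtype=float)
    samples = list(sample_groups)
    probes = probe_ids or [f"g{i}" for i in range(values.shape[0])]
    intens = pd.DataFrame(values, index=pd.Index(probes, name="probe_id"), columns=samples)
    if flags is None:
        flags = pd.DataFrame("P", index=intens.index, columns=intens.columns)
    else:
        flags = pd.DataFrame(flags, index=intens.index, columns=intens.columns)
    dose = pd.Series([sample_groups[s] for s in samples], index=pd.Index(samples, name="sample_id"))
    return ExpressionMatrix(intens, flags, dose, scale_state=scale_state)


@pytest.fixture
def tiny_matrix():
    """5 probes x 4 samples, two groups, all flags present."""
    rng = np.random.default_rng(0)
    groups = {"c1": "control", "c2": "control", "t1": "dose", "t2": "dose"}
    return make_matrix(rng.uniform(10, 1000, (5, 4)), groups)
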