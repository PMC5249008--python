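import numpy as np
import pandas as pd
import pytest

from coactive import EMConfig
from coactive.coactivation import binarize, define_maturity_groups
from coactive.mixture import build_ternary_matrix, log2cpm
from coactive.synthetic import MarkerPlan, SyntheticSpec, generate


@pytest.fixture(scope="session")
def planted_dataset():
    """One planted maturity study: counts, truth, and the fitted pipeline stages."""
    spec = SyntheticSpec(marker_plan=MarkerPlan(), seed=7)
    counts, truth = generate(spec)
    logexpr = log2cpm(counts)
    ternary, fits = build_ternary_matrix(logexpr, EMConfig(seed=11))
    binary = binarize(ternary)
    groups = define_maturity_groups(binary)
    return {
        "spec": spec,
        "counts": counts,
        "truth": truth,
        "logexpr": logexpr,
        "ternary": ternary,
        "fits": fits,
        "binary": binary,
        "groups": groups,
    }


@pytest.fixture()
def small_counts():
    """Tiny genes x cells count matrix for I/O round trips."""
    return pd.DataFrame(
        np.array([[0, 5, 2], [3, 0, 0], [1, 1, 4]]),
        index=["gA", "gB", "gC"],
        columns=["c1", "c2", "c3"],
    )
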