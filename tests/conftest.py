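import warnings

import numpy as np
import pandas as pd
import pytest

from decomix import ExpressionMatrix
from decomix.synthetic import recovery_benchmark_truth, truth_basis


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


def make_matrix(values, genes=None, samples=None, ann=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    expr = pd.DataFrame(values, index=genes, columns=samples)
    annotations = pd.DataFrame(ann, index=samples) if ann is not None else pd.DataFrame()
    return ExpressionMatrix(expr, annotations)


@pytest.fixture(scope="session")
def benchmark_truth():
    """Clean 20-cell-type, 317-gene ground truth for solver benchmarks."""
    return recovery_benchmark_truth(seed=3, n_genes=317)


@pytest.fixture(scope="session")
def benchmark_basis(benchmark_truth):
    return truth_basis(benchmark_truth)


@pytest.fixture(scope="session")
def separated_basis():
    """Well-separated reference: independent log-normal cell-type profiles
    (the conditioning regime of real signature matrices)."""
    from decomix import BasisMatrix

    rng = np.random.default_rng(29)
    cell_types = [f"ct{j}" for j in range(8)]
    values = pd.DataFrame(
        np.exp(rng.normal(5, 0.7, size=(150, 8))),
        index=[f"g{i}" for i in range(150)],
        columns=cell_types,
    )
    return BasisMatrix(values, {c: c for c in cell_types}, basis_id="separated")


@pytest.fixture(scope="session")
def toy_annotated():
    """Tiny annotated two-lineage compendium for effect-size oracles."""
    rng = np.random.default_rng(17)
    n_genes, per = 30, 5
    types = {"A": "L1", "B": "L1", "C": "L2", "D": "L2"}
    cols, ann = {}, {}
    base = np.exp(rng.normal(4, 0.5, n_genes))
    for ct, lin in types.items():
        shift = rng.normal(0, 0.3, n_genes)
        for r in range(per):
            sid = f"{ct}{r}"
            cols[sid] = base * np.exp(shift) + rng.normal(0, 5, n_genes).clip(-base * 0.5)
            ann[sid] = {"cell_type": ct, "lineage": lin}
    expr = pd.DataFrame(cols, index=[f"g{i}" for i in range(n_genes)]).clip(lower=0)
    return ExpressionMatrix(expr, pd.DataFrame(ann).T)
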