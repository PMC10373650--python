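import numpy as np
import pandas as pd
import pytest

from smfe import DirectedNetwork, ExpressionMatrix


@pytest.fixture
def tiny_expression(tmp_path):
    """3-gene x 2-sample TSV on disk."""
    path = tmp_path / "expr.tsv"
    path.write_text("gene\ts1\ts2\ng1\t1.0\t2.0\ng2\t3.0\t4.0\ng3\t5.0\t6.0\n")
    return path


@pytest.fixture
def star_network():
    """A -> {B, C, D}."""
    return DirectedNetwork([("A", "B"), ("A", "C"), ("A", "D")])


@pytest.fixture
def toy5():
    """Fixed 5-gene toy: 4 reference samples, one case sample, and a small
    directed network.  Values are printed constants so every intermediate
    quantity can be recomputed by hand or by the literal oracle."""
    reference = ExpressionMatrix(pd.DataFrame(
        {
            "r1": [2.0, 1.0, 4.0, 0.5, 3.0],
            "r2": [4.0, 3.0, 1.0, 2.5, 3.5],
            "r3": [6.0, 2.0, 2.0, 1.5, 1.0],
            "r4": [3.0, 5.0, 3.0, 0.0, 2.0],
        },
        index=["gA", "gB", "gC", "gD", "gE"],
    ))
    case = pd.Series([5.0, 4.0, 0.5, 3.0, 2.5], index=["gA", "gB", "gC", "gD", "gE"])
    net = DirectedNetwork([
        ("gA", "gB"), ("gA", "gC"), ("gA", "gD"),
        ("gB", "gA"), ("gB", "gE"),
        ("gC", "gD"), ("gC", "gE"),
        ("gD", "gA"),
        ("gE", "gA"), ("gE", "gB"), ("gE", "gC"),
    ])
    return reference, case, net


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_expression(rng, genes, n_samples, prefix="s"):
    """Nonnegative random expression matrix fixture helper."""
    values = rng.gamma(shape=2.0, scale=2.0, size=(len(genes), n_samples))
    cols = [f"{prefix}{i}" for i in range(n_samples)]
    return ExpressionMatrix(pd.DataFrame(values, index=list(genes), columns=cols))
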