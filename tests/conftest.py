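import numpy as np
import pandas as pd
import pytest

from csdnet import ExpressionMatrix, TypedNetwork, assemble_network


@pytest.fixture
def small_matrix():
    return ExpressionMatrix(
        gene_ids=["G1", "G2", "G3"],
        sample_ids=["s1", "s2"],
        values=np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
        condition_label="demo",
    )


@pytest.fixture
def tsv_file(tmp_path):
    path = tmp_path / "expr.tsv"
    path.write_text(
        "gene\ts1\ts2\n"
        "G1\t1.0\t2.0\n"
        "G2\t3.0\t4.0\n"
        "G3\t5.0\t6.0\n"
    )
    return path


@pytest.fixture
def gct_file(tmp_path):
    path = tmp_path / "expr.gct"
    path.write_text(
        "#1.2\n"
        "3\t2\n"
        "Name\tDescription\ts1\ts2\n"
        "G1\tna\t1.0\t2.0\n"
        "G2\tna\t3.0\t4.0\n"
        "G3\tna\t5.0\t6.0\n"
    )
    return path


def typed_frame(rows):
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "type", "score"])


@pytest.fixture
def mixed_network() -> TypedNetwork:
    """Node X carries 2 C-links and 1 S-link; Y carries 1 D-link."""
    return assemble_network(typed_frame([
        ("X", "A", "C", 5.0),
        ("X", "B", "C", 4.0),
        ("X", "D1", "S", 3.0),
        ("Y", "Z", "D", 6.0),
    ]))
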