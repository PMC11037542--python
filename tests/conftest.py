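import numpy as np
import pytest

from hypermir.io import (AssociationMatrix, read_dag_table)


def write_lines(path, rows):
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return path


@pytest.fixture
def dag_from_rows(tmp_path):
    """Build a DiseaseDAG from (disease, tree_number) rows."""

    def build(rows):
        path = tmp_path / "dag.tsv"
        write_lines(path, rows)
        return read_dag_table(path)

    return build


@pytest.fixture
def sibling_dag(dag_from_rows):
    """Root r with two child diseases d1, d2 (the classic sibling toy)."""
    return dag_from_rows([("r", "C04"), ("d1", "C04.100"),
                          ("d2", "C04.200")])


@pytest.fixture
def chain_dag(dag_from_rows):
    """g <- p <- d chain (d at depth 2 below g)."""
    return dag_from_rows([("g", "C04"), ("p", "C04.100"),
                          ("d", "C04.100.100")])


def random_association(rng, M=6, D=5, density=0.3):
    T = (rng.random((M, D)) < density).astype(np.int8)
    # guarantee both classes exist
    T[0, 0] = 1
    T[1, 1] = 0
    return AssociationMatrix([f"m{i}" for i in range(M)],
                             [f"d{j}" for j in range(D)], T)
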