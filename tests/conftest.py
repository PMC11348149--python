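import numpy as np
import pandas as pd
import pytest

from aopmoa.aop_knowledge import AOPEvent, AOPNetwork
from aopmoa.expression_io import ExpressionStudy


@pytest.fixture
def chain_aop() -> AOPNetwork:
    """MIE1 -> KE1 -> AO1 with small annotations."""
    events = [
        AOPEvent("MIE1", "MIE", gene_set=frozenset({"m1", "m2"})),
        AOPEvent("KE1", "KE", gene_set=frozenset({"g1", "g2"})),
        AOPEvent("AO1", "AO", gene_set=frozenset({"a1", "a2"})),
    ]
    return AOPNetwork(events, [("MIE1", "KE1"), ("KE1", "AO1")])


def write_aop_files(tmp_path, rows, annotation):
    """Write an edge table + annotation table; returns the two paths."""
    edge_path = tmp_path / "edges.tsv"
    ann_path = tmp_path / "ann.tsv"
    pd.DataFrame(
        rows,
        columns=["upstream_event_id", "downstream_event_id", "upstream_type", "downstream_type"],
    ).to_csv(edge_path, sep="\t", index=False)
    pd.DataFrame(annotation, columns=["event_id", "gene"]).to_csv(ann_path, sep="\t", index=False)
    return edge_path, ann_path


def make_study(matrix: np.ndarray, genes, n_ctrl: int, n_exp: int, study_id="s") -> ExpressionStudy:
    cols = [f"c{i}" for i in range(n_ctrl)] + [f"e{i}" for i in range(n_exp)]
    meta = pd.DataFrame(
        {
            "condition": ["control"] * n_ctrl + ["exposed"] * n_exp,
            "exposure": ["x"] * (n_ctrl + n_exp),
            "dose": [0.0] * n_ctrl + [1.0] * n_exp,
            "time": [24.0] * (n_ctrl + n_exp),
        },
        index=pd.Index(cols, name="sample_id"),
    )
    mat = pd.DataFrame(matrix, index=pd.Index(genes, name="gene"), columns=cols)
    return ExpressionStudy(matrix=mat, sample_meta=meta, study_id=study_id)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
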