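import numpy as np
import pandas as pd
import pytest

from fibreomics.decay import build_timegrid
from fibreomics.qc import ProteinMatrix


@pytest.fixture(scope="session")
def default_grid():
    return build_timegrid(5, 90, 10, 390)


def make_matrix(values: dict, annotations: dict | None = None, scale="log2", genes=None):
    """Build a small ProteinMatrix from {protein: {fibre: value}}."""
    df = pd.DataFrame(values).T
    fibres = list(df.columns)
    if annotations is None:
        annotations = {
            f: {"participant": f"p{i + 1}", "condition": "control"}
            for i, f in enumerate(fibres)
        }
    annot = pd.DataFrame(annotations).T
    annot.index.name = "fibre_id"
    if genes is None:
        genes = pd.Series({p: p for p in df.index}, name="gene")
    else:
        genes = pd.Series(genes, name="gene")
    return ProteinMatrix(values=df, annotations=annot, genes=genes, scale=scale)


@pytest.fixture
def tiny_pg_files(tmp_path):
    """A 3-protein x 2-fibre PG matrix file with one missing cell."""
    pg = tmp_path / "pg.tsv"
    pg.write_text(
        "Protein.Group\tGenes\tf1\tf2\n"
        "P1\tGENA\t100.5\t200.25\n"
        "P2\tGENB\t\t50.0\n"
        "P3\tMYH7\t300.0\t400.0\n"
    )
    annot = tmp_path / "annot.csv"
    annot.write_text(
        "fibre_id,participant,condition\nf1,p1,control\nf2,p2,control\n"
    )
    return pg, annot
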