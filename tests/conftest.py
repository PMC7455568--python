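import numpy as np
import pandas as pd
import pytest

from difsel import ExpressionMatrix, SimulationConfig, simulate_study

DESIGN = [
    ("WT_sham_w2", "WT", "sham", 2), ("WT_DMM_w2", "WT", "DMM", 2),
    ("WT_sham_w4", "WT", "sham", 4), ("WT_DMM_w4", "WT", "DMM", 4),
    ("KO_sham_w2", "KO", "sham", 2), ("KO_DMM_w2", "KO", "DMM", 2),
    ("KO_sham_w4", "KO", "sham", 4), ("KO_DMM_w4", "KO", "DMM", 4),
]
SAMPLE_IDS = [s for s, *_ in DESIGN]


def make_meta() -> pd.DataFrame:
    return pd.DataFrame(
        [{"sample_id": s, "genotype": g, "condition": c, "week": w}
         for s, g, c, w in DESIGN]
    ).set_index("sample_id")


def make_matrix(values: dict[str, list[float]]) -> ExpressionMatrix:
    """Build an 8-sample ExpressionMatrix from gene -> 8 TPMs (design order)."""
    df = pd.DataFrame(values, index=SAMPLE_IDS).T
    df.index.name = "gene"
    return ExpressionMatrix(values=df.astype(float), meta=make_meta()).validate()


def write_study(tmp_path, matrix: ExpressionMatrix):
    mpath = tmp_path / "matrix.tsv"
    spath = tmp_path / "samples.tsv"
    matrix.values.to_csv(mpath, sep="\t", index_label="gene")
    matrix.meta.reset_index().to_csv(spath, sep="\t", index=False)
    return mpath, spath


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic study (2000 genes, seed 7) shared across tests."""
    return simulate_study(SimulationConfig())


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
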