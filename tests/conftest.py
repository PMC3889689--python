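import numpy as np
import pandas as pd
import pytest

from tfdirect.models import CountMatrix, GeneModel, ScaffoldSet


@pytest.fixture
def tiny_scaffolds() -> ScaffoldSet:
    return ScaffoldSet({"s1": 50_000, "s2": 30_000, "tiny": 8_000})


@pytest.fixture
def tiny_genes() -> list[GeneModel]:
    return [
        GeneModel("gA.L", "s1", 1_000, 3_000, "+", 1_500, human_ortholog="HA"),
        GeneModel("gA.S", "s1", 20_000, 22_000, "-", 2_000, human_ortholog="HA"),
        GeneModel("gB.L", "s2", 5_000, 9_000, "+", 3_200, human_ortholog="HB"),
    ]


def make_count_matrix(rows: dict[str, list[int]], n_ctrl: int = 2, n_kd: int = 2) -> CountMatrix:
    """Counts from per-gene lists ordered [ctrl..., kd...]."""
    samples = [f"ctrl_{i + 1}" for i in range(n_ctrl)] + [f"kd_{i + 1}" for i in range(n_kd)]
    group = {s: ("control" if s.startswith("ctrl") else "knockdown") for s in samples}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    return CountMatrix(df, group)


def equal_library_matrix(rows: dict[str, list[int]], n_ctrl: int = 2, n_kd: int = 2) -> CountMatrix:
    """Counts padded with a filler gene so every column sum is equal; library
    equalization is then the identity, which keeps hand-computed
    expectations exact."""
    df = pd.DataFrame.from_dict(rows, orient="index")
    total = int(df.sum(axis=0).max()) + 10
    filler = [total - int(c) for c in df.sum(axis=0)]
    rows = dict(rows)
    rows["__filler__"] = filler
    return make_count_matrix(rows, n_ctrl=n_ctrl, n_kd=n_kd)
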