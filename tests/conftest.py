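import io

import numpy as np
import pandas as pd
import pytest

from ratiosig.io_tables import GroupedData, QuantTable, read_quant_table


@pytest.fixture
def small_quant_tsv() -> str:
    return (
        "protein_id\tcontrol\ttreated\n"
        "P1\t100\t400\n"
        "P2\t50\t50\n"
        "P3\t10\tNA\n"
    )


@pytest.fixture
def small_quant_table(small_quant_tsv) -> QuantTable:
    return read_quant_table(io.StringIO(small_quant_tsv))


@pytest.fixture
def abc_groups() -> GroupedData:
    """Three small groups: A and B close, C far away (ANOVA + LSD fixture)."""
    return GroupedData({
        "A": np.array([1.0, 2.0, 3.0]),
        "B": np.array([2.0, 3.0, 4.0]),
        "C": np.array([10.0, 11.0, 12.0]),
    })


@pytest.fixture
def normal_ratio_sample() -> np.ndarray:
    rng = np.random.default_rng(42)
    return rng.standard_normal(50_000)
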