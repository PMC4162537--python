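import numpy as np
import pytest

from mirdx.matrix import ExpressionMatrix, SampleRecord, SampleTable


@pytest.fixture
def small_counts() -> ExpressionMatrix:
    """3 miRNAs × 2 samples of raw NGS counts."""
    return ExpressionMatrix(
        values=np.array([[10.0, 0.0], [5.0, 3.0], [0.0, 7.0]]),
        mirna_ids=["mir-a", "mir-b", "mir-c"],
        sample_ids=["s1", "s2"],
        platform="ngs",
        scale="raw",
    )


@pytest.fixture
def design_table() -> SampleTable:
    """14 tumor + 6 control samples, the study's design shape."""
    records = [SampleRecord(f"T{i:02d}", "tumor") for i in range(1, 15)]
    records += [SampleRecord(f"N{i:02d}", "control") for i in range(1, 7)]
    return SampleTable(records)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20140912)
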