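import numpy as np
import pytest

import heatcraft as hc


@pytest.fixture
def tiny_sheet(tmp_path):
    """The canonical 3x3 sheet: header row/column around a 2x2 data block."""
    p = tmp_path / "tiny.tsv"
    p.write_text("g\ts1\ts2\na\t1\t2\nb\t3\t4\n")
    return p


@pytest.fixture
def small_table():
    return hc.ExpressionTable(
        values=np.array([[1.0, 2.0], [3.0, 5.0]]),
        row_labels=["a", "b"],
        col_labels=["s1", "s2"],
    )


@pytest.fixture
def default_lut():
    return hc.build_lut(hc.DEFAULT_TRICOLOR)
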