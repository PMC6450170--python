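import numpy as np
import pandas as pd
import pytest

from targettriage import io as ttio


@pytest.fixture
def small_matrix():
    values = pd.DataFrame(
        np.array([[10.0, 10.2, 8.0, 8.1],
                  [7.0, 7.1, 7.05, 7.02],
                  [5.0, 5.1, 6.4, 6.5]]),
        index=["GENEA", "GENEB", "GENEC"],
        columns=["S1", "S2", "S3", "S4"])
    groups = {"S1": "case", "S2": "case", "S3": "control", "S4": "control"}
    return ttio.ExpressionMatrix(values=values, groups=groups).validate()


@pytest.fixture
def chain_network():
    net = ttio.InteractionNetwork()
    net.add_edge("A", "B", "positive")
    net.add_edge("B", "C", "negative")
    net.add_edge("C", "D", "unspecified")
    return net.validate()
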