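import numpy as np
import pytest

from hebbseq import markov


@pytest.fixture(scope="session")
def asym3_chain():
    """3-state chain whose forward and backward conditionals differ clearly."""
    P = np.array([[0.1, 0.8, 0.1], [0.5, 0.1, 0.4], [0.2, 0.3, 0.5]])
    return markov.TransitionMatrix(P)


@pytest.fixture(scope="session")
def gaussian_22():
    """19-state circulant Gaussian matrix with 2.2-bit rows."""
    sigma = markov.solve_sigma_for_entropy(2.2)
    return markov.make_gaussian_tm(19, sigma)
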