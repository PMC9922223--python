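import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def enum_match_fraction(x, y, l, r, n_templates):
    """Exhaustive double-loop template matching: the independent oracle for
    match_fraction (strict < r, Chebyshev distance)."""
    count = 0
    for i in range(n_templates):
        for j in range(n_templates):
            if max(abs(x[i + k] - y[j + k]) for k in range(l)) < r:
                count += 1
    return count / n_templates**2


def enum_cse(x, y, m, r, convention="paper"):
    """Enumeration-based cross-sample entropy oracle."""
    import math

    L = len(x)
    if convention == "paper":
        p_m = enum_match_fraction(x, y, m, r, L - m)
        p_m1 = enum_match_fraction(x, y, m + 1, r, L - m - 1)
    else:
        p_m = enum_match_fraction(x, y, m, r, L - m)
        p_m1 = enum_match_fraction(x, y, m + 1, r, L - m)
    if p_m == 0 or p_m1 == 0:
        return None
    return -math.log(p_m1 / p_m)
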