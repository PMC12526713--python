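"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: the entropy statistics
are computed template by template, straight from their definitions (the
outer template loop is explicit; only the inner Chebyshev row is
vectorised so the oracle stays usable at N = 500).
"""

import math

import numpy as np


def apen_bruteforce(x, m, r):
    """ApEn = Phi_m - Phi_{m+1}, self-matches included (Pincus)."""
    x = np.asarray(x, dtype=float)
    n = x.size

    def phi(k):
        templates = np.array([x[i:i + k] for i in range(n - k + 1)])
        total = 0.0
        for ti in templates:
            d = np.abs(templates - ti).max(axis=1)
            total += math.log((d <= r).sum() / len(templates))
        return total / len(templates)

    return phi(m) - phi(m + 1)


def sampen_bruteforce(x, m, r):
    """SampEn = -log(A/B) over the first N-m templates, no self-matches."""
    x = np.asarray(x, dtype=float)
    n = x.size
    tm = np.array([x[i:i + m] for i in range(n - m)])
    tm1 = np.array([x[i:i + m + 1] for i in range(n - m)])
    a = b = 0
    for i in range(len(tm) - 1):
        b += int((np.abs(tm[i + 1:] - tm[i]).max(axis=1) <= r).sum())
        a += int((np.abs(tm1[i + 1:] - tm1[i]).max(axis=1) <= r).sum())
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def summary_bruteforce(x):
    """Mean/CV/kurtosis/IQR straight from the defining formulas."""
    x = np.asarray(x, dtype=float)
    n = x.size
    mean = x.sum() / n
    s = math.sqrt(((x - mean) ** 2).sum() / (n - 1))
    cv = s / mean
    kurt = ((x - mean) ** 4).sum() / (n * s ** 4)
    q1, q3 = np.percentile(x, [25, 75])
    return mean, cv, kurt, q3 - q1
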