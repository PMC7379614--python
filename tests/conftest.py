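import numpy as np
import pandas as pd
import pytest

from rifdecay import AnnotatedCounts


def bruteforce_window(t, v, min_points=3):
    """Brute-force window chooser, independent of the fitting code.

    Enumerates every window anchored at the latest maximum, computes R² of
    the log-linear fit via the plain correlation coefficient, and returns
    (t0_time, end_time) of the argmax-R² window (ties to the longer
    window; 2-point fallback when no >=3-point window exists).
    """
    t = np.asarray(t, float)
    v = np.asarray(v, float)
    i0 = int(np.flatnonzero(v == v.max())[-1])
    ends = [j for j in range(i0 + 1, len(t)) if j - i0 + 1 >= min_points]
    fallback = not ends
    if fallback:
        ends = list(range(i0 + 1, len(t)))
    best, best_key = None, None
    for j in ends:
        if fallback:
            key = (-np.inf, j)
        else:
            r = np.corrcoef(t[i0 : j + 1], np.log(v[i0 : j + 1]))[0, 1]
            key = (r * r, j)
        if best_key is None or key > best_key:
            best, best_key = j, key
    return float(t[i0]), float(t[best])


@pytest.fixture
def window_oracle():
    return bruteforce_window


@pytest.fixture
def paired_tables():
    """Build paired mRNA/rRNA AnnotatedCounts from {feature: [counts]} dicts."""

    def build(mrna_rows, rrna_rows, cols=("0", "5", "40", "60"), pre=None):
        m = pd.DataFrame.from_dict(mrna_rows, orient="index", columns=list(cols))
        r = pd.DataFrame.from_dict(rrna_rows, orient="index", columns=list(cols))
        return (
            AnnotatedCounts(m, "mRNA", pre),
            AnnotatedCounts(r, "rRNA", pre),
        )

    return build
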