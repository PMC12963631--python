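"""Independent oracles used by the test suite.

These deliberately avoid the library code paths they check.
"""

import numpy as np

from scforge.physchem import PKA_TABLES


def grid_pi(seq: str, step: float = 0.0005) -> float:
    """Dense-grid isoelectric point: evaluate the Henderson-Hasselbalch
    net charge on a pH grid (vectorised, independent of the bisection
    implementation) and take the |charge|-minimising pH, averaged across
    the configured pKa tables."""
    ph = np.arange(0.0, 14.0 + step, step)
    values = []
    for table in PKA_TABLES.values():
        pos = 1.0 / (1.0 + 10 ** (ph - table["Nterm"]))
        neg = 1.0 / (1.0 + 10 ** (table["Cterm"] - ph))
        for aa in "KRH":
            pos = pos + seq.count(aa) / (1.0 + 10 ** (ph - table[aa]))
        for aa in "DECY":
            neg = neg + seq.count(aa) / (1.0 + 10 ** (table[aa] - ph))
        charge = pos - neg
        values.append(ph[int(np.argmin(np.abs(charge)))])
    return float(np.mean(values))


def ols_fit(pairs):
    """Closed-form simple OLS, independent of numpy.polyfit."""
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    xm, ym = x.mean(), y.mean()
    slope = float(((x - xm) * (y - ym)).sum() / ((x - xm) ** 2).sum())
    intercept = float(ym - slope * xm)
    return slope, intercept
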