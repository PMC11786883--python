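"""Independent brute-force oracles used by the test suite.

Deliberately written as plain Python loops, sharing no code with the
package's vectorized implementations.
"""

import math


def brute_force_life_table(m):
    """Loop-based period life table; returns (q, l, L, e) as lists.

    Same conventions as the package documents: q = 1 - exp(-m), deaths at
    mid-year, open-ended closure with L = l/m at the top age.
    """
    n = len(m)
    if m[-1] <= 0:
        raise ValueError("closure rate must be positive")
    q = [1.0 - math.exp(-rate) for rate in m]
    q[-1] = 1.0
    l = [1.0]
    for x in range(n - 1):
        l.append(l[x] * math.exp(-m[x]))
    L = []
    for x in range(n):
        if x == n - 1:
            L.append(l[x] / m[x])
        else:
            L.append(l[x] - 0.5 * l[x] * q[x])
    e = []
    for x in range(n):
        total = sum(L[x:])
        e.append(total / l[x] if l[x] > 0 else 0.0)
    return q, l, L, e


def log_interp_rr(grid, rr, intake):
    """Piecewise log-linear interpolation with clamping, by hand."""
    if intake <= grid[0]:
        return rr[0]
    if intake >= grid[-1]:
        return rr[-1]
    for i in range(len(grid) - 1):
        if grid[i] <= intake <= grid[i + 1]:
            w = (intake - grid[i]) / (grid[i + 1] - grid[i])
            return math.exp(
                (1.0 - w) * math.log(rr[i]) + w * math.log(rr[i + 1])
            )
    raise AssertionError("unreachable")
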