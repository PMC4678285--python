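"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the Mann-Whitney oracle
enumerates every group assignment, the Holm oracle executes the step-down
rule literally, and the gEUD oracle is a direct weighted power mean.
"""

from itertools import combinations

import numpy as np


def mann_whitney_exact_p(x, y) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration of assignments."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n, total = len(x), len(pooled)

    def u_stat(xs, ys):
        return sum(1.0 for a in xs for b in ys if a > b) + sum(
            0.5 for a in xs for b in ys if a == b
        )

    u_obs = u_stat(x, y)
    mu = n * (total - n) / 2.0
    dev_obs = abs(u_obs - mu)
    count = 0
    n_comb = 0
    idx = np.arange(total)
    for chosen in combinations(idx, n):
        mask = np.zeros(total, dtype=bool)
        mask[list(chosen)] = True
        u = u_stat(pooled[mask], pooled[~mask])
        if abs(u - mu) >= dev_obs - 1e-12:
            count += 1
        n_comb += 1
    return count / n_comb


def holm_reject(p_values: dict, alpha: float = 0.05) -> dict:
    """Literal step-down Holm: sort ascending, compare p_(i) to alpha/(k-i+1),
    stop at the first failure."""
    items = sorted(p_values.items(), key=lambda kv: kv[1])
    k = len(items)
    decisions = {label: False for label in p_values}
    for i, (label, p) in enumerate(items):
        if p <= alpha / (k - i):
            decisions[label] = True
        else:
            break
    return decisions


def bonferroni_reject(p_values: dict, alpha: float = 0.05) -> dict:
    return {label: p <= alpha / len(p_values) for label, p in p_values.items()}


def geud_direct(doses, fractions, n) -> float:
    return float(sum(v * d ** (1.0 / n) for d, v in zip(doses, fractions)) ** n)
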