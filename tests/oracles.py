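"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: enumeration and direct
tallies only.
"""

import itertools

import numpy as np
from scipy import stats


def perm_welch_p(a, b, mode: str = "mid") -> float:
    """Exact permutation p-value of the two-sided Welch t-test.

    Enumerates all C(n1+n2, n1) group assignments of the pooled sample.
    ``mode='mid'`` uses the mid-p convention (half weight on ties with the
    observed statistic), appropriate when comparing the discrete permutation
    null to a continuous reference; ``mode='inclusive'`` counts ties fully.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n1, n2 = len(a), len(b)
    idx = np.array(list(itertools.combinations(range(n1 + n2), n1)))
    first = pooled[idx]
    mask = np.ones((len(idx), n1 + n2), dtype=bool)
    np.put_along_axis(mask, idx, False, axis=1)
    second = pooled[np.nonzero(mask)[1]].reshape(len(idx), n2)

    def welch_t(x, y):
        return (x.mean(1) - y.mean(1)) / np.sqrt(
            x.var(1, ddof=1) / x.shape[1] + y.var(1, ddof=1) / y.shape[1])

    t_all = np.abs(welch_t(first, second))
    t_obs = abs(stats.ttest_ind(a, b, equal_var=False).statistic)
    greater = np.mean(t_all > t_obs + 1e-9)
    ties = np.mean(np.abs(t_all - t_obs) <= 1e-9)
    return float(greater + (0.5 if mode == "mid" else 1.0) * ties)


def logrank_by_hand(time, event, in_first):
    """O/E/V accounting over event times by direct risk-set tallies."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    in_first = np.asarray(in_first, bool)
    O1 = E1 = V = 0.0
    for t in sorted(set(time[event == 1])):
        n = (time >= t).sum()
        n1 = (in_first & (time >= t)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & in_first).sum()
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return O1, E1, V


def mask_circularity(mask: np.ndarray) -> float:
    """4*pi*area/perimeter^2 from a boolean mask, perimeter by edge count.

    Brute-force boundary-edge count (exposed faces of foreground pixels);
    an independent, cruder estimate than the package's Crofton perimeter.
    """
    area = int(mask.sum())
    padded = np.pad(mask, 1)
    edges = 0
    for ax, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        edges += int((padded & ~np.roll(padded, shift, axis=ax)).sum())
    return 4 * np.pi * area / edges ** 2
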