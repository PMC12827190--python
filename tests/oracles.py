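"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as literally as possible from the definitions —
plain loops, no vectorization, no reuse of package code — so agreement with
the package is evidence, not tautology.
"""

from __future__ import annotations

import math


def brute_force_detect(values, rate, min_distance_s=0.5, n=2.0):
    """Literal two-stage detection: local maxima, spacing, amplitude band.

    Plateau maxima report their first sample; spacing keeps the larger peak
    (earlier on ties); the amplitude band uses population statistics over the
    spacing-enforced candidates and is applied in a single pass.
    """
    values = list(values)
    n_samp = len(values)
    # interior local maxima, plateau -> first sample
    maxima = []
    i = 1
    while i < n_samp - 1:
        if values[i] > values[i - 1]:
            j = i
            while j + 1 < n_samp and values[j + 1] == values[j]:
                j += 1
            if j + 1 < n_samp and values[j + 1] < values[j]:
                maxima.append(i)
            i = j + 1
        else:
            i += 1
    # greedy spacing: largest first, earlier wins ties
    min_dist = max(int(round(min_distance_s * rate)), 1)
    order = sorted(maxima, key=lambda k: (-values[k], k))
    kept = []
    for k in order:
        if all(abs(k - p) >= min_dist for p in kept):
            kept.append(k)
    kept.sort()
    if not kept:
        return []
    amps = [values[k] for k in kept]
    mu = sum(amps) / len(amps)
    sigma = math.sqrt(sum((a - mu) ** 2 for a in amps) / len(amps))
    lo, hi = mu - n * sigma, mu + n * sigma
    return [k for k in kept if lo <= values[k] <= hi]


def naive_mean(xs):
    return sum(xs) / len(xs)


def naive_sdnn(xs):
    mu = naive_mean(xs)
    return math.sqrt(sum((x - mu) ** 2 for x in xs) / len(xs))


def naive_rmssd(xs):
    diffs = [xs[i + 1] - xs[i] for i in range(len(xs) - 1)]
    return math.sqrt(sum(d * d for d in diffs) / len(diffs))


def naive_percentile(xs, q):
    """Linear-interpolation percentile (the numpy default definition)."""
    s = sorted(xs)
    pos = (len(s) - 1) * q / 100.0
    lo = math.floor(pos)
    hi = math.ceil(pos)
    if lo == hi:
        return s[lo]
    return s[lo] + (s[hi] - s[lo]) * (pos - lo)


def naive_rmse(a, b):
    return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)) / len(a))


def naive_mae(a, b):
    return sum(abs(x - y) for x, y in zip(a, b)) / len(a)


def naive_bland_altman(m, i):
    d = [x - y for x, y in zip(m, i)]
    mean = naive_mean(d)
    sd = math.sqrt(sum((x - mean) ** 2 for x in d) / len(d))
    return mean, mean + 1.96 * sd, mean - 1.96 * sd


def exhaustive_dtw(a, b):
    """Minimum over *all* monotone warping paths, by explicit recursion.

    Local cost is the squared difference; the optimal accumulated cost is
    returned as its square root. Feasible only for short series.
    """
    n, m = len(a), len(b)
    best = [math.inf]

    def walk(i, j, acc):
        acc = acc + (a[i] - b[j]) ** 2
        if acc >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = acc
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, acc)
        if i + 1 < n:
            walk(i + 1, j, acc)
        if j + 1 < m:
            walk(i, j + 1, acc)

    walk(0, 0, 0.0)
    return math.sqrt(best[0])
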