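"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected result with the most literal possible
method (explicit loops, exhaustive enumeration, textbook sums of squares)
so it shares no code with the implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_curves(values, min_diff=5.0):
    """Adjacent-extrema curve enumeration, coded independently.

    Returns a list of (upper, lower, angle) tuples before region/rank
    labelling, following the same stated rules: strict interior extrema,
    iterated smallest-first deletion of adjacent pairs differing by less
    than min_diff, endpoint augmentation, adjacent pairing, and removal of
    sub-threshold curves.
    """
    v = list(map(float, values))
    n = len(v)
    extrema = []
    for i in range(1, n - 1):
        left, mid, right = v[i - 1], v[i], v[i + 1]
        if mid > left and mid > right:
            extrema.append(i)
        if mid < left and mid < right:
            extrema.append(i)

    while True:
        if len(extrema) < 2:
            break
        pair_diffs = []
        for a, b in zip(extrema, extrema[1:]):
            pair_diffs.append(abs(v[a] - v[b]))
        smallest = min(pair_diffs)
        if smallest >= min_diff:
            break
        where = pair_diffs.index(smallest)
        extrema = extrema[:where] + extrema[where + 2 :]

    ends = sorted(set(extrema) | {0, n - 1})
    curves = []
    for a, b in zip(ends, ends[1:]):
        angle = abs(v[a] - v[b])
        if angle >= min_diff:
            curves.append((a, b, angle))
    return curves


def brute_force_local_maxima(channel, radius):
    """All cells that are >= every cell within a Chebyshev radius."""
    h, w = channel.shape
    peaks = []
    for y in range(h):
        for x in range(w):
            ok = True
            for dy in range(-radius, radius + 1):
                for dx in range(-radius, radius + 1):
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < h and 0 <= xx < w and channel[yy, xx] > channel[y, x]:
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                peaks.append((y, x))
    return peaks


def exhaustive_grouping(candidates, n_groups):
    """Optimal candidate-to-vertebra assignment by exhaustive search.

    candidates: list of objects with corner_type in 0..3 and
    estimated_center; requires exactly n_groups candidates per corner
    type.  Tries every combination of per-type permutations and returns
    the grouping (list of lists of candidates) minimising the summed
    within-group center dispersion.
    """
    by_type = {j: [c for c in candidates if c.corner_type == j] for j in range(4)}
    for j in range(4):
        if len(by_type[j]) != n_groups:
            raise ValueError("oracle needs exactly n_groups candidates per corner type")

    best, best_cost = None, np.inf
    base = by_type[0]
    for perm1 in itertools.permutations(range(n_groups)):
        for perm2 in itertools.permutations(range(n_groups)):
            for perm3 in itertools.permutations(range(n_groups)):
                cost = 0.0
                groups = []
                for g in range(n_groups):
                    members = [
                        base[g],
                        by_type[1][perm1[g]],
                        by_type[2][perm2[g]],
                        by_type[3][perm3[g]],
                    ]
                    centers = np.array([m.estimated_center for m in members])
                    cost += float(((centers - centers.mean(axis=0)) ** 2).sum())
                    groups.append(members)
                if cost < best_cost:
                    best_cost, best = cost, groups
    return best


def hand_anova_icc(matrix):
    """ICC(2,1) and ICC(3,1) from explicit textbook sums of squares."""
    x = np.asarray(matrix, dtype=float)
    n, k = x.shape
    grand = x.sum() / (n * k)
    ss_subject = 0.0
    for i in range(n):
        ss_subject += k * (x[i].mean() - grand) ** 2
    ss_rater = 0.0
    for j in range(k):
        ss_rater += n * (x[:, j].mean() - grand) ** 2
    ss_total = 0.0
    for i in range(n):
        for j in range(k):
            ss_total += (x[i, j] - grand) ** 2
    ss_error = ss_total - ss_subject - ss_rater
    msr = ss_subject / (n - 1)
    msc = ss_rater / (k - 1)
    mse = ss_error / ((n - 1) * (k - 1))
    icc21 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    icc31 = (msr - mse) / (msr + (k - 1) * mse)
    return icc21, icc31, (msr, msc, mse)
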