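"""Brute-force reference implementations used to cross-check the package's
robust estimators.  Everything here is written with explicit loops and
sorting, independent of the vectorised code under test."""

from __future__ import annotations

import math
import statistics

SN_CONSTANT = 1.1926
SN_SMALL_N = {2: 0.743, 3: 1.851, 4: 0.954, 5: 1.351,
              6: 0.993, 7: 1.198, 8: 1.005, 9: 1.131}


def _lomed(values):
    s = sorted(values)
    return s[(len(s) + 1) // 2 - 1]


def _himed(values):
    s = sorted(values)
    return s[len(s) // 2]


def sn_oracle(x):
    n = len(x)
    row_medians = []
    for i in range(n):
        diffs = [abs(x[i] - x[j]) for j in range(n) if j != i]
        row_medians.append(_himed(diffs))
    if n <= 9:
        c = SN_SMALL_N[n]
    elif n % 2:
        c = n / (n - 0.9)
    else:
        c = 1.0
    return SN_CONSTANT * c * _lomed(row_medians)


def mad_oracle(x, constant=1.4826):
    med = statistics.median(x)
    return constant * statistics.median([abs(v - med) for v in x])


def sn_correlation_oracle(x, y):
    mx, my = mad_oracle(x), mad_oracle(y)
    medx, medy = statistics.median(x), statistics.median(y)
    zx = [(v - medx) / (math.sqrt(2) * mx) for v in x]
    zy = [(v - medy) / (math.sqrt(2) * my) for v in y]
    u = [a + b for a, b in zip(zx, zy)]
    v = [a - b for a, b in zip(zx, zy)]
    su2 = sn_oracle(u) ** 2
    sv2 = sn_oracle(v) ** 2
    r = (su2 - sv2) / (su2 + sv2)
    return max(-1.0, min(1.0, r))


def theil_sen_oracle(x, y):
    slopes = []
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            if x[i] != x[j]:
                slopes.append((y[j] - y[i]) / (x[j] - x[i]))
    slope = statistics.median(slopes)
    intercept = statistics.median([yi - slope * xi for xi, yi in zip(x, y)])
    return slope, intercept


def hodges_lehmann_oracle(x):
    walsh = []
    n = len(x)
    for i in range(n):
        for j in range(i, n):
            walsh.append((x[i] + x[j]) / 2.0)
    return statistics.median(walsh)


def ned_oracle(x, y, s):
    return math.sqrt(sum((xi - yi) ** 2 / si ** 2
                         for xi, yi, si in zip(x, y, s)))


def benjamini_hochberg_oracle(pvalues):
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        adj = min(prev, pvalues[i] * m / rank_from_top)
        adjusted[i] = adj
        prev = adj
    return adjusted


def studentized_oracle(slope, intercept, sn_res, x, y):
    n = len(x)
    xbar = sum(x) / n
    ss = sum((xi - xbar) ** 2 for xi in x)
    out = []
    for xi, yi in zip(x, y):
        resid = yi - slope * xi - intercept
        h = 1.0 / n + (xi - xbar) ** 2 / ss
        out.append(resid / (sn_res * math.sqrt(1.0 - h)))
    return out


def count_reads_oracle(panel, reads):
    """Per-read maximal-overlap assignment; reads are (chrom, start, end)."""
    counts = {a.id: 0 for a in panel.amplicons}
    for chrom, start, end in reads:
        best, best_ov, best_start = None, 0, None
        for a in panel.amplicons:
            if a.chrom != chrom:
                continue
            ov = min(end, a.end) - max(start, a.start)
            if ov <= 0:
                continue
            if ov > best_ov or (ov == best_ov and a.start < best_start):
                best, best_ov, best_start = a.id, ov, a.start
        if best is not None:
            counts[best] += 1
    return counts
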