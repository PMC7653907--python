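"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plainly as possible (explicit day-by-day and
cell-by-cell scans, exact rational arithmetic) and shares no code with the
package internals it checks.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np


def brute_force_events(sst, clim_mean, pc90, doy, min_duration=5, max_gap=1):
    """Day-by-day scan for heatwave events in a single-cell series.

    Returns a list of (start, end, duration, max_intensity, cumulative)
    tuples implementing: runs of consecutive days strictly above the
    day-of-year threshold, keep runs of at least ``min_duration`` days, then
    merge chronologically adjacent kept runs separated by at most
    ``max_gap`` days.  Metrics use anomalies about the climatological mean
    over the merged span.  NaN days count as below threshold.
    """
    n = len(sst)
    runs = []
    cur = None
    for t in range(n):
        v = sst[t]
        th = pc90[doy[t] - 1]
        above = np.isfinite(v) and v > th
        if above and cur is None:
            cur = t
        elif not above and cur is not None:
            runs.append((cur, t - 1))
            cur = None
    if cur is not None:
        runs.append((cur, n - 1))

    kept = [(s, e) for s, e in runs if e - s + 1 >= min_duration]
    merged = []
    for s, e in kept:
        if merged and s - merged[-1][1] - 1 <= max_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))

    out = []
    for s, e in merged:
        best = -np.inf
        cum = 0.0
        for t in range(s, e + 1):
            a = sst[t] - clim_mean[doy[t] - 1]
            if np.isfinite(a):
                cum += a
                if a > best:
                    best = a
        out.append((s, e, e - s + 1, best, cum))
    return out


def flood_fill_components(mask, connectivity=8, wrap_longitude=True):
    """Connected components of a 2-D boolean mask via explicit BFS.

    Returns a frozenset of frozensets of (i, j) cells — label-permutation
    free, for direct comparison with any labeling implementation.
    """
    nlat, nlon = mask.shape
    if connectivity == 8:
        offs = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
                (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        offs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for i0 in range(nlat):
        for j0 in range(nlon):
            if not mask[i0, j0] or seen[i0, j0]:
                continue
            stack = [(i0, j0)]
            seen[i0, j0] = True
            comp = []
            while stack:
                i, j = stack.pop()
                comp.append((i, j))
                for di, dj in offs:
                    ii = i + di
                    jj = j + dj
                    if ii < 0 or ii >= nlat:
                        continue
                    if wrap_longitude:
                        jj %= nlon
                    elif jj < 0 or jj >= nlon:
                        continue
                    if mask[ii, jj] and not seen[ii, jj]:
                        seen[ii, jj] = True
                        stack.append((ii, jj))
            comps.append(frozenset(comp))
    return frozenset(comps)


def exact_binomial_tail(k, n, p0=Fraction(1, 2)):
    """P(X >= k) for X ~ Binomial(n, p0), exact rational summation."""
    p0 = Fraction(p0)
    total = Fraction(0)
    for j in range(k, n + 1):
        c = Fraction(1)
        for m in range(j):          # n choose j built up term by term
            c = c * (n - m) / (m + 1)
        total += c * p0 ** j * (1 - p0) ** (n - j)
    return float(total)
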