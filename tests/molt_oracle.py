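"""Independent brute-force oracle for the incrementing-threshold molt scan.

A deliberately plain per-day state machine, coded separately from the library
implementation: for each threshold in order it enumerates every maximal
qualifying run by walking the days one by one.
"""

import numpy as np


def _day_class(pf5, excluded, i, thr):
    if excluded[i]:
        return "bad"
    v = pf5[i]
    if np.isnan(v):
        return "undef"
    return "good" if v < thr else "bad"


def _maximal_runs(pf5, excluded, thr, max_gap=2):
    """All maximal runs of good days, bridging at most ``max_gap`` undefined days."""
    n = len(pf5)
    runs = []
    i = 0
    while i < n:
        if _day_class(pf5, excluded, i, thr) != "good":
            i += 1
            continue
        last_good = i
        gap = 0
        k = i + 1
        while k < n:
            c = _day_class(pf5, excluded, k, thr)
            if c == "good":
                last_good = k
                gap = 0
            elif c == "undef":
                gap += 1
                if gap > max_gap:
                    break
            else:
                break
            k += 1
        runs.append((i, last_good))
        i = last_good + 1
    return runs


def oracle_find_molt(dates, pf5, step=0.0002, min_days=30, cap=0.01, excluded_ranges=()):
    """Return (start_date, end_date, threshold) or None.

    Exhaustive scan: thresholds step, 2*step, ..., cap in order; at the first
    threshold with a qualifying run (>= min_days calendar days), take the
    longest (earliest on ties) and extend it over the containing sub-cap run.
    """
    pf5 = np.asarray(pf5, dtype=float)
    n = len(pf5)
    excluded = np.zeros(n, dtype=bool)
    for a, b in excluded_ranges:
        excluded |= (dates >= a) & (dates <= b)
    n_steps = int(round(cap / step))
    for k in range(1, n_steps + 1):
        thr = k * step
        qualifying = [(a, b) for a, b in _maximal_runs(pf5, excluded, thr)
                      if b - a + 1 >= min_days]
        if not qualifying:
            continue
        best = max(qualifying, key=lambda r: (r[1] - r[0], -r[0]))
        for a, b in _maximal_runs(pf5, excluded, cap):
            if a <= best[0] and b >= best[1]:
                best = (a, b)
                break
        return dates[best[0]], dates[best[1]], thr
    return None


def random_activity_series(rng, n_days=240):
    """A random daily prop_flight5 series with low spells, gaps and exclusions."""
    pf5 = rng.uniform(0.0, 0.05, size=n_days)
    for _ in range(int(rng.integers(0, 3))):
        s = int(rng.integers(0, n_days - 10))
        length = int(rng.integers(10, 60))
        pf5[s:s + length] = rng.uniform(0.0, 0.004, size=len(pf5[s:s + length]))
    pf5[rng.random(n_days) < 0.08] = np.nan
    excluded = []
    if rng.random() < 0.3:
        s = int(rng.integers(0, n_days - 5))
        excluded.append((s, min(n_days - 1, s + int(rng.integers(1, 20)))))
    return pf5, excluded
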