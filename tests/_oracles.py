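"""Independent brute-force reference implementations used only by tests.

Deliberately written with plain Python loops, ``statistics`` and ``np.interp``
so they share no code path with the package's vectorized implementations.
"""

import statistics

import numpy as np


def oracle_grid(day_numbers, values):
    """Daily grid with linear interpolation; returns (grid_days, vals, observed)."""
    day_numbers = np.asarray(day_numbers)
    grid = np.arange(day_numbers[0], day_numbers[-1] + 1)
    vals = np.interp(grid, day_numbers, np.asarray(values, dtype=float))
    observed = np.isin(grid, day_numbers)
    return grid, vals, observed


def oracle_rot(vals, d):
    """index[t] = vals[t] - vals[t-d] for t >= d, else None."""
    out = [None] * len(vals)
    for t in range(d, len(vals)):
        out[t] = vals[t] - vals[t - d]
    return out


def oracle_macd(vals, ns, nl):
    out = [None] * len(vals)
    for t in range(nl - 1, len(vals)):
        short = sum(vals[t - ns + 1: t + 1]) / ns
        long = sum(vals[t - nl + 1: t + 1]) / nl
        out[t] = short - long
    return out


def oracle_cusum(vals, d, c, direction, floor=1e-6):
    out = [None] * len(vals)
    s = 0.0
    for t in range(d, len(vals)):
        window = list(vals[t - d: t])
        mu = sum(window) / d
        sd = statistics.stdev(window)
        z = (vals[t] - mu) / max(sd, floor)
        if direction == "decrease":
            s = min(0.0, s + z + c)
        else:
            s = max(0.0, s + z - c)
        out[t] = s
    return out


def oracle_index_on_observed(day_numbers, values, algo, direction="increase", **kw):
    """Full oracle pipeline: interpolate, compute, keep observed days."""
    grid, vals, observed = oracle_grid(day_numbers, values)
    if algo == "rot":
        out = oracle_rot(vals, kw["d"])
    elif algo == "macd":
        out = oracle_macd(vals, kw["ns"], kw["nl"])
    else:
        out = oracle_cusum(vals, kw["d"], kw["c"], direction)
    days, idx = [], []
    for g, o, v in zip(grid, observed, out):
        if o and v is not None:
            days.append(int(g))
            idx.append(v)
    return np.array(days), np.array(idx)
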