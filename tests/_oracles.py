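"""Independent brute-force oracles used only by the test suite.

These are deliberately naive (loops, sets, hand formulas) and share no code
with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def naive_filter(clones: list[tuple[tuple, int]], min_count: int, keep_fraction: float):
    """Two-stage filter on (key, count) pairs by explicit enumeration."""
    survivors = [(k, c) for k, c in clones if c >= min_count]
    survivors.sort(key=lambda kc: (-kc[1], kc[0]))
    n_keep = math.ceil(keep_fraction * len(survivors))
    return survivors[:n_keep]


def naive_overlap_percent(ref_keys: list, query_keys: list) -> float:
    shared = 0
    for k in set(ref_keys):
        if k in set(query_keys):
            shared += 1
    return 100.0 * shared / len(set(ref_keys))


def naive_track_mass(ref: list[tuple[tuple, int]], target: dict, k: int) -> float:
    """Summary mass of the top-k reference clones in a target frequency map."""
    ranked = sorted(ref, key=lambda kc: (-kc[1], kc[0]))[:k]
    return sum(target.get(key, 0.0) for key, _ in ranked)


def naive_km(times, events):
    """Hand product-limit table: list of (time, survival) at event times."""
    order = np.argsort(times)
    times, events = np.asarray(times, float)[order], np.asarray(events, int)[order]
    out, s = [], 1.0
    for t in np.unique(times):
        at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        if d > 0:
            s *= 1.0 - d / at_risk
            out.append((float(t), s))
    return out


def naive_logrank_stat(times, events, group1_mask) -> float:
    """Chi-square log-rank statistic from the hand hypergeometric table."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    g1 = np.asarray(group1_mask, bool)
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & g1).sum())
        d = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & g1).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return o_minus_e**2 / var


def permutation_logrank_p(times, events, group1_mask, n_perm: int, rng) -> float:
    """Permutation reference distribution of the log-rank statistic.

    Vectorized over permutations: at each event time the observed and
    expected group-1 events depend only on the permuted label vector, so the
    per-time tallies reduce to matrix products.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    g1 = np.asarray(group1_mask, bool)
    obs = naive_logrank_stat(times, events, g1)

    event_times = np.unique(times[events == 1])
    at_risk = times[None, :] >= event_times[:, None]              # (T, n)
    died = (times[None, :] == event_times[:, None]) & (events == 1)  # (T, n)
    n_t = at_risk.sum(axis=1).astype(float)
    d_t = died.sum(axis=1).astype(float)

    labels = np.tile(g1, (n_perm, 1))
    for row in labels:
        rng.shuffle(row)
    n1_t = labels @ at_risk.T.astype(float)                       # (B, T)
    d1_t = labels @ died.T.astype(float)
    frac = n1_t / n_t
    o_minus_e = (d1_t - d_t * frac).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_t = d_t * frac * (1 - frac) * (n_t - d_t) / np.maximum(n_t - 1, 1)
    var = var_t.sum(axis=1)
    stat = np.where(var > 0, o_minus_e**2 / var, 0.0)
    return float(np.mean(stat >= obs - 1e-12))
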