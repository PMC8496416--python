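"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain, loop-based enumeration, deliberately
sharing no code with the package's vectorized implementations.
"""

import math

import numpy as np


def median_sigma_oracle(values):
    """sigma = sqrt(median((v - median v)^2)), finite values only."""
    v = [x for x in values if math.isfinite(x)]
    med = float(np.median(v))
    return math.sqrt(float(np.median([(x - med) ** 2 for x in v])))


def runs_oracle(mask):
    """All maximal runs of True as (start, end) inclusive pairs."""
    runs = []
    start = None
    for i, m in enumerate(list(mask) + [False]):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i - 1))
            start = None
    return runs


def saccade_intervals_oracle(
    t,
    v_left,
    v_right,
    eta_left,
    eta_right,
    min_duration_ms,
    min_separation_ms,
    binocular_required,
    rate_hz,
    start=0,
    end=None,
):
    """Exhaustive enumeration of supra-threshold runs with the overlap,
    duration, and separation rules applied step by step.  Returns a list of
    (i_start, i_end) inclusive index pairs."""
    n = len(t)
    end = n if end is None else end
    dt_ms = 1000.0 / rate_hz
    min_samples = max(1, math.ceil(min_duration_ms / dt_ms - 1e-9))

    def eye_runs(v, eta):
        mask = []
        for i in range(n):
            ok = start <= i < end and math.isfinite(v[i]) and abs(v[i]) > eta
            mask.append(ok)
        return [r for r in runs_oracle(mask) if r[1] - r[0] + 1 >= min_samples]

    rl = eye_runs(v_left, eta_left)
    rr = eye_runs(v_right, eta_right)

    def overlap(a, b):
        return a[0] <= b[1] and b[0] <= a[1]

    if binocular_required:
        kept = [r for r in rl if any(overlap(r, s) for s in rr)]
        kept += [r for r in rr if any(overlap(r, s) for s in rl)]
    else:
        kept = rl + rr

    if not kept:
        return []
    kept = sorted(kept)
    merged = [list(kept[0])]
    for a, b in kept[1:]:
        if a <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    events = [merged[0]]
    for a, b in merged[1:]:
        if t[a] - t[events[-1][1]] < min_separation_ms:
            events[-1][1] = b
        else:
            events.append([a, b])
    return [tuple(e) for e in events]


def blink_dilation_oracle(t, lost, buffer_ms):
    """Set dilation of track-lost runs by the buffer, sample by sample."""
    n = len(t)
    invalid = [False] * n
    for a, b in runs_oracle(lost):
        lo, hi = t[a] - buffer_ms, t[b] + buffer_ms
        for i in range(n):
            if lo <= t[i] <= hi:
                invalid[i] = True
    return invalid


def weibull_oracle(x, m, w):
    """Zero-asymptote cumulative Weibull, written straight from its form."""
    c = math.log(-math.log(0.05)) - math.log(-math.log(0.95))
    return 1.0 - math.exp(math.log(0.5) * math.exp(c * (math.log(x) - m) / w))


def quest_posterior_oracle(ladder, slopes, prior, trials):
    """Dense product-of-likelihoods posterior over the (threshold, slope)
    grid after a sequence of (contrast, seen) trials."""
    nt, ns = len(ladder), len(slopes)
    c = math.log(-math.log(0.05)) - math.log(-math.log(0.95))
    post = [[prior[j][k] for k in range(ns)] for j in range(nt)]
    for contrast, seen in trials:
        for j in range(nt):
            for k in range(ns):
                p = weibull_oracle(contrast, math.log(ladder[j]), c / slopes[k])
                post[j][k] *= p if seen else (1.0 - p)
    total = sum(sum(row) for row in post)
    return [[post[j][k] / total for k in range(ns)] for j in range(nt)]


def quest_selection_oracle(ladder, slopes, posterior):
    """Expected posterior entropy for each candidate contrast, enumerated
    outcome by outcome; returns (expected_entropies, argmin_contrast)."""
    c = math.log(-math.log(0.05)) - math.log(-math.log(0.95))
    nt, ns = len(ladder), len(slopes)

    def entropy(p):
        return -sum(q * math.log(q) for row in p for q in row if q > 0)

    ehs = []
    for x in ladder:
        seen = [
            [
                posterior[j][k]
                * weibull_oracle(x, math.log(ladder[j]), c / slopes[k])
                for k in range(ns)
            ]
            for j in range(nt)
        ]
        p_seen = sum(sum(row) for row in seen)
        not_seen = [
            [posterior[j][k] - seen[j][k] for k in range(ns)] for j in range(nt)
        ]
        eh = 0.0
        if p_seen > 0:
            eh += p_seen * entropy(
                [[v / p_seen for v in row] for row in seen]
            )
        if p_seen < 1:
            eh += (1 - p_seen) * entropy(
                [[v / (1 - p_seen) for v in row] for row in not_seen]
            )
        ehs.append(eh)
    best = min(range(len(ladder)), key=lambda i: (ehs[i], i))
    return ehs, ladder[best]


def psychometric_grid_mle_oracle(table, m_lo, m_hi, w_lo, w_hi, n_m=121, n_w=61):
    """Dense grid argmax of the product-binomial log-likelihood."""
    best = (-math.inf, None, None)
    for m in np.linspace(m_lo, m_hi, n_m):
        for w in np.geomspace(w_lo, w_hi, n_w):
            ll = 0.0
            for x, n, k in zip(table.contrast, table.n_presented, table.n_seen):
                p = min(max(weibull_oracle(x, m, w), 1e-12), 1 - 1e-12)
                ll += k * math.log(p) + (n - k) * math.log(1 - p)
            if ll > best[0]:
                best = (ll, m, w)
    return best
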