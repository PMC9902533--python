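"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — pure-Python loops, direct
formula evaluation, bisection — and shares no code path with the
package implementations it checks.
"""

from __future__ import annotations

import math


def lee_filter_naive(series, window_n, sigma0):
    """Per-index evaluation of the Lee filter formula with explicit loops."""
    x = [float(v) for v in series]
    n = len(x)
    out = []
    for i in range(n):
        lo = max(0, i - window_n)
        hi = min(n, i + window_n + 1)
        window = x[lo:hi]
        m = sum(window) / len(window)
        var = sum((v - m) ** 2 for v in window) / len(window)
        gain = var / (var + sigma0 * sigma0) if sigma0 != 0 else 1.0
        out.append(m + (x[i] - m) * gain)
    return out


def ipt_bursts_naive(trace, params):
    """Maximal-run scan over Lee-filtered inter-photon gaps, pure Python.

    Returns a list of (first_photon_index, last_photon_index, n_photons).
    """
    ts = list(trace.timestamps)
    if len(ts) < 2:
        return []
    ipts = [float(ts[i + 1] - ts[i]) for i in range(len(ts) - 1)]
    thr_ticks = int(params.ipt_threshold / trace.tick_resolution)
    sigma0_ticks = params.sigma0 / trace.tick_resolution
    filtered = lee_filter_naive(ipts, params.lee_window_n, sigma0_ticks)
    bursts = []
    i = 0
    n_gaps = len(filtered)
    while i < n_gaps:
        if filtered[i] <= thr_ticks:
            j = i
            while j + 1 < n_gaps and filtered[j + 1] <= thr_ticks:
                j += 1
            n_phot = (j - i + 1) + 1
            if n_phot >= params.min_photons:
                bursts.append((i, j + 1, n_phot))
            i = j + 1
        else:
            i += 1
    return bursts


def intensity_bursts_naive(counts, sd_multiplier):
    """Direct threshold scan over bin counts; returns (first_bin, last_bin, total)."""
    n = len(counts)
    mean = sum(counts) / n
    var = sum((c - mean) ** 2 for c in counts) / n
    threshold = mean + sd_multiplier * math.sqrt(var)
    bursts = []
    i = 0
    while i < n:
        if counts[i] > threshold:
            j = i
            while j + 1 < n and counts[j + 1] > threshold:
                j += 1
            bursts.append((i, j, sum(counts[i:j + 1])))
            i = j + 1
        else:
            i += 1
    return bursts


def mean_sd_two_pass(values):
    """Two-pass sample mean/SD (n-1 denominator); SD 0 for a single value."""
    n = len(values)
    m = sum(values) / n
    if n < 2:
        return m, 0.0
    return m, math.sqrt(sum((v - m) ** 2 for v in values) / (n - 1))


def equilibrium_bisection(P, A, Kd, tol=1e-15):
    """Solve Kd*PA = (P-PA)(A-PA) for PA by bisection on [0, min(P, A)]."""
    lo, hi = 0.0, min(P, A)

    def f(pa):
        return (P - pa) * (A - pa) - Kd * pa

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(1.0, hi):
            break
    return 0.5 * (lo + hi)


def acf_direct(counts, k):
    """Symmetric-normalisation autocorrelation at integer shift k, explicit loops."""
    n = len(counts)
    a = counts[: n - k]
    b = counts[k:]
    ma = sum(a) / len(a)
    mb = sum(b) / len(b)
    if ma == 0 or mb == 0:
        return 0.0
    s = 0.0
    for i in range(len(a)):
        s += a[i] * b[i]
    return s / len(a) / (ma * mb) - 1.0
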