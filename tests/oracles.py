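"""Independent brute-force oracle for the bilinear breakpoint fit.

Exhaustively enumerates every decline/plateau partition of the sorted data:
for each partition the continuity-unconstrained optimum (plateau mean +
decline OLS line, breakpoint at their intersection) is accepted when its
breakpoint is consistent with the partition, and fixed-breakpoint
constrained fits are evaluated at every data SWC value to cover interval
endpoints.  This finds the exact global least-squares optimum, so the
production fitter can be held to 1e-10 agreement.  Deliberately written
with plain formulas (np.polyfit, explicit residuals) independent of the
package's implementation.
"""

import numpy as np


def _sse_at_fixed_theta(s, y, theta):
    """Continuity-constrained fit at fixed breakpoint: y ~ a - b*max(0,theta-s)."""
    x = np.maximum(0.0, theta - s)
    if np.ptp(x) == 0:
        a, b = y.mean(), 0.0
    else:
        coef = np.polyfit(x, y, 1)  # y = coef[0]*x + coef[1]
        b, a = -coef[0], coef[1]
        if b < 0:
            a, b = y.mean(), 0.0
    sse = float(((y - (a - b * x)) ** 2).sum())
    return a, b, sse


def brute_force_fit(swc, rate, min_segment=2):
    """Exact global SSE minimiser. Returns (theta, tr_max, slope, sse)."""
    order = np.argsort(np.asarray(swc, dtype=float), kind="stable")
    s = np.asarray(swc, dtype=float)[order]
    y = np.asarray(rate, dtype=float)[order]
    n = len(s)
    lo_open = s[min_segment - 1]
    hi_closed = s[n - min_segment]

    candidates = []  # (sse, theta, a, b)
    for theta in np.unique(s):
        if lo_open < theta <= hi_closed:
            a, b, sse = _sse_at_fixed_theta(s, y, theta)
            candidates.append((sse, theta, a, b))
    for k in range(min_segment, n - min_segment + 1):
        if s[k - 1] == s[k]:
            continue
        d_s, d_y, p_y = s[:k], y[:k], y[k:]
        if np.ptp(d_s) == 0:
            continue
        b, c0 = np.polyfit(d_s, d_y, 1)
        a = p_y.mean()
        if b <= 0:
            continue
        theta = (a - c0) / b
        if s[k - 1] < theta <= s[k] and lo_open < theta <= hi_closed:
            sse = float(((d_y - (c0 + b * d_s)) ** 2).sum() + ((p_y - a) ** 2).sum())
            candidates.append((sse, theta, a, b))
    if not candidates:
        a = y.mean()
        return float(s[0]), float(a), 0.0, float(((y - a) ** 2).sum())
    best = None
    for sse, theta, a, b in candidates:
        if best is None or sse < best[0] - 1e-15 or (
            abs(sse - best[0]) <= 1e-15 and theta > best[1]
        ):
            best = (sse, theta, a, b)
    sse, theta, a, b = best
    return float(theta), float(a), float(b), float(sse)


def random_bilinear_instance(rng, n_max=50):
    """Random noisy instance spanning both regimes."""
    n = rng.integers(8, n_max + 1)
    theta = rng.uniform(0.35, 0.6)
    tr_max = rng.uniform(0.3, 0.9)
    slope = rng.uniform(0.5, 3.0)
    s = rng.uniform(theta - 0.25, theta + 0.15, size=n)
    y = np.where(s >= theta, tr_max, tr_max - slope * (theta - s))
    y = np.maximum(y + rng.normal(0, 0.05 * tr_max, size=n), 0.0)
    return s, y
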