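"""Numba kernels for the Wiener first-passage-time numerics.

Everything here is scalar/loop code compiled with numba so the hierarchical
sampler and the posterior-predictive simulator stay fast on a single CPU.
The truncation rules for the small-time / large-time series follow the
standard error-bound analysis for the two-boundary Wiener density; the
bound is set well below 1e-9 so the two representations agree at the
switch point.
"""

import numpy as np
from numba import njit

# truncation target for the series representations (absolute error in f0)
_SERIES_EPS = 1e-12


@njit(cache=True, fastmath=True)
def _f0_small(u, w):
    """Driftless unit-boundary FPT density at the lower boundary,
    small-time series, normalized time u = t / a**2."""
    if u <= 0.0:
        return 0.0
    # number of terms per the standard bound
    if 2.0 * np.sqrt(2.0 * np.pi * u) * _SERIES_EPS < 1.0:
        ks = 2.0 + np.sqrt(-2.0 * u * np.log(2.0 * _SERIES_EPS * np.sqrt(2.0 * np.pi * u)))
        ks = max(ks, np.sqrt(u) + 1.0)
    else:
        ks = 2.0
    K = int(np.ceil(ks))
    acc = 0.0
    for k in range(-K, K + 1):
        x = w + 2.0 * k
        acc += x * np.exp(-x * x / (2.0 * u))
    return acc / np.sqrt(2.0 * np.pi * u ** 3)


@njit(cache=True, fastmath=True)
def _f0_large(u, w):
    """Large-time series for the same density."""
    if u <= 0.0:
        return 0.0
    if np.pi * u * _SERIES_EPS < 1.0:
        kl = np.sqrt(-2.0 * np.log(np.pi * u * _SERIES_EPS) / (np.pi * np.pi * u))
        kl = max(kl, 1.0 / (np.pi * np.sqrt(u)))
    else:
        kl = 1.0 / (np.pi * np.sqrt(u))
    K = int(np.ceil(kl))
    acc = 0.0
    for k in range(1, K + 1):
        acc += k * np.exp(-k * k * np.pi * np.pi * u / 2.0) * np.sin(k * np.pi * w)
    return np.pi * acc


@njit(cache=True, fastmath=True)
def _f0(u, w):
    """Pick the cheaper series (fewer terms) for normalized time u."""
    # heuristic crossover: small-time terms grow ~ sqrt(-2 u log eps),
    # large-time terms shrink with u; u ~ 0.2-0.5 is the usual switch zone.
    if u < 0.28:
        return _f0_small(u, w)
    return _f0_large(u, w)


@njit(cache=True, fastmath=True)
def wfpt_pdf(t, upper, a, v, t0, w):
    """Defective first-passage density of the two-boundary Wiener process
    (diffusion coefficient 1) at decision time ``t - t0``.

    upper=True: density of absorbing at the upper boundary.
    Accuracy coding puts the correct response at the upper boundary.
    Returns 0 for t <= t0.
    """
    dt = t - t0
    if dt <= 0.0 or a <= 0.0:
        return 0.0
    if upper:
        vv = -v
        ww = 1.0 - w
    else:
        vv = v
        ww = w
    u = dt / (a * a)
    f = _f0(u, ww) / (a * a)
    return f * np.exp(-vv * a * ww - vv * vv * dt / 2.0)


@njit(cache=True, fastmath=True)
def mixture_logpdf_arr(rt, upper, a, v, t0, pi_cont, u_lo, u_hi, out):
    """Per-trial log of the contaminated Wiener likelihood.

    All parameter inputs are per-trial arrays (already mapped from the
    design cells).  Contaminant density: uniform over [u_lo, u_hi] split
    evenly over the two responses.
    """
    n = rt.shape[0]
    for i in range(n):
        f = wfpt_pdf(rt[i], upper[i], a[i], v[i], t0[i], 0.5)
        g = 0.0
        if u_hi[i] > u_lo[i] and u_lo[i] <= rt[i] <= u_hi[i]:
            g = 0.5 / (u_hi[i] - u_lo[i])
        like = (1.0 - pi_cont) * f + pi_cont * g
        if like <= 0.0:
            out[i] = -np.inf
        else:
            out[i] = np.log(like)


@njit(cache=True, fastmath=True)
def sum_by_group(values, group, n_groups):
    out = np.zeros(n_groups)
    for i in range(values.shape[0]):
        out[group[i]] += values[i]
    return out


@njit(cache=True, fastmath=True)
def simulate_fpt_arr(a, v, t0, pi_cont, u_lo, u_hi, dt, seed):
    """Simulate one trial per entry of the parameter arrays.

    Euler-Maruyama with the Brownian-bridge crossing correction, so the
    discretization bias in first-passage times is O(dt) rather than
    O(sqrt(dt)).  Contaminant trials get a uniform RT on [u_lo, u_hi] and
    a coin-flip response.

    Returns (rt, upper, contaminant).
    """
    np.random.seed(seed)
    n = a.shape[0]
    rt = np.empty(n)
    upper = np.zeros(n, dtype=np.bool_)
    contam = np.zeros(n, dtype=np.bool_)
    sq = np.sqrt(dt)
    for i in range(n):
        if pi_cont > 0.0 and np.random.random() < pi_cont:
            contam[i] = True
            rt[i] = u_lo + (u_hi - u_lo) * np.random.random()
            upper[i] = np.random.random() < 0.5
            continue
        ai = a[i]
        vi = v[i]
        x = 0.5 * ai
        t = 0.0
        while True:
            xn = x + vi * dt + sq * np.random.standard_normal()
            t += dt
            if xn >= ai:
                upper[i] = True
                break
            if xn <= 0.0:
                upper[i] = False
                break
            # bridge probability of an unobserved excursion across a
            # boundary; skip the exp when it is numerically negligible
            du = (ai - x) * (ai - xn)
            if du < 20.0 * dt and np.random.random() < np.exp(-2.0 * du / dt):
                upper[i] = True
                break
            dd = x * xn
            if dd < 20.0 * dt and np.random.random() < np.exp(-2.0 * dd / dt):
                upper[i] = False
                break
            x = xn
        rt[i] = t0[i] + t
    return rt, upper, contam
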