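"""Two-boundary Wiener diffusion numerics.

The decision process is a Wiener diffusion between two absorbing
boundaries separated by ``a`` (response caution), starting unbiased at
``a/2``, drifting at rate ``v`` toward the upper (correct) boundary with
within-trial diffusion coefficient fixed at 1 (the scale convention of
common hierarchical DDM software, so drift and caution magnitudes are
directly comparable across studies using that convention).  Observed RT
is the first-passage time plus the non-decision time ``t0``.  A fixed
proportion ``pi_cont`` of trials is contaminated: uniform RT over a
window, response at chance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import integrate

from . import _kernels

__all__ = [
    "DdmParams",
    "wfpt_density",
    "choice_probability",
    "mean_decision_time",
    "simulate_trial",
    "simulate_trials",
    "mixture_loglik",
]

#: default contaminant RT window (s) used when simulating; when fitting,
#: the window is taken per subject from the observed RT range.
DEFAULT_CONTAMINANT_WINDOW = (0.2, 3.0)


@dataclass(frozen=True)
class DdmParams:
    """Parameters of one design cell.

    a: boundary separation (> 0), v: drift rate (signed, evidence/s),
    t0: non-decision time (s, >= 0).  ``z_rel`` (relative start point)
    and ``s_diff`` (diffusion coefficient) are fixed conventions of this
    package, never estimated.  ``pi_cont`` is the contamination
    proportion of the mixture likelihood.
    """

    a: float
    v: float
    t0: float
    z_rel: float = 0.5
    s_diff: float = 1.0
    pi_cont: float = 0.05

    def __post_init__(self):
        if not (self.a > 0):
            raise ValueError(f"boundary separation must be positive, got a={self.a}")
        if not (self.t0 >= 0):
            raise ValueError(f"non-decision time must be >= 0, got t0={self.t0}")
        if not (0 < self.z_rel < 1):
            raise ValueError(f"relative start point must lie in (0,1), got {self.z_rel}")
        if not (self.s_diff > 0):
            raise ValueError(f"diffusion coefficient must be positive, got {self.s_diff}")
        if not (0 <= self.pi_cont <= 1):
            raise ValueError(f"contamination proportion must lie in [0,1], got {self.pi_cont}")

    def _unit_scale(self) -> "DdmParams":
        """Rescale to s_diff = 1 (a -> a/s, v -> v/s leaves the process law
        unchanged)."""
        if self.s_diff == 1.0:
            return self
        s = self.s_diff
        return replace(self, a=self.a / s, v=self.v / s, s_diff=1.0)


def _check_boundary(boundary: str) -> bool:
    if boundary not in ("upper", "lower"):
        raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    return boundary == "upper"


def wfpt_density(t, boundary: str, params: DdmParams):
    """Defective first-passage density (1/s) at decision time ``t``.

    ``t`` is the decision time, i.e. observed RT minus t0 (the caller
    handles t0); it must be strictly positive.  The densities at the two
    boundaries jointly integrate to 1.
    """
    up = _check_boundary(boundary)
    p = params._unit_scale()
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr <= 0):
        raise ValueError("decision time must be strictly positive")
    out = np.empty_like(t_arr)
    for i, ti in enumerate(t_arr):
        out[i] = _kernels.wfpt_pdf(ti, up, p.a, p.v, 0.0, p.z_rel)
    return out if np.ndim(t) else float(out[0])


def choice_probability(params: DdmParams, boundary: str) -> float:
    """Closed-form absorption probability at the named boundary
    (gambler's ruin)."""
    up = _check_boundary(boundary)
    p = params._unit_scale()
    w = p.z_rel
    if p.v == 0.0:
        p_upper = w
    else:
        # P(hit upper) for drift v, boundaries 0/a, start z = w*a
        x = np.exp(-2.0 * p.v * p.a * w)
        y = np.exp(-2.0 * p.v * p.a)
        p_upper = (1.0 - x) / (1.0 - y)
    return float(p_upper if up else 1.0 - p_upper)


def mean_decision_time(params: DdmParams) -> float:
    """Expected first-passage time (s), excluding t0, for the unbiased
    start point.

    For v = 0 this is z(a-z)/s^2 with z = a/2; otherwise
    (a / 2v) * tanh(a v / 2 s^2).
    """
    if params.z_rel != 0.5:
        raise ValueError("mean_decision_time assumes the unbiased start point z_rel = 0.5")
    p = params._unit_scale()
    if p.v == 0.0:
        return float(p.a * p.a / 4.0)
    return float(p.a / (2.0 * p.v) * np.tanh(p.a * p.v / 2.0))


def simulate_trials(
    params: DdmParams,
    n: int,
    rng_seed: int,
    dt: float = 1e-3,
    contaminant_window: tuple[float, float] = DEFAULT_CONTAMINANT_WINDOW,
):
    """Simulate ``n`` trials; returns (rt, upper, contaminant) arrays.

    Uses Euler steps of size ``dt`` with the Brownian-bridge crossing
    correction.  Contaminant trials (probability ``pi_cont``) draw a
    uniform RT over ``contaminant_window`` with a chance response.
    """
    p = params._unit_scale()
    lo, hi = contaminant_window
    a = np.full(n, p.a)
    v = np.full(n, p.v)
    t0 = np.full(n, p.t0)
    return _kernels.simulate_fpt_arr(a, v, t0, p.pi_cont, lo, hi, dt, int(rng_seed) % 2**31)


def simulate_trial(params: DdmParams, rng_seed: int, **kwargs):
    """Simulate a single trial -> (rt, boundary, contaminant)."""
    rt, up, contam = simulate_trials(params, 1, rng_seed, **kwargs)
    return float(rt[0]), ("upper" if up[0] else "lower"), bool(contam[0])


def mixture_loglik(
    data,
    params: DdmParams,
    contaminant_window: tuple[float, float] | None = None,
):
    """Log-likelihood of (rt, boundary) pairs under the contaminated
    Wiener model.

    ``data``: sequence of (rt, boundary) with boundary 'upper'/'lower'
    (or truthy = upper).  Trials with rt <= t0 contribute only the
    contaminant term, so the log-likelihood stays finite whenever
    pi_cont > 0 and the RT lies in the contaminant window.  With
    pi_cont = 0 such trials yield -inf by contract.

    If no window is given it is taken as the observed RT range.
    """
    data = list(data)
    if len(data) == 0:
        raise ValueError("mixture_loglik requires at least one trial")
    rt = np.array([d[0] for d in data], dtype=float)
    if np.any(rt <= 0):
        raise ValueError("all RTs must be strictly positive")
    upper = np.array(
        [(d[1] == "upper" if isinstance(d[1], str) else bool(d[1])) for d in data],
        dtype=bool,
    )
    p = params._unit_scale()
    if contaminant_window is None:
        lo, hi = float(rt.min()), float(rt.max())
    else:
        lo, hi = contaminant_window
    n = rt.shape[0]
    out = np.empty(n)
    _kernels.mixture_logpdf_arr(
        rt, upper, np.full(n, p.a), np.full(n, p.v), np.full(n, p.t0),
        p.pi_cont, np.full(n, lo), np.full(n, hi), out,
    )
    return float(out.sum())


def density_norm(params: DdmParams) -> float:
    """Numeric integral of the defective densities over both boundaries
    (should be 1); used as a self-check."""
    f = lambda t: wfpt_density(t, "upper", params) + wfpt_density(t, "lower", params)
    val, _ = integrate.quad(f, 1e-6, np.inf, limit=200)
    return float(val)
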