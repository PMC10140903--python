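"""Latent difference score (LDS) models and the latent caution factor.

The LDS model treats the two conditions of a contrast (e.g. task-repeat
vs task-switch non-decision time) as paired indicators in each of three
task blocks.  The baseline factor B loads on both members of a pair;
the change factor D additionally loads on the changed-condition member
with the same loading, so D's mean and variance capture the reliable
condition difference.  Strict measurement invariance holds within a
block (equal loading, intercept, and residual variance across the two
conditions), and the paired residuals may covary.  Working-memory
capacity (WMC) enters as a third factor measured by three parallel
parcels.  Identification is by marker variable: the block-1 loading is
fixed to 1 and the block-1 intercept to 0 (same scheme for the
parcels), so the latent means i_B and i_D are in the indicator's units.

Estimation is normal-theory maximum likelihood on the sample mean
vector and (ML, denominator n) covariance matrix via quasi-Newton
minimization of the ML discrepancy; standard errors come from the
inverse observed information, and correlations' standard errors by the
delta method.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "LdsSpec",
    "LdsFit",
    "build_lds_spec",
    "assemble_lds_data",
    "fit_sem",
    "fit_indices",
    "fit_caution_factor",
    "simulate_lds_indicators",
]

_N_BLOCKS = 3


@dataclass
class LdsSpec:
    """Specification of one LDS model: which indicator columns pair up.

    ``baseline_cols[b]`` and ``changed_cols[b]`` are the paired
    indicators of block b+1; ``parcel_cols`` are the WMC parcels.
    """

    parameter: str
    contrast: str
    baseline_cols: list
    changed_cols: list
    parcel_cols: list

    @property
    def columns(self):
        """Indicator order of the model matrices: the block pairs
        interleaved (baseline, changed per block), then the parcels."""
        pairs = [c for b in range(len(self.baseline_cols))
                 for c in (self.baseline_cols[b], self.changed_cols[b])]
        return pairs + list(self.parcel_cols)

    @property
    def n_indicators(self):
        return len(self.columns)

    @property
    def df(self):
        """Model degrees of freedom: unique first/second moments minus
        free parameters."""
        p = self.n_indicators
        moments = p * (p + 1) // 2 + p
        return moments - _n_free_lds()

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "LdsSpec":
        return cls(**json.loads(s))


@dataclass
class LdsFit:
    """Estimates and fit statistics of one LDS model."""

    i_B: float
    i_D: float
    i_W: float
    rho1: float  # corr(B, D)
    rho2: float  # corr(WMC, B)
    rho3: float  # corr(WMC, D)
    se: dict
    p_values: dict
    loadings: dict
    intercepts: dict
    residual_variances: dict
    residual_covariances: dict
    latent_cov: np.ndarray
    chi2: float
    df: int
    p: float
    rmsea: float
    rmsea_ci: tuple
    srmr: float
    cfi: float
    tli: float
    n: int
    converged: bool


def build_lds_spec(parameter: str, contrast: str,
                   estimates: pd.DataFrame | None = None,
                   wmc: pd.DataFrame | None = None) -> LdsSpec:
    """Construct the LDS specification for a diffusion parameter or an
    observed score.

    contrast='switch' pairs the congruent task-repeat cell (s0,i0) with
    the congruent task-switch cell (s1,i0); contrast='incongruency'
    pairs (s0,i0) with the incongruent task-repeat cell (s0,i1), so the
    incongruency model never uses task-switch cells.  For non-decision
    time under the reference model the cells reduce to s0/s1 per block.
    """
    if contrast not in ("switch", "incongruency"):
        raise ValueError(f"unknown contrast {contrast!r}")
    if parameter == "t0":
        if contrast != "switch":
            raise ValueError("non-decision time varies only by switch under the reference model")
        base = [f"t0_b{b}_s0" for b in range(1, _N_BLOCKS + 1)]
        chg = [f"t0_b{b}_s1" for b in range(1, _N_BLOCKS + 1)]
    elif parameter == "v":
        if contrast == "switch":
            base = [f"v_b{b}_s0_i0" for b in range(1, _N_BLOCKS + 1)]
            chg = [f"v_b{b}_s1_i0" for b in range(1, _N_BLOCKS + 1)]
        else:
            base = [f"v_b{b}_s0_i0" for b in range(1, _N_BLOCKS + 1)]
            chg = [f"v_b{b}_s0_i1" for b in range(1, _N_BLOCKS + 1)]
    else:
        # observed score: columns '<parameter>_b<b>_<cell>'
        if contrast == "switch":
            base = [f"{parameter}_b{b}_s0_i0" for b in range(1, _N_BLOCKS + 1)]
            chg = [f"{parameter}_b{b}_s1_i0" for b in range(1, _N_BLOCKS + 1)]
        else:
            base = [f"{parameter}_b{b}_s0_i0" for b in range(1, _N_BLOCKS + 1)]
            chg = [f"{parameter}_b{b}_s0_i1" for b in range(1, _N_BLOCKS + 1)]
    spec = LdsSpec(
        parameter=parameter, contrast=contrast,
        baseline_cols=base, changed_cols=chg,
        parcel_cols=["parcel_1", "parcel_2", "parcel_3"],
    )
    if estimates is not None:
        missing = [c for c in spec.baseline_cols + spec.changed_cols if c not in estimates.columns]
        if missing:
            raise ValueError(f"estimates table lacks indicator columns: {missing}")
    if wmc is not None:
        missing = [c for c in spec.parcel_cols if c not in wmc.columns]
        if missing:
            raise ValueError(f"WMC table lacks parcel columns: {missing}")
    return spec


def assemble_lds_data(spec: LdsSpec, estimates: pd.DataFrame, wmc: pd.DataFrame) -> pd.DataFrame:
    """Merge subject-level indicator and parcel tables into the 9-column
    data matrix the model is fit to (complete cases only)."""
    d = estimates.merge(wmc, on="subject", how="inner")
    cols = ["subject"] + spec.columns
    missing = [c for c in cols if c not in d.columns]
    if missing:
        raise ValueError(f"missing indicator columns: {missing}")
    return d[cols].dropna().reset_index(drop=True)


# ---------------------------------------------------------------------------
# model-implied moments

# free-parameter layout for the 9-indicator LDS model (26 parameters):
# 0-1   lam2, lam3            block loadings (block 1 fixed at 1)
# 2-3   tau2, tau3            block intercepts (block 1 fixed at 0)
# 4-5   gam2, gam3            parcel loadings (parcel 1 fixed at 1)
# 6-7   taup2, taup3          parcel intercepts (parcel 1 fixed at 0)
# 8-10  kappa_B, kappa_D, kappa_W   latent means
# 11-13 log theta_1..3        block residual variances (shared in pair)
# 14-16 c_1..3                paired residual covariances
# 17-19 log psi_1..3          parcel residual variances
# 20-25 log-Cholesky of the 3x3 latent covariance (diag logged)


def _n_free_lds() -> int:
    return 26


def _lds_moments(x: np.ndarray):
    lam = np.array([1.0, x[0], x[1]])
    tau = np.array([0.0, x[2], x[3]])
    gam = np.array([1.0, x[4], x[5]])
    taup = np.array([0.0, x[6], x[7]])
    kappa = x[8:11]
    theta = np.exp(x[11:14])
    c = x[14:17]
    psi = np.exp(x[17:20])
    L = np.zeros((3, 3))
    L[0, 0] = np.exp(x[20])
    L[1, 0] = x[21]
    L[1, 1] = np.exp(x[22])
    L[2, 0] = x[23]
    L[2, 1] = x[24]
    L[2, 2] = np.exp(x[25])
    phi = L @ L.T

    Lam = np.zeros((9, 3))
    nu = np.zeros(9)
    for b in range(3):
        Lam[2 * b, 0] = lam[b]                  # baseline indicator
        Lam[2 * b + 1, 0] = lam[b]              # changed indicator
        Lam[2 * b + 1, 1] = lam[b]
        nu[2 * b] = tau[b]
        nu[2 * b + 1] = tau[b]
    for k in range(3):
        Lam[6 + k, 2] = gam[k]
        nu[6 + k] = taup[k]

    Theta = np.zeros((9, 9))
    for b in range(3):
        Theta[2 * b, 2 * b] = theta[b]
        Theta[2 * b + 1, 2 * b + 1] = theta[b]
        Theta[2 * b, 2 * b + 1] = Theta[2 * b + 1, 2 * b] = c[b]
    for k in range(3):
        Theta[6 + k, 6 + k] = psi[k]

    Sigma = Lam @ phi @ Lam.T + Theta
    mu = nu + Lam @ kappa
    return mu, Sigma, dict(lam=lam, tau=tau, gam=gam, taup=taup, kappa=kappa,
                           theta=theta, c=c, psi=psi, phi=phi)


def _fml(x, S, m, moments_fn):
    mu, Sigma, _ = moments_fn(x)
    try:
        cf = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        return 1e10
    logdet = 2.0 * np.log(np.diag(cf)).sum()
    Sinv = np.linalg.inv(Sigma)
    diff = m - mu
    sign, logdetS = np.linalg.slogdet(S)
    p = S.shape[0]
    return float(logdet - logdetS + np.trace(S @ Sinv) - p + diff @ Sinv @ diff)


def _numeric_hessian(f, x, h=1e-4):
    n = len(x)
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            xpp = x.copy(); xpp[i] += h; xpp[j] += h
            xpm = x.copy(); xpm[i] += h; xpm[j] -= h
            xmp = x.copy(); xmp[i] -= h; xmp[j] += h
            xmm = x.copy(); xmm[i] -= h; xmm[j] -= h
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h * h)
    return H, f0


def _numeric_grad(f, x, h=1e-5):
    g = np.zeros(len(x))
    for i in range(len(x)):
        xp = x.copy(); xp[i] += h
        xm = x.copy(); xm[i] -= h
        g[i] = (f(xp) - f(xm)) / (2 * h)
    return g


def _start_values_lds(Y: np.ndarray) -> np.ndarray:
    m = Y.mean(axis=0)
    v = Y.var(axis=0)
    x = np.zeros(26)
    sd_b1 = np.sqrt(max(v[0], 1e-8))
    for b in (1, 2):
        x[b - 1] = np.sqrt(max(v[2 * b], 1e-8)) / sd_b1            # lam
        x[2 + b - 1] = m[2 * b] - x[b - 1] * m[0]                  # tau
        x[4 + b - 1] = np.sqrt(max(v[6 + b], 1e-8)) / np.sqrt(max(v[6], 1e-8))
        x[6 + b - 1] = m[6 + b] - x[4 + b - 1] * m[6]
    x[8] = m[0]
    x[9] = (Y[:, 1] - Y[:, 0]).mean()
    x[10] = m[6]
    x[11:14] = np.log(np.maximum(0.4 * v[[0, 2, 4]], 1e-6))
    x[14:17] = 0.0
    x[17:20] = np.log(np.maximum(0.4 * v[[6, 7, 8]], 1e-6))
    var_B = max(0.6 * v[0], 1e-6)
    var_D = max(0.6 * (Y[:, 1] - Y[:, 0]).var(), 1e-6)
    var_W = max(0.6 * v[6], 1e-6)
    x[20] = 0.5 * np.log(var_B)
    x[22] = 0.5 * np.log(var_D)
    x[25] = 0.5 * np.log(var_W)
    return x


def fit_sem(spec: LdsSpec, data: pd.DataFrame, n_restarts: int = 3,
            seed: int = 0) -> LdsFit:
    """Fit the LDS model to subject-level data by maximum likelihood.

    ``data`` must contain the spec's indicator columns (one row per
    subject, complete cases).  Non-convergence is flagged, not raised;
    a non-positive-definite sample covariance raises.
    """
    Y = data[spec.columns].to_numpy(float)
    n, p = Y.shape
    if n <= _n_free_lds():
        raise ValueError(f"need more subjects ({n}) than free parameters ({_n_free_lds()})")
    S = np.cov(Y, rowvar=False, ddof=0)
    if np.linalg.eigvalsh(S).min() <= 0:
        raise ValueError("sample covariance matrix is not positive definite")
    m = Y.mean(axis=0)

    obj = lambda x: _fml(x, S, m, _lds_moments)
    rng = np.random.default_rng(seed)
    best = None
    x0 = _start_values_lds(Y)
    for r in range(n_restarts):
        xi = x0 if r == 0 else x0 + rng.normal(0, 0.05, size=x0.shape)
        res = optimize.minimize(obj, xi, method="BFGS",
                                options=dict(maxiter=2000, gtol=1e-8))
        if best is None or res.fun < best.fun:
            best = res
        if best.fun < 1e-12:
            break
    x = best.x
    mu, Sigma, params = _lds_moments(x)
    chi2 = max(n * best.fun, 0.0)
    dfm = spec.df
    pval = float(stats.chi2.sf(chi2, dfm)) if dfm > 0 else 1.0

    # fit indices against the independence baseline (free means/variances)
    base_f = float(np.log(np.diag(S)).sum() - np.linalg.slogdet(S)[1])
    base_chi2 = n * base_f
    base_df = p * (p - 1) // 2
    idx = fit_indices(chi2, dfm, n, base_chi2, base_df,
                      residuals=_std_residuals(S, Sigma))

    # delta-method SEs via the observed information of the ML loglik
    se = {}
    pz = {}
    H, _ = _numeric_hessian(obj, x)
    try:
        cov_x = np.linalg.inv(0.5 * n * H)
        ok = np.all(np.diag(cov_x) > 0)
    except np.linalg.LinAlgError:
        cov_x, ok = None, False

    # convergence: optimizer success, or a negligible Newton decrement
    # (the quadratic-model improvement still available at the solution)
    grad = _numeric_grad(obj, x)
    try:
        decrement = float(abs(grad @ np.linalg.solve(H, grad)))
    except np.linalg.LinAlgError:
        decrement = np.inf
    converged = bool(best.success or decrement < 1e-5)

    phi = params["phi"]
    sd = np.sqrt(np.diag(phi))
    derived = {
        "i_B": lambda q: _lds_moments(q)[2]["kappa"][0],
        "i_D": lambda q: _lds_moments(q)[2]["kappa"][1],
        "i_W": lambda q: _lds_moments(q)[2]["kappa"][2],
        "rho1": lambda q: _corr(_lds_moments(q)[2]["phi"], 0, 1),
        "rho2": lambda q: _corr(_lds_moments(q)[2]["phi"], 2, 0),
        "rho3": lambda q: _corr(_lds_moments(q)[2]["phi"], 2, 1),
    }
    values = {k: f(x) for k, f in derived.items()}
    for k, f in derived.items():
        if cov_x is None or not ok:
            se[k] = np.nan
            pz[k] = np.nan
            continue
        g = _numeric_grad(f, x)
        var = float(g @ cov_x @ g)
        se[k] = float(np.sqrt(var)) if var > 0 else np.nan
        pz[k] = float(2 * stats.norm.sf(abs(values[k]) / se[k])) if se[k] and np.isfinite(se[k]) and se[k] > 0 else np.nan

    return LdsFit(
        i_B=values["i_B"], i_D=values["i_D"], i_W=values["i_W"],
        rho1=values["rho1"], rho2=values["rho2"], rho3=values["rho3"],
        se=se, p_values=pz,
        loadings=dict(block=params["lam"].tolist(), parcel=params["gam"].tolist()),
        intercepts=dict(block=params["tau"].tolist(), parcel=params["taup"].tolist()),
        residual_variances=dict(block=params["theta"].tolist(), parcel=params["psi"].tolist()),
        residual_covariances=dict(block=params["c"].tolist()),
        latent_cov=phi,
        chi2=float(chi2), df=dfm, p=pval,
        rmsea=idx["rmsea"], rmsea_ci=idx["rmsea_ci"], srmr=idx["srmr"],
        cfi=idx["cfi"], tli=idx["tli"], n=n, converged=converged,
    )


def _corr(phi, i, j):
    return float(phi[i, j] / np.sqrt(phi[i, i] * phi[j, j]))


def _std_residuals(S, Sigma):
    d = np.sqrt(np.diag(S))
    return (S - Sigma) / np.outer(d, d)


def fit_indices(chi2: float, df: int, n: int,
                baseline_chi2: float, baseline_df: int,
                residuals: np.ndarray | None = None,
                ci_level: float = 0.90) -> dict:
    """RMSEA (with noncentral-chi-square CI), SRMR, CFI and TLI.

    RMSEA = sqrt(max(chi2 - df, 0) / (df * n)); with df = 0 the model is
    saturated and RMSEA is defined as 0 with CFI = 1.  SRMR is computed
    over the unique elements of the standardized covariance residuals.
    """
    if df <= 0:
        rmsea, ci = 0.0, (0.0, 0.0)
        cfi, tli = 1.0, 1.0
    else:
        rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * n)))
        alpha = 1.0 - ci_level
        lo = _ncp_search(chi2, df, 1.0 - alpha / 2)
        hi = _ncp_search(chi2, df, alpha / 2)
        ci = (float(np.sqrt(lo / (df * n))), float(np.sqrt(hi / (df * n))))
        num = max(chi2 - df, 0.0)
        den = max(baseline_chi2 - baseline_df, num, 1e-300)
        cfi = float(1.0 - num / den)
        if baseline_df > 0 and baseline_chi2 / baseline_df > 1:
            tli = float(
                ((baseline_chi2 / baseline_df) - (chi2 / df))
                / ((baseline_chi2 / baseline_df) - 1.0)
            )
        else:
            tli = 1.0
    srmr = np.nan
    if residuals is not None:
        iu = np.triu_indices(residuals.shape[0])
        srmr = float(np.sqrt((residuals[iu] ** 2).mean()))
    return dict(rmsea=rmsea, rmsea_ci=ci, srmr=srmr, cfi=cfi, tli=tli)


def _ncp_search(chi2, df, target):
    """Noncentrality lambda with ncx2.cdf(chi2; df, lambda) = target."""
    if stats.ncx2.cdf(chi2, df, 0.0) < target:
        return 0.0
    hi = max(chi2 * 2, 10.0)
    while stats.ncx2.cdf(chi2, df, hi) > target:
        hi *= 2
        if hi > 1e8:
            return hi
    return float(optimize.brentq(lambda l: stats.ncx2.cdf(chi2, df, l) - target, 0.0, hi))


# ---------------------------------------------------------------------------
# latent response-caution factor

# layout (13 params): lam_a2, lam_a3, gam2, gam3, log var_C, log var_W,
# cov_CW, log theta_a1..3, log psi_1..3


def _caution_moments(x):
    lam = np.array([1.0, x[0], x[1]])
    gam = np.array([1.0, x[2], x[3]])
    vC = np.exp(x[4])
    vW = np.exp(x[5])
    cCW = x[6]
    th = np.exp(x[7:10])
    ps = np.exp(x[10:13])
    Lam = np.zeros((6, 2))
    Lam[0:3, 0] = lam
    Lam[3:6, 1] = gam
    Phi = np.array([[vC, cCW], [cCW, vW]])
    Theta = np.diag(np.concatenate([th, ps]))
    Sigma = Lam @ Phi @ Lam.T + Theta
    return None, Sigma, dict(lam=lam, gam=gam, phi=Phi, theta=th, psi=ps)


def fit_caution_factor(a_estimates: pd.DataFrame, wmc: pd.DataFrame,
                       n_restarts: int = 3, seed: int = 0) -> dict:
    """Two-factor model: response caution across blocks vs WMC parcels.

    ``a_estimates`` needs columns a_b1..a_b3 per subject; returns the
    latent correlation with SE, loadings, chi2/df and fit indices
    (covariance structure only; df = 8 for the 6-indicator model).
    """
    d = a_estimates.merge(wmc, on="subject", how="inner")
    cols = ["a_b1", "a_b2", "a_b3", "parcel_1", "parcel_2", "parcel_3"]
    missing = [c for c in cols if c not in d.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    Y = d[cols].dropna().to_numpy(float)
    n, p = Y.shape
    S = np.cov(Y, rowvar=False, ddof=0)
    if np.linalg.eigvalsh(S).min() <= 0:
        raise ValueError("sample covariance matrix is not positive definite")

    def obj(x):
        _, Sigma, _ = _caution_moments(x)
        try:
            cf = np.linalg.cholesky(Sigma)
        except np.linalg.LinAlgError:
            return 1e10
        logdet = 2.0 * np.log(np.diag(cf)).sum()
        return float(logdet - np.linalg.slogdet(S)[1]
                     + np.trace(S @ np.linalg.inv(Sigma)) - p)

    v = np.diag(S)
    x0 = np.zeros(13)
    x0[0] = np.sqrt(v[1] / v[0]); x0[1] = np.sqrt(v[2] / v[0])
    x0[2] = np.sqrt(v[4] / v[3]); x0[3] = np.sqrt(v[5] / v[3])
    x0[4] = np.log(0.6 * v[0]); x0[5] = np.log(0.6 * v[3])
    x0[6] = 0.3 * S[0, 3]
    x0[7:10] = np.log(0.4 * v[0:3]); x0[10:13] = np.log(0.4 * v[3:6])

    rng = np.random.default_rng(seed)
    best = None
    for r in range(n_restarts):
        xi = x0 if r == 0 else x0 + rng.normal(0, 0.05, size=x0.shape)
        res = optimize.minimize(obj, xi, method="BFGS", options=dict(maxiter=2000, gtol=1e-8))
        if best is None or res.fun < best.fun:
            best = res
    x = best.x
    _, Sigma, params = _caution_moments(x)
    chi2 = max(n * best.fun, 0.0)
    dfm = p * (p + 1) // 2 - 13
    base_chi2 = n * float(np.log(np.diag(S)).sum() - np.linalg.slogdet(S)[1])
    idx = fit_indices(chi2, dfm, n, base_chi2, p * (p - 1) // 2,
                      residuals=_std_residuals(S, Sigma))

    rho_fn = lambda q: _corr(_caution_moments(q)[2]["phi"], 0, 1)
    rho = rho_fn(x)
    H, _ = _numeric_hessian(obj, x)
    grad = _numeric_grad(obj, x)
    try:
        decrement = float(abs(grad @ np.linalg.solve(H, grad)))
    except np.linalg.LinAlgError:
        decrement = np.inf
    converged = bool(best.success or decrement < 1e-5)
    try:
        cov_x = np.linalg.inv(0.5 * n * H)
        g = _numeric_grad(rho_fn, x)
        var = float(g @ cov_x @ g)
        se = float(np.sqrt(var)) if var > 0 else np.nan
    except np.linalg.LinAlgError:
        se = np.nan
    pz = float(2 * stats.norm.sf(abs(rho) / se)) if se and np.isfinite(se) and se > 0 else np.nan
    return dict(
        rho=float(rho), se=se, p=pz,
        loadings_caution=params["lam"].tolist(), loadings_wmc=params["gam"].tolist(),
        chi2=float(chi2), df=dfm,
        p_chi2=float(stats.chi2.sf(chi2, dfm)) if dfm > 0 else 1.0,
        converged=converged, n=n, **idx,
    )


# ---------------------------------------------------------------------------
# generative counterpart (for recovery studies)


def simulate_lds_indicators(
    n: int,
    seed: int,
    kappa=(0.298, 0.088, 0.0),
    phi: np.ndarray | None = None,
    lam=(1.0, 1.0, 1.0),
    tau=(0.0, 0.0, 0.0),
    gam=(1.0, 1.0, 1.0),
    taup=(0.0, 0.0, 0.0),
    theta=(0.001, 0.001, 0.001),
    resid_cov=(0.0002, 0.0002, 0.0002),
    psi=(4.0, 4.0, 4.0),
    columns: LdsSpec | None = None,
) -> pd.DataFrame:
    """Draw subject-level indicator data exactly under the LDS model.

    Defaults emulate a non-decision-time switch contrast (seconds) with
    WMC parcels on an arbitrary count-like scale.
    """
    rng = np.random.default_rng(seed)
    if phi is None:
        sds = np.array([0.05, 0.035, 1.0])
        corr = np.eye(3)
        corr[0, 1] = corr[1, 0] = 0.15
        corr[2, 1] = corr[1, 2] = -0.40
        phi = np.outer(sds, sds) * corr
    lat = rng.multivariate_normal(np.asarray(kappa, float), phi, size=n)
    cols = {}
    for b in range(3):
        e = rng.multivariate_normal(
            [0, 0], [[theta[b], resid_cov[b]], [resid_cov[b], theta[b]]], size=n
        )
        y0 = tau[b] + lam[b] * lat[:, 0] + e[:, 0]
        y1 = tau[b] + lam[b] * (lat[:, 0] + lat[:, 1]) + e[:, 1]
        cols[f"base_b{b + 1}"] = y0
        cols[f"chg_b{b + 1}"] = y1
    for k in range(3):
        cols[f"parcel_{k + 1}"] = taup[k] + gam[k] * lat[:, 2] + rng.normal(0, np.sqrt(psi[k]), n)
    df = pd.DataFrame(cols)
    df.insert(0, "subject", np.arange(n))
    if columns is not None:
        ren = {f"base_b{b + 1}": columns.baseline_cols[b] for b in range(3)}
        ren.update({f"chg_b{b + 1}": columns.changed_cols[b] for b in range(3)})
        df = df.rename(columns=ren)
    return df
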