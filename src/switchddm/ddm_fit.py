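"""Hierarchical Bayesian estimation of the constrained diffusion-model
lattice.

Model variants M1-M6 share the drift-rate structure (by block x switch x
congruency unless noted) and differ in which design factors boundary
separation and non-decision time may depend on:

====  =========  ==============
id    caution a  non-decision t0
====  =========  ==============
M1    block      block
M2    block      block x switch     (the parsimonious reference model)
M3    block x s  block
M4    block x s  block x switch
M5    block      block x s x i
M6    block x s  block x s x i
====  =========  ==============

Estimation is Metropolis-within-Gibbs: subject-level parameters (log a,
drift, log t0) get adaptive random-walk updates blocked by task block,
vectorized across subjects; group-level normal means and variances get
conjugate Gibbs updates.  The likelihood is the 5%-contaminated Wiener
first-passage mixture with the contaminant window taken from each
subject's observed RT range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels

__all__ = [
    "ModelSpec",
    "McmcSettings",
    "PosteriorDraws",
    "ConvergenceReport",
    "PpcReport",
    "fit_hierarchical",
    "gelman_rubin",
    "posterior_difference_probability",
    "posterior_predictive_mse",
    "extract_subject_estimates",
]

_FAMILY_OPTIONS = {
    "a": ("b", "bs"),
    "t0": ("b", "bs", "bsi"),
    "v": ("bs", "bi", "bsi"),
}

_LATTICE = {
    "M1": dict(a="b", t0="b", v="bsi"),
    "M2": dict(a="b", t0="bs", v="bsi"),
    "M3": dict(a="bs", t0="b", v="bsi"),
    "M4": dict(a="bs", t0="bs", v="bsi"),
    "M5": dict(a="b", t0="bsi", v="bsi"),
    "M6": dict(a="bs", t0="bsi", v="bsi"),
}


@dataclass(frozen=True)
class ModelSpec:
    """Which design factors each diffusion parameter may vary over.

    ``a``/``t0``/``v`` take cell codes: 'b' (block), 'bs' (block x
    switch), 'bi' (block x congruency), 'bsi' (block x switch x
    congruency)."""

    model_id: str
    a: str
    t0: str
    v: str

    def __post_init__(self):
        for fam in ("a", "t0", "v"):
            val = getattr(self, fam)
            if val not in _FAMILY_OPTIONS[fam]:
                raise ValueError(f"invalid cell structure {val!r} for parameter {fam}")

    @classmethod
    def from_id(cls, model_id: str) -> "ModelSpec":
        if model_id not in _LATTICE:
            raise ValueError(f"unknown model id {model_id!r}; expected M1..M6")
        return cls(model_id=model_id, **_LATTICE[model_id])

    def cells(self, fam: str, blocks) -> list[tuple]:
        code = getattr(self, fam)
        out = []
        for b in blocks:
            if code == "b":
                out.append((b, None, None))
            elif code == "bs":
                out.extend([(b, 0, None), (b, 1, None)])
            elif code == "bi":
                out.extend([(b, None, 0), (b, None, 1)])
            else:
                out.extend([(b, s, i) for s in (0, 1) for i in (0, 1)])
        return out


@dataclass
class McmcSettings:
    """chains/draws/burn as in common hierarchical DDM practice
    (reference run: 10,000 draws, 1,000 burn-in); ``thin`` runs that many
    MH sweeps per stored draw."""

    chains: int = 2
    draws: int = 10_000
    burn: int = 1_000
    thin: int = 1
    seed: int = 0
    adapt: bool = True


@dataclass
class PosteriorDraws:
    """MCMC samples: ``samples`` has shape (chains, draws, n_params);
    subject-level entries are stored on the natural scale, group-level
    means/SDs on the sampling (transformed) scale."""

    samples: np.ndarray
    names: list
    burn: int
    seed: int
    spec: ModelSpec
    subjects: np.ndarray
    acceptance: float

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"parameter {name!r} not found in draws") from None

    def pooled(self, name: str) -> np.ndarray:
        return self.samples[:, :, self.index(name)].ravel()


@dataclass
class ConvergenceReport:
    rhat: pd.Series

    @property
    def mean(self):
        return float(self.rhat.mean())

    @property
    def sd(self):
        return float(self.rhat.std(ddof=1))

    @property
    def range(self):
        return float(self.rhat.min()), float(self.rhat.max())


@dataclass
class PpcReport:
    mse: float
    n_rep: int
    statistics: list
    per_statistic: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# data preparation

_CELL_LABEL = {"b": "{b}", "bs": "{b},s{s}", "bi": "{b},i{i}", "bsi": "{b},s{s},i{i}"}


def _cell_name(fam, cell):
    b, s, i = cell
    parts = [f"b{b}"]
    if s is not None:
        parts.append(f"s{s}")
    if i is not None:
        parts.append(f"i{i}")
    return f"{fam}[{','.join(parts)}]"


class _Prepared:
    """Flattened trial arrays plus cell-index bookkeeping for one fit."""

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        d = data
        if "phase" in d.columns:
            d = d[d["phase"] == "test"]
        if "warmup" in d.columns:
            d = d[~d["warmup"].astype(bool)]
        d = d.reset_index(drop=True)
        if len(d) == 0:
            raise ValueError("no scored test trials in the data")
        self.subjects = np.sort(d["subject"].unique())
        self.blocks = np.sort(d["block"].unique())
        subj_map = {s: k for k, s in enumerate(self.subjects)}
        self.J = len(self.subjects)
        self.rt = d["rt"].to_numpy(float)
        if np.any(self.rt <= 0) or not np.all(np.isfinite(self.rt)):
            bad = d.index[(self.rt <= 0) | ~np.isfinite(self.rt)][0]
            raise ValueError(f"non-positive or non-finite RT at trial row {bad}")
        self.upper = d["accuracy"].to_numpy(int).astype(bool)
        self.subj = np.array([subj_map[s] for s in d["subject"]], dtype=np.int64)
        blk = d["block"].to_numpy(int)
        s_f = d["s" if "s" in d.columns else "switch_flag"].to_numpy(int)
        i_f = d["i" if "i" in d.columns else "incon_flag"].to_numpy(int)

        # parameter layout: [a cells | v cells | t0 cells], per subject
        self.families = ("a", "v", "t0")
        self.cells = {f: spec.cells(f, self.blocks) for f in self.families}
        self.col_of = {}
        k = 0
        self.param_names = []
        self.fam_cols = {}
        for f in self.families:
            cols = []
            for c in self.cells[f]:
                self.col_of[(f, c)] = k
                self.param_names.append(_cell_name(f, c))
                cols.append(k)
                k += 1
            self.fam_cols[f] = np.array(cols)
        self.K = k

        def trial_cols(f):
            code = getattr(spec, f)
            cols = np.empty(len(d), dtype=np.int64)
            for t in range(len(d)):
                b = blk[t]
                if code == "b":
                    cell = (b, None, None)
                elif code == "bs":
                    cell = (b, s_f[t], None)
                elif code == "bi":
                    cell = (b, None, i_f[t])
                else:
                    cell = (b, s_f[t], i_f[t])
                cols[t] = self.col_of[(f, cell)]
            return cols

        self.col_a = trial_cols("a")
        self.col_v = trial_cols("v")
        self.col_t0 = trial_cols("t0")

        # every subject needs trials in every cell the model distinguishes
        missing = []
        for cols, fam in ((self.col_a, "a"), (self.col_v, "v"), (self.col_t0, "t0")):
            counts = np.zeros((self.J, self.K), dtype=np.int64)
            np.add.at(counts, (self.subj, cols), 1)
            for jj in range(self.J):
                for c in self.fam_cols[fam]:
                    if counts[jj, c] == 0:
                        missing.append((self.subjects[jj], self.param_names[c]))
        if missing:
            raise ValueError(f"subjects with empty design cells: {sorted(set(missing))[:10]}")

        # per-subject contaminant windows from the observed RT range
        lo = np.zeros(self.J)
        hi = np.zeros(self.J)
        for jj in range(self.J):
            r = self.rt[self.subj == jj]
            lo[jj], hi[jj] = r.min(), r.max()
        self.win_lo = lo[self.subj]
        self.win_hi = hi[self.subj]
        self.subj_min_rt = lo

        # trials grouped by block; MH updates are blocked by task block
        # and parameter family (separate step-size adaptation per family)
        self.block_trials = {b: np.flatnonzero(blk == b) for b in self.blocks}
        self.update_blocks = []
        for b in self.blocks:
            for f in self.families:
                cols = np.array([self.col_of[(f, c)] for c in self.cells[f] if c[0] == b])
                self.update_blocks.append((b, f, cols))

        # transform bookkeeping: log for a and t0, identity for v
        self.is_log = np.zeros(self.K, dtype=bool)
        self.is_log[self.fam_cols["a"]] = True
        self.is_log[self.fam_cols["t0"]] = True

        # group prior hyperparameters per column
        self.prior_m0 = np.zeros(self.K)
        self.prior_s0 = np.ones(self.K)
        self.prior_m0[self.fam_cols["a"]] = np.log(1.5)
        self.prior_m0[self.fam_cols["v"]] = 1.0
        self.prior_s0[self.fam_cols["v"]] = 3.0
        self.prior_m0[self.fam_cols["t0"]] = np.log(0.3)


def _initial_theta(prep: _Prepared, rng) -> np.ndarray:
    """Crude moment-based starting values per subject (transformed scale)."""
    theta = np.zeros((prep.J, prep.K))
    theta[:, prep.fam_cols["a"]] = np.log(1.5)
    theta[:, prep.fam_cols["v"]] = 1.5
    for jj in range(prep.J):
        t0_guess = max(0.85 * prep.subj_min_rt[jj], 0.05)
        theta[jj, prep.fam_cols["t0"]] = np.log(t0_guess)
        acc = prep.upper[prep.subj == jj].mean()
        acc = min(max(acc, 0.55), 0.98)
        theta[jj, prep.fam_cols["v"]] = np.log(acc / (1 - acc)) / 1.5
    theta += rng.normal(0, 0.05, size=theta.shape)
    return theta


def _trial_params(theta, prep, trials):
    sub = prep.subj[trials]
    a = np.exp(theta[sub, prep.col_a[trials]])
    v = theta[sub, prep.col_v[trials]]
    t0 = np.exp(theta[sub, prep.col_t0[trials]])
    return a, v, t0


def _block_loglik(theta, prep, b, pi_cont):
    tr = prep.block_trials[b]
    a, v, t0 = _trial_params(theta, prep, tr)
    out = np.empty(len(tr))
    _kernels.mixture_logpdf_arr(
        prep.rt[tr], prep.upper[tr], a, v, t0, pi_cont,
        prep.win_lo[tr], prep.win_hi[tr], out,
    )
    return _kernels.sum_by_group(out, prep.subj[tr], prep.J)


def _run_chain(prep, mcmc_draws, burn, seed, pi_cont, adapt, thin=1):
    rng = np.random.default_rng(seed)
    theta = _initial_theta(prep, rng)
    mu = prep.prior_m0.copy()
    sig2 = np.full(prep.K, 0.25)
    # prior for group variances: inverse-gamma(a0, b0)
    ig_a0, ig_b0 = 2.5, 0.375

    ub = prep.update_blocks
    step = [np.full(prep.J, 0.12 if f == "v" else 0.06) for (_b, f, _c) in ub]
    curr_ll = {b: _block_loglik(theta, prep, b, pi_cont) for b in prep.blocks}
    acc_count = [np.zeros(prep.J) for _ in ub]
    acc_total = 0.0
    acc_n = 0

    n_iter = burn + mcmc_draws * thin
    n_store = prep.K * 2 + prep.J * prep.K
    out = np.empty((mcmc_draws, n_store))
    stored = 0

    for it in range(n_iter):
        # --- subject-level blocked MH, vectorized over subjects
        for u, (b, _f, cols) in enumerate(ub):
            prop = theta.copy()
            prop[:, cols] += step[u][:, None] * rng.standard_normal((prep.J, len(cols)))
            ll_prop = _block_loglik(prop, prep, b, pi_cont)
            dprior = (
                -0.5 * ((prop[:, cols] - mu[cols]) ** 2 / sig2[cols]).sum(axis=1)
                + 0.5 * ((theta[:, cols] - mu[cols]) ** 2 / sig2[cols]).sum(axis=1)
            )
            log_alpha = ll_prop - curr_ll[b] + dprior
            accept = np.log(rng.random(prep.J)) < log_alpha
            theta[np.ix_(accept, cols)] = prop[np.ix_(accept, cols)]
            curr_ll[b][accept] = ll_prop[accept]
            acc_count[u] += accept
            acc_total += accept.sum()
            acc_n += prep.J
            if adapt and it < burn and (it + 1) % 25 == 0:
                rate = acc_count[u] / 25.0
                step[u] *= np.exp(0.66 * (rate - 0.3))
                step[u] = np.clip(step[u], 1e-3, 1.0)
                acc_count[u][:] = 0.0

        # --- group-level conjugate Gibbs
        xbar = theta.mean(axis=0)
        prec = prep.J / sig2 + 1.0 / prep.prior_s0**2
        mean = (prep.J * xbar / sig2 + prep.prior_m0 / prep.prior_s0**2) / prec
        mu = mean + rng.standard_normal(prep.K) / np.sqrt(prec)
        ss = ((theta - mu) ** 2).sum(axis=0)
        sig2 = 1.0 / rng.gamma(ig_a0 + prep.J / 2.0, 1.0 / (ig_b0 + ss / 2.0))

        if it >= burn and (it - burn) % thin == thin - 1:
            nat = theta.copy()
            nat[:, prep.is_log] = np.exp(nat[:, prep.is_log])
            out[stored] = np.concatenate([mu, np.sqrt(sig2), nat.ravel()])
            stored += 1

    return out[:stored], acc_total / max(acc_n, 1)


def fit_hierarchical(
    data: pd.DataFrame,
    spec: ModelSpec | str,
    mcmc: McmcSettings | None = None,
    pi_cont: float = 0.05,
) -> PosteriorDraws:
    """Fit the hierarchical contaminated-Wiener model to trial data.

    ``data`` needs columns subject, block, s/switch_flag, i/incon_flag,
    accuracy, rt (seconds); only phase=='test', non-warm-up trials are
    used when those columns are present.  Runs ``mcmc.chains``
    independent chains; fully reproducible from ``mcmc.seed``.
    """
    if isinstance(spec, str):
        spec = ModelSpec.from_id(spec)
    mcmc = mcmc or McmcSettings()
    if mcmc.chains < 1:
        raise ValueError("need at least one chain")
    prep = _Prepared(data, spec)

    names = [f"mu_{n}" for n in prep.param_names]
    names += [f"sigma_{n}" for n in prep.param_names]
    for subj in prep.subjects:
        names += [f"{n}|subj{subj}" for n in prep.param_names]

    chains = []
    acc = []
    for c in range(mcmc.chains):
        samples, a_rate = _run_chain(
            prep, mcmc.draws, mcmc.burn, (mcmc.seed * 1000003 + c * 7919) % 2**31,
            pi_cont, mcmc.adapt, mcmc.thin,
        )
        chains.append(samples)
        acc.append(a_rate)
    arr = np.stack(chains)
    if not np.all(np.isfinite(arr)):
        raise RuntimeError("non-finite values in posterior draws")
    return PosteriorDraws(
        samples=arr, names=names, burn=mcmc.burn, seed=mcmc.seed,
        spec=spec, subjects=prep.subjects, acceptance=float(np.mean(acc)),
    )


# ---------------------------------------------------------------------------
# diagnostics


def gelman_rubin(draws: PosteriorDraws) -> ConvergenceReport:
    """Split Gelman-Rubin R-hat per parameter (each chain split in half)."""
    arr = draws.samples
    m, n, P = arr.shape
    if m < 2:
        raise ValueError("Gelman-Rubin diagnostic requires at least 2 chains")
    if n < 4:
        raise ValueError("need at least 4 post-burn-in iterations")
    half = n // 2
    split = np.concatenate([arr[:, :half, :], arr[:, half: 2 * half, :]], axis=0)
    cm = split.mean(axis=1)           # (2m, P)
    cv = split.var(axis=1, ddof=1)    # (2m, P)
    W = cv.mean(axis=0)
    B = half * cm.var(axis=0, ddof=1)
    var_plus = (half - 1) / half * W + B / half
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_plus / W)
    rhat = np.where(W <= 1e-300, 1.0, rhat)
    return ConvergenceReport(rhat=pd.Series(rhat, index=draws.names))


def posterior_difference_probability(
    draws: PosteriorDraws, param_a: str, param_b: str, one_sided: bool = False
) -> float:
    """Bayesian probability-of-difference between two parameters.

    Default is the folded exceedance 2*|Pr(a > b) - .5| over pooled
    post-burn-in draws (0 = indistinguishable, 1 = fully separated);
    ``one_sided=True`` returns Pr(a > b) itself.
    """
    xa = draws.pooled(param_a)
    xb = draws.pooled(param_b)
    p = float(np.mean(xa > xb))
    return p if one_sided else 2.0 * abs(p - 0.5)


def extract_subject_estimates(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior mean and SD per subject x distinguished cell, natural
    scale: tidy rows (subject, param, block, s, i, mean, sd)."""
    rows = []
    for name in draws.names:
        if "|subj" not in name:
            continue
        cellpart, subj = name.split("|subj")
        fam, cell = cellpart.split("[")
        toks = cell.rstrip("]").split(",")
        b = int(toks[0][1:])
        s = i = None
        for t in toks[1:]:
            if t.startswith("s"):
                s = int(t[1:])
            elif t.startswith("i"):
                i = int(t[1:])
        x = draws.pooled(name)
        rows.append(
            dict(subject=type(draws.subjects[0])(subj), param=fam, block=b, s=s, i=i,
                 mean=float(x.mean()), sd=float(x.std(ddof=1)))
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# posterior predictive checks

_QUANTILES = (0.1, 0.3, 0.5, 0.7, 0.9)


def _summaries(rt, upper, subj, col_cell, J, n_cells):
    """Per subject x cell summary vector: accuracy, RT quantiles of
    correct and of error responses."""
    out = np.full((J, n_cells, 1 + 2 * len(_QUANTILES)), np.nan)
    for jj in range(J):
        for c in range(n_cells):
            m = (subj == jj) & (col_cell == c)
            if not m.any():
                continue
            u = upper[m]
            out[jj, c, 0] = u.mean()
            rc = rt[m][u]
            re = rt[m][~u]
            if rc.size:
                out[jj, c, 1:6] = np.quantile(rc, _QUANTILES)
            if re.size:
                out[jj, c, 6:11] = np.quantile(re, _QUANTILES)
    return out


def posterior_predictive_mse(
    draws: PosteriorDraws,
    data: pd.DataFrame,
    n_rep: int = 500,
    seed: int = 0,
    dt: float = 2e-3,
    pi_cont: float = 0.05,
) -> PpcReport:
    """Posterior predictive model check.

    For each replicate: draw a posterior sample, simulate the full
    design, summarize per subject x (block,s,i) cell (accuracy plus the
    .1/.3/.5/.7/.9 RT quantiles of correct and error responses), then
    compare the replicate-mean summaries to the observed ones by mean
    squared error over the entries observed in the data.
    """
    if n_rep < 2:
        raise ValueError("need at least 2 posterior predictive replicates")
    # canonical trial order makes the check invariant to row/subject order
    s_name = "s" if "s" in data.columns else "switch_flag"
    i_name = "i" if "i" in data.columns else "incon_flag"
    data = data.sort_values(["subject", "block", s_name, i_name, "rt", "accuracy"],
                            kind="mergesort").reset_index(drop=True)
    prep = _Prepared(data, draws.spec)
    rng = np.random.default_rng(seed)

    # full (b,s,i) cells for summaries, independent of the model spec
    cells = [(b, s, i) for b in prep.blocks for s in (0, 1) for i in (0, 1)]
    cell_idx = {c: k for k, c in enumerate(cells)}
    d = data
    if "phase" in d.columns:
        d = d[d["phase"] == "test"]
    if "warmup" in d.columns:
        d = d[~d["warmup"].astype(bool)]
    blk = d["block"].to_numpy(int)
    s_f = d["s" if "s" in d.columns else "switch_flag"].to_numpy(int)
    i_f = d["i" if "i" in d.columns else "incon_flag"].to_numpy(int)
    col_cell = np.array([cell_idx[(b, s, i)] for b, s, i in zip(blk, s_f, i_f)])

    obs = _summaries(prep.rt, prep.upper, prep.subj, col_cell, prep.J, len(cells))

    m, n, _ = draws.samples.shape
    subj_block_len = prep.J * prep.K
    sim_acc = np.zeros_like(obs)
    sim_cnt = np.zeros_like(obs)
    for _rep in range(n_rep):
        ci = rng.integers(m)
        ti = rng.integers(n)
        nat = draws.samples[ci, ti, 2 * prep.K: 2 * prep.K + subj_block_len].reshape(prep.J, prep.K)
        theta = nat.copy()
        theta[:, prep.is_log] = np.log(theta[:, prep.is_log])
        a, v, t0 = _trial_params(theta, prep, np.arange(len(prep.rt)))
        rt, up, _c = _kernels.simulate_fpt_arr(
            a, v, t0, pi_cont, float(prep.win_lo.min()), float(prep.win_hi.max()),
            dt, int(rng.integers(2**31)),
        )
        s = _summaries(rt, up, prep.subj, col_cell, prep.J, len(cells))
        good = np.isfinite(s)
        sim_acc[good] += s[good]
        sim_cnt[good] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        sim_mean = sim_acc / sim_cnt
    valid = np.isfinite(obs) & np.isfinite(sim_mean)
    sq = (obs - sim_mean) ** 2
    mse = float(sq[valid].mean())
    stat_names = (
        ["accuracy"]
        + [f"rt_correct_q{int(q * 100)}" for q in _QUANTILES]
        + [f"rt_error_q{int(q * 100)}" for q in _QUANTILES]
    )
    per_stat = {}
    for k, nme in enumerate(stat_names):
        v_k = valid[:, :, k]
        per_stat[nme] = float(sq[:, :, k][v_k].mean()) if v_k.any() else float("nan")
    return PpcReport(mse=mse, n_rep=n_rep, statistics=stat_names, per_statistic=per_stat)
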