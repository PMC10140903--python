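"""Synthetic task-switching and Recall-N-Back data.

Emulates a color/size switching paradigm (three mixed test blocks of 128
scored trials, eight warm-up trials each, balanced switch x congruency
cells, preceded by two task-pure blocks and a mixed practice block) and
a figural Recall-N-Back working-memory task (12 test blocks crossing
memory load 1-4 with 6/9/12 updates).  Subject-level diffusion
parameters and working-memory capacity are drawn from a multivariate
normal population with user-specified latent correlations, so the whole
downstream pipeline can be validated against known ground truth.

Default population values reproduce the magnitudes typical of this
paradigm: baseline non-decision time ~298 ms with an ~88 ms switch
increment, baseline drift ~1.94 with decrements of ~-.29 (switch) and
~-.62 (incongruency), and a negative correlation (~-.40) between
working-memory capacity and the non-decision-time increment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .wiener import DEFAULT_CONTAMINANT_WINDOW

__all__ = [
    "LATENT_NAMES",
    "PopulationSpec",
    "make_trial_list",
    "sample_population",
    "simulate_switch_task",
    "simulate_rnb",
    "rnb_design",
]

#: order of the population latents everywhere in this module
LATENT_NAMES = ("t0_base", "dt0_switch", "v_base", "dv_switch", "dv_incon", "a", "wmc")

_DEFAULT_MEANS = {
    "t0_base": 0.298,
    "dt0_switch": 0.088,
    "v_base": 1.938,
    "dv_switch": -0.293,
    "dv_incon": -0.619,
    "a": 1.5,
    "wmc": 0.0,
}
_DEFAULT_SDS = {
    "t0_base": 0.05,
    "dt0_switch": 0.035,
    "v_base": 0.45,
    "dv_switch": 0.20,
    "dv_incon": 0.25,
    "a": 0.28,
    "wmc": 1.0,
}
# nonzero latent correlations of the default population
_DEFAULT_CORR = {
    ("t0_base", "dt0_switch"): 0.15,
    ("v_base", "dv_switch"): -0.32,
    ("wmc", "t0_base"): -0.01,
    ("wmc", "dt0_switch"): -0.40,
    ("wmc", "v_base"): 0.18,
    ("wmc", "dv_switch"): 0.30,
    ("wmc", "dv_incon"): -0.27,
    ("wmc", "a"): -0.28,
}
# additive block shifts (block 1..3) applied to the baseline latents
_DEFAULT_BLOCK_EFFECTS = {
    "a": (0.12, 0.0, -0.10),
    "t0_base": (0.01, 0.0, -0.01),
    "v_base": (-0.20, 0.0, 0.15),
}


def default_corr_matrix() -> np.ndarray:
    m = np.eye(len(LATENT_NAMES))
    idx = {n: i for i, n in enumerate(LATENT_NAMES)}
    for (x, y), r in _DEFAULT_CORR.items():
        m[idx[x], idx[y]] = m[idx[y], idx[x]] = r
    return m


@dataclass
class PopulationSpec:
    """Generative ground truth for a synthetic cohort.

    ``means``/``sds`` are per-latent (see :data:`LATENT_NAMES`);
    ``corr`` is the latent correlation matrix in the same order;
    ``block_effects`` are additive shifts applied per test block.
    Sampled boundary separation and non-decision times are truncated to
    valid ranges; the truncation rate is reported by
    :func:`sample_population` and is < 1% under the defaults.
    """

    n_subjects: int = 101
    means: dict = field(default_factory=lambda: dict(_DEFAULT_MEANS))
    sds: dict = field(default_factory=lambda: dict(_DEFAULT_SDS))
    corr: np.ndarray = field(default_factory=default_corr_matrix)
    block_effects: dict = field(default_factory=lambda: {k: tuple(v) for k, v in _DEFAULT_BLOCK_EFFECTS.items()})
    pi_cont: float = 0.05
    contaminant_window: tuple = DEFAULT_CONTAMINANT_WINDOW
    min_a: float = 0.3
    min_t0: float = 0.05
    rng_seed: int = 0

    def validate(self):
        c = np.asarray(self.corr, dtype=float)
        if c.shape != (len(LATENT_NAMES),) * 2 or not np.allclose(c, c.T):
            raise ValueError("corr must be a symmetric matrix over the population latents")
        ev = np.linalg.eigvalsh(c)
        if ev.min() < -1e-10:
            raise ValueError(f"latent correlation matrix is not positive semi-definite (min eigenvalue {ev.min():.3g})")
        if any(self.sds[n] < 0 for n in LATENT_NAMES):
            raise ValueError("latent SDs must be non-negative")
        return self


# ---------------------------------------------------------------------------
# trial lists


def _balanced_si_sequence(n: int, rng: np.random.Generator, max_repeat_run: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """s/i flags for one scored block: equal s x i cell counts, with runs
    of consecutive task repeats capped (identical-task runs <= max+1)."""
    assert n % 4 == 0
    while True:  # sequential construction with restart on dead ends
        s = np.empty(n, dtype=int)
        left = [n // 2, n // 2]  # remaining zeros (repeats), ones (switches)
        run0 = 0
        ok = True
        for t in range(n):
            choices = []
            if left[0] > 0 and run0 < max_repeat_run:
                choices.append(0)
            if left[1] > 0:
                choices.append(1)
            if not choices:
                ok = False
                break
            c = choices[rng.integers(len(choices))] if len(choices) == 2 else choices[0]
            if len(choices) == 2:
                # weight by remaining counts to avoid biased tails
                p0 = left[0] / (left[0] + left[1])
                c = 0 if rng.random() < p0 else 1
                if c == 0 and run0 >= max_repeat_run:
                    c = 1
            s[t] = c
            left[c] -= 1
            run0 = run0 + 1 if c == 0 else 0
        if ok and left == [0, 0]:
            break
    i = np.empty(n, dtype=int)
    for sv in (0, 1):
        pos = np.flatnonzero(s == sv)
        flags = np.array([0] * (len(pos) // 2) + [1] * (len(pos) // 2))
        rng.shuffle(flags)
        i[pos] = flags
    return s, i


def make_trial_list(
    seed: int,
    n_test_blocks: int = 3,
    trials_per_block: int = 128,
    n_warmup: int = 8,
    pure_block_trials: int = 44,
    practice_trials: int = 24,
) -> pd.DataFrame:
    """Build the design skeleton (no responses): two task-pure blocks, a
    mixed practice block, then the mixed test blocks of
    ``n_warmup + trials_per_block`` trials each with balanced s x i cells
    among the scored trials.  The switch flag of the first scored trial
    is defined relative to the last warm-up trial."""
    rng = np.random.default_rng(seed)
    shapes = np.array(["triangle", "square", "circle"])
    rows = []

    def emit(phase, block, idx, task, s, i, warmup):
        rows.append(
            dict(
                phase=phase, block=block, trial_index=idx, task=task,
                switch_flag=s, incon_flag=i,
                shape=shapes[rng.integers(3)],
                correct_response="left" if rng.random() < 0.5 else "right",
                warmup=warmup,
            )
        )

    for b, task in enumerate(("size", "color")):
        for t in range(pure_block_trials):
            emit("pure", b + 1, t, task, 0, int(rng.random() < 0.5), False)
    task = "size" if rng.random() < 0.5 else "color"
    for t in range(practice_trials):
        s = int(rng.random() < 0.5)
        if s:
            task = "color" if task == "size" else "size"
        emit("practice", 1, t, task, s, int(rng.random() < 0.5), False)

    for b in range(1, n_test_blocks + 1):
        task = "size" if rng.random() < 0.5 else "color"
        for t in range(n_warmup):
            s = int(rng.random() < 0.5)
            if s:
                task = "color" if task == "size" else "size"
            emit("test", b, t, task, s, int(rng.random() < 0.5), True)
        s_seq, i_seq = _balanced_si_sequence(trials_per_block, rng)
        for t in range(trials_per_block):
            if s_seq[t]:
                task = "color" if task == "size" else "size"
            emit("test", b, n_warmup + t, task, int(s_seq[t]), int(i_seq[t]), False)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# population


def sample_population(spec: PopulationSpec, seed: int | None = None):
    """Draw subject latents and assemble per-cell diffusion parameters.

    Returns ``(latents, cell_params, truncation_rate)``: latents is one
    row per subject with the ground-truth values; cell_params is one row
    per subject x block x s x i with columns a, v, t0.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed if seed is None else seed)
    names = list(LATENT_NAMES)
    mu = np.array([spec.means[n] for n in names])
    sd = np.array([spec.sds[n] for n in names])
    cov = np.outer(sd, sd) * np.asarray(spec.corr, dtype=float)
    lat = rng.multivariate_normal(mu, cov, size=spec.n_subjects, method="svd")
    latents = pd.DataFrame(lat, columns=names)
    latents.insert(0, "subject", np.arange(spec.n_subjects))

    n_blocks = len(next(iter(spec.block_effects.values()))) if spec.block_effects else 3
    be = {k: np.asarray(v, dtype=float) for k, v in spec.block_effects.items()}
    zeros = np.zeros(n_blocks)
    rows = []
    n_trunc = 0
    n_cells = 0
    for j in range(spec.n_subjects):
        L = latents.iloc[j]
        for b in range(1, n_blocks + 1):
            a = L["a"] + be.get("a", zeros)[b - 1]
            if a < spec.min_a:
                a = spec.min_a
                n_trunc += 1
            for s in (0, 1):
                t0 = L["t0_base"] + be.get("t0_base", zeros)[b - 1] + s * L["dt0_switch"]
                if t0 < spec.min_t0:
                    t0 = spec.min_t0
                    n_trunc += 1
                for i in (0, 1):
                    v = (
                        L["v_base"] + be.get("v_base", zeros)[b - 1]
                        + s * L["dv_switch"] + i * L["dv_incon"]
                    )
                    rows.append(dict(subject=j, block=b, s=s, i=i, a=float(a), v=float(v), t0=float(t0)))
                    n_cells += 1
    cell_params = pd.DataFrame(rows)
    return latents, cell_params, n_trunc / n_cells


# ---------------------------------------------------------------------------
# behavior simulation


def simulate_switch_task(
    cell_params: pd.DataFrame,
    trial_list: pd.DataFrame,
    seed: int,
    pi_cont: float = 0.05,
    contaminant_window: tuple = DEFAULT_CONTAMINANT_WINDOW,
    dt: float = 1e-3,
    include_warmup: bool = True,
) -> pd.DataFrame:
    """Fill responses/RTs for every subject over the mixed test blocks.

    All subjects share the (pseudo-random, standardized) trial list.
    Accuracy coding: the upper boundary is the correct response.
    """
    design = trial_list[trial_list["phase"] == "test"]
    if not include_warmup:
        design = design[~design["warmup"]]
    design = design.reset_index(drop=True)
    subjects = np.sort(cell_params["subject"].unique())

    out = []
    for j in subjects:
        pj = cell_params[cell_params["subject"] == j]
        merged = design.merge(
            pj[["block", "s", "i", "a", "v", "t0"]],
            left_on=["block", "switch_flag", "incon_flag"],
            right_on=["block", "s", "i"],
            how="left",
        )
        if merged["a"].isna().any():
            bad = merged[merged["a"].isna()].iloc[0]
            raise ValueError(
                f"missing diffusion parameters for subject {j}, "
                f"block {bad['block']}, s={bad['switch_flag']}, i={bad['incon_flag']}"
            )
        a = merged["a"].to_numpy(float)
        v = merged["v"].to_numpy(float)
        t0 = merged["t0"].to_numpy(float)
        lo, hi = contaminant_window
        rt, up, contam = _kernels.simulate_fpt_arr(
            a, v, t0, pi_cont, lo, hi, dt, (int(seed) * 100003 + int(j)) % 2**31
        )
        d = design.copy()
        d.insert(0, "subject", j)
        d["accuracy"] = up.astype(int)
        d["rt"] = rt
        d["contaminant"] = contam
        d["response"] = np.where(
            up, d["correct_response"],
            np.where(d["correct_response"] == "left", "right", "left"),
        )
        out.append(d)
    return pd.concat(out, ignore_index=True)


def rnb_design(n_practice: int = 3) -> pd.DataFrame:
    """The 12-block test design (load 1-4 x 6/9/12 updates, each once)
    preceded by short practice blocks."""
    rows = []
    for k in range(n_practice):
        rows.append(dict(phase="practice", block=k + 1, load=min(k + 1, 3), n_updates=6))
    b = 0
    for load in (1, 2, 3, 4):
        for upd in (6, 9, 12):
            b += 1
            rows.append(dict(phase="test", block=b, load=load, n_updates=upd))
    return pd.DataFrame(rows)


def simulate_rnb(
    latents: pd.DataFrame,
    seed: int,
    design: pd.DataFrame | None = None,
    intercept: float = 2.2,
    slope_wmc: float = 0.9,
    slope_load: float = -0.55,
) -> pd.DataFrame:
    """Bernoulli correctness per update response via a logistic link:
    logit(p) = intercept + slope_wmc * wmc + slope_load * (load - 1).

    The link is a device to endow synthetic responses with a graded
    working-memory-capacity structure; higher wmc means stochastically
    more correct responses when slope_wmc > 0.
    """
    rng = np.random.default_rng(seed)
    if design is None:
        design = rnb_design()
    rows = []
    for r in latents.itertuples():
        for b in design.itertuples():
            eta = intercept + slope_wmc * r.wmc + slope_load * (b.load - 1)
            p = 1.0 / (1.0 + np.exp(-eta))
            if not (0.0 < p < 1.0):
                raise ValueError(f"link produced degenerate probability {p}")
            correct = (rng.random(b.n_updates) < p).astype(int)
            for t, c in enumerate(correct):
                rows.append(
                    dict(
                        subject=r.subject, phase=b.phase, block=b.block,
                        load=b.load, n_updates=b.n_updates, trial_index=t,
                        correct=int(c),
                    )
                )
    return pd.DataFrame(rows)
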