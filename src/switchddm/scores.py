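"""Conventional performance scoring.

Latency of correct trials is scored as speed (1/RT, responses per
second) and accuracy as probit-transformed error proportions, both to
de-skew the raw metrics.  Switch and incongruency costs come in a
global form (marginal means over the other factor) and a specific form
(only the cells that isolate the requirement).  Working-memory scores
from the Recall-N-Back task use partial-credit scoring (count of
correct individual responses over the scored test blocks, loads 2-4)
and are split into three parallel parcels by a fixed Latin square over
load x update-count.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "score_cells",
    "effect_scores",
    "rm_anova",
    "score_rnb",
    "build_parcels",
    "PARCEL_ASSIGNMENT",
]

#: fixed Latin-square assignment of the nine scored Recall-N-Back blocks
#: (load, n_updates) to parcels; each parcel sees every load and every
#: update count exactly once.
PARCEL_ASSIGNMENT = {
    1: ((2, 6), (3, 9), (4, 12)),
    2: ((2, 9), (3, 12), (4, 6)),
    3: ((2, 12), (3, 6), (4, 9)),
}


def score_cells(trials: pd.DataFrame, probit_correction: bool = True,
                speed_of_mean: bool = False) -> pd.DataFrame:
    """Per subject x block x s x i cell scores from scored test trials.

    Only rows with phase=='test' and warmup False enter (filtered here
    if the columns are present).  Speed is the mean of per-trial 1/RT
    over correct trials by default; ``speed_of_mean`` switches to the
    reciprocal of the mean RT.  Error proportions are probit-transformed
    after the edge correction (e + .5) / (n + 1) so empty and perfect
    cells stay finite.
    """
    d = trials
    if "phase" in d.columns:
        d = d[d["phase"] == "test"]
    if "warmup" in d.columns:
        d = d[~d["warmup"].astype(bool)]
    s_col = "s" if "s" in d.columns else "switch_flag"
    i_col = "i" if "i" in d.columns else "incon_flag"
    rows = []
    for (subj, b, s, i), g in d.groupby(["subject", "block", s_col, i_col]):
        n = len(g)
        n_correct = int(g["accuracy"].sum())
        corr_rt = g.loc[g["accuracy"] == 1, "rt"]
        err = n - n_correct
        e_rate = err / n
        p = (err + 0.5) / (n + 1) if probit_correction else e_rate
        rows.append(
            dict(
                subject=subj, block=b, s=s, i=i,
                n_trials=n, n_correct=n_correct,
                mean_rt=float(corr_rt.mean()) if n_correct else np.nan,
                speed=(1.0 / float(corr_rt.mean()) if speed_of_mean
                       else float((1.0 / corr_rt).mean())) if n_correct else np.nan,
                error_rate=e_rate,
                probit_error=float(stats.norm.ppf(p)),
                empty_correct=n_correct == 0,
            )
        )
    return pd.DataFrame(rows)


def effect_scores(cells: pd.DataFrame, measure: str = "mean_rt") -> pd.DataFrame:
    """Per-subject, per-block switch and incongruency effects.

    global switch  = mean(s=1 cells) - mean(s=0 cells), both i
    specific switch = (s1,i0) - (s0,i0)
    global incon   = mean(i=1) - mean(i=0), both s
    specific incon = (s0,i1) - (s0,i0)

    RT-based measures are reported in ms; other measures (error_rate,
    speed, probit_error) keep their units.
    """
    scale = 1000.0 if measure == "mean_rt" else 1.0
    rows = []
    for (subj, b), g in cells.groupby(["subject", "block"]):
        cell = {}
        for s in (0, 1):
            for i in (0, 1):
                m = g[(g["s"] == s) & (g["i"] == i)]
                if len(m) != 1:
                    raise ValueError(f"missing cell s={s}, i={i} for subject {subj}, block {b}")
                cell[(s, i)] = float(m[measure].iloc[0]) * scale
        rows.append(
            dict(
                subject=subj, block=b, measure=measure,
                global_switch=(cell[(1, 0)] + cell[(1, 1)]) / 2 - (cell[(0, 0)] + cell[(0, 1)]) / 2,
                specific_switch=cell[(1, 0)] - cell[(0, 0)],
                global_incon=(cell[(0, 1)] + cell[(1, 1)]) / 2 - (cell[(0, 0)] + cell[(1, 0)]) / 2,
                specific_incon=cell[(0, 1)] - cell[(0, 0)],
            )
        )
    return pd.DataFrame(rows)


def rm_anova(scores: pd.DataFrame, dv: str, factors: list[str],
             subject: str = "subject") -> pd.DataFrame:
    """Fully-crossed repeated-measures ANOVA by explicit sums of squares.

    One observation per subject x cell is required.  Each within-subject
    term is tested against its interaction with subjects; partial eta
    squared is SS_effect / (SS_effect + SS_error).  Degrees of freedom
    are unadjusted (no sphericity correction).
    """
    d = scores[[subject] + factors + [dv]].copy()
    levels = {f: np.sort(d[f].unique()) for f in factors}
    subs = np.sort(d[subject].unique())
    shape = [len(subs)] + [len(levels[f]) for f in factors]
    Y = np.full(shape, np.nan)
    sub_ix = {s: k for k, s in enumerate(subs)}
    lev_ix = [{v: k for k, v in enumerate(levels[f])} for f in factors]
    for row in d.itertuples(index=False):
        idx = (sub_ix[getattr(row, subject)],) + tuple(
            lev_ix[k][getattr(row, f)] for k, f in enumerate(factors)
        )
        if not np.isnan(Y[idx]):
            raise ValueError("more than one observation per subject x cell")
        Y[idx] = getattr(row, dv)
    if np.isnan(Y).any():
        raise ValueError("incomplete design: missing subject x cell combinations")

    n_sub = len(subs)
    axes_of = {f: k + 1 for k, f in enumerate(factors)}  # axis 0 = subject

    def effect_tensor(which_axes):
        """Inclusion-exclusion estimate of the effect for the given axes."""
        total = np.zeros_like(Y)
        all_axes = set(range(Y.ndim))
        for r in range(len(which_axes) + 1):
            for sub in itertools.combinations(which_axes, r):
                mean_over = tuple(all_axes - set(sub))
                m = Y.mean(axis=mean_over, keepdims=True)
                total += (-1) ** (len(which_axes) - r) * m
        return total

    out = []
    for order in range(1, len(factors) + 1):
        for term in itertools.combinations(factors, order):
            ax = tuple(axes_of[f] for f in term)
            est = effect_tensor(ax)
            ss_eff = float((est**2).sum()) / 1  # est is broadcast to full shape
            est_err = effect_tensor((0,) + ax)
            ss_err = float((est_err**2).sum())
            # est**2 summed over the full tensor counts each cell once:
            # the broadcasting already multiplies by the sizes of the
            # averaged-over axes, which is exactly the SS weighting.
            df_eff = int(np.prod([len(levels[f]) - 1 for f in term]))
            df_err = df_eff * (n_sub - 1)
            ms_eff = ss_eff / df_eff
            ms_err = ss_err / df_err
            F = ms_eff / ms_err if ms_err > 0 else 0.0
            p = float(stats.f.sf(F, df_eff, df_err)) if ms_err > 0 else 1.0
            out.append(
                dict(
                    term=" x ".join(term), ss=ss_eff, ss_error=ss_err,
                    df=df_eff, df_error=df_err, F=F, p=p,
                    eta_p2=ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0,
                )
            )
    return pd.DataFrame(out)


def score_rnb(records: pd.DataFrame) -> pd.DataFrame:
    """Partial-credit working-memory scores with parcels.

    Counts correct responses over test blocks with load >= 2 (load-one
    blocks require no memory updating and are excluded); parcels follow
    :data:`PARCEL_ASSIGNMENT`.
    """
    d = records
    if "phase" in d.columns:
        d = d[d["phase"] == "test"]
    d = d[d["load"] >= 2]
    block_scores = (
        d.groupby(["subject", "load", "n_updates"])["correct"].sum().reset_index()
    )
    rows = []
    for subj, g in block_scores.groupby("subject"):
        parcels = build_parcels(g)
        rows.append(
            dict(
                subject=subj,
                partial_credit_total=int(sum(parcels.values())),
                parcel_1=int(parcels[1]), parcel_2=int(parcels[2]), parcel_3=int(parcels[3]),
            )
        )
    return pd.DataFrame(rows)


def build_parcels(block_scores: pd.DataFrame) -> dict:
    """Sum per-block correct counts into the three fixed parcels.

    ``block_scores`` needs one row per (load, n_updates) with a
    'correct' column; all nine scored blocks must be present.
    """
    key = {(int(r.load), int(r.n_updates)): float(r.correct) for r in block_scores.itertuples()}
    out = {}
    for parcel, blocks in PARCEL_ASSIGNMENT.items():
        try:
            out[parcel] = sum(key[b] for b in blocks)
        except KeyError as e:
            raise ValueError(f"missing Recall-N-Back block (load, n_updates) = {e.args[0]}") from None
    return out
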