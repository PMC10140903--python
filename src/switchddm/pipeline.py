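"""End-to-end orchestration: simulate -> fit -> score -> LDS -> report.

The pipeline is reproducible from a single config + seed; every stage
writes plain CSV/JSON artifacts.  The recovery study repeats the
simulate->fit cycle against known population ground truth and reports
bias/RMSE of the key quantities plus how often posterior-predictive
model comparison selects the generating model.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ddm_fit, lds, scores, synthetic

log = logging.getLogger("switchddm")

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "recovery_study",
    "write_trials_csv",
    "read_trials_csv",
    "estimates_to_indicators",
]

#: canonical column schema (and dtypes) of trial-level CSV files
TRIAL_SCHEMA = [
    "subject", "phase", "block", "trial_index", "task", "switch_flag",
    "incon_flag", "shape", "correct_response", "response", "accuracy",
    "rt", "warmup",
]


@dataclass
class PipelineConfig:
    """Everything a run needs; serializable to YAML/JSON."""

    seed: int = 0
    n_subjects: int = 40
    model_id: str = "M2"
    chains: int = 2
    draws: int = 500
    burn: int = 400
    thin: int = 2
    pi_cont: float = 0.05
    speed_of_mean: bool = False
    exclude_subjects: tuple = ()
    population: dict = field(default_factory=dict)
    ppc_replicates: int = 20

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self))

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text) or {}
        if "exclude_subjects" in d:
            d["exclude_subjects"] = tuple(d["exclude_subjects"])
        return cls(**d)

    def population_spec(self) -> synthetic.PopulationSpec:
        kw = dict(self.population)
        kw.setdefault("n_subjects", self.n_subjects)
        kw.setdefault("rng_seed", self.seed)
        if "corr" in kw:
            kw["corr"] = np.asarray(kw["corr"], dtype=float)
        return synthetic.PopulationSpec(**kw)


def write_trials_csv(trials: pd.DataFrame, path, unit: str = "s") -> None:
    """Write the trial table in the canonical schema; ``unit`` records
    whether rt is in seconds ('s') or milliseconds ('ms')."""
    d = trials.copy()
    if unit == "ms":
        d["rt"] = d["rt"] * 1000.0
    elif unit != "s":
        raise ValueError("unit must be 's' or 'ms'")
    cols = [c for c in TRIAL_SCHEMA if c in d.columns]
    d[cols].to_csv(path, index=False)


def read_trials_csv(path, unit: str = "s") -> pd.DataFrame:
    """Read a trial CSV; pass unit='ms' to convert millisecond RTs to
    the seconds used internally."""
    d = pd.read_csv(path)
    missing = [c for c in ("subject", "block", "accuracy", "rt") if c not in d.columns]
    if missing:
        raise ValueError(f"trial CSV lacks required columns: {missing}")
    if unit == "ms":
        d["rt"] = d["rt"] / 1000.0
    elif unit != "s":
        raise ValueError("unit must be 's' or 'ms'")
    return d


def estimates_to_indicators(estimates: pd.DataFrame) -> pd.DataFrame:
    """Pivot tidy subject-level posterior means into wide indicator
    columns: a_b<b>, t0_b<b>_s<s>, v_b<b>_s<s>_i<i> (cells the model
    does not distinguish keep their reduced names)."""
    rows = {}
    for r in estimates.itertuples():
        name = f"{r.param}_b{r.block}"
        if r.s is not None and not (isinstance(r.s, float) and np.isnan(r.s)):
            name += f"_s{int(r.s)}"
        if r.i is not None and not (isinstance(r.i, float) and np.isnan(r.i)):
            name += f"_i{int(r.i)}"
        rows.setdefault(r.subject, {})[name] = r.mean
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out.index.name = "subject"
    return out.reset_index()


def run_pipeline(config: PipelineConfig, out_dir=None, trials: pd.DataFrame | None = None,
                 rnb: pd.DataFrame | None = None) -> dict:
    """Run the full analysis; returns the report dict (and writes
    artifacts when ``out_dir`` is given).

    Without external data, a synthetic cohort is generated from the
    config's population spec.  Stages: trial simulation, conventional
    scoring + repeated-measures ANOVAs, hierarchical diffusion fit with
    convergence diagnostics, working-memory scoring and parceling, the
    three LDS models, and the latent caution factor model.
    """
    cfg = config
    report: dict = {"config": dataclasses.asdict(cfg)}
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    spec = cfg.population_spec()
    latents = None
    if trials is None:
        log.info("simulating cohort of %d subjects (seed %d)", spec.n_subjects, cfg.seed)
        latents, cell_params, trunc = synthetic.sample_population(spec)
        trial_list = synthetic.make_trial_list(cfg.seed + 1)
        trials = synthetic.simulate_switch_task(
            cell_params, trial_list, seed=cfg.seed + 2,
            pi_cont=cfg.pi_cont, contaminant_window=spec.contaminant_window,
        )
        report["truncation_rate"] = trunc
    if rnb is None:
        if latents is None:
            raise ValueError("external trial data requires external Recall-N-Back data")
        rnb = synthetic.simulate_rnb(latents, seed=cfg.seed + 3)

    if cfg.exclude_subjects:
        trials = trials[~trials["subject"].isin(cfg.exclude_subjects)]
        rnb = rnb[~rnb["subject"].isin(cfg.exclude_subjects)]

    # --- conventional scores
    cells = scores.score_cells(trials, speed_of_mean=cfg.speed_of_mean)
    cell_means = cells.groupby(["s", "i", "block"])[["mean_rt", "error_rate"]].mean()
    report["cell_means"] = {
        f"s{s}_i{i}_b{b}": dict(mean_rt_ms=float(v["mean_rt"] * 1000), error_rate=float(v["error_rate"]))
        for (s, i, b), v in cell_means.iterrows()
    }
    anova_in = cells.copy()
    report["anova_speed"] = scores.rm_anova(anova_in, "speed", ["block", "s", "i"]).to_dict("records")
    report["anova_probit_error"] = scores.rm_anova(anova_in, "probit_error", ["block", "s", "i"]).to_dict("records")
    effects = scores.effect_scores(cells, "mean_rt")
    report["rt_effects_ms"] = effects.groupby("block")[
        ["global_switch", "specific_switch", "global_incon", "specific_incon"]
    ].mean().to_dict("index")

    # --- hierarchical diffusion fit
    mcmc = ddm_fit.McmcSettings(chains=cfg.chains, draws=cfg.draws, burn=cfg.burn,
                                thin=cfg.thin, seed=cfg.seed + 4)
    draws = ddm_fit.fit_hierarchical(trials, cfg.model_id, mcmc, pi_cont=cfg.pi_cont)
    if cfg.chains >= 2:
        conv = ddm_fit.gelman_rubin(draws)
        report["rhat"] = dict(mean=conv.mean, sd=conv.sd, range=list(conv.range))
    est = ddm_fit.extract_subject_estimates(draws)
    indicators = estimates_to_indicators(est)
    report["parameter_summaries"] = {
        p: {
            q: float(v)
            for q, v in est[est.param == p]["mean"].describe().items()
            if q in ("mean", "std", "25%", "50%", "75%")
        }
        for p in ("a", "v", "t0")
    }

    # --- working memory
    wmc = scores.score_rnb(rnb)

    # --- LDS models
    lds_results = {}
    for param, contrast, label in (
        ("t0", "switch", "switch_t0"),
        ("v", "switch", "switch_v"),
        ("v", "incongruency", "incon_v"),
    ):
        mspec = lds.build_lds_spec(param, contrast, indicators, wmc)
        data = lds.assemble_lds_data(mspec, indicators, wmc)
        fit = lds.fit_sem(mspec, data, seed=cfg.seed + 5)
        lds_results[label] = dict(
            i_B=fit.i_B, i_D=fit.i_D, rho1=fit.rho1, rho2=fit.rho2, rho3=fit.rho3,
            p_values={k: fit.p_values[k] for k in ("i_B", "i_D", "rho1", "rho2", "rho3")},
            chi2=fit.chi2, df=fit.df, p=fit.p, rmsea=fit.rmsea,
            rmsea_ci=list(fit.rmsea_ci), srmr=fit.srmr, cfi=fit.cfi, tli=fit.tli,
            converged=fit.converged, n=fit.n,
        )
    report["lds"] = lds_results

    caution = lds.fit_caution_factor(indicators, wmc, seed=cfg.seed + 6)
    report["caution_factor"] = {
        k: (list(v) if isinstance(v, tuple) else v) for k, v in caution.items()
    }

    if out_path is not None:
        write_trials_csv(trials, out_path / "trials.csv")
        cells.to_csv(out_path / "cell_scores.csv", index=False)
        indicators.to_csv(out_path / "ddm_estimates.csv", index=False)
        wmc.to_csv(out_path / "wmc_scores.csv", index=False)
        (out_path / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report


def recovery_study(config: PipelineConfig, n_replications: int = 10,
                   compare_models: tuple = ("M1", "M2", "M3"),
                   ppc_replicates: int | None = None) -> pd.DataFrame:
    """Repeat simulate -> fit over replications; per replication report
    the recovered group-level non-decision switch increment (bias
    against the generating value) and which model the posterior
    predictive MSE prefers."""
    if n_replications < 2:
        raise ValueError("need at least 2 replications")
    cfg = config
    n_rep_ppc = ppc_replicates or cfg.ppc_replicates
    rows = []
    for r in range(n_replications):
        seed = cfg.seed + 1000 * (r + 1)
        spec = cfg.population_spec()
        spec.rng_seed = seed
        latents, cell_params, _ = synthetic.sample_population(spec)
        trial_list = synthetic.make_trial_list(seed + 1)
        trials = synthetic.simulate_switch_task(
            cell_params, trial_list, seed=seed + 2, pi_cont=cfg.pi_cont,
            contaminant_window=spec.contaminant_window, dt=2e-3,
        )
        true_inc = float(latents["dt0_switch"].mean())

        mses = {}
        est_inc = np.nan
        for mid in compare_models:
            mcmc = ddm_fit.McmcSettings(chains=cfg.chains, draws=cfg.draws,
                                        burn=cfg.burn, thin=cfg.thin, seed=seed + 3)
            draws = ddm_fit.fit_hierarchical(trials, mid, mcmc, pi_cont=cfg.pi_cont)
            ppc = ddm_fit.posterior_predictive_mse(
                draws, trials, n_rep=n_rep_ppc, seed=seed + 4, pi_cont=cfg.pi_cont
            )
            mses[mid] = ppc.mse
            if mid == cfg.model_id:
                est = ddm_fit.extract_subject_estimates(draws)
                t0w = est[est.param == "t0"].pivot_table(
                    index=["subject", "block"], columns="s", values="mean"
                )
                if 1 in t0w.columns and 0 in t0w.columns:
                    est_inc = float((t0w[1] - t0w[0]).mean())
        preferred = min(mses, key=mses.get)
        rows.append(
            dict(
                replication=r, true_t0_increment=true_inc,
                est_t0_increment=est_inc, bias=est_inc - true_inc,
                preferred_model=preferred, generating_selected=preferred == cfg.model_id,
                **{f"mse_{k}": v for k, v in mses.items()},
            )
        )
    return pd.DataFrame(rows)
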