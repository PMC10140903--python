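# Methods

## Diffusion process and likelihood

A trial's decision stage is a Wiener process with drift ν between
absorbing boundaries 0 and *a*, starting at *a*/2 (unbiased; the
paradigm gives no reason for a response bias under accuracy coding,
where the upper boundary is the correct response). The within-trial
diffusion coefficient is fixed at 1, the scale convention of the common
hierarchical DDM software, so caution and drift magnitudes are directly
comparable to literature values using that convention. Inter-trial
parameter variabilities are fixed at zero. Observed RT = first-passage
time + *t*₀.

The first-passage density uses the two standard series representations
(small-time and large-time) of the unit-boundary density, with term
counts chosen from the usual error bounds at a truncation target of
1e−12; the representations agree at the internal switch point
(normalized time 0.28) to better than 1e−9. Closed forms used as
oracles: absorption probability 1/(1 + e^{−aν}) at the unbiased start,
and mean decision time a²/4 (ν = 0) or (a/2ν)·tanh(aν/2).

The fitted likelihood is a contaminant mixture: with probability
π = .05 a trial is uniform over an RT window with a chance response.
When fitting, the window is each subject's observed RT range, so every
observed RT retains positive likelihood even below *t*₀ (fast guesses);
with π = 0 such trials are impossible and the log-likelihood is −∞ by
contract. When simulating, the window defaults to [0.2 s, 3.0 s].

Simulation uses Euler–Maruyama with the Brownian-bridge crossing
correction (the probability that the path crossed a boundary inside a
step is applied explicitly), making the first-passage-time bias O(dt)
instead of O(√dt). Default dt = 1 ms; posterior-predictive replicates
use 2 ms, where the residual bias (~1 ms in mean RT) is negligible
against the quantile summaries being compared.

## Hierarchical estimation

Subject-level parameters live on transformed scales (log *a*, log *t*₀,
identity ν) and are exchangeable draws from per-cell normal group
distributions. Priors: group means N(log 1.5, 1) for log *a*,
N(log 0.3, 1) for log *t*₀, N(1, 3²) for ν; group variances
inverse-gamma(2.5, 0.375) (prior mean SD ≈ 0.4 on the transformed
scale). These are weakly informative on the scales typical for
two-choice classification data and are dominated by 384 trials per
subject.

The sampler is Metropolis-within-Gibbs: group means and variances have
conjugate Gibbs updates; subject-level parameters get random-walk
Metropolis proposals blocked by task block × parameter family,
vectorized across subjects, with per-subject step sizes adapted during
burn-in toward ~30 % acceptance. `thin` runs several sweeps per stored
draw to reduce autocorrelation. Two independent chains (different
seeds) feed the split Gelman-Rubin R̂; runs are bitwise reproducible
from the seed. A reference run uses 10,000 draws after 1,000 burn-in;
the package's desk-scale settings (250–800 draws, thin 1–5) recover
group means and subject-level rank orders well, as the recovery tests
demonstrate, and keep a full 40-subject fit in seconds.

Model lattice: all variants estimate drift by block × switch ×
congruency (except where noted) and differ in the constraint structure
of caution and non-decision time — M1 (*a*: block, *t*₀: block), M2
(*a*: block, *t*₀: block × switch; the reference), M3 (*a*: block ×
switch, *t*₀: block), M4 (both by block × switch), M5/M6 additionally
free *t*₀ by congruency. Only M2's structure is fixed by design; the
composition of the larger variants is this package's reconstruction,
ordered by parameter count.

Posterior-predictive checks simulate the full design from randomly
drawn posterior samples and compare, per subject × block × switch ×
congruency cell, accuracy and the .1/.3/.5/.7/.9 RT quantiles of
correct and of error responses, as mean squared deviation between
observed and replicate-mean summaries (entries undefined in the
observed data — e.g. error quantiles in error-free cells — are
excluded). The statistic set is this package's choice; 500 replicates
is the reference setting, 8–20 suffice for model ranking at desk scale.

The Bayesian "probability of difference" between two parameters is the
folded exceedance 2·|Pr(θ_a > θ_b) − ½| over pooled draws (0 =
indistinguishable); the one-sided mass Pr(θ_a > θ_b) is available via
an option, since published usage is ambiguous between the two.

## Synthetic cohorts

The generator emulates the paradigm: two task-pure blocks (44 trials),
a 24-trial mixed practice block, then three mixed test blocks of 8
warm-up + 128 scored trials with switch × congruency cells balanced
32/32/32/32 within each block. Pseudo-random sequences are built under
a cap of 4 consecutive same-task trials (the original lists'
constraints are unreported; ours are documented, not inferred), shared
across subjects as in a standardized assessment, and reproducible from
the seed. The first scored trial's switch flag is defined against the
last warm-up trial.

Subjects are drawn from a 7-variate normal over (baseline *t*₀, switch
increment Δ*t*₀, baseline drift, switch drift change, incongruency
drift change, caution, WMC). Default means follow the magnitudes
reported for this paradigm (298 ms, 88 ms, 1.94, −.293, −.619); default
caution (1.5) was chosen so simulated RT/error levels land in the
printed descriptive range, and the latent correlation matrix encodes
the reported relations (notably corr(WMC, Δ*t*₀) = −.40,
corr(WMC, caution) = −.28). Cell parameters are additive (baseline +
block shift + switch/congruency changes, no interactions) and truncated
at *a* ≥ 0.3, *t*₀ ≥ 0.05 s (truncation < 1 % at defaults, reported by
the sampler). Recall-N-Back responses are Bernoulli through a logistic
link in WMC and load — a device to endow synthetic data with graded
capacity structure, not a cognitive model; the real task's
binding/updating dynamics, response omissions, and practice effects are
not emulated. Passing recovery tests therefore certify the *pipeline*
(estimation and modeling code), not the behavioral realism of any
particular dataset.

## Scoring

Correct-trial latency is scored as speed (mean of per-trial 1/RT;
"reciprocal of mean RT" is available behind a flag), accuracy as
probit-transformed error proportions with the edge correction
(e + .5)/(n + 1) so perfect cells stay finite. Effects come as global
(marginal means over the other factor) and specific (cells isolating
one requirement) differences. The repeated-measures ANOVA computes
explicit within-subject sums of squares for fully crossed designs, each
term tested against its subject interaction, unadjusted degrees of
freedom, ηp² = SS/(SS + SS_error). Recall-N-Back scoring counts correct
responses over the nine test blocks with load ≥ 2 (maximum 81); parcels
follow a fixed Latin square over load × update count so each parcel
sees every load and every update count once.

## LDS estimation

Identification is by marker variable: block-1 loading fixed to 1 and
block-1 intercept to 0 (likewise parcel 1), so i_B and i_Δ are in the
indicator's units. The model-implied identity (mean gap of a block's
pair = λ_b · i_Δ) holds algebraically in the builder and is tested.
Parcels' residuals are uncorrelated. The discrepancy
F = ln|Σ| − ln|S| + tr(SΣ⁻¹) − p + (ȳ−μ)'Σ⁻¹(ȳ−μ) is minimized by BFGS
with moment-based starts and jittered restarts; variances are
log-parameterized and the latent covariance uses a log-Cholesky factor,
so Σ stays positive definite. χ² = n·F̂ with ML (denominator-n) sample
moments; standard errors come from the inverse observed information,
correlations by the delta method. Convergence is declared on optimizer
success or a Newton decrement < 1e−5.

Fit indices: RMSEA = √(max(χ²−df, 0)/(df·n)) with a noncentral-χ²
confidence interval (default 90 %, the level at which the published
interval for χ² = 41.32, df = 28, N = 101 reproduces; the level is an
argument), SRMR over the unique standardized covariance residuals
(covariance part only), CFI/TLI against the independence baseline with
free means and variances. df = 0 models are reported as RMSEA 0,
CFI 1 by convention.

The latent caution model is a two-factor covariance-structure fit
(caution over the three block-wise *a* estimates, WMC over the
parcels), df = 8. Observed-score LDS models reuse the same machinery on
cell-score indicators; no separate code path exists.

## Known limitations

- The MH sampler mixes more slowly than gradient-based samplers; very
  small cells or extreme parameters may need more thinning.
- The LDS engine covers exactly the model families above; it is not a
  general SEM package (no missing-data FIML, no robust corrections).
- Euler simulation has O(dt) bias; for bias-critical work reduce dt.
- The composition of lattice models M4–M6 is a documented
  reconstruction, not an externally fixed definition.
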