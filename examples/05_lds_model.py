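"""The latent difference score model: the change factor's mean is the
reliable condition effect, and its correlation with working-memory
capacity is estimated free of measurement error.

Here indicator data are generated directly under the model (n = 500)
with a -.40 correlation between capacity and the non-decision-time
switch increment, then refit.
"""

from switchddm import build_lds_spec, fit_sem, simulate_lds_indicators

spec = build_lds_spec("t0", "switch")
print(f"model: 6 paired indicators + 3 parcels, df = {spec.df}")

data = simulate_lds_indicators(500, seed=11, psi=(0.5,) * 3, columns=spec)
fit = fit_sem(spec, data)

print(f"chi2({fit.df}) = {fit.chi2:.1f}, p = {fit.p:.2f}; "
      f"RMSEA = {fit.rmsea:.3f} [{fit.rmsea_ci[0]:.3f}, {fit.rmsea_ci[1]:.3f}], "
      f"CFI = {fit.cfi:.2f}")
print(f"baseline mean i_B   = {fit.i_B * 1000:.0f} ms (generated 298)")
print(f"change mean   i_D   = {fit.i_D * 1000:.0f} ms (generated 88)")
print(f"rho(WMC, change)    = {fit.rho3:.2f} (generated -0.40), "
      f"p = {fit.p_values['rho3']:.4f}")
print("Strict invariance (equal loadings/intercepts/residuals within a")
print("block) makes the change factor an interpretable difference score.")
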