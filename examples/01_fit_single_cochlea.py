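"""Fit one cochlea's lateral-wall spiral with both radius models.

Builds a single synthetic specimen, fits the logarithmic and the cubic
polynomial spiral to its radius profile, and prints the coefficients and
sum of squared residuals (SSR).  The cubic fits far better because the
measured course of r(alpha) has a saddle-like flattening that an
exponential cannot reproduce.
"""

from cochleashape import default_config, fit_log_radius, fit_poly_radius, generate

pop = generate(default_config(n=1, seed=1))
rec = pop.table[0]

log_fit = fit_log_radius(rec.radius)
pol_fit = fit_poly_radius(rec.radius)

print(f"specimen {rec.id}: angular length {rec.angular_length:.0f} deg, "
      f"{log_fit.n_samples} radius samples")
print(f"logarithmic  r = {log_fit.coefficients.a0:.3f} * exp({log_fit.coefficients.a1:+.4f} a)   "
      f"SSR = {log_fit.sum_sq_residuals:.3f} mm^2")
b = pol_fit.coefficients
print(f"cubic        r = {b.b0:.3f} {b.b1:+.4f} a {b.b2:+.5f} a^2 {b.b3:+.6f} a^3   "
      f"SSR = {pol_fit.sum_sq_residuals:.3f} mm^2")
print(f"SSR ratio log/cubic = {log_fit.sum_sq_residuals / pol_fit.sum_sq_residuals:.1f}; "
      "the cubic polynomial captures the fast basal decay the log spiral misses")
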