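"""Fit SDT models to the packaged data and compare them.

Fits four representative models from the factorial family, prints a small
selection table, and runs a likelihood-ratio test of the decay parameter of
the target-rejection criterion shift.
"""

from seqsdt import ModelSpec, builtin_table, fit, lr_test, selection_table

wilson = builtin_table("wilson")

specs = [ModelSpec("tau1", "null"),   # one fixed criterion
         ModelSpec("tau2", "null"),   # criterion varies by position
         ModelSpec("tau3", "null"),   # fixed criterion + rejection shift
         ModelSpec("tau4", "null")]   # both
results = selection_table(specs, wilson, restarts=15, seed=1)

print(f"{'model':<12}{'params':>7}{'G^2':>9}{'AIC':>9}{'BIC':>9}")
for r in results:
    flag = "  <- best AIC & BIC" if r.best_aic and r.best_bic else ""
    print(f"{r.spec.to_string():<12}{r.n_parameters:>7}{r.g_squared:>9.2f}"
          f"{r.aic:>9.2f}{r.bic:>9.2f}{flag}")

full = next(r for r in results if r.spec.criterion_variant == "tau4")
restricted = fit(ModelSpec("tau4", "null", restrictions={"lambda_zero"}),
                 wilson, restarts=15, seed=1)
test = lr_test(full, restricted)
print(f"\nDoes the criterion shift decay over positions?  Fixing the decay "
      f"to zero costs\ndelta G^2 = {test.delta_g2:.2f} on {test.df} df "
      f"(p = {test.p_value:.2g}): the shift clearly fades with lag.")
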