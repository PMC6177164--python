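"""The full two-stage comparative analysis on the bundled data.

Stage 1: PGLS (maximum-likelihood Pagel's lambda) of ln rearing period on
ln lifespan; its standardized residuals are each species' degree of
altriciality — how much longer (or shorter) its offspring stay dependent
than its lifespan predicts after accounting for shared ancestry.

Stage 2: PGLS of the arcsine-square-root cylinder-task success on the
degree of altriciality, plus the same regression with lambda fixed at 0
(ordinary least squares) as the non-phylogenetic contrast.  A positive,
significant slope in both supports correlated evolution of altriciality
and motor self-control.
"""

from altripgls import StudyConfig, run_study

report = run_study(StudyConfig())

for name, fit in [("stage 1 (ln_fw ~ ln_life)", report.stage1),
                  ("stage 2 PGLS (asin_cyl ~ altriciality)", report.stage2_pgls),
                  ("stage 2 OLS  (lambda = 0)", report.stage2_ols)]:
    print(f"{name}:")
    print(f"  slope = {fit.coefficients[1]:.4f}  se = {fit.std_errors[1]:.4f}"
          f"  t = {fit.t_values[1]:.4f}  df = {fit.df_resid}"
          f"  p = {fit.p_values[1]:.4f}")
    print(f"  lambda = {fit.lambda_hat:.4f}  r2_adj = {fit.r2_adj:.4f}"
          f"  outliers flagged = {int(fit.outlier_flags.sum())}")

most = max(report.altriciality, key=report.altriciality.get)
least = min(report.altriciality, key=report.altriciality.get)
print(f"\nmost altricial for its lifespan:  {most}"
      f" ({report.altriciality[most]:+.2f} SD)")
print(f"least altricial for its lifespan: {least}"
      f" ({report.altriciality[least]:+.2f} SD)")
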