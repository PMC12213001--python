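"""Model one movement index with backward-AIC GLM selection.

Fits the full model (location, sex, sternite and femur lengths, PGI and
PYRU activities, and their interactions) for the straightness index TS,
prunes it by backward AIC, and prints the type-3 ANOVA of the final model
with its explained deviance.
"""

from sinupath import invasion_gradient_scenario, simulate_cohort, indices_table, merge_indices
from sinupath.glm import FULL_TERMS, GLMSpec, backward_select, type3_anova

cfg = invasion_gradient_scenario(seed=42)
paths, specimens, _ = simulate_cohort(cfg)
data = merge_indices(specimens, indices_table(paths, R=cfg.resolution))

fit = backward_select(GLMSpec("TS", "gaussian", FULL_TERMS), data)
print(f"terms retained by AIC: {list(fit.spec.terms)}")
print(f"AIC = {fit.aic:.2f}, D² = {fit.d2:.3f}, adjusted D² = {fit.adj_d2:.3f}\n")
table = type3_anova(fit, data)
for _, row in table.iterrows():
    print(f"{row['term']:>10}  df={row['df']}  {row['stat_name']}={row['stat']:8.3f}"
          f"  p={row['p']:.4f} {row['band']}")
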