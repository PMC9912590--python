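"""Simulation-based power for a small fixed effect.

Refits the template model to outcomes simulated from its own estimated
variance components with the group coefficient forced to each beta; power
is the fraction of replicates whose Satterthwaite test rejects at 5%.
"""

from gazesal.stats import ModelSpec, fit_lmm, power_simulation
from gazesal.synth import simulate_records

records = simulate_records(n_per_group=20, n_scenes=10, n_fix_per_scene=4, seed=42)
template = fit_lmm(ModelSpec(outcome="pupil_response", poly_time=False), records)

for beta in (0.0, 0.1, 0.3):
    rep = power_simulation(template, "group", effect_size=beta,
                           iterations=200, seed=7)
    print(f"beta = {beta:3.1f}: power {100 * rep.power:5.1f}% "
          f"[{100 * rep.ci_low:.1f}, {100 * rep.ci_high:.1f}]")
# At beta = 0 the rejection rate estimates the nominal alpha; power grows
# with the planted effect size.  The study-scale cohort (166 per group,
# 85 scenes) yields far higher power at beta = 0.1 than this desk-scale one.
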