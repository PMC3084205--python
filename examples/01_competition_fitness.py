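"""Estimate a selection coefficient from simulated competition chemostats.

A mutant with true per-generation advantage s = 0.15 competes against a
reference strain in biological triplicate; a wild-type-vs-wild-type control
from the same cross is run alongside.  The log mutant/reference ratio is
regressed on generations per replicate, replicates are pooled, and the
pooled estimate is normalised against the control.
"""

import evoscape as ev

S_TRUE = 0.15
cfg = ev.SimulationConfig(seed=11)

mutant_reps = ev.gen_competition_series(S_TRUE, cfg)
control_reps = ev.gen_competition_series(0.0, ev.SimulationConfig(seed=12))

mut = ev.pool_replicates([ev.estimate_selection(s) for s in mutant_reps])
wt = ev.pool_replicates([ev.estimate_selection(s) for s in control_reps])
norm = ev.normalize_selection(mut, wt)
w = ev.relative_fitness(norm)
f_stat, p = ev.ancova_slope_test(mutant_reps[0], control_reps[0])

print(f"true s                 : {S_TRUE}")
print(f"pooled mutant s        : {mut.s:.4f} (SEM {mut.se:.4f}, {mut.n_replicates} replicates)")
print(f"wild-type control s    : {wt.s:.4f}")
print(f"normalised s           : {norm.s:.4f}  95% CI ({norm.ci95[0]:.4f}, {norm.ci95[1]:.4f})")
print(f"relative fitness w=1+s : {w.w:.3f}")
print(f"ANCOVA slope test      : F = {f_stat:.1f}, p = {p:.2g}")
print()
print("The normalised selection coefficient should recover ~0.15: the mutant")
print("gains ~15% in log abundance per generation relative to wild type, and")
print("the ANCOVA confirms its slope differs from the control's.")
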