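"""Cohort analysis: condition ordering, rank patterns and feeling scores.

Generates a small synthetic cohort (8 participants, three task-difficulty
conditions) with the default planted effects -- Easy and Difficult elevate
task-phase coupling, and the Boring rating is loaded on each participant's
Easy-condition response -- then runs the full pipeline: per-condition mean
sum-z(log Phi), the Monte-Carlo rank-pattern test, and the correlation
between the Phi-based feeling score s_i and the baseline-adjusted Boring
rating.  (The full study profile uses 18 participants; 8 keeps this demo
under a minute.)
"""

from phistress import SyntheticSpec, generate_cohort
from phistress.io import analyze_cohort
from phistress.pipeline import WindowingPlan

cohort = generate_cohort(SyntheticSpec.reduced(), n_participants=8, seed=5)
res = analyze_cohort(cohort, tau=1, plan=WindowingPlan(500, 250), n_mc=10**5, seed=5)

print("task-phase mean sum-z(log Phi) per condition:")
for cond, val in sorted(res["mean_sum_z"].items(), key=lambda kv: -kv[1]):
    print(f"  {cond:10s} {val:+.2f}")
rank = res["rank"]
top = rank.patterns[int(rank.counts.argmax())]
print(f"\nmost frequent condition ordering: {' > '.join(top)} "
      f"({int(rank.counts.max())}/{rank.n_participants} participants)")
print(f"rank-pattern test vs uniform: chi2 = {rank.chi_square:.1f}, "
      f"p = {rank.p_value:.4f}")

boring = res["item_corr"]("Easy", "Boring")
print(f"\ns_i(Easy) vs dr(Boring, Easy):  r = {boring.r:+.2f}, "
      f"p = {boring.p:.3f}, n = {boring.n}")
print()
print("The Moderate condition (active coping) stays lowest; the planted")
print("loading makes participants whose Easy-task physiology is more")
print("entangled also report more boredom.")
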