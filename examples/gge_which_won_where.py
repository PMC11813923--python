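"""GGE biplot: which-won-where sectors and mean-vs-stability ranking.

Builds the genotype-by-environment table from model-based predictions,
decomposes it with the GGE SVD, partitions environments into sectors won
by convex-hull vertex genotypes, and projects genotypes on the
average-environment axis.  A strong planted crossover makes the southern
and northern trial groups come out as two mega-environments.
"""

from megaenv import (default_simulation_params, extract_blups, fit_gge,
                     fit_multitrial_lmm, mean_vs_stability, simulate_met,
                     two_way_from_blups, which_won_where)

params = default_simulation_params(n_genotypes=120, seed=11,
                                   crossover_strength=8.0, botanical=False)
dataset = simulate_met(params)
fit = fit_multitrial_lmm(dataset, "DTF")
meta = dataset.trial_meta().rename(columns={"trial_id": "env"})
model = fit_gge(two_way_from_blups(extract_blups(fit), meta))
print(f"PC1+PC2 explain {model.varexp_pc12:.1f}% of G+GE variation")

www = which_won_where(model)
print(f"hull vertices: {', '.join(www.hull_vertices)}")
for env, winner in sorted(www.env_winner.items()):
    print(f"  {env}: winner {winner}")
print(f"repeatable across years: {www.repeatable}")
for me in www.mega_environments:
    print(f"  mega-environment {me['locations']} won by {me['winner']}")

ms = mean_vs_stability(model)
top = ms.ideal_ranking.index[:5]
print("\nclosest to the ideal genotype (high mean, stable):",
      ", ".join(top))
print("(mean performance is the projection on the average-environment "
      "axis; stability is the orthogonal distance from it)")
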