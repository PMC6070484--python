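"""Rank TFs by Master Regulator Index against an edge-randomized null.

The MRI of a TF is the fraction of the terminal-state population (genes
still differentially expressed at the last timepoint) that it coherently
regulates after propagation. Significance comes from re-scoring the same TF
on networks with identical nodes and edge counts but rewired connectivity.
"""

import tetranet as tn

dataset = tn.generate(tn.SyntheticSpec(seed=3))  # 200-gene default fixture
trajectories = tn.discretize(dataset.expression)
grn = tn.reconstruct(dataset.priors, trajectories,
                     tf_list=set(dataset.tf_list))
population = tn.target_population(grn, mode="terminal")
print(f"terminal population: {len(population)} genes")

ranked = tn.rank_tfs(grn, population, n_random=100, seed=7)
print(f"{'tf':8} {'MRI':>6} {'null mean':>10} {'p_emp':>8} {'p_param':>9}")
for r in ranked[:5]:
    print(f"{r.tf:8} {r.mri:6.2f} {r.null_mean:10.3f} "
          f"{r.p_empirical:8.4f} {r.p_parametric:9.2e}")

# The planted regulator drives 50% of the terminal population by design;
# the empirical p sits at the add-one floor 1/(n_random+1) because no
# rewired network reproduces its cascade.
top = ranked[0]
print(f"\ntop TF {top.tf}: MRI={top.mri:.2f} "
      f"({top.regulated_count}/{top.population_size} terminal genes), "
      f"p_empirical={top.p_empirical:.4f}")
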