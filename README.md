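# tetranet

Temporal gene-regulatory network reconstruction and master-regulator
prediction from time-series transcriptomes.

## The problem

During a cell fate transition — differentiation, reprogramming,
trans-differentiation — thousands of genes change expression, but only a
handful of transcription factors (TFs) *drive* the process. `tetranet`
identifies those candidate master regulators from two inputs a lab can
assemble without new experiments:

1. **Prior TF→target edge tables** exported from public regulatory-network
   databases (expression-derived regulons, promoter/enhancer-based circuits,
   ChIP-seq binding collections), each edge optionally signed
   (activation / repression) and tagged with its source database;
2. **A temporal transcriptome** for the transition of interest: one
   expression (or log2 fold-change) column per ordered timepoint.

The priors describe regulation observed across many heterologous cell
systems; the time course says what actually happened in *this* transition.
`tetranet` intersects the two and simulates how regulatory signal could
have flowed through the network over time.

## The model

Each gene's trajectory is discretized to a ternary state per timepoint
(+1 induced, −1 repressed, 0 unchanged; default call threshold 2-fold on
the log2 scale, first timepoint = reference). A transition-specific network
is built from the prior edges whose endpoints both responded, then signal
propagation from any seed TF applies three logical rules:

1. **responsiveness** — unresponsive genes terminate propagation and are
   removed at construction;
2. **coherence** — a traversed edge's sign must explain its endpoint
   states: `state(target) = sign × state(source)` on each gene's first
   non-zero state (binding-only, unsigned edges always pass, with the
   effective sign inferred);
3. **temporal order** — a target's first expression change may not precede
   its regulator's (same-timepoint changes allowed by default).

Nodes downstream of rule-violating edges are reached only if another fully
coherent, temporally ordered path exists. The **Master Regulator Index**
(MRI) of a TF is the fraction of a defined population — by default the
*terminal* genes, those still differentially expressed at the last
timepoint — that it coherently regulates:

    MRI(tf) = |regulated(tf) ∩ population| / |population|

Confidence comes from an edge-randomization null: networks with the same
nodes, trajectories and edge count but rewired connectivity (default 100),
giving an add-one empirical p-value (floor 1/(R+1)) and a parametric
upper-tail p under a normal fit to the null MRIs. Networks from different
transitions are compared by the Tanimoto (Jaccard) index over signed edges
and clustered by average linkage (UPGMA) on 1 − similarity; per-transition
MRI tables aggregate into a consensus ranking toward a shared destination
cell type.

## Worked example

A built-in generator produces ground-truth fixtures: a planted master
regulator whose cascade coherently reaches a known fraction of the terminal
population, plus decoy TFs and rule-violating decoy edges
(`examples/03_rank_master_regulators.py`; the other scripts in `examples/`
walk through reconstruction, propagation and network comparison):

```python
import tetranet as tn

dataset = tn.generate(tn.SyntheticSpec(seed=3))   # 200 genes, 6 timepoints
trajectories = tn.discretize(dataset.expression)  # ±2-fold thresholds
grn = tn.reconstruct(dataset.priors, trajectories,
                     tf_list=set(dataset.tf_list))
population = tn.target_population(grn, mode="terminal")
ranked = tn.rank_tfs(grn, population, n_random=100, seed=7)
```

Output:

```
tf          MRI  null mean    p_emp   p_param
MR1        0.50      0.094   0.0099  1.45e-09
TF002      0.05      0.038   0.2574  3.24e-01
TF003      0.05      0.037   0.2376  3.18e-01
...
top TF MR1: MRI=0.50 (90/180 terminal genes), p_empirical=0.0099
```

The planted regulator `MR1` was designed to drive exactly half of the 180
terminal genes: its MRI is recovered as 0.50 and it ranks first. Its
empirical p sits at the add-one floor 1/101 — none of the 100 rewired
networks reproduces a comparable cascade — while decoy TFs score near the
null mean. The same workflow is available from the shell:

```sh
tetranet simulate --config spec.yaml --out-dir fixtures/
tetranet run --config run.yaml        # reconstruct → rank, two artifacts
tetranet propagate --network net.graphml --seed CEBPA --out prop.json
tetranet similarity --networks a.graphml --networks b.graphml \
    --out sim.tsv --tree tree.nwk
```

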