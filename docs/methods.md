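# Methods

## Model

`tetranet` treats a cell fate transition as a flow of transcription-
regulatory information over a signed directed multigraph whose nodes are
genes measured in a temporal transcriptome. The model is deliberately
qualitative: no rate constants, no Boolean update scheme, no ODEs.
Propagation is *reachability under logical constraints*, which keeps the
method applicable to the coarsely sampled time courses (a handful of
timepoints over hours to days) it is designed for.

### Discretization

Expression is reduced to a ternary state per gene and timepoint by
thresholding log2 fold-changes against the first timepoint:
state = +1 if log2FC ≥ `up_threshold`, −1 if ≤ `down_threshold`, else 0.
The reference timepoint is always state 0. A gene is *responsive* if any
later state is non-zero; its *first change* is the earliest non-zero index
and its *terminal state* the value at the last timepoint. Raw expression
input is converted with `log2((x + c) / (x₀ + c))` using pseudocount
`c = 1` to guard zeros. Comparison against the preceding rather than the
first timepoint is available (`reference="previous"`) for designs where
the baseline drifts.

### Network reconstruction

Prior edges are deduplicated `(tf, target, sign, source)` tuples;
identifiers are upper-cased and trimmed so symbols match across databases,
and an optional synonym map handles residual nomenclature conflicts. The
transition-specific network keeps exactly the prior edges whose two
endpoints are responsive; genes absent from the transcriptome count as
unresponsive. Evidence for the same signed pair from several databases
merges into one edge carrying the union of source tags; *conflicting*
signs (and unsigned binding evidence) remain parallel edges, because the
propagation rules — not the input — decide which sign is consistent with
this transition. Every discarded edge is counted by reason
(`gene_absent`, `unresponsive_tf`, `unresponsive_target`), and
retained + discarded always equals the deduplicated input: nothing is
dropped silently.

### Propagation

From a seed TF, an edge `u → v` is traversed iff

1. `u` is already regulated,
2. the edge sign explains the endpoint states
   (`state(v) = sign × state(u)`, evaluated on each node's first non-zero
   state; unsigned edges always pass, with effective sign
   `state(u) × state(v)`), and
3. `first_change(v) ≥ first_change(u)` (non-strict default;
   `strict` requires `>`).

Because a node's activation time is its own first-change index — a fixed
property — any admissible walk can be shortened to a simple path, and
plain breadth-first reachability is exact; the test suite verifies this
against exhaustive simple-path enumeration. Downstream exclusion is
implicit: a node reached only through rule-violating edges is simply not
regulated. Coherence is judged on first changes only — a later sign
reversal does not retroactively invalidate an edge — and self-loops are
reported but never traversed, since a node cannot temporally precede
itself. Nodes reached by both a coherent and an incoherent edge count as
regulated: exclusion applies to routes, not to nodes with at least one
valid route.

### Master Regulator Index and null

`MRI(tf) = |regulated(tf) ∩ population| / |population|`, with the seed
excluded from its own numerator. The default population is the *terminal*
set (non-zero state at the last timepoint), the natural denominator when
the question is "who drives the end state"; `all_responsive` and `custom`
modes are provided because the right denominator is study-specific.

The null rewires every edge — keeping nodes, trajectories, edge count and
each edge's sign/source payload — drawing the TF end uniformly from
seed-eligible nodes and the target end uniformly from all nodes;
self-loops and duplicate triples are redrawn (bounded retries). A
degree-preserving variant (pairwise endpoint swaps) is available for
sensitivity analysis. Two p-values are reported per TF: the add-one
empirical `p = (1 + #{null ≥ observed}) / (R + 1)`, whose resolution is
bounded by `1/(R+1)` at the default `R = 100`, and a parametric upper-tail
probability under a normal fit to the null — the only route to the extreme
significance levels a large network can warrant. Ranked tables add a
Benjamini–Hochberg FDR over the empirical p-values; ties in MRI break by
regulated count, then TF name, so output order is fully deterministic.

### Network similarity and consensus

Networks are compared as sets of `(tf, target, sign)` triples (or node
sets) via the Tanimoto index |A∩B| / |A∪B|; 1 − Tanimoto is a metric, so
average-linkage (UPGMA) clustering on it is well-behaved. A normalized
dot-product similarity of binary edge-indicator vectors (cosine) is
exposed as an alternative metric, as the two readings of "average dot
product distance" differ only in normalization. Consensus ranking over
transitions sharing a destination averages each TF's MRI with absent-TFs
contributing 0 — a regulator that cannot drive a transition has zero
master-regulator capacity for it.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `up_threshold` / `down_threshold` | +1 / −1 log2 units | 2-fold induction/repression call; the field's convention, surfaced in config and logs |
| `pseudocount` | 1.0 | added before log-ratio of raw expression |
| `reference` | `baseline` | discretize vs. first timepoint (`previous` optional) |
| `temporal_rule` | `non_strict` | allow same-timepoint regulator→target change; appropriate for coarse sampling |
| `population` | `terminal` | MRI denominator |
| `n_random` | 100 | null networks per TF; empirical p floor 1/101 |
| `null` | `uniform` | rewiring scheme (`degree_preserving` optional) |

## Synthetic data generator

The generator emulates the statistical skeleton the pipeline assumes, with
a known answer built in. One planted TF (first change at the second
timepoint) roots a cascade wired as feed-forward motifs — planted →
intermediate TFs → targets, plus direct planted → target edges — the
hub-like wiring typical of genuine master regulators; redundancy makes
recovery degrade gracefully instead of losing whole subtrees to a single
corrupted intermediate. Cascade targets persist to the last timepoint
(terminal); TF states return to baseline (non-terminal), so the terminal
population is exactly the target genes, and the cascade reaches
`⌈coverage × n_targets⌉` of them. Decoy TFs coherently drive the remaining
terminal genes, so ranking is not trivial; decoy *edges* violate the
coherence or temporal rule by construction and must never be retained.
Edges are split across source tags with overlap; binding-only (unsigned)
corroboration is added to a fraction `unsigned_fraction` (default 0.10) of
edges. Because unsigned edges pass the coherence rule unconditionally,
this rate directly controls how permissive randomized nulls are — at high
rates random reachability percolates and the null loses power, which is a
property of the method worth knowing, not just of the fixture.

Log2 fold-changes are drawn as `state × (threshold + |N(0.5, 0.2)|)` for
non-zero states and `N(0, 0.25)` clipped to ±0.8 otherwise, so
discretization at the default thresholds reproduces the designed states
with unambiguous margins. State-flip noise replaces each post-reference
state with one of the other two values with probability `noise`,
*before* expression values are drawn. Defaults (200 genes: 20 TFs + 180
targets, 6 timepoints, coverage 0.5, 50 decoy edges, 3 sources) keep every
test and the acceptance script fast while leaving the null non-trivial.

What the generator does **not** emulate: count distributions, replicate
variance, library-size effects, correlated noise, or realistic network
motifs beyond the planted cascade. The pipeline only sees data through
ternary discretization, so passing tests demonstrate correctness of the
logic and recoverability under the stated noise model — not performance on
real transcriptomes, where threshold choice and identifier matching
dominate.

## Numerical and degenerate-input choices

- Empty networks after filtering are a hard error (advising threshold
  review), as are empty populations and similarity between feature-empty
  networks.
- Parametric p-values are floored at the smallest positive double rather
  than reported as 0; a degenerate null (sd = 0) yields p = 1 when the
  observation does not exceed the null mean, else the floor.
- Rewiring retries self-loops/duplicates 100 times, then accepts with a
  logged warning, so randomization cannot loop forever on pathological
  graphs.
- All iteration orders feeding output files are sorted; identical
  config + seed reproduces byte-identical artifacts (provenance headers
  contain a config hash, never a timestamp).
- Seeds derived internally stay below 2³¹.

## Known limitations

- Propagation evaluates coherence on first changes only; regulation
  expressed in a later sign reversal is invisible to it.
- The method is sensitive to misdiscretization of the seed TF itself: if
  noise corrupts the seed's first-change state, its entire cascade is lost
  for that dataset. In the generator this is the dominant residual error
  mode at 5% state-flip noise — occasional single-replicate collapses
  rather than diffuse error.
- The uniform null conditions only on node set, edge count and
  seed-eligibility, not on degree structure; hub TFs therefore get a
  conservative null (their real out-degree exceeds the rewired
  expectation). The degree-preserving mode exists precisely to check this.
- Tanimoto over signed-edge triples treats an unsigned and a signed record
  of the same pair as different features; comparing networks built from
  differently signed source collections should use `on="nodes"`.
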