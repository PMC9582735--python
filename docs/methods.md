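# Methods

This note documents the models and procedures implemented in `deltadock`, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not demonstrate.

## Problem setting

Structure-based optimisation of CYP inhibitors (or any binder) by single-point
substitution poses a combinatorial scoring problem: a molecule with `p`
substitutable ring positions and a library of `m` fragments has `p·m`
derivatives, each of which would normally require a docking run. The package
reframes this as node regression on the molecular graph: one network forward
pass yields the full `n_atoms x m` matrix of predicted docking-score changes
(ΔDS), with ΔDS < 0 meaning the modification improves predicted binding.

## Derivative enumeration

A position is substitutable when it is a ring atom carrying at least one
implicit hydrogen — the new single bond replaces that hydrogen, and the
substitution chemistry is defined over the ring scaffold. The attachment point
is always the *first* atom of the fragment SMILES, which disambiguates the
written forms (`OC` = methoxy via oxygen, `CO` = hydroxymethyl via carbon).
Products are sanitised by RDKit; a sanitisation or valence failure marks the
combination infeasible, and infeasible combinations are retained as masked
records rather than dropped, so downstream label matrices know what is
missing. Symmetry-equivalent positions are deliberately not deduplicated:
labels are per-node, and each node must carry its own vector.

Di-substitution is restricted to two *distinct* atoms (modifying the same atom
twice is out of scope chemically and by definition of "more than one place").
The full pair space `C(p,2)·m²` grows quickly, so a seeded uniform sample is
drawn when a caller caps the record count; the sample is deterministic in the
seed.

## Scoring backends

`SminaBackend` wraps an external Smina/AutoDock-Vina-style binary: one seeded
ETKDG conformer per ligand (MMFF-relaxed), default program settings, and the
best (minimum) affinity over returned poses as the molecule's score — the
standard Vina convention; the pose file is preserved. Receptor preparation
(stripping all non-protein atoms except the heme cofactor) is a documented
manual prerequisite and is not automated. Failures are per-molecule, logged,
and never abort a batch; results are cached by (backend, canonical SMILES,
receptor, seed) so large enumerations can resume.

`OracleBackend` is a deterministic synthetic scorer used for development,
testing and the desk-scale benchmark. Its ground truth is

    base(M)        = a·n_heavy(M) + b + eps,             eps ~ N(0, sigma²)
    delta(M, i, f) = alpha_f + beta_f·aromatic(i) + gamma_f·(deg(i) − 2) + eps'

with the derivative's absolute score *defined* as `base(parent) + delta`, so
score differences recover the delta exactly at any noise level. Defaults:
`a = −0.2` kcal/mol per heavy atom, `b = −6.0` kcal/mol (typical small-molecule
docking range); per-fragment intercepts `alpha` are negative for F (−0.4) and
Cl (−0.3), positive for S (+0.25), OC (+0.3) and COC (+0.35), with the
remaining fragments between −0.2 and +0.2 — matching the qualitative pattern
that halogenation tends to improve CYP docking scores while thioether/ether
substitutions worsen them, and keeping most |ΔDS| below 1 as observed in real
campaigns. `beta ~ U(−0.1, 0.1)` and `gamma ~ U(−0.05, 0.05)` are drawn once
per fragment from the seed, making the target depend on the local atom
environment (so a model must read the graph, not just the fragment index);
noise sd defaults to `sigma = 0.1`. All per-item noise is derived from a CRC
hash of the item identity mixed with the seed: scores are reproducible across
processes and independent of evaluation order.

## Dataset assembly and splitting

Each molecule becomes a `LabeledGraph`: the 42-dim feature matrix plus the
`n_atoms x 15` ΔDS matrix and binary mask (1 = feasible and scored). Splits
are always by molecule — atoms of one molecule never straddle train/test. Two
modes: seeded random, and a "time" split holding out the last
`ceil(0.2·N)` molecules by record order, the stand-in for database-deposition
order when benchmarking prospective use. The held-out fraction defaults to
0.2. Labels are stored as raw ΔDS; the binary increase/decrease view is always
derived downstream (decrease ⇔ ΔDS < 0, with 0 counted as increase), never
stored.

Serialisation uses a long-format CSV (`parent_id, atom_index,
substituent_index, delta, mask`) plus a molecules table whose SMILES carry
atom-map numbers encoding the original atom order, so label indices survive
the round trip bit-exactly; floats are re-read with round-trip precision.

## Synthetic fixture generator

Fixtures emulate small drug-like ring systems: a scaffold drawn from twelve
aromatic/heteroaromatic/partially saturated cores (benzene, pyridine,
naphthalene, indole, furan, thiophene, pyrrole, pyrimidine, quinoline,
tetralin, benzothiophene, cyclohexane), decorated at 0–3 ring positions with
small chains (methyl, ethyl, hydroxyl, amino, halogen, hydroxymethyl, methoxy,
isopropyl). Every fixture keeps at least one substitutable position and 6–30
heavy atoms, and outputs are unique by canonical SMILES while the combinatorial
space allows. What the generator does **not** emulate: realistic activity
distributions, large flexible scaffolds, charged/zwitterionic species,
stereochemistry, and — most importantly — the non-local, pose-dependent
physics of real docking. Passing the synthetic benchmark therefore shows that
the pipeline learns a local structure-dependent signal through the masked
node-regression machinery; it does not certify accuracy on real docking data,
where published sign accuracies for this task sit around 0.58–0.67.

## Networks and training

Input features are exactly 42 per atom: element one-hot over a fixed
28-symbol vocabulary (27 named elements + "other"), implicit-H one-hot over
{0..4}, heavy-degree one-hot over {0..5} (counts clip to the top slot), formal
charge clipped to [−1, 1], ring flag, aromatic flag. Bond orders are not
encoded; connectivity enters only through the unweighted adjacency.

A conv block computes `z = act(BN(conv(x)))`, applies dropout, and adds a skip
connection from the block input (a linear projection where widths differ,
identity otherwise). `conv` is either the spectral rule `D^{-1/2}(A+I)D^{-1/2}
x W` or single-head graph attention with LeakyReLU(0.2) edge logits and
softmax over incoming edges (self loops included). Activation is ReLU and
BatchNorm precedes it; the attention uses one head. These three choices are
not dictated by the task definition and are fixed here as package defaults.
The head is one linear layer (hidden→15) or two (hidden→hidden→15 with ReLU).
The optional dummy node has all-zero features, connects to every atom, and is
excluded from labels, loss, metrics and saliency — its only role is whole-graph
signal aggregation during convolution.

Training: Adam (lr 0.01 or 0.001, optional L2 weight decay 5e-4 in the
classical coupled form), masked MSE objective, 200 epochs by default, batches
of 256 *graphs* collated into one block-diagonal disjoint union, and a
reduce-on-plateau schedule (factor 0.1, patience 10) monitoring validation
loss when a validation set is supplied, training loss otherwise. An all-masked
batch raises instead of silently contributing zero; a non-finite loss aborts
with the offending configuration in the message. All randomness (init,
shuffling, dropout) flows from a single `random_state`, making runs exactly
reproducible. Model selection over the 64-point grid (2 depths x 2 layer
types x 2 head depths x 2 dropouts x 2 learning rates x 2 weight-decay
settings; hidden size fixed at 256) uses mean 5-fold validation masked MSE,
and the winning configuration is retrained on the full training partition.

The whole stack — tensors, backprop, layers, optimiser — runs on NumPy via the
package's reverse-mode autodiff core (`deltadock._autodiff`), with SciPy
sparse matrices for the batched propagation operator. Every op's gradient is
verified against central finite differences in the test suite.

## Evaluation and explanation

*Sign accuracy* compares the predicted and true direction of change over
unmasked entries, optionally discarding entries with |true ΔDS| < margin (the
margin filters by absolute value; the direction tie-break maps 0 to
"increase"). *MSE ranking* is the masked MSE reported as a metric. *SRD* (sum
of ranking differences) ranks both score lists with average ranks for ties,
sums absolute rank differences, and normalises by the exact maximum (`n²/2`
for even n, `(n²−1)/2` for odd) attained by the reversed ranking; it is
computed entry-level, with compound-level aggregation left to the caller.

Saliency differentiates one predicted (atom, substituent) output with respect
to the *continuous relaxation* of the input feature matrix — one-hot entries
are treated as real coordinates, the standard relaxation for gradient
attribution on discrete inputs. The classical map is the per-atom Euclidean
norm of the positive gradient part, the negative map uses the negated
gradient, and the positive–negative map is their difference. Message passing
bounds information flow, so attribution is exactly zero beyond `n_conv` hops
from the target atom (the dummy node, when enabled, removes this locality).
Requesting a map for an infeasible substitution is an error.

## Benchmark scales and reproducibility

The desk-scale study conditions, fixed once and used by both the test suite
and `scripts/acceptance.py`: 400 generated molecules, all feasible
single-point modifications oracle-scored, random 80/20 molecule split, and a
3-layer GCN (hidden 256, lr 0.01, dropout 0.2, no weight decay — grid options)
trained for 50 epochs. On the noiseless oracle this recovers the generating
rule (held-out sign accuracy ≥ 0.95, masked MSE ≤ 0.01); at noise sd 0.1 the
network exceeds the majority baseline by ≈ 0.3 and the margin-accuracy curve
rises monotonically, because prediction errors concentrate on near-zero true
changes. Grid search in tests runs on reduced grids and small hidden sizes;
the selection machinery is identical to the full 64-point grid.

## Known limitations

- The oracle's additive, local ground truth is far easier than real docking;
  absolute benchmark numbers are not comparable to docking-trained models.
- No stereochemistry, tautomers, or substituent *replacement* (only addition
  at H-bearing ring atoms); no receptor preparation or pose validation.
- The external docking wrapper is exercised against a stub binary in tests;
  behaviour against specific Smina/Vina versions' output formats may need the
  affinity-table regex extended.
- BatchNorm statistics are computed over all nodes of a batch including dummy
  rows; with very small batches the running statistics are noisy.
- The GAT implementation uses a single attention head and dense per-edge
  softmax; it is the slower of the two layer types at large batch sizes.
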