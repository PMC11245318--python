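# Methods

This note records the model, the choices that were genuinely open when the
package was designed, and what the synthetic benchmark does and does not
demonstrate.

## Molecular graphs and featurisation

A SMILES string is parsed (RDKit, sanitised, heavy atoms only) into a
directed graph G = ⟨X, E, A⟩. Every chemical bond contributes two directed
arcs with identical features, so A is symmetric with zero diagonal and the
arc set is closed under reversal.

Atom features (d_atom = 42): element one-hot over
{C, N, O, S, F, Cl, Br, I, P, B, Si} plus an "other" slot (covers the
functional groups the explanation module reports; rare elements fold into
"other" rather than erroring); heavy-atom degree and bonded-H count as
one-hots capped at 6 with an overflow bucket; formal charge one-hot over
−2…+2 with an "other" slot (a one-hot rather than a raw integer keeps all
blocks on a common 0/1 scale; recorded in the featuriser config); hybridisation
one-hot over {sp, sp2, sp3, sp3d, sp3d2, other}; aromaticity flag; atomic
mass divided by 100 so the feature stays O(1). Bond features (d_bond = 6):
bond-type one-hot {single, double, triple, aromatic}, conjugation, ring
membership. Salts keep the largest fragment; stereochemistry is ignored.
The featuriser config serialises to JSON next to every checkpoint so a
reloaded model featurises identically.

## Structure remapping

The bond graph Gʳ has one node per directed arc and one edge per
consecutive arc pair ("bond–atom–bond" path), with concatenated features

    Xʳ_{u,v}   = X_u ‖ E_{u,v} ‖ X_v           (node, length 2·d_atom + d_bond)
    Eʳ_{uv,vz} = E_{u,v} ‖ X_v ‖ E_{v,z}       (edge, length 2·d_bond + d_atom)
    Aʳ_{uv,vz} = 1  ⇔  A_{u,v} = A_{v,z} = 1.

The adjacency rule literally includes backtracking pairs (z = u), and that
is the default; an `exclude_backtrack` flag implements the
directed-message-passing convention that omits them, because both readings
are defensible and the choice measurably changes the graph (ethanol: 6 vs 2
remapped edges). Gʳ is directed and Aʳ generally asymmetric. A molecule
with no bonds has no remapped graph; the encoder then substitutes the
original-graph representation for the remapped stream (logged), which keeps
single-atom SMILES in-distribution instead of erroring.

## Multi-view pooling

Per pooling layer, on the current (coarsened) adjacency Aʰ and embeddings
Zʰ:

* structure view: p_c = σ(α·log(deg(Aʰ)+ε)+β), ε = 1e-5; α, β learnable
  scalars that rescale integer degrees onto the same (0,1) scale as the
  other views.
* feature view: p_f = σ(MLP(Zʰ)) with a two-layer perceptron (hidden width
  = embedding width, ReLU, scalar output).
* structure–feature view: seed PR = σ(D̂^{-1/2} Â^k D̂^{-1/2} Zʰ Φ) with
  Â = Aʰ + I, then personalised-PageRank propagation
  p_cf = σ(δ(I − (1−δ)Ã)^{-1} PR), Ã the symmetrically normalised Â.
  Defaults k = 1 and δ = 0.2; both are config (`k_power`, `delta`) because
  the exponent and the locality trade-off are genuinely free parameters.
  The outer sigmoid is applied once after propagation — applying it per
  iteration would not approximate the closed form. Inside training the
  linear system is solved densely (graphs here are small and the solve is
  differentiable); the functional API also offers power iteration
  (defaults: 100 iterations, tolerance 1e-6, warning on budget exhaustion),
  and the two agree to < 1e-6 max-abs by test.

Fusion: each view j gets weight g_j = softmax_j(σ(sᵀw_j + b_j)) where s is
the three-vector of per-view score means. A literal inner product of a
learnable w_j with the concatenation of all three score vectors would make
w_j's dimension depend on the molecule; summarising by per-view means keeps
the parameters size-invariant while preserving the intended behaviour
(identical w_j, b_j ⇒ uniform weights). The fused score p = Σ_j g_j·p_j is
a convex combination, so it is bounded per node by the view min/max.

Top-rank selection keeps the ⌈r·N⌉ highest-p nodes (default r = 0.8); ties
break toward the lower original index via a stable sort, which makes the
permutation-equivariance property testable modulo ties. Retained rows are
multiplied by the gate σ(p) — the only path through which the score
parameters receive gradient — and the adjacency (and the COO edge-feature
list) is sub-indexed at the retained set. ⌈r·N⌉ ≥ 1 for N ≥ 1, so deep
stacks degrade gracefully to single-node graphs.

## Encoder

K layers (default K = 2), each a GIN step
Z′_u = MLP((1+ε_gin)·Z_u + Σ_{v∈N(u)} Z_v) with a learnable ε_gin and a
two-layer ReLU MLP, followed by MVPool. Edge features (present in both
streams: bond vectors in G, path vectors in Gʳ) enter each GIN layer by
adding a linear projection of the node's summed incident edge features to
its aggregated neighbour message, and are sub-indexed alongside pooling;
`use_edge_features=False` disables this path. Messages flow along arc
direction (the aggregation uses Aᵀ), which matters only for the directed
remapped graph. After each pooled layer a mean‖max column readout
(2·hidden) is taken; the K readouts are fused by softmax attention over
readoutᵀw logits. Width default hidden_dim = 32. The K = 2 / 32-wide
default is sized for the small synthetic molecules this package targets
and for pure-NumPy training; both are ordinary config and scale up.

## Training

Two encoder streams (original, remapped) produce h_o, h_r per molecule; a
linear head on h_o ‖ h_r gives the toxicity logit. Loss per minibatch:

    L = BCE(logits, y) + λ · NT-Xent(H_o, H_r; τ)

with λ = 0.1 and τ = 0.5 by default. The contrastive term is the symmetric
normalised-temperature cross-entropy: cosine similarities scaled by 1/τ,
each molecule's (original, remapped) pair positive against all in-batch
negatives, averaged over both directions. In-batch negatives were chosen
over pair-only alignment because pair-only alignment admits a collapse to a
constant representation. Optimisation is Adam (lr 1e-3), batch size 32,
with an internal stratified validation split (10 %) for early stopping on
validation AUC (patience 20); the best-validation parameters are restored.
All randomness flows from `random_state`. Metrics: AUC by rank statistic,
accuracy, MCC (0 when any denominator factor is 0), sensitivity,
specificity at threshold 0.5.

The whole computation runs on a small reverse-mode autodiff engine over
float64 NumPy arrays (`graphadt.autodiff`), implementing exactly the
operator set the model needs, including a differentiable dense solve for
the PageRank view; gradients are verified against central finite
differences in the test suite.

## Shapley bond attribution

Players are undirected bonds; the value function f(S) is the model's
positive-class probability with every bond outside S masked in the
remapped stream: the feature rows of the bond's two directed arcs are
zeroed and their incident remapped edges removed, jointly for the two arcs
(attributing per directed arc would double-count each chemical bond). The
original stream is left intact and cached, so a coalition evaluation costs
one remapped-stream encode. Molecules with ≤ 6 bonds are solved exactly by
coalition enumeration; larger molecules use Monte-Carlo permutation
sampling (default 500 permutations; 200 in the recovery benchmark) with a
coalition cache and per-bond standard errors. Because every permutation's
marginals telescope, the efficiency identity
Σ_b φ_b = f(full) − f(empty) holds to float precision for both estimators.
Bonds with φ ≥ 0.2 (raw, unnormalised values) are flagged and matched to
functional-group SMARTS patterns (nitro, ester, ether, tertiary amine,
chlorobenzene, trichloromethyl, phenol, cyano, phosphoryl, halogenated
hydrocarbon; editable JSON). A bond carries a group tag when both endpoint
atoms lie inside one SMARTS match; overlapping groups are counted per
group, so frequency fractions may sum above 1.

## Synthetic benchmark

The generator emulates a binary ADT dataset: random branched carbon
scaffolds of 4–12 heavy atoms (40 % include a benzene ring), positives get
one toxicophore fragment — nitro, trichloromethyl, cyano or methyl ester —
attached at a random free-valence site, labels flip with probability
`label_noise`. Scaffolds are pure carbon, so the planted fragment is
provably the only label signal, and the Bayes-optimal accuracy against the
noisy labels is exactly 1 − noise. The benchmark condition used in the
tests and the acceptance script is n = 1000 molecules, 5 % label noise,
stratified 80/20 train/test.

What passing this benchmark shows: the pipeline can learn a
substructure-determined property from SMILES alone, its held-out accuracy
respects the noise ceiling (no label memorisation), and the Shapley
attribution localises the signal to the planted bonds (top-bond recovery is
scored as: the maximum-Shapley bond has at least one endpoint inside a
toxicophore match — this includes the attachment bond, which genuinely
carries label information). What it does not show: performance on real ADT
chemistry, where toxicity signals are weaker, confounded and multi-factor;
no realistic ADME-like property distributions, charges, stereochemistry or
3D geometry are emulated.

## Numerical and degenerate-input behaviour

Sigmoid inputs are clipped at ±500 before exponentiation; BCE uses the
log-sum-exp-stable form; cosine normalisation adds 1e-12 under the square
root; NT-Xent and the layer attention subtract a detached row max before
exponentiating. Single-atom molecules: remapping raises `EmptyRemapError`
and the model substitutes the original-stream representation. Pooling of a
single node keeps it (ceiling ≥ 1). Isolated nodes are handled by ε in the
log-degree and by the self-loop in Â. Training aborts with diagnostics on
non-finite loss; a single-class dataset is rejected up front.

## Problem sizes used in the shipped checks

The test suite and acceptance script use 500 molecules for the remapping
oracles, 200 random graphs for the PageRank equivalence, the n = 1000
benchmark with 12 training epochs (validation AUC plateaus well before
that on this data), and 20 true-positive molecules at 200 permutations for
the recovery rate — sizes chosen so a full run completes in a few minutes
on one CPU while keeping every estimate's sampling error far from the
asserted margins.

## Known limitations

* Training is pure-Python/NumPy and processes one graph at a time; it is
  sized for hundreds-to-thousands of small molecules, not large screens.
* The attention fusion uses per-view mean summaries; per-node view
  weighting is not implemented.
* Masked bonds are zeroed, not removed, in the remapped node set, so the
  coalition graphs keep their node count; zero rows are slightly
  informative to the mean readout.
* The contrastive loss form (NT-Xent with in-batch negatives) and the GIN
  internals are canonical choices where the architecture leaves them open;
  alternatives (pair-only alignment, GraphSAGE-style aggregation) were not
  explored.
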