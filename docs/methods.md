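# Methods

## Problem and model

A retrosynthesis pathway is a rooted tree: the root reaction produces the
target, children produce their parent's reactants, and leaves are
reactions whose reactants are treated as purchasable. `routestrat` scores
the *strategy* of such trees — whether the step structure looks like a
route a practicing chemist would run — and uses the learned representation
to group similar routes. Single-step feasibility is deliberately out of
scope: routes are assumed pre-filtered by a single-step model, and
reagents are dropped during curation so the encoder sees the
decomposition strategy rather than condition choices.

### Curation

Reactions sharing a source identifier form a bipartite digraph
(product → reaction → reactants). Root compounds (products that are never
reactants) head the routes. Enumeration is a complete DFS with three
semantics choices:

* every intermediate with at least one producing reaction **must** expand;
  multiple producers spawn one pathway per choice, and choices across the
  reactants of one step combine as a Cartesian product;
* a reaction already on the current root-to-leaf path is never reused
  (cycle guard), so emitted trees are acyclic and enumeration terminates
  on cyclic networks;
* pathways identical under order-independent canonical serialization are
  emitted once, and output order is deterministic.

Extraction keeps depth ≤ 20; dataset assembly narrows to 4–10 (both
configurable): shorter routes carry little design information, longer
ones are impractical.

### Encoder and ranking head

Each reaction node is featurized with a 2048-bit radius-2 Morgan product
fingerprint plus a signed count-difference reaction fingerprint
(product − Σ reactants, clipped to ±255; reagents excluded). The
concatenated 4096-vector passes through a ReLU FFNN
(4096 → 512 → 256 by default, linear output) into a child-sum tree-LSTM
(hidden 256): input/output/update gates act on the summed child hidden
states, one forget gate per child acts on that child's hidden state, and
cell states combine as c = i⊙u + Σ f_k⊙c_k. The root hidden state is the
pathway embedding; a 256 → 128 → 1 FFNN maps it to the SLScore.

Training minimizes, per group {reference, alternatives}, the listwise
softmax cross-entropy with the reference as the positive class (a
pairwise logistic loss is available via `loss="pairwise"`); this directly
optimizes the reported top-1 metric. Optimization is Adam (lr 1e-3),
mini-batches of 8 groups, 8 epochs by default, Glorot initialization with
forget-gate bias +1. Alternatives beyond `max_alternatives` (300) are
subsampled once with the run seed. Everything is numpy with hand-written
backpropagation — verified against central finite differences to 1e-4
relative in the test suite — so results are bit-reproducible from
`TreeLSTMConfig.seed` on one CPU. The scorer consumes the root hidden
state only (not the cell state), matching the convention that the root
hidden state *is* the pathway representation.

Splits partition **sources**, not groups (80/10/10 by default), so no
patent contributes to two splits.

### Baselines

* **Depth**: sort ascending by depth. Ties are bracketed rather than
  broken: best rank = 1 + #strictly shallower, worst = #(depth ≤ ref).
  The bracket provably covers exactly the achievable positions under
  arbitrary tie permutation (tested exhaustively for groups ≤ 6).
* **Complexity flow**: split the tree at branch points into root-to-leaf
  chains; per step record the most complex reactant; pad the vector to
  `max_depth` (10) with zeros, truncating deeper chains; score each chain
  with a small FFNN and min-pool, so the least strategic chain dominates.
* **Hybrid**: 11 descriptors (depth, #chains, #nodes, #leaf nodes, max
  children, max starting-material complexity, min/max intermediate
  complexity, min/max per-step complexity delta, target complexity)
  through a small FFNN. For single-node routes the intermediate
  descriptors are 0 by convention. Inputs are standardized with training
  statistics stored in the model.

Compound complexity is a pluggable callable. The built-in stand-in is a
deterministic structural proxy, 1 + 0.06·(heavy−1) + 0.3·rings +
0.4·stereocenters capped at 5 — it pins methane to the scale floor and is
monotone in rings/stereocenters. It is a proxy of convenience on the
conventional 1–5 complexity scale, not a learned model; any learned
complexity function can be passed through the same interface.

### Clustering

HDBSCAN (scikit-learn) on Euclidean distance over raw embeddings, default
`min_cluster_size` 5, noise = −1; cosine available via config. When fewer
points than `min_cluster_size` are given everything is noise by
definition. The cluster report intersects member compound sets to surface
the shared intermediates that define a strategy. t-SNE projections are
diagnostics only: seed-dependent, layout-unstable, never consumed
downstream and never gated on.

## Synthetic data

The generator defines the study conditions for all end-to-end claims. A
target is a linear assembly of 3–12 small fragments (alkyl chains and
para-phenylene units from a composable SMILES grammar) joined by amide,
ether or ester linkages; exactly one fragment carries a spectator
secondary amine. A route is a binary bracketing of the fragment sequence
(each internal node = one coupling, reactants derived with the proper
handles: acid + amine, alcohol + bromide, acid + alcohol), optional
refunctionalization steps below leaves (oxidation, ester reduction,
bromination, amination, decarboxylation — each applied where its string
handle exists), and a protection motif: the spectator amine is
Boc-protected before the couplings and deprotected in the final step.
Every molecule string is RDKit-validated and canonicalized; every tree
satisfies the pathway invariants programmatically.

Corruptions emulate the failure modes of unguided route search:

* `detour_pair` — inserts make-then-unmake reactions on an intermediate
  along the deepest chain (depth +2, one extra compound, composes to
  identity), the nonproductive-sequence pattern;
* `reversed_protection` — moves deprotection before the couplings so the
  protection becomes pointless and couplings run on the free amine:
  depth-preserving, the classic stage-selectivity flaw;
* `step_order_swap` — re-associates two consecutive couplings
  (A·B then ·C vs B·C then A·), a strategy-preserving near-duplicate
  that changes exactly the re-bracketed intermediate while preserving the
  reaction-type multiset. These twins are the positive pairs for the
  clustering-cohesion property, not ranking negatives.

Default conditions: 5–20 alternatives per group (the lower end of the
5–300 range a curated patent corpus provides, chosen for single-CPU
experiment times), depth 4–10, one source per group. In `depth_matched`
mode reference and alternatives draw independent assembly orders of the
same target from one sampler (k ≥ 5 fragments so enough distinct orders
exist) and alternatives carry the depth-preserving reversed-protection
flaw, making depth uninformative in distribution — this isolates strategy
content from route length when comparing against the depth baseline.

What the generator does **not** emulate: template-plausible chemistry
(pseudo-reactions are grammar rewrites with consistent handles, not
validated transformations), realistic molecule diversity, noisy text
extraction, or search-engine alternatives whose flaws are subtler than
the three modeled ones. Passing the synthetic experiments therefore shows
that the encoder separates the modeled strategy flaws and groups
structural near-twins at desk scale — not that patent-scale accuracies
transfer.

## Experiment sizes and numerical choices

End-to-end experiments use 200 training / 50 test groups (seed 0), a size
chosen so the full suite trains both fixture variants in a few CPU
minutes; the first layer exploits fingerprint sparsity (CSR matmuls), and
the embedding FFNN is batched over every node of a group. Structural
equivalences (chain-LSTM reduction, child-permutation invariance) are
asserted to 1e-6 absolute; gradient checks to 1e-4 relative; exact
invariants (enumeration vs. brute force, tie brackets, round-trips)
exactly. Softmax probabilities are floored at 1e-300 inside the log;
sigmoid is `scipy.special.expit`. Non-finite LSTM states raise with the
offending node rather than propagating NaNs. Checkpoints are npz archives
with the config embedded; loading refuses a fingerprint-width mismatch.

## Known limitations

* The ranking signal is only as good as the reference/alternative
  labeling assumption; a creative alternative better than the reference
  counts as an error by construction.
* SLScores are not comparable across targets, and their absolute values
  carry no meaning.
* The complexity stand-in is a structural proxy; baseline accuracies with
  a learned complexity model may differ.
* Curation is per-source; merging networks across sources would introduce
  cycles and role reversals that the cycle guard handles but the strategy
  semantics do not address.
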