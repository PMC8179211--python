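# routestrat

Strategy-level evaluation and clustering of retrosynthesis pathways.

Modern computer-aided synthesis planning (CASP) programs propose thousands
of formally valid routes for one target molecule, but most of them are
strategically poor — padded with nonproductive protection/deprotection
sequences, or deprotecting at the wrong stage — and most of the rest are
near-duplicates of each other. `routestrat` addresses both problems for
chemists and CASP developers:

1. **Curation.** Single-step reactions sharing a source (typically one
   patent) form a bipartite compound/reaction network; compounds appearing
   only as products are *root nodes*, and a complete depth-first search
   from each root enumerates every retrosynthesis pathway embedded in the
   network (reagents omitted, depth-filterable, default 4–10 steps).
2. **Ranking.** Every reaction node of a pathway tree is featurized as a
   2048-bit radius-2 Morgan fingerprint of its product plus a signed
   count-difference reaction fingerprint (product − Σ reactants), embedded
   by an FFNN, and fed to a **child-sum tree-LSTM** built dynamically to
   mirror the tree: for node *j* with children *k*,

   h̃ⱼ = Σₖ hₖ,  iⱼ/oⱼ/uⱼ = gates(Wxⱼ + Uh̃ⱼ + b),
   fⱼₖ = σ(W_f xⱼ + U_f hₖ + b_f),
   cⱼ = iⱼ⊙uⱼ + Σₖ fⱼₖ⊙cₖ,  hⱼ = oⱼ⊙tanh(cⱼ).

   The root hidden state is the pathway embedding; a scorer FFNN maps it
   to the **SLScore**, a strategy-level score meaningful only relative to
   other routes for the same target. Training is group-wise (one reference
   route that was actually practiced vs. its machine-generated
   alternatives) with a listwise softmax cross-entropy.
3. **Baselines.** Depth sorting with worst/best-case tie bracketing; a
   complexity-flow model (linearize the tree at branch points, track
   per-step compound complexity, FFNN per chain, min-pool); and an
   11-descriptor hybrid FFNN. Compound complexity is pluggable (a
   deterministic structural proxy on the 1–5 scale ships by default).
4. **Clustering.** HDBSCAN over pathway embeddings groups strategically
   similar routes (noise = −1), with per-cluster shared-intermediate
   reports; t-SNE projections of reaction embeddings serve as diagnostics.

A seeded synthetic generator (`routestrat.synthetic`) produces pathway
groups with controlled strategy flaws — identity detour pairs, reversed
protection order, step re-association twins — so the whole pipeline is
testable without licensed reaction data.

## Worked example

`examples/extract_routes.py` enumerates all routes of the packaged
20-compound, 15-reaction patent-style network:

```
network: 20 compounds, 15 reactions
root compounds (candidate targets): ['1', '2', '3', '9', '13']

5 routes found by complete DFS:
  (1) depth 4: [1] -> [5, 6, 10] -> [14] -> [16, 17] -> [19, 20]
  (2) depth 4: [13] -> [11, 12] -> [15] -> [17, 18] -> [19, 20]
  ...
```

Each listing reads target → reactant frontier per step: route (1)
decomposes compound 1 into {5, 6, 10}, expands 5 via 14, and stops at
purchasable materials. `examples/rank_synthetic_routes.py` trains the
ranker on synthetic groups and prints:

```
training loss per epoch: [2.022, 1.738, 1.324, 0.722, 0.268, 0.084]
held-out top-1: 1.0
group G0032 (reference = G0032/ref):
  1. G0032/ref     SLScore +0.595 <- reference
  2. G0032/alt001  SLScore -3.189
  ...
```

Top-1 is the fraction of held-out groups whose reference route out-scores
every corrupted alternative; the SLScore gap shows the margin. The other
examples compare the heuristic baselines and cluster embeddings into
strategy groups (`examples/compare_baselines.py`,
`examples/cluster_strategies.py`).

The same workflow is scriptable from the shell:

```bash
routestrat simulate --n-groups 40 --seed 0 --out data/
routestrat train --groups data/ --out model.ckpt.npz
routestrat rank --model model.ckpt.npz --group data/G0000.json --k 10
routestrat cluster --model model.ckpt.npz --pathways data/ --out clusters.csv
```

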