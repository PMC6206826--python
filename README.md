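# multimod

Detection of **conserved functional modules** in multi-layer biological
networks — gene sets that are densely interconnected in many of a collection
of networks simultaneously (e.g. co-expression networks of different cancer
types, or tissue-specific protein interaction networks).

## The method

Given M undirected networks `G^(t) = (V^(t), E^(t), W^(t))` over a (possibly
partially shared) node universe of size `N = |∪_t V^(t)|`, the whole stack is
compressed into two symmetric N×N edge-feature matrices:

* **connection strength** — the average edge weight over layers,
  `x_ij^(s) = (Σ_t w_ij^(t)) / M`;
* **participation coefficient** — how uniformly the total weight
  `o_ij = Σ_t w_ij^(t)` spreads over layers,
  `x_ij^(p) = (M/(M−1)) · [1 − Σ_t (w_ij^(t)/o_ij)²]`
  (1 for an edge with identical weight everywhere, 0 for an edge confined to
  one layer).

For weighted inputs, weights are first max-normalized per layer and squashed
with a logistic `L(w) = 1/(1 + exp(c·w + d))` calibrated so that
`L(0) = 0.0001` (`d = log 9999`, `c = −2 log 9999`); this stops the many weak
edges from scoring as perfectly conserved.

The two feature matrices are treated as two views of one latent module
structure and factorized jointly by **multi-view symmetric NMF**:

```
min  Σ_v ‖X^(v) − H^(v) H^(v)ᵀ‖²_F  +  Σ_v λ_v ‖H^(v) − H_c‖²_F ,   H^(v), H_c ≥ 0
```

solved by alternating a multiplicative update of each view factor with the
closed-form consensus `H_c = (Σ_v λ_v H^(v)) / (Σ_v λ_v)`, with random
restarts (defaults λ_s = 0.01, λ_p = 0.05). Modules are read off the
consensus columns by **soft node selection**: column z-scores are computed
with the sample (N−1) deviation and node i joins the module of column j when
`z_ij > θ` (θ typically in [2, 5]); near-duplicate candidates
(overlap ratio > 0.5) are merged and modules smaller than five nodes dropped.
Finally a **permutation test** per (module, layer) compares the cluster
quality `q_t` = within-density / outside-density against random node sets of
the same size; after Benjamini–Hochberg correction, adjusted p < 0.01 marks
presence, and modules present in no more than half of the layers are removed.

Because the module search runs only on the two N×N feature matrices, time and
memory are essentially independent of the number of input networks.

## Worked example

Plant three 30-node modules into 8, 6 and 4 of 10 unweighted networks over
200 nodes (intra-module edge probability α = 0.5, background β = 0.05), then
run the full pipeline:

```python
from multimod import (NMFConfig, compute_features, extract_modules,
                      filter_by_presence, generate_common_blocks,
                      pair_confusion, permutation_test, solve, tpr_fpr_mcc)

bench = generate_common_blocks(
    M=10, N=200, module_sizes=[30, 30, 30], layers_per_module=[8, 6, 4],
    alpha=0.5, beta=0.05, seed=0,
)
fp = compute_features(bench.networks)
res = solve(fp.strength, fp.participation,
            NMFConfig(k=3, lambda_s=0.01, lambda_p=0.05, n_restarts=5, seed=0))
modules = extract_modules(res, bench.networks.node_labels, theta=2.0)
report = permutation_test(bench.networks, modules, n_perm=999, seed=0)
retained = filter_by_presence(report, modules)
tpr, fpr, mcc = tpr_fpr_mcc(pair_confusion(modules, bench.truth_sets(),
                                           bench.networks.node_labels))
print(f"modules found: {len(modules)} (sizes {[len(m) for m in modules.modules]})")
print(f"present in >half the layers: {len(retained)}")
print(f"presence counts per module: {report.presence.sum(axis=1).tolist()}")
print(f"TPR={tpr:.3f}  FPR={fpr:.4f}  MCC={mcc:.3f}")
```

prints

```
modules found: 3 (sizes [30, 29, 25])
present in >half the layers: 2
presence counts per module: [8, 6, 4]
TPR=0.874  FPR=0.0000  MCC=0.931
```

All three planted modules are recovered nearly node-for-node (pair-counting
Matthews correlation 0.93 against the planted truth, no false-positive
pairs), and the permutation test reconstructs exactly the layers each module
was planted in: 8, 6 and 4. The module present in only 4 of 10 layers is then
removed by the strictly-more-than-half presence rule, leaving 2 conserved
modules.

The same pipeline is available from the shell:

```sh
multimod simulate --design common_blocks -M 10 -N 200 \
    --module-sizes 30,30,30 --layers-per-module 8,6,4 \
    --alpha 0.5 --beta 0.05 --seed 0 -o bench/
multimod run bench/layer_*.tsv -k 3 --theta 2.0 --seed 0 -o out/
```

which writes the module memberships (TSV and GMT), consensus factors,
validation matrices (quality, adjusted p, binary presence) and a JSON run
manifest under `out/`. `multimod scan-k` tabulates precision/recall/f-score
(or TPR/FPR/MCC against a truth file) over several ranks k to guide the
choice of k; `multimod evaluate` and `multimod validate` score and
re-validate existing module files.

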