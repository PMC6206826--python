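"""Planted-partition benchmarks for multi-layer module detection.

Two designs, each with known ground truth:

* **common_blocks** — disjoint node blocks are planted, each into a random
  subset of layers (default: five 80-node blocks into 25/20/15/10/5 of M=30
  layers over N=500 nodes).  Within a layer, pairs inside a planted block
  connect with probability alpha and every other pair with probability
  beta < alpha.
* **overlapping_cores** — each layer carries layer-specific modules that all
  contain a shared conserved core (default: cores of 50 and 40 nodes in M=15
  layers, each padded with 30 layer-private nodes per layer); the conserved
  signal is the intersection of the per-layer modules.

With ``weighted=True`` present edges get Gaussian weights clipped to [0, 1]:
mean 0.8 for module-internal edges, mean 0.2 for background edges, standard
deviation ``noise_sd`` (default 0.1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .network_io import MultiNetwork, UsageError

MODULE_EDGE_MEAN = 0.8
BACKGROUND_EDGE_MEAN = 0.2


@dataclass
class SyntheticParams:
    M: int = 30
    N: int = 500
    module_sizes: list[int] = field(default_factory=lambda: [80, 80, 80, 80, 80])
    layers_per_module: list[int] = field(default_factory=lambda: [25, 20, 15, 10, 5])
    alpha: float = 0.5
    beta: float = 0.05
    weighted: bool = False
    noise_sd: float = 0.1
    private_nodes_per_layer: int = 30
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise UsageError("alpha must be in (0, 1]")
        if not (0 <= self.beta < self.alpha):
            raise UsageError("beta must satisfy 0 <= beta < alpha")
        if self.M < 2:
            raise UsageError("need at least 2 layers")
        if len(self.module_sizes) != len(self.layers_per_module):
            raise UsageError("module_sizes and layers_per_module must align")
        if sum(self.module_sizes) > self.N:
            raise UsageError("planted modules exceed the node universe")
        if any(l > self.M for l in self.layers_per_module):
            raise UsageError("a module cannot be planted in more layers than exist")


@dataclass
class PlantedBenchmark:
    networks: MultiNetwork
    truth: list[tuple[frozenset[str], frozenset[int]]]
    design: str
    params: SyntheticParams

    def truth_sets(self) -> list[frozenset[str]]:
        return [members for members, _ in self.truth]


def _node_labels(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"n{i:0{width}d}" for i in range(n)]


def _sample_layer(
    n: int,
    blocks: list[np.ndarray],
    alpha: float,
    beta: float,
    weighted: bool,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One layer: background Bernoulli(beta) everywhere, Bernoulli(alpha)
    inside each planted block; optional Gaussian edge weights."""
    upper = np.triu(rng.random((n, n)) < beta, k=1)
    module_mask = np.zeros((n, n), dtype=bool)
    for block in blocks:
        intra = np.zeros((n, n), dtype=bool)
        intra[np.ix_(block, block)] = True
        upper[intra] = np.triu(rng.random((n, n)) < alpha, k=1)[intra]
        module_mask |= intra
    w = upper.astype(float)
    if weighted:
        means = np.where(module_mask, MODULE_EDGE_MEAN, BACKGROUND_EDGE_MEAN)
        noise = rng.normal(means, noise_sd)
        w[upper] = np.clip(noise, 0.0, 1.0)[upper]
    return np.triu(w, k=1) + np.triu(w, k=1).T


def generate_common_blocks(params: SyntheticParams | None = None, **overrides) -> PlantedBenchmark:
    """Design 1: disjoint blocks planted into random layer subsets."""
    params = replace(params or SyntheticParams(), **overrides)
    rng = np.random.default_rng(params.seed)
    labels = _node_labels(params.N)

    start = 0
    blocks: list[np.ndarray] = []
    for size in params.module_sizes:
        blocks.append(np.arange(start, start + size))
        start += size
    assignments = [
        frozenset(rng.choice(params.M, size=n_lay, replace=False).tolist())
        for n_lay in params.layers_per_module
    ]

    layers = []
    for t in range(params.M):
        present = [b for b, a in zip(blocks, assignments) if t in a]
        layers.append(
            _sample_layer(params.N, present, params.alpha, params.beta,
                          params.weighted, params.noise_sd, rng)
        )
    mn = MultiNetwork(labels, layers, [f"layer_{t:02d}" for t in range(params.M)],
                      weighted=params.weighted)
    truth = [
        (frozenset(labels[i] for i in block), assign)
        for block, assign in zip(blocks, assignments)
    ]
    return PlantedBenchmark(networks=mn, truth=truth, design="common_blocks", params=params)


def generate_overlapping_cores(
    params: SyntheticParams | None = None, **overrides
) -> PlantedBenchmark:
    """Design 2: conserved cores embedded inside larger layer-specific modules.

    Each core appears in every layer, padded with layer-private nodes drawn
    disjointly from the non-core universe, so only the core is conserved.
    """
    if params is None:
        params = SyntheticParams(M=15, N=500, module_sizes=[50, 40],
                                 layers_per_module=[15, 15])
    params = replace(params, **overrides)
    rng = np.random.default_rng(params.seed)
    labels = _node_labels(params.N)

    start = 0
    cores: list[np.ndarray] = []
    for size in params.module_sizes:
        cores.append(np.arange(start, start + size))
        start += size
    core_nodes = start
    n_private = len(cores) * params.private_nodes_per_layer
    if core_nodes + n_private > params.N:
        raise UsageError("not enough non-core nodes for the layer-private parts")

    layers = []
    for _ in range(params.M):
        pool = rng.permutation(np.arange(core_nodes, params.N))
        full_modules = []
        for ci, core in enumerate(cores):
            private = pool[
                ci * params.private_nodes_per_layer : (ci + 1) * params.private_nodes_per_layer
            ]
            full_modules.append(np.concatenate([core, private]))
        layers.append(
            _sample_layer(params.N, full_modules, params.alpha, params.beta,
                          params.weighted, params.noise_sd, rng)
        )
    mn = MultiNetwork(labels, layers, [f"layer_{t:02d}" for t in range(params.M)],
                      weighted=params.weighted)
    truth = [
        (frozenset(labels[i] for i in core), frozenset(range(params.M))) for core in cores
    ]
    return PlantedBenchmark(networks=mn, truth=truth, design="overlapping_cores", params=params)


def write_truth_tsv(bench: PlantedBenchmark, members_path: str, layers_path: str) -> None:
    """Persist ground truth: (module_id, node_label) and (module_id, layer_index)."""
    with open(members_path, "w") as fh:
        fh.write("module_id\tnode_label\n")
        for i, (members, _) in enumerate(bench.truth):
            for lab in sorted(members):
                fh.write(f"{i}\t{lab}\n")
    with open(layers_path, "w") as fh:
        fh.write("module_id\tlayer_index\n")
        for i, (_, assign) in enumerate(bench.truth):
            for t in sorted(assign):
                fh.write(f"{i}\t{t}\n")
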