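"""Per-layer module significance via a cluster-quality permutation test.

A module detected from the consensus factors need not be present in every
layer.  For each (module, layer) pair the cluster quality

    q_t = (mean weight over node pairs inside the module)
        / (mean weight over all other node pairs)

is compared against the qualities of random node sets of the same size drawn
uniformly from the node universe.  The permutation p-value uses add-one
smoothing, p = (1 + #{random q >= q_t}) / (1 + n_perm), ties counting against
the module.  All module x layer p-values are Benjamini-Hochberg corrected
jointly; an adjusted p below 0.01 marks the module as present in that layer.
Modules present in no more than half of the layers are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .module_extraction import ModuleSet
from .network_io import MultiNetwork, UsageError

logger = logging.getLogger(__name__)

PRESENCE_ALPHA = 0.01


@dataclass
class ValidationReport:
    """Module x layer matrices of qualities, p-values and binary presence."""

    quality: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    presence: np.ndarray
    n_permutations: int
    seed: int | None
    module_ids: list[int]
    layer_names: list[str]


def cluster_quality(layer: np.ndarray, members: np.ndarray) -> float:
    """Within-module mean pair weight over outside mean pair weight.

    Returns +inf when the module has internal weight but the rest of the
    layer is empty, and 0 when both densities are zero.  ``members`` are node
    indices; the module must be a strict subset with at least 2 nodes.
    """
    n = layer.shape[0]
    m = len(members)
    if m < 2 or m >= n:
        raise UsageError("module must contain 2 <= |C| < N nodes")
    inside_sum = layer[np.ix_(members, members)].sum() / 2.0
    total_sum = layer.sum() / 2.0
    inside_pairs = m * (m - 1) / 2.0
    outside_pairs = n * (n - 1) / 2.0 - inside_pairs
    d_in = inside_sum / inside_pairs
    d_out = (total_sum - inside_sum) / outside_pairs
    if d_out == 0:
        return float("inf") if d_in > 0 else 0.0
    return float(d_in / d_out)


def _random_qualities(
    layer: np.ndarray, size: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Qualities of ``n_perm`` uniform node sets of the given size."""
    n = layer.shape[0]
    total_sum = layer.sum() / 2.0
    inside_pairs = size * (size - 1) / 2.0
    outside_pairs = n * (n - 1) / 2.0 - inside_pairs
    # indicator matrix S (n_perm x N): inside sum for set s is s W s^T / 2
    sets = np.zeros((n_perm, n))
    for r in range(n_perm):
        sets[r, rng.choice(n, size=size, replace=False)] = 1.0
    inside = np.einsum("rn,nm,rm->r", sets, layer, sets) / 2.0
    d_in = inside / inside_pairs
    d_out = (total_sum - inside) / outside_pairs
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(d_out > 0, d_in / d_out, np.where(d_in > 0, np.inf, 0.0))
    return q


def permutation_pvalue(
    layer: np.ndarray,
    members: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """(cluster quality, raw permutation p-value) for one module in one layer."""
    q = cluster_quality(layer, members)
    rand_q = _random_qualities(layer, len(members), n_perm, rng)
    exceed = int(np.sum(rand_q >= q))
    p = (1.0 + exceed) / (1.0 + n_perm)
    return q, p


def permutation_test(
    mn: MultiNetwork,
    modules: ModuleSet,
    n_perm: int = 1000,
    seed: int | None = None,
) -> ValidationReport:
    """Permutation test of every module in every layer, BH-corrected jointly.

    Random modules are node sets of identical size drawn uniformly from the
    global node universe, so qualities are comparable across layers.  A module
    too large to leave any outside pair gets p = 1 with a warning.
    """
    if n_perm < 100:
        raise UsageError("n_perm must be >= 100")
    n_mod, n_lay = len(modules.modules), mn.n_layers
    quality = np.zeros((n_mod, n_lay))
    p_raw = np.ones((n_mod, n_lay))
    label_idx = {lab: i for i, lab in enumerate(mn.node_labels)}
    rng = np.random.default_rng(seed)
    for mi, mod in enumerate(modules.modules):
        members = np.array(sorted(label_idx[l] for l in mod.members))
        if len(members) < 2 or len(members) >= mn.n_nodes:
            logger.warning("module %d: quality undefined (size %d of %d nodes), p set to 1",
                           mi, len(members), mn.n_nodes)
            quality[mi, :] = np.nan
            continue
        for ti, layer in enumerate(mn.layers):
            quality[mi, ti], p_raw[mi, ti] = permutation_pvalue(layer, members, n_perm, rng)
    _, p_adj_flat, _, _ = multipletests(p_raw.ravel(), method="fdr_bh")
    p_adj = p_adj_flat.reshape(p_raw.shape)
    presence = (p_adj < PRESENCE_ALPHA).astype(int)
    return ValidationReport(
        quality=quality,
        p_raw=p_raw,
        p_adj=p_adj,
        presence=presence,
        n_permutations=n_perm,
        seed=seed,
        module_ids=list(range(n_mod)),
        layer_names=list(mn.layer_names),
    )


def filter_by_presence(
    report: ValidationReport, modules: ModuleSet, min_fraction: float = 0.5
) -> ModuleSet:
    """Keep modules present in strictly more than ``min_fraction`` of layers."""
    if len(report.module_ids) != len(modules.modules):
        raise UsageError("report and module set are not aligned")
    m_layers = report.presence.shape[1]
    keep = [
        mod
        for mod, row in zip(modules.modules, report.presence)
        if row.sum() > min_fraction * m_layers
    ]
    return ModuleSet(modules=keep, theta=modules.theta, source=modules.source)


def write_report_tsvs(report: ValidationReport, prefix: str) -> list[str]:
    """Persist quality / adjusted-p / presence as labeled TSVs."""
    import pandas as pd

    paths = []
    for name, mat in (
        ("quality", report.quality),
        ("p_adj", report.p_adj),
        ("presence", report.presence),
    ):
        path = f"{prefix}_{name}.tsv"
        pd.DataFrame(
            mat,
            index=[f"module_{i}" for i in report.module_ids],
            columns=report.layer_names,
        ).to_csv(path, sep="\t")
        paths.append(path)
    return paths
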