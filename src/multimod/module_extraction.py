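"""Soft node selection from the consensus factors.

Hard clustering (assigning each node to its argmax consensus column) is a poor
fit for biological networks: multifunctional genes belong to several modules
and many genes belong to none.  Instead each consensus column is standardized
to z-scores and a node joins a candidate module when its z-score exceeds a
threshold theta (typically in [2, 5]); a node may pass the threshold in
several columns and so belong to several modules.  Candidate modules that are
near-duplicates — overlap ratio |Cx n Cy| / min(|Cx|, |Cy|) above 0.5 — are
merged to a fixpoint, and modules smaller than five nodes are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .factorization import FactorizationResult
from .network_io import UsageError

logger = logging.getLogger(__name__)

MERGE_OVERLAP = 0.5
MIN_MODULE_SIZE = 5


@dataclass
class Module:
    """A conserved-module candidate.

    ``column_index`` is the consensus column the module came from, or -1 for
    a module produced by merging; ``z_scores`` maps each member to its
    (maximal, over contributing columns) selection z-score.
    """

    members: frozenset[str]
    column_index: int
    z_scores: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ModuleSet:
    modules: list[Module]
    theta: float
    source: FactorizationResult | None = None

    def __len__(self) -> int:
        return len(self.modules)

    def member_sets(self) -> list[frozenset[str]]:
        return [m.members for m in self.modules]


def column_zscores(H_c: np.ndarray) -> np.ndarray:
    """Standardize each column with its own mean and sample (N-1) deviation.

    A constant column (sigma = 0) yields all-zero z-scores with a warning —
    no node is selectable from it.
    """
    H_c = np.asarray(H_c, dtype=float)
    if H_c.ndim != 2 or H_c.shape[0] < 2:
        raise UsageError("consensus matrix must be N x k with N >= 2")
    mu = H_c.mean(axis=0)
    sigma = H_c.std(axis=0, ddof=1)
    z = np.zeros_like(H_c)
    ok = sigma > 0
    if not ok.all():
        logger.warning("constant consensus column(s) %s: z-scores set to 0", np.nonzero(~ok)[0])
    z[:, ok] = (H_c[:, ok] - mu[ok]) / sigma[ok]
    return z


def select_nodes(z: np.ndarray, theta: float) -> list[set[int]]:
    """Per column, the node indices with z-score above theta (soft selection)."""
    if theta <= 0:
        raise UsageError("theta must be positive")
    return [set(np.nonzero(z[:, j] > theta)[0].tolist()) for j in range(z.shape[1])]


def _overlap_ratio(a: frozenset, b: frozenset) -> float:
    return len(a & b) / min(len(a), len(b))


def merge_and_filter(
    candidates: list[set[int] | frozenset[int]],
    min_size: int = MIN_MODULE_SIZE,
) -> list[tuple[frozenset[int], frozenset[int]]]:
    """Merge highly overlapping candidates to a fixpoint, then drop small ones.

    Greedy: repeatedly merge the pair with the highest overlap ratio while it
    exceeds 0.5; ties broken by smaller combined size, then by the
    lexicographically smallest sorted member tuple of the union (deterministic
    regardless of the input order).  Returns ``(members, origin_columns)``
    pairs, where ``origin_columns`` collects the candidate indices merged in.
    """
    # (members, origin column indices); empty candidates never merge or survive
    items: list[tuple[frozenset, frozenset]] = [
        (frozenset(c), frozenset([i])) for i, c in enumerate(candidates) if c
    ]
    while True:
        best = None
        for a in range(len(items)):
            for b in range(a + 1, len(items)):
                ratio = _overlap_ratio(items[a][0], items[b][0])
                if ratio <= MERGE_OVERLAP:
                    continue
                union = items[a][0] | items[b][0]
                key = (-ratio, len(union), tuple(sorted(union)))
                if best is None or key < best[0]:
                    best = (key, a, b, union)
        if best is None:
            break
        _, a, b, union = best
        origins = items[a][1] | items[b][1]
        items = [it for i, it in enumerate(items) if i not in (a, b)]
        items.append((union, origins))
    return [(m, o) for m, o in items if len(m) >= min_size]


def extract_modules(
    result: FactorizationResult,
    node_labels: list[str],
    theta: float = 2.0,
    min_size: int = MIN_MODULE_SIZE,
) -> ModuleSet:
    """Full extraction: z-scores -> thresholding -> merge & size filter."""
    z = column_zscores(result.H_c)
    candidates = select_nodes(z, theta)
    merged = merge_and_filter(candidates, min_size=min_size)
    modules = []
    for members_idx, origins in merged:
        col = next(iter(origins)) if len(origins) == 1 else -1
        zmap = {
            node_labels[i]: float(max(z[i, j] for j in origins if z[i, j] > theta))
            for i in members_idx
        }
        modules.append(
            Module(
                members=frozenset(node_labels[i] for i in members_idx),
                column_index=col,
                z_scores=zmap,
            )
        )
    modules.sort(key=lambda m: tuple(sorted(m.members)))
    return ModuleSet(modules=modules, theta=theta, source=result)


def write_modules_tsv(ms: ModuleSet, path: str) -> None:
    """TSV: module_id, node_label, z_score."""
    with open(path, "w") as fh:
        fh.write("module_id\tnode_label\tz_score\n")
        for i, mod in enumerate(ms.modules):
            for label in sorted(mod.members):
                fh.write(f"{i}\t{label}\t{mod.z_scores.get(label, float('nan')):.6g}\n")


def write_modules_gmt(ms: ModuleSet, path: str, description: str = "conserved_module") -> None:
    """GMT-like lines: module_id, description, tab-separated members."""
    with open(path, "w") as fh:
        for i, mod in enumerate(ms.modules):
            fh.write("\t".join([f"module_{i}", description] + sorted(mod.members)) + "\n")
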