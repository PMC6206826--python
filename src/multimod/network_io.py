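"""Reading, validating, aligning and writing collections of undirected networks.

A multi-layer (multiplex) network is an ordered collection of M >= 2 undirected,
non-negatively weighted networks over a shared node universe.  Layers may cover
different node sets; the in-memory representation aligns every layer to the
union of all node labels, with all-zero rows/columns for nodes a layer does not
observe (equivalent to "no observed interactions" for that node in that layer).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SYMMETRY_TOL = 1e-12


class MultimodError(Exception):
    """Base class for package errors."""


class UsageError(MultimodError):
    """Caller violated a precondition (bad parameters, too few inputs)."""


class ValidationError(MultimodError):
    """Input data violates the model's constraints (e.g. negative weights)."""


class FormatError(MultimodError):
    """A file does not parse in the declared format."""


@dataclass
class MultiNetwork:
    """An aligned collection of M symmetric non-negative adjacency matrices.

    Parameters
    ----------
    node_labels
        Ordered list of N unique node labels, the union of all layers' nodes.
    layers
        List of M dense symmetric ``(N, N)`` float arrays with zero diagonal
        and non-negative entries, aligned to ``node_labels``.
    layer_names
        One name per layer (file stem for file-backed networks).
    weighted
        True if any weight lies outside {0, 1}.
    """

    node_labels: list[str]
    layers: list[np.ndarray]
    layer_names: list[str]
    weighted: bool = field(default=False)

    def __post_init__(self) -> None:
        if len(self.layers) < 2:
            raise UsageError("a multi-layer network needs at least 2 layers")
        if len(self.layer_names) != len(self.layers):
            raise ValidationError("layer_names and layers length mismatch")
        n = len(self.node_labels)
        if len(set(self.node_labels)) != n:
            raise ValidationError("duplicate node labels")
        for name, w in zip(self.layer_names, self.layers):
            w = np.asarray(w, dtype=float)
            if w.shape != (n, n):
                raise ValidationError(f"layer {name!r}: shape {w.shape} != ({n}, {n})")
            if np.any(w < 0):
                raise ValidationError(f"layer {name!r}: negative weights")
            if np.abs(w - w.T).max(initial=0.0) > SYMMETRY_TOL:
                raise ValidationError(f"layer {name!r}: not symmetric within {SYMMETRY_TOL}")
            if np.any(np.diag(w) != 0):
                raise ValidationError(f"layer {name!r}: nonzero diagonal")

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def index_of(self, label: str) -> int:
        return self.node_labels.index(label)


def _is_weighted(layers: list[np.ndarray]) -> bool:
    for w in layers:
        vals = w[w != 0]
        if vals.size and np.any(vals != 1):
            return True
    return False


def _read_edgelist(path: str) -> tuple[dict[tuple[str, str], float], set[str]]:
    """Parse one TSV edge list; returns {(u, v) sorted: weight} and node set."""
    edges: dict[tuple[str, str], float] = {}
    nodes: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:  # tolerate whitespace-delimited files
                parts = line.split()
            if len(parts) not in (2, 3):
                raise FormatError(f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}")
            u, v = parts[0].strip(), parts[1].strip()
            if len(parts) == 3:
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad weight {parts[2]!r}") from exc
            else:
                w = 1.0
            if w < 0:
                raise ValidationError(f"{path}:{lineno}: negative weight {w}")
            if u == v:
                logger.warning("%s:%d: dropping self-loop on %r", path, lineno, u)
                nodes.add(u)
                continue
            key = (u, v) if u <= v else (v, u)
            if key in edges:
                logger.warning("%s:%d: duplicate edge %s-%s, last value wins", path, lineno, u, v)
            edges[key] = w
            nodes.update((u, v))
    return edges, nodes


def _read_adjacency(path: str) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    labels = [str(c) for c in df.columns]
    row_labels = [str(r) for r in df.index]
    if len(labels) != len(row_labels):
        raise FormatError(f"{path}: adjacency matrix not square ({len(row_labels)}x{len(labels)})")
    if len(set(labels)) != len(labels):
        raise FormatError(f"{path}: duplicate node labels in header")
    if labels != row_labels:
        raise FormatError(f"{path}: row labels do not match column labels")
    try:
        mat = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric adjacency entries") from exc
    if np.any(mat < 0):
        raise ValidationError(f"{path}: negative weights in adjacency matrix")
    if np.abs(mat - mat.T).max(initial=0.0) > SYMMETRY_TOL:
        logger.warning("%s: asymmetric adjacency, symmetrizing with max(A, A^T)", path)
        mat = np.maximum(mat, mat.T)
    if np.any(np.diag(mat) != 0):
        logger.warning("%s: dropping self-loops (nonzero diagonal)", path)
        np.fill_diagonal(mat, 0.0)
    return labels, mat


def read_networks(paths: list[str], format: str = "edgelist") -> MultiNetwork:
    """Read M >= 2 network files and align them to the union node index.

    Parameters
    ----------
    paths
        Paths to the per-layer files.
    format
        ``"edgelist"`` (TSV: node, node[, weight]; '#' comments ignored) or
        ``"adjacency"`` (TSV with node-label header row and index column).

    Returns
    -------
    MultiNetwork
        Layers ordered as ``paths``; node labels are the sorted union of all
        layers' nodes.  Each listed edge is copied to both triangles.
    """
    if len(paths) < 2:
        raise UsageError("need at least 2 network files")
    if format not in ("edgelist", "adjacency"):
        raise UsageError(f"unknown format {format!r}")

    per_layer: list[tuple[dict[tuple[str, str], float] | np.ndarray, list[str] | set[str]]] = []
    all_nodes: set[str] = set()
    for p in paths:
        if format == "edgelist":
            edges, nodes = _read_edgelist(p)
            per_layer.append((edges, nodes))
            all_nodes |= nodes
        else:
            labels, mat = _read_adjacency(p)
            per_layer.append((mat, labels))
            all_nodes |= set(labels)

    node_labels = sorted(all_nodes)
    idx = {lab: i for i, lab in enumerate(node_labels)}
    n = len(node_labels)

    layers: list[np.ndarray] = []
    for data, labels in per_layer:
        w = np.zeros((n, n))
        if format == "edgelist":
            for (u, v), weight in data.items():
                i, j = idx[u], idx[v]
                w[i, j] = weight
                w[j, i] = weight
        else:
            pos = [idx[lab] for lab in labels]
            w[np.ix_(pos, pos)] = data
        layers.append(w)

    names = [os.path.splitext(os.path.basename(p))[0] for p in paths]
    return MultiNetwork(node_labels, layers, names, weighted=_is_weighted(layers))


def write_networks(mn: MultiNetwork, out_dir: str, format: str = "edgelist") -> list[str]:
    """Write one file per layer into ``out_dir``; returns the paths written.

    Edge-list files emit each undirected edge once (lexicographically smaller
    label first) at full float precision; adjacency files emit the full
    labeled square matrix.
    """
    if format not in ("edgelist", "adjacency"):
        raise UsageError(f"unknown format {format!r}")
    os.makedirs(out_dir, exist_ok=True)
    ext = ".tsv"
    paths = []
    for name, w in zip(mn.layer_names, mn.layers):
        path = os.path.join(out_dir, name + ext)
        if format == "edgelist":
            with open(path, "w") as fh:
                fh.write("# node\tnode\tweight\n")
                ii, jj = np.nonzero(np.triu(w, k=1))
                for i, j in zip(ii, jj):
                    fh.write(f"{mn.node_labels[i]}\t{mn.node_labels[j]}\t{float(w[i, j])!r}\n")
        else:
            df = pd.DataFrame(w, index=mn.node_labels, columns=mn.node_labels)
            df.to_csv(path, sep="\t")
        paths.append(path)
    return paths
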