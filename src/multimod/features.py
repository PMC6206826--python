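"""Compression of a multi-layer network into two edge-feature matrices.

Conserved modules are sets of nodes whose mutual edges are (a) heavy on
average and (b) evenly spread across layers.  Both properties are per-edge
summaries, so the whole M-layer stack collapses into two symmetric N x N
matrices:

* **connection strength** ``x_ij^(s)`` — the average weight of edge (i, j)
  over all M layers;
* **participation coefficient** ``x_ij^(p)`` — how uniformly the total weight
  ``o_ij = sum_t w_ij^(t)`` is distributed over layers,
  ``(M/(M-1)) * (1 - sum_t (w_ij^(t)/o_ij)^2)``, which is 1 for an edge with
  identical weight in every layer and 0 for an edge confined to one layer.

For weighted inputs a logistic squashing ``L(w) = 1/(1 + exp(c*w + d))`` is
applied first (after per-layer max-normalization into [0, 1]) so that the many
weak edges do not masquerade as perfectly conserved: a weight of 0.01 present
in every layer has participation 1, but carries no module signal.  The default
calibration fixes ``L(0) = 0.0001``, giving ``d = log(9999)`` and
``c = -2*log(9999)`` (so L(0.5) = 0.5 and L(1) = 0.9999).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .network_io import MultiNetwork, UsageError, ValidationError

logger = logging.getLogger(__name__)

_D_DEFAULT = math.log(9999.0)
_C_DEFAULT = -2.0 * math.log(9999.0)


@dataclass
class LogisticParams:
    """Calibration of the logistic squashing L(w) = 1/(1 + exp(c*w + d)).

    ``zero_value`` is the target for L(0); with the defaults, L(0) = 0.0001
    exactly and L is increasing (c < 0) with midpoint L(0.5) = 0.5.
    Transformed values below ``zero_value`` are truncated to zero so that
    near-absent edges stay absent.
    """

    c: float = _C_DEFAULT
    d: float = _D_DEFAULT
    zero_value: float = 1e-4

    def __post_init__(self) -> None:
        if self.c >= 0:
            raise UsageError("logistic slope c must be negative (L increasing in w)")
        l0 = 1.0 / (1.0 + math.exp(self.d))
        if abs(l0 - self.zero_value) > 1e-9:
            raise UsageError(
                f"inconsistent logistic params: L(0)={l0:.6g} != zero_value={self.zero_value:.6g}"
            )

    def __call__(self, w: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(self.c * np.asarray(w, dtype=float) + self.d))


@dataclass
class FeaturePair:
    """The two symmetric N x N feature matrices, aligned to ``node_labels``."""

    strength: np.ndarray
    participation: np.ndarray
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, m in (("strength", self.strength), ("participation", self.participation)):
            if np.any(m < -1e-12) or np.any(m > 1 + 1e-12):
                raise ValidationError(f"{name} matrix has entries outside [0, 1]")
            if np.abs(m - m.T).max(initial=0.0) > 1e-12:
                raise ValidationError(f"{name} matrix not symmetric")
        if np.any((self.strength == 0) & (self.participation != 0)):
            raise ValidationError("participation nonzero where strength is zero")


def connection_strength(mn: MultiNetwork) -> np.ndarray:
    """Average edge weight across layers; symmetric, zero diagonal, in [0, 1]."""
    return np.mean(np.stack(mn.layers), axis=0)


def participation_coefficient(mn: MultiNetwork) -> np.ndarray:
    """Uniformity of each edge's weight distribution across the M layers.

    Zero where the edge appears in no layer.  Requires M >= 2 (the M/(M-1)
    normalization is undefined for a single layer).
    """
    m = mn.n_layers
    if m < 2:
        raise UsageError("participation coefficient requires at least 2 layers")
    stack = np.stack(mn.layers)
    o = stack.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(o > 0, stack / o, 0.0)
    p = (m / (m - 1.0)) * (1.0 - (frac**2).sum(axis=0))
    p = np.where(o > 0, p, 0.0)
    # guard float round-off at the boundaries
    return np.clip(p, 0.0, 1.0)


def logistic_transform(mn: MultiNetwork, params: LogisticParams | None = None) -> MultiNetwork:
    """Apply the logistic squashing to every observed (positive) weight.

    Layers must already be normalized into [0, 1].  Structural zeros are left
    exactly zero — an absent edge stays absent — and transformed values below
    ``params.zero_value`` are truncated to zero.
    """
    params = params or LogisticParams()
    out = []
    for name, w in zip(mn.layer_names, mn.layers):
        if w.max(initial=0.0) > 1.0 + 1e-12:
            raise ValidationError(f"layer {name!r}: weights not normalized into [0, 1]")
        t = params(w)
        t[w == 0] = 0.0
        t[t < params.zero_value] = 0.0
        out.append(t)
    return MultiNetwork(mn.node_labels, out, mn.layer_names, weighted=True)


def normalize_layers(mn: MultiNetwork, per_layer: bool = True) -> MultiNetwork:
    """Scale weights into [0, 1] by dividing by the (per-layer or global) max."""
    if per_layer:
        maxima = [w.max(initial=0.0) for w in mn.layers]
    else:
        g = max(w.max(initial=0.0) for w in mn.layers)
        maxima = [g] * mn.n_layers
    out = [w / m if m > 0 else w.copy() for w, m in zip(mn.layers, maxima)]
    return MultiNetwork(mn.node_labels, out, mn.layer_names, weighted=mn.weighted)


def compute_features(
    mn: MultiNetwork,
    apply_logistic: bool | None = None,
    params: LogisticParams | None = None,
    per_layer_norm: bool = True,
) -> FeaturePair:
    """Compute the connection-strength / participation feature pair.

    Parameters
    ----------
    mn
        The input multi-layer network.
    apply_logistic
        Whether to normalize and logistic-squash weights first.  ``None``
        (default) auto-detects: weighted inputs are transformed, unweighted
        (all weights in {0, 1}) are used directly.
    params
        Logistic calibration; defaults to L(0) = 0.0001.
    per_layer_norm
        Normalize each layer by its own maximum (default) or by the global
        maximum across layers.
    """
    if apply_logistic is None:
        apply_logistic = mn.weighted
    if apply_logistic:
        mn = logistic_transform(normalize_layers(mn, per_layer=per_layer_norm), params)
    return FeaturePair(
        strength=connection_strength(mn),
        participation=participation_coefficient(mn),
        node_labels=list(mn.node_labels),
    )
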