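"""Scoring predicted modules against ground truth and gene-set collections.

Pair-counting: over all unordered node pairs in the universe, a pair is
*related* when the two nodes share at least one truth module and *assigned
together* when they share at least one predicted module (modules may overlap;
nodes in no module are singletons and never co-members).  TPR, FPR and the
Matthews correlation coefficient are computed from the resulting confusion
counts.

Gene-set scoring: each predicted module is tested for enrichment against each
reference set with a one-sided Fisher's exact test over a stated universe,
BH-corrected across all module x set tests.  Precision is the fraction of
modules significantly overlapping some reference set, recall the fraction of
reference sets significantly overlapped by some module, and the f-score their
harmonic mean.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .module_extraction import ModuleSet
from .network_io import FormatError, UsageError

logger = logging.getLogger(__name__)


@dataclass
class PairConfusion:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def _comembership(sets: Iterable[frozenset[str]], index: Mapping[str, int]) -> np.ndarray:
    n = len(index)
    co = np.zeros((n, n), dtype=bool)
    for members in sets:
        idx = np.array([index[m] for m in members if m in index])
        if idx.size:
            co[np.ix_(idx, idx)] = True
    np.fill_diagonal(co, False)
    return co


def _as_sets(predicted: ModuleSet | Sequence[Iterable[str]]) -> list[frozenset[str]]:
    if isinstance(predicted, ModuleSet):
        return predicted.member_sets()
    return [frozenset(s) for s in predicted]


def pair_confusion(
    predicted: ModuleSet | Sequence[Iterable[str]],
    truth: Sequence[Iterable[str]],
    universe: Sequence[str],
) -> PairConfusion:
    """Confusion counts over all unordered node pairs of the universe."""
    if not universe:
        raise UsageError("empty node universe")
    index = {lab: i for i, lab in enumerate(universe)}
    pred_co = _comembership(_as_sets(predicted), index)
    true_co = _comembership([frozenset(s) for s in truth], index)
    iu = np.triu_indices(len(universe), k=1)
    p, t = pred_co[iu], true_co[iu]
    return PairConfusion(
        TP=int(np.sum(p & t)),
        TN=int(np.sum(~p & ~t)),
        FP=int(np.sum(p & ~t)),
        FN=int(np.sum(~p & t)),
    )


def tpr_fpr_mcc(c: PairConfusion) -> tuple[float, float, float]:
    """True-positive rate, false-positive rate and Matthews correlation.

    MCC is in [-1, 1]; a zero denominator (some margin empty) yields MCC = 0
    with a warning.  Degenerate TPR/FPR denominators also yield 0.
    """
    tp, tn, fp, fn = (float(x) for x in (c.TP, c.TN, c.FP, c.FN))
    tpr = tp / (tp + fn) if tp + fn > 0 else 0.0
    fpr = fp / (fp + tn) if fp + tn > 0 else 0.0
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        logger.warning("MCC denominator zero; returning 0")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / denom
    return tpr, fpr, mcc


def read_gmt(path: str) -> dict[str, frozenset[str]]:
    """Read a GMT file: per line, set name, description, tab-separated members."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, description, members")
            sets[parts[0]] = frozenset(p for p in parts[2:] if p)
    return sets


def geneset_scores(
    predicted: ModuleSet | Sequence[Iterable[str]],
    reference: Mapping[str, Iterable[str]],
    universe_size: int,
    fdr: float = 0.05,
) -> tuple[float, float, float]:
    """(precision, recall, f_score) of predicted modules vs reference sets.

    Enrichment of module vs set uses the one-sided Fisher's exact test on the
    2x2 overlap table over ``universe_size`` genes; BH correction is applied
    over all module x set tests and significance means adjusted p < ``fdr``.
    Returns zeros when there are no modules or no reference sets.
    """
    pred_sets = _as_sets(predicted)
    ref_sets = {name: frozenset(s) for name, s in reference.items()}
    if not pred_sets or not ref_sets:
        return 0.0, 0.0, 0.0
    if universe_size < max(
        [len(s) for s in pred_sets] + [len(s) for s in ref_sets.values()]
    ):
        raise UsageError("universe_size smaller than a gene set")

    pvals, pairs = [], []
    for mi, mod in enumerate(pred_sets):
        for name, ref in ref_sets.items():
            k = len(mod & ref)
            table = [
                [k, len(mod) - k],
                [len(ref) - k, universe_size - len(mod) - len(ref) + k],
            ]
            _, p = fisher_exact(table, alternative="greater")
            pvals.append(p)
            pairs.append((mi, name))
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")

    enriched_modules = {mi for (mi, _), p in zip(pairs, p_adj) if p < fdr}
    covered_sets = {name for (_, name), p in zip(pairs, p_adj) if p < fdr}
    precision = len(enriched_modules) / len(pred_sets)
    recall = len(covered_sets) / len(ref_sets)
    f = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return precision, recall, f
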