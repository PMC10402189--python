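"""Per-ancestry model scoring, signature stability and cancer-gene recovery.

AUC is the rank-based Mann-Whitney estimator with midranks for ties:
the probability that a random positive sample scores above a random
negative one.  Signature stability across training batches is measured by
pairwise set overlap (Jaccard by default), and recovery of known cancer
genes by exact intersection with a reference list (COSMIC-style).
"""

from __future__ import annotations

import itertools
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "auc",
    "recall_basal",
    "signature_overlap",
    "overlap_matrix",
    "count_cancer_genes",
]


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney AUC with midranks for tied scores.

    Returns NaN (with a warning) when only one class is present, where
    the statistic is undefined.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    pos = labels == np.max(labels)
    n1 = int(pos.sum())
    n0 = int(len(labels) - n1)
    if n1 == 0 or n0 == 0 or len(np.unique(labels)) < 2:
        warnings.warn("AUC undefined for single-class labels; returning NaN")
        return float("nan")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def recall_basal(scores: Sequence[float], threshold: float = 0.5) -> float:
    """Fraction of samples called positive at the threshold.

    For validation sets that are positive by construction (e.g. triple-
    negative breast cancers, which are basal), accuracy reduces to this
    recall.  Scores exactly at the threshold count as positive.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score list")
    return float(np.mean(scores >= threshold))


def _gene_set(sig) -> set[str]:
    if hasattr(sig, "gene_set"):
        return set(sig.gene_set)
    return set(sig)


def signature_overlap(a, b, metric: str = "jaccard") -> float:
    """Set overlap between two signatures.

    Metrics: ``jaccard`` = |A∩B|/|A∪B| (default), ``min`` = |A∩B| over the
    smaller set, ``containment`` = |A∩B|/|A| (the one asymmetric option).
    """
    sa, sb = _gene_set(a), _gene_set(b)
    if not sa or not sb:
        raise ValueError("signatures must be non-empty")
    inter = len(sa & sb)
    if metric == "jaccard":
        return inter / len(sa | sb)
    if metric == "min":
        return inter / min(len(sa), len(sb))
    if metric == "containment":
        return inter / len(sa)
    raise ValueError(f"unknown overlap metric {metric!r}")


def overlap_matrix(
    signatures: Sequence,
    metric: str = "jaccard",
    names: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Pairwise overlap matrix for a model family plus its off-diagonal mean."""
    n = len(signatures)
    names = list(names) if names is not None else [f"model_{i}" for i in range(n)]
    mat = np.ones((n, n))
    pair_vals = []
    for i, j in itertools.combinations(range(n), 2):
        v = signature_overlap(signatures[i], signatures[j], metric=metric)
        mat[i, j] = mat[j, i] = v
        pair_vals.append(v)
    mean = float(np.mean(pair_vals)) if pair_vals else float("nan")
    return pd.DataFrame(mat, index=names, columns=names), mean


def count_cancer_genes(
    signatures: Sequence,
    gene_list: Iterable[str],
) -> dict:
    """Intersect signatures with a known-cancer-gene list.

    Returns per-signature hit counts and lists, the count of unique list
    genes across all signatures, and the fraction of those found in at
    least two signatures.
    """
    ref = set(gene_list)
    if not ref:
        raise ValueError("gene list is empty")
    per_sig = []
    tally: dict[str, int] = {}
    for sig in signatures:
        hits = sorted(_gene_set(sig) & ref)
        per_sig.append({"count": len(hits), "genes": hits})
        for g in hits:
            tally[g] = tally.get(g, 0) + 1
    union = sorted(tally)
    shared = [g for g, c in tally.items() if c >= 2]
    shared_fraction = len(shared) / len(union) if union else 0.0
    return {
        "per_signature": per_sig,
        "union_count": len(union),
        "union_genes": union,
        "shared_fraction": shared_fraction,
    }
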