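"""Expression cohorts and ancestry-balanced training batches.

Disease cohorts are wildly imbalanced by ancestry (TCGA is majority
European), so models trained on the pooled data inherit that bias.  The
batching scheme counters it: samples are grouped by ancestry (admixed
samples pooled into one group regardless of primary ancestry), a base
batch size is taken from the smallest ancestry group that can still train
a model (at least 9 samples, at least 4 per subtype), each ancestry group
is split into ``floor(n / base_size)`` batches with its subtypes divided
evenly across them, and leftover samples are dealt round-robin one per
batch.  "Mixed" batches draw each ancestry in proportion to its cohort
frequency.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionCohort",
    "Batch",
    "BatchPlan",
    "BatchingError",
    "load_cohort",
    "make_batches",
    "make_mixed_batches",
    "largest_remainder_counts",
    "MIN_BATCH_SIZE",
    "MIN_PER_SUBTYPE",
]

logger = logging.getLogger(__name__)

#: Viability floor for a training set: total size and per-subtype minimum.
MIN_BATCH_SIZE = 9
MIN_PER_SUBTYPE = 4

ADMIX_LABEL = "ADMIX"


class BatchingError(ValueError):
    """Raised when a batch plan cannot satisfy the viability floor."""


@dataclasses.dataclass
class ExpressionCohort:
    """A samples x genes expression matrix with per-sample metadata.

    ``meta`` is indexed by sample id and carries ``subtype`` (binary
    label), optional ``ancestry`` and optional ``admixture_fraction``.
    """

    expression: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.expression.index.equals(self.meta.index):
            raise ValueError("expression and metadata sample ids do not align")
        if self.expression.index.has_duplicates:
            dups = self.expression.index[self.expression.index.duplicated()].tolist()
            raise ValueError(f"duplicated sample ids: {dups}")

    @property
    def n_samples(self) -> int:
        return len(self.expression)

    @property
    def genes(self) -> list[str]:
        return list(self.expression.columns)

    def subset(self, sample_ids: Sequence[str]) -> "ExpressionCohort":
        ids = list(sample_ids)
        return ExpressionCohort(
            expression=self.expression.loc[ids], meta=self.meta.loc[ids]
        )

    def labels(self) -> pd.Series:
        return self.meta["subtype"]


def load_cohort(
    expr_path: str | Path,
    clin_path: str | Path,
    orientation: str = "samples_by_genes",
) -> ExpressionCohort:
    """Read expression and clinical TSVs and align them on sample id.

    The intersection of sample ids is taken (mismatches are logged);
    samples without a subtype label are dropped.  ``orientation`` may be
    ``"samples_by_genes"`` or ``"genes_by_samples"``.
    """
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    if orientation == "genes_by_samples":
        expr = expr.T
    elif orientation != "samples_by_genes":
        raise ValueError(f"unknown orientation {orientation!r}")
    clin = pd.read_csv(clin_path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in clin.columns:
        raise ValueError("clinical file must have a 'sample_id' column")
    if clin["sample_id"].duplicated().any() or expr.index.duplicated().any():
        raise ValueError("duplicated sample ids in input")
    clin = clin.set_index("sample_id")

    common = expr.index.intersection(clin.index)
    n_expr_only = len(expr.index.difference(clin.index))
    n_clin_only = len(clin.index.difference(expr.index))
    if n_expr_only or n_clin_only:
        logger.info(
            "dropped %d expression-only and %d clinical-only sample id(s)",
            n_expr_only,
            n_clin_only,
        )
    if len(common) == 0:
        raise ValueError("no sample ids shared between expression and clinical files")
    clin = clin.loc[common]
    labeled = clin["subtype"].notna()
    if (~labeled).any():
        logger.info("dropped %d sample(s) without a subtype label", int((~labeled).sum()))
    keep = clin.index[labeled]
    return ExpressionCohort(expression=expr.loc[keep], meta=clin.loc[keep])


@dataclasses.dataclass
class Batch:
    """One training batch: sample ids plus its composition tag."""

    sample_ids: tuple[str, ...]
    composition: str
    subtype_counts: dict = dataclasses.field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sample_ids)


@dataclasses.dataclass
class BatchPlan:
    """The full set of batches for a cohort plus bookkeeping."""

    batches: list[Batch]
    base_size: int
    excluded: dict = dataclasses.field(default_factory=dict)

    def by_composition(self, composition: str) -> list[Batch]:
        return [b for b in self.batches if b.composition == composition]

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for b in self.batches:
            out[b.composition] = out.get(b.composition, 0) + 1
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "base_size": self.base_size,
            "excluded": self.excluded,
            "batches": [
                {
                    "composition": b.composition,
                    "size": len(b),
                    "subtype_counts": {str(k): v for k, v in b.subtype_counts.items()},
                    "sample_ids": list(b.sample_ids),
                }
                for b in self.batches
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _is_viable(group: pd.DataFrame) -> bool:
    counts = group["subtype"].value_counts()
    return (
        len(group) >= MIN_BATCH_SIZE
        and len(counts) == 2
        and int(counts.min()) >= MIN_PER_SUBTYPE
    )


def make_batches(
    meta: pd.DataFrame,
    base_size: int | None = None,
    seed: int = 0,
    admix_label: str = ADMIX_LABEL,
) -> BatchPlan:
    """Partition each ancestry group into equal-sized training batches.

    ``meta`` must carry ``subtype`` and ``ancestry`` columns (index =
    sample id).  Admixed samples are pooled into a single group under
    ``admix_label``.  ``base_size`` defaults to the size of the smallest
    viable ancestry group.  For each viable group the batch count is
    ``floor(n / base_size)`` (minimum 1); each subtype is split evenly
    across the group's batches by floor division and the overflow is dealt
    round-robin, one sample per batch, in a seeded shuffled order.

    Every emitted batch must satisfy the viability floor (>= 9 samples,
    >= 4 per subtype); a violation raises :class:`BatchingError` rather
    than silently re-planning.  Non-viable ancestry groups are excluded
    and recorded in the plan.
    """
    if "subtype" not in meta.columns or "ancestry" not in meta.columns:
        raise ValueError("metadata needs 'subtype' and 'ancestry' columns")
    rng = np.random.default_rng(seed)

    key = meta["ancestry"].where(meta["ancestry"] != admix_label, ADMIX_LABEL)
    groups: dict[str, pd.DataFrame] = {}
    excluded: dict[str, str] = {}
    for name, sub in meta.groupby(key.fillna("__missing__"), sort=True):
        if name == "__missing__":
            excluded["<missing ancestry>"] = f"{len(sub)} samples without ancestry label"
            continue
        groups[str(name)] = sub

    viable = {name: g for name, g in groups.items() if _is_viable(g)}
    for name, g in groups.items():
        if name not in viable:
            excluded[name] = (
                f"not viable: {len(g)} samples, subtype counts "
                f"{g['subtype'].value_counts().to_dict()}"
            )
    if not viable:
        raise BatchingError("no ancestry group satisfies the viability floor")

    if base_size is None:
        base_size = min(len(g) for g in viable.values())
    if base_size < MIN_BATCH_SIZE:
        raise BatchingError(f"base batch size {base_size} below floor {MIN_BATCH_SIZE}")

    batches: list[Batch] = []
    for name in sorted(viable):
        group = viable[name]
        n_batches = max(1, len(group) // base_size)
        per_batch: list[list[str]] = [[] for _ in range(n_batches)]
        overflow: list[str] = []
        for subtype in sorted(group["subtype"].unique(), key=str):
            ids = list(group.index[group["subtype"] == subtype])
            rng.shuffle(ids)
            q = len(ids) // n_batches
            for b in range(n_batches):
                per_batch[b].extend(ids[b * q : (b + 1) * q])
            overflow.extend(ids[n_batches * q :])
        rng.shuffle(overflow)
        for i, sid in enumerate(overflow):
            per_batch[i % n_batches].append(sid)
        for ids in per_batch:
            sub = group.loc[ids]
            counts = sub["subtype"].value_counts()
            if len(sub) < MIN_BATCH_SIZE or int(counts.min()) < MIN_PER_SUBTYPE:
                raise BatchingError(
                    f"batch for ancestry {name!r} violates the viability floor: "
                    f"{len(sub)} samples, subtype counts {counts.to_dict()}"
                )
            batches.append(
                Batch(
                    sample_ids=tuple(ids),
                    composition=name,
                    subtype_counts={k: int(v) for k, v in counts.items()},
                )
            )
    return BatchPlan(batches=batches, base_size=int(base_size), excluded=excluded)


def largest_remainder_counts(total: int, proportions: Mapping[str, float]) -> dict[str, int]:
    """Apportion ``total`` across keys by largest-remainder rounding."""
    if abs(sum(proportions.values()) - 1.0) > 1e-6:
        raise ValueError("proportions must sum to 1")
    floors = {k: int(math.floor(total * p)) for k, p in proportions.items()}
    short = total - sum(floors.values())
    remainders = sorted(
        proportions,
        key=lambda k: (total * proportions[k] - floors[k], proportions[k], k),
        reverse=True,
    )
    for k in remainders[:short]:
        floors[k] += 1
    return floors


def make_mixed_batches(
    meta: pd.DataFrame,
    n_batches: int,
    proportions: Mapping[str, float],
    base_size: int,
    seed: int = 0,
) -> list[Batch]:
    """Draw Mixed-composition batches matching cohort ancestry proportions.

    Each batch holds ``base_size`` samples drawn without replacement
    (within the batch) from the full pool, with per-ancestry counts given
    by largest-remainder rounding of ``base_size * proportion``.  Batches
    are drawn independently, so a sample may recur across batches (the
    overlap is the caller's to track).
    """
    counts = largest_remainder_counts(base_size, proportions)
    pools = {
        anc: list(meta.index[meta["ancestry"] == anc]) for anc in proportions
    }
    for anc, c in counts.items():
        if c > len(pools[anc]):
            raise ValueError(
                f"requested {c} samples from ancestry {anc!r} but only "
                f"{len(pools[anc])} available"
            )
    rng = np.random.default_rng(seed)
    batches = []
    for _ in range(n_batches):
        ids: list[str] = []
        for anc in sorted(counts):
            ids.extend(rng.choice(pools[anc], size=counts[anc], replace=False))
        sub = meta.loc[ids]
        batches.append(
            Batch(
                sample_ids=tuple(ids),
                composition="Mixed",
                subtype_counts={
                    k: int(v) for k, v in sub["subtype"].value_counts().items()
                },
            )
        )
    return batches
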