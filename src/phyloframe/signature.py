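"""Penalized disease signatures with forced inclusion of ancestry genes.

The pipeline fits a LASSO logistic baseline on the training expression,
projects the nonzero genes into a functional-interaction network to
collect their first/second neighbors, keeps the neighbors that are
ancestry-enriched (gene-level enhanced allele frequency inside the
configured window) and expression-variable in the training data, and then
refits a ridge logistic model on the union of the baseline and these
"equitable" genes.  Because ridge never zeroes a coefficient, restricting
the design to that union forces every equitable gene into the returned
signature.  A size-matched LASSO-only benchmark provides the comparison.
"""

from __future__ import annotations

import contextlib
import dataclasses
import hashlib
import json
import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from .network import FunctionalNetwork, NeighborhoodParams, expand_neighborhood
from .popgen import GeneEAFProfile

__all__ = [
    "PenalizedModel",
    "Signature",
    "PhyloFrameConfig",
    "standardize_expression",
    "fit_lasso_baseline",
    "select_equitable_genes",
    "fit_equitable_model",
    "fit_benchmark",
    "predict_scores",
    "run_phyloframe",
]

logger = logging.getLogger(__name__)

_LASSO_CS = np.logspace(-2, 1.5, 16)
_RIDGE_CS = np.logspace(-3, 2, 16)


@contextlib.contextmanager
def _sklearn_quiet():
    # scikit-learn 1.9 deprecation chatter about the penalty=/l1_ratios
    # transition in LogisticRegressionCV; the legacy spelling is used on
    # purpose for solver compatibility
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        yield


@dataclasses.dataclass
class PenalizedModel:
    """A fitted penalized logistic model, self-contained for prediction.

    The per-gene standardization statistics learned on the training data
    travel with the model so that scoring new samples needs nothing else.
    """

    genes: list[str]
    coefficients: np.ndarray
    intercept: float
    penalty: str  # "lasso" | "ridge" | "elastic-net"
    C: float
    seed: int
    cv_folds: int
    mean: np.ndarray
    sd: np.ndarray
    zero_variance_genes: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float).ravel()
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.sd = np.asarray(self.sd, dtype=float).ravel()
        if len(self.coefficients) != len(self.genes):
            raise ValueError("one coefficient per gene required")

    def nonzero_genes(self) -> list[str]:
        return [g for g, c in zip(self.genes, self.coefficients) if c != 0.0]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "genes": self.genes,
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "penalty": self.penalty,
            "C": self.C,
            "seed": self.seed,
            "cv_folds": self.cv_folds,
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "zero_variance_genes": self.zero_variance_genes,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PenalizedModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            genes=payload["genes"],
            coefficients=np.asarray(payload["coefficients"]),
            intercept=payload["intercept"],
            penalty=payload["penalty"],
            C=payload["C"],
            seed=payload["seed"],
            cv_folds=payload["cv_folds"],
            mean=np.asarray(payload["mean"]),
            sd=np.asarray(payload["sd"]),
            zero_variance_genes=payload.get("zero_variance_genes", []),
        )


@dataclasses.dataclass
class Signature:
    """Gene-to-weight map with per-gene provenance.

    Provenance is ``baseline`` (nonzero in the initial LASSO),
    ``equitable`` (forced in through the ancestry-enrichment route) or
    ``network`` (carried from the neighborhood without enrichment
    filtering; only emitted in degraded configurations).
    """

    table: pd.DataFrame  # columns: gene, weight, provenance [+ extras]

    def __post_init__(self) -> None:
        if self.table["gene"].duplicated().any():
            raise ValueError("signature genes must be unique")

    @property
    def size(self) -> int:
        return len(self.table)

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])

    @property
    def gene_set(self) -> set[str]:
        return set(self.table["gene"])

    def provenance_counts(self) -> dict[str, int]:
        return self.table["provenance"].value_counts().to_dict()

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Signature":
        return cls(table=pd.read_csv(path, sep="\t"))


@dataclasses.dataclass(frozen=True)
class PhyloFrameConfig:
    """End-to-end pipeline parameters (all randomness flows from ``seed``)."""

    eaf_lo: float = 0.001
    eaf_hi: float = 1.0
    order: int = 2
    wmin: float = 0.2
    wmax: float = 0.5
    k_per_ancestry: int = 10
    cv_folds: int | None = None
    seed: int = 0

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def standardize_expression(
    X: pd.DataFrame,
    stats: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene z-score using training-derived statistics.

    When ``stats`` (a frame with ``mean`` and ``sd`` indexed by gene) is
    supplied — e.g. to transform a test matrix with training statistics —
    it is applied as-is, so no information leaks from the new samples.
    Zero-variance genes map to all-zero columns and are flagged in the
    returned statistics (``zero_variance`` column).
    """
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"NaN values in expression for genes: {bad}")
    if stats is None:
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        stats = pd.DataFrame(
            {"mean": mean, "sd": sd, "zero_variance": sd == 0.0}
        )
    else:
        if not set(X.columns) <= set(stats.index):
            missing = sorted(set(X.columns) - set(stats.index))
            raise ValueError(f"no standardization statistics for genes: {missing}")
        stats = stats.loc[X.columns]
    safe_sd = stats["sd"].replace(0.0, 1.0)
    Xz = (X - stats["mean"]) / safe_sd
    Xz.loc[:, stats.index[stats["sd"] == 0.0]] = 0.0
    return Xz, stats


def _check_training_inputs(X: pd.DataFrame, y: np.ndarray) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    if len(classes) > 2:
        raise ValueError(f"expected binary labels, got {len(classes)} classes")
    if len(X) < 9 or counts.min() < 4:
        raise ValueError(
            "training set below the viability floor "
            f"(n={len(X)}, per-class counts={counts.tolist()}; need >=9 and >=4 per class)"
        )
    if X.shape[1] < 2:
        raise ValueError("need at least 2 genes")


def _cv_splitter(y: np.ndarray, cv: int | None, seed: int) -> StratifiedKFold:
    minority = int(np.unique(y, return_counts=True)[1].min())
    folds = cv if cv is not None else min(5, minority)
    return StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)


def fit_lasso_baseline(
    X: pd.DataFrame,
    y: Sequence,
    cv: int | None = None,
    seed: int = 0,
) -> PenalizedModel:
    """L1-penalized logistic fit with CV-chosen regularization strength.

    The penalty is selected by stratified cross-validated deviance
    (log-loss) over a fixed strength grid with ``min(5, minority count)``
    folds.  The baseline gene set is the genes with nonzero coefficient.
    Deterministic for fixed (data, seed).
    """
    y = np.asarray(y)
    _check_training_inputs(X, y)
    Xz, stats = standardize_expression(X)
    splitter = _cv_splitter(y, cv, seed)
    with _sklearn_quiet():
        clf = LogisticRegressionCV(
            Cs=_LASSO_CS,
            penalty="l1",
            solver="liblinear",
            scoring="neg_log_loss",
            cv=splitter,
            max_iter=500,
            random_state=seed,
        )
        clf.fit(Xz.to_numpy(), y)
    return PenalizedModel(
        genes=list(X.columns),
        coefficients=clf.coef_.ravel(),
        intercept=float(clf.intercept_[0]),
        penalty="lasso",
        C=float(clf.C_[0]),
        seed=seed,
        cv_folds=splitter.get_n_splits(),
        mean=stats["mean"].to_numpy(),
        sd=stats["sd"].to_numpy(),
        zero_variance_genes=list(stats.index[stats["zero_variance"]]),
    )


def _relax_l1_until(
    Xz: np.ndarray,
    y: np.ndarray,
    start_C: float,
    target_active: int,
    seed: int,
) -> tuple[np.ndarray, float, float]:
    """Walk the L1 path toward weaker penalty until enough genes activate.

    Returns (coefficients, intercept, C) at the first strength with at
    least ``target_active`` nonzero coefficients, or at the weakest grid
    point if the target is never reached.
    """
    coef = intercept = None
    for C in np.logspace(np.log10(start_C), 4, 25):
        clf = LogisticRegression(
            C=float(C),
            l1_ratio=1.0,
            solver="liblinear",
            max_iter=500,
            random_state=seed,
        )
        clf.fit(Xz, y)
        coef, intercept = clf.coef_.ravel(), float(clf.intercept_[0])
        if np.count_nonzero(coef) >= target_active:
            return coef, intercept, float(C)
    return coef, intercept, 1e4


def fit_benchmark(
    X: pd.DataFrame,
    y: Sequence,
    target_size: int,
    cv: int | None = None,
    seed: int = 0,
) -> tuple[PenalizedModel, Signature]:
    """Size-matched LASSO-only comparison model.

    Fits the same LASSO implementation as the baseline and returns the
    ``target_size`` genes with the largest absolute coefficients at the
    cross-validated strength (ties broken lexicographically by symbol).
    If fewer genes are active there, the penalty is relaxed along the path
    until ``target_size`` genes activate.  The returned model keeps the
    fitted coefficients of exactly those genes, so the benchmark signature
    size equals ``target_size``.
    """
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    if target_size > X.shape[1]:
        raise ValueError(
            f"target_size {target_size} exceeds gene count {X.shape[1]}"
        )
    base = fit_lasso_baseline(X, y, cv=cv, seed=seed)
    coef, intercept, C = base.coefficients, base.intercept, base.C
    if np.count_nonzero(coef) < target_size:
        Xz, _ = standardize_expression(X)
        coef, intercept, C = _relax_l1_until(
            Xz.to_numpy(), np.asarray(y), base.C, target_size, seed
        )
        if np.count_nonzero(coef) < target_size:
            raise RuntimeError(
                f"could not activate {target_size} genes on the LASSO path "
                f"(max {np.count_nonzero(coef)})"
            )
    order = sorted(
        range(len(base.genes)),
        key=lambda j: (-abs(coef[j]), base.genes[j]),
    )[:target_size]
    order = sorted(order, key=lambda j: (-abs(coef[j]), base.genes[j]))
    genes = [base.genes[j] for j in order]
    model = PenalizedModel(
        genes=genes,
        coefficients=coef[order],
        intercept=intercept,
        penalty="lasso",
        C=float(C),
        seed=seed,
        cv_folds=base.cv_folds,
        mean=base.mean[order],
        sd=base.sd[order],
    )
    sig = Signature(
        table=pd.DataFrame(
            {
                "gene": genes,
                "weight": coef[order],
                "provenance": "baseline",
            }
        )
    )
    return model, sig


def select_equitable_genes(
    candidates: Iterable[str],
    profile: GeneEAFProfile,
    X_train: pd.DataFrame,
    k_per_ancestry: int = 10,
    lo: float = 0.001,
    hi: float = 1.0,
) -> list[str]:
    """Pick ancestry-enriched, expression-variable genes per ancestry.

    For each ancestry in the gene-level enrichment profile, candidate
    genes are ranked by their gene-level EAF, those inside ``[lo, hi]``
    are kept, and the survivors are re-ordered by training-data expression
    variance (computed on the raw, pre-z-score values — post-z-score
    variance is uniformly 1) to take the top ``k_per_ancestry``.  The
    union over ancestries is returned, deduplicated and sorted.
    """
    if k_per_ancestry < 1:
        raise ValueError("k_per_ancestry must be >= 1")
    candidates = set(candidates) & set(X_train.columns)
    in_profile = candidates & profile.genes
    if not in_profile:
        logger.warning(
            "no candidate gene has an enrichment profile entry; "
            "pipeline degrades to the baseline signature"
        )
        return []
    variance = X_train[sorted(in_profile)].var(axis=0, ddof=0)
    selected: set[str] = set()
    for ancestry in sorted(set(profile.data["ancestry"])):
        ranked = profile.genes_for(ancestry)
        ranked = ranked[ranked["gene"].isin(in_profile)]
        ranked = ranked[(ranked["score"] >= lo) & (ranked["score"] <= hi)]
        if ranked.empty:
            continue
        by_var = sorted(
            ranked["gene"],
            key=lambda g: (-variance[g], g),
        )[:k_per_ancestry]
        selected.update(by_var)
    return sorted(selected)


def fit_equitable_model(
    X: pd.DataFrame,
    y: Sequence,
    baseline_genes: Sequence[str],
    equitable_genes: Sequence[str],
    cv: int | None = None,
    seed: int = 0,
) -> tuple[PenalizedModel, Signature]:
    """Ridge refit on baseline plus forced equitable genes.

    Forced inclusion is implemented by restricting the design matrix to
    the union of the two gene sets: ridge shrinks but never zeroes, so
    every union gene carries a (generically nonzero) weight in the final
    signature.  Genes in both sets keep provenance ``baseline``.
    """
    baseline_genes = list(baseline_genes)
    equitable_only = [g for g in equitable_genes if g not in set(baseline_genes)]
    union = baseline_genes + sorted(equitable_only)
    if not union:
        raise ValueError("baseline and equitable gene sets are both empty")
    missing = [g for g in union if g not in X.columns]
    if missing:
        raise ValueError(f"genes absent from expression matrix: {missing}")
    y = np.asarray(y)
    Xu = X[union]
    _check_training_inputs(Xu, y)
    Xz, stats = standardize_expression(Xu)
    splitter = _cv_splitter(y, cv, seed)
    with _sklearn_quiet():
        clf = LogisticRegressionCV(
            Cs=_RIDGE_CS,
            penalty="l2",
            solver="lbfgs",
            scoring="neg_log_loss",
            cv=splitter,
            max_iter=2000,
            random_state=seed,
        )
        clf.fit(Xz.to_numpy(), y)
    model = PenalizedModel(
        genes=union,
        coefficients=clf.coef_.ravel(),
        intercept=float(clf.intercept_[0]),
        penalty="ridge",
        C=float(clf.C_[0]),
        seed=seed,
        cv_folds=splitter.get_n_splits(),
        mean=stats["mean"].to_numpy(),
        sd=stats["sd"].to_numpy(),
        zero_variance_genes=list(stats.index[stats["zero_variance"]]),
    )
    provenance = [
        "baseline" if g in set(baseline_genes) else "equitable" for g in union
    ]
    sig = Signature(
        table=pd.DataFrame(
            {"gene": union, "weight": model.coefficients, "provenance": provenance}
        )
    )
    return model, sig


def predict_scores(model: PenalizedModel, X_new: pd.DataFrame) -> pd.Series:
    """Per-sample probability of the positive class in (0, 1).

    Applies the model's stored standardization statistics, so prediction
    is deterministic and independent of the composition of ``X_new``.
    """
    missing = [g for g in model.genes if g not in X_new.columns]
    if missing:
        raise ValueError(f"genes missing from new data: {missing}")
    X = X_new[model.genes].to_numpy(dtype=float)
    sd = np.where(model.sd == 0.0, 1.0, model.sd)
    Xz = (X - model.mean) / sd
    Xz[:, model.sd == 0.0] = 0.0
    scores = expit(Xz @ model.coefficients + model.intercept)
    return pd.Series(scores, index=X_new.index, name="score")


def run_phyloframe(
    expression: pd.DataFrame,
    labels: Sequence,
    net: FunctionalNetwork,
    profile: GeneEAFProfile,
    config: PhyloFrameConfig | None = None,
) -> tuple[Signature, PenalizedModel, dict]:
    """The full ancestry-aware signature pipeline on one training set.

    Stages: LASSO baseline -> neighborhood expansion of the nonzero genes
    -> enrichment/variance selection of equitable genes -> ridge refit on
    the union.  The run report records every intermediate gene-set size,
    all parameters and the config hash, so a run is fully reproducible
    from (config, seed).
    """
    cfg = config or PhyloFrameConfig()
    y = np.asarray(labels)
    base = fit_lasso_baseline(expression, y, cv=cfg.cv_folds, seed=cfg.seed)
    baseline_genes = base.nonzero_genes()
    if not baseline_genes:
        # CV picked the null model; relax the penalty until one gene activates
        Xz, _ = standardize_expression(expression)
        coef, _, _ = _relax_l1_until(Xz.to_numpy(), y, base.C, 1, cfg.seed)
        baseline_genes = [g for g, c in zip(expression.columns, coef) if c != 0.0]
        logger.warning(
            "baseline LASSO selected no genes at the CV strength; "
            "relaxed to %d gene(s)", len(baseline_genes)
        )

    params = NeighborhoodParams(order=cfg.order, wmin=cfg.wmin, wmax=cfg.wmax)
    expanded = expand_neighborhood(net, baseline_genes, params)
    candidates = expanded - set(baseline_genes)
    equitable = select_equitable_genes(
        candidates,
        profile,
        expression,
        k_per_ancestry=cfg.k_per_ancestry,
        lo=cfg.eaf_lo,
        hi=cfg.eaf_hi,
    )
    model, sig = fit_equitable_model(
        expression, y, baseline_genes, equitable, cv=cfg.cv_folds, seed=cfg.seed
    )

    # annotate the signature with enrichment and variance context
    eaf_max = [profile.max_score(g) for g in sig.genes]
    train_var = expression[sig.genes].var(axis=0, ddof=0)
    sig.table["gene_eaf_max"] = [
        np.nan if v is None else v for v in eaf_max
    ]
    sig.table["train_variance"] = train_var.to_numpy()

    report = {
        "config": dataclasses.asdict(cfg),
        "config_hash": cfg.hash(),
        "n_samples": int(len(expression)),
        "n_genes": int(expression.shape[1]),
        "n_baseline_genes": len(baseline_genes),
        "n_expanded": len(expanded),
        "n_candidates": len(candidates),
        "n_equitable": len(equitable),
        "signature_size": sig.size,
        "degraded": len(equitable) == 0,
        "lasso_C": base.C,
        "ridge_C": model.C,
    }
    if report["degraded"]:
        logger.warning("no equitable genes selected; signature is the ridge-refit baseline")
    return sig, model, report
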