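"""Synthetic multi-population fixtures with planted ground truth.

Generates the three inputs the pipeline consumes — a gnomAD-style
multi-population variant table, a HumanBase-style weighted gene network,
and a multi-ancestry expression cohort — plus a COSMIC-style gene list,
all from a single :class:`SimulationSpec` and seed.

The default spec is the *confounded* scenario used throughout the test
suite: a handful of planted disease genes drive the subtype, and one of
them (the confounded gene) is a weak subtype marker in the majority
training ancestry but a strong marker in the minority ancestry.  That
gene is ancestry-enriched in the variant data and wired into the disease
module of the network, so the ancestry-aware pipeline can recover it
from population data even though a penalized fit on majority-ancestry
expression alone tends to drop it.

Expression model: for a sample of ancestry ``a`` with subtype ``y``,

    x_g = baseline_a[g] + y * effect_a[g] + Normal(0, noise_sd)

Admixed samples interpolate the two reference ancestries' baselines and
effects by their admixture fraction.  For a single gene with effect d and
unit noise this yields the closed-form AUC Phi(d / sqrt(2)).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import ExpressionCohort
from .network import FunctionalNetwork
from .popgen import DEFAULT_PANEL, AncestryPanel, VariantTable

import networkx as nx

__all__ = [
    "SimulationSpec",
    "gen_variant_table",
    "gen_network",
    "gen_expression_cohort",
    "gen_gene_list",
    "confounded_trial",
]


def _default_effects() -> dict[str, dict[str, float]]:
    # G0005 is the confounded gene: weak in EUR (majority / training),
    # strong in AFR (minority / held-out).
    return {
        "EUR": {"G0001": 1.6, "G0002": 1.3, "G0003": 1.1, "G0004": 0.9, "G0005": 0.4},
        "AFR": {"G0001": 1.6, "G0002": 1.3, "G0003": 1.1, "G0004": 0.9, "G0005": 2.0},
    }


def _default_enrichment() -> dict[str, tuple[str, float]]:
    # gene -> (panel ancestry, target gene-level EAF); G0005 is the
    # confounded disease gene, the others are non-disease decoys.
    return {"G0005": ("afr", 0.35), "G0010": ("eas", 0.30), "G0020": ("sas", 0.25)}


@dataclasses.dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic study; the defaults are the confounded
    scenario (majority-ancestry training, minority-ancestry testing)."""

    seed: int = 0
    n_genes: int = 150
    n_variants: int = 450
    panel: AncestryPanel = dataclasses.field(default_factory=lambda: DEFAULT_PANEL)
    an_per_ancestry: int = 100_000
    af_beta: tuple[float, float] = (0.5, 10.0)
    disease_effects: Mapping[str, Mapping[str, float]] = dataclasses.field(
        default_factory=_default_effects
    )
    enriched_genes: Mapping[str, tuple[str, float]] = dataclasses.field(
        default_factory=_default_enrichment
    )
    sample_counts: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: {"EUR": 120, "AFR": 40}
    )
    n_admixed: int = 0
    admix_pair: tuple[str, str] = ("EUR", "AFR")
    subtype_p: float = 0.45
    noise_sd: float = 1.0
    ancestry_shift_sd: float = 0.3
    edge_prob: float = 0.04
    weight_beta: tuple[float, float] = (1.5, 5.0)
    module_weight_window: tuple[float, float] = (0.25, 0.45)

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_variants < 1:
            raise ValueError("counts must be positive")
        for g in self.enriched_genes:
            if g not in self.gene_names():
                raise ValueError(f"enriched gene {g} outside the gene universe")
        for eff in self.disease_effects.values():
            for g in eff:
                if g not in self.gene_names():
                    raise ValueError(f"disease gene {g} outside the gene universe")

    def gene_names(self) -> list[str]:
        return [f"G{i + 1:04d}" for i in range(self.n_genes)]

    @property
    def disease_genes(self) -> list[str]:
        genes: set[str] = set()
        for eff in self.disease_effects.values():
            genes.update(g for g, e in eff.items() if e != 0.0)
        return sorted(genes)

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def gen_variant_table(spec: SimulationSpec) -> VariantTable:
    """Draw a gnomAD-style variant table with planted enrichment.

    Each variant's baseline allele frequency is drawn once from a Beta
    distribution and shared across ancestries; per-ancestry allele counts
    are binomial draws at the configured allele number, and AF = AC/AN
    exactly.  For each enriched gene, its first variant's target AF in the
    designated ancestry is shifted additively by the target gene-level
    EAF, so pushing the table through the EAF pipeline recovers the
    target within sampling error.
    """
    rng = spec.rng(1)
    genes = spec.gene_names()
    n = spec.n_variants
    gene_of = [genes[i % spec.n_genes] for i in range(n)]
    base_af = rng.beta(*spec.af_beta, size=n)

    # index of each enriched gene's designated variant (first occurrence)
    planted: dict[int, tuple[str, float]] = {}
    for g, (ancestry, tau) in spec.enriched_genes.items():
        if ancestry not in spec.panel.labels:
            raise ValueError(f"unknown panel ancestry {ancestry!r}")
        idx = genes.index(g)
        if base_af[idx] + tau > 1.0:
            raise ValueError(
                f"target EAF {tau} for gene {g} infeasible: baseline AF "
                f"{base_af[idx]:.3f} would exceed 1"
            )
        planted[idx] = (ancestry, tau)

    an = spec.an_per_ancestry
    rows: dict[str, object] = {
        "chrom": ["1"] * n,
        "pos": [1000 + 10 * i for i in range(n)],
        "rsid": [f"rs{i + 1}" for i in range(n)],
        "ref": ["A"] * n,
        "alt": ["C"] * n,
        "gene": gene_of,
        "consequence": ["missense_variant"] * n,
        "impact": ["MODERATE"] * n,
        "distance": [0] * n,
    }
    for a in spec.panel:
        target = base_af.copy()
        for idx, (anc, tau) in planted.items():
            if anc == a:
                target[idx] = base_af[idx] + tau
        ac = rng.binomial(an, target)
        rows[f"ac_{a}"] = ac
        rows[f"an_{a}"] = np.full(n, an)
        rows[f"af_{a}"] = ac / an
    return VariantTable(data=pd.DataFrame(rows), panel=spec.panel)


def gen_network(spec: SimulationSpec) -> FunctionalNetwork:
    """Random background graph plus a planted disease module.

    Background edges appear independently with ``edge_prob`` and carry
    Beta-distributed weights.  The planted module chains the disease
    genes together and attaches each ancestry-enriched gene to the two
    strongest disease genes, all with weights inside the module window —
    so neighborhood expansion with the default [0.2, 0.5] window reaches
    the enriched genes from a disease-gene seed.
    """
    rng = spec.rng(2)
    genes = spec.gene_names()
    g = nx.Graph()
    g.add_nodes_from(genes)
    n = len(genes)
    # vectorized upper-triangle edge draw
    iu, ju = np.triu_indices(n, k=1)
    present = rng.random(len(iu)) < spec.edge_prob
    weights = rng.beta(*spec.weight_beta, size=len(iu))
    for i, j, w in zip(iu[present], ju[present], weights[present]):
        g.add_edge(genes[i], genes[j], weight=float(w))

    lo, hi = spec.module_weight_window
    primary = spec.disease_genes
    # rank disease genes by their strongest effect anywhere
    strength = {
        d: max(abs(eff.get(d, 0.0)) for eff in spec.disease_effects.values())
        for d in primary
    }
    ranked = sorted(primary, key=lambda d: (-strength[d], d))
    for a, b in zip(ranked, ranked[1:]):
        g.add_edge(a, b, weight=float(rng.uniform(lo, hi)))
    anchors = ranked[:2] if len(ranked) >= 2 else ranked
    for e in sorted(spec.enriched_genes):
        for anchor in anchors:
            if e != anchor:
                g.add_edge(e, anchor, weight=float(rng.uniform(lo, hi)))
    return FunctionalNetwork(graph=g, tissue="synthetic")


def _ancestry_baselines(spec: SimulationSpec) -> dict[str, np.ndarray]:
    rng = spec.rng(3)
    out = {}
    for a in sorted(set(spec.sample_counts) | set(spec.admix_pair)):
        out[a] = rng.normal(0.0, spec.ancestry_shift_sd, size=spec.n_genes)
    return out


def _effect_vector(spec: SimulationSpec, ancestry: str) -> np.ndarray:
    genes = spec.gene_names()
    eff = spec.disease_effects.get(ancestry, {})
    return np.array([eff.get(g, 0.0) for g in genes])


def gen_expression_cohort(spec: SimulationSpec) -> ExpressionCohort:
    """Draw a multi-ancestry expression cohort with planted subtype effects.

    Subtype labels are Bernoulli(``subtype_p``); expression follows the
    conditional-shift model in the module docstring.  Admixed samples
    (``n_admixed`` of them, ancestry label ``ADMIX``) interpolate the two
    reference ancestries of ``admix_pair`` at an evenly spaced grid of
    admixture fractions.
    """
    rng = spec.rng(4)
    genes = spec.gene_names()
    baselines = _ancestry_baselines(spec)
    rows, meta_rows = [], []

    def add_samples(tag: str, count: int, baseline: np.ndarray,
                    effect: np.ndarray, ancestry: str, frac: float | None):
        for k in range(count):
            y = int(rng.random() < spec.subtype_p)
            x = baseline + y * effect + rng.normal(0.0, spec.noise_sd, size=spec.n_genes)
            rows.append(x)
            meta_rows.append(
                {
                    "sample_id": f"{tag}_{len(meta_rows) + 1:04d}",
                    "subtype": y,
                    "ancestry": ancestry,
                    "admixture_fraction": frac,
                }
            )

    for a in sorted(spec.sample_counts):
        add_samples(
            a, spec.sample_counts[a], baselines[a], _effect_vector(spec, a), a, None
        )
    if spec.n_admixed > 0:
        a1, a2 = spec.admix_pair
        fracs = np.linspace(0.0, 1.0, spec.n_admixed)
        e1, e2 = _effect_vector(spec, a1), _effect_vector(spec, a2)
        for f in fracs:
            baseline = f * baselines[a1] + (1 - f) * baselines[a2]
            effect = f * e1 + (1 - f) * e2
            add_samples("ADMIX", 1, baseline, effect, "ADMIX", float(f))

    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    expr = pd.DataFrame(np.vstack(rows), index=meta.index, columns=genes)
    return ExpressionCohort(expression=expr, meta=meta)


def gen_gene_list(spec: SimulationSpec, size: int = 20) -> set[str]:
    """COSMIC-style reference list: the planted genes plus random decoys."""
    rng = spec.rng(5)
    planted = sorted(set(spec.disease_genes) | set(spec.enriched_genes))
    if size < len(planted):
        raise ValueError(f"size {size} smaller than the planted set ({len(planted)})")
    pool = [g for g in spec.gene_names() if g not in planted]
    decoys = rng.choice(pool, size=size - len(planted), replace=False)
    return set(planted) | set(decoys.tolist())


def confounded_trial(seed: int, n_batches: int | None = None) -> dict:
    """One full majority-train / minority-test comparison at one seed.

    Generates the confounded scenario, builds the gene-level enrichment
    profile from the variant table, splits the majority-ancestry (EUR)
    samples into training batches, fits the ancestry-aware pipeline and
    the size-matched benchmark on each batch, and scores both on the
    held-out minority (AFR) samples.  Returns the per-family mean minority
    AUC and mean pairwise signature Jaccard.
    """
    from . import evaluation
    from .cohort import make_batches
    from .popgen import aggregate_gene_eaf, compute_eaf, filter_eaf
    from .signature import PhyloFrameConfig, fit_benchmark, predict_scores, run_phyloframe

    spec = SimulationSpec(seed=seed)
    table = gen_variant_table(spec)
    profile = aggregate_gene_eaf(filter_eaf(compute_eaf(table)))
    net = gen_network(spec)
    cohort = gen_expression_cohort(spec)

    train_meta = cohort.meta[cohort.meta["ancestry"] == "EUR"]
    test_ids = cohort.meta.index[cohort.meta["ancestry"] == "AFR"]
    base_size = int(cohort.meta["ancestry"].value_counts().min())
    plan = make_batches(train_meta, base_size=base_size, seed=seed)
    batches = plan.batches if n_batches is None else plan.batches[:n_batches]

    X_test = cohort.expression.loc[test_ids]
    y_test = cohort.meta.loc[test_ids, "subtype"].to_numpy()

    pf_sigs, bench_sigs, pf_aucs, bench_aucs = [], [], [], []
    cfg = PhyloFrameConfig(seed=seed)
    for batch in batches:
        sub = cohort.subset(batch.sample_ids)
        y_train = sub.labels().to_numpy()
        sig, model, _ = run_phyloframe(sub.expression, y_train, net, profile, cfg)
        bench_model, bench_sig = fit_benchmark(
            sub.expression, y_train, target_size=sig.size, seed=seed
        )
        pf_sigs.append(sig)
        bench_sigs.append(bench_sig)
        pf_aucs.append(evaluation.auc(predict_scores(model, X_test), y_test))
        bench_aucs.append(evaluation.auc(predict_scores(bench_model, X_test), y_test))

    _, pf_jac = evaluation.overlap_matrix(pf_sigs)
    _, bench_jac = evaluation.overlap_matrix(bench_sigs)
    return {
        "auc_phyloframe": float(np.mean(pf_aucs)),
        "auc_benchmark": float(np.mean(bench_aucs)),
        "jaccard_phyloframe": pf_jac,
        "jaccard_benchmark": bench_jac,
        "signatures_phyloframe": pf_sigs,
        "signatures_benchmark": bench_sigs,
        "n_batches": len(batches),
    }
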