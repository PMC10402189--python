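"""Multi-population variant data and the enhanced allele frequency statistic.

Enhanced allele frequency (EAF) quantifies how much more common a variant is
in one ancestry than in the rest of the human populations sampled by a
reference panel.  For a variant with per-ancestry allele frequencies
``AF_1 .. AF_K`` the EAF of ancestry ``a`` is

    EAF_a = AF_a - mean(AF_b for b != a)

so positive values mark population-specific enrichment and, by construction,
the K values of one variant sum to zero.  Gene-level enrichment profiles are
obtained by filtering variant EAFs to a positive window (default 0.001-1)
and aggregating the surviving variants of each gene per ancestry.

The module reads gnomAD-v2.1.1-style VCFs: biallelic SNP records carrying
per-ancestry allele count / allele number / allele frequency INFO triples
plus a gene annotation.  Multiallelic rows are split per ALT allele; records
missing any configured ancestry (or with a zero allele number) are dropped
and tallied in a skip log, which keeps the zero-sum identity of the
statistic exact.
"""

from __future__ import annotations

import collections
import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "GNOMAD_V2_ANCESTRIES",
    "AncestryPanel",
    "VariantTable",
    "EAFTable",
    "GeneEAFProfile",
    "parse_population_vcf",
    "write_annotated_vcf",
    "compute_eaf",
    "filter_eaf",
    "aggregate_gene_eaf",
]

#: The 17 gnomAD v2.1.1 exome ancestries (field suffix -> display name).
#: The East Asian and European (non-Finnish) super-populations are kept
#: alongside their sub-populations, as in the source database.
GNOMAD_V2_ANCESTRIES: dict[str, str] = {
    "afr": "African/African American",
    "amr": "Latino/Admixed American",
    "asj": "Ashkenazi Jewish",
    "eas": "East Asian",
    "fin": "European (Finnish)",
    "nfe": "European (non-Finnish)",
    "sas": "South Asian",
    "oth": "Other",
    "eas_kor": "East Asian Korean",
    "eas_jpn": "East Asian Japanese",
    "eas_oea": "East Asian Other East Asian",
    "nfe_bgr": "European (non-Finnish) Bulgarian",
    "nfe_est": "European (non-Finnish) Estonian",
    "nfe_nwe": "European (non-Finnish) North-Western European",
    "nfe_seu": "European (non-Finnish) Southern European",
    "nfe_swe": "European (non-Finnish) Swedish",
    "nfe_onf": "European (non-Finnish) Other non-Finnish",
}

_VARIANT_COLUMNS = (
    "chrom",
    "pos",
    "rsid",
    "ref",
    "alt",
    "gene",
    "consequence",
    "impact",
    "distance",
)


@dataclasses.dataclass(frozen=True)
class AncestryPanel:
    """An ordered set of ancestry labels with their VCF INFO field names.

    ``key_map`` maps each label to its ``(allele count, allele number,
    allele frequency)`` INFO keys.  The default panel is the 17-ancestry
    gnomAD v2.1.1 exome panel with ``AC_<label>`` / ``AN_<label>`` /
    ``AF_<label>`` fields.
    """

    labels: tuple[str, ...]
    key_map: Mapping[str, tuple[str, str, str]]
    display_names: Mapping[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("ancestry labels must be unique")
        if len(self.labels) < 2:
            raise ValueError("an ancestry panel needs at least 2 ancestries")
        missing = [a for a in self.labels if a not in self.key_map]
        if missing:
            raise ValueError(f"key_map missing ancestries: {missing}")

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    @classmethod
    def gnomad_v2(cls) -> "AncestryPanel":
        labels = tuple(GNOMAD_V2_ANCESTRIES)
        key_map = {a: (f"AC_{a}", f"AN_{a}", f"AF_{a}") for a in labels}
        return cls(labels=labels, key_map=key_map, display_names=GNOMAD_V2_ANCESTRIES)

    @classmethod
    def from_labels(cls, labels: Sequence[str]) -> "AncestryPanel":
        labels = tuple(labels)
        key_map = {a: (f"AC_{a}", f"AN_{a}", f"AF_{a}") for a in labels}
        return cls(labels=labels, key_map=key_map)


DEFAULT_PANEL = AncestryPanel.gnomad_v2()


@dataclasses.dataclass
class VariantTable:
    """Per-variant records with per-ancestry AC/AN/AF and a gene annotation.

    ``data`` holds one row per biallelic SNP with the columns in
    ``_VARIANT_COLUMNS`` plus ``ac_<label>``, ``an_<label>`` and
    ``af_<label>`` for every panel ancestry.  ``skip_log`` counts the input
    rows dropped during parsing, keyed by reason.
    """

    data: pd.DataFrame
    panel: AncestryPanel = dataclasses.field(default_factory=lambda: DEFAULT_PANEL)
    skip_log: collections.Counter = dataclasses.field(default_factory=collections.Counter)

    def __len__(self) -> int:
        return len(self.data)

    def af_matrix(self) -> pd.DataFrame:
        """Allele frequencies as a (variant x ancestry) frame."""
        cols = {a: self.data[f"af_{a}"] for a in self.panel}
        return pd.DataFrame(cols, index=self.data.index)

    def write_skip_log(self, path: str | Path) -> None:
        rows = sorted(self.skip_log.items())
        pd.DataFrame(rows, columns=["reason", "count"]).to_csv(
            path, sep="\t", index=False
        )


@dataclasses.dataclass
class EAFTable:
    """Per-variant enhanced allele frequencies for every panel ancestry."""

    data: pd.DataFrame  # variant key columns + gene + eaf_<label>
    panel: AncestryPanel

    def __len__(self) -> int:
        return len(self.data)

    def eaf_matrix(self) -> pd.DataFrame:
        cols = {a: self.data[f"eaf_{a}"] for a in self.panel}
        return pd.DataFrame(cols, index=self.data.index)


@dataclasses.dataclass
class GeneEAFProfile:
    """Gene-level, per-ancestry enrichment scores.

    ``data`` has one row per (gene, ancestry) that survived the EAF filter,
    with the aggregated ``score`` and the number of contributing variants.
    ``rule`` records the SNP-to-gene aggregation rule used.
    """

    data: pd.DataFrame  # columns: gene, ancestry, score, n_variants
    rule: str = "max"

    def __len__(self) -> int:
        return len(self.data)

    @property
    def genes(self) -> set[str]:
        return set(self.data["gene"])

    def genes_for(self, ancestry: str) -> pd.DataFrame:
        """Rows for one ancestry, ranked by score (descending)."""
        sub = self.data[self.data["ancestry"] == ancestry]
        return sub.sort_values(["score", "gene"], ascending=[False, True])

    def score(self, gene: str, ancestry: str) -> float | None:
        sub = self.data[(self.data["gene"] == gene) & (self.data["ancestry"] == ancestry)]
        return None if sub.empty else float(sub["score"].iloc[0])

    def max_score(self, gene: str) -> float | None:
        sub = self.data[self.data["gene"] == gene]
        return None if sub.empty else float(sub["score"].max())

    def pivot(self) -> pd.DataFrame:
        return self.data.pivot(index="gene", columns="ancestry", values="score")


def _ith(value, i: int):
    """Pull the i-th per-ALT entry from a scalar-or-tuple INFO value."""
    if isinstance(value, (tuple, list)):
        return value[i] if i < len(value) else None
    return value if i == 0 else None


def parse_population_vcf(
    path: str | Path,
    panel: AncestryPanel | None = None,
    gene_key: str = "GENE",
    consequence_key: str = "CONSEQUENCE",
    impact_key: str = "IMPACT",
    distance_key: str = "DISTANCE",
) -> VariantTable:
    """Read a multi-population VCF into a :class:`VariantTable`.

    One record is emitted per biallelic SNP; multiallelic rows are split per
    ALT allele, each with its own AC/AF entries.  Rows that are not SNPs,
    are missing any panel ancestry's allele frequency, or have a zero
    allele number for any ancestry are dropped and counted in the returned
    table's ``skip_log``.

    Raises
    ------
    ValueError
        If the file cannot be read as VCF.
    KeyError
        If an INFO key named in the panel's key map is absent from the
        header (the message names the key).
    """
    panel = panel or DEFAULT_PANEL
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot read VCF at {path}: {exc}") from exc

    header_keys = set(vcf.header.info.keys())
    for a in panel:
        for key in panel.key_map[a]:
            if key not in header_keys:
                raise KeyError(
                    f"INFO key {key!r} (ancestry {a!r}) not declared in VCF header"
                )

    rows: list[dict] = []
    skip: collections.Counter = collections.Counter()
    for rec in vcf:
        alts = rec.alts or ()
        for i, alt in enumerate(alts):
            if len(rec.ref) != 1 or alt is None or len(alt) != 1 or alt == "*":
                skip["non_snp"] += 1
                continue
            row: dict = {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "rsid": rec.id or "",
                "ref": rec.ref,
                "alt": alt,
                "gene": str(rec.info.get(gene_key, "") or ""),
                "consequence": str(rec.info.get(consequence_key, "") or ""),
                "impact": str(rec.info.get(impact_key, "") or ""),
                "distance": int(rec.info.get(distance_key, 0) or 0),
            }
            ok = True
            for a in panel:
                ac_key, an_key, af_key = panel.key_map[a]
                ac = _ith(rec.info.get(ac_key), i)
                an = rec.info.get(an_key)
                if isinstance(an, (tuple, list)):
                    an = an[0] if an else None
                af = _ith(rec.info.get(af_key), i)
                if af is None or an is None:
                    skip["missing_ancestry_field"] += 1
                    ok = False
                    break
                if int(an) == 0:
                    skip["zero_allele_number"] += 1
                    ok = False
                    break
                row[f"ac_{a}"] = int(ac) if ac is not None else int(round(float(af) * int(an)))
                row[f"an_{a}"] = int(an)
                row[f"af_{a}"] = float(af)
            if ok:
                rows.append(row)
    vcf.close()

    columns = list(_VARIANT_COLUMNS) + [
        f"{p}_{a}" for a in panel for p in ("ac", "an", "af")
    ]
    data = pd.DataFrame(rows, columns=columns)
    return VariantTable(data=data, panel=panel, skip_log=skip)


def write_annotated_vcf(table: VariantTable, path: str | Path) -> None:
    """Serialize a :class:`VariantTable` back to an annotated VCF.

    Round-trip property: ``parse_population_vcf(write_annotated_vcf(T))``
    reproduces ``T`` with allele frequencies preserved to within 1e-6
    (values are stored as 32-bit floats in the VCF INFO fields).
    """
    panel = table.panel
    header = pysam.VariantHeader()
    for chrom in pd.unique(table.data["chrom"]) if len(table.data) else []:
        header.contigs.add(str(chrom))
    for a in panel:
        ac_key, an_key, af_key = panel.key_map[a]
        header.info.add(ac_key, "A", "Integer", f"Allele count, {a}")
        header.info.add(an_key, "1", "Integer", f"Allele number, {a}")
        header.info.add(af_key, "A", "Float", f"Allele frequency, {a}")
    header.info.add("GENE", "1", "String", "Gene symbol")
    header.info.add("CONSEQUENCE", "1", "String", "Variant consequence")
    header.info.add("IMPACT", "1", "String", "Variant impact")
    header.info.add("DISTANCE", "1", "Integer", "Distance to gene")

    out = pysam.VariantFile(str(path), "w", header=header)
    for _, row in table.data.iterrows():
        rec = out.new_record(
            contig=str(row["chrom"]),
            start=int(row["pos"]) - 1,
            alleles=(row["ref"], row["alt"]),
        )
        if row["rsid"]:
            rec.id = str(row["rsid"])
        for a in panel:
            ac_key, an_key, af_key = panel.key_map[a]
            rec.info[ac_key] = (int(row[f"ac_{a}"]),)
            rec.info[an_key] = int(row[f"an_{a}"])
            rec.info[af_key] = (float(row[f"af_{a}"]),)
        if row["gene"]:
            rec.info["GENE"] = str(row["gene"])
        if row["consequence"]:
            rec.info["CONSEQUENCE"] = str(row["consequence"])
        if row["impact"]:
            rec.info["IMPACT"] = str(row["impact"])
        rec.info["DISTANCE"] = int(row["distance"])
        out.write(rec)
    out.close()


def compute_eaf(table: VariantTable) -> EAFTable:
    """Per-variant enhanced allele frequency for every panel ancestry.

    ``EAF_a = AF_a - mean(AF_b, b != a)``; with K panel ancestries the K
    values of a variant sum to zero exactly (up to float rounding) and each
    lies in [-1, 1].
    """
    k = len(table.panel)
    if k < 2:
        raise ValueError("EAF needs at least 2 ancestries")
    af = table.af_matrix().to_numpy(dtype=float)
    total = af.sum(axis=1, keepdims=True)
    eaf = af - (total - af) / (k - 1)
    out = table.data[list(_VARIANT_COLUMNS[:6])].copy()  # chrom..gene
    for j, a in enumerate(table.panel):
        out[f"eaf_{a}"] = eaf[:, j]
    return EAFTable(data=out, panel=table.panel)


def filter_eaf(
    eafs: EAFTable,
    lo: float = 0.001,
    hi: float = 1.0,
    absolute: bool = False,
) -> pd.DataFrame:
    """Retain, per ancestry, the variants with EAF inside ``[lo, hi]``.

    Retention is per-ancestry: a variant may survive for one ancestry and
    not another, so the result is a long frame with one row per surviving
    (variant, ancestry) pair.  Both bounds are inclusive and only positive
    enrichment qualifies unless ``absolute`` is set.
    """
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError(f"invalid EAF window [{lo}, {hi}]; need 0 <= lo <= hi <= 1")
    frames = []
    key_cols = list(_VARIANT_COLUMNS[:6])
    for a in eafs.panel:
        vals = eafs.data[f"eaf_{a}"]
        crit = vals.abs() if absolute else vals
        keep = eafs.data.loc[(crit >= lo) & (crit <= hi), key_cols].copy()
        keep["ancestry"] = a
        keep["eaf"] = vals[keep.index]
        frames.append(keep)
    if not frames:
        return pd.DataFrame(columns=key_cols + ["ancestry", "eaf"])
    return pd.concat(frames, ignore_index=True)


def aggregate_gene_eaf(filtered: pd.DataFrame, rule: str = "max") -> GeneEAFProfile:
    """Aggregate surviving variant EAFs to a per-gene, per-ancestry score.

    The default rule keeps the maximum EAF over a gene's surviving variants
    for each ancestry (the strongest enrichment signal); ``rule="mean"`` is
    available.  Genes with no surviving variant for an ancestry are absent
    for that ancestry.
    """
    if rule not in ("max", "mean"):
        raise ValueError(f"unknown aggregation rule {rule!r}")
    if filtered.empty:
        return GeneEAFProfile(
            data=pd.DataFrame(columns=["gene", "ancestry", "score", "n_variants"]),
            rule=rule,
        )
    grouped = (
        filtered[filtered["gene"] != ""]
        .groupby(["gene", "ancestry"], sort=True)["eaf"]
        .agg(score=rule, n_variants="count")
        .reset_index()
    )
    return GeneEAFProfile(data=grouped, rule=rule)
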