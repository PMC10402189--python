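import numpy as np
import pandas as pd
import pytest

from phyloframe.popgen import AncestryPanel, VariantTable


@pytest.fixture
def panel3() -> AncestryPanel:
    return AncestryPanel.from_labels(["a1", "a2", "a3"])


def make_variant_table(af: np.ndarray, panel: AncestryPanel,
                       genes=None, an: int = 1000) -> VariantTable:
    """Build a VariantTable directly from an (n_variants x K) AF matrix."""
    af = np.asarray(af, dtype=float)
    n = af.shape[0]
    genes = list(genes) if genes is not None else [f"G{i+1}" for i in range(n)]
    data = {
        "chrom": ["1"] * n,
        "pos": list(range(100, 100 + n)),
        "rsid": [f"rs{i}" for i in range(n)],
        "ref": ["A"] * n,
        "alt": ["C"] * n,
        "gene": genes,
        "consequence": ["missense_variant"] * n,
        "impact": ["MODERATE"] * n,
        "distance": [0] * n,
    }
    for j, a in enumerate(panel):
        ac = np.round(af[:, j] * an).astype(int)
        data[f"ac_{a}"] = ac
        data[f"an_{a}"] = [an] * n
        data[f"af_{a}"] = af[:, j]
    return VariantTable(data=pd.DataFrame(data), panel=panel)


def write_vcf_text(path, panel: AncestryPanel, rows: list[str]) -> None:
    """Write a minimal VCF with the panel's INFO declarations plus rows."""
    lines = ["##fileformat=VCFv4.2", "##contig=<ID=1>"]
    for a in panel:
        ac, an, af = panel.key_map[a]
        lines.append(f'##INFO=<ID={ac},Number=A,Type=Integer,Description="ac">')
        lines.append(f'##INFO=<ID={an},Number=1,Type=Integer,Description="an">')
        lines.append(f'##INFO=<ID={af},Number=A,Type=Float,Description="af">')
    for key in ("GENE", "CONSEQUENCE", "IMPACT"):
        lines.append(f'##INFO=<ID={key},Number=1,Type=String,Description="x">')
    lines.append('##INFO=<ID=DISTANCE,Number=1,Type=Integer,Description="x">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    lines.extend(rows)
    path.write_text("\n".join(lines) + "\n")
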