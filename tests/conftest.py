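import numpy as np
import pytest

from bimpadr.data import ADRRecord, BipartiteDataset, DrugRecord


def make_toy_dataset(m=5, n=4, p=6, f=8, edges=None, seed=0, density=0.5):
    """Small fully-populated bipartite dataset with random features."""
    rng = np.random.default_rng(seed)
    drugs = [
        DrugRecord(
            f"D{i}",
            fingerprint=(rng.random(f) < 0.5).astype(float),
            gene_expression=rng.standard_normal(p),
        )
        for i in range(m)
    ]
    adrs = [
        ADRRecord(f"A{j}", gene_assoc=(rng.random(p) < 0.3).astype(float))
        for j in range(n)
    ]
    if edges is None:
        edges = {(i, j) for i in range(m) for j in range(n)
                 if rng.random() < density}
        if not edges:
            edges = {(0, 0)}
    return BipartiteDataset(drugs=drugs, adrs=adrs, edges=set(edges))


@pytest.fixture
def toy_dataset():
    return make_toy_dataset()


@pytest.fixture
def fixture_tables(tmp_path):
    """A hand-written 5-drug / 4-ADR study on disk: 9 association pairs."""
    pairs = [
        ("D0", "A0"), ("D0", "A1"), ("D1", "A0"), ("D1", "A2"),
        ("D2", "A1"), ("D2", "A2"), ("D3", "A3"), ("D4", "A0"),
        ("D4", "A3"),
    ]
    assoc = tmp_path / "associations.tsv"
    assoc.write_text(
        "drug_id\tadr_id\n" + "\n".join(f"{d}\t{a}" for d, a in pairs) + "\n"
    )
    rng = np.random.default_rng(42)
    p, f = 6, 4
    expr = tmp_path / "expression.tsv"
    lines = ["id\t" + "\t".join(f"g{k}" for k in range(p))]
    for i in range(5):
        vals = rng.standard_normal(p)
        lines.append(f"D{i}\t" + "\t".join(f"{v:.6f}" for v in vals))
    expr.write_text("\n".join(lines) + "\n")
    fp = tmp_path / "fingerprints.tsv"
    lines = ["id\t" + "\t".join(f"b{k}" for k in range(f))]
    for i in range(5):
        bits = (rng.random(f) < 0.5).astype(int)
        lines.append(f"D{i}\t" + "\t".join(str(b) for b in bits))
    fp.write_text("\n".join(lines) + "\n")
    adr_gene = tmp_path / "adr_gene.tsv"
    lines = ["id\t" + "\t".join(f"g{k}" for k in range(p))]
    for j in range(3):  # A3 deliberately missing -> zero-fill path
        bits = (rng.random(p) < 0.3).astype(int)
        lines.append(f"A{j}\t" + "\t".join(str(b) for b in bits))
    adr_gene.write_text("\n".join(lines) + "\n")
    return {
        "associations": assoc,
        "expression": expr,
        "fingerprints": fp,
        "adr_gene": adr_gene,
        "pairs": set(pairs),
        "p": p,
        "f": f,
    }
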