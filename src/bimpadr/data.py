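"""Bipartite drug-ADR dataset handling.

Reads the four tabular inputs (drug-ADR associations, drug expression
signatures over the 978 LINCS landmark genes, binary drug fingerprints,
binary ADR-gene association profiles), assembles them into an aligned
bipartite dataset, and provides the experimental plumbing around it:
drug-stratified fold plans, 1:1 negative sampling, and all-pairs external
validation sets for cold-start drugs.

Conventions: tab-separated tables with a header row and a leading ID column;
IDs are matched as exact strings; indices are 0-based and internal only.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

N_LANDMARK_GENES = 978

__all__ = [
    "DrugRecord",
    "ADRRecord",
    "BipartiteDataset",
    "FoldPlan",
    "LabeledPairSet",
    "load_association_table",
    "load_feature_matrix",
    "load_smiles_table",
    "assemble_dataset",
    "make_drug_folds",
    "sample_negatives",
    "build_external_pairset",
    "external_drugs_from_matrix",
    "fingerprints_from_smiles",
    "write_feature_matrix",
    "write_association_table",
]


@dataclass
class DrugRecord:
    """One drug: identifier, fingerprint bits, optional expression signature.

    ``gene_expression`` is the signed differential-expression signature over
    the landmark genes; it is absent for external (cold-start) drugs, which
    are scored from structure alone.
    """

    drug_id: str
    fingerprint: np.ndarray | None = None
    gene_expression: np.ndarray | None = None
    smiles: str | None = None

    def __post_init__(self):
        if self.fingerprint is not None:
            self.fingerprint = np.asarray(self.fingerprint, dtype=np.float64)
            bits = np.unique(self.fingerprint)
            if not np.all(np.isin(bits, (0.0, 1.0))):
                raise ValueError(
                    f"fingerprint of drug {self.drug_id!r} is not binary"
                )
        if self.gene_expression is not None:
            self.gene_expression = np.asarray(
                self.gene_expression, dtype=np.float64
            )


@dataclass
class ADRRecord:
    """One adverse reaction: identifier and its binary gene-association profile."""

    adr_id: str
    gene_assoc: np.ndarray = field(default_factory=lambda: np.zeros(0))
    name: str | None = None

    def __post_init__(self):
        self.gene_assoc = np.asarray(self.gene_assoc, dtype=np.float64)
        bits = np.unique(self.gene_assoc)
        if bits.size and not np.all(np.isin(bits, (0.0, 1.0))):
            raise ValueError(f"gene_assoc of ADR {self.adr_id!r} is not binary")


@dataclass
class BipartiteDataset:
    """The bipartite graph BG(U, V, E) of drugs, ADRs and known associations."""

    drugs: list[DrugRecord]
    adrs: list[ADRRecord]
    edges: set[tuple[int, int]]

    def __post_init__(self):
        m, n = len(self.drugs), len(self.adrs)
        seen_d = {d.drug_id for d in self.drugs}
        seen_a = {a.adr_id for a in self.adrs}
        if len(seen_d) != m:
            raise ValueError("duplicate drug IDs in dataset")
        if len(seen_a) != n:
            raise ValueError("duplicate ADR IDs in dataset")
        for i, j in self.edges:
            if not (0 <= i < m and 0 <= j < n):
                raise ValueError(f"edge ({i}, {j}) out of range for {m}x{n}")

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    @property
    def n_adrs(self) -> int:
        return len(self.adrs)

    @property
    def drug_ids(self) -> list[str]:
        return [d.drug_id for d in self.drugs]

    @property
    def adr_ids(self) -> list[str]:
        return [a.adr_id for a in self.adrs]

    def expression_matrix(self) -> np.ndarray:
        """Drug expression signatures, (M, P); errors on a missing signature."""
        missing = [d.drug_id for d in self.drugs if d.gene_expression is None]
        if missing:
            raise ValueError(f"drugs lack gene expression: {missing}")
        return np.stack([d.gene_expression for d in self.drugs])

    def fingerprint_matrix(self) -> np.ndarray:
        missing = [d.drug_id for d in self.drugs if d.fingerprint is None]
        if missing:
            raise ValueError(f"drugs lack fingerprints: {missing}")
        return np.stack([d.fingerprint for d in self.drugs])

    def adr_feature_matrix(self) -> np.ndarray:
        return np.stack([a.gene_assoc for a in self.adrs])

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Edge list as two index arrays in a canonical order.

        Edges are ordered by (ADR ID, drug ID) strings, not by indices, so
        any relabeling/permutation of the node lists yields the same
        accumulation order downstream — summations stay bit-reproducible.
        """
        if not self.edges:
            return np.zeros(0, dtype=np.intp), np.zeros(0, dtype=np.intp)
        ordered = sorted(
            self.edges,
            key=lambda e: (self.adrs[e[1]].adr_id, self.drugs[e[0]].drug_id),
        )
        e = np.array(ordered, dtype=np.intp)
        return e[:, 0], e[:, 1]

    def restrict_edges_to_drugs(self, drug_indices) -> "BipartiteDataset":
        """Same node sets, edges restricted to the given drugs (fold training graph)."""
        keep = set(int(i) for i in drug_indices)
        return BipartiteDataset(
            drugs=self.drugs,
            adrs=self.adrs,
            edges={(i, j) for (i, j) in self.edges if i in keep},
        )


@dataclass
class FoldPlan:
    """Assignment of every modeling drug to exactly one cross-validation fold."""

    n_folds: int
    assignment: np.ndarray  # drug index -> fold index

    def fold_drugs(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)

    def complement_drugs(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment != fold)


@dataclass
class LabeledPairSet:
    """(drug index, ADR index, label) triples with a provenance tag."""

    drug_idx: np.ndarray
    adr_idx: np.ndarray
    labels: np.ndarray
    provenance: str  # "train" | "test" | "external"

    def __post_init__(self):
        self.drug_idx = np.asarray(self.drug_idx, dtype=np.intp)
        self.adr_idx = np.asarray(self.adr_idx, dtype=np.intp)
        self.labels = np.asarray(self.labels, dtype=np.float64)
        if not (len(self.drug_idx) == len(self.adr_idx) == len(self.labels)):
            raise ValueError("triple arrays must share a length")
        pairs = set(zip(self.drug_idx.tolist(), self.adr_idx.tolist()))
        if len(pairs) != len(self.drug_idx):
            raise ValueError("duplicate (drug, adr) pair in pair set")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())


# ---------------------------------------------------------------------------
# readers / writers


def load_association_table(
    path,
    sep: str = "\t",
    drug_col: str = "drug_id",
    adr_col: str = "adr_id",
) -> set[tuple[str, str]]:
    """Read a two-column drug-ADR association list; returns de-duplicated pairs."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.empty:
        raise ValueError(f"association table {path} is empty")
    for col in (drug_col, adr_col):
        if col not in df.columns:
            raise ValueError(
                f"association table {path} lacks required column {col!r} "
                f"(found {list(df.columns)})"
            )
    return set(zip(df[drug_col], df[adr_col]))


def load_feature_matrix(
    path,
    expected_width: int | None = None,
    binary: bool = False,
    sep: str = "\t",
) -> tuple[list[str], np.ndarray]:
    """Read an ID-indexed numeric matrix; row order preserved as on disk."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    try:
        mat = df.to_numpy(dtype=np.float64)
    except ValueError as exc:
        raise ValueError(f"non-numeric entries in {path}: {exc}") from exc
    if np.isnan(mat).any():
        bad = int(np.flatnonzero(np.isnan(mat).any(axis=1))[0])
        raise ValueError(f"missing/ragged values in {path} at data row {bad}")
    if expected_width is not None and mat.shape[1] != expected_width:
        raise ValueError(
            f"{path}: expected {expected_width} columns, found {mat.shape[1]}"
        )
    if binary and not np.all(np.isin(mat, (0.0, 1.0))):
        raise ValueError(f"{path}: non-binary value under binary flag")
    return [str(i) for i in df.index], mat


def load_smiles_table(path, sep: str = "\t") -> dict[str, str]:
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in ("drug_id", "smiles"):
        if col not in df.columns:
            raise ValueError(f"SMILES table {path} lacks column {col!r}")
    return dict(zip(df["drug_id"], df["smiles"]))


def write_feature_matrix(path, ids, matrix, sep: str = "\t",
                         col_prefix: str = "f") -> None:
    mat = np.asarray(matrix)
    df = pd.DataFrame(
        mat, index=ids, columns=[f"{col_prefix}{k}" for k in range(mat.shape[1])]
    )
    df.index.name = "id"
    df.to_csv(path, sep=sep)


def write_association_table(path, pairs, sep: str = "\t") -> None:
    df = pd.DataFrame(sorted(pairs), columns=["drug_id", "adr_id"])
    df.to_csv(path, sep=sep, index=False)


def fingerprints_from_smiles(
    smiles: dict[str, str], kind: str = "maccs", n_bits: int = 1024
) -> tuple[list[str], np.ndarray]:
    """Compute binary fingerprints from SMILES via rdkit (optional dependency).

    ``kind``: "maccs" (166 bits), "ecfp" (Morgan radius 2, ``n_bits``).
    """
    from rdkit import Chem
    from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

    ids, rows = [], []
    gen = None
    if kind == "ecfp":
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
    for drug_id, smi in smiles.items():
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES for drug {drug_id!r}: {smi!r}")
        if kind == "maccs":
            fp = MACCSkeys.GenMACCSKeys(mol)
        elif kind == "ecfp":
            fp = gen.GetFingerprint(mol)
        else:
            raise ValueError(f"unknown fingerprint kind {kind!r}")
        ids.append(drug_id)
        rows.append(np.array(fp, dtype=np.float64))
    return ids, np.stack(rows)


# ---------------------------------------------------------------------------
# assembly


def assemble_dataset(
    pairs: set[tuple[str, str]],
    expr: tuple[list[str], np.ndarray],
    fingerprints: tuple[list[str], np.ndarray],
    adr_gene: tuple[list[str], np.ndarray],
    fill_missing_adr: bool = True,
) -> tuple[BipartiteDataset, dict]:
    """Align the four inputs into a :class:`BipartiteDataset`.

    Drugs are the distinct drug IDs appearing in ``pairs`` (sorted); every one
    must have a fingerprint and an expression signature.  ADRs observed with
    at least one drug are kept; an ADR missing from the ADR-gene table gets an
    all-zero profile when ``fill_missing_adr`` is set and is dropped otherwise.
    Returns the dataset and a manifest of counts.
    """
    expr_ids, expr_mat = expr
    fp_ids, fp_mat = fingerprints
    adr_ids, adr_mat = adr_gene
    if len(set(expr_ids)) != len(expr_ids):
        raise ValueError("duplicate IDs in expression matrix")
    if len(set(fp_ids)) != len(fp_ids):
        raise ValueError("duplicate IDs in fingerprint matrix")
    if len(set(adr_ids)) != len(adr_ids):
        raise ValueError("duplicate IDs in ADR-gene matrix")
    expr_by_id = dict(zip(expr_ids, expr_mat))
    fp_by_id = dict(zip(fp_ids, fp_mat))
    adr_by_id = dict(zip(adr_ids, adr_mat))
    q = adr_mat.shape[1]

    drug_order = sorted({d for d, _ in pairs})
    missing_fp = [d for d in drug_order if d not in fp_by_id]
    if missing_fp:
        raise ValueError(f"drugs in pairs lack fingerprints: {missing_fp}")
    missing_expr = [d for d in drug_order if d not in expr_by_id]
    if missing_expr:
        raise ValueError(f"modeling drugs lack expression signatures: {missing_expr}")

    observed_adrs = sorted({a for _, a in pairs})
    zero_filled: list[str] = []
    kept_adrs: list[str] = []
    for a in observed_adrs:
        if a in adr_by_id:
            kept_adrs.append(a)
        elif fill_missing_adr:
            kept_adrs.append(a)
            zero_filled.append(a)

    drugs = [
        DrugRecord(d, fingerprint=fp_by_id[d], gene_expression=expr_by_id[d])
        for d in drug_order
    ]
    adrs = [
        ADRRecord(a, gene_assoc=adr_by_id.get(a, np.zeros(q)))
        for a in kept_adrs
    ]
    d_index = {d: i for i, d in enumerate(drug_order)}
    a_index = {a: j for j, a in enumerate(kept_adrs)}
    edges = {
        (d_index[d], a_index[a]) for d, a in pairs if a in a_index
    }
    ds = BipartiteDataset(drugs=drugs, adrs=adrs, edges=edges)
    manifest = {
        "n_drugs": ds.n_drugs,
        "n_adrs": ds.n_adrs,
        "n_edges": len(ds.edges),
        "n_input_pairs": len(pairs),
        "zero_filled_adrs": zero_filled,
        "dropped_adrs": sorted(set(observed_adrs) - set(kept_adrs)),
    }
    return ds, manifest


def dataset_manifest(ds: BipartiteDataset, input_paths: dict | None = None) -> dict:
    """Manifest with counts and sha256 checksums of the input files."""
    manifest = {
        "n_drugs": ds.n_drugs,
        "n_adrs": ds.n_adrs,
        "n_edges": len(ds.edges),
    }
    if input_paths:
        checks = {}
        for name, p in input_paths.items():
            checks[name] = hashlib.sha256(Path(p).read_bytes()).hexdigest()
        manifest["input_sha256"] = checks
    return manifest


# ---------------------------------------------------------------------------
# experimental design


def make_drug_folds(ds: BipartiteDataset, n_folds: int = 5,
                    seed: int = 0) -> FoldPlan:
    """Drug-stratified fold plan: a balanced random partition of drug indices.

    Every pair involving a drug inherits the drug's fold, so no drug's pairs
    can straddle a train/test split derived from this plan.
    """
    m = ds.n_drugs
    if n_folds < 2 or n_folds > m:
        raise ValueError(f"n_folds={n_folds} invalid for {m} drugs")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(m)
    assignment = np.empty(m, dtype=np.intp)
    for pos, drug in enumerate(perm):
        assignment[drug] = pos % n_folds
    return FoldPlan(n_folds=n_folds, assignment=assignment)


def sample_negatives(
    ds: BipartiteDataset,
    drug_subset,
    ratio: float = 1.0,
    seed: int = 0,
    provenance: str = "train",
) -> LabeledPairSet:
    """Positives = all edges of the subset's drugs; negatives sampled 1:ratio.

    Negatives are drawn uniformly without replacement from the unobserved
    cells of the subset's rows of the adjacency, so they can never collide
    with a positive of any drug in the subset.
    """
    drug_subset = np.asarray(sorted(set(int(d) for d in np.atleast_1d(drug_subset))),
                             dtype=np.intp)
    if drug_subset.size == 0:
        raise ValueError("drug subset is empty")
    n = ds.n_adrs
    subset_set = set(drug_subset.tolist())
    positives = sorted((i, j) for (i, j) in ds.edges if i in subset_set)
    n_pos = len(positives)
    n_neg = int(round(ratio * n_pos))
    pos_set = set(positives)
    candidates = [
        (int(i), j) for i in drug_subset for j in range(n) if (int(i), j) not in pos_set
    ]
    if len(candidates) < n_neg:
        raise ValueError(
            f"cannot sample {n_neg} negatives: only {len(candidates)} unobserved "
            f"pairs among the subset's {drug_subset.size} drugs x {n} ADRs"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n_neg, replace=False)
    negatives = [candidates[k] for k in sorted(chosen.tolist())]
    di = np.array([p[0] for p in positives] + [p[0] for p in negatives], dtype=np.intp)
    aj = np.array([p[1] for p in positives] + [p[1] for p in negatives], dtype=np.intp)
    lab = np.concatenate([np.ones(n_pos), np.zeros(n_neg)])
    return LabeledPairSet(di, aj, lab, provenance=provenance)


def build_external_pairset(
    ds: BipartiteDataset,
    external_drugs: list[DrugRecord],
    known_pairs: set[tuple[str, str]],
) -> LabeledPairSet:
    """All-pairs validation set for cold-start drugs.

    Enumerates every (external drug, dataset ADR) combination; the label is 1
    iff the pair's IDs appear in ``known_pairs``.  Drug indices in the result
    index into ``external_drugs``, not into the dataset.
    """
    model_ids = set(ds.drug_ids)
    collisions = [d.drug_id for d in external_drugs if d.drug_id in model_ids]
    if collisions:
        raise ValueError(f"external drugs collide with modeling drugs: {collisions}")
    no_fp = [d.drug_id for d in external_drugs if d.fingerprint is None]
    if no_fp:
        raise ValueError(f"external drugs lack fingerprints: {no_fp}")
    n = ds.n_adrs
    adr_ids = ds.adr_ids
    di, aj, lab = [], [], []
    for i, d in enumerate(external_drugs):
        for j in range(n):
            di.append(i)
            aj.append(j)
            lab.append(1.0 if (d.drug_id, adr_ids[j]) in known_pairs else 0.0)
    return LabeledPairSet(
        np.array(di, dtype=np.intp),
        np.array(aj, dtype=np.intp),
        np.array(lab),
        provenance="external",
    )


def external_drugs_from_matrix(
    fingerprints: tuple[list[str], np.ndarray]
) -> list[DrugRecord]:
    ids, mat = fingerprints
    return [DrugRecord(i, fingerprint=row) for i, row in zip(ids, mat)]


def save_manifest(path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
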