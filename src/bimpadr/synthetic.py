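"""Synthetic drug-ADR data with the structure the model assumes.

A shared low-dimensional latent space links everything the pipeline consumes:
drugs and ADRs get standard-normal latent vectors; a drug's expression
signature is a fixed linear image of its latent plus Gaussian noise; its
fingerprint bits are Bernoulli draws whose log-odds are linear in the latent
(then flipped with small probability, emulating fingerprint noise); an ADR's
gene-association bits are Bernoulli draws with a latent-dependent probability
calibrated to a target density; and the drug-ADR association label is
Bernoulli(sigmoid(beta * <z_drug, z_adr> + c)) with the intercept c solved by
bisection so the realized positive rate matches ``base_rate``.

External (cold-start) drugs receive latents and fingerprints like any other
drug, but their expression is withheld from the returned records and they
contribute no edges — exactly the information available for a new compound.

The generator encodes the modeling hypotheses (structurally similar drugs
share ADRs; expression perturbation is informative about ADRs) in the
simplest form; it does not emulate LINCS replicate structure, dosage or
cell-line effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ADRRecord, BipartiteDataset, DrugRecord, LabeledPairSet

__all__ = ["SimSpec", "SimTruth", "simulate", "permute_labels",
           "external_known_pairs", "true_logit_pairset_scores"]


@dataclass
class SimSpec:
    """Generator settings; defaults are the package's standard test-bed
    conditions (reduced gene and fingerprint dimensionality for speed)."""

    n_drugs: int = 200
    n_external_drugs: int = 50
    n_adrs: int = 60
    n_genes: int = 100
    fp_dim: int = 64
    latent_dim: int = 4
    signal_strength: float = 3.0
    expr_noise_sd: float = 0.5
    fp_flip_prob: float = 0.02
    adr_gene_density: float = 0.05
    base_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in ("n_drugs", "n_external_drugs", "n_adrs", "n_genes",
                     "fp_dim", "latent_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("fp_flip_prob", "adr_gene_density"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 < self.base_rate < 1:
            raise ValueError("base_rate must lie in (0, 1)")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be >= 0")


@dataclass
class SimTruth:
    """Ground truth retained for recovery tests: latents and pair logits for
    all drugs (modeling first, then external) against all ADRs."""

    z_drugs: np.ndarray  # (M + n_external, k)
    z_adrs: np.ndarray  # (N, k)
    logits: np.ndarray  # (M + n_external, N)
    labels: np.ndarray  # (M + n_external, N) binary
    intercept: float


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _calibrate_intercept(raw: np.ndarray, target: float,
                         tol: float = 1e-3) -> float:
    """Bisection on c so that mean sigmoid(raw + c) = target."""
    lo, hi = -60.0, 60.0
    if _sigmoid(raw + lo).mean() > target or _sigmoid(raw + hi).mean() < target:
        feas = (float(_sigmoid(raw + lo).mean()), float(_sigmoid(raw + hi).mean()))
        raise ValueError(
            f"target rate {target} unreachable; feasible range ~{feas}"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        rate = _sigmoid(raw + mid).mean()
        if abs(rate - target) < tol:
            return mid
        if rate < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate(
    spec: SimSpec,
) -> tuple[BipartiteDataset, list[DrugRecord], SimTruth]:
    """Draw one complete synthetic study from ``spec``.

    Returns the modeling dataset (drugs with expression + fingerprints, ADRs
    with gene profiles, positive edges), the external drug records
    (fingerprints only), and the generating truth.
    """
    rng = np.random.default_rng(spec.seed)
    m, ext, n, k = (spec.n_drugs, spec.n_external_drugs, spec.n_adrs,
                    spec.latent_dim)
    z_u = rng.standard_normal((m + ext, k))
    z_v = rng.standard_normal((n, k))

    # expression: fixed linear map of the latent plus noise
    a_map = rng.standard_normal((spec.n_genes, k)) / np.sqrt(k)
    expr = z_u @ a_map.T + spec.expr_noise_sd * rng.standard_normal(
        (m + ext, spec.n_genes)
    )

    # fingerprints: per-bit logistic in the latent, then random flips
    b_map = rng.standard_normal((spec.fp_dim, k)) / np.sqrt(k)
    fp_prob = _sigmoid(z_u @ b_map.T)
    fp = (rng.random((m + ext, spec.fp_dim)) < fp_prob).astype(np.float64)
    flips = rng.random((m + ext, spec.fp_dim)) < spec.fp_flip_prob
    fp = np.where(flips, 1.0 - fp, fp)

    # ADR-gene profiles: latent-dependent Bernoulli, calibrated density
    g_map = rng.standard_normal((spec.n_genes, k)) / np.sqrt(k)
    g_raw = z_v @ g_map.T
    g_c = _calibrate_intercept(g_raw, spec.adr_gene_density)
    gene_assoc = (rng.random((n, spec.n_genes))
                  < _sigmoid(g_raw + g_c)).astype(np.float64)

    # association labels: bilinear latent interaction, calibrated base rate
    raw = spec.signal_strength * (z_u @ z_v.T)
    c = _calibrate_intercept(raw, spec.base_rate)
    logits = raw + c
    labels = (rng.random((m + ext, n)) < _sigmoid(logits)).astype(np.float64)

    drugs = [
        DrugRecord(f"D{i:04d}", fingerprint=fp[i], gene_expression=expr[i])
        for i in range(m)
    ]
    adrs = [ADRRecord(f"A{j:04d}", gene_assoc=gene_assoc[j]) for j in range(n)]
    edges = {(i, j) for i in range(m) for j in range(n) if labels[i, j] == 1}
    dataset = BipartiteDataset(drugs=drugs, adrs=adrs, edges=edges)
    external = [
        DrugRecord(f"X{i:04d}", fingerprint=fp[m + i]) for i in range(ext)
    ]
    truth = SimTruth(z_drugs=z_u, z_adrs=z_v, logits=logits, labels=labels,
                     intercept=c)
    return dataset, external, truth


def external_known_pairs(
    spec_or_truth: SimTruth, external: list[DrugRecord],
    dataset: BipartiteDataset,
) -> set[tuple[str, str]]:
    """The (external drug ID, ADR ID) pairs that are true associations."""
    truth = spec_or_truth
    m = dataset.n_drugs
    adr_ids = dataset.adr_ids
    out = set()
    for i, d in enumerate(external):
        for j in range(dataset.n_adrs):
            if truth.labels[m + i, j] == 1:
                out.add((d.drug_id, adr_ids[j]))
    return out


def true_logit_pairset_scores(
    truth: SimTruth, pairs: LabeledPairSet, drug_offset: int = 0
) -> np.ndarray:
    """Ground-truth logits for a pair set (Bayes-optimal ranking scores)."""
    return truth.logits[pairs.drug_idx + drug_offset, pairs.adr_idx]


def permute_labels(pairs: LabeledPairSet, seed: int = 0) -> LabeledPairSet:
    """Negative control: shuffle labels across pairs, preserving the margin."""
    if len(pairs) == 0:
        raise ValueError("empty pair set")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pairs))
    return LabeledPairSet(
        pairs.drug_idx.copy(), pairs.adr_idx.copy(),
        pairs.labels[perm], provenance=pairs.provenance,
    )
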