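"""The full drug-ADR association network and its ablation variants.

Architecture: a drug's binary fingerprint passes through a fully connected
encoder; each ADR's embedding comes from the bipartite attention layer (or an
ablation substitute); the two are concatenated and fed to a fully connected
head whose hidden layers use LeakyReLU and whose single output unit is a
sigmoid giving the association probability.  Dropout acts on the head's
hidden layers only, and only in training mode.

Variants:
  full              attention message passing with self-loop (the method)
  zero_adr_features ADR-gene profiles replaced by zero vectors
  no_self_loop      vertex update h = ReLU(m) without the W_v x_v term
  no_mpnn           no message passing; the raw ADR-gene profile feeds the head
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._autodiff import Tensor
from .data import BipartiteDataset, DrugRecord, LabeledPairSet
from .mpnn import MPNNParams, embed_adrs, embed_adrs_tape

__all__ = [
    "BiMPADRConfig",
    "BiMPADRModel",
    "init_model",
    "encode_drug",
    "adr_features",
    "score_pairs",
    "score_cold_start",
    "save_checkpoint",
    "load_checkpoint",
    "write_predictions",
]

VARIANTS = ("full", "zero_adr_features", "no_self_loop", "no_mpnn")


@dataclass
class BiMPADRConfig:
    """Hyperparameters and dimensions; defaults follow the training protocol
    (dropout 0.2) with architecture widths chosen as package defaults."""

    variant: str = "full"
    fingerprint_dim: int = 881
    expr_dim: int = 978
    adr_dim: int = 978
    latent_dim: int = 64
    encoder_hidden: list[int] = field(default_factory=list)  # [] -> [latent_dim]
    head_hidden: list[int] = field(default_factory=lambda: [128, 32])
    dropout_rate: float = 0.2
    leaky_slope: float = 0.01
    message_form: str = "conventional"
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if not self.encoder_hidden:
            self.encoder_hidden = [self.latent_dim]
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must lie in [0, 1)")
        for w in (*self.encoder_hidden, *self.head_hidden, self.latent_dim,
                  self.fingerprint_dim, self.expr_dim, self.adr_dim):
            if w < 1:
                raise ValueError("all widths and dimensions must be >= 1")

    @property
    def uses_mpnn(self) -> bool:
        return self.variant != "no_mpnn"

    @property
    def adr_feature_dim(self) -> int:
        """Width of the ADR representation entering the head."""
        return self.latent_dim if self.uses_mpnn else self.adr_dim

    @property
    def head_input_dim(self) -> int:
        return self.encoder_hidden[-1] + self.adr_feature_dim


class BiMPADRModel:
    """Weight container; numerical behavior lives in the module functions.

    ``weights`` maps parameter names to float64 arrays.  Linear layers store
    weight (in, out) and bias (out,); the attention vector is (2S, 1).
    """

    def __init__(self, config: BiMPADRConfig, weights: dict[str, np.ndarray]):
        self.config = config
        self.weights = weights

    def parameter_names(self) -> list[str]:
        return sorted(self.weights)

    def n_parameters(self) -> int:
        return sum(w.size for w in self.weights.values())

    def copy_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.weights.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k in self.weights:
            self.weights[k] = weights[k].copy()

    def mpnn_params(self) -> MPNNParams:
        if not self.config.uses_mpnn:
            raise ValueError("variant no_mpnn has no message-passing parameters")
        return MPNNParams(
            W_u=self.weights["mpnn.W_u"],
            W_v=self.weights["mpnn.W_v"],
            attn=self.weights["mpnn.attn"][:, 0],
            leaky_slope=self.config.leaky_slope,
            self_loop=self.config.variant != "no_self_loop",
            message_form=self.config.message_form,
        )


def _linear_init(rng: np.random.Generator, fan_in: int, fan_out: int):
    """Uniform fan-in scaling, U(-1/sqrt(fan_in), 1/sqrt(fan_in))."""
    bound = 1.0 / np.sqrt(fan_in)
    w = rng.uniform(-bound, bound, size=(fan_in, fan_out))
    b = rng.uniform(-bound, bound, size=(fan_out,))
    return w, b


def init_model(config: BiMPADRConfig) -> BiMPADRModel:
    """Deterministically initialize all weights from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    weights: dict[str, np.ndarray] = {}
    if config.uses_mpnn:
        s = config.latent_dim
        bound_u = 1.0 / np.sqrt(config.expr_dim)
        bound_v = 1.0 / np.sqrt(config.adr_dim)
        weights["mpnn.W_u"] = rng.uniform(-bound_u, bound_u, (config.expr_dim, s))
        weights["mpnn.W_v"] = rng.uniform(-bound_v, bound_v, (config.adr_dim, s))
        weights["mpnn.attn"] = rng.uniform(
            -1.0 / np.sqrt(2 * s), 1.0 / np.sqrt(2 * s), (2 * s, 1)
        )
    widths = [config.fingerprint_dim, *config.encoder_hidden]
    for k, (fi, fo) in enumerate(zip(widths[:-1], widths[1:])):
        w, b = _linear_init(rng, fi, fo)
        weights[f"enc.{k}.w"], weights[f"enc.{k}.b"] = w, b
    widths = [config.head_input_dim, *config.head_hidden, 1]
    for k, (fi, fo) in enumerate(zip(widths[:-1], widths[1:])):
        w, b = _linear_init(rng, fi, fo)
        weights[f"head.{k}.w"], weights[f"head.{k}.b"] = w, b
    return BiMPADRModel(config, weights)


# ---------------------------------------------------------------------------
# forward passes (numpy, inference)


def _leaky(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x > 0, x, slope * x)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def encode_drugs(model: BiMPADRModel, fingerprints: np.ndarray) -> np.ndarray:
    """Fingerprint encoder on a (B, F) matrix; every layer LeakyReLU-activated."""
    x = np.asarray(fingerprints, dtype=np.float64)
    if x.shape[-1] != model.config.fingerprint_dim:
        raise ValueError(
            f"fingerprint width {x.shape[-1]} != configured "
            f"{model.config.fingerprint_dim}"
        )
    for k in range(len(model.config.encoder_hidden)):
        x = _leaky(
            x @ model.weights[f"enc.{k}.w"] + model.weights[f"enc.{k}.b"],
            model.config.leaky_slope,
        )
    return x


def encode_drug(model: BiMPADRModel, fingerprint: np.ndarray) -> np.ndarray:
    return encode_drugs(model, np.asarray(fingerprint)[None, :])[0]


def _head_logits(model: BiMPADRModel, x: np.ndarray,
                 dropout_masks: list[np.ndarray] | None = None) -> np.ndarray:
    cfg = model.config
    for k in range(len(cfg.head_hidden)):
        x = _leaky(
            x @ model.weights[f"head.{k}.w"] + model.weights[f"head.{k}.b"],
            cfg.leaky_slope,
        )
        if dropout_masks is not None:
            x = x * dropout_masks[k]
    k = len(cfg.head_hidden)
    z = x @ model.weights[f"head.{k}.w"] + model.weights[f"head.{k}.b"]
    return z[:, 0]


def adr_features(model: BiMPADRModel, dataset: BipartiteDataset) -> np.ndarray:
    """ADR representation entering the head, per the configured variant."""
    cfg = model.config
    if cfg.variant == "no_mpnn":
        return dataset.adr_feature_matrix()
    override = None
    if cfg.variant == "zero_adr_features":
        override = np.zeros((dataset.n_adrs, cfg.adr_dim))
    return embed_adrs(model.mpnn_params(), dataset, adr_features=override).h


def score_pairs(
    model: BiMPADRModel,
    dataset: BipartiteDataset,
    pairs: LabeledPairSet,
    training_mode: bool = False,
    rng: np.random.Generator | None = None,
    adr_feats: np.ndarray | None = None,
) -> np.ndarray:
    """Association probability for each (drug, ADR) pair in ``pairs``.

    The ADR features are computed from the dataset's edges (the training
    graph); pass ``adr_feats`` to reuse a precomputed matrix.  In training
    mode dropout is applied to the head's hidden activations using ``rng``.
    """
    if adr_feats is None:
        adr_feats = adr_features(model, dataset)
    if pairs.drug_idx.size and (
        pairs.drug_idx.max() >= dataset.n_drugs
        or pairs.adr_idx.max() >= dataset.n_adrs
    ):
        raise IndexError("pair references an index outside the dataset")
    fp = dataset.fingerprint_matrix()[pairs.drug_idx]
    latent = encode_drugs(model, fp)
    x = np.concatenate([latent, adr_feats[pairs.adr_idx]], axis=1)
    masks = None
    if training_mode:
        if rng is None:
            raise ValueError("training_mode requires an rng for dropout")
        masks = _dropout_masks(model.config, len(x), rng)
    return _sigmoid(_head_logits(model, x, masks))


def score_cold_start(
    model: BiMPADRModel,
    external_drugs: list[DrugRecord],
    adr_feats: np.ndarray,
    pairs: LabeledPairSet,
) -> np.ndarray:
    """Score external (cold-start) drugs: fingerprints only, frozen ADR features."""
    fp = np.stack([external_drugs[i].fingerprint for i in pairs.drug_idx])
    latent = encode_drugs(model, fp)
    x = np.concatenate([latent, adr_feats[pairs.adr_idx]], axis=1)
    return _sigmoid(_head_logits(model, x))


def _dropout_masks(cfg: BiMPADRConfig, batch: int,
                   rng: np.random.Generator) -> list[np.ndarray]:
    """Inverted-dropout masks for the head's hidden layers."""
    rate = cfg.dropout_rate
    masks = []
    for w in cfg.head_hidden:
        if rate == 0:
            masks.append(np.ones((batch, w)))
        else:
            keep = (rng.random((batch, w)) >= rate).astype(np.float64)
            masks.append(keep / (1.0 - rate))
    return masks


# ---------------------------------------------------------------------------
# forward pass on the autodiff tape (training)


def make_param_tensors(model: BiMPADRModel) -> dict[str, Tensor]:
    """Wrap the model's arrays as trainable Tensors sharing the same memory."""
    return {k: Tensor(v, requires_grad=True) for k, v in model.weights.items()}


def forward_tape(
    model: BiMPADRModel,
    params: dict[str, Tensor],
    dataset: BipartiteDataset,
    pairs: LabeledPairSet,
    rng: np.random.Generator | None = None,
    training_mode: bool = True,
) -> Tensor:
    """Logits for ``pairs`` with gradients flowing to every parameter Tensor."""
    cfg = model.config
    if cfg.uses_mpnn:
        override = None
        if cfg.variant == "zero_adr_features":
            override = np.zeros((dataset.n_adrs, cfg.adr_dim))
        x_v = override if override is not None else dataset.adr_feature_matrix()
        edge_drug, edge_adr = dataset.edge_arrays()
        p = cfg.expr_dim
        x_u = np.zeros((dataset.n_drugs, p))
        for i in set(edge_drug.tolist()):
            ge = dataset.drugs[i].gene_expression
            if ge is None:
                raise ValueError(
                    f"drug {dataset.drugs[i].drug_id!r} on an edge lacks expression"
                )
            x_u[i] = ge
        adr_feats = embed_adrs_tape(
            params["mpnn.W_u"], params["mpnn.W_v"], params["mpnn.attn"],
            x_u, x_v, edge_drug, edge_adr, dataset.n_adrs,
            leaky_slope=cfg.leaky_slope,
            self_loop=cfg.variant != "no_self_loop",
            message_form=cfg.message_form,
        )
    else:
        adr_feats = Tensor(dataset.adr_feature_matrix())
    fp = dataset.fingerprint_matrix()[pairs.drug_idx]
    x = Tensor(fp)
    for k in range(len(cfg.encoder_hidden)):
        x = (x @ params[f"enc.{k}.w"] + params[f"enc.{k}.b"]).leaky_relu(
            cfg.leaky_slope
        )
    x = x.concat(adr_feats.gather_rows(pairs.adr_idx))
    masks = None
    if training_mode:
        if rng is None:
            raise ValueError("training_mode requires an rng for dropout")
        masks = _dropout_masks(cfg, len(pairs), rng)
    for k in range(len(cfg.head_hidden)):
        x = (x @ params[f"head.{k}.w"] + params[f"head.{k}.b"]).leaky_relu(
            cfg.leaky_slope
        )
        if masks is not None:
            x = x * Tensor(masks[k])
    k = len(cfg.head_hidden)
    z = x @ params[f"head.{k}.w"] + params[f"head.{k}.b"]
    return z.reshape(-1)


# ---------------------------------------------------------------------------
# persistence


def save_checkpoint(model: BiMPADRModel, path) -> None:
    """Single-file archive: config JSON plus one .npy entry per weight."""
    path = Path(path)
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("config.json", json.dumps(asdict(model.config)))
        for name, arr in model.weights.items():
            buf = io.BytesIO()
            np.save(buf, arr)
            zf.writestr(f"weights/{name}.npy", buf.getvalue())


def load_checkpoint(path) -> BiMPADRModel:
    path = Path(path)
    with zipfile.ZipFile(path) as zf:
        config = BiMPADRConfig(**json.loads(zf.read("config.json")))
        weights = {}
        for info in zf.namelist():
            if info.startswith("weights/") and info.endswith(".npy"):
                name = info[len("weights/"):-len(".npy")]
                weights[name] = np.load(io.BytesIO(zf.read(info)))
    return BiMPADRModel(config, weights)


def write_predictions(path, drug_ids, adr_ids, scores) -> None:
    pd.DataFrame(
        {"drug_id": drug_ids, "adr_id": adr_ids, "score": scores}
    ).to_csv(path, sep="\t", index=False)
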