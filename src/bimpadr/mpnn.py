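"""Single-iteration bipartite attention message passing.

One round of information propagation over the drug-ADR bipartite graph turns
each ADR's binary gene-association profile x_v into an embedding h_v that
fuses the gene-expression signatures x_u of the drugs known to cause it:

    e_(u,v)   = LeakyReLU( a . [W_u x_u || W_v x_v] )        attention logit
    alpha_(u,v) = softmax over the ADR's drug neighborhood of e
    m_v       = sum_u alpha_(u,v) W_u x_u                     message
    h_v       = W_v x_v + ReLU(m_v)                           update (self-loop)

The projections W_u (P x S) and W_v (Q x S), and the attention vector a
(length 2S), are the learnable parameters.  A single iteration (T = 1) is
performed; the layer is never stacked.

Two documented deviations from a literal reading of the printed equations are
controlled by flags: ``message_form="literal"`` makes the message
sum alpha * W_v x_v, which collapses to W_v x_v because the attention weights
sum to one and therefore carries no drug information; the default
"conventional" form aggregates the drug projections as in standard graph
attention.  The attention normalizer is a true softmax (exponential in both
numerator and denominator, with max subtraction for stability).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._autodiff import Tensor
from .data import BipartiteDataset

__all__ = [
    "MPNNParams",
    "ADREmbedding",
    "attention_coefficients",
    "aggregate_message",
    "update_adr",
    "embed_adrs",
    "embed_adrs_tape",
]

MESSAGE_FORMS = ("conventional", "literal")


@dataclass
class MPNNParams:
    """Learnable weights and behavioral flags of the message-passing layer."""

    W_u: np.ndarray  # (P, S) drug-expression projection
    W_v: np.ndarray  # (Q, S) ADR-feature projection
    attn: np.ndarray  # (2S,) attention vector
    leaky_slope: float = 0.01
    self_loop: bool = True
    message_form: str = "conventional"

    def __post_init__(self):
        self.W_u = np.asarray(self.W_u, dtype=np.float64)
        self.W_v = np.asarray(self.W_v, dtype=np.float64)
        self.attn = np.asarray(self.attn, dtype=np.float64)
        s = self.W_u.shape[1]
        if self.W_v.shape[1] != s:
            raise ValueError("W_u and W_v must share the latent dimension S")
        if self.attn.shape != (2 * s,):
            raise ValueError(f"attention vector must have length 2S={2 * s}")
        if s < 1:
            raise ValueError("latent dimension S must be >= 1")
        if self.leaky_slope <= 0:
            raise ValueError("leaky_slope must be positive")
        if self.message_form not in MESSAGE_FORMS:
            raise ValueError(f"message_form must be one of {MESSAGE_FORMS}")

    @property
    def latent_dim(self) -> int:
        return self.W_u.shape[1]


@dataclass
class ADREmbedding:
    """Row j is the propagated feature vector h_vj of ADR j."""

    h: np.ndarray  # (N, S)
    adr_ids: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        ids = self.adr_ids or [str(j) for j in range(self.h.shape[0])]
        df = pd.DataFrame(
            self.h, index=ids,
            columns=[f"s{k}" for k in range(self.h.shape[1])],
        )
        df.index.name = "adr_id"
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def _leaky(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x > 0, x, slope * x)


def attention_coefficients(
    params: MPNNParams, x_v: np.ndarray, neighbors: list[np.ndarray]
) -> np.ndarray:
    """Softmax attention weights of one ADR over its drug neighborhood."""
    if len(neighbors) == 0:
        raise ValueError("attention undefined for an empty neighborhood")
    pv = params.W_v.T @ np.asarray(x_v, dtype=np.float64)
    s = params.latent_dim
    logits = np.array(
        [
            _leaky(
                params.attn[:s] @ (params.W_u.T @ np.asarray(x_u, dtype=np.float64))
                + params.attn[s:] @ pv,
                params.leaky_slope,
            )
            for x_u in neighbors
        ]
    )
    logits -= logits.max()
    w = np.exp(logits)
    return w / w.sum()


def aggregate_message(
    params: MPNNParams,
    x_v: np.ndarray,
    neighbors: list[np.ndarray],
    weights: np.ndarray,
) -> np.ndarray:
    """Attention-weighted message m_v (length S) from the drug neighborhood."""
    weights = np.asarray(weights, dtype=np.float64)
    if len(weights) != len(neighbors):
        raise ValueError("weights and neighbors differ in length")
    if params.message_form == "conventional":
        proj = np.stack([params.W_u.T @ np.asarray(x, np.float64) for x in neighbors])
    else:  # literal printed form: every term is the ADR's own projection
        pv = params.W_v.T @ np.asarray(x_v, dtype=np.float64)
        proj = np.broadcast_to(pv, (len(neighbors), pv.shape[0]))
    return weights @ proj


def update_adr(params: MPNNParams, x_v: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Vertex update: self-loop term plus rectified message."""
    m = np.asarray(m, dtype=np.float64)
    if m.shape != (params.latent_dim,):
        raise ValueError(f"message must have length S={params.latent_dim}")
    rect = np.maximum(m, 0.0)
    if params.self_loop:
        return params.W_v.T @ np.asarray(x_v, dtype=np.float64) + rect
    return rect


def _edge_inputs(
    params: MPNNParams,
    dataset: BipartiteDataset,
    adr_features: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    edge_drug, edge_adr = dataset.edge_arrays()
    if edge_drug.size:
        missing = sorted(
            {
                dataset.drugs[i].drug_id
                for i in set(edge_drug.tolist())
                if dataset.drugs[i].gene_expression is None
            }
        )
        if missing:
            raise ValueError(f"drugs on edges lack gene expression: {missing}")
    p = params.W_u.shape[0]
    x_u = np.zeros((dataset.n_drugs, p))
    for i in set(edge_drug.tolist()):
        x_u[i] = dataset.drugs[i].gene_expression
    x_v = (
        np.asarray(adr_features, dtype=np.float64)
        if adr_features is not None
        else dataset.adr_feature_matrix()
    )
    if x_v.shape != (dataset.n_adrs, params.W_v.shape[0]):
        raise ValueError(
            f"ADR feature matrix has shape {x_v.shape}, expected "
            f"({dataset.n_adrs}, {params.W_v.shape[0]})"
        )
    return x_u, x_v, edge_drug, edge_adr


def embed_adrs(
    params: MPNNParams,
    dataset: BipartiteDataset,
    adr_features: np.ndarray | None = None,
) -> ADREmbedding:
    """Propagate drug expression into every ADR's embedding (vectorized).

    ``adr_features`` overrides the dataset's ADR-gene matrix (used by the
    zero-feature ablation).  ADRs with no neighboring drug fall back to the
    self-loop term W_v x_v (or the zero vector without the self-loop).
    """
    x_u, x_v, edge_drug, edge_adr = _edge_inputs(params, dataset, adr_features)
    h = _embed_arrays(
        params.W_u, params.W_v, params.attn, x_u, x_v, edge_drug, edge_adr,
        dataset.n_adrs, params.leaky_slope, params.self_loop, params.message_form,
    )
    return ADREmbedding(h=h, adr_ids=dataset.adr_ids)


def _embed_arrays(
    w_u, w_v, attn, x_u, x_v, edge_drug, edge_adr, n_adrs,
    slope, self_loop, message_form,
) -> np.ndarray:
    s = w_u.shape[1]
    u_proj = x_u @ w_u  # (M, S)
    v_proj = x_v @ w_v  # (N, S)
    m = np.zeros((n_adrs, s))
    if edge_drug.size:
        logits = _leaky(
            u_proj[edge_drug] @ attn[:s] + v_proj[edge_adr] @ attn[s:], slope
        )
        # per-ADR softmax with max subtraction
        seg_max = np.full(n_adrs, -np.inf)
        np.maximum.at(seg_max, edge_adr, logits)
        ex = np.exp(logits - seg_max[edge_adr])
        denom = np.zeros(n_adrs)
        np.add.at(denom, edge_adr, ex)
        alpha = ex / denom[edge_adr]
        src = u_proj[edge_drug] if message_form == "conventional" else v_proj[edge_adr]
        np.add.at(m, edge_adr, alpha[:, None] * src)
    h = np.maximum(m, 0.0)
    if self_loop:
        h = v_proj + h
    return h


def embed_adrs_tape(
    w_u: Tensor,
    w_v: Tensor,
    attn: Tensor,
    x_u: np.ndarray,
    x_v: np.ndarray,
    edge_drug: np.ndarray,
    edge_adr: np.ndarray,
    n_adrs: int,
    leaky_slope: float = 0.01,
    self_loop: bool = True,
    message_form: str = "conventional",
) -> Tensor:
    """Differentiable twin of :func:`embed_adrs` over parameter Tensors.

    ``attn`` is shaped (2S, 1) on the tape.  Mirrors `_embed_arrays` exactly;
    agreement between the two paths is pinned by tests.
    """
    s = w_u.data.shape[1]
    u_proj = Tensor(x_u) @ w_u  # (M, S)
    v_proj = Tensor(x_v) @ w_v  # (N, S)
    if edge_drug.size:
        eu = u_proj.gather_rows(edge_drug)  # (E, S)
        ev = v_proj.gather_rows(edge_adr)  # (E, S)
        logits = (eu.concat(ev) @ attn).leaky_relu(leaky_slope)  # (E, 1)
        seg_max = np.full(n_adrs, -np.inf)
        np.maximum.at(seg_max, edge_adr, logits.data[:, 0])
        ex = (logits - Tensor(seg_max[edge_adr][:, None])).exp()
        denom = ex.segment_sum(edge_adr, n_adrs)  # (N, 1)
        alpha = ex / denom.gather_rows(edge_adr)  # (E, 1)
        src = eu if message_form == "conventional" else ev
        m = (alpha * src).segment_sum(edge_adr, n_adrs)  # (N, S)
        h = m.relu()
    else:
        h = Tensor(np.zeros((n_adrs, s)))
    if self_loop:
        h = v_proj + h
    return h
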