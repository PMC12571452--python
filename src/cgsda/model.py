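"""End-to-end association model: encoders, dual branches, decoder, training.

Pipeline: per-side initial features pass through a single-layer MLP
(affine + ReLU) into a shared hidden space; the stacked encodings feed a
ChebNetII spectral branch and a gated graph sequence branch, each with
residual feature injection; the two branch outputs are concatenated and
scored with a sigmoid inner-product decoder,

    Y_hat = sigmoid(F_final F_final^T),

whose snoRNA x disease block gives association probabilities.  Training
minimizes balanced binary cross-entropy: each epoch uses all training
positives plus an equal-size negative sample drawn uniformly from pairs
that are neither positives (train or held-out) nor explicitly excluded
(e.g. a fold's evaluation negatives).

Ablation variants: ``no-cheb`` drops the spectral branch, ``no-gated``
drops the gated branch, ``no-residual`` keeps both branches but disables
the residual injection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Adam, Tensor, concat, dropout, matmul, relu, sigmoid, take_pairs
from .chebnetii import ChebBranch, scaled_laplacian
from .data import AssociationDataset, HeteroGraph, TrainSplit, build_block_adjacency
from .gatedgcn import GatedBranch

__all__ = ["ModelConfig", "CGSDAModel", "TrainedModel", "bce_loss",
           "decode_scores", "train"]

VARIANTS = ("full", "no-cheb", "no-gated", "no-residual")


@dataclass
class ModelConfig:
    """Hyperparameters; defaults are the tuned operating point."""

    cheb_layers: int = 2
    cheb_orders: tuple[int, ...] = (3, 5)
    cheb_halve_k0: bool = False
    gated_layers: int = 3
    gated_seq_len: int = 1
    gated_literal_sum: bool = False
    hidden_dim: int = 64
    learning_rate: float = 5e-4
    weight_decay: float = 1e-4
    dropout: float = 0.01
    epochs: int = 600
    seed: int = 0
    variant: str = "full"

    def __post_init__(self) -> None:
        self.cheb_orders = tuple(self.cheb_orders)
        if len(self.cheb_orders) != self.cheb_layers:
            raise ValueError("cheb_orders length must equal cheb_layers")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cheb_orders"] = list(self.cheb_orders)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-bound, bound, size=(n_in, n_out))


class CGSDAModel:
    """Parameter container plus the differentiable forward pass."""

    def __init__(self, feat_dim_snorna: int, feat_dim_disease: int,
                 config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        h = config.hidden_dim
        residual = config.variant != "no-residual"
        self.W_s = Tensor(_glorot(rng, feat_dim_snorna, h), requires_grad=True)
        self.b_s = Tensor(np.zeros((1, h)), requires_grad=True)
        self.W_d = Tensor(_glorot(rng, feat_dim_disease, h), requires_grad=True)
        self.b_d = Tensor(np.zeros((1, h)), requires_grad=True)
        self.cheb = None
        self.gated = None
        if config.variant != "no-cheb":
            self.cheb = ChebBranch(h, orders=config.cheb_orders,
                                   residual=residual,
                                   halve_k0=config.cheb_halve_k0, rng=rng)
        if config.variant != "no-gated":
            self.gated = GatedBranch(h, n_layers=config.gated_layers,
                                     seq_len=config.gated_seq_len,
                                     residual=residual,
                                     literal_sum=config.gated_literal_sum,
                                     rng=rng)

    def parameters(self) -> list[Tensor]:
        params = [self.W_s, self.b_s, self.W_d, self.b_d]
        if self.cheb is not None:
            params.extend(self.cheb.parameters())
        if self.gated is not None:
            params.extend(self.gated.parameters())
        return params

    def encode(self, F_s0: np.ndarray, F_d0: np.ndarray, *,
               training: bool = False,
               rng: np.random.Generator | None = None) -> Tensor:
        """Per-side single-layer MLP into the shared space, snoRNAs first."""
        rng = rng or np.random.default_rng(0)
        if F_s0.shape[1] != self.W_s.data.shape[0]:
            raise ValueError("snoRNA feature width mismatch with encoder")
        if F_d0.shape[1] != self.W_d.data.shape[0]:
            raise ValueError("disease feature width mismatch with encoder")
        enc_s = relu(matmul(Tensor(F_s0), self.W_s) + self.b_s)
        enc_d = relu(matmul(Tensor(F_d0), self.W_d) + self.b_d)
        stacked = concat([enc_s, enc_d], axis=0)
        return dropout(stacked, self.config.dropout, rng, training)

    def forward(self, graph: HeteroGraph, F_s0: np.ndarray, F_d0: np.ndarray, *,
                training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """Fused node embedding F_final (ChebNetII block first, then gated)."""
        rng = rng or np.random.default_rng(0)
        F_mlp = self.encode(F_s0, F_d0, training=training, rng=rng)
        parts = []
        if self.cheb is not None:
            L_hat = scaled_laplacian(graph.Y)
            parts.append(self.cheb.forward(
                L_hat, F_mlp, training=training,
                dropout_rate=self.config.dropout, rng=rng))
        if self.gated is not None:
            parts.append(self.gated.forward(
                graph.Y, F_mlp, training=training,
                dropout_rate=self.config.dropout, rng=rng))
        return parts[0] if len(parts) == 1 else concat(parts, axis=1)


def decode_scores(fusion) -> "Tensor | np.ndarray":
    """Sigmoid inner-product decoder over all node pairs."""
    tensor_out = isinstance(fusion, Tensor)
    f = fusion if tensor_out else Tensor(fusion)
    out = sigmoid(matmul(f, f.T))
    return out if tensor_out else out.data


def bce_loss(scores, labels) -> "Tensor":
    """Mean binary cross-entropy, probabilities clamped at 1e-12."""
    p = scores if isinstance(scores, Tensor) else Tensor(scores)
    y = np.asarray(labels, dtype=np.float64)
    if p.data.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    pos = p.clamp_min(1e-12).log() * Tensor(y)
    neg = (1.0 - p).clamp_min(1e-12).log() * Tensor(1.0 - y)
    return -((pos + neg).mean())


@dataclass
class TrainedModel:
    """A fitted model bound to its dataset ordering and training split."""

    model: CGSDAModel
    dataset: AssociationDataset
    split: TrainSplit
    F_s0: np.ndarray
    F_d0: np.ndarray
    loss_history: list[float] = field(default_factory=list)

    def score_matrix(self) -> np.ndarray:
        """The decoded snoRNA x disease block (probabilities)."""
        graph = build_block_adjacency(self.dataset, self.split)
        fusion = self.model.forward(graph, self.F_s0, self.F_d0, training=False)
        scores = decode_scores(fusion)
        n_s = self.dataset.n_snorna
        return scores.data[:n_s, n_s:]

    def predict(self, pairs: list[tuple[str, str]]) -> np.ndarray:
        """Scores for (snoRNA id, disease id) pairs, order-preserving."""
        block = self.score_matrix()
        out = np.empty(len(pairs))
        for k, (s, d) in enumerate(pairs):
            out[k] = block[self.dataset.snorna_index(s),
                           self.dataset.disease_index(d)]
        return out


def _negative_pool(dataset: AssociationDataset,
                   exclude_pairs: set[tuple[int, int]]) -> np.ndarray:
    """Flat indices of pairs that are neither positives nor excluded."""
    candidate = dataset.A == 0
    for i, j in exclude_pairs:
        candidate[i, j] = False
    return np.flatnonzero(candidate.ravel())


def train(dataset: AssociationDataset, split: TrainSplit,
          F_s0: np.ndarray, F_d0: np.ndarray, config: ModelConfig, *,
          exclude_negatives: set[tuple[int, int]] | None = None) -> TrainedModel:
    """Fit the model on the split's training positives.

    Per epoch the loss is computed on all training positives plus an
    equal-size set of negatives resampled uniformly from pairs that are
    not positives anywhere in ``dataset`` (held-out positives are thus
    never used as negatives) and not in ``exclude_negatives``.
    """
    split.validate_against(dataset)
    pos = np.argwhere(split.A_train == 1)
    if len(pos) == 0:
        raise ValueError("no training positives")
    graph = build_block_adjacency(dataset, split)
    n_d = dataset.n_disease

    model = CGSDAModel(F_s0.shape[1], F_d0.shape[1], config)
    opt = Adam(model.parameters(), lr=config.learning_rate,
               weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed)

    pool = _negative_pool(dataset, exclude_negatives or set())
    if len(pool) < len(pos):
        raise ValueError("negative pool smaller than positive count")
    n_s = dataset.n_snorna
    pos_rows, pos_cols = pos[:, 0], pos[:, 1] + n_s  # block coordinates
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(pos))])

    trained = TrainedModel(model, dataset, split, F_s0, F_d0)
    for _ in range(config.epochs):
        neg_flat = rng.choice(pool, size=len(pos), replace=False)
        neg_rows = neg_flat // n_d
        neg_cols = neg_flat % n_d + n_s
        rows = np.concatenate([pos_rows, neg_rows])
        cols = np.concatenate([pos_cols, neg_cols])

        fusion = model.forward(graph, F_s0, F_d0, training=True, rng=rng)
        logits = take_pairs(matmul(fusion, fusion.T), rows, cols)
        loss = bce_loss(sigmoid(logits), labels)
        opt.zero_grad()
        loss.backward()
        opt.step()
        trained.loss_history.append(float(loss.data))
    return trained
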