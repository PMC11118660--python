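"""Graph-transformer model for binary drug-sensitivity prediction.

Architecture: three entity-specific linear layers project the drug, cell and
gene RBF similarity matrices into a shared hidden space; the stacked node
features pass through ``n_gnn_layers`` blocks of

    Dropout(ReLU(GraphNorm(GT(X, A))))

where GT is a multi-head dot-product attention layer restricted to graph
neighborhoods (TransformerConv-style, with a root/skip weight); a drug-cell
pair is scored by concatenating the two final embeddings and passing them
through fully connected layers with a sigmoid output, trained with binary
cross-entropy under Adam.

Edge weights of the adjacency participate multiplicatively in the attention
softmax: alpha_ij = w_ij exp(s_ij) / sum_k w_ik exp(s_ik), so per-head
incoming attention still sums to one over each node's neighborhood.
Self-loops with weight 1 are added to every node so isolated nodes (e.g. a
held-out drug under zero padding) attend to themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Parameter, Tensor, concat
from .graph import HeteroGraph

__all__ = [
    "ModelConfig",
    "EdgeSet",
    "AttentionTensor",
    "DrugResponseGT",
    "project_features",
    "bce_loss",
    "train_model",
    "TrainResult",
]


@dataclass
class ModelConfig:
    """Hyperparameters of the model and its training loop."""

    hidden_size: int = 120
    n_gnn_layers: int = 2
    n_fc_layers: int = 2
    n_heads: int = 5
    dropout_rate: float = 0.2
    attn_dropout: float = 0.3
    standardize_features: bool = True
    activation: str = "relu"
    norm: str = "graphnorm"
    optimizer: str = "adam"
    learning_rate: float = 0.005
    weight_decay: float = 1e-4
    epochs: int = 300
    seed: int = 0

    def __post_init__(self):
        if self.n_heads < 1:
            raise ValueError("n_heads must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if not 0 <= self.attn_dropout < 1:
            raise ValueError("attn_dropout must be in [0, 1)")
        if self.hidden_size % self.n_heads != 0:
            raise ValueError(
                f"hidden_size ({self.hidden_size}) must be divisible by "
                f"n_heads ({self.n_heads})"
            )
        if self.activation != "relu":
            raise ValueError("only 'relu' activation is supported")
        if self.norm != "graphnorm":
            raise ValueError("only 'graphnorm' normalization is supported")
        if self.optimizer != "adam":
            raise ValueError("only 'adam' optimization is supported")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EdgeSet:
    """Weighted connectivity of the graph in the dense masked form the
    attention layer consumes: W[i, j] > 0 iff j is an in-neighbor of i, with
    unit-weight self-loops added so every node attends at least to itself."""

    weights: np.ndarray  # (N, N), row = destination/target node
    n_nodes: int

    @staticmethod
    def from_graph(graph: HeteroGraph, add_self_loops: bool = True) -> "EdgeSet":
        W = graph.adjacency.astype(np.float64).copy()
        if add_self_loops:
            idx = np.arange(graph.n_nodes)
            W[idx, idx] = np.maximum(W[idx, idx], 1.0)
        return EdgeSet(weights=W, n_nodes=graph.n_nodes)


@dataclass
class AttentionTensor:
    """Per-layer attention weights: ``weights[i, j, h]`` is the attention
    node i (target) pays to in-neighbor j (source) in head h."""

    weights: np.ndarray  # (N, N, n_heads)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_heads(self) -> int:
        return self.weights.shape[2]

    def to_dense(self) -> np.ndarray:
        return self.weights

    def head_mean_dense(self) -> np.ndarray:
        """(N, N) matrix indexed [target, source], averaged over heads."""
        return self.weights.mean(axis=2)

    def triplets(self):
        """Yield (head, src, dst, weight) for every nonzero attention entry."""
        dst, src, head = np.nonzero(self.weights)
        for i, j, h in zip(dst, src, head):
            yield int(h), int(j), int(i), float(self.weights[i, j, h])


def _standardize_columns(S: np.ndarray) -> np.ndarray:
    S = np.asarray(S, dtype=np.float64)
    if S.shape[0] < 2:
        return S - S.mean(axis=0, keepdims=True)
    mu = S.mean(axis=0, keepdims=True)
    sd = S.std(axis=0, ddof=1, keepdims=True)
    sd = np.where(np.isfinite(sd) & (sd > 0), sd, 1.0)
    return (S - mu) / sd


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class _Linear:
    def __init__(self, rng, n_in: int, n_out: int):
        self.W = Parameter(_glorot(rng, n_in, n_out))
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self):
        return [self.W, self.b]


class _GraphNorm:
    """Graph normalization: learnable mean-shift alpha, scale gamma, bias beta
    per feature, statistics taken over all nodes of the graph."""

    def __init__(self, n_features: int, eps: float = 1e-5):
        self.alpha = Parameter(np.ones(n_features))
        self.gamma = Parameter(np.ones(n_features))
        self.beta = Parameter(np.zeros(n_features))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=0, keepdims=True)
        shifted = x - mu * self.alpha
        var = (shifted * shifted).mean(axis=0, keepdims=True)
        return shifted / ((var + self.eps) ** 0.5) * self.gamma + self.beta

    def parameters(self):
        return [self.alpha, self.gamma, self.beta]


class _GTLayer:
    """Multi-head dot-product graph attention with edge-weighted softmax.

    Dense masked formulation: alpha_ij = w_ij exp(s_ij) / sum_k w_ik exp(s_ik)
    where s = Q K'/sqrt(D) and w is the nonnegative weighted adjacency (zero
    weight excludes a pair). Head outputs are concatenated, linearly mixed,
    and a root/skip weight re-injects the layer input.
    """

    def __init__(self, rng, n_in: int, hidden: int, n_heads: int):
        self.n_heads = n_heads
        self.head_dim = hidden // n_heads
        D = self.head_dim
        self.Wq = [Parameter(_glorot(rng, n_in, D)) for _ in range(n_heads)]
        self.Wk = [Parameter(_glorot(rng, n_in, D)) for _ in range(n_heads)]
        self.Wv = [Parameter(_glorot(rng, n_in, D)) for _ in range(n_heads)]
        self.Wmix = Parameter(_glorot(rng, hidden, hidden))
        self.Wskip = Parameter(_glorot(rng, n_in, hidden))
        self.b = Parameter(np.zeros(hidden))

    def __call__(
        self, x: Tensor, edges: EdgeSet, attn_drop_mask: np.ndarray | None = None
    ) -> tuple[Tensor, AttentionTensor]:
        H, D = self.n_heads, self.head_dim
        N = edges.n_nodes
        W = edges.weights
        edge_mask = W > 0
        head_outs = []
        alphas = np.empty((N, N, H))
        for h in range(H):
            q = x @ self.Wq[h]
            k = x @ self.Wk[h]
            v = x @ self.Wv[h]
            scores = (q @ k.transpose2d()) * (1.0 / np.sqrt(D))  # (N, N)
            # detached stability shift: per-row max over edge positions
            shift = np.where(edge_mask, scores.data, -np.inf).max(axis=1, keepdims=True)
            num = scores.weighted_masked_exp(W, shift)
            alpha = num / num.sum(axis=1, keepdims=True)
            alphas[:, :, h] = alpha.data
            if attn_drop_mask is not None:
                alpha = alpha * Tensor(attn_drop_mask[:, :, h])
            head_outs.append(alpha @ v)
        msg = concat(head_outs, axis=1)  # (N, H*D)
        out = msg @ self.Wmix + x @ self.Wskip + self.b
        return out, AttentionTensor(weights=alphas)

    def parameters(self):
        return [*self.Wq, *self.Wk, *self.Wv, self.Wmix, self.Wskip, self.b]


def project_features(Sd, Sc, Sg, config: ModelConfig, rng=None):
    """Build the feature-projection layers and return them with the stacked
    similarity input. Convenience wrapper used by tests; the model itself owns
    its projections."""
    model = DrugResponseGT(
        n_drugs=Sd.shape[0],
        n_cells=Sc.shape[0],
        n_genes=Sg.shape[0],
        config=config,
    )
    X = model.project(Sd, Sc, Sg)
    return model, X


class DrugResponseGT:
    """The full model: projections, GT stack, FC head."""

    def __init__(self, n_drugs: int, n_cells: int, n_genes: int, config: ModelConfig):
        self.config = config
        self.n_drugs, self.n_cells, self.n_genes = n_drugs, n_cells, n_genes
        rng = np.random.default_rng(config.seed)
        h = config.hidden_size
        self.proj_d = _Linear(rng, n_drugs, h)
        self.proj_c = _Linear(rng, n_cells, h)
        self.proj_g = _Linear(rng, n_genes, h)
        self.gt_layers = [
            _GTLayer(rng, h, h, config.n_heads) for _ in range(config.n_gnn_layers)
        ]
        self.norms = [_GraphNorm(h) for _ in range(config.n_gnn_layers)]
        self.fc_layers = []
        n_in = 2 * h
        for i in range(config.n_fc_layers - 1):
            self.fc_layers.append(_Linear(rng, n_in, h))
            n_in = h
        self.fc_layers.append(_Linear(rng, n_in, 1))
        self._dropout_rng = np.random.default_rng(config.seed + 1)

    # -- parameter plumbing ---------------------------------------------------

    def parameters(self) -> list[Parameter]:
        params = []
        for mod in (self.proj_d, self.proj_c, self.proj_g, *self.gt_layers,
                    *self.norms, *self.fc_layers):
            params.extend(mod.parameters())
        return params

    def state_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "params": [p.data.copy() for p in self.parameters()],
            "dims": (self.n_drugs, self.n_cells, self.n_genes),
        }

    def load_state(self, state: dict) -> None:
        for p, d in zip(self.parameters(), state["params"]):
            p.data = np.asarray(d, dtype=np.float64).copy()

    # -- forward passes -------------------------------------------------------

    def project(self, Sd, Sc, Sg) -> Tensor:
        """Unified feature matrix: projected drug rows, then cell, then gene.

        With ``standardize_features`` (default), similarity columns are
        z-scored before projection. RBF similarities concentrate near 1, so
        raw projected features start nearly collinear; centering is absorbed
        into the affine projection's function class but conditions training.
        """
        for name, S, n in (("Sd", Sd, self.n_drugs), ("Sc", Sc, self.n_cells),
                           ("Sg", Sg, self.n_genes)):
            if S.shape != (n, n):
                raise ValueError(f"{name} has shape {S.shape}, expected ({n}, {n})")
        if self.config.standardize_features:
            Sd, Sc, Sg = (_standardize_columns(S) for S in (Sd, Sc, Sg))
        xd = self.proj_d(Tensor(Sd))
        xc = self.proj_c(Tensor(Sc))
        xg = self.proj_g(Tensor(Sg))
        return concat([xd, xc, xg], axis=0)

    def gt_forward(
        self, X: Tensor, edges: EdgeSet, training: bool = False
    ) -> tuple[Tensor, list[AttentionTensor]]:
        """Stacked Dropout(ReLU(GraphNorm(GT(.)))) blocks; returns final node
        embeddings and the per-layer attention tensors."""
        z = X
        attns = []
        p = self.config.dropout_rate
        pa = self.config.attn_dropout
        for i, (layer, norm) in enumerate(zip(self.gt_layers, self.norms)):
            drop_mask = None
            if training and pa > 0:
                shape = (edges.n_nodes, edges.n_nodes, self.config.n_heads)
                drop_mask = (self._dropout_rng.random(shape) >= pa) / (1.0 - pa)
            z, attn = layer(z, edges, attn_drop_mask=drop_mask)
            z = norm(z).relu()
            if training and p > 0:
                mask = (self._dropout_rng.random(z.shape) >= p) / (1.0 - p)
                z = z * Tensor(mask)
            if not np.isfinite(z.data).all():
                raise FloatingPointError(f"non-finite activations in GT block {i}")
            attns.append(attn)
        return z, attns

    def predict_pairs(self, Z2: Tensor, pairs) -> Tensor:
        """Sigmoid scores for (drug_idx, cell_idx) pairs (local indices)."""
        pairs = np.asarray(pairs, dtype=np.intp)
        if pairs.size == 0:
            raise ValueError("empty pair list")
        d, c = pairs[:, 0], pairs[:, 1]
        if (d < 0).any() or (d >= self.n_drugs).any():
            raise IndexError("drug index out of range")
        if (c < 0).any() or (c >= self.n_cells).any():
            raise IndexError("cell index out of range")
        zd = Z2.gather_rows(d)
        zc = Z2.gather_rows(self.n_drugs + c)
        h = concat([zd, zc], axis=1)
        for fc in self.fc_layers[:-1]:
            h = fc(h).relu()
        logits = self.fc_layers[-1](h)
        return logits.reshape(len(pairs)).sigmoid()

    def forward(self, Sd, Sc, Sg, edges: EdgeSet, pairs, training: bool = False):
        X = self.project(Sd, Sc, Sg)
        Z2, attns = self.gt_forward(X, edges, training=training)
        return self.predict_pairs(Z2, pairs), Z2, attns


def bce_loss(y, y_hat, eps: float = 1e-7):
    """Binary cross-entropy; probabilities clamped into [eps, 1-eps]."""
    y = np.asarray(y, dtype=np.float64) if not isinstance(y, Tensor) else y.data
    if y.size == 0:
        raise ValueError("empty input to bce_loss")
    y_hat = Tensor._as_tensor(y_hat)
    if y_hat.data.size != y.size:
        raise ValueError("y and y_hat lengths differ")
    # clamp via relu composition: max(x, eps) then min(., 1-eps)
    clipped = (y_hat - eps).relu() + eps
    clipped = -(((1.0 - eps) - clipped).relu()) + (1.0 - eps)
    yt = Tensor(y)
    per = yt * clipped.log() + (1.0 - yt) * (1.0 - clipped).log()
    return -per.mean()


class _Adam:
    def __init__(self, params, lr: float, weight_decay: float = 0.0,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.wd * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


@dataclass
class TrainResult:
    """Trained model plus its loss trace and eval-mode attention capture."""

    model: DrugResponseGT
    losses: list[float]
    attention: list[AttentionTensor]
    embeddings: np.ndarray
    edges: EdgeSet = field(repr=False, default=None)


def train_model(
    graph: HeteroGraph,
    Sd: np.ndarray,
    Sc: np.ndarray,
    Sg: np.ndarray,
    train_pairs,
    train_labels,
    config: ModelConfig,
) -> TrainResult:
    """Full-batch training on labeled (drug, cell) pairs.

    ``train_pairs`` are local (drug_idx, cell_idx) tuples whose labels are
    0/1 (uncertain pairs must already be excluded); masked test pairs must
    carry no edge in the graph's Adc block. Attention is captured on a final
    eval-mode pass, unaffected by dropout.
    """
    y = np.asarray(train_labels, dtype=np.float64)
    if not np.isin(y, [0.0, 1.0]).all():
        raise ValueError("train labels must be 0/1 (exclude uncertain pairs)")
    model = DrugResponseGT(graph.n_drugs, graph.n_cells, graph.n_genes, config)
    edges = EdgeSet.from_graph(graph)
    opt = _Adam(model.parameters(), lr=config.learning_rate,
                weight_decay=config.weight_decay)
    losses: list[float] = []
    for epoch in range(config.epochs):
        opt.zero_grad()
        y_hat, _, _ = model.forward(Sd, Sc, Sg, edges, train_pairs, training=True)
        loss = bce_loss(y, y_hat)
        if not np.isfinite(loss.data):
            raise FloatingPointError(f"divergent loss at epoch {epoch}")
        loss.backward()
        opt.step()
        losses.append(float(loss.data))
    # eval-mode capture of embeddings and attention
    X = model.project(Sd, Sc, Sg)
    Z2, attns = model.gt_forward(X, edges, training=False)
    return TrainResult(
        model=model, losses=losses, attention=attns,
        embeddings=Z2.data.copy(), edges=edges,
    )
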