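"""The gated graph attention model.

Each layer performs masked multi-head attention over every node's 1-hop
neighbourhood (*layer-in* attention):

    b_ij = LeakyReLU(a^T [W h_i || W h_j])          raw score, j in N(i)
    alpha_ij = softmax_j(b_ij)                      normalised over N(i)
    m_i = sigma(sum_j alpha_ij W h_j)               aggregated embedding

with K heads either concatenated (hidden layers) or averaged (output layer).
Gated layers then filter what flows between layers through a GRU-style chain
(*layer-out* attention):

    z_i = sigmoid(Wz m_i + Uz h_i)                  update gate
    r_i = sigmoid(Wr m_i + Ur h_i)                  reset gate
    n_i = tanh(Wn m_i + Un (r_i . h_i))             new information
    h'_i = (1 - z_i) . h_i + z_i . n_i              convex combination

The reset gate lives in the layer-input space so it masks the incoming
embedding elementwise; when the layer input and gate space differ in width
(the output layer), a learned projection P maps h_i into the gate space
before the final combination.  Stacking one ungated layer followed by gated
layers gives a receptive field of exactly one hop per layer, with the gates
deciding how much multi-hop information survives.

Everything is written against ``autograd.numpy`` so that the training loop
can differentiate the full forward pass; a deliberately naive per-node,
per-neighbour reference implementation (:func:`dense_oracle_forward`) is
provided for cross-checking.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import autograd.numpy as anp
import numpy as np

from .errors import ConfigError, ValidationError

__all__ = [
    "LayerConfig",
    "ModelConfig",
    "default_model_config",
    "init_params",
    "raw_attention",
    "normalize_attention",
    "aggregate",
    "multi_head_combine",
    "apply_activation",
    "compute_gates",
    "new_information",
    "gate_combine",
    "ggat_layer",
    "ggat_forward",
    "dense_oracle_forward",
    "save_model",
    "load_model",
]

_MASK_FILL = -1e30  # exp(x - rowmax) underflows to exactly 0.0 for masked entries

_ACTIVATIONS = ("softmax", "elu", "sigmoid", "identity")
_INTERLAYER = ("logsoftmax", "elu", "identity")


@dataclass
class LayerConfig:
    """Configuration of one attention layer.

    ``combine`` is ``"concat"`` for hidden layers and must be ``"average"``
    on the endmost attention layer; ``activation`` is the nonlinearity sigma
    applied to the aggregated embedding (feature-wise softmax by default).
    """

    heads: int = 8
    out_dim: int = 8
    combine: str = "concat"
    gated: bool = False
    activation: str = "softmax"
    leaky_slope: float = 0.2

    def __post_init__(self) -> None:
        if self.heads < 1 or self.out_dim < 1:
            raise ConfigError("heads and out_dim must be positive")
        if self.combine not in ("concat", "average"):
            raise ConfigError(f"unknown combine mode {self.combine!r}")
        if self.activation not in _ACTIVATIONS:
            raise ConfigError(f"unknown activation {self.activation!r}")

    @property
    def combined_dim(self) -> int:
        return self.heads * self.out_dim if self.combine == "concat" else self.out_dim


@dataclass
class ModelConfig:
    """Stack of layer configs plus the between-layer activation."""

    layers: list[LayerConfig] = field(default_factory=list)
    interlayer: str = "elu"

    def __post_init__(self) -> None:
        if not self.layers:
            raise ConfigError("a model needs at least one layer")
        if self.interlayer not in _INTERLAYER:
            raise ConfigError(f"unknown interlayer activation {self.interlayer!r}")
        if self.layers[-1].combine != "average":
            raise ConfigError("the endmost attention layer must average its heads")


def default_model_config(
    n_classes: int,
    hidden: int = 8,
    heads: int = 8,
    n_layers: int = 3,
    activation: str = "softmax",
    interlayer: str = "elu",
) -> ModelConfig:
    """The default stack: one ungated layer, then gated layers, the last of
    which averages its heads down to ``n_classes`` outputs."""
    if n_classes < 2:
        raise ConfigError("need at least two classes")
    if n_layers < 1:
        raise ConfigError("need at least one layer")
    layers = []
    for i in range(n_layers - 1):
        layers.append(
            LayerConfig(heads, hidden, "concat", gated=(i > 0), activation=activation)
        )
    layers.append(
        LayerConfig(heads, n_classes, "average", gated=(n_layers > 1), activation=activation)
    )
    return ModelConfig(layers, interlayer)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in = shape[0] if len(shape) > 1 else shape[0]
    fan_out = shape[1] if len(shape) > 1 else 1
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_params(config: ModelConfig, n_features: int, seed: int = 0) -> dict:
    """Glorot-uniform initialisation of every head and gate matrix."""
    rng = np.random.default_rng(seed)
    layers = []
    f_in = n_features
    for cfg in config.layers:
        heads = [
            {"W": _glorot(rng, (f_in, cfg.out_dim)), "a": _glorot(rng, (2 * cfg.out_dim,))}
            for _ in range(cfg.heads)
        ]
        layer: dict = {"heads": heads}
        if cfg.gated:
            m = cfg.combined_dim
            gates = {
                "Wz": _glorot(rng, (m, m)),
                "Uz": _glorot(rng, (f_in, m)),
                "Wr": _glorot(rng, (m, f_in)),
                "Ur": _glorot(rng, (f_in, f_in)),
                "Wn": _glorot(rng, (m, m)),
                "Un": _glorot(rng, (f_in, m)),
            }
            if f_in != m:
                gates["P"] = _glorot(rng, (f_in, m))
            layer["gates"] = gates
        layers.append(layer)
        f_in = cfg.combined_dim
    return {"layers": layers}


# ---------------------------------------------------------------------------
# elementwise pieces (autograd-traceable)

def _leaky_relu(x, slope):
    return anp.where(x >= 0, x, slope * x)


def _sigmoid(x):
    return 0.5 * (anp.tanh(0.5 * x) + 1.0)


def _log_softmax(H):
    m = anp.max(H, axis=1, keepdims=True)
    return H - m - anp.log(anp.sum(anp.exp(H - m), axis=1, keepdims=True))


def apply_activation(x, name: str):
    """Nonlinearity sigma over per-node embeddings (rows)."""
    if name == "softmax":
        m = anp.max(x, axis=1, keepdims=True)
        e = anp.exp(x - m)
        return e / anp.sum(e, axis=1, keepdims=True)
    if name == "elu":
        return anp.where(x > 0, x, anp.exp(anp.minimum(x, 0.0)) - 1.0)
    if name == "sigmoid":
        return _sigmoid(x)
    if name == "identity":
        return x
    raise ConfigError(f"unknown activation {name!r}")


# ---------------------------------------------------------------------------
# layer-in attention

def raw_attention(H, head: dict, A: np.ndarray, leaky_slope: float = 0.2):
    """Masked raw attention scores b_ij for one head.

    Entries outside the adjacency support are filled with a large negative
    constant so their softmax weight underflows to exactly zero.
    """
    W, a = head["W"], head["a"]
    if H.shape[1] != W.shape[0]:
        raise ValidationError(
            f"feature dim {H.shape[1]} incompatible with W {W.shape}"
        )
    f_out = W.shape[1]
    Wh = anp.dot(H, W)
    left = anp.dot(Wh, a[:f_out])    # a^T (W h_i) contribution
    right = anp.dot(Wh, a[f_out:])   # a^T (W h_j) contribution
    B = _leaky_relu(left[:, None] + right[None, :], leaky_slope)
    return anp.where(A > 0, B, _MASK_FILL)


def normalize_attention(B, A: np.ndarray):
    """Row-wise softmax of masked scores over each node's neighbourhood."""
    mask = (A > 0).astype(float)
    row_max = anp.max(B, axis=1, keepdims=True)
    E = anp.exp(B - row_max) * mask
    return E / anp.sum(E, axis=1, keepdims=True)


def aggregate(alpha, H, head: dict, activation: str = "identity"):
    """Attention-weighted neighbour aggregation m_i = sigma(sum_j alpha_ij W h_j)."""
    out = anp.dot(alpha, anp.dot(H, head["W"]))
    return apply_activation(out, activation)


def multi_head_combine(per_head: list, mode: str):
    """Concatenate or average the per-head embeddings."""
    shapes = {tuple(np.shape(m)) for m in per_head}
    if len(shapes) != 1:
        raise ValidationError(f"mixed per-head shapes: {shapes}")
    if mode == "concat":
        return anp.concatenate(per_head, axis=1)
    if mode == "average":
        return sum(per_head) / len(per_head)
    raise ConfigError(f"unknown combine mode {mode!r}")


# ---------------------------------------------------------------------------
# layer-out gating

def compute_gates(m, h, gp: dict):
    """Update and reset gates; both strictly inside (0, 1)."""
    z = _sigmoid(anp.dot(m, gp["Wz"]) + anp.dot(h, gp["Uz"]))
    r = _sigmoid(anp.dot(m, gp["Wr"]) + anp.dot(h, gp["Ur"]))
    return z, r


def new_information(m, h, r, gp: dict):
    """Candidate update n_i = tanh(Wn m_i + Un (r_i . h_i))."""
    return anp.tanh(anp.dot(m, gp["Wn"]) + anp.dot(r * h, gp["Un"]))


def gate_combine(h, n, z):
    """Convex combination h' = (1 - z) . h + z . n (h already in gate space)."""
    return (1.0 - z) * h + z * n


def ggat_layer(H, A: np.ndarray, layer_params: dict, cfg: LayerConfig):
    """One full layer: masked multi-head attention, then (optionally) gating."""
    per_head_raw = []
    for head in layer_params["heads"]:
        B = raw_attention(H, head, A, cfg.leaky_slope)
        alpha = normalize_attention(B, A)
        per_head_raw.append(aggregate(alpha, H, head, activation="identity"))
    if cfg.combine == "concat":
        m = multi_head_combine(
            [apply_activation(s, cfg.activation) for s in per_head_raw], "concat"
        )
    else:
        # the endmost layer applies sigma after averaging the heads
        m = apply_activation(multi_head_combine(per_head_raw, "average"), cfg.activation)
    if not cfg.gated:
        return m
    gp = layer_params["gates"]
    z, r = compute_gates(m, H, gp)
    n = new_information(m, H, r, gp)
    h_proj = anp.dot(H, gp["P"]) if "P" in gp else H
    return gate_combine(h_proj, n, z)


def attention_coefficients(
    X, A: np.ndarray, params: dict, config: ModelConfig
) -> list[list[np.ndarray]]:
    """Replay the forward pass and collect every layer's per-head normalised
    attention matrices (for inspection and invariant checks)."""
    coeffs: list[list[np.ndarray]] = []
    H = X
    last = len(config.layers) - 1
    for i, (lp, cfg) in enumerate(zip(params["layers"], config.layers)):
        coeffs.append(
            [
                normalize_attention(raw_attention(H, head, A, cfg.leaky_slope), A)
                for head in lp["heads"]
            ]
        )
        H = ggat_layer(H, A, lp, cfg)
        if i == last or config.interlayer == "logsoftmax":
            H = _log_softmax(H)
        elif config.interlayer == "elu":
            H = apply_activation(H, "elu")
    return coeffs


def ggat_forward(X, A: np.ndarray, params: dict, config: ModelConfig):
    """Full forward pass: N x C log-probabilities (each row logsumexps to 0)."""
    if len(params["layers"]) != len(config.layers):
        raise ValidationError("parameter/config layer count mismatch")
    H = X
    last = len(config.layers) - 1
    for i, (lp, cfg) in enumerate(zip(params["layers"], config.layers)):
        H = ggat_layer(H, A, lp, cfg)
        if i == last:
            H = _log_softmax(H)
        elif config.interlayer == "logsoftmax":
            H = _log_softmax(H)
        elif config.interlayer == "elu":
            H = apply_activation(H, "elu")
    return H


# ---------------------------------------------------------------------------
# reference implementation

def dense_oracle_forward(X, A, params: dict, config: ModelConfig):
    """Reference forward pass with explicit per-node, per-neighbour loops.

    Computes the same mathematics as :func:`ggat_forward` using plain Python
    floats, dict-based neighbourhoods and no masking or vectorisation tricks.
    Intended for small graphs (N <= 64) in tests.
    """
    X = np.asarray(X, float)
    A = np.asarray(A, float)
    N = X.shape[0]
    H = [[float(v) for v in row] for row in X]

    def mat(x):  # parameter arrays -> nested lists of floats
        return np.asarray(x, float).tolist()

    def sigma_vec(v, name):
        if name == "softmax":
            mx = max(v)
            e = [math.exp(t - mx) for t in v]
            s = sum(e)
            return [t / s for t in e]
        if name == "elu":
            return [t if t > 0 else math.exp(t) - 1.0 for t in v]
        if name == "sigmoid":
            return [1.0 / (1.0 + math.exp(-t)) for t in v]
        return list(v)

    def logsoftmax_vec(v):
        mx = max(v)
        s = sum(math.exp(t - mx) for t in v)
        return [t - mx - math.log(s) for t in v]

    def matvec(M, v):  # v (len f_in) times M (f_in x f_out)
        return [sum(v[f] * M[f][c] for f in range(len(v))) for c in range(len(M[0]))]

    last = len(config.layers) - 1
    for li, (lp, cfg) in enumerate(zip(params["layers"], config.layers)):
        f_in = len(H[0])
        per_head = []
        for head in lp["heads"]:
            W, a = mat(head["W"]), mat(head["a"])
            fp = len(W[0])
            Wh = [matvec(W, H[i]) for i in range(N)]
            out = []
            for i in range(N):
                neigh = [j for j in range(N) if A[i][j] != 0]
                raw = {}
                for j in neigh:
                    s = sum(a[c] * Wh[i][c] for c in range(fp)) + sum(
                        a[fp + c] * Wh[j][c] for c in range(fp)
                    )
                    raw[j] = s if s >= 0 else cfg.leaky_slope * s
                mx = max(raw.values())
                ex = {j: math.exp(raw[j] - mx) for j in neigh}
                tot = sum(ex.values())
                out.append(
                    [sum(ex[j] / tot * Wh[j][c] for j in neigh) for c in range(fp)]
                )
            per_head.append(out)

        K = len(per_head)
        if cfg.combine == "concat":
            m_rows = [
                [v for h_out in per_head for v in sigma_vec(h_out[i], cfg.activation)]
                for i in range(N)
            ]
        else:
            m_rows = [
                sigma_vec(
                    [
                        sum(per_head[k][i][c] for k in range(K)) / K
                        for c in range(len(per_head[0][0]))
                    ],
                    cfg.activation,
                )
                for i in range(N)
            ]

        if cfg.gated:
            gp = {k: mat(v) for k, v in lp["gates"].items()}
            new_H = []
            for i in range(N):
                m_i, h_i = m_rows[i], H[i]
                z = [
                    1.0 / (1.0 + math.exp(-(u + v)))
                    for u, v in zip(matvec(gp["Wz"], m_i), matvec(gp["Uz"], h_i))
                ]
                r = [
                    1.0 / (1.0 + math.exp(-(u + v)))
                    for u, v in zip(matvec(gp["Wr"], m_i), matvec(gp["Ur"], h_i))
                ]
                rh = [r[f] * h_i[f] for f in range(f_in)]
                n = [
                    math.tanh(u + v)
                    for u, v in zip(matvec(gp["Wn"], m_i), matvec(gp["Un"], rh))
                ]
                h_p = matvec(gp["P"], h_i) if "P" in gp else h_i
                new_H.append(
                    [(1.0 - z[c]) * h_p[c] + z[c] * n[c] for c in range(len(n))]
                )
            H = new_H
        else:
            H = m_rows

        if li == last or config.interlayer == "logsoftmax":
            H = [logsoftmax_vec(row) for row in H]
        elif config.interlayer == "elu":
            H = [sigma_vec(row, "elu") for row in H]
    return np.array(H)


# ---------------------------------------------------------------------------
# serialization

def save_model(params: dict, config: ModelConfig, path: str | Path) -> Path:
    """Write the model to a single JSON container (version tag, layer configs,
    named arrays as nested lists)."""
    path = Path(path)
    doc = {
        "format": "ggat-model",
        "version": 1,
        "interlayer": config.interlayer,
        "layers": [
            {
                "config": asdict(cfg),
                "heads": [
                    {"W": h["W"].tolist(), "a": h["a"].tolist()} for h in lp["heads"]
                ],
                **(
                    {"gates": {k: v.tolist() for k, v in lp["gates"].items()}}
                    if "gates" in lp
                    else {}
                ),
            }
            for lp, cfg in zip(params["layers"], config.layers)
        ],
    }
    path.write_text(json.dumps(doc) + "\n")
    return path


def load_model(path: str | Path) -> tuple[dict, ModelConfig]:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "ggat-model":
        raise ValidationError(f"{path} is not a ggat model container")
    layers, cfgs = [], []
    for entry in doc["layers"]:
        cfgs.append(LayerConfig(**entry["config"]))
        lp: dict = {
            "heads": [
                {"W": np.array(h["W"]), "a": np.array(h["a"])} for h in entry["heads"]
            ]
        }
        if "gates" in entry:
            lp["gates"] = {k: np.array(v) for k, v in entry["gates"].items()}
        layers.append(lp)
    return {"layers": layers}, ModelConfig(cfgs, doc["interlayer"])
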