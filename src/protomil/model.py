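"""Prototype-guided MIL model.

Forward pass for one bag:

1. (training only) dual instance sampling: uniform random subset of R
   instances, then the S instances with the highest selector scores
   (a linear layer on the raw features, placed before the shared
   projection).
2. A weight-shared linear projection ``f_p`` maps instances and
   prototypes from d1 to d3.
3. Prototypes act as Query, instances as Key, through linear maps
   ``w_q``/``w_k``; the measurement matrix is the pairwise cosine
   ``M[k, j] = <Q_k, K_j> / (||Q_k|| ||K_j||)``, an (L x n) matrix that
   serves directly as the bag representation.
4. A classifier head reduces M over the instance axis and emits a
   two-class probability vector (mean+MLP, attention-weighted sum+MLP,
   or a transformer encoder over the columns with a class token).

Prototype modes: "cluster" (frozen embeddings from the clustering
module), "random_fixed" (frozen uniform random vectors),
"random_learnable" (uniform random init, optimized with the model), and
"none" (queries are the projected instances themselves — self-attention;
the n x n measurement is mean-pooled over the query axis to a 1 x n
effective measurement so the head input width stays fixed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .autograd import Tensor, concat, softmax
from .bags import FeatureBag
from .clustering import PrototypeSet
from .errors import ConfigError, DimensionError, ParameterError

__all__ = [
    "ModelConfig",
    "ModelState",
    "MeasurementMatrix",
    "PredictionResult",
    "R_GRID",
    "init_model_state",
    "random_sample",
    "instance_scores",
    "mine_instances",
    "measurement",
    "head_mean",
    "head_attention",
    "head_transformer",
    "forward",
]

# Random-sampling sizes explored in the source study (median-scaled grid)
# and the mining size found optimal there.
R_GRID = (10_000, 5_000, 2_000, 1_000, 500, 200)
DEFAULT_S = 500

PROTOTYPE_MODES = ("cluster", "random_fixed", "random_learnable", "none")
HEADS = ("mean", "attention", "transformer")

_COS_EPS = 1e-24  # inside sqrt: zero-norm vectors yield cosine 0, not NaN


@dataclass(frozen=True)
class ModelConfig:
    d1: int = 64
    d3: int = 256
    prototype_mode: str = "cluster"
    head: str = "mean"
    R: int = R_GRID[0]
    S: int = DEFAULT_S
    mlp_hidden: int = 128
    n_heads: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.prototype_mode not in PROTOTYPE_MODES:
            raise ConfigError(f"prototype_mode must be one of {PROTOTYPE_MODES}")
        if self.head not in HEADS:
            raise ConfigError(f"head must be one of {HEADS}")
        if self.S > self.R:
            raise ConfigError("S (mined count) must not exceed R (random-sample count)")
        if self.d3 < 1 or self.d1 < 1:
            raise ConfigError("d1 and d3 must be >= 1")


@dataclass
class MeasurementMatrix:
    """The (L x n) cosine cross-attention matrix for one bag."""

    values: np.ndarray
    bag_id: str = ""

    def __post_init__(self):
        v = self.values
        if not np.isfinite(v).all() or (np.abs(v) > 1.0 + 1e-12).any():
            raise ParameterError("measurement entries must be finite and in [-1, 1]")

    @property
    def L(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]


@dataclass
class PredictionResult:
    bag_id: str
    prob_positive: float
    probs: np.ndarray  # (2,)
    measurement: MeasurementMatrix
    used_indices: np.ndarray  # original instance indices fed forward
    _probs_t: Tensor | None = field(default=None, repr=False)


@dataclass
class ModelState:
    """All learnable parameters plus the prototype bank and its mode."""

    params: dict[str, Tensor]
    prototypes: Tensor | None
    config: ModelConfig
    prototype_learnable: bool = False
    schema_version: int = 1

    @property
    def L(self) -> int:
        """Width of the head input (1 in self-attention mode)."""
        return 1 if self.config.prototype_mode == "none" else self.prototypes.shape[0]

    def trainable(self) -> list[Tensor]:
        out = list(self.params.values())
        if self.prototype_learnable and self.prototypes is not None:
            out.append(self.prototypes)
        return out

    def clone_arrays(self) -> dict[str, np.ndarray]:
        arrs = {k: v.data.copy() for k, v in self.params.items()}
        if self.prototypes is not None:
            arrs["__prototypes__"] = self.prototypes.data.copy()
        return arrs

    def load_arrays(self, arrs: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            v.data = arrs[k].copy()
        if self.prototypes is not None:
            self.prototypes.data = arrs["__prototypes__"].copy()


def _linear_init(rng, fan_in, fan_out):
    std = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.standard_normal((fan_in, fan_out)) * std


def init_model_state(
    config: ModelConfig,
    prototypes: PrototypeSet | np.ndarray | None = None,
    n_prototypes: int | None = None,
) -> ModelState:
    """Build a freshly initialized :class:`ModelState`.

    cluster mode requires `prototypes` (frozen); the random modes draw
    ``n_prototypes`` rows from a uniform distribution on
    ``[-1/sqrt(d1), 1/sqrt(d1)]`` (frozen for "random_fixed", learnable
    for "random_learnable"); "none" takes no prototypes.
    """
    rng = np.random.default_rng(config.seed)
    mode = config.prototype_mode
    proto_t: Tensor | None = None
    learnable = False
    if mode == "cluster":
        if prototypes is None:
            raise ConfigError("cluster mode requires a PrototypeSet")
        emb = prototypes.embeddings if isinstance(prototypes, PrototypeSet) else prototypes
        emb = np.asarray(emb, dtype=np.float64)
        if emb.shape[1] != config.d1:
            raise DimensionError(
                f"prototype width {emb.shape[1]} does not match model d1={config.d1}"
            )
        proto_t = Tensor(emb.copy())
    elif mode in ("random_fixed", "random_learnable"):
        if n_prototypes is None:
            if prototypes is not None:
                n_prototypes = (
                    prototypes.L if isinstance(prototypes, PrototypeSet) else len(prototypes)
                )
            else:
                raise ConfigError(f"{mode} mode requires n_prototypes")
        lim = 1.0 / np.sqrt(config.d1)
        emb = rng.uniform(-lim, lim, size=(n_prototypes, config.d1))
        learnable = mode == "random_learnable"
        proto_t = Tensor(emb, requires_grad=learnable)

    d1, d3, h = config.d1, config.d3, config.mlp_hidden
    L = 1 if mode == "none" else proto_t.data.shape[0]
    p: dict[str, Tensor] = {}

    def add(name, arr):
        p[name] = Tensor(arr, requires_grad=True)

    add("sel_w", _linear_init(rng, d1, 1))
    add("sel_b", np.zeros(1))
    add("fp_w", _linear_init(rng, d1, d3))
    add("fp_b", np.zeros(d3))
    add("wq_w", _linear_init(rng, d3, d3))
    add("wq_b", np.zeros(d3))
    add("wk_w", _linear_init(rng, d3, d3))
    add("wk_b", np.zeros(d3))

    if config.head == "mean":
        add("mlp_w1", _linear_init(rng, L, h))
        add("mlp_b1", np.zeros(h))
        add("mlp_w2", _linear_init(rng, h, 2))
        add("mlp_b2", np.zeros(2))
    elif config.head == "attention":
        add("attn_w", _linear_init(rng, L, h))
        add("attn_b", np.zeros(h))
        add("attn_v", _linear_init(rng, h, 1))
        add("mlp_w1", _linear_init(rng, L, h))
        add("mlp_b1", np.zeros(h))
        add("mlp_w2", _linear_init(rng, h, 2))
        add("mlp_b2", np.zeros(2))
    else:  # transformer
        if L % config.n_heads != 0:
            raise ConfigError(
                f"token width L={L} must be divisible by n_heads={config.n_heads}"
            )
        add("cls", rng.standard_normal((1, L)) * 0.02)
        for nm in ("tq", "tk", "tv", "to"):
            add(f"{nm}_w", _linear_init(rng, L, L))
            add(f"{nm}_b", np.zeros(L))
        add("ln1_g", np.ones(L))
        add("ln1_b", np.zeros(L))
        add("ff_w1", _linear_init(rng, L, h))
        add("ff_b1", np.zeros(h))
        add("ff_w2", _linear_init(rng, h, L))
        add("ff_b2", np.zeros(L))
        add("ln2_g", np.ones(L))
        add("ln2_b", np.zeros(L))
        add("out_w", _linear_init(rng, L, 2))
        add("out_b", np.zeros(2))

    return ModelState(params=p, prototypes=proto_t, config=config, prototype_learnable=learnable)


# --------------------------------------------------------------------------
# dual instance sampling
# --------------------------------------------------------------------------

def random_sample(bag: FeatureBag, R: int, seed: int = 0) -> FeatureBag:
    """Uniform subset of min(R, n) instances without replacement.

    Selected instances keep their original relative order; when R >= n
    the bag is returned unchanged (identity, same object).
    """
    if R < 1:
        raise ParameterError("R must be >= 1")
    n = bag.n_instances
    if R >= n:
        return bag
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(n, size=R, replace=False))
    return bag.subset(keep)


def instance_scores(features: np.ndarray, state: ModelState) -> np.ndarray:
    """Selector scores: one scalar per instance from a linear layer on d1."""
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2 or features.shape[1] != state.config.d1:
        raise DimensionError(
            f"instance_scores expects (n, {state.config.d1}) features, got {features.shape}"
        )
    return (features @ state.params["sel_w"].data + state.params["sel_b"].data).ravel()


def mine_instances(bag: FeatureBag, state: ModelState, S: int) -> FeatureBag:
    """Keep the min(S, n) instances with the highest selector scores.

    Ties break toward the lower original index; survivors keep their
    original order and coordinates. Identity when S >= n.
    """
    if S < 1:
        raise ParameterError("S must be >= 1")
    n = bag.n_instances
    if S >= n:
        return bag
    scores = instance_scores(bag.features, state)
    order = np.argsort(-scores, kind="stable")  # stable: ties -> lower index first
    keep = np.sort(order[:S])
    return bag.subset(keep)


# --------------------------------------------------------------------------
# measurement matrix (cosine cross-attention)
# --------------------------------------------------------------------------

def _row_cosine(Q: Tensor, K: Tensor) -> Tensor:
    qn = ((Q * Q).sum(axis=1, keepdims=True) + _COS_EPS).sqrt()
    kn = ((K * K).sum(axis=1, keepdims=True) + _COS_EPS).sqrt()
    return (Q @ K.T) / (qn @ kn.T)


def _measurement_t(features: Tensor, state: ModelState) -> Tensor:
    p = state.params
    if features.shape[1] != state.config.d1:
        raise DimensionError(
            f"features width {features.shape[1]} does not match model d1={state.config.d1}"
        )
    P_hat = features @ p["fp_w"] + p["fp_b"]
    K = P_hat @ p["wk_w"] + p["wk_b"]
    if state.config.prototype_mode == "none":
        Q = P_hat @ p["wq_w"] + p["wq_b"]  # self-attention: instances query themselves
    else:
        p_hat = state.prototypes @ p["fp_w"] + p["fp_b"]
        Q = p_hat @ p["wq_w"] + p["wq_b"]
    return _row_cosine(Q, K)


def measurement(features: np.ndarray, state: ModelState, bag_id: str = "") -> MeasurementMatrix:
    """Cosine Query-Key measurement matrix (L x n), entries in [-1, 1]."""
    M = _measurement_t(Tensor(np.asarray(features, dtype=np.float64)), state)
    return MeasurementMatrix(values=M.data, bag_id=bag_id)


# --------------------------------------------------------------------------
# classifier heads
# --------------------------------------------------------------------------

def _mlp(x: Tensor, state: ModelState) -> Tensor:
    p = state.params
    hdn = (x @ p["mlp_w1"] + p["mlp_b1"]).relu()
    return hdn @ p["mlp_w2"] + p["mlp_b2"]


def _as_tensor_M(M) -> Tensor:
    if isinstance(M, Tensor):
        return M
    if isinstance(M, MeasurementMatrix):
        return Tensor(M.values)
    return Tensor(np.asarray(M, dtype=np.float64))


def head_mean(M, state: ModelState) -> np.ndarray:
    """Instance-axis mean of M -> MLP -> two-class softmax."""
    return _head_mean_t(_as_tensor_M(M), state).data


def _head_mean_t(M: Tensor, state: ModelState) -> Tensor:
    pooled = M.mean(axis=1)
    return softmax(_mlp(pooled, state), axis=-1)


def head_attention(M, state: ModelState) -> np.ndarray:
    """Attention-weighted column sum of M -> MLP -> softmax."""
    return _head_attention_t(_as_tensor_M(M), state).data


def _head_attention_t(M: Tensor, state: ModelState) -> Tensor:
    p = state.params
    H = (M.T @ p["attn_w"] + p["attn_b"]).tanh()  # (n, h)
    logits = H @ p["attn_v"]  # (n, 1)
    a = softmax(logits, axis=0)
    pooled = (M @ a).reshape(-1)  # (L,)
    return softmax(_mlp(pooled, state), axis=-1)


def attention_weights(M, state: ModelState) -> np.ndarray:
    """Per-instance attention weights of the attention head (sum to 1)."""
    p = state.params
    Mt = _as_tensor_M(M)
    H = (Mt.T @ p["attn_w"] + p["attn_b"]).tanh()
    logits = H @ p["attn_v"]
    return softmax(logits, axis=0).data.ravel()


def _layernorm(x: Tensor, g: Tensor, b: Tensor) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
    return (x - mu) / (var + 1e-8).sqrt() * g + b


def head_transformer(M, state: ModelState) -> np.ndarray:
    """Columns of M as an unordered token set; class token -> softmax.

    One encoder layer (multi-head self-attention + feed-forward, both
    with residual connections and layer normalization), no positional
    encoding, prediction from the class-token output.
    """
    return _head_transformer_t(_as_tensor_M(M), state).data


def _head_transformer_t(M: Tensor, state: ModelState) -> Tensor:
    p = state.params
    L = M.shape[0]
    nh = state.config.n_heads
    dh = L // nh
    X = concat([p["cls"], M.T], axis=0)  # (n+1, L)
    T = X.shape[0]

    def heads_of(t: Tensor) -> Tensor:  # (n+1, L) -> (nh, n+1, dh)
        return t.reshape(T, nh, dh).swapaxes(0, 1)

    Qh = heads_of(X @ p["tq_w"] + p["tq_b"])
    Kh = heads_of(X @ p["tk_w"] + p["tk_b"])
    Vh = heads_of(X @ p["tv_w"] + p["tv_b"])
    attn = softmax((Qh @ Kh.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh)), axis=-1)
    ctx = (attn @ Vh).swapaxes(0, 1).reshape(T, L)
    X = _layernorm(X + (ctx @ p["to_w"] + p["to_b"]), p["ln1_g"], p["ln1_b"])
    ff = (X @ p["ff_w1"] + p["ff_b1"]).relu() @ p["ff_w2"] + p["ff_b2"]
    X = _layernorm(X + ff, p["ln2_g"], p["ln2_b"])
    cls_out = X[0]
    return softmax(cls_out @ p["out_w"] + p["out_b"], axis=-1)


_HEAD_FNS = {
    "mean": _head_mean_t,
    "attention": _head_attention_t,
    "transformer": _head_transformer_t,
}


# --------------------------------------------------------------------------
# forward
# --------------------------------------------------------------------------

def forward(
    bag: FeatureBag, state: ModelState, training: bool = False, seed: int = 0
) -> PredictionResult:
    """Full bag-level forward pass.

    At training time the dual sampling (random R then top-S mining) is
    applied per call; at inference the full bag is used, so repeated
    inference is deterministic.
    """
    if bag.d1 != state.config.d1:
        raise DimensionError(
            f"bag width {bag.d1} does not match model d1={state.config.d1}"
        )
    used = bag
    if training:
        used = random_sample(used, state.config.R, seed=seed)
        used = mine_instances(used, state, state.config.S)
    # original indices of the survivors, by exact coordinate match
    if used is bag:
        idx = np.arange(bag.n_instances)
    else:
        lookup = {tuple(c): i for i, c in enumerate(bag.coords)}
        idx = np.array([lookup[tuple(c)] for c in used.coords], dtype=np.int64)

    M_t = _measurement_t(Tensor(used.features), state)
    mm = MeasurementMatrix(values=M_t.data, bag_id=bag.bag_id)
    if state.config.prototype_mode == "none":
        M_head = M_t.mean(axis=0, keepdims=True)  # (1, n) effective measurement
    else:
        M_head = M_t
    probs_t = _HEAD_FNS[state.config.head](M_head, state)
    probs = probs_t.data
    return PredictionResult(
        bag_id=bag.bag_id,
        prob_positive=float(probs[1]),
        probs=probs,
        measurement=mm,
        used_indices=idx,
        _probs_t=probs_t,
    )


def config_replace(cfg: ModelConfig, **kw) -> ModelConfig:
    return replace(cfg, **kw)
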