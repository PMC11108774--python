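"""Attention- and transformer-based multiple-instance-learning classifiers.

A cytology smear is a *bag* of patch feature vectors carrying a single
case-level label over five categories (digestive, female reproductive,
respiratory, blood/lymphatic, benign).  Four weakly supervised heads share
this contract:

* ``AbMIL`` — gated-attention pooling: a two-layer instance transform
  h_i = ReLU(W2 ReLU(W1 x_i + b1) + b2), attention weights
  a_i = softmax_i[ tanh(V h_i) ⊙ sigmoid(U h_i) ], bag feature Z = Hᵀ A and
  class probabilities p = softmax(W3 Z + b3).
* ``AbMILMB`` — the multi-branch variant: a shared gated trunk splits into
  one attention branch and one linear classifier per class.
* ``TransMIL`` — a 3-layer transformer encoder over the token sequence
  {h_class, h_1..h_k, h_sex, h_age, h_origin} with position embeddings; the
  class-token output feeds a linear classifier.
* ``TransMILCMA`` — cross-modality attention: image and clinical token
  streams exchange information through two stacked multimodal attention
  blocks (self-term + cross-term per stream), are concatenated through one
  standard self-attention block, average-pooled and classified by a
  two-layer MLP.

Clinical covariates fuse additively for the AbMIL variants
(X = X_image + X_age + X_sex + X_location, learned d-vector embeddings) and
as extra 384-dimensional tokens for the transformer variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ._autodiff import Adam, Tensor, concat, log_softmax, softmax, stack
from .bagio import CATEGORIES, ClinicalCovariates
from .errors import (
    ConfigurationError,
    DataError,
    EmptyBagError,
    IncompleteCovariatesError,
    ParameterError,
)
from .nn import Embedding, Linear, LayerNorm, MLP, Module

AGE_MIN, AGE_MAX, AGE_BIN = 18, 90, 5
N_AGE_BINS = (AGE_MAX - AGE_MIN) // AGE_BIN + 1


# ------------------------------------------------------------------- types
@dataclass
class FeatureBag:
    """Per-case n x d feature matrix (rows = patches, order preserved)."""

    X: np.ndarray
    case_id: str = ""

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]


class ProbabilityVector:
    """Length-5 category distribution in the fixed order of ``CATEGORIES``."""

    def __init__(self, p: np.ndarray, categories: Sequence[str] = CATEGORIES):
        self.p = np.asarray(p, dtype=float)
        self.categories = tuple(categories)
        if self.p.shape != (len(self.categories),):
            raise ParameterError("probability vector has wrong length")
        if (self.p < -1e-9).any() or abs(self.p.sum() - 1.0) > 1e-6:
            raise ParameterError("entries must be non-negative and sum to 1 (tol 1e-6)")

    @property
    def p_benign(self) -> float:
        return float(self.p[self.categories.index("benign")])

    @property
    def p_cancer(self) -> float:
        return 1.0 - self.p_benign

    def top_category(self) -> str:
        # ties broken by fixed category order
        return self.categories[int(np.argmax(self.p))]

    def as_dict(self) -> dict:
        return dict(zip(self.categories, map(float, self.p)))


@dataclass
class MILConfig:
    d: int = 1024                      # input feature dimension
    n_classes: int = len(CATEGORIES)
    abmil_hidden: Tuple[int, int] = (512, 256)
    attn_width: int = 384
    mb_proj: int = 512
    d_model: int = 384
    d_k: int = 64
    n_layers: int = 3
    ffn_hidden: Optional[int] = None   # default: d_model
    per_index_positions: bool = False
    max_patches: int = 512             # only used with per-index positions

    def __post_init__(self):
        if self.d_model % self.d_k != 0:
            raise ConfigurationError("model width must be divisible by d_k")
        if self.ffn_hidden is None:
            self.ffn_hidden = self.d_model

    @property
    def n_heads(self) -> int:
        return self.d_model // self.d_k

    @classmethod
    def tiny(cls, d: int = 64) -> "MILConfig":
        return cls(d=d, abmil_hidden=(96, 48), attn_width=32, mb_proj=32,
                   d_model=48, d_k=8)


# -------------------------------------------------------- clinical embedding
def age_bucket(age: int) -> int:
    """5-year age bins over the supported range 18-90."""
    return int((np.clip(age, AGE_MIN, AGE_MAX) - AGE_MIN) // AGE_BIN)


class ClinicalEmbedding(Module):
    """Learned embedding tables for age bin, sex and sampling site."""

    def __init__(self, dim: int, rng: np.random.Generator):
        self.dim = dim
        self.age = Embedding(N_AGE_BINS, dim, rng)
        self.sex = Embedding(2, dim, rng)
        self.site = Embedding(2, dim, rng)

    def forward(self, cov: ClinicalCovariates):
        if cov is None or not cov.complete:
            raise IncompleteCovariatesError(
                "clinical covariates incomplete; use the image-only model instead")
        return (self.age(age_bucket(cov.age)),
                self.sex(0 if cov.sex == "male" else 1),
                self.site(0 if cov.site == "hydrothorax" else 1))


def embed_clinical(cov: ClinicalCovariates, mode: str, tables: ClinicalEmbedding):
    """Covariate embeddings: ``additive`` d-vectors (X_age, X_sex, X_location)
    or transformer ``tokens`` (h_age, h_sex, h_origin).  Deterministic."""
    if mode not in ("additive", "tokens"):
        raise ParameterError(f"unknown embedding mode {mode!r}")
    x_age, x_sex, x_site = tables(cov)
    return x_age, x_sex, x_site


# ------------------------------------------------------------ attention ops
def gated_attention(H: np.ndarray, V: np.ndarray, U: np.ndarray,
                    branch: Optional[np.ndarray] = None) -> np.ndarray:
    """Normalized gated-attention weights over the k instances of H (k x h).

    Per-instance score: branchᵀ(tanh(V h_i) ⊙ sigmoid(U h_i)); with no branch
    vector the gated trunk units are summed with equal weight.  Softmax
    normalization guarantees a_i >= 0 and sum a_i = 1.
    """
    H = np.atleast_2d(np.asarray(H, dtype=float))
    if H.shape[0] == 0:
        raise EmptyBagError("gated attention over an empty bag")
    V = np.atleast_2d(V)
    U = np.atleast_2d(U)
    G = np.tanh(H @ V.T) * (1.0 / (1.0 + np.exp(-H @ U.T)))
    s = G @ np.asarray(branch, float) if branch is not None else G.sum(axis=1)
    s = s - s.max()
    e = np.exp(s)
    return e / e.sum()


def scaled_dot_attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray,
                         d_k: float) -> np.ndarray:
    """softmax(Q Kᵀ / sqrt(d_k)) V with rows of the softmax summing to 1."""
    if d_k <= 0:
        raise ParameterError("d_k must be positive")
    S = np.asarray(Q, float) @ np.asarray(K, float).T / np.sqrt(d_k)
    S = S - S.max(axis=-1, keepdims=True)
    E = np.exp(S)
    A = E / E.sum(axis=-1, keepdims=True)
    return A @ np.asarray(V, float)


def _gated_trunk(H: Tensor, v: Linear, u: Linear) -> Tensor:
    return v(H).tanh() * u(H).sigmoid()


def _attend(Q: Tensor, K: Tensor, V: Tensor, d_k: int) -> Tensor:
    A = softmax((Q @ K.transpose(0, 2, 1)) / np.sqrt(d_k), axis=-1)
    return A @ V, A


# ------------------------------------------------------------------- models
class MILModel(Module):
    """Shared surface: forward(bag, cov) -> probability Tensor of length 5."""

    categories: Tuple[str, ...] = CATEGORIES
    uses_clinical: bool = True

    def predict_proba(self, bag: FeatureBag,
                      cov: Optional[ClinicalCovariates] = None) -> ProbabilityVector:
        return ProbabilityVector(self.forward(bag, cov).data.copy(), self.categories)

    def _check_bag(self, bag: FeatureBag):
        if bag.n == 0:
            raise EmptyBagError("bag has no instances")
        if bag.d != self.config.d:
            raise ConfigurationError(
                f"bag feature dim {bag.d} != model dim {self.config.d}")


class _AdditiveFusion(Module):
    def __init__(self, d: int, rng: np.random.Generator):
        self.tables = ClinicalEmbedding(d, rng)

    def forward(self, X: Tensor, cov: Optional[ClinicalCovariates], use_clinical: bool):
        if not use_clinical:
            return X
        x_age, x_sex, x_site = self.tables(cov)
        return X + (x_age + x_sex + x_site).reshape(1, -1)


class AbMIL(MILModel):
    """Gated-attention MIL with additive clinical fusion."""

    def __init__(self, config: MILConfig, rng: np.random.Generator,
                 use_clinical: bool = True):
        self.config = config
        self.uses_clinical = use_clinical
        h1, h2 = config.abmil_hidden
        self.fusion = _AdditiveFusion(config.d, rng) if use_clinical else None
        self.fc1 = Linear(config.d, h1, rng)
        self.fc2 = Linear(h1, h2, rng)
        self.v = Linear(h2, config.attn_width, rng, bias=False)
        self.u = Linear(h2, config.attn_width, rng, bias=False)
        self.classifier = Linear(h2, config.n_classes, rng)

    def _instance_hidden(self, bag: FeatureBag, cov) -> Tensor:
        X = Tensor(bag.X)
        if self.uses_clinical:
            X = self.fusion(X, cov, True)
        return self.fc2(self.fc1(X).relu()).relu()

    def _attention(self, H: Tensor) -> Tensor:
        G = _gated_trunk(H, self.v, self.u)
        return softmax(G.sum(axis=1), axis=-1)

    def forward(self, bag: FeatureBag, cov=None) -> Tensor:
        self._check_bag(bag)
        H = self._instance_hidden(bag, cov)
        A = self._attention(H)
        Z = H.T @ A
        logits = self.classifier(Z.reshape(1, -1))[0]
        return softmax(logits, axis=-1)

    def attention_scores(self, bag: FeatureBag, cov=None) -> np.ndarray:
        self._check_bag(bag)
        return self._attention(self._instance_hidden(bag, cov)).data.copy()


class AbMILMB(MILModel):
    """Class-specific attention branches over a shared gated trunk."""

    def __init__(self, config: MILConfig, rng: np.random.Generator,
                 use_clinical: bool = True):
        self.config = config
        self.uses_clinical = use_clinical
        n = config.n_classes
        if n != len(self.categories):
            raise ConfigurationError("branch count must equal category count")
        self.fusion = _AdditiveFusion(config.d, rng) if use_clinical else None
        self.proj = Linear(config.d, config.mb_proj, rng)
        self.v = Linear(config.mb_proj, config.attn_width, rng, bias=False)
        self.u = Linear(config.mb_proj, config.attn_width, rng, bias=False)
        bound = 1.0 / np.sqrt(config.attn_width)
        self.branches = Tensor(rng.uniform(-bound, bound, (n, config.attn_width)),
                               requires_grad=True)
        bound_c = 1.0 / np.sqrt(config.mb_proj)
        self.class_weights = Tensor(rng.uniform(-bound_c, bound_c, (n, config.mb_proj)),
                                    requires_grad=True)

    def _hidden(self, bag: FeatureBag, cov) -> Tensor:
        X = Tensor(bag.X)
        if self.uses_clinical:
            X = self.fusion(X, cov, True)
        return self.proj(X)

    def _branch_attention(self, H: Tensor) -> Tensor:
        G = _gated_trunk(H, self.v, self.u)          # (k, attn)
        S = G @ self.branches.T                       # (k, N)
        return softmax(S.T, axis=-1)                  # (N, k): each branch sums to 1

    def forward(self, bag: FeatureBag, cov=None) -> Tensor:
        self._check_bag(bag)
        H = self._hidden(bag, cov)
        A = self._branch_attention(H)                 # (N, k)
        Hc = A @ H                                    # per-class bag features (N, proj)
        logits = (Hc * self.class_weights).sum(axis=1)
        return softmax(logits, axis=-1)

    def attention_scores(self, bag: FeatureBag, cov=None,
                         branch: Optional[int] = None) -> np.ndarray:
        """Attention of one branch (default: the predicted class's branch)."""
        self._check_bag(bag)
        H = self._hidden(bag, cov)
        A = self._branch_attention(H).data
        if branch is None:
            branch = int(np.argmax(self.forward(bag, cov).data))
        return A[branch].copy()


class _MultiHeadSelfAttention(Module):
    def __init__(self, cfg: MILConfig, rng):
        inner = cfg.n_heads * cfg.d_k
        self.cfg = cfg
        self.wq = Linear(cfg.d_model, inner, rng)
        self.wk = Linear(cfg.d_model, inner, rng)
        self.wv = Linear(cfg.d_model, inner, rng)
        self.wo = Linear(inner, cfg.d_model, rng)
        self.last_attention = None

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        t = x.shape[0]
        def split(t_lin):
            return t_lin.reshape(t, cfg.n_heads, cfg.d_k).transpose(1, 0, 2)
        out, A = _attend(split(self.wq(x)), split(self.wk(x)), split(self.wv(x)), cfg.d_k)
        self.last_attention = A.data.copy()
        return self.wo(out.transpose(1, 0, 2).reshape(t, -1))


class _EncoderLayer(Module):
    """Self-attention + position-wise FFN with LayerNorm around the FFN and
    residual connections on both sublayers."""

    def __init__(self, cfg: MILConfig, rng):
        self.attn = _MultiHeadSelfAttention(cfg, rng)
        self.ln_pre = LayerNorm(cfg.d_model)
        self.ln_post = LayerNorm(cfg.d_model)
        self.ffn = MLP(cfg.d_model, cfg.ffn_hidden, cfg.d_model, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(x)
        return self.ln_post(x + self.ffn(self.ln_pre(x)))


class TransMIL(MILModel):
    """Transformer MIL over {class token, patches, clinical tokens}."""

    def __init__(self, config: MILConfig, rng: np.random.Generator,
                 use_clinical: bool = True):
        self.config = config
        self.uses_clinical = use_clinical
        dm = config.d_model
        self.input_proj = Linear(config.d, dm, rng)
        self.class_token = Tensor(rng.normal(0, 0.02, dm), requires_grad=True)
        self.clinical = ClinicalEmbedding(dm, rng) if use_clinical else None
        # position embeddings: 4 named slots + a shared patch-slot embedding
        # (bags are unordered sets); per-index positions optional in config
        self.pos_slots = Tensor(rng.normal(0, 0.02, (4, dm)), requires_grad=True)
        if config.per_index_positions:
            self.pos_patches = Tensor(rng.normal(0, 0.02, (config.max_patches, dm)),
                                      requires_grad=True)
        else:
            self.pos_patches = Tensor(rng.normal(0, 0.02, (1, dm)), requires_grad=True)
        self.layers = [_EncoderLayer(config, rng) for _ in range(config.n_layers)]
        self.classifier = Linear(dm, config.n_classes, rng)

    def _tokens(self, bag: FeatureBag, cov) -> Tensor:
        k = bag.n
        patches = self.input_proj(Tensor(bag.X))
        if self.config.per_index_positions:
            if k > self.config.max_patches:
                raise ConfigurationError("bag larger than per-index position capacity")
            patches = patches + self.pos_patches[0:k]
        else:
            patches = patches + self.pos_patches
        toks = [(self.class_token + self.pos_slots[0]).reshape(1, -1), patches]
        if self.uses_clinical:
            x_age, x_sex, x_site = self.clinical(cov)
            toks += [(x_sex + self.pos_slots[1]).reshape(1, -1),
                     (x_age + self.pos_slots[2]).reshape(1, -1),
                     (x_site + self.pos_slots[3]).reshape(1, -1)]
        return concat(toks, axis=0)  # (k+4, d_model) with clinical tokens

    def forward(self, bag: FeatureBag, cov=None) -> Tensor:
        self._check_bag(bag)
        x = self._tokens(bag, cov)
        for layer in self.layers:
            x = layer(x)
        logits = self.classifier(x[0].reshape(1, -1))[0]
        return softmax(logits, axis=-1)

    def attention_scores(self, bag: FeatureBag, cov=None) -> np.ndarray:
        """Class-token -> patch attention of the last layer, averaged over heads
        and renormalized over the k patch tokens."""
        self.forward(bag, cov)
        A = self.layers[-1].attn.last_attention          # (heads, T, T)
        scores = A.mean(axis=0)[0, 1:1 + bag.n]
        return scores / scores.sum()


class _MultimodalBlock(Module):
    """Cross-modality attention block: per-stream self-term + cross-term,
    then LayerNorm -> MLP -> residual on each stream."""

    def __init__(self, cfg: MILConfig, rng):
        inner = cfg.n_heads * cfg.d_k
        self.cfg = cfg
        self.img_qkv = [Linear(cfg.d_model, inner, rng) for _ in range(3)]
        self.cli_qkv = [Linear(cfg.d_model, inner, rng) for _ in range(3)]
        self.ln_img = LayerNorm(cfg.d_model)
        self.ln_cli = LayerNorm(cfg.d_model)
        self.mlp_img = MLP(cfg.d_model, cfg.ffn_hidden, cfg.d_model, rng)
        self.mlp_cli = MLP(cfg.d_model, cfg.ffn_hidden, cfg.d_model, rng)

    def _split(self, x: Tensor) -> Tensor:
        return x.reshape(x.shape[0], self.cfg.n_heads, self.cfg.d_k).transpose(1, 0, 2)

    def forward(self, x_img: Tensor, x_cli: Tensor):
        cfg = self.cfg
        qi, ki, vi = [self._split(lin(x_img)) for lin in self.img_qkv]
        qc, kc, vc = [self._split(lin(x_cli)) for lin in self.cli_qkv]

        def merge(h):
            return h.transpose(1, 0, 2).reshape(h.shape[1], -1)

        img_self, _ = _attend(qi, ki, vi, cfg.d_k)
        img_cross, _ = _attend(qi, kc, vc, cfg.d_k)
        cli_self, _ = _attend(qc, kc, vc, cfg.d_k)
        cli_cross, _ = _attend(qc, ki, vi, cfg.d_k)
        xi = merge(img_self) + merge(img_cross)
        xc = merge(cli_self) + merge(cli_cross)
        xi = self.mlp_img(self.ln_img(xi)) + xi
        xc = self.mlp_cli(self.ln_cli(xc)) + xc
        return xi, xc


class TransMILCMA(MILModel):
    """TransMIL with cross-modality attention between image and clinical streams.

    Block order is fixed: two multimodal attention blocks, then one standard
    self-attention encoder block over the concatenated streams; average
    pooling and a two-layer MLP head produce the class logits.
    """

    def __init__(self, config: MILConfig, rng: np.random.Generator):
        self.config = config
        dm = config.d_model
        self.input_proj = Linear(config.d, dm, rng)
        self.class_token = Tensor(rng.normal(0, 0.02, dm), requires_grad=True)
        self.clinical = ClinicalEmbedding(dm, rng)
        self.pos_class = Tensor(rng.normal(0, 0.02, dm), requires_grad=True)
        self.pos_patches = Tensor(rng.normal(0, 0.02, (1, dm)), requires_grad=True)
        self.mm_blocks = [_MultimodalBlock(config, rng) for _ in range(2)]
        self.self_block = _EncoderLayer(config, rng)
        self.head = MLP(dm, config.ffn_hidden, config.n_classes, rng)

    def _streams(self, bag: FeatureBag, cov):
        patches = self.input_proj(Tensor(bag.X)) + self.pos_patches
        x_img = concat([(self.class_token + self.pos_class).reshape(1, -1), patches], axis=0)
        x_age, x_sex, x_site = self.clinical(cov)
        x_cli = stack([x_sex, x_age, x_site], axis=0)
        return x_img, x_cli

    def forward(self, bag: FeatureBag, cov=None) -> Tensor:
        self._check_bag(bag)
        if cov is None or not cov.complete:
            raise IncompleteCovariatesError("cross-modality model requires complete covariates")
        x_img, x_cli = self._streams(bag, cov)
        for block in self.mm_blocks:
            x_img, x_cli = block(x_img, x_cli)
        x = self.self_block(concat([x_img, x_cli], axis=0))
        pooled = x.mean(axis=0)
        logits = self.head(pooled.reshape(1, -1))[0]
        return softmax(logits, axis=-1)

    def attention_scores(self, bag: FeatureBag, cov=None) -> np.ndarray:
        """Class-token -> patch attention from the final self-attention block."""
        self.forward(bag, cov)
        A = self.self_block.attn.last_attention
        scores = A.mean(axis=0)[0, 1:1 + bag.n]
        return scores / scores.sum()


ARCHITECTURES = {"abmil": AbMIL, "abmil_mb": AbMILMB,
                 "transmil": TransMIL, "transmil_cma": TransMILCMA}


def save_model(model: MILModel, path) -> None:
    """Persist architecture, config and weights to an .npz archive."""
    import json
    from dataclasses import asdict

    arch = next(k for k, v in ARCHITECTURES.items() if isinstance(model, v))
    meta = json.dumps({"arch": arch, "config": asdict(model.config),
                       "use_clinical": model.uses_clinical})
    state = {f"param::{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.array(meta), **state)


def load_model(path) -> MILModel:
    import json

    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["__meta__"]))
        state = {k[len("param::"):]: archive[k] for k in archive.files
                 if k.startswith("param::")}
    kwargs = {} if meta["arch"] == "transmil_cma" else {"use_clinical": meta["use_clinical"]}
    model = build_model(meta["arch"], MILConfig(**meta["config"]), seed=0, **kwargs)
    model.load_state_dict(state)
    return model


def build_model(arch: str, config: MILConfig, seed: int = 0, **kwargs) -> MILModel:
    if arch not in ARCHITECTURES:
        raise ParameterError(f"unknown architecture {arch!r}; choose from {sorted(ARCHITECTURES)}")
    rng = np.random.default_rng(seed)
    return ARCHITECTURES[arch](config, rng, **kwargs)


# ----------------------------------------------------------------- training
@dataclass
class TrainConfig:
    epochs: int = 100
    lr: float = 2e-4            # constant learning rate
    weight_decay: float = 1e-5
    select_from_epoch: int = 60  # checkpoint selection window (1-based)


@dataclass
class MILTrainLog:
    train_loss: List[float] = field(default_factory=list)
    val_loss: List[float] = field(default_factory=list)
    selected_epoch: int = -1


def select_checkpoint(val_losses: Sequence[float], select_from: int = 60) -> int:
    """1-based epoch of the lowest validation loss at epoch >= select_from
    (earliest epoch on ties).  If no epoch qualifies, the window starts at the
    last epoch available."""
    n = len(val_losses)
    if n == 0:
        raise DataError("no validation losses recorded")
    start = min(select_from, n)
    window = np.asarray(val_losses[start - 1:])
    return start + int(np.argmin(window))


def train_mil(model: MILModel, train_set: Sequence[tuple], val_set: Sequence[tuple],
              config: TrainConfig = TrainConfig(), seed: int = 0) -> MILTrainLog:
    """End-to-end weakly supervised training with cross-entropy on bag labels.

    ``train_set``/``val_set`` are sequences of (FeatureBag, ClinicalCovariates
    or None, class index).  Adam, batch size 1, constant lr.  The checkpoint
    with the lowest validation loss from ``select_from_epoch`` onward is
    restored into the model.  Deterministic per seed.
    """
    if not train_set or not val_set:
        raise DataError("train and validation splits must be non-empty")
    rng = np.random.default_rng(seed)
    opt = Adam(model.parameters(), lr=config.lr, weight_decay=config.weight_decay)
    log = MILTrainLog()
    best_state, checkpoints = None, {}
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(train_set))
        losses = []
        for idx in order:
            bag, cov, y = train_set[idx]
            p = model.forward(bag, cov)
            loss = -(p[int(y)] + 1e-12).log()
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        log.train_loss.append(float(np.mean(losses)))
        vloss = float(np.mean([
            -np.log(model.forward(b, c).data[int(y)] + 1e-12) for b, c, y in val_set]))
        log.val_loss.append(vloss)
        if epoch >= min(config.select_from_epoch, config.epochs):
            checkpoints[epoch] = model.state_dict()
    log.selected_epoch = select_checkpoint(log.val_loss, config.select_from_epoch)
    best_state = checkpoints.get(log.selected_epoch)
    if best_state is not None:
        model.load_state_dict(best_state)
    return log


# ---------------------------------------------------------------- ensembling
@dataclass
class EnsembleSpec:
    """Member models whose probability vectors are arithmetically averaged.

    The reference configuration pairs the 4 architectures with 3 feature
    inputs (cytological, histological, both) for 12 members."""

    members: List[MILModel]

    def __post_init__(self):
        if not self.members:
            raise ConfigurationError("ensemble needs at least one member")
        ref = self.members[0].categories
        for m in self.members[1:]:
            if tuple(m.categories) != tuple(ref):
                raise ConfigurationError("ensemble members disagree on category order")


def ensemble_predict(spec: EnsembleSpec, bag: FeatureBag,
                     cov: Optional[ClinicalCovariates] = None) -> ProbabilityVector:
    """Arithmetic mean of member probability vectors.

    Members whose required inputs are unavailable (e.g. a cross-modality
    model given incomplete covariates) are dropped with a warning."""
    preds = []
    for m in spec.members:
        try:
            preds.append(m.predict_proba(bag, cov).p)
        except IncompleteCovariatesError:
            warnings.warn(f"dropping ensemble member {type(m).__name__}: "
                          "required covariates unavailable")
    if not preds:
        raise DataError("no ensemble member could produce a prediction")
    return ProbabilityVector(np.mean(preds, axis=0), spec.members[0].categories)
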