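"""Per-protein feature matrices from evidence networks and attributes.

Each evidence channel is turned into one feature matrix by a pluggable
backend; together with the attribute matrix (and any precomputed extras,
e.g. protein language-model embeddings) they form the ordered feature
matrix space the selector searches over.

Backends
--------
``noembed``
    The min-max-normalized adjacency rows themselves (d_f = n).
``mlpae``
    Bottleneck activations of an MLP autoencoder trained to reconstruct
    the adjacency rows under binary cross-entropy.
``transformerae``
    Per protein, the network row and the attribute row are projected to a
    common width and fused as a two-token sequence through multi-head
    self-attention encoder layers; a mirror-image decoder reconstructs
    both inputs under binary cross-entropy.  Only the network-side hidden
    state enters the feature space.
``node2vec`` / ``gae``
    Recognized names without an implementation here (the selection method
    is largely insensitive to the embedding backend); requesting them
    raises ``NotImplementedError``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import h5py
import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import _autodiff as ad
from ._autodiff import Tensor
from .data_io import CHANNELS, AttributeMatrix, EvidenceNetwork

__all__ = [
    "FeatureMatrix",
    "FeatureMatrixSpace",
    "AutoencoderConfig",
    "minmax_normalize",
    "embed_noembed",
    "MLPAutoencoder",
    "TransformerAutoencoder",
    "train_mlp_autoencoder",
    "train_transformer_autoencoder",
    "build_feature_space",
    "save_feature_space",
    "load_feature_space",
]

BACKENDS = ("noembed", "mlpae", "transformerae", "node2vec", "gae")


@dataclass
class FeatureMatrix:
    """An n x d_f real matrix tagged with its source."""

    values: np.ndarray
    source: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if not np.isfinite(self.values).all():
            raise ValueError(f"non-finite entries in feature matrix {self.source!r}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d_f(self) -> int:
        return self.values.shape[1]


class FeatureMatrixSpace:
    """Ordered collection of candidate feature matrices (the space M)."""

    def __init__(self, matrices):
        matrices = list(matrices)
        if not matrices:
            raise ValueError("feature matrix space must be non-empty")
        n = matrices[0].n
        for m in matrices:
            if m.n != n:
                raise ValueError(
                    f"matrix {m.source!r} has {m.n} rows, expected {n}"
                )
        self.matrices = matrices

    def __len__(self) -> int:
        return len(self.matrices)

    def __getitem__(self, i) -> FeatureMatrix:
        return self.matrices[i]

    @property
    def n(self) -> int:
        return self.matrices[0].n

    @property
    def sources(self) -> tuple[str, ...]:
        return tuple(m.source for m in self.matrices)

    @property
    def dims(self) -> tuple[int, ...]:
        return tuple(m.d_f for m in self.matrices)

    def arrays(self) -> list[np.ndarray]:
        return [m.values for m in self.matrices]


@dataclass
class AutoencoderConfig:
    """Shared knobs for the autoencoder backends.

    ``d_hidden`` is the latent width (and, for the transformer backend, the
    shared token width — it must be divisible by ``heads``).  ``layers``
    counts attention blocks per side of the transformer.
    """

    d_hidden: int = 64
    layers: int = 2
    heads: int = 4
    epochs: int = 200
    lr: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.d_hidden < 1:
            raise ValueError("d_hidden must be >= 1")
        if self.d_hidden % self.heads != 0:
            raise ValueError(
                f"d_hidden={self.d_hidden} not divisible by heads={self.heads}"
            )


def minmax_normalize(matrix: np.ndarray) -> np.ndarray:
    """Scale a whole matrix to [0, 1]; a constant matrix maps to zeros."""
    m = np.asarray(matrix, dtype=np.float64)
    if not np.isfinite(m).all():
        raise ValueError("matrix has non-finite entries")
    lo, hi = m.min(), m.max()
    if hi == lo:
        return np.zeros_like(m)
    return (m - lo) / (hi - lo)


def embed_noembed(net: EvidenceNetwork) -> FeatureMatrix:
    """Use the (normalized) adjacency rows directly as features."""
    return FeatureMatrix(values=net.adjacency.copy(), source=net.channel)


# ---------------------------------------------------------------------------
# MLP autoencoder
# ---------------------------------------------------------------------------


class MLPAutoencoder(TransformerMixin, BaseEstimator):
    """One-hidden-layer autoencoder; ``transform`` returns the bottleneck.

    Inputs are expected in [0, 1]; reconstruction is optimized under binary
    cross-entropy with Adam, full batch, deterministic per ``random_state``.
    """

    def __init__(self, d_hidden=64, epochs=200, lr=1e-3, random_state=0):
        self.d_hidden = d_hidden
        self.epochs = epochs
        self.lr = lr
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        n, d = X.shape
        if self.d_hidden >= d:
            import warnings

            warnings.warn("d_hidden >= input dimension: autoencoder is not a bottleneck")
        rng = np.random.default_rng(self.random_state)
        w_enc = Tensor(rng.normal(0, np.sqrt(2.0 / d), (d, self.d_hidden)), True)
        b_enc = Tensor(np.zeros(self.d_hidden), True)
        w_dec = Tensor(rng.normal(0, np.sqrt(2.0 / self.d_hidden), (self.d_hidden, d)), True)
        b_dec = Tensor(np.zeros(d), True)
        params = [w_enc, b_enc, w_dec, b_dec]
        opt = ad.Adam(params, lr=self.lr)
        xt = Tensor(X)
        losses = []
        for _ in range(self.epochs):
            opt.zero_grad()
            hidden = ad.relu(xt @ w_enc + b_enc)
            recon = ad.sigmoid(hidden @ w_dec + b_dec)
            loss = _bce(recon, xt)
            losses.append(float(loss.data))
            loss.backward()
            opt.step()
        self.w_enc_, self.b_enc_ = w_enc.data, b_enc.data
        self.loss_curve_ = losses
        self.n_features_in_ = d
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=np.float64)
        return np.maximum(X @ self.w_enc_ + self.b_enc_, 0.0)


def _bce(p: Tensor, target: Tensor, eps: float = 1e-7) -> Tensor:
    pc = ad.clip(p, eps, 1.0 - eps)
    return -(target * ad.log(pc) + (1.0 - target) * ad.log(1.0 - pc)).mean()


def train_mlp_autoencoder(matrix: np.ndarray, cfg: AutoencoderConfig) -> FeatureMatrix:
    ae = MLPAutoencoder(
        d_hidden=cfg.d_hidden, epochs=cfg.epochs, lr=cfg.lr, random_state=cfg.seed
    )
    ae.fit(matrix)
    return FeatureMatrix(values=ae.transform(matrix), source="mlpae")


# ---------------------------------------------------------------------------
# transformer (attention-fusion) autoencoder
# ---------------------------------------------------------------------------


def scaled_dot_product_attention(q: Tensor, k: Tensor, v: Tensor) -> Tensor:
    """softmax(Q K^T / sqrt(d_k)) V along the last two axes."""
    d_k = q.shape[-1]
    scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(d_k))
    return ad.softmax(scores, axis=-1) @ v


class _AttentionBlock:
    """Multi-head self-attention + position-wise ReLU layer, with residuals."""

    def __init__(self, width: int, heads: int, rng: np.random.Generator):
        s = np.sqrt(1.0 / width)
        self.heads = heads
        self.wq = Tensor(rng.normal(0, s, (width, width)), True)
        self.wk = Tensor(rng.normal(0, s, (width, width)), True)
        self.wv = Tensor(rng.normal(0, s, (width, width)), True)
        self.wo = Tensor(rng.normal(0, s, (width, width)), True)
        self.bo = Tensor(np.zeros(width), True)
        self.wf = Tensor(rng.normal(0, np.sqrt(2.0 / width), (width, width)), True)
        self.bf = Tensor(np.zeros(width), True)

    def params(self):
        return [self.wq, self.wk, self.wv, self.wo, self.bo, self.wf, self.bf]

    def __call__(self, h: Tensor) -> Tensor:
        n, t, w = h.shape
        hd = w // self.heads

        def split_heads(x: Tensor) -> Tensor:
            # (n, t, w) -> (n, heads, t, w/heads)
            return x.reshape(n, t, self.heads, hd).swapaxes(1, 2)

        q, k, v = split_heads(h @ self.wq), split_heads(h @ self.wk), split_heads(h @ self.wv)
        att = scaled_dot_product_attention(q, k, v)
        merged = att.swapaxes(1, 2).reshape(n, t, w)
        h = h + merged @ self.wo + self.bo
        return h + ad.relu(h @ self.wf + self.bf)


class TransformerAutoencoder(TransformerMixin, BaseEstimator):
    """Attention autoencoder fusing one network with the attribute matrix.

    Each protein contributes a two-token sequence — its adjacency row and its
    attribute row, linearly projected to a common width ``d_hidden`` — that
    passes through ``layers`` self-attention encoder blocks and as many
    decoder blocks.  Both modalities are reconstructed under binary
    cross-entropy; ``transform`` returns only the network-side encoder
    hidden state (n x d_hidden).
    """

    def __init__(self, d_hidden=64, layers=2, heads=4, epochs=200, lr=1e-3, random_state=0):
        self.d_hidden = d_hidden
        self.layers = layers
        self.heads = heads
        self.epochs = epochs
        self.lr = lr
        self.random_state = random_state

    def _config(self) -> AutoencoderConfig:
        return AutoencoderConfig(
            d_hidden=self.d_hidden,
            layers=self.layers,
            heads=self.heads,
            epochs=self.epochs,
            lr=self.lr,
            seed=self.random_state,
        )

    def fit(self, X, attributes=None):
        """Fit on ``X`` (normalized adjacency) and the attribute matrix."""
        cfg = self._config()  # validates width/heads
        adj = np.asarray(X, dtype=np.float64)
        if attributes is None:
            raise ValueError("the transformer backend needs the attribute matrix")
        attr = attributes.x if isinstance(attributes, AttributeMatrix) else attributes
        attr = np.asarray(attr, dtype=np.float64)
        if attr.shape[0] != adj.shape[0]:
            raise ValueError("adjacency and attributes disagree on protein count")
        n, d_net = adj.shape
        d_attr = attr.shape[1]
        w = cfg.d_hidden
        rng = np.random.default_rng(cfg.seed)

        p_net = Tensor(rng.normal(0, np.sqrt(1.0 / d_net), (d_net, w)), True)
        p_attr = Tensor(rng.normal(0, np.sqrt(1.0 / d_attr), (d_attr, w)), True)
        tok_emb = Tensor(rng.normal(0, 0.02, (2, w)), True)  # modality embedding
        enc = [_AttentionBlock(w, cfg.heads, rng) for _ in range(cfg.layers)]
        dec = [_AttentionBlock(w, cfg.heads, rng) for _ in range(cfg.layers)]
        out_net = Tensor(rng.normal(0, np.sqrt(1.0 / w), (w, d_net)), True)
        ob_net = Tensor(np.zeros(d_net), True)
        out_attr = Tensor(rng.normal(0, np.sqrt(1.0 / w), (w, d_attr)), True)
        ob_attr = Tensor(np.zeros(d_attr), True)

        params = [p_net, p_attr, tok_emb, out_net, ob_net, out_attr, ob_attr]
        for blk in enc + dec:
            params += blk.params()
        opt = ad.Adam(params, lr=cfg.lr)

        adj_t, attr_t = Tensor(adj), Tensor(attr)
        losses = []
        for _ in range(cfg.epochs):
            opt.zero_grad()
            tokens = ad.stack([adj_t @ p_net, attr_t @ p_attr], axis=1) + tok_emb
            h = tokens
            for blk in enc:
                h = blk(h)
            hidden = h
            for blk in dec:
                h = blk(h)
            recon_net = ad.sigmoid(h[:, 0, :] @ out_net + ob_net)
            recon_attr = ad.sigmoid(h[:, 1, :] @ out_attr + ob_attr)
            loss = _bce(recon_net, adj_t) + _bce(recon_attr, attr_t)
            losses.append(float(loss.data))
            loss.backward()
            opt.step()

        self._frozen = dict(
            p_net=p_net.data, p_attr=p_attr.data, tok_emb=tok_emb.data,
            enc=[[p.data for p in blk.params()] for blk in enc],
        )
        self._enc_blocks = enc
        self.loss_curve_ = losses
        self.n_features_in_ = d_net
        self._attr_dim = d_attr
        return self

    def transform(self, X, attributes=None):
        """Encoder forward pass; returns the network-token hidden state."""
        adj = np.asarray(X, dtype=np.float64)
        attr = attributes.x if isinstance(attributes, AttributeMatrix) else attributes
        attr = np.asarray(attr, dtype=np.float64)
        f = self._frozen
        tokens = ad.stack(
            [Tensor(adj @ f["p_net"]), Tensor(attr @ f["p_attr"])], axis=1
        ) + Tensor(f["tok_emb"])
        h = tokens
        for blk in self._enc_blocks:
            h = blk(h)
        return h.data[:, 0, :]


def train_transformer_autoencoder(
    adjacency: np.ndarray,
    attributes: AttributeMatrix | np.ndarray,
    cfg: AutoencoderConfig,
    source: str = "transformerae",
) -> FeatureMatrix:
    ae = TransformerAutoencoder(
        d_hidden=cfg.d_hidden, layers=cfg.layers, heads=cfg.heads,
        epochs=cfg.epochs, lr=cfg.lr, random_state=cfg.seed,
    )
    ae.fit(adjacency, attributes)
    return FeatureMatrix(values=ae.transform(adjacency, attributes), source=source)


# ---------------------------------------------------------------------------
# assembling the space
# ---------------------------------------------------------------------------


def build_feature_space(
    networks,
    attrs: AttributeMatrix,
    backend: str = "transformerae",
    extras=None,
    cfg: AutoencoderConfig | None = None,
    normalize: bool = True,
) -> FeatureMatrixSpace:
    """Embed every channel and stack channels + attributes (+ extras) into M.

    Channels are ordered canonically (``data_io.CHANNELS``); the attribute
    matrix follows them, then any extra matrices.  With 7 channels and no
    extras, |M| = 8.
    """
    if backend not in BACKENDS:
        raise ValueError(f"unknown backend {backend!r}; choose from {BACKENDS}")
    if backend in ("node2vec", "gae"):
        raise NotImplementedError(f"backend {backend!r} is an interface stub")
    cfg = cfg or AutoencoderConfig()
    by_channel = {net.channel: net for net in networks}
    ordered = [by_channel[c] for c in CHANNELS if c in by_channel]
    ordered += [net for net in networks if net.channel not in CHANNELS]

    mats: list[FeatureMatrix] = []
    for k, net in enumerate(ordered):
        adj = minmax_normalize(net.adjacency) if normalize else net.adjacency
        if backend == "noembed":
            fm = FeatureMatrix(values=adj, source=net.channel)
        elif backend == "mlpae":
            sub = AutoencoderConfig(**{**cfg.__dict__, "seed": cfg.seed + k})
            fm = train_mlp_autoencoder(adj, sub)
            fm.source = net.channel
        else:  # transformerae
            sub = AutoencoderConfig(**{**cfg.__dict__, "seed": cfg.seed + k})
            fm = train_transformer_autoencoder(adj, attrs, sub, source=net.channel)
        mats.append(fm)
    mats.append(FeatureMatrix(values=attrs.x.astype(np.float64), source="attributes"))
    for extra in extras or []:
        fm = extra if isinstance(extra, FeatureMatrix) else FeatureMatrix(*extra)
        if not fm.source.startswith("extra:"):
            fm.source = f"extra:{fm.source}"
        mats.append(fm)
    return FeatureMatrixSpace(mats)


def save_feature_space(space: FeatureMatrixSpace, path, manifest: dict | None = None) -> None:
    """Persist the space to HDF5 with its ordering and an optional manifest."""
    with h5py.File(path, "w") as fh:
        fh.attrs["sources"] = json.dumps(list(space.sources))
        fh.attrs["manifest"] = json.dumps(manifest or {})
        for i, m in enumerate(space.matrices):
            fh.create_dataset(f"matrix_{i:03d}", data=m.values)


def load_feature_space(path) -> tuple[FeatureMatrixSpace, dict]:
    with h5py.File(path, "r") as fh:
        sources = json.loads(fh.attrs["sources"])
        manifest = json.loads(fh.attrs["manifest"])
        mats = [
            FeatureMatrix(values=fh[f"matrix_{i:03d}"][()], source=src)
            for i, src in enumerate(sources)
        ]
    return FeatureMatrixSpace(mats), manifest
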