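"""The masked-embedding attention classifier.

Architecture, per cell (expression vector e of length n):

1. Masked token embedding.  A weight tensor W of shape (n genes, k sets,
   m dims) is gated by the binary membership mask M (genes x sets), so the
   effective weight is W' = W * M (M broadcast over the embedding axis) and
   token j is built only from genes belonging to set j:
   ``T[j, d] = sum_i W'[i, j, d] * e[i]``.
2. A learnable class token (CLS) is prepended, giving I of shape (1+k, m).
3. ``depth`` pre-norm multi-head self-attention blocks: per head,
   ``A = softmax(Q K^T / sqrt(m/H))``, context ``A V``; heads are
   concatenated and projected by W_O, with a residual connection, followed
   by a two-layer feed-forward sublayer with its own residual.
4. The CLS row of the final block feeds a fully connected classifier with
   softmax output over cell types.

The head-averaged attention of the CLS query over the k pathway tokens in
the final block is the cell's interpretable attention embedding.

Everything is implemented in float64 NumPy with hand-derived gradients
(checked against finite differences in the test suite).  The mask is
re-applied to W after every optimizer step, so off-mask effective weights
are exactly zero at all times.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.special import erf

from .gene_sets import GeneVocabulary, MaskMatrix

_LN_EPS = 1e-6


@dataclass
class ModelConfig:
    m: int = 48                      # embedding dimension
    heads: int = 4                   # attention heads H; m/H is the per-head dim
    depth: int = 1                   # number of attention blocks
    ffn_hidden: int | None = None    # feed-forward width, default 2*m
    classifier_hidden: int | None = None  # classifier hidden width, default 2*m
    dropout: float = 0.0
    norm: str = "post"               # layer-norm placement: "pre", "post" or "none"
    input_norm: str = "linear"       # how raw counts were normalized for the model
    unknown_cutoff: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.norm not in ("pre", "post", "none"):
            raise ValueError("norm must be 'pre', 'post' or 'none'")
        if self.input_norm not in ("linear", "log1p", "none"):
            raise ValueError("input_norm must be 'linear', 'log1p' or 'none'")
        if self.m % self.heads != 0:
            raise ValueError(f"heads ({self.heads}) must divide m ({self.m})")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not (0.0 < self.unknown_cutoff <= 1.0):
            raise ValueError("unknown_cutoff must be in (0, 1]")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.ffn_hidden is None:
            self.ffn_hidden = 2 * self.m
        if self.classifier_hidden is None:
            self.classifier_hidden = 2 * self.m


@dataclass
class ModelState:
    """All learnable parameters plus the mask, vocabularies and config."""

    params: dict[str, np.ndarray]
    mask: MaskMatrix
    labels: tuple[str, ...]
    config: ModelConfig

    @property
    def n_genes(self) -> int:
        return self.mask.n_genes

    @property
    def n_sets(self) -> int:
        return self.mask.n_sets

    @property
    def n_classes(self) -> int:
        return len(self.labels)

    def effective_embedding(self) -> np.ndarray:
        """W' = W * M: the masked (n, k, m) embedding tensor."""
        return self.params["embed_W"] * self.mask.values[:, :, None]

    def apply_mask(self) -> None:
        """Zero off-mask embedding entries in place (call after every update)."""
        self.params["embed_W"] *= self.mask.values[:, :, None]

    # ---- serialization -------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Single-archive checkpoint: parameter arrays + mask + metadata JSON."""
        path = Path(path)
        meta = {
            "labels": list(self.labels),
            "gene_names": list(self.mask.gene_names.names),
            "set_names": list(self.mask.set_names),
            "config": asdict(self.config),
            "mask_params": {k: str(v) for k, v in self.mask.params.items()},
        }
        buf = io.BytesIO()
        np.savez(buf, mask=self.mask.values, **self.params)
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("arrays.npz", buf.getvalue())
            zf.writestr("meta.json", json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "ModelState":
        with zipfile.ZipFile(Path(path)) as zf:
            meta = json.loads(zf.read("meta.json"))
            with np.load(io.BytesIO(zf.read("arrays.npz"))) as npz:
                arrays = {k: npz[k] for k in npz.files}
        mask = MaskMatrix(
            values=arrays.pop("mask"),
            gene_names=GeneVocabulary(tuple(meta["gene_names"])),
            set_names=tuple(meta["set_names"]),
            params=meta.get("mask_params", {}),
        )
        return cls(
            params=arrays,
            mask=mask,
            labels=tuple(meta["labels"]),
            config=ModelConfig(**meta["config"]),
        )


def init_state(mask: MaskMatrix, labels: tuple[str, ...], config: ModelConfig) -> ModelState:
    """Initialize parameters under ``config.seed``.

    Embedding entries on the mask are uniform with a per-set fan-in scale
    (fan-in = number of member genes of the set); dense layers use the
    standard +-1/sqrt(fan_in) uniform; CLS is a small Gaussian; layer norms
    start at identity.
    """
    if len(labels) < 2:
        raise ValueError("need at least 2 cell-type labels")
    rng = np.random.default_rng(config.seed)
    n, k, m = mask.n_genes, mask.n_sets, config.m
    params: dict[str, np.ndarray] = {}
    fan_in = np.maximum(mask.values.sum(axis=0), 1.0)  # (k,)
    bounds = 1.0 / np.sqrt(fan_in)[None, :, None]
    params["embed_W"] = rng.uniform(-1.0, 1.0, size=(n, k, m)) * bounds * mask.values[:, :, None]
    params["cls"] = rng.normal(0.0, 0.02, size=m)

    def dense(fin: int, fout: int) -> tuple[np.ndarray, np.ndarray]:
        b = 1.0 / np.sqrt(fin)
        return rng.uniform(-b, b, size=(fin, fout)), rng.uniform(-b, b, size=fout)

    f = config.ffn_hidden
    for blk in range(config.depth):
        p = f"blk{blk}."
        params[p + "ln1_g"] = np.ones(m)
        params[p + "ln1_b"] = np.zeros(m)
        for name in ("Wq", "Wk", "Wv", "Wo"):
            params[p + name], params[p + name.replace("W", "b")] = dense(m, m)
        params[p + "ln2_g"] = np.ones(m)
        params[p + "ln2_b"] = np.zeros(m)
        params[p + "W1"], params[p + "b1"] = dense(m, f)
        params[p + "W2"], params[p + "b2"] = dense(f, m)
    h = config.classifier_hidden
    params["clf_W0"], params["clf_b0"] = dense(m, h)
    params["clf_W1"], params["clf_b1"] = dense(h, len(labels))
    return ModelState(params=params, mask=mask, labels=tuple(labels), config=config)


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def _softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + erf(x / np.sqrt(2.0)))


def _gelu_grad(x: np.ndarray) -> np.ndarray:
    phi = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
    return 0.5 * (1.0 + erf(x / np.sqrt(2.0))) + x * phi


def _layer_norm(x: np.ndarray, g: np.ndarray, b: np.ndarray):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * inv
    return g * xhat + b, (xhat, inv)


def _layer_norm_backward(dy: np.ndarray, g: np.ndarray, cache) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    xhat, inv = cache
    dims = tuple(range(dy.ndim - 1))
    dg = (dy * xhat).sum(axis=dims)
    db = dy.sum(axis=dims)
    dxhat = dy * g
    dx = inv * (
        dxhat
        - dxhat.mean(axis=-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
    )
    return dx, dg, db


# ---------------------------------------------------------------------------
# forward
# ---------------------------------------------------------------------------

def _forward_batch(
    E: np.ndarray,
    state: ModelState,
    training: bool = False,
    rng: np.random.Generator | None = None,
    need_cache: bool = False,
):
    """Run the whole model on a (cells, n_genes) batch.

    Returns (probabilities (b, nc), cls_attention (b, k), cache) where
    ``cls_attention`` is the head-averaged CLS->token attention of the final
    block.  ``cache`` is None unless ``need_cache``.
    """
    cfg = state.config
    b = E.shape[0]
    if E.shape[1] != state.n_genes:
        raise ValueError(f"expected {state.n_genes} genes, got {E.shape[1]}")
    m, H = cfg.m, cfg.heads
    dh = m // H
    k = state.n_sets
    s = 1 + k
    p_drop = cfg.dropout if training else 0.0
    if p_drop > 0 and rng is None:
        raise ValueError("dropout requires an RNG in training mode")

    W_eff = state.effective_embedding()
    tokens = np.einsum("bi,ijd->bjd", E, W_eff)              # (b, k, m)
    X = np.concatenate([np.broadcast_to(state.params["cls"], (b, 1, m)), tokens], axis=1)

    cache: dict = {"E": E, "blocks": []} if need_cache else None
    cls_attention = None
    for blk in range(cfg.depth):
        p = f"blk{blk}."
        P = state.params
        # attention sublayer; layer-norm placement per cfg.norm
        if cfg.norm == "pre":
            h1, ln1c = _layer_norm(X, P[p + "ln1_g"], P[p + "ln1_b"])
        else:
            h1, ln1c = X, None
        Q = h1 @ P[p + "Wq"] + P[p + "bq"]
        K = h1 @ P[p + "Wk"] + P[p + "bk"]
        V = h1 @ P[p + "Wv"] + P[p + "bv"]
        # (b, s, m) -> (b, H, s, dh)
        Qh = Q.reshape(b, s, H, dh).transpose(0, 2, 1, 3)
        Kh = K.reshape(b, s, H, dh).transpose(0, 2, 1, 3)
        Vh = V.reshape(b, s, H, dh).transpose(0, 2, 1, 3)
        scores = Qh @ Kh.transpose(0, 1, 3, 2) / np.sqrt(dh)  # (b, H, s, s)
        A = _softmax(scores)
        ctx = A @ Vh                                          # (b, H, s, dh)
        merged = ctx.transpose(0, 2, 1, 3).reshape(b, s, m)
        attn_out = merged @ P[p + "Wo"] + P[p + "bo"]
        drop1 = None
        if p_drop > 0:
            drop1 = (rng.random(attn_out.shape) >= p_drop) / (1.0 - p_drop)
            attn_out = attn_out * drop1
        y1 = X + attn_out
        if cfg.norm == "post":
            X2, ln1c = _layer_norm(y1, P[p + "ln1_g"], P[p + "ln1_b"])
        else:
            X2 = y1
        # feed-forward sublayer
        if cfg.norm == "pre":
            h2, ln2c = _layer_norm(X2, P[p + "ln2_g"], P[p + "ln2_b"])
        else:
            h2, ln2c = X2, None
        z1 = h2 @ P[p + "W1"] + P[p + "b1"]
        a1 = _gelu(z1)
        ffn = a1 @ P[p + "W2"] + P[p + "b2"]
        drop2 = None
        if p_drop > 0:
            drop2 = (rng.random(ffn.shape) >= p_drop) / (1.0 - p_drop)
            ffn = ffn * drop2
        y2 = X2 + ffn
        if cfg.norm == "post":
            X_next, ln2c = _layer_norm(y2, P[p + "ln2_g"], P[p + "ln2_b"])
        else:
            X_next = y2
        cls_attention = A[:, :, 0, 1:].mean(axis=1)           # (b, k), final block wins
        if need_cache:
            cache["blocks"].append(
                dict(X=X, h1=h1, ln1c=ln1c, Qh=Qh, Kh=Kh, Vh=Vh, A=A, ctx=ctx,
                     merged=merged, drop1=drop1, X2=X2, h2=h2, ln2c=ln2c,
                     z1=z1, a1=a1, drop2=drop2)
            )
        X = X_next
        if not np.isfinite(X).all():
            raise FloatingPointError(f"non-finite activations in attention block {blk}")

    c = X[:, 0, :]                                            # CLS row
    z0 = c @ state.params["clf_W0"] + state.params["clf_b0"]
    a0 = _gelu(z0)
    dropc = None
    if p_drop > 0:
        dropc = (rng.random(a0.shape) >= p_drop) / (1.0 - p_drop)
        a0 = a0 * dropc
    logits = a0 @ state.params["clf_W1"] + state.params["clf_b1"]
    probs = _softmax(logits)
    if need_cache:
        cache.update(c=c, z0=z0, a0=a0, dropc=dropc, probs=probs)
    return probs, cls_attention, cache


def _backward_batch(dlogits: np.ndarray, state: ModelState, cache: dict) -> dict[str, np.ndarray]:
    """Gradients of a scalar loss wrt every parameter, given d(loss)/d(logits).

    Embedding gradients are masked, so off-mask entries never move.
    """
    cfg = state.config
    P = state.params
    m, H = cfg.m, cfg.heads
    dh = m // H
    k = state.n_sets
    s = 1 + k
    b = dlogits.shape[0]
    g: dict[str, np.ndarray] = {}

    a0 = cache["a0"]
    g["clf_W1"] = a0.T @ dlogits
    g["clf_b1"] = dlogits.sum(axis=0)
    da0 = dlogits @ P["clf_W1"].T
    if cache["dropc"] is not None:
        da0 = da0 * cache["dropc"]
    dz0 = da0 * _gelu_grad(cache["z0"])
    g["clf_W0"] = cache["c"].T @ dz0
    g["clf_b0"] = dz0.sum(axis=0)
    dc = dz0 @ P["clf_W0"].T

    dX = np.zeros((b, s, m))
    dX[:, 0, :] = dc

    for blk in reversed(range(cfg.depth)):
        p = f"blk{blk}."
        C = cache["blocks"][blk]
        # FFN sublayer: y2 = X2 + drop2(gelu(h2 W1 + b1) W2 + b2)
        if cfg.norm == "post":
            dy2, g[p + "ln2_g"], g[p + "ln2_b"] = _layer_norm_backward(
                dX, P[p + "ln2_g"], C["ln2c"]
            )
        else:
            dy2 = dX
        dffn = dy2 if C["drop2"] is None else dy2 * C["drop2"]
        g[p + "W2"] = np.einsum("bsf,bsm->fm", C["a1"], dffn)
        g[p + "b2"] = dffn.sum(axis=(0, 1))
        da1 = dffn @ P[p + "W2"].T
        dz1 = da1 * _gelu_grad(C["z1"])
        g[p + "W1"] = np.einsum("bsm,bsf->mf", C["h2"], dz1)
        g[p + "b1"] = dz1.sum(axis=(0, 1))
        dh2 = dz1 @ P[p + "W1"].T
        if cfg.norm == "pre":
            dX2_ln, g[p + "ln2_g"], g[p + "ln2_b"] = _layer_norm_backward(
                dh2, P[p + "ln2_g"], C["ln2c"]
            )
            dX2 = dy2 + dX2_ln
        else:
            dX2 = dy2 + dh2
            if cfg.norm == "none":
                g[p + "ln2_g"] = np.zeros(m)
                g[p + "ln2_b"] = np.zeros(m)

        # attention sublayer: y1 = X + drop1(merged Wo + bo)
        if cfg.norm == "post":
            dy1, g[p + "ln1_g"], g[p + "ln1_b"] = _layer_norm_backward(
                dX2, P[p + "ln1_g"], C["ln1c"]
            )
        else:
            dy1 = dX2
        dattn = dy1 if C["drop1"] is None else dy1 * C["drop1"]
        g[p + "Wo"] = np.einsum("bsm,bsn->mn", C["merged"], dattn)
        g[p + "bo"] = dattn.sum(axis=(0, 1))
        dmerged = dattn @ P[p + "Wo"].T
        dctx = dmerged.reshape(b, s, H, dh).transpose(0, 2, 1, 3)
        A, Vh, Qh, Kh = C["A"], C["Vh"], C["Qh"], C["Kh"]
        dA = dctx @ Vh.transpose(0, 1, 3, 2)
        dVh = A.transpose(0, 1, 3, 2) @ dctx
        dscores = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        dscores /= np.sqrt(dh)
        dQh = dscores @ Kh
        dKh = dscores.transpose(0, 1, 3, 2) @ Qh
        dQ = dQh.transpose(0, 2, 1, 3).reshape(b, s, m)
        dK = dKh.transpose(0, 2, 1, 3).reshape(b, s, m)
        dV = dVh.transpose(0, 2, 1, 3).reshape(b, s, m)
        h1 = C["h1"]
        dh1 = np.zeros_like(h1)
        for name, dmat in (("Wq", dQ), ("Wk", dK), ("Wv", dV)):
            g[p + name] = np.einsum("bsm,bsn->mn", h1, dmat)
            g[p + name.replace("W", "b")] = dmat.sum(axis=(0, 1))
            dh1 += dmat @ P[p + name].T
        if cfg.norm == "pre":
            dX_ln, g[p + "ln1_g"], g[p + "ln1_b"] = _layer_norm_backward(
                dh1, P[p + "ln1_g"], C["ln1c"]
            )
            dX = dy1 + dX_ln
        else:
            dX = dy1 + dh1
            if cfg.norm == "none":
                g[p + "ln1_g"] = np.zeros(m)
                g[p + "ln1_b"] = np.zeros(m)

    g["cls"] = dX[:, 0, :].sum(axis=0)
    dtokens = dX[:, 1:, :]                                    # (b, k, m)
    g["embed_W"] = np.einsum("bi,bjd->ijd", cache["E"], dtokens) * state.mask.values[:, :, None]
    return g


# ---------------------------------------------------------------------------
# public single-cell / single-matrix surface
# ---------------------------------------------------------------------------

@dataclass
class AttentionOutput:
    """One attention block's result: per-head attention, block output, CLS scores."""

    A: np.ndarray            # (H, 1+k, 1+k), rows softmax-normalized
    O: np.ndarray            # (1+k, m) block output (post residual + FFN)
    cls_attention: np.ndarray  # (k,) head-averaged CLS->token attention


def embed(expression: np.ndarray, state: ModelState) -> np.ndarray:
    """Masked token embedding of one cell: (k sets, m dims).

    Column d equals (W[:, :, d] * M)^T e; token j only sees genes with
    M[i, j] = 1.
    """
    e = np.asarray(expression, dtype=np.float64)
    if e.shape != (state.n_genes,):
        raise ValueError(f"expected expression of length {state.n_genes}, got {e.shape}")
    return np.einsum("i,ijd->jd", e, state.effective_embedding())


def attend(tokens: np.ndarray, state: ModelState, block: int = 0) -> AttentionOutput:
    """Run one attention block on a CLS-augmented (1+k, m) token matrix."""
    cfg = state.config
    P = state.params
    m, H = cfg.m, cfg.heads
    dh = m // H
    X = np.asarray(tokens, dtype=np.float64)[None]            # batch of one
    s = X.shape[1]
    p = f"blk{block}."
    norm = cfg.norm
    h1 = _layer_norm(X, P[p + "ln1_g"], P[p + "ln1_b"])[0] if norm == "pre" else X
    Q = (h1 @ P[p + "Wq"] + P[p + "bq"]).reshape(1, s, H, dh).transpose(0, 2, 1, 3)
    K = (h1 @ P[p + "Wk"] + P[p + "bk"]).reshape(1, s, H, dh).transpose(0, 2, 1, 3)
    V = (h1 @ P[p + "Wv"] + P[p + "bv"]).reshape(1, s, H, dh).transpose(0, 2, 1, 3)
    A = _softmax(Q @ K.transpose(0, 1, 3, 2) / np.sqrt(dh))
    merged = (A @ V).transpose(0, 2, 1, 3).reshape(1, s, m)
    y1 = X + merged @ P[p + "Wo"] + P[p + "bo"]
    X2 = _layer_norm(y1, P[p + "ln1_g"], P[p + "ln1_b"])[0] if norm == "post" else y1
    h2 = _layer_norm(X2, P[p + "ln2_g"], P[p + "ln2_b"])[0] if norm == "pre" else X2
    y2 = X2 + _gelu(h2 @ P[p + "W1"] + P[p + "b1"]) @ P[p + "W2"] + P[p + "b2"]
    out = _layer_norm(y2, P[p + "ln2_g"], P[p + "ln2_b"])[0] if norm == "post" else y2
    if not np.isfinite(out).all():
        raise FloatingPointError(f"non-finite activations in attention block {block}")
    return AttentionOutput(A=A[0], O=out[0], cls_attention=A[0, :, 0, 1:].mean(axis=0))


def classify(cls_out: np.ndarray, state: ModelState) -> np.ndarray:
    """Class probabilities from a CLS representation (softmax over cell types)."""
    c = np.asarray(cls_out, dtype=np.float64)[None]
    z0 = c @ state.params["clf_W0"] + state.params["clf_b0"]
    logits = _gelu(z0) @ state.params["clf_W1"] + state.params["clf_b1"]
    return _softmax(logits)[0]


def forward(expression: np.ndarray, state: ModelState) -> tuple[np.ndarray, np.ndarray]:
    """Full model on one cell: (class probabilities, CLS->token attention scores)."""
    e = np.asarray(expression, dtype=np.float64)
    if e.ndim != 1:
        raise ValueError("forward takes a single expression vector; see inference.predict")
    probs, attn, _ = _forward_batch(e[None], state)
    return probs[0], attn[0]
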