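"""Model-core tests: masked embedding, attention, classifier, whole-model oracle.

The whole-model oracle re-implements the forward pass as straight-line
Python loops (token embedding, per-head scaled dot-product attention,
residuals, feed-forward, classifier softmax) independent of the vectorized
implementation, and the gradient test compares hand-derived backprop with
central finite differences.
"""

import math

import numpy as np
import pytest

from pathattn import GeneVocabulary, ModelConfig, classify, embed, forward, random_mask
from pathattn.gene_sets import MaskMatrix
from pathattn.model import (
    ModelState,
    _backward_batch,
    _forward_batch,
    attend,
    init_state,
)


def make_state(n=6, k=3, m=4, heads=2, depth=1, seed=7, norm="post", labels=("A", "B")):
    rng = np.random.default_rng(seed)
    values = np.zeros((n, k))
    for j in range(k):  # ensure every column is non-empty
        members = rng.choice(n, size=rng.integers(1, n), replace=False)
        values[members, j] = 1.0
    mask = MaskMatrix(values=values,
                      gene_names=GeneVocabulary(tuple(f"g{i}" for i in range(n))),
                      set_names=tuple(f"S{j}" for j in range(k)))
    cfg = ModelConfig(m=m, heads=heads, depth=depth, seed=seed, norm=norm)
    return init_state(mask, labels, cfg)


# ---------------------------------------------------------------------------
# straight-line oracle
# ---------------------------------------------------------------------------

def _ln(row, g, b, eps=1e-6):
    mu = sum(row) / len(row)
    var = sum((v - mu) ** 2 for v in row) / len(row)
    return [g[d] * (row[d] - mu) / math.sqrt(var + eps) + b[d] for d in range(len(row))]


def _gelu1(x):
    return 0.5 * x * (1.0 + math.erf(x / math.sqrt(2.0)))


def _softmax_list(z):
    mx = max(z)
    e = [math.exp(v - mx) for v in z]
    s = sum(e)
    return [v / s for v in e]


def straight_line_forward(e, state):
    """Loop-by-loop re-implementation of the model on one cell."""
    P = {k: np.asarray(v).tolist() for k, v in state.params.items()}
    M = state.mask.values.tolist()
    cfg = state.config
    n, k, m, H = state.n_genes, state.n_sets, cfg.m, cfg.heads
    dh = m // H
    W = state.params["embed_W"]

    # masked embedding: token j, dim d = sum_i W[i,j,d]*M[i,j]*e[i]
    T = [[sum(W[i][j][d] * M[i][j] * e[i] for i in range(n)) for d in range(m)]
         for j in range(k)]
    X = [list(P["cls"])] + T
    s = 1 + k

    for blk in range(cfg.depth):
        p = f"blk{blk}."
        h1 = [_ln(row, P[p + "ln1_g"], P[p + "ln1_b"]) for row in X] \
            if cfg.norm == "pre" else [list(r) for r in X]

        def proj(rows, Wn, bn):
            return [[sum(rows[i][a] * P[p + Wn][a][d] for a in range(m)) + P[p + bn][d]
                     for d in range(m)] for i in range(s)]

        Q, K, V = proj(h1, "Wq", "bq"), proj(h1, "Wk", "bk"), proj(h1, "Wv", "bv")
        merged = [[0.0] * m for _ in range(s)]
        A_heads = []
        for h in range(H):
            lo = h * dh
            A_h = []
            for i in range(s):
                scores = [sum(Q[i][lo + d] * K[j][lo + d] for d in range(dh)) / math.sqrt(dh)
                          for j in range(s)]
                A_h.append(_softmax_list(scores))
            A_heads.append(A_h)
            for i in range(s):
                for d in range(dh):
                    merged[i][lo + d] = sum(A_h[i][j] * V[j][lo + d] for j in range(s))
        y1 = [[X[i][d] + sum(merged[i][a] * P[p + "Wo"][a][d] for a in range(m))
               + P[p + "bo"][d] for d in range(m)] for i in range(s)]
        X2 = [_ln(row, P[p + "ln1_g"], P[p + "ln1_b"]) for row in y1] \
            if cfg.norm == "post" else y1
        h2 = [_ln(row, P[p + "ln2_g"], P[p + "ln2_b"]) for row in X2] \
            if cfg.norm == "pre" else X2
        f = cfg.ffn_hidden
        z1 = [[sum(h2[i][a] * P[p + "W1"][a][d] for a in range(m)) + P[p + "b1"][d]
               for d in range(f)] for i in range(s)]
        ffn = [[sum(_gelu1(z1[i][a]) * P[p + "W2"][a][d] for a in range(f))
                + P[p + "b2"][d] for d in range(m)] for i in range(s)]
        y2 = [[X2[i][d] + ffn[i][d] for d in range(m)] for i in range(s)]
        X = [_ln(row, P[p + "ln2_g"], P[p + "ln2_b"]) for row in y2] \
            if cfg.norm == "post" else y2
        cls_attention = [sum(A_heads[h][0][1 + j] for h in range(H)) / H for j in range(k)]

    c = X[0]
    hidden = cfg.classifier_hidden
    z0 = [sum(c[a] * P["clf_W0"][a][d] for a in range(m)) + P["clf_b0"][d]
          for d in range(hidden)]
    logits = [sum(_gelu1(z0[a]) * P["clf_W1"][a][d] for a in range(hidden))
              + P["clf_b1"][d] for d in range(len(state.labels))]
    return _softmax_list(logits), cls_attention


class TestEmbed:
    def test_all_ones_sums_expression(self):
        state = make_state(n=3, k=2, m=4)
        state.mask.values[:] = 1.0
        state.params["embed_W"][:] = 1.0
        tokens = embed(np.array([1.0, 2.0, 3.0]), state)
        assert np.allclose(tokens, 6.0)

    def test_brute_force_oracle(self):
        state = make_state(n=6, k=3, m=2, heads=1)
        rng = np.random.default_rng(0)
        e = rng.random(6)
        tokens = embed(e, state)
        W, M = state.params["embed_W"], state.mask.values
        for j in range(3):
            for d in range(2):
                expected = sum(W[i, j, d] * e[i] for i in range(6) if M[i, j] == 1)
                assert abs(tokens[j, d] - expected) < 1e-12

    def test_mask_annihilation_of_empty_column(self):
        state = make_state(n=4, k=2, m=4)
        state.mask.values[:, 1] = 0.0  # bypass invariant deliberately
        tokens = np.einsum("i,ijd->jd", np.ones(4), state.effective_embedding())
        assert (tokens[1] == 0).all()

    def test_length_mismatch(self):
        state = make_state()
        with pytest.raises(ValueError):
            embed(np.ones(5), state)


class TestAttend:
    def test_single_token_attention_is_one(self):
        state = make_state(m=4, heads=2)
        out = attend(np.random.default_rng(0).random((1, 4)), state)
        assert np.allclose(out.A, 1.0)
        assert out.A.shape == (2, 1, 1)

    def test_identical_rows_get_half_half(self):
        state = make_state(m=4, heads=2)
        row = np.random.default_rng(1).random(4)
        out = attend(np.stack([row, row]), state)
        assert np.allclose(out.A, 0.5, atol=1e-12)

    def test_rows_sum_to_one(self):
        state = make_state(k=3, m=4, heads=2)
        out = attend(np.random.default_rng(2).random((4, 4)), state)
        assert np.allclose(out.A.sum(axis=-1), 1.0, atol=1e-6)
        assert out.cls_attention.shape == (3,)
        assert (out.cls_attention >= 0).all() and out.cls_attention.sum() <= 1 + 1e-9


class TestClassify:
    def test_zero_weights_give_uniform(self):
        state = make_state(labels=("A", "B", "C"))
        for key in ("clf_W0", "clf_b0", "clf_W1", "clf_b1"):
            state.params[key][:] = 0.0
        probs = classify(np.random.default_rng(0).random(4), state)
        assert np.allclose(probs, 1 / 3)

    def test_softmax_arithmetic(self):
        # logits (ln 2, 0) -> (2/3, 1/3)
        z = np.array([np.log(2.0), 0.0])
        p = np.exp(z) / np.exp(z).sum()
        assert np.allclose(p, [2 / 3, 1 / 3])
        state = make_state(labels=("A", "B"))
        probs = classify(np.random.default_rng(3).random(4), state)
        assert abs(probs.sum() - 1) < 1e-9


class TestForward:
    @pytest.mark.parametrize("norm", ["pre", "post", "none"])
    def test_matches_straight_line_oracle(self, norm):
        state = make_state(n=6, k=3, m=4, heads=2, depth=1, seed=11, norm=norm)
        e = np.random.default_rng(4).random(6)
        probs, attn = forward(e, state)
        o_probs, o_attn = straight_line_forward(e.tolist(), state)
        np.testing.assert_allclose(probs, o_probs, atol=1e-5)
        np.testing.assert_allclose(attn, o_attn, atol=1e-5)
        assert abs(probs.sum() - 1) < 1e-6

    def test_two_block_oracle(self):
        state = make_state(n=6, k=3, m=4, heads=2, depth=2, seed=13)
        e = np.random.default_rng(5).random(6)
        probs, attn = forward(e, state)
        o_probs, o_attn = straight_line_forward(e.tolist(), state)
        np.testing.assert_allclose(probs, o_probs, atol=1e-5)
        np.testing.assert_allclose(attn, o_attn, atol=1e-5)

    def test_determinism(self):
        state = make_state()
        e = np.random.default_rng(6).random(6)
        p1, a1 = forward(e, state)
        p2, a2 = forward(e, state)
        assert (p1 == p2).all() and (a1 == a2).all()

    def test_permutation_equivariance(self):
        """Consistently permuting genes in input, mask rows and W leaves output unchanged."""
        state = make_state(n=6, k=3, m=4, seed=21)
        e = np.random.default_rng(7).random(6)
        p0, a0 = forward(e, state)
        perm = np.random.default_rng(8).permutation(6)
        state2 = make_state(n=6, k=3, m=4, seed=21)
        state2.mask.values = state.mask.values[perm]
        state2.params["embed_W"] = state.params["embed_W"][perm]
        p2, a2 = forward(e[perm], state2)
        np.testing.assert_allclose(p0, p2, atol=1e-12)
        np.testing.assert_allclose(a0, a2, atol=1e-12)

    def test_nonmember_gene_perturbation_leaves_token_unchanged(self):
        state = make_state(n=6, k=3, m=4, seed=9)
        M = state.mask.values
        j = 0
        outside = np.where(M[:, j] == 0)[0]
        if len(outside) == 0:
            pytest.skip("column 0 covers all genes in this draw")
        e = np.random.default_rng(10).random(6)
        t0 = embed(e, state)[j]
        e2 = e.copy()
        e2[outside] += 100.0
        t1 = embed(e2, state)[j]
        assert (t0 == t1).all()


class TestGradients:
    @pytest.mark.parametrize("norm", ["pre", "post", "none"])
    def test_backprop_matches_finite_differences(self, norm):
        state = make_state(n=7, k=3, m=4, heads=2, depth=2, seed=5, norm=norm,
                           labels=("A", "B", "C"))
        rng = np.random.default_rng(0)
        E = rng.random((5, 7))
        y = rng.integers(0, 3, 5)

        def loss():
            probs, _, _ = _forward_batch(E, state)
            return -np.log(probs[np.arange(5), y]).mean()

        probs, _, cache = _forward_batch(E, state, need_cache=True)
        dlogits = probs.copy()
        dlogits[np.arange(5), y] -= 1
        dlogits /= 5
        grads = _backward_batch(dlogits, state, cache)
        eps = 1e-6
        for key, g in grads.items():
            if norm == "none" and "ln" in key:
                assert (g == 0).all()
                continue
            p = state.params[key]
            for idx in [tuple(rng.integers(0, s) for s in p.shape) for _ in range(3)]:
                if key == "embed_W" and state.mask.values[idx[0], idx[1]] == 0:
                    assert g[idx] == 0
                    continue
                orig = p[idx]
                p[idx] = orig + eps
                lp = loss()
                p[idx] = orig - eps
                lm = loss()
                p[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert abs(num - g[idx]) <= 1e-3 * max(1e-4, abs(num), abs(g[idx])), (
                    f"{key}{idx}: analytic {g[idx]}, numeric {num}"
                )


class TestCheckpoint:
    def test_round_trip_restores_forward_exactly(self, tmp_path):
        state = make_state(seed=17)
        e = np.random.default_rng(11).random(6)
        p0, a0 = forward(e, state)
        path = tmp_path / "model.ckpt"
        state.save(path)
        restored = ModelState.load(path)
        p1, a1 = forward(e, restored)
        assert (p0 == p1).all() and (a0 == a1).all()
        assert restored.labels == state.labels
        assert restored.config == state.config

    def test_heads_must_divide_m(self):
        with pytest.raises(ValueError):
            ModelConfig(m=10, heads=4)
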