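"""Numerical core: a BERT-style transformer encoder in numpy.

Forward pass, masked-LM head with tied output embeddings, and hand-written
reverse-mode gradients for every parameter, plus LoRA adapter paths.  The
implementation favours explicitness over speed: all shapes are (batch, seq,
hidden) with post-layer-norm residual blocks, ReLU activations and learned
position embeddings.

Parameter dictionary layout (all float64 numpy arrays)::

    word_emb (V, d)      pos_emb (P, d)      emb_ln_g/b (d,)
    layer{i}.Wq/Wk/Wv/Wo (d, d)   + bq/bk/bv/bo (d,)
    layer{i}.ln1_g/b (d,)
    layer{i}.W1 (d, f)  b1 (f,)   W2 (f, d)  b2 (d,)
    layer{i}.ln2_g/b (d,)
    head_W (d, d)  head_b (d,)  head_ln_g/b (d,)  out_bias (V,)

The masked-LM decoder reuses ``word_emb`` (weight tying), so it contributes
no extra parameters beyond ``out_bias``.
"""

from __future__ import annotations

import numpy as np

IGNORE_LABEL = -100

# ---------------------------------------------------------------------------
# Parameter bookkeeping


def param_shapes(spec) -> dict[str, tuple[int, ...]]:
    """Shape of every trainable tensor; the order is the counting convention."""
    d, f, V, P = spec.hidden_size, spec.ff_size, spec.vocab_size, spec.max_positions
    shapes: dict[str, tuple[int, ...]] = {
        "word_emb": (V, d),
        "pos_emb": (P, d),
        "emb_ln_g": (d,),
        "emb_ln_b": (d,),
    }
    for i in range(spec.layers):
        p = f"layer{i}."
        for w in ("Wq", "Wk", "Wv", "Wo"):
            shapes[p + w] = (d, d)
        for b in ("bq", "bk", "bv", "bo"):
            shapes[p + b] = (d,)
        shapes[p + "ln1_g"] = (d,)
        shapes[p + "ln1_b"] = (d,)
        shapes[p + "W1"] = (d, f)
        shapes[p + "b1"] = (f,)
        shapes[p + "W2"] = (f, d)
        shapes[p + "b2"] = (d,)
        shapes[p + "ln2_g"] = (d,)
        shapes[p + "ln2_b"] = (d,)
    shapes["head_W"] = (d, d)
    shapes["head_b"] = (d,)
    shapes["head_ln_g"] = (d,)
    shapes["head_ln_b"] = (d,)
    shapes["out_bias"] = (V,)
    return shapes


def _sinusoidal(P: int, d: int) -> np.ndarray:
    pos = np.arange(P)[:, None]
    i = np.arange(d)[None, :]
    angle = pos / np.power(10_000.0, (2 * (i // 2)) / d)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc


def init_params(spec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Gaussian(0, init_std) weights; position embeddings start from a smooth
    sinusoidal pattern (scaled to init_std) so that neighbouring ranks are
    nearly identical at initialization — they remain fully learned."""
    params = {}
    for name, shape in param_shapes(spec).items():
        if name.endswith("_g"):
            params[name] = np.ones(shape)
        elif name.endswith("_b") or name.startswith("b") or ".b" in name or name == "out_bias":
            params[name] = np.zeros(shape)
        elif len(shape) == 1:
            params[name] = np.zeros(shape)
        elif name == "pos_emb":
            params[name] = spec.init_std * _sinusoidal(*shape)
        else:
            params[name] = rng.normal(0.0, spec.init_std, size=shape)
    return params


def count_parameters_from_shapes(spec) -> int:
    return sum(int(np.prod(s)) for s in param_shapes(spec).values())


# ---------------------------------------------------------------------------
# Primitive forward/backward blocks


def _layer_norm(x, g, b, eps):
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    return xhat * g + b, (xhat, inv, g)


def _layer_norm_bwd(cache, dy):
    xhat, inv, g = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    m1 = dxhat.mean(axis=-1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = (dxhat - m1 - xhat * m2) * inv
    return dx, dg, db


def _dropout(x, p, train, rng):
    if not train or p <= 0.0:
        return x, None
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * mask, mask


def _lin_fwd(x, W, b, adapters, name):
    """x: (..., d_in). Returns y and a cache for the adapter path."""
    y = x @ W + b
    acache = None
    if adapters and name in adapters:
        ad = adapters[name]
        xa = x @ ad["A"]
        y = y + (ad["alpha"] / ad["r"]) * (xa @ ad["B"])
        acache = xa
    return y, acache


def _lin_bwd(dy, x, W, adapters, name, acache, grads, lora_grads):
    """Accumulate dW/db (and LoRA dA/dB) and return dx."""
    x2 = x.reshape(-1, x.shape[-1])
    dy2 = dy.reshape(-1, dy.shape[-1])
    grads[name] = grads.get(name, 0) + x2.T @ dy2
    bname = _bias_name(name)
    grads[bname] = grads.get(bname, 0) + dy2.sum(axis=0)
    dx = dy @ W.T
    if adapters and name in adapters:
        ad = adapters[name]
        s = ad["alpha"] / ad["r"]
        dyB = dy2 @ ad["B"].T
        lora_grads[(name, "B")] = lora_grads.get((name, "B"), 0) + s * acache.reshape(
            -1, acache.shape[-1]
        ).T @ dy2
        lora_grads[(name, "A")] = lora_grads.get((name, "A"), 0) + s * x2.T @ dyB
        dx = dx + s * (dy @ ad["B"].T @ ad["A"].T)
    return dx


_BIAS = {"Wq": "bq", "Wk": "bk", "Wv": "bv", "Wo": "bo", "W1": "b1", "W2": "b2", "head_W": "head_b"}


def _bias_name(name: str) -> str:
    if "." in name:
        prefix, w = name.rsplit(".", 1)
        return f"{prefix}.{_BIAS[w]}"
    return _BIAS[name]


# ---------------------------------------------------------------------------
# Encoder forward


def _effective(params, qweights, name):
    if qweights is not None and name in qweights:
        return qweights[name].dequantize()
    return params[name]


def forward(
    params,
    spec,
    ids: np.ndarray,
    lengths: np.ndarray,
    train: bool = False,
    rng: np.random.Generator | None = None,
    adapters=None,
    qweights=None,
):
    """Run the encoder. Returns (hidden_states, cache).

    ``hidden_states`` has ``layers + 1`` entries: the embedding output
    followed by each block's output, all (B, T, d).  Padded key positions are
    excluded from attention; padded query positions produce unused states.
    """
    B, T = ids.shape
    if T > spec.max_positions:
        raise ValueError(f"sequence length {T} exceeds max positions {spec.max_positions}")
    d, H = spec.hidden_size, spec.heads
    dh = d // H
    valid = np.arange(T)[None, :] < lengths[:, None]  # (B, T)
    key_bias = np.where(valid, 0.0, -1e9)[:, None, None, :]  # (B,1,1,T)

    x = params["word_emb"][ids] + params["pos_emb"][:T][None, :, :]
    h, ln_cache = _layer_norm(x, params["emb_ln_g"], params["emb_ln_b"], spec.ln_eps)
    h, emb_drop = _dropout(h, spec.dropout, train, rng)
    cache = {
        "ids": ids,
        "valid": valid,
        "emb_ln": ln_cache,
        "emb_drop": emb_drop,
        "layers": [],
    }
    hidden_states = [h]
    for i in range(spec.layers):
        p = f"layer{i}."
        lc: dict = {"h_in": h}
        Wq, Wk, Wv, Wo = (_effective(params, qweights, p + w) for w in ("Wq", "Wk", "Wv", "Wo"))
        q, lc["aq"] = _lin_fwd(h, Wq, params[p + "bq"], adapters, p + "Wq")
        k, lc["ak"] = _lin_fwd(h, Wk, params[p + "bk"], adapters, p + "Wk")
        v, lc["av"] = _lin_fwd(h, Wv, params[p + "bv"], adapters, p + "Wv")
        q = q.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
        k = k.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
        v = v.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
        S = q @ k.transpose(0, 1, 3, 2) / np.sqrt(dh) + key_bias
        S = S - S.max(axis=-1, keepdims=True)
        P = np.exp(S)
        P = P / P.sum(axis=-1, keepdims=True)
        Pd, attn_mask = _dropout(P, spec.attn_dropout, train, rng)
        C = (Pd @ v).transpose(0, 2, 1, 3).reshape(B, T, d)
        lc.update(q=q, k=k, v=v, P=P, attn_mask=attn_mask, Pd=Pd, C=C)
        A, lc["ao"] = _lin_fwd(C, Wo, params[p + "bo"], adapters, p + "Wo")
        A, lc["drop_A"] = _dropout(A, spec.dropout, train, rng)
        h1, lc["ln1"] = _layer_norm(h + A, params[p + "ln1_g"], params[p + "ln1_b"], spec.ln_eps)
        W1 = _effective(params, qweights, p + "W1")
        W2 = _effective(params, qweights, p + "W2")
        Z1, lc["a1"] = _lin_fwd(h1, W1, params[p + "b1"], adapters, p + "W1")
        M = np.maximum(Z1, 0.0)
        F, lc["a2"] = _lin_fwd(M, W2, params[p + "b2"], adapters, p + "W2")
        F, lc["drop_F"] = _dropout(F, spec.dropout, train, rng)
        h, lc["ln2"] = _layer_norm(h1 + F, params[p + "ln2_g"], params[p + "ln2_b"], spec.ln_eps)
        lc.update(h1=h1, Z1=Z1, M=M)
        cache["layers"].append(lc)
        hidden_states.append(h)
    return hidden_states, cache


def mlm_logits(params, spec, h_last, adapters=None):
    """Masked-LM head: transform + LayerNorm + tied decoder."""
    t, _ = _lin_fwd(h_last, params["head_W"], params["head_b"], None, "head_W")
    tr = np.maximum(t, 0.0)
    u, ln_cache = _layer_norm(tr, params["head_ln_g"], params["head_ln_b"], spec.ln_eps)
    logits = u @ params["word_emb"].T + params["out_bias"]
    head_cache = {"t": t, "tr": tr, "u": u, "ln": ln_cache}
    return logits, head_cache


def mlm_loss(params, spec, hidden_states, labels):
    """Mean cross-entropy over labeled positions. Returns loss, aux for backward."""
    h_last = hidden_states[-1]
    logits, head_cache = mlm_logits(params, spec, h_last)
    sel = labels != IGNORE_LABEL
    n = int(sel.sum())
    if n == 0:
        raise ValueError("no labeled (masked) positions in batch")
    z = logits[sel]  # (n, V)
    z = z - z.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    y = labels[sel]
    loss = -logp[np.arange(n), y].mean()
    aux = {"head_cache": head_cache, "sel": sel, "logp": logp, "y": y, "n": n, "h_last": h_last}
    return loss, aux


def mlm_backward(params, spec, cache, aux, adapters=None, qweights=None):
    """Gradients of the masked-LM loss wrt every parameter (and adapters)."""
    grads: dict[str, np.ndarray] = {}
    lora_grads: dict = {}
    hc, sel, logp, y, n = aux["head_cache"], aux["sel"], aux["logp"], aux["y"], aux["n"]
    B, T = sel.shape
    V = params["word_emb"].shape[0]

    dz = np.exp(logp)
    dz[np.arange(n), y] -= 1.0
    dz /= n  # (n, V)
    dlogits = np.zeros((B, T, V))
    dlogits[sel] = dz

    u = hc["u"]
    dl2 = dlogits.reshape(-1, V)
    u2 = u.reshape(-1, u.shape[-1])
    grads["word_emb"] = dl2.T @ u2
    grads["out_bias"] = dl2.sum(axis=0)
    du = dlogits @ params["word_emb"]
    dtr, dg, db = _layer_norm_bwd(hc["ln"], du)
    grads["head_ln_g"], grads["head_ln_b"] = dg, db
    dt = dtr * (hc["t"] > 0)
    dh = _lin_bwd(dt, aux["h_last"], params["head_W"], None, "head_W", None, grads, lora_grads)

    dh = backward_hidden(params, spec, cache, dh, from_layer=spec.layers, grads=grads,
                         lora_grads=lora_grads, adapters=adapters, qweights=qweights)
    return grads, lora_grads


def backward_hidden(
    params,
    spec,
    cache,
    d_h,
    from_layer: int,
    grads=None,
    lora_grads=None,
    adapters=None,
    qweights=None,
):
    """Backpropagate a gradient at hidden_states[from_layer] down to the input.

    Accumulates into ``grads``/``lora_grads`` and returns the gradient wrt the
    embedding-layer output (for completeness).
    """
    if grads is None:
        grads = {}
    if lora_grads is None:
        lora_grads = {}
    B, T = cache["ids"].shape
    d, H = spec.hidden_size, spec.heads
    dh_ = d // H

    for i in range(from_layer - 1, -1, -1):
        p = f"layer{i}."
        lc = cache["layers"][i]
        Wq, Wk, Wv, Wo = (_effective(params, qweights, p + w) for w in ("Wq", "Wk", "Wv", "Wo"))
        W1 = _effective(params, qweights, p + "W1")
        W2 = _effective(params, qweights, p + "W2")

        d_sum2, dg, db = _layer_norm_bwd(lc["ln2"], d_h)
        grads[p + "ln2_g"] = grads.get(p + "ln2_g", 0) + dg
        grads[p + "ln2_b"] = grads.get(p + "ln2_b", 0) + db
        dF = d_sum2 if lc["drop_F"] is None else d_sum2 * lc["drop_F"]
        dM = _lin_bwd(dF, lc["M"], W2, adapters, p + "W2", lc["a2"], grads, lora_grads)
        dZ1 = dM * (lc["Z1"] > 0)
        dh1 = d_sum2 + _lin_bwd(dZ1, lc["h1"], W1, adapters, p + "W1", lc["a1"], grads, lora_grads)

        d_sum1, dg, db = _layer_norm_bwd(lc["ln1"], dh1)
        grads[p + "ln1_g"] = grads.get(p + "ln1_g", 0) + dg
        grads[p + "ln1_b"] = grads.get(p + "ln1_b", 0) + db
        dA = d_sum1 if lc["drop_A"] is None else d_sum1 * lc["drop_A"]
        dC = _lin_bwd(dA, lc["C"], Wo, adapters, p + "Wo", lc["ao"], grads, lora_grads)

        dC4 = dC.reshape(B, T, H, dh_).transpose(0, 2, 1, 3)
        dPd = dC4 @ lc["v"].transpose(0, 1, 3, 2)
        dv4 = lc["Pd"].transpose(0, 1, 3, 2) @ dC4
        dP = dPd if lc["attn_mask"] is None else dPd * lc["attn_mask"]
        P = lc["P"]
        dS = P * (dP - (dP * P).sum(axis=-1, keepdims=True))
        dq4 = dS @ lc["k"] / np.sqrt(dh_)
        dk4 = dS.transpose(0, 1, 3, 2) @ lc["q"] / np.sqrt(dh_)

        dq = dq4.transpose(0, 2, 1, 3).reshape(B, T, d)
        dk = dk4.transpose(0, 2, 1, 3).reshape(B, T, d)
        dv = dv4.transpose(0, 2, 1, 3).reshape(B, T, d)
        h_in = lc["h_in"]
        d_h = d_sum1
        d_h = d_h + _lin_bwd(dq, h_in, Wq, adapters, p + "Wq", lc["aq"], grads, lora_grads)
        d_h = d_h + _lin_bwd(dk, h_in, Wk, adapters, p + "Wk", lc["ak"], grads, lora_grads)
        d_h = d_h + _lin_bwd(dv, h_in, Wv, adapters, p + "Wv", lc["av"], grads, lora_grads)

    # embedding block
    if cache["emb_drop"] is not None:
        d_h = d_h * cache["emb_drop"]
    dx, dg, db = _layer_norm_bwd(cache["emb_ln"], d_h)
    grads["emb_ln_g"] = grads.get("emb_ln_g", 0) + dg
    grads["emb_ln_b"] = grads.get("emb_ln_b", 0) + db
    ids = cache["ids"]
    we = np.zeros_like(params["word_emb"])
    np.add.at(we, ids.reshape(-1), dx.reshape(-1, d))
    grads["word_emb"] = grads.get("word_emb", 0) + we
    pe = np.zeros_like(params["pos_emb"])
    pe[:T] = dx.sum(axis=0)
    grads["pos_emb"] = grads.get("pos_emb", 0) + pe
    return dx


# ---------------------------------------------------------------------------
# AdamW with cosine warm-up schedule


class AdamW:
    """Adam with decoupled weight decay on 2-D weight matrices."""

    def __init__(self, trainable: dict, lr=2e-4, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.044):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.m = {k: np.zeros_like(v) for k, v in trainable.items()}
        self.v = {k: np.zeros_like(v) for k, v in trainable.items()}
        self.t = 0

    def step(self, trainable: dict, grads: dict, lr: float | None = None):
        self.t += 1
        lr = self.lr if lr is None else lr
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, w in trainable.items():
            g = grads.get(k)
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            update = (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
            if w.ndim >= 2:
                update = update + self.wd * w
            w -= lr * update


def cosine_warmup_lr(step: int, total_steps: int, max_lr: float, warmup_ratio: float) -> float:
    warm = max(1, int(round(warmup_ratio * total_steps)))
    if step < warm:
        return max_lr * (step + 1) / warm
    if total_steps <= warm:
        return max_lr
    frac = (step - warm) / max(1, total_steps - warm)
    return 0.5 * max_lr * (1.0 + np.cos(np.pi * min(frac, 1.0)))
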