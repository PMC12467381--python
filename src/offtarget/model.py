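"""The cross-modal attention interaction model and its loss functions.

Architecture, in the order a pair flows through it:

1.  Two independent 3-layer ReLU feed-forward projection stacks map the raw
    modality embeddings (protein k-mer embedding, compound fingerprint) into
    a shared non-negative latent space of width ``p``:
    L3 = ReLU(W3' ReLU(W2' ReLU(W1' E + b1) + b2) + b3).
2.  A dual-headed cross-modal attention block: head 1 forms queries from the
    target stream and keys/values from the compound stream, head 2 reverses
    the roles.  Each head works at width p/2 and the scaling denominator is
    sqrt(p/2); the two head outputs are concatenated and mixed by a global
    p x p weight W_G.  Because each entity is a single latent vector (not a
    token sequence) a softmax over the key axis would be the constant 1, so
    the default "gate" semantics uses a scalar sigmoid gate
    sigmoid(<q, k>/sqrt(p/2)) * v, which keeps all parameters live.  A
    "tokens" mode that reshapes the per-head projections into a short token
    sequence and applies standard softmax attention is available behind a
    config flag.
3.  A residual sum of the two projections and the attention output is layer
    normalised (empirical mean/variance, stabiliser eps, learned gain alpha
    and shift beta) and read out by a single linear unit into one logit;
    sigmoid of the logit is the interaction probability.

Training losses: numerically stable mean binary cross-entropy on logits, and
a Euclidean triplet loss on the projection outputs (anchor = target
projection, positive/negatives = compound projections) averaged over each
triplet set.

Everything is plain float64 NumPy with hand-written backward passes; the
gradients are validated against finite differences in the test suite.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ModelConfig",
    "InteractionModel",
    "project_modality",
    "dual_cross_attention",
    "classify_pair",
    "bce_sigmoid_loss",
    "triplet_loss",
    "sigmoid",
]


def sigmoid(x):
    x = np.asarray(x, dtype=np.float64)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclasses.dataclass
class ModelConfig:
    """Shapes and mode flags of an :class:`InteractionModel`.

    ``p`` is the shared latent width (1024 in the published configuration;
    the test preset uses 64).  ``hidden`` gives the widths of the first two
    projection layers (the third is always ``p``); ``attention_mode`` selects
    the sigmoid-gate ("gate") or token-reshape softmax ("tokens") semantics,
    with ``n_tokens`` tokens per head in the latter.
    """

    d_protein: int = 100
    d_compound: int = 2048
    p: int = 64
    hidden: tuple[int, int] | None = None
    attention_mode: str = "gate"
    n_tokens: int = 8
    eps: float = 1e-5
    seed: int = 0

    def __post_init__(self):
        if self.hidden is None:
            self.hidden = (self.p, self.p)
        self.hidden = tuple(self.hidden)
        if self.p % 2:
            raise ValueError("latent width p must be even (two heads of width p/2)")
        if self.attention_mode not in ("gate", "tokens"):
            raise ValueError(f"unknown attention_mode {self.attention_mode!r}")
        if self.attention_mode == "tokens" and (self.p // 2) % self.n_tokens:
            raise ValueError("p/2 must be divisible by n_tokens in tokens mode")
        if self.eps <= 0:
            raise ValueError("eps must be > 0")


def _he_uniform(rng, fan_in, shape):
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


class InteractionModel:
    """All learned parameters of the cross-modal interaction model.

    Parameters live in ``self.params`` (name -> float64 array).  The forward
    pass is deterministic given the parameters, and a saved checkpoint
    reloads to bit-identical predictions.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        c = config
        rng = np.random.default_rng(c.seed)
        h1, h2 = c.hidden
        p, half = c.p, c.p // 2
        P: dict[str, np.ndarray] = {}
        for name, d_in in (("t", c.d_protein), ("c", c.d_compound)):
            dims = [(d_in, h1), (h1, h2), (h2, p)]
            for i, (a, b) in enumerate(dims, start=1):
                P[f"{name}.W{i}"] = _he_uniform(rng, a, (a, b))
                P[f"{name}.b{i}"] = np.zeros(b)
        for stream in ("1", "2"):
            for role in ("q", "k", "v"):
                P[f"att.W{role}{stream}"] = _he_uniform(rng, p, (p, half))
        P["att.WG"] = _he_uniform(rng, p, (p, p))
        P["head.alpha"] = np.ones(p)
        P["head.beta"] = np.zeros(p)
        P["head.W4"] = _he_uniform(rng, p, (p,))
        P["head.b4"] = np.zeros(())
        self.params = P

    # -- projection stacks ---------------------------------------------------

    def _stack_forward(self, E: np.ndarray, which: str):
        P = self.params
        cache = {"E": E}
        x = E
        for i in (1, 2, 3):
            z = x @ P[f"{which}.W{i}"] + P[f"{which}.b{i}"]
            x = np.maximum(z, 0.0)
            cache[f"z{i}"], cache[f"a{i}"] = z, x
        return x, cache

    def _stack_backward(self, dL3: np.ndarray, which: str, cache, grads):
        P = self.params
        d = dL3
        for i in (3, 2, 1):
            d = d * (cache[f"z{i}"] > 0)
            prev = cache[f"a{i-1}"] if i > 1 else cache["E"]
            grads[f"{which}.W{i}"] += prev.T @ d
            grads[f"{which}.b{i}"] += d.sum(axis=0)
            d = d @ P[f"{which}.W{i}"].T
        return d  # dE

    def project_target(self, E1: np.ndarray) -> np.ndarray:
        """Latent projection L3 of protein embeddings (rows)."""
        E1 = np.atleast_2d(np.asarray(E1, float))
        return self._stack_forward(E1, "t")[0]

    def project_compound(self, E2: np.ndarray) -> np.ndarray:
        """Latent projection L3 of compound fingerprints (rows)."""
        E2 = np.atleast_2d(np.asarray(E2, float))
        return self._stack_forward(E2, "c")[0]

    # -- attention -----------------------------------------------------------

    def _attention_forward(self, L31, L32):
        P, c = self.params, self.config
        half = c.p // 2
        scale = 1.0 / np.sqrt(half)
        q1, k1, v1 = (L31 @ P[f"att.W{r}1"] for r in ("q", "k", "v"))
        q2, k2, v2 = (L32 @ P[f"att.W{r}2"] for r in ("q", "k", "v"))
        cache = dict(L31=L31, L32=L32, q1=q1, k1=k1, v1=v1, q2=q2, k2=k2, v2=v2)
        if c.attention_mode == "gate":
            s1 = np.einsum("bh,bh->b", q1, k2) * scale
            s2 = np.einsum("bh,bh->b", q2, k1) * scale
            g1, g2 = sigmoid(s1), sigmoid(s2)
            H1 = g1[:, None] * v2
            H2 = g2[:, None] * v1
            cache.update(g1=g1, g2=g2)
        else:
            T = c.n_tokens
            dt = half // T
            tscale = 1.0 / np.sqrt(dt)

            def tok(x):
                return x.reshape(x.shape[0], T, dt)

            def head(q, k, v, tag):
                Q, K, V = tok(q), tok(k), tok(v)
                S = np.einsum("bij,bkj->bik", Q, K) * tscale
                S = S - S.max(axis=-1, keepdims=True)
                Pm = np.exp(S)
                Pm /= Pm.sum(axis=-1, keepdims=True)
                O = np.einsum("bik,bkj->bij", Pm, V)
                cache[f"P{tag}"] = Pm
                return O.reshape(q.shape[0], half)

            H1 = head(q1, k2, v2, "1")
            H2 = head(q2, k1, v1, "2")
        C = np.concatenate([H1, H2], axis=1)
        A = C @ P["att.WG"]
        cache["C"] = C
        return A, cache

    def _attention_backward(self, dA, cache, grads):
        P, c = self.params, self.config
        half = c.p // 2
        scale = 1.0 / np.sqrt(half)
        grads["att.WG"] += cache["C"].T @ dA
        dC = dA @ P["att.WG"].T
        dH1, dH2 = dC[:, :half], dC[:, half:]
        q1, k1, v1 = cache["q1"], cache["k1"], cache["v1"]
        q2, k2, v2 = cache["q2"], cache["k2"], cache["v2"]
        if c.attention_mode == "gate":
            g1, g2 = cache["g1"], cache["g2"]
            dg1 = np.einsum("bh,bh->b", dH1, v2)
            dv2 = g1[:, None] * dH1
            ds1 = dg1 * g1 * (1 - g1) * scale
            dq1 = ds1[:, None] * k2
            dk2 = ds1[:, None] * q1
            dg2 = np.einsum("bh,bh->b", dH2, v1)
            dv1 = g2[:, None] * dH2
            ds2 = dg2 * g2 * (1 - g2) * scale
            dq2 = ds2[:, None] * k1
            dk1 = ds2[:, None] * q2
        else:
            T = c.n_tokens
            dt = half // T
            tscale = 1.0 / np.sqrt(dt)

            def tok(x):
                return x.reshape(x.shape[0], T, dt)

            def head_back(dH, q, k, v, tag):
                Q, K, V = tok(q), tok(k), tok(v)
                Pm = cache[f"P{tag}"]
                dO = dH.reshape(dH.shape[0], T, dt)
                dP = np.einsum("bij,bkj->bik", dO, V)
                dV = np.einsum("bik,bij->bkj", Pm, dO)
                dS = Pm * (dP - np.einsum("bik,bik->bi", dP, Pm)[..., None])
                dS *= tscale
                dQ = np.einsum("bik,bkj->bij", dS, K)
                dK = np.einsum("bik,bij->bkj", dS, Q)
                n = dH.shape[0]
                return (dQ.reshape(n, half), dK.reshape(n, half), dV.reshape(n, half))

            dq1, dk2, dv2 = head_back(dH1, q1, k2, v2, "1")
            dq2, dk1, dv1 = head_back(dH2, q2, k1, v1, "2")
        L31, L32 = cache["L31"], cache["L32"]
        grads["att.Wq1"] += L31.T @ dq1
        grads["att.Wk1"] += L31.T @ dk1
        grads["att.Wv1"] += L31.T @ dv1
        grads["att.Wq2"] += L32.T @ dq2
        grads["att.Wk2"] += L32.T @ dk2
        grads["att.Wv2"] += L32.T @ dv2
        dL31 = dq1 @ P["att.Wq1"].T + dk1 @ P["att.Wk1"].T + dv1 @ P["att.Wv1"].T
        dL32 = dq2 @ P["att.Wq2"].T + dk2 @ P["att.Wk2"].T + dv2 @ P["att.Wv2"].T
        return dL31, dL32

    # -- classifier head -----------------------------------------------------

    def _head_forward(self, L31, L32, A):
        P, c = self.params, self.config
        Ahat = L31 + L32 + A
        mu = Ahat.mean(axis=1, keepdims=True)
        var = Ahat.var(axis=1, keepdims=True)
        inv = 1.0 / np.sqrt(var + c.eps)
        xhat = (Ahat - mu) * inv
        y = xhat * P["head.alpha"] + P["head.beta"]
        z = y @ P["head.W4"] + P["head.b4"]
        cache = dict(xhat=xhat, inv=inv, y=y)
        return z, cache

    def _head_backward(self, dz, cache, grads):
        P = self.params
        xhat, inv, y = cache["xhat"], cache["inv"], cache["y"]
        grads["head.W4"] += y.T @ dz
        grads["head.b4"] += dz.sum()
        dy = dz[:, None] * P["head.W4"]
        grads["head.alpha"] += (dy * xhat).sum(axis=0)
        grads["head.beta"] += dy.sum(axis=0)
        dxhat = dy * P["head.alpha"]
        m1 = dxhat.mean(axis=1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=1, keepdims=True)
        dAhat = inv * (dxhat - m1 - xhat * m2)
        return dAhat

    # -- public forward / backward -------------------------------------------

    def forward(self, E1: np.ndarray, E2: np.ndarray, return_cache: bool = False):
        """Logits for a batch of (target embedding, compound fingerprint) rows."""
        E1 = np.atleast_2d(np.asarray(E1, float))
        E2 = np.atleast_2d(np.asarray(E2, float))
        if E1.shape[1] != self.config.d_protein:
            raise ValueError(
                f"target embedding width {E1.shape[1]} != configured {self.config.d_protein}"
            )
        if E2.shape[1] != self.config.d_compound:
            raise ValueError(
                f"compound fingerprint width {E2.shape[1]} != configured {self.config.d_compound}"
            )
        L31, c1 = self._stack_forward(E1, "t")
        L32, c2 = self._stack_forward(E2, "c")
        A, ca = self._attention_forward(L31, L32)
        z, ch = self._head_forward(L31, L32, A)
        if return_cache:
            return z, dict(c1=c1, c2=c2, ca=ca, ch=ch)
        return z

    def predict_proba(self, E1, E2) -> np.ndarray:
        return sigmoid(self.forward(E1, E2))

    def zero_grads(self) -> dict[str, np.ndarray]:
        return {k: np.zeros_like(v) for k, v in self.params.items()}

    def bce_loss_and_grads(self, E1, E2, labels):
        """Mean sigmoid-BCE over a batch plus gradients for every parameter."""
        labels = np.asarray(labels, float)
        z, cache = self.forward(E1, E2, return_cache=True)
        loss = bce_sigmoid_loss(z, labels)
        grads = self.zero_grads()
        dz = (sigmoid(z) - labels) / len(labels)
        dAhat = self._head_backward(dz, cache["ch"], grads)
        dL31_att, dL32_att = self._attention_backward(dAhat, cache["ca"], grads)
        self._stack_backward(dAhat + dL31_att, "t", cache["c1"], grads)
        self._stack_backward(dAhat + dL32_att, "c", cache["c2"], grads)
        return loss, grads

    def triplet_loss_and_grads(self, E1_anchor, E2_pos, E2_neg, margin: float,
                               anchor: str = "t"):
        """Triplet loss on projection-space Euclidean distances, with grads.

        With ``anchor="t"`` (default) the anchor is a target embedding and the
        positive/negatives are compound fingerprints; ``anchor="c"`` mirrors
        the roles (compound anchor, target positive/negatives).  ``E2_neg``
        has shape (B, N, d): N decoys per anchor.  The loss is the mean over
        every (anchor, decoy) triplet of max(0, d(a, p) - d(a, n) + margin).
        """
        if anchor not in ("t", "c"):
            raise ValueError("anchor must be 't' or 'c'")
        other = "c" if anchor == "t" else "t"
        E1_anchor = np.atleast_2d(np.asarray(E1_anchor, float))
        E2_pos = np.atleast_2d(np.asarray(E2_pos, float))
        E2_neg = np.asarray(E2_neg, float)
        B, N, d2 = E2_neg.shape
        Pa, ca = self._stack_forward(E1_anchor, anchor)
        Pp, cp = self._stack_forward(E2_pos, other)
        Pn_flat, cn = self._stack_forward(E2_neg.reshape(B * N, d2), other)
        Pn = Pn_flat.reshape(B, N, -1)

        diff_ap = Pa - Pp
        dap = np.linalg.norm(diff_ap, axis=1)
        diff_an = Pa[:, None, :] - Pn
        dan = np.linalg.norm(diff_an, axis=2)
        terms = np.maximum(0.0, dap[:, None] - dan + margin)
        loss = terms.mean()

        active = (terms > 0).astype(float)
        w = 1.0 / (B * N)
        with np.errstate(invalid="ignore", divide="ignore"):
            u_ap = np.where(dap[:, None] > 0, diff_ap / np.maximum(dap[:, None], 1e-300), 0.0)
            u_an = np.where(
                dan[..., None] > 0, diff_an / np.maximum(dan[..., None], 1e-300), 0.0
            )
        n_active = active.sum(axis=1)
        dPa = w * (n_active[:, None] * u_ap - np.einsum("bn,bnp->bp", active, u_an))
        dPp = -w * n_active[:, None] * u_ap
        dPn = w * active[..., None] * u_an

        grads = self.zero_grads()
        self._stack_backward(dPa, anchor, ca, grads)
        self._stack_backward(dPp, other, cp, grads)
        self._stack_backward(dPn.reshape(B * N, -1), other, cn, grads)
        return loss, grads

    # -- persistence ----------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Checkpoint: every parameter tensor plus a JSON config block."""
        cfg = dataclasses.asdict(self.config)
        cfg["hidden"] = list(cfg["hidden"])
        arrays = dict(self.params)
        arrays["__config__"] = np.frombuffer(
            json.dumps(cfg).encode(), dtype=np.uint8
        ).copy()
        np.savez(str(path), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "InteractionModel":
        with np.load(str(path)) as data:
            cfg = json.loads(bytes(data["__config__"]).decode())
            cfg["hidden"] = tuple(cfg["hidden"])
            model = cls(ModelConfig(**cfg))
            for name in model.params:
                arr = data[name]
                if arr.shape != model.params[name].shape:
                    raise ValueError(
                        f"checkpoint shape mismatch for {name}: "
                        f"{arr.shape} != {model.params[name].shape}"
                    )
                model.params[name] = arr.astype(np.float64)
        return model


# ---------------------------------------------------------------------------
# functional single-pair operations
# ---------------------------------------------------------------------------


def project_modality(E: np.ndarray, model: InteractionModel, which: str) -> np.ndarray:
    """Run one vector through a projection stack ('t' target / 'c' compound)."""
    if which not in ("t", "c"):
        raise ValueError("which must be 't' or 'c'")
    E = np.asarray(E, float)
    out, _ = model._stack_forward(np.atleast_2d(E), which)
    return out[0] if E.ndim == 1 else out


def dual_cross_attention(
    L3_target: np.ndarray, L3_compound: np.ndarray, model: InteractionModel
) -> np.ndarray:
    """Dual-headed cross-modal attention output A for one latent pair."""
    A, _ = model._attention_forward(
        np.atleast_2d(np.asarray(L3_target, float)),
        np.atleast_2d(np.asarray(L3_compound, float)),
    )
    return A[0]


def classify_pair(
    L3_target: np.ndarray,
    L3_compound: np.ndarray,
    A: np.ndarray,
    model: InteractionModel,
) -> tuple[float, float]:
    """Residual + layer-norm + linear readout: (logit, probability)."""
    z, _ = model._head_forward(
        np.atleast_2d(np.asarray(L3_target, float)),
        np.atleast_2d(np.asarray(L3_compound, float)),
        np.atleast_2d(np.asarray(A, float)),
    )
    logit = float(z[0])
    return logit, float(sigmoid(np.array([logit]))[0])


# ---------------------------------------------------------------------------
# losses (functional forms)
# ---------------------------------------------------------------------------


def bce_sigmoid_loss(logits: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy of sigmoid(logits) against 0/1 labels.

    Computed in the log-sum-exp form max(z,0) - z*y + log(1 + exp(-|z|)),
    which is exact and stable for logits of any magnitude.
    """
    z = np.asarray(logits, float).ravel()
    y = np.asarray(labels, float).ravel()
    if z.size == 0:
        raise ValueError("empty batch")
    if z.shape != y.shape:
        raise ValueError(f"length mismatch: {z.shape} vs {y.shape}")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be 0 or 1")
    per = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    return float(per.mean())


def triplet_loss(
    anchor: np.ndarray,
    positive: np.ndarray,
    negatives: Sequence[np.ndarray],
    margin: float = 1.0,
) -> float:
    """Mean over negatives of max(0, d(a,p) - d(a,n) + margin), d Euclidean."""
    if margin <= 0:
        raise ValueError("margin must be > 0")
    negatives = [np.asarray(n, float) for n in negatives]
    if not negatives:
        raise ValueError("negatives must be non-empty")
    a = np.asarray(anchor, float)
    p = np.asarray(positive, float)
    dap = float(np.linalg.norm(a - p))
    terms = [max(0.0, dap - float(np.linalg.norm(a - n)) + margin) for n in negatives]
    return float(np.mean(terms))
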