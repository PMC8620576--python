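"""Shared network, loss heads, and analytic gradients.

All three ranking variants share a five-layer architecture: one-hot drug
and target inputs, embedding lookup into P (n x k) and Q (m x k), an
element-wise-product interaction layer h0 = p_d * q_t, a ReLU multilayer
perceptron, and a linear prediction head producing a raw score x_dt.
The variants differ only in how scores enter the loss:

* point-wise: squared error between sigmoid(x_dt) and the 0/1 label;
* pair-wise:  -ln sigmoid(x_dt - x_di) over (positive, negative) target
  pairs for the same drug, i.e. a Bayesian-personalized-ranking loss on
  the network score;
* list-wise:  cross entropy against the top-one (softmax) probability of
  a list holding one positive and K sampled negatives.

Similarity side information enters as Frobenius penalties
``lam_d * ||S_d - P P^T||_F^2 + lam_t * ||S_t - Q Q^T||_F^2`` tying the
embedding Gram matrices to precomputed chemical / sequence similarities.

Gradients are computed by explicit reverse-mode backpropagation in numpy;
they are validated against central finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Literal, Optional

import numpy as np

from .data import SimilarityMatrix

Variant = Literal["pointwise", "pairwise", "listwise"]

_VARIANTS = ("pointwise", "pairwise", "listwise")


@dataclass
class ModelSpec:
    """Architecture description: loss family, embedding size, MLP tower shape."""

    variant: Variant = "pointwise"
    k: int = 16
    hidden_widths: Optional[list[int]] = None  # default: one layer of width k
    # The ReLU activation is fixed; recorded for serialization completeness.
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.variant not in _VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.k < 1:
            raise ValueError("embedding size k must be >= 1")
        if self.hidden_widths is None:
            self.hidden_widths = [self.k]
        self.hidden_widths = [int(w) for w in self.hidden_widths]
        if len(self.hidden_widths) < 1 or any(w < 1 for w in self.hidden_widths):
            raise ValueError("hidden_widths must hold at least one positive width")

    @property
    def depth(self) -> int:
        return len(self.hidden_widths)


@dataclass
class ModelState:
    """All learnable parameters: embeddings plus the MLP tower."""

    P: np.ndarray  # (n, k) drug embeddings
    Q: np.ndarray  # (m, k) target embeddings
    hidden: list[tuple[np.ndarray, np.ndarray]]  # [(W_l in x out, b_l out)]
    out_weight: np.ndarray  # (last width,)
    out_bias: float
    spec: ModelSpec = field(default_factory=ModelSpec)

    def __post_init__(self) -> None:
        k = self.P.shape[1]
        if self.Q.shape[1] != k:
            raise ValueError("P and Q embedding sizes differ")
        prev = k
        for i, (W, b) in enumerate(self.hidden):
            if W.shape[0] != prev or W.shape[1] != b.shape[0]:
                raise ValueError(f"hidden layer {i} shape mismatch: {W.shape} after {prev}")
            prev = W.shape[1]
        if self.out_weight.shape != (prev,):
            raise ValueError("out_weight length does not match last hidden width")
        for name, arr in self.param_items():
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite parameter {name}")

    @property
    def n_drugs(self) -> int:
        return self.P.shape[0]

    @property
    def n_targets(self) -> int:
        return self.Q.shape[0]

    def param_items(self) -> Iterator[tuple[str, np.ndarray]]:
        yield "P", self.P
        yield "Q", self.Q
        for i, (W, b) in enumerate(self.hidden):
            yield f"W{i}", W
            yield f"b{i}", b
        yield "out_weight", self.out_weight
        yield "out_bias", np.asarray(self.out_bias, dtype=float)

    def set_param(self, name: str, value: np.ndarray) -> None:
        if name == "P":
            self.P = value
        elif name == "Q":
            self.Q = value
        elif name == "out_weight":
            self.out_weight = value
        elif name == "out_bias":
            self.out_bias = float(value)
        elif name.startswith("W"):
            i = int(name[1:])
            self.hidden[i] = (value, self.hidden[i][1])
        elif name.startswith("b"):
            i = int(name[1:])
            self.hidden[i] = (self.hidden[i][0], value)
        else:
            raise KeyError(name)

    def sq_norm(self) -> float:
        """Sum of squared entries over every parameter (the L2 term Omega)."""
        return float(sum(np.sum(np.square(a)) for _, a in self.param_items()))

    def zero_grads(self) -> dict[str, np.ndarray]:
        return {name: np.zeros_like(arr, dtype=float) for name, arr in self.param_items()}

    def copy(self) -> "ModelState":
        return ModelState(
            P=self.P.copy(),
            Q=self.Q.copy(),
            hidden=[(W.copy(), b.copy()) for W, b in self.hidden],
            out_weight=self.out_weight.copy(),
            out_bias=float(self.out_bias),
            spec=ModelSpec(
                variant=self.spec.variant,
                k=self.spec.k,
                hidden_widths=list(self.spec.hidden_widths),
            ),
        )


def init_state(spec: ModelSpec, n: int, m: int, seed: int) -> ModelState:
    """Draw a fresh parameter set: He-scaled normals for the ReLU tower,
    small normals (sd 0.01) for embeddings.  Deterministic under ``seed``."""
    if n < 1 or m < 1:
        raise ValueError("need at least one drug and one target")
    rng = np.random.default_rng(seed)
    P = rng.normal(0.0, 0.01, size=(n, spec.k))
    Q = rng.normal(0.0, 0.01, size=(m, spec.k))
    hidden = []
    prev = spec.k
    for width in spec.hidden_widths:
        W = rng.normal(0.0, np.sqrt(2.0 / prev), size=(prev, width))
        b = np.zeros(width)
        hidden.append((W, b))
        prev = width
    out_weight = rng.normal(0.0, np.sqrt(2.0 / prev), size=(prev,))
    return ModelState(P=P, Q=Q, hidden=hidden, out_weight=out_weight, out_bias=0.0, spec=spec)


# ---------------------------------------------------------------------------
# forward pass


def embed(state: ModelState, d: int, t: int) -> tuple[np.ndarray, np.ndarray]:
    """Embedding lookup: rows d of P and t of Q (one-hot input times matrix)."""
    if not (0 <= d < state.n_drugs and 0 <= t < state.n_targets):
        raise IndexError(f"index ({d}, {t}) out of range")
    return state.P[d], state.Q[t]


def interact(p_d: np.ndarray, q_t: np.ndarray) -> np.ndarray:
    """Element-wise product interaction layer h0."""
    p_d = np.asarray(p_d, dtype=float)
    q_t = np.asarray(q_t, dtype=float)
    if p_d.shape != q_t.shape:
        raise ValueError(f"dimension mismatch: {p_d.shape} vs {q_t.shape}")
    return p_d * q_t


def _forward_batch(state: ModelState, d_idx: np.ndarray, t_idx: np.ndarray):
    """Vectorized forward pass over index arrays; returns (scores, cache)."""
    p = state.P[d_idx]
    q = state.Q[t_idx]
    h = p * q
    pre_acts = []
    acts = [h]
    for W, b in state.hidden:
        z = h @ W + b
        pre_acts.append(z)
        h = np.maximum(z, 0.0)
        acts.append(h)
    x = h @ state.out_weight + state.out_bias
    cache = (p, q, pre_acts, acts)
    return x, cache


def _backward_batch(
    state: ModelState,
    d_idx: np.ndarray,
    t_idx: np.ndarray,
    cache,
    dx: np.ndarray,
    grads: dict[str, np.ndarray],
) -> None:
    """Accumulate parameter gradients given d loss / d score for each pair."""
    p, q, pre_acts, acts = cache
    h_last = acts[-1]
    grads["out_weight"] += h_last.T @ dx
    grads["out_bias"] += dx.sum()
    dh = np.outer(dx, state.out_weight)
    for l in range(len(state.hidden) - 1, -1, -1):
        W, _ = state.hidden[l]
        dz = dh * (pre_acts[l] > 0)
        grads[f"W{l}"] += acts[l].T @ dz
        grads[f"b{l}"] += dz.sum(axis=0)
        dh = dz @ W.T
    # dh is now d loss / d h0; h0 = p * q
    np.add.at(grads["P"], d_idx, dh * q)
    np.add.at(grads["Q"], t_idx, dh * p)


def forward_score(state: ModelState, d: int, t: int) -> float:
    """Raw (pre-sigmoid) network score x_dt for one drug-target pair."""
    embed(state, d, t)  # range check
    x, _ = _forward_batch(state, np.array([d]), np.array([t]))
    return float(x[0])


def forward_scores(state: ModelState, d_idx: np.ndarray, t_idx: np.ndarray) -> np.ndarray:
    """Raw scores for parallel index arrays."""
    d_idx = np.asarray(d_idx, dtype=np.intp)
    t_idx = np.asarray(t_idx, dtype=np.intp)
    x, _ = _forward_batch(state, d_idx, t_idx)
    return x


def score_matrix(state: ModelState) -> np.ndarray:
    """Raw scores for every (drug, target) cell, shape (n, m)."""
    n, m = state.n_drugs, state.n_targets
    d_idx = np.repeat(np.arange(n), m)
    t_idx = np.tile(np.arange(m), n)
    return forward_scores(state, d_idx, t_idx).reshape(n, m)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    """Overflow- and underflow-safe logistic function, strictly inside (0, 1)."""
    x = np.clip(x, -709.0, 709.0)  # exp underflow bound for float64
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softplus(x: np.ndarray) -> np.ndarray:
    """ln(1 + e^x) without overflow; note -ln sigmoid(z) = softplus(-z)."""
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


def predict_pointwise(state: ModelState, d: int, t: int) -> float:
    """Interaction probability sigmoid(x_dt) in (0, 1)."""
    return float(_sigmoid(np.array([forward_score(state, d, t)]))[0])


# ---------------------------------------------------------------------------
# loss heads (values only; gradients below)


def _as_idx(a) -> np.ndarray:
    return np.asarray(a, dtype=np.intp)


def pointwise_loss(state: ModelState, batch, lam: float) -> float:
    """Squared-error loss sum (y - sigmoid(x))^2 plus lam * Omega(all params)."""
    d_idx, t_idx, y = _unpack_pointwise(batch)
    x, _ = _forward_batch(state, d_idx, t_idx)
    yhat = _sigmoid(x)
    return float(np.sum((y - yhat) ** 2)) + lam * state.sq_norm()


def _unpack_pointwise(batch):
    d_idx, t_idx, y = batch
    d_idx, t_idx = _as_idx(d_idx), _as_idx(t_idx)
    y = np.asarray(y, dtype=float)
    if len(d_idx) == 0:
        raise ValueError("empty batch")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be 0 or 1")
    return d_idx, t_idx, y


def pairwise_prob(
    state: ModelState, d: int, t: int, i: int, squash: bool = False
) -> float:
    """Probability sigmoid(x_dt - x_di) that drug d prefers target t over i.

    With ``squash=True`` the difference is taken between sigmoid outputs
    (the literal double-sigmoid reading) rather than raw scores.
    """
    if t == i:
        raise ValueError("observed and unobserved target must differ")
    x = forward_scores(state, np.array([d, d]), np.array([t, i]))
    if squash:
        x = _sigmoid(x)
    return float(_sigmoid(np.array([x[0] - x[1]]))[0])


def pairwise_loss(
    state: ModelState, triples, lam_p: float, squash: bool = False
) -> float:
    """Ranking loss -sum ln sigmoid(x_dt - x_di) plus lam_p * Omega."""
    d_idx, t_idx, i_idx = _unpack_triples(triples)
    x_pos = forward_scores(state, d_idx, t_idx)
    x_neg = forward_scores(state, d_idx, i_idx)
    if squash:
        x_pos, x_neg = _sigmoid(x_pos), _sigmoid(x_neg)
    gap = x_pos - x_neg
    return float(np.sum(_softplus(-gap))) + lam_p * state.sq_norm()


def _unpack_triples(triples):
    if isinstance(triples, tuple) and len(triples) == 3:
        d_idx, t_idx, i_idx = triples
    else:
        arr = np.asarray(triples, dtype=np.intp)
        d_idx, t_idx, i_idx = arr[:, 0], arr[:, 1], arr[:, 2]
    d_idx, t_idx, i_idx = _as_idx(d_idx), _as_idx(t_idx), _as_idx(i_idx)
    if len(d_idx) == 0:
        raise ValueError("empty triple batch")
    if np.any(t_idx == i_idx):
        raise ValueError("triple with identical positive and negative target")
    return d_idx, t_idx, i_idx


def listwise_probs(state: ModelState, d: int, targets) -> np.ndarray:
    """Top-one (softmax) probabilities over a list of K+1 targets for drug d."""
    targets = _as_idx(targets)
    if len(targets) < 2:
        raise ValueError("list must hold at least two targets")
    if len(np.unique(targets)) != len(targets):
        raise ValueError("duplicate targets in list")
    x = forward_scores(state, np.full(len(targets), d, dtype=np.intp), targets)
    return _softmax(x)


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def listwise_loss(state: ModelState, lists, lam_l: float) -> float:
    """Cross-entropy against the top-one distribution of each sampled list.

    Each list holds one positive target (first entry) and K negatives; the
    loss is -[ln p(positive) + sum ln(1 - p(negative))] summed over lists,
    plus lam_l * Omega.
    """
    d_idx, T = _unpack_lists(lists)
    probs = _list_probs_batch(state, d_idx, T)
    pos = probs[:, 0]
    neg = probs[:, 1:]
    return float(-np.sum(np.log(pos)) - np.sum(np.log1p(-neg))) + lam_l * state.sq_norm()


def _unpack_lists(lists):
    if isinstance(lists, tuple) and len(lists) == 2:
        d_idx, T = lists
    else:
        d_idx = np.asarray([d for d, *_ in lists], dtype=np.intp)
        T = np.asarray([list(ts) for _, *ts in lists], dtype=np.intp)
    d_idx = _as_idx(d_idx)
    T = np.asarray(T, dtype=np.intp)
    if T.ndim != 2 or T.shape[1] < 2:
        raise ValueError("each list needs one positive and at least one negative")
    if len(d_idx) == 0:
        raise ValueError("empty list batch")
    for row in T:
        if len(np.unique(row)) != len(row):
            raise ValueError("duplicate targets within a list")
    return d_idx, T


def _list_scores_batch(state: ModelState, d_idx: np.ndarray, T: np.ndarray):
    B, L = T.shape
    flat_d = np.repeat(d_idx, L)
    flat_t = T.ravel()
    x, cache = _forward_batch(state, flat_d, flat_t)
    return x.reshape(B, L), (flat_d, flat_t, cache)


def _list_probs_batch(state: ModelState, d_idx: np.ndarray, T: np.ndarray) -> np.ndarray:
    x, _ = _list_scores_batch(state, d_idx, T)
    return _softmax(x, axis=1)


def similarity_penalty(
    state,
    S_d: Optional[SimilarityMatrix | np.ndarray],
    S_t: Optional[SimilarityMatrix | np.ndarray],
    lam_d: float,
    lam_t: float,
) -> float:
    """Frobenius penalties tying P P^T to S_d and Q Q^T to S_t.

    Accepts any object with P/Q attributes (shared with the MF baselines).
    Absent similarity matrices contribute zero.
    """
    total = 0.0
    if S_d is not None and lam_d != 0.0:
        Sd = S_d.values if isinstance(S_d, SimilarityMatrix) else np.asarray(S_d)
        if Sd.shape != (state.P.shape[0],) * 2:
            raise ValueError(f"drug similarity shape {Sd.shape} does not match P")
        R = Sd - state.P @ state.P.T
        total += lam_d * float(np.sum(R * R))
    if S_t is not None and lam_t != 0.0:
        St = S_t.values if isinstance(S_t, SimilarityMatrix) else np.asarray(S_t)
        if St.shape != (state.Q.shape[0],) * 2:
            raise ValueError(f"target similarity shape {St.shape} does not match Q")
        R = St - state.Q @ state.Q.T
        total += lam_t * float(np.sum(R * R))
    return total


def total_loss(
    state: ModelState,
    batch,
    lam: float,
    lam_d: float = 0.0,
    lam_t: float = 0.0,
    S_d=None,
    S_t=None,
    variant: Optional[Variant] = None,
    squash: bool = False,
) -> float:
    """Variant interaction loss plus the similarity penalty."""
    variant = variant or state.spec.variant
    if variant == "pointwise":
        loss = pointwise_loss(state, batch, lam)
    elif variant == "pairwise":
        loss = pairwise_loss(state, batch, lam, squash=squash)
    elif variant == "listwise":
        loss = listwise_loss(state, batch, lam)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return loss + similarity_penalty(state, S_d, S_t, lam_d, lam_t)


# ---------------------------------------------------------------------------
# gradients


def _l2_grads(state: ModelState, lam: float, grads: dict[str, np.ndarray]) -> None:
    if lam == 0.0:
        return
    for name, arr in state.param_items():
        grads[name] += 2.0 * lam * arr


def similarity_grads(
    state,
    S_d,
    S_t,
    lam_d: float,
    lam_t: float,
    grads: dict[str, np.ndarray],
    rows_d: Optional[np.ndarray] = None,
    rows_t: Optional[np.ndarray] = None,
) -> None:
    """Accumulate d similarity_penalty / d P and / d Q.

    For symmetric S the exact gradient is -4 lam (S - P P^T) P.  When
    ``rows_d``/``rows_t`` restrict the residual to a row block, the block
    term ||S[B,:] - P[B] P^T||^2 is differentiated instead (stochastic
    approximation used on large matrices).
    """
    if S_d is not None and lam_d != 0.0:
        Sd = S_d.values if isinstance(S_d, SimilarityMatrix) else np.asarray(S_d)
        if rows_d is None:
            R = Sd - state.P @ state.P.T
            grads["P"] += -4.0 * lam_d * (R @ state.P)
        else:
            rows_d = np.unique(rows_d)
            R = Sd[rows_d] - state.P[rows_d] @ state.P.T  # (|B|, n)
            scale = state.P.shape[0] / len(rows_d)
            np.add.at(grads["P"], rows_d, -2.0 * lam_d * scale * (R @ state.P))
            grads["P"] += -2.0 * lam_d * scale * (R.T @ state.P[rows_d])
    if S_t is not None and lam_t != 0.0:
        St = S_t.values if isinstance(S_t, SimilarityMatrix) else np.asarray(S_t)
        if rows_t is None:
            R = St - state.Q @ state.Q.T
            grads["Q"] += -4.0 * lam_t * (R @ state.Q)
        else:
            rows_t = np.unique(rows_t)
            R = St[rows_t] - state.Q[rows_t] @ state.Q.T
            scale = state.Q.shape[0] / len(rows_t)
            np.add.at(grads["Q"], rows_t, -2.0 * lam_t * scale * (R @ state.Q))
            grads["Q"] += -2.0 * lam_t * scale * (R.T @ state.Q[rows_t])


def interaction_loss_and_grads(
    state: ModelState,
    batch,
    lam: float,
    variant: Optional[Variant] = None,
    squash: bool = False,
) -> tuple[float, dict[str, np.ndarray]]:
    """Value and gradients of the variant loss (incl. L2, excl. similarity)."""
    variant = variant or state.spec.variant
    grads = state.zero_grads()
    if variant == "pointwise":
        d_idx, t_idx, y = _unpack_pointwise(batch)
        x, cache = _forward_batch(state, d_idx, t_idx)
        yhat = _sigmoid(x)
        loss = float(np.sum((y - yhat) ** 2))
        dx = 2.0 * (yhat - y) * yhat * (1.0 - yhat)
        _backward_batch(state, d_idx, t_idx, cache, dx, grads)
    elif variant == "pairwise":
        d_idx, t_idx, i_idx = _unpack_triples(batch)
        x_pos, cache_pos = _forward_batch(state, d_idx, t_idx)
        x_neg, cache_neg = _forward_batch(state, d_idx, i_idx)
        if squash:
            s_pos, s_neg = _sigmoid(x_pos), _sigmoid(x_neg)
            gap = s_pos - s_neg
            loss = float(np.sum(_softplus(-gap)))
            dgap = -_sigmoid(-gap)
            dx_pos = dgap * s_pos * (1.0 - s_pos)
            dx_neg = -dgap * s_neg * (1.0 - s_neg)
        else:
            gap = x_pos - x_neg
            loss = float(np.sum(_softplus(-gap)))
            dgap = -_sigmoid(-gap)
            dx_pos = dgap
            dx_neg = -dgap
        _backward_batch(state, d_idx, t_idx, cache_pos, dx_pos, grads)
        _backward_batch(state, d_idx, i_idx, cache_neg, dx_neg, grads)
    elif variant == "listwise":
        d_idx, T = _unpack_lists(batch)
        x, (flat_d, flat_t, cache) = _list_scores_batch(state, d_idx, T)
        p = _softmax(x, axis=1)  # (B, K+1)
        pos = p[:, 0]
        neg = p[:, 1:]
        loss = float(-np.sum(np.log(pos)) - np.sum(np.log1p(-neg)))
        # d(-ln p_0)/dx_j = p_j - [j == 0]
        dx = p.copy()
        dx[:, 0] -= 1.0
        # d(-ln(1 - p_i))/dx_j = p_i (delta_ij - p_j) / (1 - p_i), summed over
        # the negative positions i >= 1.
        w = neg / (1.0 - neg)  # (B, K)
        dx[:, 1:] += w
        dx -= w.sum(axis=1, keepdims=True) * p
        _backward_batch(state, flat_d, flat_t, cache, dx.ravel(), grads)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    loss += lam * state.sq_norm()
    _l2_grads(state, lam, grads)
    return loss, grads


def total_loss_and_grads(
    state: ModelState,
    batch,
    lam: float,
    lam_d: float = 0.0,
    lam_t: float = 0.0,
    S_d=None,
    S_t=None,
    variant: Optional[Variant] = None,
    squash: bool = False,
) -> tuple[float, dict[str, np.ndarray]]:
    """Value and gradients of the full objective (interaction + similarity)."""
    loss, grads = interaction_loss_and_grads(state, batch, lam, variant, squash)
    loss += similarity_penalty(state, S_d, S_t, lam_d, lam_t)
    similarity_grads(state, S_d, S_t, lam_d, lam_t, grads)
    return loss, grads


# ---------------------------------------------------------------------------
# serialization


def save_state(path, state: ModelState) -> None:
    """Serialize a model to a single .npz archive; round-trips bit-exactly."""
    arrays = {name: np.asarray(arr) for name, arr in state.param_items()}
    meta = json.dumps(
        {
            "variant": state.spec.variant,
            "k": state.spec.k,
            "hidden_widths": state.spec.hidden_widths,
            "depth": state.spec.depth,
        }
    )
    arrays["_spec_json"] = np.frombuffer(meta.encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_state(path) -> ModelState:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["_spec_json"]).decode())
        spec = ModelSpec(
            variant=meta["variant"], k=meta["k"], hidden_widths=meta["hidden_widths"]
        )
        hidden = [
            (npz[f"W{i}"], npz[f"b{i}"]) for i in range(len(spec.hidden_widths))
        ]
        return ModelState(
            P=npz["P"],
            Q=npz["Q"],
            hidden=hidden,
            out_weight=npz["out_weight"],
            out_bias=float(npz["out_bias"]),
            spec=spec,
        )
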